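"""Reference loading, CDS splicing and coordinate projection."""

import pytest

from protohap.genome_model import (
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    genomic_to_cds,
    load_gene_models,
    load_reference,
    select_canonical,
    spliced_cds,
)


def _tx(chrom="chr1", strand=1, exons=((1, 12),), cds=None, tx_id="T1", tags=()):
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id="G1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_intervals=cds or exons,
        tags=frozenset(tags),
    )


class TestLoadReference:
    def test_single_record_identity(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n")
        genome = load_reference(p)
        assert genome.fetch("chr1", 1, 4) == "ACGT"

    def test_wrapped_lines_and_case(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nacgta\ncgt\n>chr2\nTTTT\n")
        genome = load_reference(p)
        assert genome.sequence("chr1") == "ACGTACGT"
        assert genome.sequence("chr2") == "TTTT"

    def test_duplicate_records_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_reference(p)

    def test_fetch_bounds_checked(self):
        genome = GenomeSequence({"chr1": "ACGT"})
        with pytest.raises(ValueError):
            genome.fetch("chr1", 2, 5)


class TestTranscriptModel:
    def test_cds_must_lie_within_exons(self):
        with pytest.raises(ValueError, match="not contained"):
            _tx(exons=((1, 6),), cds=((5, 10),))

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _tx(exons=((1, 20),), cds=((1, 6), (5, 12)))

    def test_strand_validated(self):
        with pytest.raises(ValueError):
            _tx(strand=0)


class TestSplicedCds:
    def test_single_interval_plus(self):
        genome = GenomeSequence({"chr1": "ATGAAATAA"})
        t = _tx(exons=((1, 9),))
        assert spliced_cds(t, genome) == "ATGAAATAA"

    def test_minus_strand_two_intervals(self):
        # hand splice: "TTA" + "GGG" = "TTAGGG"; reverse complement = "CCCTAA"
        genome = GenomeSequence({"chr1": "TTACATGGGCAT"})
        t = _tx(strand=-1, exons=((1, 3), (7, 9)), cds=((1, 3), (7, 9)))
        assert spliced_cds(t, genome) == "CCCTAA"

    def test_plus_strand_two_intervals(self):
        # hand splice of positions 3-5 and 9-11
        genome = GenomeSequence({"chr1": "AAATGCCCGGGTTT"})
        t = _tx(exons=((3, 5), (9, 11)))
        assert spliced_cds(t, genome) == "ATG" + "GGG"

    def test_length_is_sum_of_intervals(self, toy, toy_genome):
        for t in toy.transcripts:
            assert len(spliced_cds(t, toy_genome)) == t.cds_length

    def test_minus_equals_revcomp_of_plus_declaration(self, toy, toy_genome):
        from protohap.genome_model import reverse_complement

        for t in toy.transcripts:
            if t.strand != -1:
                continue
            as_plus = TranscriptModel(
                transcript_id=t.transcript_id + "F",
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=1,
                exons=t.exons,
                cds_intervals=t.cds_intervals,
            )
            assert spliced_cds(t, toy_genome) == reverse_complement(
                spliced_cds(as_plus, toy_genome)
            )


class TestGenomicToCds:
    def test_first_cds_base_plus(self):
        t = _tx(exons=((10, 21),), cds=((10, 21),))
        coord = genomic_to_cds(t, (10, 10))
        assert coord.is_coding and coord.start == 1

    def test_intronic_marker(self):
        t = _tx(exons=((1, 6), (13, 18)), cds=((1, 6), (13, 18)))
        assert genomic_to_cds(t, (8, 9)).kind == "intronic"

    def test_splice_boundary_marker(self):
        t = _tx(exons=((1, 6), (13, 18)), cds=((1, 6), (13, 18)))
        assert genomic_to_cds(t, (5, 8)).kind == "splice_boundary"

    def test_outside_marker(self):
        t = _tx(exons=((10, 15),), cds=((10, 15),))
        assert genomic_to_cds(t, (1, 3)).kind == "outside"

    def test_minus_strand_last_base_maps_to_one(self):
        t = _tx(strand=-1, exons=((1, 3), (7, 9)), cds=((1, 3), (7, 9)))
        coord = genomic_to_cds(t, (9, 9))
        assert coord.is_coding and coord.start == 1

    @pytest.mark.parametrize("strand", [1, -1])
    def test_roundtrip_per_base(self, strand):
        t = _tx(strand=strand, exons=((3, 8), (12, 17)), cds=((3, 8), (12, 17)))
        c2g = t.cds_to_genomic_map()
        for cds_pos, g in enumerate(c2g, start=1):
            coord = genomic_to_cds(t, (g, g))
            assert (coord.start, coord.end) == (cds_pos, cds_pos)
        assert sorted(c2g) == [g for s, e in t.exons for g in range(s, e + 1)]


class TestLoadGeneModels:
    def test_toy_gff_roundtrip(self, toy, toy_paths):
        genes = load_gene_models(toy_paths["gff"])
        by_id = {t.transcript_id: t for g in genes for t in g.transcripts}
        for t in toy.transcripts:
            loaded = by_id[t.transcript_id]
            assert loaded.exons == t.exons
            assert loaded.cds_intervals == t.cds_intervals
            assert loaded.strand == t.strand
            assert loaded.display_name == t.display_name

    def test_gtf_dialect(self, tmp_path):
        gtf = "\n".join(
            [
                'chr1\ttoy\tgene\t1\t12\t.\t+\t.\tgene_id "G1"; gene_name "G1";',
                'chr1\ttoy\ttranscript\t1\t12\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
                'chr1\ttoy\texon\t1\t12\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
                'chr1\ttoy\tCDS\t1\t12\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
            ]
        )
        p = tmp_path / "m.gtf"
        p.write_text(gtf + "\n")
        genes = load_gene_models(p)
        assert len(genes) == 1
        assert genes[0].transcripts[0].cds_intervals == ((1, 12),)

    def test_cds_outside_exons_rejected(self, tmp_path):
        gff = "\n".join(
            [
                "##gff-version 3",
                "chr1\ttoy\tgene\t1\t30\t.\t+\t.\tID=G1",
                "chr1\ttoy\tmRNA\t1\t30\t.\t+\t.\tID=T1;Parent=G1",
                "chr1\ttoy\texon\t1\t12\t.\t+\t.\tParent=T1",
                "chr1\ttoy\tCDS\t20\t30\t.\t+\t.\tParent=T1",
            ]
        )
        p = tmp_path / "m.gff3"
        p.write_text(gff + "\n")
        with pytest.raises(ValueError, match="not contained"):
            load_gene_models(p)


class TestSelectCanonical:
    def _gene(self, *transcripts):
        return GeneModel(gene_id="G1", symbol="G1", transcripts=list(transcripts))

    def test_ccds_beats_longer_untagged(self):
        genome = GenomeSequence({"chr1": "ATGAAATAA" + "ATGAAACCCGGGTAA"})
        short_ccds = _tx(exons=((1, 9),), tx_id="TA", tags=("CCDS",))
        long_plain = _tx(exons=((10, 24),), cds=((10, 24),), tx_id="TB")
        assert select_canonical(self._gene(short_ccds, long_plain), genome) is short_ccds

    def test_longest_translation_wins_without_tags(self):
        genome = GenomeSequence({"chr1": "ATGAAATAA" + "ATGAAACCCGGGTAA"})
        short = _tx(exons=((1, 9),), tx_id="TA")
        long = _tx(exons=((10, 24),), cds=((10, 24),), tx_id="TB")
        assert select_canonical(self._gene(short, long), genome) is long

    def test_internal_stop_disqualifies(self):
        genome = GenomeSequence({"chr1": "ATGTAATAA" + "ATGAAATAA"})
        stopped = _tx(exons=((1, 9),), tx_id="TA")  # internal TAA
        clean = _tx(exons=((10, 18),), cds=((10, 18),), tx_id="TB")
        assert select_canonical(self._gene(stopped, clean), genome) is clean

    def test_tie_breaks_lexicographically(self):
        genome = GenomeSequence({"chr1": "ATGAAATAA" + "ATGCCCTAA"})
        a = _tx(exons=((10, 18),), cds=((10, 18),), tx_id="TB")
        b = _tx(exons=((1, 9),), tx_id="TA")
        chosen = select_canonical(self._gene(a, b), genome)
        assert chosen.transcript_id == "TA"
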