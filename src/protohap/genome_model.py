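"""Reference sequences and transcript models.

This module provides the coordinate frame for everything else in the
package: chromosome sequences loaded from FASTA, transcript exon/CDS
structures loaded from GFF3 or GTF, spliced CDS extraction (strand aware)
and projection between genomic and CDS coordinates.

All genomic coordinates are 1-based inclusive throughout the package,
matching the native conventions of VCF and GFF. CDS coordinates are
1-based indices into the spliced coding sequence read 5'->3' in transcript
orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Markers returned by :func:`genomic_to_cds` for non-coding intervals.
INTRONIC = "intronic"
SPLICE_BOUNDARY = "splice_boundary"
OUTSIDE = "outside"
CODING = "coding"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            self._seqs[name] = seq.upper()

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        seqs: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in seqs:
                raise ValueError(f"duplicate FASTA record {record.id!r}")
            seqs[record.id] = str(record.seq)
        if not seqs:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring for a 1-based inclusive interval."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end + 1:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds (1-{len(seq)})"
            )
        return seq[start - 1 : end]


def load_reference(fasta_path) -> GenomeSequence:
    """Load a (possibly line-wrapped, multi-record) FASTA reference."""
    return GenomeSequence.from_fasta(fasta_path)


def _check_sorted_non_overlapping(intervals: tuple[Interval, ...], what: str) -> None:
    prev_end = None
    for s, e in intervals:
        if s > e:
            raise ValueError(f"{what} interval ({s}, {e}) has start > end")
        if prev_end is not None and s <= prev_end:
            raise ValueError(f"{what} intervals overlap or are unsorted at ({s}, {e})")
        prev_end = e


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds_intervals`` are 1-based inclusive genomic
    intervals stored in genomic (ascending) order regardless of strand;
    ``strand`` is +1 or -1.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: int
    exons: tuple[Interval, ...]
    cds_intervals: tuple[Interval, ...]
    display_name: str = ""
    tags: frozenset = frozenset()
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand!r}")
        object.__setattr__(self, "exons", tuple(tuple(iv) for iv in self.exons))
        object.__setattr__(
            self, "cds_intervals", tuple(tuple(iv) for iv in self.cds_intervals)
        )
        object.__setattr__(self, "tags", frozenset(self.tags))
        _check_sorted_non_overlapping(self.exons, "exon")
        _check_sorted_non_overlapping(self.cds_intervals, "CDS")
        for cs, ce in self.cds_intervals:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"CDS interval ({cs}, {ce}) of {self.transcript_id} "
                    "not contained in any exon"
                )
        if self.cds_length < 3:
            raise ValueError(f"total CDS length of {self.transcript_id} is < 3")
        if self.cds_length % 3 != 0:
            logger.warning(
                "transcript %s has CDS length %d not divisible by 3 (incomplete_cds)",
                self.transcript_id,
                self.cds_length,
            )

    @property
    def label(self) -> str:
        return self.display_name or self.transcript_id

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def incomplete_cds(self) -> bool:
        return self.cds_length % 3 != 0

    @property
    def span(self) -> Interval:
        """Genomic interval bounded by the transcript's exons."""
        return (self.exons[0][0], self.exons[-1][1])

    def cds_to_genomic_map(self) -> tuple[int, ...]:
        """Genomic position of each CDS base, index 0 = CDS position 1.

        The map runs 5'->3' in transcript orientation, so for minus-strand
        transcripts it is genomically descending.
        """
        positions: list[int] = []
        for s, e in self.cds_intervals:
            positions.extend(range(s, e + 1))
        if self.strand == -1:
            positions.reverse()
        return tuple(positions)

    def genomic_to_cds_map(self) -> dict[int, int]:
        """Inverse of :meth:`cds_to_genomic_map` (genomic pos -> CDS pos)."""
        return {g: i + 1 for i, g in enumerate(self.cds_to_genomic_map())}


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id} spans chromosomes {chroms}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom


@dataclass(frozen=True)
class CdsCoordinate:
    """Result of projecting a genomic interval into CDS space.

    ``kind`` is "coding" (with 1-based inclusive ``start``/``end`` in the
    spliced CDS) or one of the non-coding markers "intronic",
    "splice_boundary", "outside".
    """

    kind: str
    start: int | None = None
    end: int | None = None

    @property
    def is_coding(self) -> bool:
        return self.kind == CODING


def spliced_cds(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced coding sequence, 5'->3' in transcript orientation."""
    if transcript.chrom not in genome:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    parts = [genome.fetch(transcript.chrom, s, e) for s, e in transcript.cds_intervals]
    seq = "".join(parts)
    if transcript.strand == -1:
        seq = reverse_complement(seq)
    return seq


def genomic_to_cds(
    transcript: TranscriptModel, genomic_interval: Interval
) -> CdsCoordinate:
    """Project a 1-based inclusive genomic interval into CDS coordinates.

    The interval maps to a coding interval only when every base is inside
    the transcript's CDS. Otherwise a marker is returned: an interval that
    touches coding bases but is not fully coding is a splice_boundary; a
    fully intronic interval (between exons) is intronic; anything else
    (outside the transcript, or exonic UTR) is outside.

    On minus-strand transcripts orientation reverses: the genomic end maps
    to the smaller CDS position.
    """
    gstart, gend = genomic_interval
    if gstart > gend:
        raise ValueError(f"bad interval ({gstart}, {gend})")
    g2c = transcript.genomic_to_cds_map()
    cds_positions = [g2c.get(g) for g in range(gstart, gend + 1)]
    if all(p is not None for p in cds_positions):
        return CdsCoordinate(CODING, min(cds_positions), max(cds_positions))
    if any(p is not None for p in cds_positions):
        return CdsCoordinate(SPLICE_BOUNDARY)

    def in_intron(g: int) -> bool:
        span_s, span_e = transcript.span
        if not (span_s <= g <= span_e):
            return False
        return not any(s <= g <= e for s, e in transcript.exons)

    if all(in_intron(g) for g in range(gstart, gend + 1)):
        return CdsCoordinate(INTRONIC)
    return CdsCoordinate(OUTSIDE)


# ---------------------------------------------------------------------------
# GFF3/GTF loading (via gffutils)
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _translation_length(cds: str) -> int:
    """Number of residues, excluding a terminal stop codon if present."""
    n_codons = len(cds) // 3
    if n_codons and cds[(n_codons - 1) * 3 : n_codons * 3] in _STOP_CODONS:
        return n_codons - 1
    return n_codons


def _has_internal_stop(cds: str) -> bool:
    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        if cds[i * 3 : i * 3 + 3] in _STOP_CODONS:
            return True
    return False


def _first_attr(feature, *keys, default="") -> str:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return default


def load_gene_models(gff_path) -> list[GeneModel]:
    """Load gene models from a GFF3 or GTF file.

    Both Ensembl dialects are accepted (gffutils sniffs the format; for
    GTF, gene and transcript parents are inferred from gene_id and
    transcript_id attributes). Transcript tags such as CCDS or merged
    annotation are read from ``tag`` attributes, with a ``ccds_id``
    attribute also implying the CCDS tag.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        # explicit gene/transcript features are required, so skip inference
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    transcripts: dict[str, dict] = {}
    tx_gene: dict[str, str] = {}
    gene_symbols: dict[str, str] = {}
    tx_order: list[str] = []

    for ft in ("mRNA", "transcript"):
        for f in db.features_of_type(ft):
            tx_id = _first_attr(f, "transcript_id", "ID", default=f.id)
            gene_id = _first_attr(f, "gene_id", default="")
            if not gene_id and "Parent" in f.attributes:
                gene_id = f.attributes["Parent"][0]
            tags = set(f.attributes.get("tag", []))
            if _first_attr(f, "ccds_id"):
                tags.add("CCDS")
            if f.source in ("ensembl_havana", "havana_ensembl"):
                tags.add("merged")
            transcripts[tx_id] = {
                "feature": f,
                "chrom": f.seqid,
                "strand": 1 if f.strand != "-" else -1,
                "display_name": _first_attr(f, "Name", "transcript_name"),
                "biotype": _first_attr(
                    f, "biotype", "transcript_biotype", default="protein_coding"
                ),
                "tags": tags,
                "exons": [],
                "cds": [],
            }
            tx_gene[tx_id] = gene_id
            tx_order.append(tx_id)

    for gf in db.features_of_type("gene"):
        gid = _first_attr(gf, "gene_id", "ID", default=gf.id)
        gene_symbols[gid] = _first_attr(gf, "Name", "gene_name", default=gid)

    def parent_tx_ids(f):
        ids = []
        if "transcript_id" in f.attributes:
            ids = [f.attributes["transcript_id"][0]]
        elif "Parent" in f.attributes:
            ids = list(f.attributes["Parent"])
        return ids

    for ftype, key in (("exon", "exons"), ("CDS", "cds")):
        for f in db.features_of_type(ftype):
            parents = parent_tx_ids(f)
            if not parents:
                raise ValueError(f"{ftype} feature at {f.seqid}:{f.start} has no parent")
            for tx_id in parents:
                if tx_id not in transcripts:
                    raise ValueError(
                        f"{ftype} feature references unknown transcript {tx_id!r}"
                    )
                transcripts[tx_id][key].append((f.start, f.end))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tx_id in tx_order:
        info = transcripts[tx_id]
        if not info["cds"]:
            continue  # non-coding transcript: out of scope
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=tx_gene[tx_id],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=tuple(sorted(info["exons"])),
            cds_intervals=tuple(sorted(info["cds"])),
            display_name=info["display_name"],
            tags=frozenset(info["tags"]),
            biotype=info["biotype"],
        )
        gid = tx_gene[tx_id]
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid, symbol=gene_symbols.get(gid, gid), transcripts=[model]
            )
            gene_order.append(gid)
        else:
            genes[gid].transcripts.append(model)
    return [genes[g] for g in gene_order]


def select_canonical(gene: GeneModel, genome: GenomeSequence) -> TranscriptModel:
    """Pick the canonical transcript of a gene.

    Three-tier hierarchy on translation length: (1) longest CCDS-tagged
    translation with no internal stop codons; (2) longest merged-annotation
    translation with no internal stops; (3) longest translation with no
    internal stops. Ties break to the lexicographically smaller
    transcript_id. If every transcript has internal stops the longest
    translation is returned with a warning.
    """
    coding = [t for t in gene.transcripts if t.biotype == "protein_coding"]
    if not coding:
        raise ValueError(f"gene {gene.gene_id} has no protein-coding transcript")

    scored = []
    for t in coding:
        cds = spliced_cds(t, genome)
        scored.append((t, _translation_length(cds), _has_internal_stop(cds)))

    def best(cands):
        return min(cands, key=lambda rec: (-rec[1], rec[0].transcript_id))[0]

    for tier_filter in (
        lambda rec: "CCDS" in rec[0].tags and not rec[2],
        lambda rec: "merged" in rec[0].tags and not rec[2],
        lambda rec: not rec[2],
    ):
        cands = [rec for rec in scored if tier_filter(rec)]
        if cands:
            return best(cands)
    warnings.warn(
        f"all transcripts of {gene.gene_id} have internal stop codons; "
        "falling back to longest translation"
    )
    return best(scored)
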