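"""Synthetic genomes, phased population VCFs, and an independent oracle.

Everything the pipeline consumes can be generated here with known ground
truth: toy reference chromosomes carrying multi-exon transcripts on both
strands, a comprehensive mutation series (SNV, MNV, in-frame and
frameshift indels, stop gain/loss, start/terminal-base edits, intronic
and splice-boundary variants, het/hom and haploid genotypes), and phased
population VCFs drawn from specified haplotype frequencies under
Hardy-Weinberg random pairing.

``oracle_haplotypes`` re-derives haplotype proteins through a deliberately
different computation path -- edit the whole chromosome sequence, shift
the annotation coordinates for indels, re-splice, translate -- and shares
no coordinate or editing logic with the main pipeline. Like comparable
whole-genome consensus tools it applies intronic and splice-site edits
naively, so agreement with the pipeline is expected only for variants
whose span is wholly exonic; the disagreement regime for splice-touching
variants is a known, documented difference, not an error.

All generators are pure functions of their configuration (seeded numpy
Generators); fixed seed means byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .genome_model import GenomeSequence, TranscriptModel, reverse_complement, spliced_cds

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NON_STOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


def _translate(seq: str) -> str:
    return str(Seq(seq[: len(seq) // 3 * 3]).translate())


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecipe:
    """Shape of one synthetic transcript.

    ``n_codons`` counts residues; a terminal stop codon is appended, so
    the CDS length is ``3 * (n_codons + 1)``.
    """

    name: str
    n_exons: int = 2
    strand: int = 1
    n_codons: int = 60
    intron_length: int = 30
    utr5: int = 6
    utr3: int = 6
    tags: tuple = ()

    def __post_init__(self):
        if self.n_exons < 1 or self.n_codons < 10 or self.intron_length < 10:
            raise ValueError("infeasible transcript recipe")


DEFAULT_RECIPES = (
    TranscriptRecipe(name="TOYA-001", n_exons=2, strand=1, n_codons=60),
    TranscriptRecipe(name="TOYB-001", n_exons=3, strand=-1, n_codons=48),
    TranscriptRecipe(name="TOYC-001", n_exons=1, strand=1, n_codons=40),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    The population defaults mirror the recovery check used throughout the
    package: three haplotypes at true frequencies 0.7 / 0.2 / 0.1 sampled
    for 500 diploid individuals under Hardy-Weinberg pairing, split over
    two panel populations.
    """

    seed: int = 0
    n_samples: int = 500
    chrom: str = "chrT"
    spacer: int = 80
    transcripts: tuple = DEFAULT_RECIPES
    haplotype_frequencies: tuple = (0.7, 0.2, 0.1)
    population_profiles: dict | None = None  # population -> frequency tuple
    superpopulation_of: dict | None = None
    fraction_haploid: float = 0.0

    def __post_init__(self):
        freqs = np.asarray(self.haplotype_frequencies, dtype=float)
        if np.any(freqs <= 0) or np.any(freqs >= 1) or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("haplotype frequencies must lie in (0,1) and sum to 1")
        if not 0 <= self.fraction_haploid <= 1:
            raise ValueError("fraction_haploid must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Toy reference construction
# ---------------------------------------------------------------------------


@dataclass
class ToyReference:
    fasta_text: str
    gff_text: str
    chrom: str
    sequence: str
    transcripts: list  # TranscriptModel
    cds_sequences: dict  # transcript_id -> CDS (transcript orientation)

    @property
    def genome(self) -> GenomeSequence:
        return GenomeSequence({self.chrom: self.sequence})


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


def _make_cds(rng, n_codons: int) -> str:
    codons = ["ATG"]
    body = [str(rng.choice(_NON_STOP_CODONS)) for _ in range(n_codons - 1)]
    # guarantee codons one substitution away from a stop (for stop-gain
    # scenarios) and an arginine for classic R>* notation
    if n_codons >= 20:
        body[len(body) // 2] = "TAC"  # TAC -> TAA with one edit
        body[len(body) // 2 + 1] = "CGA"  # R; CGA -> TGA with one edit
    codons += body + ["TAA"]
    return "".join(codons)


def _split_lengths(total: int, parts: int, rng) -> list:
    """Split ``total`` into ``parts`` pieces of at least 6."""
    if parts == 1:
        return [total]
    cuts = sorted(rng.choice(np.arange(6, total - 6), size=parts - 1, replace=False))
    # enforce minimum piece size by evening out degenerate draws
    lengths = []
    prev = 0
    for c in list(cuts) + [total]:
        lengths.append(int(c) - prev)
        prev = int(c)
    if min(lengths) < 4:
        base = total // parts
        lengths = [base] * (parts - 1) + [total - base * (parts - 1)]
    return lengths


def _build_transcript(rng, recipe: TranscriptRecipe, chrom: str, offset: int):
    """Assemble one transcript region; returns (region_seq, model, cds_seq)."""
    cds = _make_cds(rng, recipe.n_codons)
    exon_cds_lengths = _split_lengths(len(cds), recipe.n_exons, rng)

    # assemble in transcript orientation, tracking 1-based local intervals
    parts: list[str] = []
    pos = 0

    def emit(seq: str):
        nonlocal pos
        parts.append(seq)
        start = pos + 1
        pos += len(seq)
        return (start, pos)

    exon_local: list[tuple[int, int]] = []
    cds_local: list[tuple[int, int]] = []
    consumed = 0
    for i, seg_len in enumerate(exon_cds_lengths):
        lead = recipe.utr5 if i == 0 else 0
        tail = recipe.utr3 if i == recipe.n_exons - 1 else 0
        exon_start = pos + 1
        if lead:
            emit(_random_seq(rng, lead))
        cds_local.append(emit(cds[consumed : consumed + seg_len]))
        consumed += seg_len
        if tail:
            emit(_random_seq(rng, tail))
        exon_local.append((exon_start, pos))
        if i < recipe.n_exons - 1:
            emit("GT" + _random_seq(rng, recipe.intron_length - 4) + "AG")

    region = "".join(parts)
    L = len(region)
    if recipe.strand == -1:
        region = reverse_complement(region)
        exon_local = sorted((L - e + 1, L - s + 1) for s, e in exon_local)
        cds_local = sorted((L - e + 1, L - s + 1) for s, e in cds_local)

    shift = offset  # region starts at genomic position offset+1
    model = TranscriptModel(
        transcript_id=recipe.name.replace("-001", "") + "-T1",
        gene_id=recipe.name.replace("-001", "") + "-G",
        chrom=chrom,
        strand=recipe.strand,
        exons=tuple((s + shift, e + shift) for s, e in sorted(exon_local)),
        cds_intervals=tuple((s + shift, e + shift) for s, e in sorted(cds_local)),
        display_name=recipe.name,
        tags=frozenset(recipe.tags),
    )
    return region, model, cds


def _gff_text(chrom: str, chrom_len: int, transcripts) -> str:
    lines = ["##gff-version 3", f"##sequence-region {chrom} 1 {chrom_len}"]
    for t in transcripts:
        strand = "+" if t.strand == 1 else "-"
        span_s, span_e = t.span
        gene_attrs = f"ID={t.gene_id};Name={t.gene_id}"
        lines.append(
            f"{chrom}\ttoy\tgene\t{span_s}\t{span_e}\t.\t{strand}\t.\t{gene_attrs}"
        )
        tx_attrs = (
            f"ID={t.transcript_id};Parent={t.gene_id};Name={t.display_name};"
            f"biotype=protein_coding"
        )
        if t.tags:
            tx_attrs += ";tag=" + ",".join(sorted(t.tags))
        lines.append(
            f"{chrom}\ttoy\tmRNA\t{span_s}\t{span_e}\t.\t{strand}\t.\t{tx_attrs}"
        )
        for i, (s, e) in enumerate(t.exons, 1):
            lines.append(
                f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
            )
        cds_in_order = list(t.cds_intervals)
        if t.strand == -1:
            cds_in_order = cds_in_order[::-1]
        cum = 0
        phases = []
        for s, e in cds_in_order:
            phases.append((3 - cum % 3) % 3)
            cum += e - s + 1
        for (s, e), phase in sorted(zip(cds_in_order, phases)):
            lines.append(
                f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                f"ID={t.transcript_id}.cds;Parent={t.transcript_id}"
            )
    return "\n".join(lines) + "\n"


def _fasta_text(chrom: str, seq: str, width: int = 70) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{chrom}\n{body}\n"


def build_toy_reference(config: SimulationConfig) -> ToyReference:
    """Construct the toy chromosome and its transcript models."""
    rng = np.random.default_rng(config.seed)
    pieces = [_random_seq(rng, config.spacer)]
    offset = config.spacer
    models = []
    cds_seqs = {}
    for recipe in config.transcripts:
        region, model, cds = _build_transcript(rng, recipe, config.chrom, offset)
        pieces.append(region)
        offset += len(region)
        pieces.append(_random_seq(rng, config.spacer))
        offset += config.spacer
        models.append(model)
        cds_seqs[model.transcript_id] = cds
    seq = "".join(pieces)
    return ToyReference(
        fasta_text=_fasta_text(config.chrom, seq),
        gff_text=_gff_text(config.chrom, len(seq), models),
        chrom=config.chrom,
        sequence=seq,
        transcripts=models,
        cds_sequences=cds_seqs,
    )


def generate_toy_reference(config: SimulationConfig) -> tuple[str, str]:
    """(FASTA text, GFF3 text) for the configured toy genome."""
    ref = build_toy_reference(config)
    return ref.fasta_text, ref.gff_text


# ---------------------------------------------------------------------------
# VCF text assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimVariant:
    pos: int  # 1-based genomic, VCF convention
    ref: str
    alt: str
    variant_id: str = "."


def _vcf_text(chrom: str, chrom_len: int, samples, rows) -> str:
    """rows: list of (SimVariant, {sample: gt_string}); missing -> hom ref."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    ploidy = {s: 2 for s in samples}
    for _, gts in rows:
        for s, gt in gts.items():
            if "|" not in gt and "/" not in gt:
                ploidy[s] = 1
    for var, gts in sorted(rows, key=lambda r: r[0].pos):
        default = {1: "0", 2: "0|0"}
        fields = [
            chrom,
            str(var.pos),
            var.variant_id,
            var.ref,
            var.alt,
            ".",
            "PASS",
            ".",
            "GT",
        ] + [gts.get(s, default[ploidy[s]]) for s in samples]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Mutation series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """One validation scenario: a sample carrying a single variant."""

    name: str
    variant: SimVariant
    genotype: str  # e.g. "1|0", "1|1", "1"
    kind: str
    cds_edit: tuple | None  # (cds_start, cds_end, alt_seq) on CDS strand, or None if skipped

    @property
    def carrying_phases(self) -> tuple:
        alleles = self.genotype.replace("/", "|").split("|")
        return tuple(i for i, a in enumerate(alleles) if a != "0")


@dataclass
class MutationSeries:
    vcf_text: str
    scenarios: list
    transcript_id: str


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base]


class _VariantFactory:
    """Builds VCF-convention variants from CDS-frame specifications."""

    def __init__(self, transcript: TranscriptModel, genome: GenomeSequence):
        self.transcript = transcript
        self.genome = genome
        self.cds = spliced_cds(transcript, genome)
        self.c2g = transcript.cds_to_genomic_map()
        self.chrom = transcript.chrom
        self.minus = transcript.strand == -1

    def genomic_base(self, g: int) -> str:
        return self.genome.fetch(self.chrom, g, g)

    def snv(self, cds_pos: int, alt_cds_base: str) -> SimVariant:
        g = self.c2g[cds_pos - 1]
        alt = _complement(alt_cds_base) if self.minus else alt_cds_base
        return SimVariant(pos=g, ref=self.genomic_base(g), alt=alt)

    def exonic_span(self, cds_start: int, length: int):
        """Genomic (start, end) if the CDS run maps to contiguous bases."""
        if cds_start < 1 or cds_start + length - 1 > len(self.cds):
            return None
        gs = [self.c2g[cds_start - 1 + k] for k in range(length)]
        lo, hi = min(gs), max(gs)
        if hi - lo + 1 != length:
            return None
        return lo, hi

    def find_contiguous(self, cds_start: int, length: int) -> int:
        c = cds_start
        while c + length - 1 <= len(self.cds):
            if self.exonic_span(c, length) is not None:
                return c
            c += 3
        raise ValueError("no contiguous exonic run found")

    def substitution(self, cds_start: int, alt_seq_cds: str) -> SimVariant:
        lo, hi = self.exonic_span(cds_start, len(alt_seq_cds))
        ref = self.genome.fetch(self.chrom, lo, hi)
        alt = reverse_complement(alt_seq_cds) if self.minus else alt_seq_cds
        return SimVariant(pos=lo, ref=ref, alt=alt)

    def deletion(self, cds_start: int, length: int) -> SimVariant:
        lo, hi = self.exonic_span(cds_start, length)
        anchor = lo - 1
        return SimVariant(
            pos=anchor,
            ref=self.genome.fetch(self.chrom, anchor, hi),
            alt=self.genomic_base(anchor),
        )

    def adjacent(self, cds_pos: int) -> bool:
        """True if CDS positions cds_pos and cds_pos+1 touch genomically."""
        if not 1 <= cds_pos < len(self.cds):
            return False
        return abs(self.c2g[cds_pos - 1] - self.c2g[cds_pos]) == 1

    def insertion_after(self, cds_pos: int, insert_cds: str) -> SimVariant:
        """Insertion between CDS positions cds_pos and cds_pos+1."""
        g_a, g_b = self.c2g[cds_pos - 1], self.c2g[cds_pos]
        if abs(g_a - g_b) != 1:
            raise ValueError("insertion point spans an intron")
        g = min(g_a, g_b)
        ins = reverse_complement(insert_cds) if self.minus else insert_cds
        return SimVariant(pos=g, ref=self.genomic_base(g), alt=self.genomic_base(g) + ins)


def generate_mutation_series(
    transcript: TranscriptModel, genome: GenomeSequence
) -> MutationSeries:
    """A comprehensive series of single-variant validation scenarios.

    One synthetic sample per scenario, all in one phased VCF: exonic SNV,
    multi-nucleotide substitution, in-frame insertion and deletion,
    frameshift insertion and deletion, stop gain, stop loss, variants at
    the first and last CDS base, an intronic SNV, a splice-boundary
    deletion, heterozygous / homozygous-alternate genotypes and one
    haploid sample.
    """
    vf = _VariantFactory(transcript, genome)
    cds = vf.cds
    chrom = transcript.chrom
    genomic_base = vf.genomic_base
    snv = vf.snv
    exonic_span = vf.exonic_span
    find_contiguous = vf.find_contiguous
    substitution = vf.substitution
    deletion = vf.deletion
    insertion_after = vf.insertion_after

    def alt_base(base: str, want=None) -> str:
        for b in _BASES:
            if b != base and (want is None or want(b)):
                return b
        raise AssertionError

    scenarios: list[Scenario] = []

    def add(name, variant, genotype, kind, cds_edit):
        scenarios.append(Scenario(name, variant, genotype, kind, cds_edit))

    cursor = 10  # CDS position allocator (leave the start codon region free)

    def take_codon(n: int = 1) -> int:
        nonlocal cursor
        c = find_contiguous(cursor, 3 * n)
        cursor = c + 3 * n + 3
        return c

    # exonic SNV (missense where possible)
    c = take_codon()
    codon = cds[c - 1 : c + 2]
    b = alt_base(codon[0], want=lambda x: _aa(x + codon[1:]) not in (_aa(codon), "*"))
    add("exonic_snv", snv(c, b), "1|0", "snv", (c, c, b))

    # multi-nucleotide substitution within one codon
    c = take_codon()
    codon = cds[c - 1 : c + 2]
    new = next(
        x for x in _NON_STOP_CODONS if x[0] != codon[0] and x[1] != codon[1] and x[2] == codon[2]
    )
    add("mnv", substitution(c, new[:2]), "0|1", "mnv", (c, c + 1, new[:2]))

    # in-frame insertion (one codon) at a codon boundary
    c = take_codon()
    while not vf.adjacent(c + 2):  # junction at this codon's end: move on
        c = take_codon()
    boundary = c + 2  # insert after the codon's final base
    var = insertion_after(boundary, "GCT")
    add("inframe_ins", var, "1|0", "inframe_ins", (boundary + 1, boundary, "GCT"))

    # in-frame deletion of one codon
    c = take_codon(2)
    add("inframe_del", deletion(c, 3), "1|0", "inframe_del", (c, c + 2, ""))

    # frameshift insertion (single base)
    c = take_codon()
    while not vf.adjacent(c):
        c = take_codon()
    var = insertion_after(c, "A")
    add("frameshift_ins", var, "1|0", "frameshift_ins", (c + 1, c, "A"))

    # frameshift deletion (two bases)
    c = take_codon(2)
    add("frameshift_del", deletion(c, 2), "1|0", "frameshift_del", (c, c + 1, ""))

    # stop gain: search for a codon one substitution from a stop
    def find_stop_gain(start_cds: int):
        c = find_contiguous(start_cds, 3)
        while c + 2 <= len(cds) - 3:
            codon = cds[c - 1 : c + 2]
            for off in range(3):
                for b in _BASES:
                    if b == codon[off]:
                        continue
                    mutated = codon[:off] + b + codon[off + 1 :]
                    if mutated in _STOPS and exonic_span(c + off, 1):
                        return c + off, b
            c = find_contiguous(c + 3, 3)
        raise ValueError("no stop-gain site found")

    pos_sg, b = find_stop_gain(cursor)
    cursor = (pos_sg // 3) * 3 + 7
    add("stop_gain", snv(pos_sg, b), "1|0", "stop_gain", (pos_sg, pos_sg, b))

    # stop loss: mutate the terminal stop codon's first base (TAA -> CAA)
    stop_first = len(cds) - 2
    add("stop_loss", snv(stop_first, "C"), "1|0", "stop_loss", (stop_first, stop_first, "C"))

    # first CDS base (start-codon loss)
    add("first_cds_base", snv(1, "G"), "1|0", "start_loss", (1, 1, "G"))

    # last CDS base (TAA -> TAG: stop retained)
    last = len(cds)
    add("last_cds_base", snv(last, "G"), "1|0", "synonymous_stop", (last, last, "G"))

    # intronic SNV and splice-boundary deletion (multi-exon transcripts)
    if len(transcript.cds_intervals) > 1:
        first_iv, second_iv = transcript.cds_intervals[0], transcript.cds_intervals[1]
        intron_mid = (first_iv[1] + second_iv[0]) // 2
        ref_b = genomic_base(intron_mid)
        add(
            "intronic_snv",
            SimVariant(pos=intron_mid, ref=ref_b, alt=alt_base(ref_b)),
            "1|0",
            "intronic",
            None,
        )
        boundary_end = first_iv[1]  # last CDS base of the first genomic interval
        anchor = boundary_end - 2
        add(
            "splice_del",
            SimVariant(
                pos=anchor,
                ref=genome.fetch(chrom, anchor, boundary_end + 2),
                alt=genomic_base(anchor),
            ),
            "1|0",
            "splice_boundary",
            None,
        )

    # homozygous alternate genotype (middle-base change: always missense)
    c = take_codon()
    codon = cds[c - 1 : c + 2]
    b = alt_base(codon[1], want=lambda x: _aa(codon[0] + x + codon[2]) != "*")
    add("hom_alt", snv(c + 1, b), "1|1", "hom_alt_snv", (c + 1, c + 1, b))

    # haploid sample
    c = take_codon()
    codon = cds[c - 1 : c + 2]
    b = alt_base(codon[1], want=lambda x: _aa(codon[0] + x + codon[2]) != "*")
    add("haploid_snv", snv(c + 1, b), "1", "haploid_snv", (c + 1, c + 1, b))

    samples = [s.name for s in scenarios]
    rows = [(s.variant, {s.name: s.genotype}) for s in scenarios]
    vcf = _vcf_text(chrom, genome.length(chrom), samples, rows)
    return MutationSeries(vcf_text=vcf, scenarios=scenarios, transcript_id=transcript.transcript_id)


def generate_random_exonic_vcf(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    seed: int = 0,
    n_samples: int = 60,
    max_variants: int = 4,
) -> str:
    """Phased VCF of randomized, wholly-exonic variant sets.

    Each sample carries up to ``max_variants`` randomly typed variants
    (SNV, MNV, in-frame/frameshift insertion or deletion) at
    well-separated codons, randomly phased (1|0, 0|1 or 1|1). Every
    variant span is wholly exonic and contiguous in CDS space, i.e. the
    regime where the pipeline and the independent whole-genome oracle
    must agree exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    vf = _VariantFactory(transcript, genome)
    n_codons = len(vf.cds) // 3
    rows = []
    samples = [f"R{i:04d}" for i in range(n_samples)]
    for sample in samples:
        n_var = int(rng.integers(0, max_variants + 1))
        # separated codons, away from start codon and the terminal stop
        codon_pool = np.arange(2, n_codons - 2)
        rng.shuffle(codon_pool)
        chosen: list = []
        for codon in codon_pool:
            if len(chosen) >= n_var:
                break
            if all(abs(int(codon) - c) >= 4 for c in chosen):
                chosen.append(int(codon))
        for codon in sorted(chosen):
            c = 3 * codon + 1  # first base of the codon (cds pos)
            kind = rng.choice(
                ["snv", "mnv", "ins3", "del3", "ins1", "del2"],
                p=[0.4, 0.12, 0.12, 0.12, 0.12, 0.12],
            )
            try:
                if kind == "snv":
                    base = vf.cds[c - 1]
                    alt = str(rng.choice([b for b in _BASES if b != base]))
                    var = vf.snv(c, alt)
                elif kind == "mnv":
                    ref2 = vf.cds[c - 1 : c + 1]
                    alt2 = "".join(
                        str(rng.choice([b for b in _BASES if b != r])) for r in ref2
                    )
                    var = vf.substitution(c, alt2)
                elif kind == "ins3":
                    var = vf.insertion_after(c + 2, "".join(rng.choice(list(_BASES), 3)))
                elif kind == "del3":
                    var = vf.deletion(c, 3)
                elif kind == "ins1":
                    var = vf.insertion_after(c, str(rng.choice(list(_BASES))))
                else:
                    var = vf.deletion(c, 2)
            except (TypeError, ValueError):
                continue  # span not contiguous within one exon: skip site
            gt = str(rng.choice(["1|0", "0|1", "1|1"], p=[0.4, 0.4, 0.2]))
            rows.append((var, {sample: gt}))
    return _vcf_text(transcript.chrom, genome.length(transcript.chrom), samples, rows)


# ---------------------------------------------------------------------------
# Population VCF with ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, derived without it."""

    haplotype_variants: tuple  # per haplotype, tuple of SimVariant
    haplotype_cds: tuple  # per haplotype, expected CDS string
    haplotype_proteins: tuple  # per haplotype, expected protein string
    sample_phases: dict  # sample -> tuple of haplotype indices (len = ploidy)
    true_frequencies: dict  # population -> tuple of frequencies
    panel_rows: list  # (sample, pop, superpop, sex)
    transcript_id: str

    def expected_foo(self, population: str = "ALL") -> tuple:
        """Empirical haplotype frequencies actually drawn (the estimand)."""
        counts = np.zeros(len(self.haplotype_proteins))
        total = 0
        row_of = {r[0]: r for r in self.panel_rows}
        for sample, haps in self.sample_phases.items():
            row = row_of[sample]
            if population != "ALL" and population not in (row[1], row[2]):
                continue
            for h in haps:
                counts[h] += 1
                total += 1
        return tuple(counts / total) if total else tuple(counts)


@dataclass
class PopulationDataset:
    vcf_text: str
    panel_text: str
    truth: GroundTruth
    reference: ToyReference


def generate_population_dataset(config: SimulationConfig) -> PopulationDataset:
    """Phased population VCF + panel + ground truth over the toy genome.

    Haplotype k (k >= 1) carries missense SNVs v1..vk on the first toy
    transcript (nested sets, so variant-level frequencies accumulate
    across haplotypes); haplotype 0 is the reference. Per-sample phases
    are drawn i.i.d. from the configured frequency profile of the
    sample's population and paired at random (Hardy-Weinberg).
    """
    ref = build_toy_reference(config)
    transcript = ref.transcripts[0]
    genome = ref.genome
    cds = ref.cds_sequences[transcript.transcript_id]
    c2g = transcript.cds_to_genomic_map()
    minus = transcript.strand == -1
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    k = len(config.haplotype_frequencies)
    n_variants = k - 1
    # one missense SNV per non-reference haplotype, on well-separated codons
    variants: list[SimVariant] = []
    cds_edits: list[tuple] = []
    codon_idx = 4
    for i in range(n_variants):
        c = codon_idx * 3 + 1  # first base of the codon
        codon = cds[c - 1 : c + 2]
        alt_cds = next(
            b
            for b in _BASES
            if b != codon[1] and _aa(codon[0] + b + codon[2]) not in (_aa(codon), "*")
        )
        g = c2g[c]  # middle base of the codon
        alt_g = _complement(alt_cds) if minus else alt_cds
        variants.append(
            SimVariant(pos=g, ref=genome.fetch(transcript.chrom, g, g), alt=alt_g,
                       variant_id=f"rs{900000 + i}")
        )
        cds_edits.append((c + 1, alt_cds))
        codon_idx += 5

    hap_variant_sets = [tuple()] + [tuple(variants[: i + 1]) for i in range(n_variants)]
    hap_cds = []
    for i in range(k):
        seq = cds
        for cpos, alt_b in cds_edits[:i]:
            seq = seq[: cpos - 1] + alt_b + seq[cpos:]
        hap_cds.append(seq)
    hap_prot = []
    for seq in hap_cds:
        prot = _translate(seq)
        hap_prot.append(prot[: prot.index("*")] if "*" in prot else prot)

    profiles = config.population_profiles or {
        "P1": tuple(config.haplotype_frequencies),
        "P2": tuple(config.haplotype_frequencies),
    }
    sup_of = config.superpopulation_of or {
        pop: f"S{i + 1}" for i, pop in enumerate(sorted(profiles))
    }
    pops = sorted(profiles)

    samples = [f"S{i:05d}" for i in range(config.n_samples)]
    sample_pop = {s: pops[i % len(pops)] for i, s in enumerate(samples)}
    n_haploid = int(round(config.fraction_haploid * config.n_samples))
    haploid = set(rng.choice(samples, size=n_haploid, replace=False)) if n_haploid else set()

    sample_phases: dict = {}
    panel_rows = []
    for s in samples:
        pop = sample_pop[s]
        probs = np.asarray(profiles[pop])
        ploidy = 1 if s in haploid else 2
        draws = tuple(int(x) for x in rng.choice(k, size=ploidy, p=probs))
        sample_phases[s] = draws
        sex = "male" if s in haploid else ("female" if rng.random() < 0.5 else "male")
        panel_rows.append((s, pop, sup_of[pop], sex))

    rows = []
    for vi, var in enumerate(variants):
        gts = {}
        for s in samples:
            alleles = ["1" if var in hap_variant_sets[h] else "0" for h in sample_phases[s]]
            gts[s] = "|".join(alleles)
        rows.append((var, gts))
    vcf = _vcf_text(transcript.chrom, len(ref.sequence), samples, rows)

    panel_lines = ["sample\tpop\tsuper_pop\tgender"] + [
        "\t".join(r) for r in panel_rows
    ]
    truth = GroundTruth(
        haplotype_variants=tuple(hap_variant_sets),
        haplotype_cds=tuple(hap_cds),
        haplotype_proteins=tuple(hap_prot),
        sample_phases=sample_phases,
        true_frequencies={**{p: tuple(profiles[p]) for p in pops}},
        panel_rows=panel_rows,
        transcript_id=transcript.transcript_id,
    )
    return PopulationDataset(
        vcf_text=vcf,
        panel_text="\n".join(panel_lines) + "\n",
        truth=truth,
        reference=ref,
    )


def generate_population_vcf(config: SimulationConfig) -> tuple[str, str, GroundTruth]:
    """(VCF text, panel text, ground truth); see generate_population_dataset."""
    ds = generate_population_dataset(config)
    return ds.vcf_text, ds.panel_text, ds.truth


# ---------------------------------------------------------------------------
# Engineered single-transcript cases (exact residue changes at exact positions)
# ---------------------------------------------------------------------------

_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _codon_pair(ref_aa: str, alt_aa: str) -> tuple[str, str]:
    """Codons one substitution apart translating to (ref_aa, alt_aa)."""
    for c1 in _ALL_CODONS:
        if c1 in _STOPS or _aa(c1) != ref_aa:
            continue
        for pos in range(3):
            for b in _BASES:
                if b == c1[pos]:
                    continue
                c2 = c1[:pos] + b + c1[pos + 1 :]
                if alt_aa == "*":
                    if c2 in _STOPS:
                        return c1, c2
                elif c2 not in _STOPS and _aa(c2) == alt_aa:
                    return c1, c2
    raise ValueError(f"no single-base codon change for {ref_aa}>{alt_aa}")


@dataclass
class EngineeredCase:
    fasta_text: str
    gff_text: str
    vcf_text: str
    transcript: TranscriptModel
    sample: str
    reference_protein: str


def engineer_notation_case(
    display_name: str,
    protein_length: int,
    substitutions,
    chrom: str = "chrE",
    sample: str = "CASE",
) -> EngineeredCase:
    """A transcript carrying exact residue changes at exact positions.

    ``substitutions`` is a list of (residue_pos, ref_aa, alt_aa) with
    alt_aa "*" for a stop gain. The reference protein is M followed by a
    repeat-free cycling residue scaffold (a homopolymer scaffold would
    make indel placement ambiguous) with the required ref residues at
    their positions; one phased diploid sample carries every change as an
    SNV on phase 0. Used to regression-test the difference notation
    against published haplotype names (e.g. 299D>G,399T>I or
    211R>Q,577R>*,578del(325)).
    """
    scaffold = "ACDEFGHIKLNPQSVWY"  # cycle length coprime with repeats
    codon_of = {}
    for c in _ALL_CODONS:
        if c not in _STOPS:
            codon_of.setdefault(_aa(c), c)
    residues = ["M"] + [scaffold[i % len(scaffold)] for i in range(protein_length - 1)]
    codons = ["ATG"] + [codon_of[aa] for aa in residues[1:]]
    snvs = []
    for pos, ref_aa, alt_aa in substitutions:
        if pos < 2 or pos > protein_length:
            raise ValueError(f"substitution position {pos} outside protein")
        c_ref, c_alt = _codon_pair(ref_aa, alt_aa)
        residues[pos - 1] = ref_aa
        codons[pos - 1] = c_ref
        off = next(k for k in range(3) if c_ref[k] != c_alt[k])
        snvs.append((3 * (pos - 1) + off + 1, c_alt[off]))  # (cds_pos, alt base)
    cds = "".join(codons) + "TAA"

    pad = 30
    seq = ("G" * pad) + cds + ("G" * pad)
    tx_id = display_name.replace("-", "_") + "_T"
    model = TranscriptModel(
        transcript_id=tx_id,
        gene_id=tx_id + "G",
        chrom=chrom,
        strand=1,
        exons=((pad + 1, pad + len(cds)),),
        cds_intervals=((pad + 1, pad + len(cds)),),
        display_name=display_name,
    )
    rows = []
    for cds_pos, alt in snvs:
        g = pad + cds_pos
        rows.append((SimVariant(pos=g, ref=seq[g - 1], alt=alt), {sample: "1|0"}))
    return EngineeredCase(
        fasta_text=_fasta_text(chrom, seq),
        gff_text=_gff_text(chrom, len(seq), [model]),
        vcf_text=_vcf_text(chrom, len(seq), [sample], rows),
        transcript=model,
        sample=sample,
        reference_protein="".join(residues),
    )


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------


def _parse_fasta_text(text: str) -> dict:
    seqs: dict = {}
    name = None
    chunks: list = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def _parse_gff_cds(text: str) -> dict:
    """transcript_id -> (chrom, strand, [CDS intervals ascending])."""
    out: dict = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        parent = attrs.get("Parent") or attrs.get("transcript_id")
        chrom, strand = f[0], (1 if f[6] != "-" else -1)
        rec = out.setdefault(parent, (chrom, strand, []))
        rec[2].append((int(f[3]), int(f[4])))
    return {k: (c, s, sorted(iv)) for k, (c, s, iv) in out.items()}


def _parse_vcf_sample_phase(text: str, sample: str, phase: int) -> list:
    """[(pos, ref, alt)] carried by one phase of one sample."""
    header = None
    edits = []
    for line in text.splitlines():
        if line.startswith("#CHROM"):
            header = line.split("\t")
        elif line and not line.startswith("#"):
            f = line.split("\t")
            col = header.index(sample)
            gt = f[col].split(":")[0].replace("/", "|")
            alleles = gt.split("|")
            if phase >= len(alleles):
                raise IndexError(f"sample {sample} has no phase {phase}")
            idx = alleles[phase]
            if idx not in (".", "0"):
                alts = f[4].split(",")
                edits.append((int(f[1]), f[3], alts[int(idx) - 1]))
    return edits


def oracle_haplotypes(
    fasta_text: str,
    gff_text: str,
    vcf_text: str,
    sample: str,
    phase: int,
    transcript_id: str | None = None,
):
    """Haplotype protein(s) by an independent whole-genome edit path.

    Applies the phase's VCF alleles directly to the chromosome sequence
    (3'->5'), shifts every annotation coordinate downstream of an indel by
    its net length change, re-splices the shifted CDS from the edited
    chromosome, reverse-complements for minus-strand transcripts, and
    translates. Intronic and splice-site edits are applied naively, as the
    comparable consensus-building tools do.

    Returns the protein string for ``transcript_id``, or a dict over all
    transcripts when it is None.
    """
    genomes = _parse_fasta_text(fasta_text)
    annotations = _parse_gff_cds(gff_text)
    edits = sorted(_parse_vcf_sample_phase(vcf_text, sample, phase), reverse=True)

    edited = dict(genomes)
    applied = []  # (pos, ref_len, delta)
    last_start = None
    for pos, ref, alt in edits:  # descending: no coordinate shifting needed
        if last_start is not None and pos + len(ref) - 1 >= last_start:
            raise ValueError(f"overlapping edits at position {pos}")
        last_start = pos
        applied.append((pos, len(ref), len(alt) - len(ref)))

    def edit_chrom(chrom: str) -> str:
        seq = genomes[chrom]
        for pos, ref, alt in edits:
            assert seq[pos - 1 : pos - 1 + len(ref)].upper() == ref.upper()
            seq = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
        return seq

    def shift(x: int, inclusive: bool) -> int:
        """Coordinate x in the edited sequence; inclusive counts edits ending at x."""
        s = x
        for pos, ref_len, delta in applied:
            end = pos + ref_len - 1
            if end < x or (inclusive and end <= x):
                s += delta
        return s

    def protein_for(tx: str) -> str:
        chrom, strand, intervals = annotations[tx]
        seq = edit_chrom(chrom)
        ref_chrom = genomes[chrom]

        def splice(source: str, ivs) -> str:
            s = "".join(source[a - 1 : b] for a, b in ivs)
            return reverse_complement(s) if strand == -1 else s

        ref_cds = splice(ref_chrom, intervals)
        ref_prot = _translate(ref_cds)
        ref_len = ref_prot.index("*") if "*" in ref_prot else len(ref_prot)

        shifted = [(shift(a, inclusive=False), shift(b, inclusive=True)) for a, b in intervals]
        hap_cds = splice(seq, shifted)
        prot = _translate(hap_cds)
        stop = prot.find("*")
        if stop == -1:
            return prot
        if stop + 1 <= ref_len:
            return prot[: stop + 1]
        return prot[:stop]

    if transcript_id is not None:
        return protein_for(transcript_id)
    return {tx: protein_for(tx) for tx in annotations}
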