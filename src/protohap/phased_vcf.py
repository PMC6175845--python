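"""Phased genotypes and population panels.

Reads VCF records overlapping a transcript's exon span, filters
homozygous-reference genotypes, and reshapes the remainder into
per-sample, per-phase lists of non-reference alleles ready for CDS
editing. Also loads 1000 Genomes-style population panels
(sample / population / superpopulation / sex).

Policy for data the method cannot use: samples with unphased
heterozygous or missing genotypes anywhere in the region are excluded
from that transcript's haplotype set (with a logged reason) and the
population denominators shrink accordingly. The method's premise is
pre-existing chromosomally phased input, so no attempt is made to phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

#: Exclusion / skip reasons
UNPHASED_HET = "unphased_heterozygote"
MISSING_GENOTYPE = "missing_genotype"
OVERLAP_DROPPED = "overlapping_allele_dropped"
MIXED_PLOIDY = "inconsistent_ploidy"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF convention (position of first REF base)
    variant_id: str
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self):
        if not self.ref_allele:
            raise ValueError("empty REF allele")
        if not self.alt_alleles or any(not a for a in self.alt_alleles):
            raise ValueError(f"bad ALT alleles at {self.chrom}:{self.pos}")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by the REF allele (1-based inclusive)."""
        return (self.pos, self.pos + len(self.ref_allele) - 1)

    def allele(self, index: int) -> str:
        """Allele sequence for a GT index (0 = REF)."""
        return self.ref_allele if index == 0 else self.alt_alleles[index - 1]


@dataclass(frozen=True)
class SampleGenotype:
    sample_id: str
    allele_indices: tuple  # ints, or None for missing
    phased: bool

    @property
    def ploidy(self) -> int:
        return len(self.allele_indices)

    @property
    def is_missing(self) -> bool:
        return any(i is None for i in self.allele_indices)

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_missing and all(i == 0 for i in self.allele_indices)

    @property
    def is_het(self) -> bool:
        return (
            not self.is_missing
            and self.ploidy == 2
            and self.allele_indices[0] != self.allele_indices[1]
        )


@dataclass
class PhasedSampleAlleles:
    """Per phase, the ordered non-reference alleles a sample carries.

    ``phases`` has two entries for diploid samples and one for haploid;
    each entry is a list of (VariantRecord, alt allele string) sorted by
    genomic position.
    """

    sample_id: str
    phases: tuple
    dropped: list = field(default_factory=list)  # (VariantRecord, phase, reason)

    @property
    def ploidy(self) -> int:
        return len(self.phases)

    @property
    def has_variants(self) -> bool:
        return any(self.phases)


GenotypeTable = list[tuple[VariantRecord, list[SampleGenotype]]]


def fetch_genotypes(vcf_path, region) -> tuple[GenotypeTable, list[str]]:
    """Records whose REF span intersects ``region`` = (chrom, start, end).

    Returns (records, samples): the genotype table in file order and the
    sample names in header order. Works on plain or bgzipped VCF; a tabix
    index is used when present, otherwise the file is scanned.
    """
    chrom, start, end = region
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        try:
            iterator = vcf.fetch(chrom, max(0, start - 1_000), end)
            records = list(iterator)
        except ValueError:
            records = [rec for rec in vcf if rec.chrom == chrom]
        if not records and chrom not in vcf.header.contigs:
            logger.warning("chromosome %s absent from VCF %s", chrom, vcf_path)

        table: GenotypeTable = []
        for rec in records:
            if rec.chrom != chrom or rec.alts is None:
                continue
            ref_end = rec.pos + len(rec.ref) - 1
            if ref_end < start or rec.pos > end:
                continue
            variant = VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                variant_id=rec.id or ".",
                ref_allele=rec.ref.upper(),
                alt_alleles=tuple(a.upper() for a in rec.alts),
            )
            genotypes = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None:
                    raise ValueError(f"no GT field for sample {s} at {rec.chrom}:{rec.pos}")
                genotypes.append(
                    SampleGenotype(
                        sample_id=s, allele_indices=tuple(gt), phased=call.phased
                    )
                )
            table.append((variant, genotypes))
    table.sort(key=lambda item: item[0].pos)
    return table, samples


def sample_ploidies(records: GenotypeTable) -> dict[str, int]:
    """Observed GT ploidy per sample.

    Capture this from the raw genotype table *before* hom-ref filtering:
    a haploid sample carrying only reference alleles would otherwise
    leave no trace of its ploidy.
    """
    ploidies: dict[str, int] = {}
    for _, genotypes in records:
        for g in genotypes:
            ploidies.setdefault(g.sample_id, g.ploidy)
    return ploidies


def drop_homref(records: GenotypeTable) -> GenotypeTable:
    """Remove homozygous-reference genotypes and carrier-less records."""
    out: GenotypeTable = []
    for variant, genotypes in records:
        kept = [g for g in genotypes if not g.is_hom_ref]
        if kept:
            out.append((variant, kept))
    return out


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def split_phases(
    records: GenotypeTable,
    samples: list[str],
    default_ploidy: int = 2,
    ploidy_map: dict[str, int] | None = None,
) -> tuple[list[PhasedSampleAlleles], dict[str, str]]:
    """Assign each sample's non-reference alleles to phases.

    Returns (alleles, excluded): one :class:`PhasedSampleAlleles` per
    retained sample (samples with no non-reference genotype yield empty
    phase lists, with ploidy taken from ``ploidy_map`` -- typically
    :func:`sample_ploidies` of the unfiltered table -- or else
    ``default_ploidy``), plus a mapping of excluded
    sample -> reason. Exclusion reasons: unphased heterozygous genotypes
    and missing genotypes (the method requires fully phased input);
    inconsistent ploidy across records.

    Overlapping non-reference alleles on one phase are resolved by
    dropping the later-starting allele, recorded in ``dropped``.
    """
    per_sample: dict[str, list[tuple[VariantRecord, SampleGenotype]]] = {
        s: [] for s in samples
    }
    for variant, genotypes in records:
        for g in genotypes:
            if g.sample_id in per_sample:
                per_sample[g.sample_id].append((variant, g))

    excluded: dict[str, str] = {}
    result: list[PhasedSampleAlleles] = []
    for sample in samples:
        entries = per_sample[sample]
        ploidies = {g.ploidy for _, g in entries}
        if len(ploidies) > 1:
            excluded[sample] = MIXED_PLOIDY
            logger.warning("sample %s: inconsistent ploidy across records", sample)
            continue
        if ploidies:
            ploidy = ploidies.pop()
        elif ploidy_map and sample in ploidy_map:
            ploidy = ploidy_map[sample]
        else:
            ploidy = default_ploidy
        reason = None
        for variant, g in entries:
            if g.is_missing:
                reason = MISSING_GENOTYPE
                break
            if g.is_het and not g.phased:
                reason = UNPHASED_HET
                break
        if reason:
            excluded[sample] = reason
            logger.warning("sample %s excluded: %s", sample, reason)
            continue

        phases: list[list[tuple[VariantRecord, str]]] = [[] for _ in range(ploidy)]
        for variant, g in entries:
            for phase_idx, allele_idx in enumerate(g.allele_indices):
                if allele_idx:
                    phases[phase_idx].append((variant, variant.allele(allele_idx)))

        dropped = []
        clean_phases = []
        for phase_idx, alleles in enumerate(phases):
            alleles.sort(key=lambda pair: pair[0].pos)
            kept: list[tuple[VariantRecord, str]] = []
            last_span = None
            for variant, allele in alleles:
                if last_span is not None and _spans_overlap(last_span, variant.span):
                    dropped.append((variant, phase_idx, OVERLAP_DROPPED))
                    logger.warning(
                        "sample %s phase %d: dropping %s:%d (overlaps previous allele)",
                        sample,
                        phase_idx,
                        variant.chrom,
                        variant.pos,
                    )
                    continue
                kept.append((variant, allele))
                last_span = variant.span
            clean_phases.append(tuple(kept))
        result.append(
            PhasedSampleAlleles(
                sample_id=sample, phases=tuple(clean_phases), dropped=dropped
            )
        )
    return result, excluded


@dataclass
class PopulationPanel:
    """sample -> (population, superpopulation, sex)."""

    assignments: dict[str, tuple[str, str, str]]

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments

    def population(self, sample: str) -> str | None:
        rec = self.assignments.get(sample)
        return rec[0] if rec else None

    def superpopulation(self, sample: str) -> str | None:
        rec = self.assignments.get(sample)
        return rec[1] if rec else None

    def sex(self, sample: str) -> str | None:
        rec = self.assignments.get(sample)
        return rec[2] if rec else None

    def population_keys(self, sample: str) -> list[str]:
        """Population labels a sample's observations count towards."""
        rec = self.assignments.get(sample)
        if rec is None:
            return ["ALL"]
        return ["ALL", rec[1], rec[0]]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for pop, _, _ in self.assignments.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    @property
    def superpopulations(self) -> list[str]:
        seen: list[str] = []
        for _, sup, _ in self.assignments.values():
            if sup not in seen:
                seen.append(sup)
        return seen


def load_panel(panel_path) -> PopulationPanel:
    """Read a whitespace/tab separated sample panel.

    Columns: sample, population, superpopulation, sex (header row
    optional, detected by a leading "sample" field). Duplicate rows with
    conflicting assignments raise; exact duplicates are tolerated.
    """
    assignments: dict[str, tuple[str, str, str]] = {}
    with open(panel_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if line_no == 1 and fields[0].lower() in ("sample", "sample_id"):
                continue
            if len(fields) < 3:
                raise ValueError(f"panel line {line_no}: expected >= 3 columns")
            sample, pop, sup = fields[:3]
            sex = fields[3] if len(fields) > 3 else ""
            rec = (pop, sup, sex)
            if sample in assignments and assignments[sample] != rec:
                raise ValueError(
                    f"conflicting panel rows for sample {sample!r}: "
                    f"{assignments[sample]} vs {rec}"
                )
            assignments[sample] = rec
    return PopulationPanel(assignments)
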