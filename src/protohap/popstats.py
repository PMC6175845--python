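"""Population aggregation of haplotypes and diplotypes.

Once per-sample, per-phase haplotypes exist for a transcript they are
collated here into unique-haplotype tallies with per-population counts
and frequencies of occurrence. The frequency of occurrence (FoO) of a
unique haplotype in a population is its observation count divided by the
total haplotype observation count in that population: twice the number of
diploid individuals, plus one per haploid individual (male X/Y loci
contribute a single observation and no diplotype).

Derived statistics: common haplotypes at a FoO threshold (1% by
default), gene complexity categories (one / two-or-three / four-or-more
common haplotypes), variant-level FoO summed over containing haplotypes,
the variants-versus-haplotypes point (common haplotypes plus a minimal
greedy top-up covering every common variant, which accounts for "diluted"
variants spread across many rare haplotypes), the squared-coverage
diplotype bound, and FoO-threshold sensitivity tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .diff_namer import DiffBlock
from .haplotype_core import CdsHaplotype, ProteinHaplotype
from .phased_vcf import PopulationPanel

PROTEIN = "protein"
CDS = "cds"

CATEGORY_NONE = "none"
CATEGORY_SINGLE = "single"
CATEGORY_TWO_OR_THREE = "two_or_three"
CATEGORY_FOUR_PLUS = "four_plus"


@dataclass
class HaplotypeTally:
    """One unique haplotype sequence with its population bookkeeping."""

    name: str
    sequence: str
    level: str  # "protein" | "cds"
    counts: dict = field(default_factory=dict)  # population -> observations
    carriers: dict = field(default_factory=dict)  # sample -> copies (1 or 2)
    flags: frozenset = frozenset()
    diffs: tuple = ()

    @property
    def is_reference(self) -> bool:
        return not self.diffs

    def count(self, population: str = "ALL") -> int:
        return self.counts.get(population, 0)


@dataclass
class DiplotypeTally:
    """Unordered pair of protein haplotype names carried by individuals."""

    pair: tuple  # (name_a, name_b), sorted
    counts: dict = field(default_factory=dict)
    carriers: list = field(default_factory=list)

    def count(self, population: str = "ALL") -> int:
        return self.counts.get(population, 0)


@dataclass
class TranscriptHaplotypeContainer:
    transcript_id: str
    display_id: str
    reference_protein: str
    reference_cds: str
    protein_haplotypes: list = field(default_factory=list)
    cds_haplotypes: list = field(default_factory=list)
    diplotypes: list = field(default_factory=list)
    hap_denominators: dict = field(default_factory=dict)  # population -> observations
    dip_denominators: dict = field(default_factory=dict)  # population -> diploid individuals
    populations: list = field(default_factory=list)  # ALL, superpops, pops (panel order)
    excluded_samples: dict = field(default_factory=dict)

    @property
    def total_haplotype_observations(self) -> int:
        return self.hap_denominators.get("ALL", 0)

    @property
    def total_diplotype_observations(self) -> int:
        return self.dip_denominators.get("ALL", 0)

    def haplotypes(self, level: str = PROTEIN) -> list:
        return self.protein_haplotypes if level == PROTEIN else self.cds_haplotypes


def aggregate(
    per_sample_haplotypes: dict,
    panel: PopulationPanel | None,
    transcript_id: str = "",
    display_id: str = "",
    reference_protein: str = "",
    reference_cds: str = "",
    excluded_samples: dict | None = None,
) -> TranscriptHaplotypeContainer:
    """Collate per-sample haplotypes into a container.

    ``per_sample_haplotypes`` maps sample_id -> list of
    (CdsHaplotype, ProteinHaplotype) pairs, one per phase (so length 2
    for diploid samples, 1 for haploid); an iterable of
    (sample_id, pairs) tuples is also accepted, in which case a sample
    appearing twice is an error. Haplotypes must already carry their
    names (see diff_namer); uniqueness is keyed on the exact sequence
    string, separately at protein and CDS level, so synonymous CDS
    changes merge at the protein level.
    """
    container = TranscriptHaplotypeContainer(
        transcript_id=transcript_id,
        display_id=display_id,
        reference_protein=reference_protein,
        reference_cds=reference_cds,
        excluded_samples=dict(excluded_samples or {}),
    )
    pops: list[str] = ["ALL"]
    if panel is not None:
        pops += panel.superpopulations + panel.populations
    container.populations = pops

    prot_tallies: dict[str, HaplotypeTally] = {}
    cds_tallies: dict[str, HaplotypeTally] = {}
    dip_tallies: dict[tuple, DiplotypeTally] = {}
    seen: set = set()

    items = (
        per_sample_haplotypes.items()
        if hasattr(per_sample_haplotypes, "items")
        else per_sample_haplotypes
    )
    for sample_id, phase_haps in items:
        if sample_id in seen:
            raise ValueError(f"sample {sample_id} appears twice")
        seen.add(sample_id)
        keys = panel.population_keys(sample_id) if panel is not None else ["ALL"]

        for _, prot in phase_haps:
            if not prot.name:
                raise ValueError("protein haplotype has no name; run diff_namer first")
        for key in keys:
            container.hap_denominators[key] = (
                container.hap_denominators.get(key, 0) + len(phase_haps)
            )

        for tallies, hap_of in (
            (prot_tallies, lambda pair: pair[1]),
            (cds_tallies, lambda pair: pair[0]),
        ):
            by_seq: dict[str, int] = {}
            for pair in phase_haps:
                hap = hap_of(pair)
                seq = hap.sequence
                if seq not in tallies:
                    if isinstance(hap, ProteinHaplotype):
                        tallies[seq] = HaplotypeTally(
                            name=hap.name,
                            sequence=seq,
                            level=PROTEIN,
                            flags=hap.flags,
                            diffs=tuple(hap.diffs),
                        )
                    else:
                        tallies[seq] = HaplotypeTally(
                            name=getattr(hap, "name", "") or "",
                            sequence=seq,
                            level=CDS,
                            diffs=tuple(getattr(hap, "diffs", ())),
                        )
                by_seq[seq] = by_seq.get(seq, 0) + 1
            for seq, copies in by_seq.items():
                tally = tallies[seq]
                tally.carriers[sample_id] = copies
                for key in keys:
                    tally.counts[key] = tally.counts.get(key, 0) + copies

        if len(phase_haps) == 2:
            pair = tuple(sorted(p.name for _, p in phase_haps))
            dip = dip_tallies.setdefault(pair, DiplotypeTally(pair=pair))
            dip.carriers.append(sample_id)
            for key in keys:
                dip.counts[key] = dip.counts.get(key, 0) + 1
                container.dip_denominators[key] = (
                    container.dip_denominators.get(key, 0) + 1
                )

    def sort_key(t):
        return (-t.count("ALL"), t.name)

    container.protein_haplotypes = sorted(prot_tallies.values(), key=sort_key)
    container.cds_haplotypes = sorted(cds_tallies.values(), key=sort_key)
    container.diplotypes = sorted(
        dip_tallies.values(), key=lambda d: (-d.count("ALL"), d.pair)
    )
    return container


def frequency_of_occurrence(
    tally: HaplotypeTally, population: str, container: TranscriptHaplotypeContainer
) -> float:
    """count / total haplotype observations in the population."""
    denom = container.hap_denominators.get(population, 0)
    if denom == 0:
        raise ZeroDivisionError(f"no haplotype observations for population {population!r}")
    return tally.count(population) / denom


def diplotype_frequency(
    dip: DiplotypeTally, population: str, container: TranscriptHaplotypeContainer
) -> float:
    denom = container.dip_denominators.get(population, 0)
    if denom == 0:
        raise ZeroDivisionError(f"no diplotype observations for population {population!r}")
    return dip.count(population) / denom


def common_haplotypes(
    container: TranscriptHaplotypeContainer,
    threshold: float = 0.01,
    population: str = "ALL",
    level: str = PROTEIN,
) -> list:
    """Haplotypes with FoO >= threshold (inclusive), sorted by FoO desc then name."""
    out = [
        t
        for t in container.haplotypes(level)
        if frequency_of_occurrence(t, population, container) >= threshold
    ]
    out.sort(
        key=lambda t: (-frequency_of_occurrence(t, population, container), t.name)
    )
    return out


@dataclass
class GeneComplexity:
    n_unique: int
    n_common: int
    category: str
    most_common: str
    most_common_per_population: dict
    most_common_differs_from_reference: bool


def classify_gene(
    container: TranscriptHaplotypeContainer, threshold: float = 0.01
) -> GeneComplexity:
    """Complexity category from the number of common protein haplotypes."""
    commons = common_haplotypes(container, threshold)
    n_common = len(commons)
    if n_common >= 4:
        category = CATEGORY_FOUR_PLUS
    elif n_common >= 2:
        category = CATEGORY_TWO_OR_THREE
    elif n_common == 1:
        category = CATEGORY_SINGLE
    else:
        category = CATEGORY_NONE

    def most_common_in(pop: str) -> HaplotypeTally | None:
        haps = [t for t in container.protein_haplotypes if t.count(pop) > 0]
        if not haps:
            return None
        return min(haps, key=lambda t: (-t.count(pop), t.name))

    top = most_common_in("ALL")
    per_pop = {}
    for pop in container.populations:
        t = most_common_in(pop)
        if t is not None:
            per_pop[pop] = t.name
    return GeneComplexity(
        n_unique=len(container.protein_haplotypes),
        n_common=n_common,
        category=category,
        most_common=top.name if top else "",
        most_common_per_population=per_pop,
        most_common_differs_from_reference=bool(top and not t_is_reference(top, container)),
    )


def t_is_reference(tally: HaplotypeTally, container: TranscriptHaplotypeContainer) -> bool:
    if tally.level == PROTEIN:
        return tally.sequence == container.reference_protein
    return tally.sequence == container.reference_cds


def variant_foo(
    container: TranscriptHaplotypeContainer,
    population: str = "ALL",
    level: str = PROTEIN,
) -> dict:
    """FoO of each diff identity, summed over the haplotypes containing it.

    A diff identity is (position, ref, alt) at the chosen level.
    """
    out: dict = {}
    for t in container.haplotypes(level):
        foo = frequency_of_occurrence(t, population, container)
        for d in t.diffs:
            out[d.identity] = out.get(d.identity, 0.0) + foo
    return out


def variants_vs_haplotypes_point(
    container: TranscriptHaplotypeContainer,
    threshold: float = 0.01,
    population: str = "ALL",
) -> tuple[int, int]:
    """(number of common variants, common haplotypes + minimal top-up).

    The top-up greedily adds non-common haplotypes in descending FoO
    until every variant with FoO >= threshold is contained in at least
    one selected haplotype ("diluted" variants would otherwise be missed
    by a purely haplotype-frequency-based selection).
    """
    vfoo = variant_foo(container, population)
    significant = {ident for ident, f in vfoo.items() if f >= threshold}
    commons = common_haplotypes(container, threshold, population)
    covered = set()
    for t in commons:
        covered.update(d.identity for d in t.diffs)
    remaining = significant - covered

    selected_names = {t.name for t in commons}
    rest = [t for t in container.protein_haplotypes if t.name not in selected_names]
    rest.sort(key=lambda t: (-frequency_of_occurrence(t, population, container), t.name))
    top_up = 0
    for t in rest:
        if not remaining:
            break
        idents = {d.identity for d in t.diffs}
        if idents & remaining:
            top_up += 1
            remaining -= idents
    if remaining:
        raise AssertionError("significant variant not contained in any haplotype")
    return (len(significant), len(commons) + top_up)


def diplotype_coverage_bound(haplotype_coverage: float) -> float:
    """Fraction of individuals with both haplotypes covered, under random pairing.

    A drug effective for a fraction c of haplotypes covers at least c**2
    of diplotypes (0.99 -> 0.9801, the 99%-haplotype / 98%-diplotype rule).
    """
    if not 0.0 <= haplotype_coverage <= 1.0:
        raise ValueError("coverage must be within [0, 1]")
    return haplotype_coverage**2


def enumerate_variant_combinations(protein_variants, cap: int = 20) -> list:
    """All 2**n presence/absence combinations of n protein variants.

    Each combination is returned as a tuple of the variants present,
    ordered by position -- the hypothetical haplotype set one would have
    to engineer to test every combination exhaustively (e.g. 5 variants
    -> 32 proteins).
    """
    variants = list(protein_variants)
    if len(variants) > cap:
        raise ValueError(f"{len(variants)} variants exceed the combination cap ({cap})")

    def pos(v):
        return v.ref_pos if isinstance(v, DiffBlock) else v

    combos = []
    for r in range(len(variants) + 1):
        for subset in itertools.combinations(variants, r):
            combos.append(tuple(sorted(subset, key=pos)))
    return combos


@dataclass
class ExternalProteinMapping:
    matches: dict  # haplotype name -> list of external ids
    unmatched_external: list  # external ids matching no haplotype


def map_to_external_proteins(
    container: TranscriptHaplotypeContainer, protein_fasta
) -> ExternalProteinMapping:
    """Exact full-length matches of protein haplotypes to an external set.

    Sequences are compared after stripping any trailing stop residue from
    either side. Duplicate external entries are all reported.
    """
    externals = [
        (rec.id, str(rec.seq).rstrip("*")) for rec in SeqIO.parse(str(protein_fasta), "fasta")
    ]
    matches: dict = {}
    matched_ids: set = set()
    for t in container.protein_haplotypes:
        seq = t.sequence.rstrip("*")
        hits = [ext_id for ext_id, ext_seq in externals if ext_seq == seq]
        if hits:
            matches[t.name] = hits
            matched_ids.update(hits)
    unmatched = [ext_id for ext_id, _ in externals if ext_id not in matched_ids]
    return ExternalProteinMapping(matches=matches, unmatched_external=unmatched)


def threshold_sensitivity(containers, thresholds) -> pd.DataFrame:
    """Significant-haplotype and complexity-category counts per threshold."""
    rows = []
    for thr in thresholds:
        n_sig = 0
        cats = {
            CATEGORY_NONE: 0,
            CATEGORY_SINGLE: 0,
            CATEGORY_TWO_OR_THREE: 0,
            CATEGORY_FOUR_PLUS: 0,
        }
        for c in containers:
            commons = common_haplotypes(c, thr)
            n_sig += len(commons)
            cats[classify_gene(c, thr).category] += 1
        rows.append(
            {
                "threshold": thr,
                "n_significant_haplotypes": n_sig,
                "genes_single": cats[CATEGORY_SINGLE],
                "genes_two_or_three": cats[CATEGORY_TWO_OR_THREE],
                "genes_four_plus": cats[CATEGORY_FOUR_PLUS],
            }
        )
    return pd.DataFrame(rows)
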