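"""Aggregation, frequency-of-occurrence and derived gene statistics."""

import itertools

import pytest

from protohap.diff_namer import DiffBlock
from protohap.haplotype_core import CdsHaplotype, ProteinHaplotype
from protohap.phased_vcf import PopulationPanel
from protohap.popstats import (
    CATEGORY_FOUR_PLUS,
    CATEGORY_SINGLE,
    CATEGORY_TWO_OR_THREE,
    aggregate,
    classify_gene,
    common_haplotypes,
    diplotype_coverage_bound,
    enumerate_variant_combinations,
    frequency_of_occurrence,
    map_to_external_proteins,
    threshold_sensitivity,
    variant_foo,
    variants_vs_haplotypes_point,
)

REF_PROT = "MKPW"


def hap(seq, name, diffs=(), sample="S1", phase=0):
    prot = ProteinHaplotype("T1", seq, sample_id=sample, phase=phase)
    prot.name = name
    prot.diffs = tuple(diffs)
    cds = CdsHaplotype("T1", "ATG" + seq[1:] * 3, sample_id=sample, phase=phase)
    cds.name = name + ".cds"
    return (cds, prot)


def build_container(assignment, panel=None):
    """assignment: sample -> list of (seq, name, diffs) per phase."""
    per_sample = {
        s: [hap(seq, name, diffs, sample=s, phase=i) for i, (seq, name, diffs) in enumerate(haps)]
        for s, haps in assignment.items()
    }
    return aggregate(
        per_sample,
        panel,
        transcript_id="T1",
        display_id="T1-001",
        reference_protein=REF_PROT,
        reference_cds="ATG",
    )


D1 = DiffBlock("substitution", 2, "K", "Q")
D2 = DiffBlock("substitution", 3, "P", "L")
D3 = DiffBlock("substitution", 4, "W", "C")

REF = (REF_PROT, "T1-001:REF", ())
A = ("MQPW", "T1-001:2K>Q", (D1,))
AB = ("MQLW", "T1-001:2K>Q,3P>L", (D1, D2))
AC = ("MQPC", "T1-001:2K>Q,4W>C", (D1, D3))


class TestAggregate:
    def test_one_diploid_sample_counts(self):
        c = build_container({"S1": [REF, REF]})
        assert c.total_haplotype_observations == 2
        assert c.total_diplotype_observations == 1
        assert len(c.protein_haplotypes) == 1
        assert c.protein_haplotypes[0].carriers == {"S1": 2}

    def test_haploid_plus_diploid(self):
        c = build_container({"S1": [REF, A], "S2": [REF]})
        assert c.total_haplotype_observations == 3
        assert c.total_diplotype_observations == 1

    def test_zygosity_conserved(self):
        c = build_container({"S1": [A, A], "S2": [A, REF], "S3": [REF, REF]})
        for t in c.protein_haplotypes:
            assert sum(t.carriers.values()) == t.count("ALL")

    def test_panel_population_counts_sum_to_all(self):
        panel = PopulationPanel(
            {"S1": ("GBR", "EUR", "female"), "S2": ("JPT", "EAS", "male")}
        )
        c = build_container({"S1": [A, REF], "S2": [REF, REF]}, panel)
        for t in c.protein_haplotypes:
            assert t.count("ALL") == t.count("EUR") + t.count("EAS")
        assert c.hap_denominators["ALL"] == 4

    def test_duplicate_sample_rejected(self):
        pairs = [("S1", [hap(*REF)]), ("S1", [hap(*REF)])]
        with pytest.raises(ValueError, match="twice"):
            aggregate(pairs, None)

    def test_foo_normalises_to_one_per_population(self):
        panel = PopulationPanel(
            {"S1": ("GBR", "EUR", "f"), "S2": ("GBR", "EUR", "f"), "S3": ("JPT", "EAS", "m")}
        )
        c = build_container({"S1": [A, AB], "S2": [REF, REF], "S3": [AC, REF]}, panel)
        for pop in c.populations:
            total = sum(
                frequency_of_occurrence(t, pop, c)
                for t in c.protein_haplotypes
                if c.hap_denominators.get(pop)
            )
            assert total == pytest.approx(1.0, abs=1e-9)


class TestFrequencies:
    def test_single_carrier_among_ten_diploids(self):
        assignment = {f"S{i}": [REF, REF] for i in range(10)}
        assignment["S0"] = [A, REF]
        c = build_container(assignment)
        t = next(t for t in c.protein_haplotypes if t.sequence == "MQPW")
        assert frequency_of_occurrence(t, "ALL", c) == 0.05

    def test_three_copies_among_ten_diploids(self):
        assignment = {f"S{i}": [REF, REF] for i in range(10)}
        assignment["S0"] = [A, A]
        assignment["S1"] = [A, REF]
        c = build_container(assignment)
        t = next(t for t in c.protein_haplotypes if t.sequence == "MQPW")
        assert frequency_of_occurrence(t, "ALL", c) == 0.15

    def test_sole_haplotype_has_foo_one(self):
        c = build_container({"S1": [REF, REF]})
        assert frequency_of_occurrence(c.protein_haplotypes[0], "ALL", c) == 1.0


class TestCommonHaplotypes:
    def _container_with_foo(self, weights):
        """weights: name -> observation count over one big pool."""
        assignment = {}
        idx = 0
        variants = {"REF": REF, "A": A, "AB": AB, "AC": AC}
        flat = []
        for key, n in weights.items():
            flat += [variants[key]] * n
        assert len(flat) % 2 == 0
        for i in range(0, len(flat), 2):
            assignment[f"S{idx}"] = [flat[i], flat[i + 1]]
            idx += 1
        return build_container(assignment)

    def test_threshold_inclusive(self):
        # 1 copy in 100 observations is exactly 1%
        c = self._container_with_foo({"REF": 99, "A": 1})
        commons = common_haplotypes(c, threshold=0.01)
        assert {t.sequence for t in commons} == {REF_PROT, "MQPW"}

    def test_zero_threshold_returns_all(self):
        c = self._container_with_foo({"REF": 6, "A": 2, "AB": 2})
        assert len(common_haplotypes(c, threshold=0.0)) == 3

    def test_monotone_in_threshold(self):
        c = self._container_with_foo({"REF": 70, "A": 20, "AB": 8, "AC": 2})
        sizes = [len(common_haplotypes(c, thr)) for thr in (0.002, 0.01, 0.05, 0.5)]
        assert sizes == sorted(sizes, reverse=True)


class TestClassifyGene:
    def test_categories(self):
        c1 = build_container({"S1": [REF, REF]})
        assert classify_gene(c1).category == CATEGORY_SINGLE
        c2 = build_container({"S1": [REF, A], "S2": [AB, REF]})
        assert classify_gene(c2).category == CATEGORY_TWO_OR_THREE
        c3 = build_container({"S1": [REF, A], "S2": [AB, AC]})
        assert classify_gene(c3).category == CATEGORY_FOUR_PLUS

    def test_most_common_differs_from_reference(self):
        c = build_container({"S1": [A, A], "S2": [A, REF]})
        gc = classify_gene(c)
        assert gc.most_common == "T1-001:2K>Q"
        assert gc.most_common_differs_from_reference is True

    def test_most_common_reference(self):
        c = build_container({"S1": [REF, REF], "S2": [A, REF]})
        assert classify_gene(c).most_common_differs_from_reference is False


class TestVariantFoo:
    def test_summed_over_containing_haplotypes(self):
        # A in 3 haplotypes; B only in AB; C only in AC
        assignment = {
            "S0": [A, REF],
            "S1": [AB, REF],
            "S2": [AC, REF],
            "S3": [REF, REF],
        }
        c = build_container(assignment)
        vf = variant_foo(c)
        assert vf[D1.identity] == pytest.approx(3 / 8)
        assert vf[D2.identity] == pytest.approx(1 / 8)
        assert (4, "W", "Q") not in vf


def brute_force_minimal_topup(container, threshold=0.01, population="ALL"):
    """Smallest top-up set covering all significant variants (exhaustive)."""
    vf = variant_foo(container, population)
    significant = {k for k, v in vf.items() if v >= threshold}
    commons = common_haplotypes(container, threshold, population)
    covered = set().union(*[{d.identity for d in t.diffs} for t in commons]) if commons else set()
    remaining = significant - covered
    rest = [t for t in container.protein_haplotypes if t not in commons]
    for size in range(len(rest) + 1):
        for subset in itertools.combinations(rest, size):
            got = set().union(*[{d.identity for d in t.diffs} for t in subset]) if subset else set()
            if remaining <= got:
                return size
    raise AssertionError("uncoverable")


class TestVariantsVsHaplotypes:
    def _diluted_container(self):
        # FoO: REF 111/114, A 1/114, AB 1/114, AC 1/114 -> variant A foo 3/114
        assignment = {f"S{i}": [REF, REF] for i in range(57)}
        assignment["S0"] = [A, REF]
        assignment["S1"] = [AB, REF]
        assignment["S2"] = [AC, REF]
        return build_container(assignment)

    def test_diluted_variant_drives_top_up(self):
        c = self._diluted_container()
        x, y = variants_vs_haplotypes_point(c, threshold=0.02)
        assert x == 1  # only variant 2K>Q is common
        assert y == 2  # REF (common) + one A-carrying haplotype

    def test_all_variants_inside_common_haplotypes(self):
        assignment = {"S0": [A, A], "S1": [A, REF], "S2": [REF, REF]}
        c = build_container(assignment)
        x, y = variants_vs_haplotypes_point(c, threshold=0.01)
        assert y == len(common_haplotypes(c, 0.01))

    def test_no_variants(self):
        c = build_container({"S1": [REF, REF]})
        assert variants_vs_haplotypes_point(c, 0.01) == (0, 1)

    def test_greedy_matches_brute_force(self):
        containers = [
            self._diluted_container(),
            build_container({"S0": [A, AB], "S1": [AC, REF], "S2": [REF, REF]}),
            build_container({"S0": [AB, AC], "S1": [REF, REF]}),
        ]
        for thr in (0.01, 0.02, 0.2):
            for c in containers:
                x, y = variants_vs_haplotypes_point(c, thr)
                commons = len(common_haplotypes(c, thr))
                assert y >= commons
                assert y - commons == brute_force_minimal_topup(c, thr)


class TestCoverageBound:
    def test_ninety_nine_percent_rule(self):
        assert diplotype_coverage_bound(0.99) == pytest.approx(0.9801)
        assert diplotype_coverage_bound(0.99) >= 0.98

    @pytest.mark.parametrize("c,expected", [(1.0, 1.0), (0.9, 0.81), (0.0, 0.0)])
    def test_closed_form(self, c, expected):
        assert diplotype_coverage_bound(c) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diplotype_coverage_bound(1.5)


class TestEnumerateCombinations:
    @pytest.mark.parametrize("n,expected", [(0, 1), (3, 8), (5, 32)])
    def test_counts(self, n, expected):
        variants = [DiffBlock("substitution", 10 * (i + 1), "A", "V") for i in range(n)]
        assert len(enumerate_variant_combinations(variants)) == expected

    def test_cap_guard(self):
        with pytest.raises(ValueError):
            enumerate_variant_combinations(range(25), cap=20)


class TestExternalProteinMapping:
    def test_trailing_stop_stripped_and_duplicates_reported(self, tmp_path):
        c = build_container({"S1": [("MQPW*", "T1-001:x", (D1,)), REF]})
        fasta = tmp_path / "ext.fa"
        fasta.write_text(">P1\nMQPW\n>P1copy\nMQPW\n>P9\nWWWW\n")
        mapping = map_to_external_proteins(c, fasta)
        assert mapping.matches == {"T1-001:x": ["P1", "P1copy"]}
        assert mapping.unmatched_external == ["P9"]

    def test_no_matches(self, tmp_path):
        c = build_container({"S1": [REF, REF]})
        fasta = tmp_path / "ext.fa"
        fasta.write_text(">P9\nWWWW\n")
        mapping = map_to_external_proteins(c, fasta)
        assert mapping.matches == {}


class TestThresholdSensitivity:
    def test_counts_match_direct_evaluation(self):
        assignment = {f"S{i}": [REF, REF] for i in range(5)}
        assignment["S0"] = [A, AB]
        assignment["S1"] = [A, REF]
        c = build_container(assignment)  # FoO: REF .7, A .2, AB .1
        table = threshold_sensitivity([c], thresholds=[0.05, 0.15, 0.5])
        assert list(table["n_significant_haplotypes"]) == [3, 2, 1]

    def test_monotone_non_increasing(self):
        c = build_container({"S0": [A, AB], "S1": [REF, AC], "S2": [REF, REF]})
        table = threshold_sensitivity([c], thresholds=[0.0, 0.1, 0.2, 0.9])
        counts = list(table["n_significant_haplotypes"])
        assert counts == sorted(counts, reverse=True)
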