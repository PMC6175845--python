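"""Generators: determinism, structure, ground truth, and the oracle."""

import numpy as np
import pytest

from protohap.genome_model import spliced_cds
from protohap.synthetic_data import (
    SimulationConfig,
    TranscriptRecipe,
    build_toy_reference,
    engineer_notation_case,
    generate_mutation_series,
    generate_population_dataset,
    generate_population_vcf,
    generate_random_exonic_vcf,
    generate_toy_reference,
    oracle_haplotypes,
)

EXPECTED_SCENARIOS = {
    "exonic_snv",
    "mnv",
    "inframe_ins",
    "inframe_del",
    "frameshift_ins",
    "frameshift_del",
    "stop_gain",
    "stop_loss",
    "first_cds_base",
    "last_cds_base",
    "intronic_snv",
    "splice_del",
    "hom_alt",
    "haploid_snv",
}


class TestToyReference:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=5)
        assert generate_toy_reference(cfg) == generate_toy_reference(cfg)

    def test_different_seed_different_sequence(self):
        fa1, _ = generate_toy_reference(SimulationConfig(seed=5))
        fa2, _ = generate_toy_reference(SimulationConfig(seed=6))
        assert fa1 != fa2

    def test_strand_mix_and_structure(self, toy, toy_genome):
        strands = {t.strand for t in toy.transcripts}
        assert strands == {1, -1}
        assert any(len(t.exons) == 1 for t in toy.transcripts)
        assert any(len(t.exons) > 1 for t in toy.transcripts)
        for t in toy.transcripts:
            cds = spliced_cds(t, toy_genome)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            assert len(cds) % 3 == 0

    def test_gff_cds_feature_count_matches_recipe(self, toy):
        for t in toy.transcripts:
            n = sum(
                1
                for line in toy.gff_text.splitlines()
                if "\tCDS\t" in line and f"Parent={t.transcript_id}" in line
            )
            assert n == len(t.cds_intervals)

    def test_infeasible_recipe_rejected(self):
        with pytest.raises(ValueError):
            TranscriptRecipe(name="X", n_codons=2)


@pytest.fixture(scope="module", params=[0, 1, 2])
def series(request, toy, toy_genome):
    t = toy.transcripts[request.param]
    return t, generate_mutation_series(t, toy_genome)


class TestMutationSeries:
    def test_scenario_coverage(self, series):
        t, ms = series
        names = {s.name for s in ms.scenarios}
        expected = set(EXPECTED_SCENARIOS)
        if len(t.cds_intervals) == 1:  # no intron to mutate
            expected -= {"intronic_snv", "splice_del"}
        assert names == expected

    def test_genotype_shapes(self, series):
        _, ms = series
        by_name = {s.name: s for s in ms.scenarios}
        assert by_name["hom_alt"].carrying_phases == (0, 1)
        assert by_name["haploid_snv"].genotype == "1"
        assert by_name["mnv"].carrying_phases == (1,)

    def test_variant_refs_match_genome(self, series, toy_genome):
        t, ms = series
        for s in ms.scenarios:
            g = s.variant.pos
            fetched = toy_genome.fetch(t.chrom, g, g + len(s.variant.ref) - 1)
            assert fetched == s.variant.ref, s.name

    def test_stop_gain_creates_premature_stop_codon(self, series, toy):
        t, ms = series
        cds = toy.cds_sequences[t.transcript_id]
        sg = next(s for s in ms.scenarios if s.name == "stop_gain")
        cds_start, cds_end, alt = sg.cds_edit
        mutated = cds[: cds_start - 1] + alt + cds[cds_end:]
        codon_i = (cds_start - 1) // 3
        assert mutated[codon_i * 3 : codon_i * 3 + 3] in {"TAA", "TAG", "TGA"}
        assert codon_i < len(cds) // 3 - 1  # strictly before the terminal stop


class TestPopulationDataset:
    def test_truth_frequencies_within_three_se(self):
        cfg = SimulationConfig(seed=9, n_samples=500)
        ds = generate_population_dataset(cfg)
        counts = np.zeros(3)
        for haps in ds.truth.sample_phases.values():
            for h in haps:
                counts[h] += 1
        n = counts.sum()
        assert n == 1000
        for p_true, p_hat in zip((0.7, 0.2, 0.1), counts / n):
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(p_hat - p_true) <= 3 * se

    def test_single_sample_single_diplotype(self):
        vcf, panel, truth = generate_population_vcf(
            SimulationConfig(seed=9, n_samples=1)
        )
        assert len(truth.sample_phases) == 1
        (haps,) = truth.sample_phases.values()
        assert len(haps) == 2

    def test_population_profiles_differ_in_expectation(self):
        cfg = SimulationConfig(
            seed=9,
            n_samples=400,
            population_profiles={"P1": (0.7, 0.2, 0.1), "P2": (0.1, 0.2, 0.7)},
        )
        ds = generate_population_dataset(cfg)
        f1 = ds.truth.expected_foo("P1")
        f2 = ds.truth.expected_foo("P2")
        assert f1[0] > 0.5 > f2[0]

    def test_haploid_fraction(self):
        ds = generate_population_dataset(
            SimulationConfig(seed=9, n_samples=100, fraction_haploid=0.2)
        )
        ploidies = [len(h) for h in ds.truth.sample_phases.values()]
        assert ploidies.count(1) == 20

    def test_vcf_text_deterministic(self):
        cfg = SimulationConfig(seed=4, n_samples=30)
        assert generate_population_vcf(cfg)[0] == generate_population_vcf(cfg)[0]


class TestOracle:
    def test_zero_variant_sample_reference_protein(self, toy, toy_genome):
        t = toy.transcripts[0]
        ms = generate_mutation_series(t, toy_genome)
        # every sample is hom-ref at other scenarios' sites; pick a phase
        # of a sample that does not carry its own variant on that phase
        sc = next(s for s in ms.scenarios if s.genotype == "1|0")
        protein = oracle_haplotypes(
            toy.fasta_text, toy.gff_text, ms.vcf_text, sc.name, 1, t.transcript_id
        )
        from protohap.haplotype_core import ReferenceContext

        rc = ReferenceContext.build(t, toy_genome)
        assert protein == rc.protein

    def test_intronic_variant_excised_by_splicing(self, toy, toy_genome):
        t = toy.transcripts[0]
        ms = generate_mutation_series(t, toy_genome)
        sc = next(s for s in ms.scenarios if s.name == "intronic_snv")
        protein = oracle_haplotypes(
            toy.fasta_text, toy.gff_text, ms.vcf_text, sc.name, 0, t.transcript_id
        )
        from protohap.haplotype_core import ReferenceContext

        assert protein == ReferenceContext.build(t, toy_genome).protein

    def test_random_exonic_vcf_deterministic(self, toy, toy_genome):
        t = toy.transcripts[0]
        a = generate_random_exonic_vcf(t, toy_genome, seed=3, n_samples=5)
        b = generate_random_exonic_vcf(t, toy_genome, seed=3, n_samples=5)
        assert a == b


class TestEngineeredCase:
    def test_reference_protein_layout(self):
        case = engineer_notation_case("X-001", 50, [(10, "R", "Q")])
        assert len(case.reference_protein) == 50
        assert case.reference_protein[9] == "R"
        assert case.reference_protein[0] == "M"

    def test_impossible_change_rejected(self):
        with pytest.raises(ValueError):
            engineer_notation_case("X-001", 50, [(10, "M", "W")])
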