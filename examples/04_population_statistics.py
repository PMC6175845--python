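"""Population statistics: complexity, diluted variants, coverage bounds.

Builds a population with two panel populations of different haplotype
frequency profiles, then derives the statistics a drug-discovery
scientist would ask for: common haplotypes at the 1% FoO threshold,
the gene complexity category, per-variant FoO (summed over containing
haplotypes), the variants-versus-haplotypes selection point, threshold
sensitivity, and the squared-coverage diplotype guarantee.
"""

import tempfile
from pathlib import Path

from protohap import (
    classify_gene,
    common_haplotypes,
    compute_container,
    diplotype_coverage_bound,
    enumerate_variant_combinations,
    frequency_of_occurrence,
    load_reference,
    threshold_sensitivity,
    variant_foo,
    variants_vs_haplotypes_point,
)
from protohap.phased_vcf import load_panel
from protohap.synthetic_data import SimulationConfig, generate_population_dataset

cfg = SimulationConfig(
    seed=5,
    n_samples=400,
    haplotype_frequencies=(0.55, 0.25, 0.12, 0.08),
    population_profiles={
        "P1": (0.70, 0.20, 0.06, 0.04),
        "P2": (0.40, 0.30, 0.18, 0.12),
    },
)
ds = generate_population_dataset(cfg)
with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    (d / "r.fa").write_text(ds.reference.fasta_text)
    (d / "p.vcf").write_text(ds.vcf_text)
    (d / "s.panel").write_text(ds.panel_text)
    container = compute_container(
        ds.reference.transcripts[0],
        load_reference(d / "r.fa"),
        str(d / "p.vcf"),
        load_panel(d / "s.panel"),
    )

print("per-population frequency of occurrence:")
for t in container.protein_haplotypes:
    foos = "  ".join(
        f"{pop}={frequency_of_occurrence(t, pop, container):.3f}"
        for pop in ("ALL", "P1", "P2")
    )
    print(f"  {t.name:<45s} {foos}")

gc = classify_gene(container, threshold=0.01)
print(f"\ncommon haplotypes (FoO >= 1%): {gc.n_common} -> category '{gc.category}'")
print(f"most common haplotype: {gc.most_common}"
      f" (differs from reference: {gc.most_common_differs_from_reference})")

x, y = variants_vs_haplotypes_point(container, threshold=0.01)
print(f"\nvariants-vs-haplotypes point: {x} common variants need {y} haplotypes")
vf = variant_foo(container)
for ident, foo in sorted(vf.items()):
    print(f"  variant {ident[0]}{ident[1]}>{ident[2]}: FoO={foo:.3f}")

print("\nthreshold sensitivity:")
print(threshold_sensitivity([container], [0.002, 0.01, 0.05]).to_string(index=False))

n_common = gc.n_common
covered = sum(
    frequency_of_occurrence(t, "ALL", container)
    for t in common_haplotypes(container, 0.01)
)
print(f"\nselected common haplotypes cover {covered:.1%} of haplotype observations;")
print(f"guaranteed diplotype (individual) coverage: {diplotype_coverage_bound(covered):.1%}")
print(f"(99% haplotype coverage would guarantee "
      f"{diplotype_coverage_bound(0.99):.2%} of individuals)")

n_var = len(vf)
print(f"\ntesting every combination of {n_var} variants would need "
      f"{len(enumerate_variant_combinations(list(vf)))} engineered proteins")
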