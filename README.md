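# protohap

Protein haplotypes from phased genotypes.

Most genomic resources describe protein variation one variant at a time, as
per-site minor allele frequencies. But a protein molecule is produced from
one phased copy of a gene: what circulates in a population is not a bag of
independent substitutions, it is a set of *protein haplotypes* — complete
amino-acid sequences carrying each chromosome's particular combination of
coding variants — and, per diploid individual, an unordered pair of them (a
*diplotype*). For anyone selecting a protein sequence to work with — most
acutely in therapeutic antibody design, where binding is exquisitely
sequence-specific — the right question is "which full-length protein forms
occur in the population, and how often?", not "which sites vary?".

`protohap` answers that question. From a reference genome (FASTA), transcript
models (GFF3/GTF) and phased genotypes (VCF) it reconstructs, per individual
and per phase, the coding sequence and protein of each transcript; names
every haplotype by its alignment-derived differences from the reference; and
aggregates across a cohort into per-population frequencies.

## Method

For each transcript and each sample phase:

1. phased genotypes overlapping the transcript's exon span are fetched from
   the VCF; homozygous-reference genotypes are dropped, and male X/Y
   monoploidy is honoured (one haplotype, no diplotype);
2. each allele is projected into the spliced CDS frame (strand-aware);
   alleles whose span is not wholly exonic-coding (intronic, splice-boundary,
   UTR) are skipped and recorded;
3. edits are applied to the reference CDS in 3′→5′ order, so indels never
   shift the coordinates of edits yet to be applied, and the edited CDS is
   translated *in silico* (a premature stop is kept as a terminal `*`
   residue);
4. each haplotype is globally re-aligned to its reference with a
   linear-space affine-gap aligner (Miller–Myers divide and conquer over
   Gotoh's recurrences; leftmost gap placement among co-optimal alignments),
   and contiguous difference blocks are named in a compact HGVS-like
   notation — `299D>G` (substitution), `578del(325)` (deletion),
   `42ins(QQ)` (insertion) — joined onto the transcript identifier:
   `TLR4-001:299D>G,399T>I`;
5. unique sequences are tallied into a transcript haplotype container with
   per-population counts, carriers with zygosity, and diplotypes.

The frequency of occurrence (FoO) of a unique haplotype *h* in a population
of *N* diploid individuals is

```
FoO(h) = count(h) / total haplotype observations   (= count(h) / 2N)
```

with haploid-adjusted denominators where applicable. Haplotypes with
FoO ≥ 1% are *common* by default; genes are classified by their number of
common haplotypes (1 / 2–3 / ≥4). A variant's FoO is the sum over the
haplotypes containing it, which exposes "diluted" variants — common variants
found only in individually-rare haplotypes. Because haplotypes pair randomly
into diplotypes, covering a fraction *c* of haplotypes guarantees at least
*c²* of individuals (99% of haplotypes ⇒ 98% of diplotypes).

A synthetic-data module generates toy genomes (multi-exon transcripts on
both strands), a comprehensive mutation series, and phased population VCFs
with known ground truth — plus an independently implemented oracle that
derives haplotypes by editing the whole chromosome and coordinate-shifting
the annotation, sharing no logic with the pipeline.

## Worked example

`examples/01_compute_haplotypes.py` simulates 500 phased diploid individuals
drawing three haplotypes at true frequencies 0.7 / 0.2 / 0.1 under
Hardy–Weinberg pairing, then runs the full pipeline:

```
transcript TOYA-T1: 1000 haplotype observations, 500 diplotypes

  TOYA-001:REF                             count= 701  FoO=0.701
  TOYA-001:5S>L                            count= 203  FoO=0.203
  TOYA-001:5S>L,10V>E                      count=  96  FoO=0.096

simulated true frequencies: 0.700 / 0.200 / 0.100
```

Each row is one unique protein: its name lists its residue differences from
the reference translation (`5S>L` = serine→leucine at residue 5), `count` its
observations among the 1000 phased genome copies, and FoO the resulting
population frequency — recovering the simulated truth to sampling error.
Known variant identifiers (`rs…`) are attached to diffs where the mapping is
unambiguous.

`examples/02_notation.py` shows the notation on engineered cases, including
a stop gain rendered as the premature `*` plus the truncated tail:

```
ACTN3-001:211R>Q,577R>*,578del(325)
TLR4-001:299D>G,399T>I
C5-001:802V>I,885R>H
```

The other examples demonstrate the oracle validation
(`03_validation_oracle.py`) and the population statistics — gene complexity,
diluted variants, threshold sensitivity, coverage bounds
(`04_population_statistics.py`).

A thin CLI wraps the same pipeline:

```bash
protohap --fasta ref.fa --gff models.gff3 --vcf phased.vcf \
         --panel samples.panel --gene TOYA-G --canonical-only --format json
```

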