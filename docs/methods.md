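# Methods

This note records the model, the concrete policies adopted where the
design was genuinely open, the numerical choices, and what the synthetic
validation does and does not establish.

## Haplotype reconstruction model

A protein haplotype is the translation of one phased copy of a
transcript's coding sequence. The pipeline is a deterministic sequence
transformer: it applies exactly the phased alleles the VCF asserts, and
makes no biological judgement calls (no nonsense-mediated-decay
prediction, no start-loss rescue, no functional scoring).

**Coordinates.** External formats keep their native conventions (VCF and
GFF are 1-based inclusive). Internally everything is 1-based inclusive:
genomic positions on the chromosome, CDS positions in the spliced coding
sequence read 5′→3′ in transcript orientation. On minus-strand
transcripts the genomic end of an interval maps to the smaller CDS
position and allele sequences are reverse-complemented on projection.

**Allele trimming.** VCF represents indels anchored on a shared base.
Shared leading bases are trimmed first (advancing the position), then
shared trailing bases. Leading-first order matters: the anchor sits on
the left, so trimming leading-first keeps the minimal span at its
rightful position instead of sliding it leftward onto the anchor — which
could relocate an exon-internal indel onto an intronic anchor base and
misclassify it.

**Splice policy.** An allele is applied only when its trimmed reference
span lies wholly inside CDS exonic bases; anything touching intronic,
splice-boundary or UTR sequence is skipped and recorded with its reason.
This is the strictest consistent reading of "no intronic or splice-site
edits"; no boundary width parameter is introduced. A pure insertion is
applied only when both flanking bases are coding (exon-interior).

**Edit application.** Edits are sorted by descending CDS start and
spliced in 3′→5′ order, making the result independent of input order.
Overlapping non-reference alleles on one phase are resolved upstream by
dropping the later-starting allele (deterministic and conservative; the
3′→5′ scheme presumes non-overlap). The edit set re-checks overlap in
CDS space after projection.

**Translation.** Standard genetic code (table 1), no selenocysteine.
Translation runs from CDS position 1 and stops at the first stop codon.
A stop at or before the reference protein length is a premature stop and
is retained as a terminal `*` residue — this is what makes the `577R>*`
notation well defined. A stop at reference length + 1 is the reference's
own terminal stop and is never included. If the stop codon is destroyed
(stop loss), translation continues to the next stop *within the CDS
only*: the CDS is the universe of the method and there is no 3′ UTR
read-through. A destroyed start codon still translates from position 1
(flagged); a trailing incomplete codon is dropped and flagged.

**Ploidy.** Ploidy is taken from the GT field, and is captured from the
genotype table *before* homozygous-reference filtering — a haploid
sample carrying only reference alleles would otherwise leave no trace of
its ploidy and would silently be counted as diploid. Haploid samples
contribute one haplotype observation and no diplotype.

**Unphased and missing genotypes.** The method consumes
chromosomally-phased input; a sample with an unphased heterozygous or
missing genotype anywhere in a transcript's region is excluded from that
transcript's haplotype set, with the exclusion logged and the
population denominators reduced accordingly (FoO must remain a proper
frequency). Fully phased cohort inputs are unaffected.

## Alignment and naming

Haplotypes are re-aligned to their reference with global affine-gap
alignment (match +1, mismatch −1, gap open 2, gap extend 0.5 — all
configurable). The alignment itself is computed in linear space by
Miller–Myers divide and conquer over Gotoh's recurrences, with two exact
fast paths that carry essentially all production traffic:

* equal-length pairs whose mismatch count *d* satisfies
  `d·(match − mismatch) ≤ match + 2·open + 2·extend` take the gap-free
  alignment directly (no gapped alignment can score higher: any gap
  costs two runs, one per row);
* otherwise the problem is reduced to the differing core plus a 50-column
  matched guard band on each side before the divide and conquer runs.

Optimality of the returned score is property-tested against an
independent quadratic dynamic-programming implementation (Biopython's
PairwiseAligner) on random pairs, including low-complexity alphabets.

**Tie-breaking.** Among co-optimal alignments, whole gap runs are
rotated leftward while the ungapped row carries the same character just
before the run as at the run's end (the classic indel left-alignment
rule). This yields the leftmost, most 5′/N-terminal placement, so
co-optimal alignments always produce identical names.

**Diff calling.** Maximal runs of non-matching columns merge into single
blocks; a run mixing substitutions and gaps is a substitution block with
unequal-length sequences (frameshift tails are one such block, stored in
full). One notation rule: a final block aligning the haplotype's lone
terminal `*` against the remaining reference is split into the stop
substitution plus a tail deletion, producing `577R>*,578del(325)` rather
than one opaque mixed block.

**Notation.** Substitution `{pos}{ref}>{alt}`, deletion
`{pos}del({length})`, insertion `{pos}ins({seq})`; names join onto the
transcript or protein identifier; a haplotype identical to its reference
is `{id}:REF`. This is deliberately a compact HGVS-like form, not the
full HGVS p./c. grammar. The insertion form extrapolates the `del(n)`
style; no published example constrains it.

**Known-variant identifiers.** A diff block overlapping (at codon
resolution for proteins) exactly one applied, non-frameshift edit whose
VCF ID is informative inherits that ID. Blocks spanning multiple
variants and frameshift-composite blocks stay unassigned — attribution
there would be a guess.

## Population statistics

Uniqueness is keyed on the exact sequence string, separately at protein
and CDS level, so synonymous CDS changes merge at the protein level.
Denominators are per-transcript and haploid-adjusted: FoO is count over
total haplotype observations (2 per included diploid, 1 per haploid).
Population labels are ALL, the panel's superpopulations, and its
populations; samples absent from the panel count toward ALL only.

Common haplotypes use an inclusive threshold (FoO ≥ 1% by default).
Gene complexity categories are 1 / 2–3 / ≥4 common haplotypes (a
container can also report zero). Variant-level FoO sums the FoO of
containing haplotypes, a diff identity being (position, ref, alt). The
variants-versus-haplotypes point counts common variants on one axis and,
on the other, the common haplotypes plus a greedy top-up — adding
non-common haplotypes in descending FoO until every common variant is
contained in a selected haplotype. The greedy rule follows the
"minimum number of haplotypes of the highest frequency" wording
literally; tests verify it equals the brute-force minimum on all
containers with ≤ 12 haplotypes. The diplotype coverage bound is the
closed form c² of random pairing. External protein mapping is exact
full-length string equality after stripping a trailing stop residue on
either side.

**Canonical transcript.** Three tiers on translation length — CCDS-tagged,
merged-annotation, then any transcript — each requiring no internal stop
codons; ties break to the lexicographic transcript ID (the upstream
convention's tie-break is unpublished; this one is reproducible). If
every transcript has internal stops the longest translation is returned
with a warning rather than failing the gene. CDS phase fields are not
used beyond a modulo-3 length check; length-incomplete transcripts are
processed with an `incomplete_cds` flag rather than rejected.

## Synthetic data and validation

The generators are pure functions of (configuration, seed): fixed seed
means byte-identical FASTA/GFF/VCF/panel text.

* **Toy references** carry a 2-exon plus-strand, a 3-exon minus-strand
  and a single-exon transcript (60/48/40 codons), GT…AG introns, short
  UTRs, ATG start and TAA stop. These sizes keep the whole validation
  suite inside seconds while exercising every coordinate regime (strand,
  splicing, boundaries).
* **The mutation series** applies one scenario per synthetic sample:
  exonic SNV, MNV, in-frame and frameshift insertion and deletion, stop
  gain (a codon one substitution from a stop is guaranteed in the
  generated CDS), stop loss, first/last CDS base edits, intronic SNV,
  splice-boundary deletion, het / hom-alt genotypes and one haploid
  sample.
* **Population VCFs** draw each sample's phases i.i.d. from specified
  haplotype frequencies (default 0.7/0.2/0.1, 500 diploids, two panel
  populations) and pair them randomly — Hardy–Weinberg by construction.
  Non-reference haplotypes carry nested missense SNV sets, so
  variant-level FoO accumulates across haplotypes and the diluted-variant
  machinery is exercised.
* **The oracle** re-derives each haplotype by editing the whole
  chromosome sequence, shifting annotation coordinates across indels,
  re-splicing and translating — an independent computation path with its
  own minimal text parsing. It applies splice-touching edits naively, as
  whole-genome consensus tools do; the test harness enumerates that
  known-difference regime explicitly (the pipeline must skip such
  variants and return the reference) instead of hiding it.

What passing does *not* show: the simulations have no linkage
disequilibrium structure, no phasing or genotyping error, no structural
variants, and frequencies are specified rather than evolved — so the
tests validate the sequence transformation and the bookkeeping, not
robustness to upstream data pathology. Haplotype counts on real cohorts
inherit any phasing/calling errors of their input.

## Degenerate inputs and numerical choices

* FoO normalisation is exact rational arithmetic over integer counts;
  tests assert Σ FoO = 1 within 1e−9.
* Zero denominators (population with no observations) raise rather than
  return NaN.
* A VCF REF inconsistent with the reference genome is a hard error
  (corrupt input), not a skip.
* Multi-allelic records are kept as-is; the phase's GT index selects the
  alt. Duplicate panel rows are tolerated when identical, rejected when
  conflicting.
* TSV numbers print with 6 significant digits; JSON serialisation is
  deterministic and round-trips byte-identically.

## Scope limits

No phasing or imputation, no structural variants beyond simple
indels/MNVs, no non-coding transcript support, no pathogenicity scores,
no database or web layer. The acceptance script's cohort-scale
observation counts are arithmetic over the container counting rule at
published cohort dimensions, not a genome-wide run.
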