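"""End-to-end orchestration: files in, haplotype container out.

The canonical flow for one transcript:

1. fetch phased genotypes for the genomic span bounded by the
   transcript's exons and drop homozygous-reference genotypes;
2. split the remainder into per-sample, per-phase allele lists
   (excluding samples with unphased/missing genotypes);
3. project, edit and translate each phase into CDS and protein
   haplotypes;
4. re-align each unique sequence to its reference, call and name diffs,
   and attach known-variant identifiers;
5. aggregate into a TranscriptHaplotypeContainer with per-population
   counts and frequencies.
"""

from __future__ import annotations

from dataclasses import replace

from . import diff_namer, haplotype_core, phased_vcf, popstats
from .diff_namer import AlignmentScoring, DEFAULT_SCORING
from .genome_model import GenomeSequence, TranscriptModel
from .phased_vcf import PopulationPanel


def name_haplotypes(
    pairs_by_sample: dict,
    reference: haplotype_core.ReferenceContext,
    display_id: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> None:
    """Fill diffs/names on every haplotype, in place.

    Alignment runs once per unique sequence (haplotypes are shared across
    many samples); known-variant IDs come from a representative carrier's
    applied edits.
    """
    prot_cache: dict = {}
    cds_cache: dict = {}
    for pairs in pairs_by_sample.values():
        for cds_hap, prot_hap in pairs:
            if prot_hap.sequence not in prot_cache:
                diffs, name = diff_namer.diff_and_name(
                    reference.protein, prot_hap.sequence, display_id, scoring
                )
                diffs = diff_namer.assign_variant_ids(diffs, cds_hap.edits, level="protein")
                prot_cache[prot_hap.sequence] = (tuple(diffs), name)
            prot_hap.diffs, prot_hap.name = prot_cache[prot_hap.sequence]

            if cds_hap.sequence not in cds_cache:
                diffs, name = diff_namer.diff_and_name(
                    reference.cds, cds_hap.sequence, display_id, scoring
                )
                diffs = diff_namer.assign_variant_ids(diffs, cds_hap.edits, level="cds")
                cds_cache[cds_hap.sequence] = (tuple(diffs), name)
            cds_hap.diffs, cds_hap.name = cds_cache[cds_hap.sequence]


def compute_container(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    vcf_path,
    panel: PopulationPanel | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    display_id: str | None = None,
) -> popstats.TranscriptHaplotypeContainer:
    """Compute the full haplotype container for one transcript."""
    display_id = display_id or transcript.label
    reference = haplotype_core.ReferenceContext.build(transcript, genome)

    span_start, span_end = transcript.span
    records, samples = phased_vcf.fetch_genotypes(
        vcf_path, (transcript.chrom, span_start, span_end)
    )
    ploidies = phased_vcf.sample_ploidies(records)
    records = phased_vcf.drop_homref(records)
    sample_alleles, excluded = phased_vcf.split_phases(
        records, samples, ploidy_map=ploidies
    )

    pairs_by_sample = {
        sa.sample_id: haplotype_core.build_sample_haplotypes(
            transcript, genome, sa, reference
        )
        for sa in sample_alleles
    }
    name_haplotypes(pairs_by_sample, reference, display_id, scoring)

    return popstats.aggregate(
        pairs_by_sample,
        panel,
        transcript_id=transcript.transcript_id,
        display_id=display_id,
        reference_protein=reference.protein,
        reference_cds=reference.cds,
        excluded_samples=excluded,
    )
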