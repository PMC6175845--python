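"""CDS editing and in-silico translation.

The heart of the method: project each phased non-reference allele from
genomic coordinates into the spliced CDS frame, apply all of a phase's
edits to the reference CDS in 3'->5' order (so earlier edits never shift
the coordinates of later ones), and translate the edited CDS into a
protein haplotype.

Splice policy: an allele is applied only when its trimmed reference span
lies wholly inside CDS exonic bases. Variants touching intronic, splice
boundary or UTR sequence are skipped and recorded, never applied.

Premature stop codons are retained as a terminal "*" residue (so a stop
gain at residue 577 names as 577R>*); the reference's own terminal stop
is never part of the protein string. Stop-loss translation continues to
the next stop within the CDS only -- the CDS is the universe of the
method, there is no 3' UTR read-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome_model import (
    CODING,
    GenomeSequence,
    TranscriptModel,
    genomic_to_cds,
    reverse_complement,
    spliced_cds,
)
from .phased_vcf import PhasedSampleAlleles, VariantRecord

#: flags carried by protein haplotypes
CONTAINS_INDEL = "contains_indel"
CONTAINS_STOP_CHANGE = "contains_stop_change"
INCOMPLETE_CDS = "incomplete_cds"
IS_REFERENCE = "is_reference"

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CdsEdit:
    """One allele projected into reference-CDS coordinates.

    ``cds_start``/``cds_end`` are 1-based inclusive positions in the
    *reference* CDS. A pure insertion has ``cds_end == cds_start - 1``
    (empty reference span; the insertion lands before ``cds_start``).
    Sequences are on the CDS strand (reverse-complemented for minus-strand
    transcripts).
    """

    cds_start: int
    cds_end: int
    ref_seq: str
    alt_seq: str
    variant: VariantRecord | None = None

    def __post_init__(self):
        if not self.ref_seq and not self.alt_seq:
            raise ValueError("edit with empty ref and alt")
        expected_len = self.cds_end - self.cds_start + 1
        if len(self.ref_seq) != max(expected_len, 0):
            raise ValueError("ref_seq length inconsistent with CDS interval")

    @property
    def is_insertion(self) -> bool:
        return not self.ref_seq

    @property
    def length_change(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)


@dataclass(frozen=True)
class SkippedVariant:
    variant: VariantRecord
    allele: str
    reason: str  # intronic | splice_boundary | outside | overlap


@dataclass
class CdsHaplotype:
    transcript_id: str
    sequence: str
    edits: tuple = ()
    skipped: tuple = ()
    sample_id: str = ""
    phase: int = 0
    diffs: tuple = ()  # filled by diff_namer (DNA-alphabet blocks)
    name: str = ""  # filled by diff_namer

    @property
    def is_reference(self) -> bool:
        return not self.edits


@dataclass
class ProteinHaplotype:
    transcript_id: str
    sequence: str
    sample_id: str = ""
    phase: int = 0
    flags: frozenset = frozenset()
    diffs: tuple = ()  # filled by diff_namer
    name: str = ""  # filled by diff_namer

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty protein sequence")
        star = self.sequence.find("*")
        if star != -1 and star != len(self.sequence) - 1:
            raise ValueError("internal stop in protein haplotype string")


def _trim_shared_flanks(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip bases shared by REF and ALT (VCF anchor bases and padding).

    Leading bases are trimmed first (advancing the position), then
    trailing bases: the VCF anchor base sits on the left, so trimming
    leading-first keeps the minimal span anchored at its rightful
    position rather than sliding it onto the anchor.
    """
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def project_variant(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    variant: VariantRecord,
    allele: str,
) -> CdsEdit | SkippedVariant:
    """Map one non-reference allele into the reference CDS frame.

    Returns a :class:`CdsEdit` when the trimmed reference span lies wholly
    inside CDS exonic sequence, otherwise a :class:`SkippedVariant` whose
    reason records why (intronic / splice_boundary / outside). A REF
    allele inconsistent with the reference genome is a hard error: the
    input VCF does not belong to this reference.
    """
    gstart, gend = variant.span
    genome_ref = genome.fetch(variant.chrom, gstart, gend)
    if genome_ref != variant.ref_allele:
        raise ValueError(
            f"VCF REF {variant.ref_allele!r} at {variant.chrom}:{variant.pos} "
            f"does not match reference genome ({genome_ref!r})"
        )

    pos, ref, alt = _trim_shared_flanks(variant.pos, variant.ref_allele, allele)
    g2c = transcript.genomic_to_cds_map()

    if not ref:
        # pure insertion between pos-1 and pos
        left, right = g2c.get(pos - 1), g2c.get(pos)
        if left is None or right is None:
            coord = genomic_to_cds(transcript, (pos - 1, pos))
            reason = coord.kind if coord.kind != CODING else "splice_boundary"
            return SkippedVariant(variant, allele, reason)
        if transcript.strand == -1:
            alt = reverse_complement(alt)
        insert_before = max(left, right)
        return CdsEdit(
            cds_start=insert_before,
            cds_end=insert_before - 1,
            ref_seq="",
            alt_seq=alt,
            variant=variant,
        )

    coord = genomic_to_cds(transcript, (pos, pos + len(ref) - 1))
    if not coord.is_coding:
        return SkippedVariant(variant, allele, coord.kind)
    if transcript.strand == -1:
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
    return CdsEdit(
        cds_start=coord.start,
        cds_end=coord.end,
        ref_seq=ref,
        alt_seq=alt,
        variant=variant,
    )


def _edits_overlap(a: CdsEdit, b: CdsEdit) -> bool:
    # insertions occupy the empty interval [start, start-1]
    return a.cds_start <= max(b.cds_end, b.cds_start - 1) and b.cds_start <= max(
        a.cds_end, a.cds_start - 1
    )


def apply_edits(reference_cds: str, edits) -> str:
    """Splice every edit's alt sequence into the reference CDS.

    Edits are applied in 3'->5' order (descending cds_start) so indels
    never shift the coordinates of edits still to be applied; the result
    is therefore independent of the input order. Overlapping edits are an
    error -- they must be resolved upstream.
    """
    edits = sorted(edits, key=lambda e: (-e.cds_start, -e.cds_end))
    for i in range(len(edits) - 1):
        if _edits_overlap(edits[i], edits[i + 1]):
            raise ValueError(
                f"overlapping CDS edits at {edits[i + 1].cds_start} and "
                f"{edits[i].cds_start}"
            )
    seq = reference_cds
    for e in edits:
        if e.ref_seq and seq[e.cds_start - 1 : e.cds_end] != e.ref_seq:
            raise ValueError(
                f"edit ref {e.ref_seq!r} does not match CDS at {e.cds_start}"
            )
        seq = seq[: e.cds_start - 1] + e.alt_seq + seq[e.cds_end :]
    return seq


def translate_cds(sequence: str, reference_protein_length: int) -> tuple[str, frozenset]:
    """Translate a CDS haplotype; returns (protein, flags).

    Standard genetic code from position 1. Translation stops at the first
    stop codon: a stop at or before ``reference_protein_length`` is a
    premature stop retained as a terminal "*" residue; a stop beyond that
    (the reference's own terminal stop, or one pushed downstream by an
    insertion) simply ends the protein. Absence of any stop codon
    (stop-loss) and premature stops set the contains_stop_change flag. A
    trailing incomplete codon is ignored and flagged incomplete_cds.
    """
    if len(sequence) < 3:
        raise ValueError("CDS shorter than one codon")
    flags = set()
    n_codons = len(sequence) // 3
    if len(sequence) % 3:
        flags.add(INCOMPLETE_CDS)
    translated = str(Seq(sequence[: n_codons * 3]).translate())
    stop = translated.find("*")
    if stop == -1:
        flags.add(CONTAINS_STOP_CHANGE)
        protein = translated
    elif stop + 1 <= reference_protein_length:
        flags.add(CONTAINS_STOP_CHANGE)
        protein = translated[: stop + 1]  # keep "*" as terminal residue
    else:
        protein = translated[:stop]
    return protein, frozenset(flags)


@dataclass
class ReferenceContext:
    """Reference CDS and translation for one transcript (computed once)."""

    transcript: TranscriptModel
    cds: str
    protein: str

    @classmethod
    def build(cls, transcript: TranscriptModel, genome: GenomeSequence):
        cds = spliced_cds(transcript, genome)
        n_codons = len(cds) // 3
        # the reference's own terminal stop codon is not a residue
        ref_len = n_codons - 1 if cds[(n_codons - 1) * 3 : n_codons * 3] in _STOP_CODONS else n_codons
        protein, _ = translate_cds(cds, reference_protein_length=ref_len)
        return cls(transcript=transcript, cds=cds, protein=protein)


def build_sample_haplotypes(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    sample_alleles: PhasedSampleAlleles,
    reference: ReferenceContext | None = None,
) -> list[tuple[CdsHaplotype, ProteinHaplotype]]:
    """One (CDS, protein) haplotype pair per phase of one sample.

    Diploid samples yield two pairs, haploid samples one. Variants that
    cannot be applied (non-coding span, or overlap after projection) are
    recorded on the CDS haplotype as skipped.
    """
    if reference is None:
        reference = ReferenceContext.build(transcript, genome)
    ref_len = len(reference.protein)

    results = []
    for phase_idx, alleles in enumerate(sample_alleles.phases):
        edits: list[CdsEdit] = []
        skipped: list[SkippedVariant] = []
        for variant, allele in alleles:
            projected = project_variant(transcript, genome, variant, allele)
            if isinstance(projected, SkippedVariant):
                skipped.append(projected)
            else:
                edits.append(projected)
        # projection can reorder alleles on minus strand; re-resolve overlap
        edits.sort(key=lambda e: (e.cds_start, e.cds_end))
        resolved: list[CdsEdit] = []
        for e in edits:
            if resolved and _edits_overlap(resolved[-1], e):
                skipped.append(SkippedVariant(e.variant, e.alt_seq, "overlap"))
                continue
            resolved.append(e)

        sequence = apply_edits(reference.cds, resolved)
        protein_seq, flags = translate_cds(sequence, ref_len)
        flags = set(flags)
        if any(e.length_change != 0 for e in resolved):
            flags.add(CONTAINS_INDEL)
        if protein_seq == reference.protein:
            flags.add(IS_REFERENCE)

        cds_hap = CdsHaplotype(
            transcript_id=transcript.transcript_id,
            sequence=sequence,
            edits=tuple(resolved),
            skipped=tuple(skipped),
            sample_id=sample_alleles.sample_id,
            phase=phase_idx,
        )
        prot_hap = ProteinHaplotype(
            transcript_id=transcript.transcript_id,
            sequence=protein_seq,
            sample_id=sample_alleles.sample_id,
            phase=phase_idx,
            flags=frozenset(flags),
        )
        results.append((cds_hap, prot_hap))
    return results
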