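"""Global re-alignment of haplotypes and HGVS-like difference naming.

Each haplotype is globally re-aligned to its reference sequence with a
linear-space affine-gap algorithm (Miller-Myers divide and conquer over
Gotoh recurrences). Contiguous runs of non-matching alignment columns
become difference blocks ("diffs"); blocks are rendered with a compact
notation similar to HGVS:

* substitution  ``{pos}{ref}>{alt}``      e.g. ``299D>G``
* deletion      ``{pos}del({length})``    e.g. ``578del(325)``
* insertion     ``{pos}ins({seq})``       e.g. ``42ins(QQ)``

and joined onto the transcript or protein identifier, e.g.
``TLR4-001:299D>G,399T>I``. A haplotype identical to its reference is
named ``{id}:REF``.

A premature stop codon is represented as a terminal "*" residue: a stop
gain therefore names as a substitution at the stop's position followed by
a deletion covering the truncated reference tail (``577R>*,578del(325)``).

Among co-optimal alignments, gaps are placed leftmost (deterministic
names); the same machinery names nucleotide (CDS) haplotypes over the DNA
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .haplotype_core import CdsEdit

_INF = float("inf")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring: a gap of length k scores -(gap_open + k*gap_extend)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 2.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be >= 0")


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class Alignment:
    """Two gapped strings of equal length ('-' = gap) plus the score."""

    ref_aligned: str
    alt_aligned: str
    score: float

    def __post_init__(self):
        if len(self.ref_aligned) != len(self.alt_aligned):
            raise ValueError("aligned strings differ in length")


def _alignment_score(ra: str, aa: str, scoring: AlignmentScoring) -> float:
    score = 0.0
    in_gap_ref = in_gap_alt = False
    for r, a in zip(ra, aa):
        if r == "-":
            score -= scoring.gap_extend + (0.0 if in_gap_ref else scoring.gap_open)
            in_gap_ref, in_gap_alt = True, False
        elif a == "-":
            score -= scoring.gap_extend + (0.0 if in_gap_alt else scoring.gap_open)
            in_gap_alt, in_gap_ref = True, False
        else:
            score += scoring.match if r == a else scoring.mismatch
            in_gap_ref = in_gap_alt = False
    return score


# ---------------------------------------------------------------------------
# Miller-Myers linear-space global alignment (cost minimisation internally)
# ---------------------------------------------------------------------------


def _mm_recurse(A, B, g, h, sub, tb, te, out):
    """Emit alignment ops for A vs B into ``out``.

    Costs: substitution cost sub(a,b); a gap of length k costs
    open + k*extend, where the open cost at the top/bottom boundary of
    this subproblem is tb/te (0 when a deletion gap continues across the
    boundary from the parent problem). Ops: ('M', m) aligned columns,
    ('D', k) gap in B (reference residues deleted... from A's view), and
    ('I', k) gap in A.
    """
    M, N = len(A), len(B)
    if N == 0:
        if M > 0:
            out.append(("D", M))
        return
    if M == 0:
        out.append(("I", N))
        return
    if M == 1:
        t = min(tb, te)
        best = (t + h) + (g + h * N)  # delete A[0], insert all of B
        bestj = 0
        for j in range(1, N + 1):
            c = (g + h * (j - 1) if j > 1 else 0.0)
            c += sub(A[0], B[j - 1])
            c += g + h * (N - j) if j < N else 0.0
            if c < best:
                best, bestj = c, j
        if bestj == 0:
            out.append(("D", 1))
            out.append(("I", N))
        else:
            if bestj > 1:
                out.append(("I", bestj - 1))
            out.append(("M", 1))
            if bestj < N:
                out.append(("I", N - bestj))
        return

    mid = M // 2

    # forward pass: CC[j] = best cost of A[:mid] vs B[:j];
    # DD[j] = best cost ending in a deletion (gap in B) open into row mid+1
    CC = [0.0] * (N + 1)
    DD = [0.0] * (N + 1)
    t = g
    for j in range(1, N + 1):
        t += h
        CC[j] = t
        DD[j] = t + g
    t = tb
    for i in range(1, mid + 1):
        s = CC[0]
        t += h
        c = t
        CC[0] = c
        e = t + g
        ai = A[i - 1]
        for j in range(1, N + 1):
            e = min(e, c + g) + h
            DD[j] = min(DD[j], CC[j] + g) + h
            c = min(DD[j], e, s + sub(ai, B[j - 1]))
            s = CC[j]
            CC[j] = c
    DD[0] = CC[0]

    # backward pass over the suffixes
    RR = [0.0] * (N + 1)
    SS = [0.0] * (N + 1)
    t = g
    for j in range(N - 1, -1, -1):
        t += h
        RR[j] = t
        SS[j] = t + g
    t = te
    for i in range(M - 1, mid - 1, -1):
        s = RR[N]
        t += h
        c = t
        RR[N] = c
        e = t + g
        ai = A[i]
        for j in range(N - 1, -1, -1):
            e = min(e, c + g) + h
            SS[j] = min(SS[j], RR[j] + g) + h
            c = min(SS[j], e, s + sub(ai, B[j]))
            s = RR[j]
            RR[j] = c
    SS[N] = RR[N]

    best = _INF
    bestj = 0
    best_type = 1
    for j in range(N + 1):
        c = CC[j] + RR[j]
        if c < best:
            best, bestj, best_type = c, j, 1
    for j in range(N + 1):
        c = DD[j] + SS[j] - g  # deletion gap crossing the split: one open only
        if c < best:
            best, bestj, best_type = c, j, 2

    if best_type == 1:
        _mm_recurse(A[:mid], B[:bestj], g, h, sub, tb, g, out)
        _mm_recurse(A[mid:], B[bestj:], g, h, sub, g, te, out)
    else:
        _mm_recurse(A[: mid - 1], B[:bestj], g, h, sub, tb, 0.0, out)
        out.append(("D", 2))
        _mm_recurse(A[mid + 1 :], B[bestj:], g, h, sub, 0.0, te, out)


def _left_shift_gaps(ra: list, aa: list) -> None:
    """Move whole gap runs leftward wherever score-neutral (in place).

    A gap run in one row can rotate one column left past an aligned
    column exactly when the ungapped row carries the same character just
    before the run as at the run's end (the classic indel left-alignment
    rule). Iterating to a fixed point yields the leftmost co-optimal gap
    placement, so co-optimal alignments always name identically.
    """
    n = len(ra)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < n:
            for gapped, solid in ((aa, ra), (ra, aa)):
                if gapped[i] == "-" and solid[i] != "-":
                    s = i
                    e = i
                    while e + 1 < n and gapped[e + 1] == "-" and solid[e + 1] != "-":
                        e += 1
                    while (
                        s > 0
                        and gapped[s - 1] != "-"
                        and solid[s - 1] != "-"
                        and solid[s - 1] == solid[e]
                    ):
                        gapped[e] = gapped[s - 1]
                        gapped[s - 1] = "-"
                        s -= 1
                        e -= 1
                        changed = True
                    i = e
                    break
            i += 1


def global_align(
    reference: str, haplotype: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> Alignment:
    """Optimal global alignment of haplotype to reference.

    Linear-space divide and conquer; optimality of the returned score is
    property-tested against an independent quadratic dynamic-programming
    implementation. Gap columns are normalised to their leftmost
    score-neutral position so that co-optimal alignments always produce
    the same (and the most 5'/N-terminal) difference names.
    """
    if not reference or not haplotype:
        raise ValueError("cannot align empty sequences")

    # equal-length fast path: with d mismatches, the gap-free alignment is
    # provably optimal when even a single length-1 double gap could not
    # pay for itself: d*(match - mismatch) <= match + 2*open + 2*extend
    if len(reference) == len(haplotype):
        d = sum(a != b for a, b in zip(reference, haplotype))
        if d * (scoring.match - scoring.mismatch) <= (
            scoring.match + 2 * scoring.gap_open + 2 * scoring.gap_extend
        ):
            score = _alignment_score(reference, haplotype, scoring)
            return Alignment(reference, haplotype, score)

    # shrink the problem to the differing core plus a generous matched
    # guard band; haplotypes are near-identical to their reference, so
    # this is where essentially all the speed comes from
    guard = 50
    p = 0
    while (
        p < min(len(reference), len(haplotype)) and reference[p] == haplotype[p]
    ):
        p += 1
    s = 0
    while (
        s < min(len(reference), len(haplotype)) - p
        and reference[len(reference) - 1 - s] == haplotype[len(haplotype) - 1 - s]
    ):
        s += 1
    p = max(0, p - guard)
    s = max(0, s - guard)
    core_ref = reference[p : len(reference) - s]
    core_alt = haplotype[p : len(haplotype) - s]

    match_cost = -scoring.match
    mismatch_cost = -scoring.mismatch

    def sub(a, b):
        return match_cost if a == b else mismatch_cost

    ops: list = [("M", p)] if p else []
    _mm_recurse(
        core_ref,
        core_alt,
        scoring.gap_open,
        scoring.gap_extend,
        sub,
        scoring.gap_open,
        scoring.gap_open,
        ops,
    )
    if s:
        ops.append(("M", s))

    ra: list = []
    aa: list = []
    i = j = 0
    for op, k in ops:
        if op == "M":
            for _ in range(k):
                ra.append(reference[i])
                aa.append(haplotype[j])
                i += 1
                j += 1
        elif op == "D":  # reference residues against gap
            ra.extend(reference[i : i + k])
            aa.extend("-" * k)
            i += k
        else:  # 'I': haplotype residues against gap
            ra.extend("-" * k)
            aa.extend(haplotype[j : j + k])
            j += k
    assert i == len(reference) and j == len(haplotype)
    _left_shift_gaps(ra, aa)
    ra_s, aa_s = "".join(ra), "".join(aa)
    return Alignment(ra_s, aa_s, _alignment_score(ra_s, aa_s, scoring))


# ---------------------------------------------------------------------------
# Diff calling and naming
# ---------------------------------------------------------------------------

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class DiffBlock:
    """One contiguous block of difference between haplotype and reference.

    ``ref_pos`` is the 1-based position in the reference of the block's
    first reference residue; for an insertion it is the reference position
    after which the inserted residues occur (0 for an insertion before the
    first residue).
    """

    kind: str
    ref_pos: int
    ref_seq: str
    alt_seq: str
    variant_id: str | None = None

    def __post_init__(self):
        if self.kind == SUBSTITUTION and (not self.ref_seq or not self.alt_seq):
            raise ValueError("substitution requires both sequences")
        if self.kind == INSERTION and (self.ref_seq or not self.alt_seq):
            raise ValueError("insertion must have empty ref and non-empty alt")
        if self.kind == DELETION and (self.alt_seq or not self.ref_seq):
            raise ValueError("deletion must have non-empty ref and empty alt")

    @property
    def name(self) -> str:
        return name_diff(self)

    @property
    def identity(self) -> tuple:
        """(position, ref, alt): the unit of variant-level frequency."""
        return (self.ref_pos, self.ref_seq, self.alt_seq)


def call_diffs(alignment: Alignment) -> list[DiffBlock]:
    """Maximal runs of non-matching alignment columns as DiffBlocks.

    Mixed runs (substitution columns adjacent to gap columns) become a
    single substitution block with unequal-length sequences (this is how
    frameshift tails are represented). One exception for readability of
    stop gains: a final block aligning the haplotype's lone terminal "*"
    against the remaining reference tail is split into the stop
    substitution plus a deletion of the truncated tail.
    """
    ra, aa = alignment.ref_aligned, alignment.alt_aligned
    ref_len = sum(1 for ch in ra if ch != "-")
    blocks: list[DiffBlock] = []
    ref_pos = 0
    i = 0
    n = len(ra)
    while i < n:
        if ra[i] != "-" and ra[i] == aa[i]:
            ref_pos += 1
            i += 1
            continue
        # start of a difference run
        start_ref_pos = ref_pos + 1
        ref_chars: list = []
        alt_chars: list = []
        while i < n and not (ra[i] != "-" and ra[i] == aa[i]):
            if ra[i] != "-":
                ref_chars.append(ra[i])
                ref_pos += 1
            if aa[i] != "-":
                alt_chars.append(aa[i])
            i += 1
        ref_seq = "".join(ref_chars)
        alt_seq = "".join(alt_chars)
        if not ref_seq:
            blocks.append(
                DiffBlock(INSERTION, ref_pos=start_ref_pos - 1, ref_seq="", alt_seq=alt_seq)
            )
        elif not alt_seq:
            blocks.append(
                DiffBlock(DELETION, ref_pos=start_ref_pos, ref_seq=ref_seq, alt_seq="")
            )
        elif (
            alt_seq == "*"
            and len(ref_seq) >= 2
            and start_ref_pos + len(ref_seq) - 1 == ref_len
        ):
            # stop gain: "*" vs the truncated reference tail
            blocks.append(
                DiffBlock(SUBSTITUTION, ref_pos=start_ref_pos, ref_seq=ref_seq[0], alt_seq="*")
            )
            blocks.append(
                DiffBlock(DELETION, ref_pos=start_ref_pos + 1, ref_seq=ref_seq[1:], alt_seq="")
            )
        else:
            blocks.append(
                DiffBlock(SUBSTITUTION, ref_pos=start_ref_pos, ref_seq=ref_seq, alt_seq=alt_seq)
            )
    return blocks


def name_diff(block: DiffBlock) -> str:
    if block.kind == SUBSTITUTION:
        return f"{block.ref_pos}{block.ref_seq}>{block.alt_seq}"
    if block.kind == DELETION:
        return f"{block.ref_pos}del({len(block.ref_seq)})"
    return f"{block.ref_pos}ins({block.alt_seq})"


def haplotype_name(display_id: str, diffs) -> str:
    """``{display_id}:{diff1,diff2,...}``; no diffs names the reference."""
    if not diffs:
        return f"{display_id}:REF"
    return f"{display_id}:" + ",".join(name_diff(d) for d in diffs)


def apply_diffs(reference: str, diffs) -> str:
    """Reconstruct the haplotype from the reference and its diff blocks."""
    seq = reference
    for d in sorted(diffs, key=lambda d: -d.ref_pos):
        if d.kind == INSERTION:
            seq = seq[: d.ref_pos] + d.alt_seq + seq[d.ref_pos :]
        else:
            start = d.ref_pos - 1
            end = start + len(d.ref_seq)
            if seq[start:end] != d.ref_seq:
                raise ValueError(f"diff {d.name} inconsistent with reference")
            seq = seq[:start] + d.alt_seq + seq[end:]
    return seq


def diff_and_name(
    reference: str,
    haplotype: str,
    display_id: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[list[DiffBlock], str]:
    """Convenience: align, call diffs, and build the haplotype name."""
    if haplotype == reference:
        return [], haplotype_name(display_id, [])
    diffs = call_diffs(global_align(reference, haplotype, scoring))
    return diffs, haplotype_name(display_id, diffs)


# ---------------------------------------------------------------------------
# Known-variant identifier assignment
# ---------------------------------------------------------------------------


def _edit_ref_interval(edit: CdsEdit, residues: bool) -> tuple[int, int]:
    start = edit.cds_start
    end = max(edit.cds_end, edit.cds_start - 1)
    if edit.is_insertion:
        start, end = max(1, edit.cds_start - 1), edit.cds_start
    if residues:
        return ((start - 1) // 3 + 1, (end - 1) // 3 + 1)
    return (start, end)


def assign_variant_ids(diffs, edits, level: str = "protein") -> list[DiffBlock]:
    """Attach VCF identifiers of known variants to diff blocks.

    A block overlapping (in reference coordinates; codon-resolution for
    protein level) exactly one applied edit inherits that edit's VCF ID,
    provided the ID is informative (not ".") and the edit is not a
    frameshift -- frameshift-composite blocks mix the indel with every
    downstream codon and are left unassigned, as are blocks spanning
    multiple variants.
    """
    residues = level == "protein"
    out: list[DiffBlock] = []
    for d in diffs:
        d_start = d.ref_pos if d.kind != INSERTION else max(1, d.ref_pos)
        d_end = d.ref_pos + max(len(d.ref_seq), 1) - 1 if d.kind != INSERTION else d.ref_pos + 1
        candidates = []
        for e in edits:
            es, ee = _edit_ref_interval(e, residues)
            if es <= d_end and d_start <= ee:
                candidates.append(e)
        if len(candidates) == 1:
            e = candidates[0]
            frameshift = residues and e.length_change % 3 != 0
            vid = e.variant.variant_id if e.variant else None
            if vid and vid != "." and not frameshift:
                out.append(replace(d, variant_id=vid))
                continue
        out.append(d)
    return out
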