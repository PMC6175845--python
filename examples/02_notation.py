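"""Haplotype naming: the compact HGVS-like difference notation.

Engineers transcripts whose samples carry specific residue changes and
prints the names the pipeline derives by re-aligning each protein
haplotype to its reference. A stop gain is rendered as a "*" residue
followed by a deletion covering the truncated tail, so
'211R>Q,577R>*,578del(325)' reads: R-to-Q at 211, a premature stop at
577, and loss of the following 325 residues.
"""

import tempfile
from pathlib import Path

from protohap import compute_container, load_reference
from protohap.synthetic_data import engineer_notation_case

CASES = [
    ("ACTN3-001", 902, [(211, "R", "Q"), (577, "R", "*")]),
    ("TLR4-001", 839, [(299, "D", "G"), (399, "T", "I")]),
    ("C5-001", 1676, [(802, "V", "I"), (885, "R", "H")]),
]

for display, length, changes in CASES:
    case = engineer_notation_case(display, length, changes)
    with tempfile.TemporaryDirectory() as tmp:
        d = Path(tmp)
        (d / "e.fa").write_text(case.fasta_text)
        (d / "e.vcf").write_text(case.vcf_text)
        container = compute_container(
            case.transcript, load_reference(d / "e.fa"), str(d / "e.vcf")
        )
    changed = ", ".join(f"{p}{r}>{a}" for p, r, a in changes)
    print(f"{display} ({length} aa reference; engineered {changed}):")
    for t in container.protein_haplotypes:
        print(f"  {t.name}")
    print()
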