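"""Classify protein decoys with the nine-point homolog triage.

BACE-like proteases differ from their soluble cathepsin relatives by a
C-terminal transmembrane stretch, a ~100-residue length excess, and a single
proximal aspartyl active-site (PS00141) match. The classifier turns that
evidence into explicit per-criterion booleans.
"""

from paradiv.simulate import decorate_architecture
from paradiv.triage import classify

ref_bace = decorate_architecture("bace-like", 1000)
ref_caths = [decorate_architecture("cathepsin-like", 2000 + k) for k in range(3)]

for kind, seed in (("bace-like", 7), ("cathepsin-like", 8)):
    candidate = decorate_architecture(kind, seed)
    verdict = classify(candidate, ref_bace, ref_caths)
    print(f"{candidate.id} ({len(candidate)} aa) -> {verdict.label}")
    print(f"  identity to reference: {verdict.identity_pct:.1f}%  "
          f"coverage {verdict.coverage_frac:.2f}  gaps {verdict.gap_pct:.1f}%")
    print(f"  length excess over cathepsin median: {verdict.length_delta:+.0f} aa; "
          f"motifs: {verdict.motif_count}; RBH: {verdict.rbh}")
    print(f"  criteria: {verdict.checks}")
# A bace-like decoy passes all seven criteria; the cathepsin-like one fails
# the mandatory transmembrane test and the corroborative length/motif tests.
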