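"""Haploinsufficiency screen: the segregation of ERK and GluR1 effects.

D1R and Golf are distributed over two signaling compartments by anchors of
different capacity and affinity.  Halving the D1R gene dose empties the
NMDAR-linked compartment (reducing ERK activation) but spares the
AC5-linked one (GluR1 phosphorylation intact); halving Gα-olf does the
opposite.  Knockout of DARPP-32 releases PP1 and blunts both.  Printed are
ratios of psychostimulant-induced fold changes relative to wild type at 15
minutes; each takes ~1 min of stiff ODE integration.
"""
from msnsig.experiments import ModelSession, run_apa_cell

ses = ModelSession(scheme="010", mechanism="yTrf")
values, r2 = run_apa_cell(ses)
for key in ("haploD1R-ERKpp", "haploD1R-GluR1p", "haploGolf-ERKpp",
            "haploGolf-GluR1p", "D32KO-ERKpp", "D32KO-GluR1p"):
    print(f"  {key:18s} {values[key]:5.2f} x WT")
print(f"  mutant-panel r^2 vs experimental targets: {r2:.2f}")
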