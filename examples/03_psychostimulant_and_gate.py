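"""The acute-psychostimulant paradigm and the ERK AND gate.

A psychostimulant dopamine transient (peak 300 nM around 10 minutes)
combined with 0.1 s⁻¹ Ca²⁺ spiking activates ERK at 15 minutes; either
input alone leaves ERK at baseline -- the coincidence-detection property of
the striatal ERK pathway.
"""
from msnsig.experiments import ModelSession
from msnsig.phenotypes import readout

ses = ModelSession(scheme="010", mechanism="yTrf")
arms = {name: ses.run("WT", name) for name in
        ("APA", "saline", "DA_only", "Ca_only")}
base = readout(arms["saline"], "ERKpp", 900.0)
print(f"ERK-pp at 15 min (uM); saline baseline {base:.4f}")
for name in ("APA", "DA_only", "Ca_only"):
    v = readout(arms[name], "ERKpp", 900.0)
    print(f"  {name:8s} {v:7.4f}  (rise {100*(v-base)/base:+6.1f} % of baseline)")
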