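# msnsig

A mass-action kinetic model of dopamine/glutamate signaling in striatal
dopamine-D1-receptor medium spiny neurons (D1R⁺ MSN), written for
researchers studying striatal plasticity and psychostimulant action.

Acute psychostimulants flood the striatum with dopamine.  In D1R⁺ MSNs this
activates two cascades: the AC5/cAMP/PKA axis (read out as GluR1
phosphorylated at Ser845) and the NMDAR/Ca²⁺/RAS/ERK axis (read out as
doubly phosphorylated ERK).  Experimentally the two are *segregated*:
halving D1R reduces ERK activation but not GluR1 phosphorylation, halving
Gα-olf does the reverse — puzzling, because both cascades start from the
same D1R/Golf pair and are coupled by the tyrosine phosphatase STEP.  This
package implements, as tested and reusable code, the modelling programme
that explains the segregation: a ~150-reaction mass-action ODE network in
which

* one common pool of D1R and Golf distributes between two signaling
  compartments (AC5-coupled and NMDAR-coupled) by anchors of opposite
  affinity/capacity asymmetry, and
* STEP-mediated crosstalk is configured by 3-bit schemes
  (crosstalk-at-Fyn&NR2B, crosstalk-at-ERK, one/two STEP pools), with the
  single-pool, ERK-only scheme `010` as the default — sequestration of
  STEP by phospho-ERK (retroactivity) then preserves the segregation.

The library covers network assembly from TSV parameter tables, stiff ODE
simulation with pulsed Ca²⁺/dopamine inputs, the three NMDAR-enhancement
mechanisms (`sSCh`, `ySCh`, `yTrf`), the 17-variable phenotype panel with
Hill/monoexponential compression and immunoblot heterogeneity correction,
genotype experiments (D1R and Gα-olf haploinsufficiency, DARPP-32
knockout), the crosstalk-scheme screen, Poisson-vs-regular spike-train
convergence, and local one-at-a-time parameter sensitivity with the
K_M/k_cat perturbation conventions.

## Worked example

```python
from msnsig import build_network
from msnsig.simulate import equilibrate
from msnsig.phenotypes import marker_value

net, params = build_network(scheme="010")
state = equilibrate(net, params, tol=3e-8)
traj = type("T", (), {"net": net, "params": params, "scaling": None})
for m in ("cAMP", "D32p34", "D32p75", "STEPact"):
    print(m, round(marker_value(traj, m, state), 3))
```

prints the resting phenotype of the wild-type neuron:

```
cAMP 0.062        # µM — basal cAMP ~60 nM
D32p34 0.321      # µM — DARPP-32 phospho-Thr34, the PP1 inhibitor
D32p75 12.145     # µM — DARPP-32 phospho-Thr75, the PKA brake
STEPact 0.715     # fraction of STEP in the active form
```

`examples/` contains one short script per capability: the basal state,
slice pharmacology (tonic DA / tonic NMDA-Ca²⁺), the psychostimulant
paradigm and its ERK AND-gate, the mutant segregation screen, the
compartment-distribution sweep, and the sensitivity conventions.  Each
builds its inputs, runs the model and prints what the numbers mean.

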