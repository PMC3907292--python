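"""Equilibrate the standard model and print the basal phenotype panel.

The resting D1R⁺ medium spiny neuron sees tonic 10 nM dopamine and 60 nM
Ca²⁺.  The printed markers are the experimentally constrained resting
values: cAMP near 60 nM, DARPP-32 phospho-Thr75 around 13 µM with
phospho-Thr34 a hundred-fold lower, and about 80 % of STEP in its active,
non-phosphorylated form.
"""
from msnsig import build_network
from msnsig.simulate import equilibrate
from msnsig.phenotypes import marker_value

net, params = build_network(scheme="010")
print(f"network: {net.n_reactions} reactions, {net.n_species} species, "
      f"{len(params.totals)} conserved pools")
y = equilibrate(net, params, tol=3e-8)

traj = type("T", (), {"net": net, "params": params, "scaling": None})
for marker, unit, scale in [("cAMP", "nM", 1e3), ("D32p34", "uM", 1),
                            ("D32p75", "uM", 1), ("STEPact", "%", 100),
                            ("GluR1p845", "uM", 1), ("ERKpp", "uM", 1)]:
    v = marker_value(traj, marker, y) * scale
    print(f"  basal {marker:10s} {v:8.3f} {unit}")
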