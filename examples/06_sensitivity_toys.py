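"""Local sensitivity analysis: conventions and a reduced real computation.

Normalised sensitivities S = (Δo/o)/(Δp/p) from ±0.5 % central differences.
K_M is perturbed through k_f; k_cat perturbations co-scale k_f and k_r so
K_M stays fixed.  The full 316-parameter matrix is a batch job; here we
probe a handful of parameters against the basal markers.
"""
from msnsig import build_network
from msnsig.simulate import equilibrate
from msnsig.phenotypes import marker_value
from msnsig.sensitivity import sensitivity_matrix, perturb

net, params = build_network(scheme="010")

def evaluate(p):
    y = equilibrate(net, p, tol=1e-7)
    traj = type("T", (), {"net": net, "params": p, "scaling": None})
    return {m: marker_value(traj, m, y) for m in ("cAMP", "D32p34", "D32p75")}

targets = [("total", "AC5"), ("kcat", "cyc_golf"), ("KM", "pde4_camp"),
           ("total", "CDK5")]
sm = sensitivity_matrix(evaluate, params, targets, ["cAMP", "D32p34", "D32p75"])
print("normalised sensitivities (rows: parameters):")
print(sm.to_frame().round(3))
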