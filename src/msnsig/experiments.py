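"""In-silico experiments: the acute-psychostimulant grid over genotypes ×
crosstalk schemes, compartment-distribution sweeps, the culture
sensitization assay, Poisson-vs-regular convergence, and the PP2B-inhibition
scenario.

All experiments start from a freshly equilibrated basal state of the
configured model (mutants re-equilibrate after their totals are rescaled)
and share a WT-calibrated NMDAR-enhancement mechanism, so a mutant with less
membrane NMDAR genuinely sees weaker Ca²⁺ enhancement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .network import apply_genotype, SCHEME_CODES
from .model_def import build_default, build_network, DEFAULT_F
from .stimuli import protocol
from .simulate import (equilibrate, simulate, calibrate_mechanism,
                       ScalingState, nmdar_ratio)
from .phenotypes import (readout, wt_ratio, marker_series, fit_hill,
                               load_panel, evaluate_panel)

MUTANTS = ("Drd1a_het", "Gnal_het", "D32KO")
MUTANT_PANEL_VARS = ("haploD1R-ERKpp", "haploD1R-GluR1p",
                     "haploGolf-ERKpp", "haploGolf-GluR1p",
                     "D32KO-ERKpp", "D32KO-GluR1p")
_GENO_TO_VAR = {"Drd1a_het": "haploD1R", "Gnal_het": "haploGolf",
                "D32KO": "D32KO"}


def run_key(**kw) -> str:
    """Content hash identifying one run (used for caching grid cells)."""
    blob = json.dumps(kw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ModelSession:
    """A configured model (scheme, mechanism, compartments) with its
    equilibrated WT state and calibrated scaling, reused across arms."""
    scheme: str = "010"
    mechanism: str = "yTrf"
    two_compartments: bool = True
    eq_tol: float = 3e-8
    F: float | None = None          # None -> packaged calibrated value
    recalibrate: bool = False       # force a fresh calibration

    def __post_init__(self):
        self.net, self.params = build_network(
            scheme=self.scheme, two_compartments=self.two_compartments)
        self.basal = equilibrate(self.net, self.params, tol=self.eq_tol)
        r0 = nmdar_ratio(self.net, self.basal, self.mechanism,
                         self.params.totals["NMDAR"])
        if self.recalibrate:
            self.scaling = calibrate_mechanism(self.net, self.params,
                                               self.basal, self.mechanism)
        else:
            F = DEFAULT_F[self.mechanism] if self.F is None else self.F
            self.scaling = ScalingState(self.mechanism, F, r0)
        self._mutant_states = {}

    def genotype_state(self, genotype):
        if genotype == "WT":
            return self.params, self.basal
        if genotype not in self._mutant_states:
            pg = apply_genotype(self.params, genotype)
            yg = equilibrate(self.net, pg, tol=self.eq_tol)
            self._mutant_states[genotype] = (pg, yg)
        return self._mutant_states[genotype]

    def run(self, genotype, protocol_name, duration=960.0,
            readout_s=(900.0,), seed=None, spike_kind=None, dt=30.0, **over):
        pg, yg = self.genotype_state(genotype)
        proto = protocol(protocol_name, duration=duration,
                         readout_s=tuple(readout_s), **over)
        if spike_kind is not None:
            proto.spike_kind = spike_kind
        return simulate(self.net, pg, yg, proto, scaling=self.scaling,
                        genotype=genotype, scheme=self.scheme, seed=seed,
                        dt=dt)


# ---------------------------------------------------------------------------
# APA grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentGrid:
    genotypes: tuple = ("WT",) + MUTANTS
    schemes: tuple = SCHEME_CODES
    mechanisms: tuple = ("yTrf",)
    readout_min: float = 15.0
    seeds: tuple = (None,)


def run_apa_cell(session: ModelSession, t_read=900.0):
    """ERKpp and GluR1p WT-ratios at the readout time for one (scheme,
    mechanism) cell, plus the panel r² over the mutant phenotypes."""
    wt_apa = session.run("WT", "APA")
    wt_sal = session.run("WT", "saline")
    values = {}
    for g in MUTANTS:
        try:
            apa = session.run(g, "APA")
            sal = session.run(g, "saline")
        except RuntimeError as exc:     # failed cell: record, keep going
            values[f"{_GENO_TO_VAR[g]}-ERKpp"] = np.nan
            values[f"{_GENO_TO_VAR[g]}-GluR1p"] = np.nan
            values[f"{_GENO_TO_VAR[g]}-error"] = str(exc)
            continue
        values[f"{_GENO_TO_VAR[g]}-ERKpp"] = wt_ratio(
            apa, sal, wt_apa, wt_sal, "ERKpp", t_read)
        values[f"{_GENO_TO_VAR[g]}-GluR1p"] = wt_ratio(
            apa, sal, wt_apa, wt_sal, "GluR1p845", t_read)
    panel = load_panel()
    sim = {k: v for k, v in values.items() if not k.endswith("error")}
    ok = [k for k in MUTANT_PANEL_VARS if np.isfinite(sim.get(k, np.nan))]
    _df, r2 = evaluate_panel(sim, [p for p in panel if p.name in ok],
                             r2_subset=ok)
    return values, r2


def run_apa_grid(schemes=SCHEME_CODES, mechanism="yTrf", F=None):
    """The scheme screen: mutant ratios and panel r² per crosstalk scheme."""
    results = {}
    for code in schemes:
        session = ModelSession(scheme=code, mechanism=mechanism, F=F)
        values, r2 = run_apa_cell(session)
        results[code] = {"values": values, "r2": r2}
    return results


# ---------------------------------------------------------------------------
# compartment sweep
# ---------------------------------------------------------------------------

def compartment_sweep(ligand="D1R", fractions=(0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
                      eq_tol=3e-8):
    """Equilibrium occupancy of the AC5- and NMDAR-compartments as a function
    of total dosage (fraction of the WT total)."""
    if ligand not in ("D1R", "Golf"):
        raise ValueError("ligand must be D1R or Golf")
    net, base = build_default()
    params = net.apply_scheme(base, "010")
    rows = []
    for frac in fractions:
        p = params.copy()
        if ligand == "D1R":
            p.totals["D1R"] = base.totals["D1R"] * frac
        else:
            p.totals["Gaolf"] = base.totals["Gaolf"] * frac
            p.totals["Gbg"] = base.totals["Gbg"] * frac
        y = equilibrate(net, p, tol=eq_tol)
        if ligand == "D1R":
            in_a = sum(y[net.index[s]] for s in ("D1R_A", "D1RDA_A"))
            in_a += y[net.index["cx_gef_A"]]
            in_n = sum(y[net.index[s]] for s in ("D1R_N", "D1RDA_N"))
            in_n += y[net.index["cx_gef_N"]]
        else:
            w = net.moiety_vector("Gaolf")
            mask_a = np.array([s.compartment == "D1R_Golf_AC5" for s in net.species])
            mask_n = np.array([s.compartment == "D1R_Golf_NMDAR" for s in net.species])
            in_a = float((w * mask_a) @ y)
            in_n = float((w * mask_n) @ y)
        rows.append({"fraction": frac, "AC5_compartment": float(in_a),
                     "NMDAR_compartment": float(in_n)})
    return rows


# ---------------------------------------------------------------------------
# culture sensitization (single scaled Ca²⁺ transient, DA 3 µM)
# ---------------------------------------------------------------------------

def sensitization_assay(mechanism="yTrf", amplitudes=(0.2, 0.4, 0.6, 0.9,
                                                      1.3, 2.0, 3.0),
                        da_level=3.0, read_min=8.0, F=None, session=None):
    """Ratio of half-activating Ca²⁺ amplitude without over with dopamine.

    A ratio > 1 means dopamine left-shifts the ERK dose-response curve
    (sensitization); mechanisms too slow to boost the early transient give
    a ratio near 1.
    """
    if session is None:
        session = ModelSession(scheme="010", mechanism=mechanism, F=F)
    read_s = 60.0 + read_min * 60.0

    def dose_curve(da):
        resp = []
        for amp in amplitudes:
            traj = session.run("WT", "culture_sensitization",
                               duration=read_s + 60.0, readout_s=(read_s,),
                               da=da, single_spikes=((60.0, amp),))
            resp.append(readout(traj, "ERKpp", read_s))
        return np.array(resp)

    with_da = dose_curve(da_level)
    without = dose_curve(0.010)
    k_with = fit_hill(np.array(amplitudes), with_da)["K"]
    k_without = fit_hill(np.array(amplitudes), without)["K"]
    return {"K_without": k_without, "K_with": k_with,
            "ratio": k_without / k_with,
            "curve_with": with_da.tolist(), "curve_without": without.tolist()}


# ---------------------------------------------------------------------------
# Poisson-vs-regular convergence
# ---------------------------------------------------------------------------

def poisson_convergence(n_replicates=20, seed=0, session=None,
                        duration=2700.0, dt=30.0):
    """R² between the mean of n Poisson-train ERK time courses and the
    regular-train time course over the APA paradigm."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if session is None:
        session = ModelSession(scheme="010", mechanism="yTrf")
    reg = session.run("WT", "APA", duration=duration, readout_s=(900.0,), dt=dt)
    ref = marker_series(reg, "ERKpp")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_replicates):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        traj = session.run("WT", "APA", duration=duration, readout_s=(900.0,),
                           seed=sub, spike_kind="poisson", dt=dt)
        ser = np.interp(reg.t, traj.t, marker_series(traj, "ERKpp"))
        acc = ser if acc is None else acc + ser
    mean = acc / n_replicates
    ss_res = float(np.sum((mean - ref) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    return {"r2": 1.0 - ss_res / ss_tot, "t": reg.t, "regular": ref,
            "poisson_mean": mean}


# ---------------------------------------------------------------------------
# PP2B inhibition (cyclosporin-A scenario under tonic high Ca²⁺)
# ---------------------------------------------------------------------------

def pp2b_inhibition(session=None, duration=600.0):
    """Paired trajectories ± PP2B under tonic 10 µM Ca²⁺: with calcineurin
    blocked, phospho-STEP stays high (PP1 remains inhibited), so ERK
    activation by the Ca²⁺/glutamate input is larger."""
    if session is None:
        session = ModelSession(scheme="010", mechanism="yTrf")
    control = session.run("WT", "PP2B_inhibition", duration=duration,
                          readout_s=(duration,))
    inhibited = session.run("WT", "PP2B_inhibition", duration=duration,
                            readout_s=(duration,), pp2b_inhibited=True)
    out = {}
    for m in ("STEPp", "ERKpp"):
        out[m] = {"control": marker_series(control, m),
                  "inhibited": marker_series(inhibited, m)}
    out["t"] = control.t
    return out
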