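"""Phenotypic variables: marker readouts, fold changes, WT ratios, the
immunoblot heterogeneity correction, and Hill / monoexponential compression
of dose-response and time-series data.

The default panel holds 17 phenotypic variables: four basal markers (cAMP,
active-STEP fraction, DARPP-32-Thr34, DARPP-32-Thr75), the DA- and
NMDA-slice fold changes of the two DARPP-32 sites, the Hill parameters
(h, K) of Ca²⁺-triggered RAS·RAF formation, the monoexponential rate of
DA-driven NMDAR traffic, and the ERK / GluR1 ratios-to-WT for the three
mutants under acute psychostimulant administration.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stimuli import hill_curve, monoexp_curve

MARKER_NAMES = ("cAMP", "D32p34", "D32p75", "STEPact", "ERKpp", "GluR1p845",
                "RASRAF_fraction", "STEPp", "NMDAR_current_scale")


def _sum_tag(traj_or_net, state, tag):
    net = getattr(traj_or_net, "net", traj_or_net)
    mask = np.array([tag in s.tags for s in net.species])
    return float(state @ mask)


def marker_value(traj, marker, state):
    """Marker from a full state vector, summing over every species that
    carries the corresponding modification (free and complexed)."""
    net = traj.net
    if marker == "cAMP":
        return float(state[net.index["cAMP"]])
    if marker == "D32p34":
        return _sum_tag(net, state, "p34")
    if marker == "D32p75":
        return _sum_tag(net, state, "p75")
    if marker == "STEPact":
        tot = traj.params.totals["STEP"] + traj.params.totals["STEP2"]
        return _sum_tag(net, state, "STEPu") / tot
    if marker == "STEPp":
        return _sum_tag(net, state, "STEPph")
    if marker == "ERKpp":
        return _sum_tag(net, state, "ERKpp")
    if marker == "GluR1p845":
        return _sum_tag(net, state, "GluR1p")
    if marker == "RASRAF_fraction":
        return _sum_tag(net, state, "RASRAF") / traj.params.totals["RAS"]
    if marker == "NMDAR_current_scale":
        if traj.scaling is None:
            raise ValueError("trajectory has no scaling mechanism attached")
        from .simulate import nmdar_ratio
        r = nmdar_ratio(net, state, traj.scaling.mechanism,
                        traj.params.totals["NMDAR"])
        return traj.scaling.factor(r)
    raise KeyError(f"unknown marker {marker!r}")


def readout(traj, marker, t):
    """Marker value at time t (s) of a trajectory."""
    return marker_value(traj, marker, traj.state_at(t))


def marker_series(traj, marker):
    return np.array([marker_value(traj, marker, traj.y[:, i])
                     for i in range(traj.y.shape[1])])


# ---------------------------------------------------------------------------
# immunoblot heterogeneity correction
# ---------------------------------------------------------------------------

def ib_correction(W, f_c, f_t):
    """Cell-specific fold change from a whole-sample Western-blot fold change.

    The sample is a mixture: every cell contributes the basal marker level,
    the responsive cell type is the fraction ``f_c`` of cells (its positive
    fraction in the control), and upon treatment the fraction ``f_t`` of
    those respond, moving from basal to FC-fold.  The blot then measures
    W = 1 + f_c·f_t·(FC − 1), which is inverted here.  The correction is the
    identity for a homogeneous, fully responding sample (f_c = f_t = 1).
    """
    for f in (f_c, f_t):
        if not (0 < f <= 1):
            raise ValueError("fractions must lie in (0, 1]")
    if W <= 0:
        raise ValueError("fold change W must be positive")
    return 1.0 + (W - 1.0) / (f_c * f_t)


def ib_forward(FC, f_c, f_t):
    """Forward mixture: whole-sample fold change produced by a cell-specific
    fold change FC (the model ib_correction inverts)."""
    return 1.0 + f_c * f_t * (FC - 1.0)


# ---------------------------------------------------------------------------
# parametric compression
# ---------------------------------------------------------------------------

def fit_hill(doses, responses):
    """Least-squares Hill fit; returns dict with C_min, C_max, K, h, r2."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 dose points")
    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y.max()), 1.0):
        raise RuntimeError("flat dose response: K and h unidentifiable")
    p0 = [y.min(), y.max(), x[np.argmin(np.abs(y - (y.min() + span / 2)))], 2.0]
    popt, _ = curve_fit(hill_curve, x, y, p0=p0,
                        bounds=([-np.inf, -np.inf, x.min() / 100, 0.1],
                                [np.inf, np.inf, x.max() * 100, 20.0]),
                        maxfev=20000)
    yhat = hill_curve(x, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {"C_min": popt[0], "C_max": popt[1], "K": popt[2], "h": popt[3],
            "r2": 1.0 - ss_res / ss_tot}


def fit_monoexp(times, values):
    """Fit A·(1 − e^{−kt}); returns dict with A, k, r2 (k in the unit of
    1/times).  Warns (in the result) on non-monotone data."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    span = abs(y).max()
    if span <= 1e-15:
        return {"A": 0.0, "k": 0.0, "r2": 1.0, "flat": True}
    k0 = 1.0 / max(t.max() / 3.0, 1e-12)
    popt, _ = curve_fit(monoexp_curve, t, y, p0=[y[-1] if y[-1] else span, k0],
                        maxfev=20000)
    yhat = monoexp_curve(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    out = {"A": popt[0], "k": abs(popt[1]), "r2": r2}
    dy = np.diff(y)
    if np.any(dy < -0.05 * span):
        out["warning"] = "non-monotone data"
    return out


# ---------------------------------------------------------------------------
# ratios and panel evaluation
# ---------------------------------------------------------------------------

def fold_change(traj, saline, marker, t):
    num = readout(traj, marker, t)
    den = readout(saline, marker, t)
    if den == 0:
        raise ZeroDivisionError(f"zero baseline for {marker}")
    return num / den


def wt_ratio(mut_traj, mut_saline, wt_traj, wt_saline, marker, t):
    """(mutant fold change over saline) / (WT fold change over saline)."""
    wt_fc = fold_change(wt_traj, wt_saline, marker, t)
    if wt_fc == 0:
        raise ZeroDivisionError("zero WT fold change")
    return fold_change(mut_traj, mut_saline, marker, t) / wt_fc


@dataclass(frozen=True)
class PanelVariable:
    name: str
    target: float
    target_hi: float | None      # upper bound for range targets, else None
    mode: str                    # absolute | fold-over-basal | ratio-to-WT | fitted-parameter
    units: str = ""


def load_panel(path=None) -> list:
    """The packaged experimental target panel (17 phenotypic variables)."""
    if path is None:
        path = importlib.resources.files("msnsig").joinpath("data/panel.csv")
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        hi = None if pd.isna(r["target_hi"]) else float(r["target_hi"])
        out.append(PanelVariable(r["variable"], float(r["target"]), hi,
                                 r["mode"], r.get("units", "")))
    return out


def divergence(var: PanelVariable, value: float) -> float:
    """Relative divergence; zero anywhere inside a range target, linear
    outside of it."""
    lo = var.target
    hi = var.target_hi if var.target_hi is not None else var.target
    if lo <= value <= hi:
        return 0.0
    ref = lo if value < lo else hi
    return abs(value - ref) / abs(ref)


def evaluate_panel(simulated: dict, panel: list, r2_subset=None):
    """Per-variable divergence plus r² between simulated and target values.

    ``simulated`` maps variable name -> value.  r² = 1 − SS_res/SS_tot over
    the (sub)set of panel values (range targets contribute their midpoint),
    the same summary used to rank crosstalk schemes on the mutant panel.
    """
    rows = []
    for var in panel:
        if var.name not in simulated:
            raise KeyError(f"missing simulated value for {var.name}")
        v = simulated[var.name]
        rows.append({"variable": var.name, "simulated": v,
                     "target": var.target, "target_hi": var.target_hi,
                     "mode": var.mode, "divergence": divergence(var, v)})
    df = pd.DataFrame(rows)
    names = r2_subset if r2_subset is not None else [v.name for v in panel]
    tgt = []
    sim = []
    by_name = {v.name: v for v in panel}
    for nm in names:
        var = by_name[nm]
        mid = var.target if var.target_hi is None else 0.5 * (var.target + var.target_hi)
        tgt.append(mid)
        sim.append(simulated[nm])
    tgt = np.asarray(tgt)
    sim = np.asarray(sim)
    ss_tot = float(np.sum((tgt - tgt.mean()) ** 2))
    r2 = 1.0 - float(np.sum((tgt - sim) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return df, r2
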