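"""Local one-at-a-time parameter sensitivity.

Normalised sensitivities S_ij = (Δo_i/o_i) / (Δp_j/p_j) from central
differences with a total relative perturbation of 1 % (two runs at ±0.5 %).
Perturbable parameters follow the enzymatic-reaction convention: for each
enzymatic reaction only k_cat and K_M are free -- K_M is perturbed through
k_f with a factor (1 ± 0.005)⁻¹ (k_cat untouched), and k_cat perturbations
multiply k_cat, k_f and k_r jointly so K_M stays fixed.  Non-enzymatic rate
constants and the conserved totals are perturbed directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DELTA = 0.005   # half of the 1 % total relative perturbation


def parameter_targets(net, params):
    """Ordered list of perturbable parameters: (kind, key) with kind in
    {KM, kcat, rate, total}."""
    targets = []
    for r in net.reactions:
        if r.klass == "enzymatic":
            targets.append(("KM", r.id))
            targets.append(("kcat", r.id))
        elif r.klass == "reversible":
            targets.append(("rate", (r.id, "kf")))
            targets.append(("rate", (r.id, "kr")))
        else:
            targets.append(("rate", (r.id, "kf")))
    for m in params.totals:
        targets.append(("total", m))
    return targets


def perturb(params, target, direction="+", delta=DELTA):
    """Return a copy of the parameter set with one parameter nudged."""
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    f = 1.0 + delta if direction == "+" else 1.0 - delta
    kind, key = target
    out = params.copy()
    if kind == "kcat":
        for name in ("kcat", "kf", "kr"):
            out.constants[(key, name)] *= f
    elif kind == "KM":
        out.constants[(key, "kf")] /= f
    elif kind == "rate":
        if key not in out.constants:
            raise KeyError(f"unknown rate constant {key}")
        out.constants[key] *= f
    elif kind == "total":
        if key not in out.totals:
            raise KeyError(f"unknown total {key}")
        out.totals[key] *= f
    else:
        raise KeyError(f"unknown target kind {kind}")
    return out


def target_label(target):
    kind, key = target
    if kind == "rate":
        return f"{key[0]}.{key[1]}"
    if kind == "total":
        return f"TA.{key}"
    return f"{key}.{kind}"


@dataclass
class SensitivityMatrix:
    S: np.ndarray                 # parameters × outputs
    parameters: list
    outputs: list
    delta: float = DELTA

    def to_frame(self):
        return pd.DataFrame(self.S, index=[target_label(t) for t in self.parameters],
                            columns=self.outputs)

    def max_per_parameter(self):
        return np.nanmax(np.abs(self.S), axis=1)

    def mean_per_parameter(self):
        return np.nanmean(np.abs(self.S), axis=1)

    def ranking(self):
        """Parameters ordered by the sum of |S_ij| across outputs."""
        score = np.nansum(np.abs(self.S), axis=0 * 0 + 1)
        order = np.argsort(score)[::-1]
        return [(target_label(self.parameters[i]), float(score[i])) for i in order]


def sensitivity_matrix(evaluate, params, targets, outputs, delta=DELTA,
                       cache=None, progress=None):
    """Central-difference sensitivity of ``evaluate`` over ``targets``.

    ``evaluate(params) -> dict output -> value`` runs the model; failures in
    a perturbed run flag the corresponding row as missing (NaN) rather than
    aborting the matrix.  ``cache`` (a dict) makes the computation resumable.
    """
    base = evaluate(params)
    o0 = np.array([base[k] for k in outputs], dtype=float)
    if np.any(o0 == 0):
        zeros = [k for k, v in zip(outputs, o0) if v == 0]
        raise ZeroDivisionError(f"baseline output is zero for {zeros}")
    S = np.full((len(targets), len(outputs)), np.nan)
    for j, target in enumerate(targets):
        key = target_label(target)
        if cache is not None and key in cache:
            S[j] = cache[key]
            continue
        try:
            up = evaluate(perturb(params, target, "+", delta))
            dn = evaluate(perturb(params, target, "-", delta))
            o_up = np.array([up[k] for k in outputs], dtype=float)
            o_dn = np.array([dn[k] for k in outputs], dtype=float)
            S[j] = (o_up - o_dn) / o0 / (2 * delta)
        except Exception:
            pass        # row stays NaN and is reported as missing
        if cache is not None:
            cache[key] = S[j].copy()
        if progress is not None:
            progress(j, len(targets))
    return SensitivityMatrix(S, list(targets), list(outputs), delta)


# ---------------------------------------------------------------------------
# sensitive sets and overlap
# ---------------------------------------------------------------------------

def sensitive_sets(sm: SensitivityMatrix, threshold=None):
    """Per-output sets of sensitive parameters plus summary statistics.

    The default threshold is the median of the per-parameter maxima of
    |S_ij| across outputs, the demarcation between insensitive and sensitive
    parameters."""
    A = np.abs(sm.S)
    valid = ~np.all(np.isnan(A), axis=1)
    maxima = np.nanmax(np.where(np.isnan(A), -np.inf, A), axis=1)
    maxima[~valid] = np.nan
    if threshold is None:
        threshold = float(np.nanmedian(maxima)) if valid.any() else 0.0
        if not np.isfinite(threshold):
            threshold = 0.0
    labels = [target_label(t) for t in sm.parameters]
    sets = {}
    for i, out in enumerate(sm.outputs):
        col = A[:, i]
        sets[out] = {labels[j] for j in range(len(labels))
                     if np.isfinite(col[j]) and col[j] > threshold}
    n_pairs = np.isfinite(A).sum()
    frac_pairs = float((A > threshold).sum()) / n_pairs if n_pairs else 0.0
    mean_abs = np.nanmean(A, axis=1)
    frac_params = float(np.mean(mean_abs[valid] > threshold)) if valid.any() else 0.0
    return {"sets": sets, "threshold": threshold,
            "max_per_parameter": maxima,
            "fraction_sensitive_pairs": frac_pairs,
            "fraction_sensitive_parameters_mean": frac_params,
            "n_missing": int((~valid).sum())}


def overlap(set_a, set_b) -> float:
    """|A ∩ B| / max(|A|, |B|); zero when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0
    return len(a & b) / max(len(a), len(b))
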