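"""Stiff ODE integration of the network under a stimulus protocol.

The reaction system is compiled once into index arrays; the right-hand side
is plain vectorised mass action.  Dopamine and Ca²⁺ enter as clamped inputs
appended to the state vector.  Spike trains are handled by restarting the
integrator at every spike onset, where the spike amplitude is fixed to
(C_max − C_b) times the NMDAR-enhancement factor evaluated from the current
state -- this closes the loop from signaling state back to the Ca²⁺ input.

Scaling mechanisms (all normalised to 1 at the equilibrated basal state,
factor = 1 + F·(r/r₀ − 1)):

* ``sSCh`` -- r = PKA-phosphorylated membrane NMDAR / membrane NMDAR
  (fast single-channel conductance effect of the PKA site);
* ``yTrf`` -- r = membrane NMDAR / total NMDAR (Fyn/NR2B-Y1472 traffic);
* ``ySCh`` -- r = Y1472-phosphorylated membrane NMDAR / membrane NMDAR
  (fast single-channel effect of tyrosine phosphorylation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, ParameterSet
from .stimuli import StimulusProtocol, spike_train

MECHANISMS = ("sSCh", "yTrf", "ySCh")

#: spike contributions are dropped once they decay below this level (µM)
SPIKE_FLOOR = 1e-7


class CompiledModel:
    """Mass-action right-hand side compiled to index arrays."""

    def __init__(self, net: ReactionNetwork, params: ParameterSet):
        self.net = net
        self.params = params
        n = net.n_species
        self.n = n
        steps = net.elementary_steps(params)
        m = len(steps)
        self.k = np.array([s[1] for s in steps])
        # up to three reactant slots per step (index into extended state;
        # n -> DA, n+1 -> Ca, n+2 -> constant 1)
        self.ext_index = {"DA": n, "Ca": n + 1}
        pad = n + 2
        slots = np.full((m, 3), pad, dtype=np.int64)
        S = sparse.lil_matrix((n, m))
        for j, (_key, _k, lhs, rhs) in enumerate(steps):
            flat = []
            for sid, cnt in lhs:
                idx = self.ext_index.get(sid, None)
                if idx is None:
                    idx = net.index[sid]
                flat.extend([idx] * cnt)
            if len(flat) > 3:
                raise ValueError("more than trimolecular step")
            slots[j, :len(flat)] = flat
            for sid, cnt in lhs:
                if sid not in self.ext_index:
                    S[net.index[sid], j] -= cnt
            for sid, cnt in rhs:
                if sid not in self.ext_index:
                    S[net.index[sid], j] += cnt
        self.slots = slots
        self.S = S.tocsr()
        # Jacobian sparsity: dy_i/dy_l nonzero if step j consumes l and moves i
        R = sparse.lil_matrix((m, n))
        for j in range(m):
            for idx in slots[j]:
                if idx < n:
                    R[j, idx] = 1
        self.jac_sparsity = (abs(self.S) @ R.tocsr()).astype(bool)

    def rhs(self, t, y, da_fun, ca_fun):
        ext = np.empty(self.n + 3)
        ext[:self.n] = y
        ext[self.n] = da_fun(t)
        ext[self.n + 1] = ca_fun(t)
        ext[self.n + 2] = 1.0
        rates = self.k * ext[self.slots[:, 0]] * ext[self.slots[:, 1]] \
            * ext[self.slots[:, 2]]
        return self.S @ rates

    def jac(self, t, y, da_fun, ca_fun):
        """Analytic sparse Jacobian of the mass-action right-hand side.
        Duplicate reactant slots sum in the COO assembly, which yields the
        correct 2·k·y derivative for second-order self-reactions."""
        ext = np.empty(self.n + 3)
        ext[:self.n] = y
        ext[self.n] = da_fun(t)
        ext[self.n + 1] = ca_fun(t)
        ext[self.n + 2] = 1.0
        c = [ext[self.slots[:, p]] for p in range(3)]
        m = self.slots.shape[0]
        j_idx = np.arange(m)
        rows, cols, data = [], [], []
        for p in range(3):
            others = [q for q in range(3) if q != p]
            partial = self.k * c[others[0]] * c[others[1]]
            idx = self.slots[:, p]
            mask = idx < self.n
            rows.append(j_idx[mask])
            cols.append(idx[mask])
            data.append(partial[mask])
        dR = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(m, self.n)).tocsr()
        return (self.S @ dR).tocsc()


# ---------------------------------------------------------------------------
# scaling factors
# ---------------------------------------------------------------------------

def _tag_mask(net, *required):
    req = set(required)
    return np.array([req <= s.tags for s in net.species])


@dataclass
class ScalingState:
    """NMDAR-enhancement mechanism with its calibrated fold constant F and
    the basal normalisation ratio r0 (factor == 1 at the basal state)."""
    mechanism: str
    F: float
    r0: float

    def factor(self, ratio: float) -> float:
        return 1.0 + self.F * (ratio / self.r0 - 1.0)


def nmdar_ratio(net: ReactionNetwork, state: np.ndarray, mechanism: str,
                nmdar_total: float) -> float:
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    mem = _tag_mask(net, "NR_mem")
    if mechanism == "yTrf":
        return float(state @ mem) / nmdar_total
    num = _tag_mask(net, "NR_mem", "NR_Sp" if mechanism == "sSCh" else "NR_Yp")
    denom = float(state @ mem)
    if denom <= 0:
        raise ZeroDivisionError("no membrane NMDAR in state")
    return float(state @ num) / denom


def scaling_factor(net, state, scaling: ScalingState, nmdar_total: float) -> float:
    return scaling.factor(nmdar_ratio(net, state, scaling.mechanism, nmdar_total))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    t: np.ndarray                 # seconds from protocol onset
    y: np.ndarray                 # species × time, µM
    net: ReactionNetwork
    params: ParameterSet
    protocol: StimulusProtocol
    genotype: str = "WT"
    scheme: str | None = None
    mechanism: str | None = None
    scaling: ScalingState | None = None
    spike_onsets: np.ndarray | None = None
    spike_amplitudes: np.ndarray | None = None

    def state_at(self, time: float) -> np.ndarray:
        if not (self.t[0] - 1e-9 <= time <= self.t[-1] + 1e-9):
            raise ValueError(f"time {time} outside trajectory span")
        out = np.empty(self.y.shape[0])
        for i in range(self.y.shape[0]):
            out[i] = np.interp(time, self.t, self.y[i])
        return out

    def moiety_drift(self) -> float:
        """Worst relative drift of any conserved total along the trajectory."""
        worst = 0.0
        for m, total in self.params.totals.items():
            w = self.net.moiety_vector(m)
            series = w @ self.y
            ref = max(abs(total), 1e-12)
            worst = max(worst, float(np.max(np.abs(series - total))) / ref)
        return worst

    def min_concentration(self) -> float:
        return float(self.y.min())

    def to_frame(self):
        import pandas as pd
        recs = pd.DataFrame(self.y.T, columns=[s.id for s in self.net.species])
        recs.insert(0, "time", self.t)
        return recs.melt(id_vars="time", var_name="species", value_name="value")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _solve(cm, y0, t0, t1, da_fun, ca_fun, t_eval, rtol, atol, max_step=np.inf):
    sol = solve_ivp(cm.rhs, (t0, t1), y0, method="BDF",
                    t_eval=t_eval, args=(da_fun, ca_fun),
                    jac=cm.jac, rtol=rtol, atol=atol,
                    max_step=max_step)
    if not sol.success:
        raise RuntimeError(f"solver failed at t={sol.t[-1] if sol.t.size else t0}: "
                           f"{sol.message}")
    return sol


def equilibrate(net, params, da=0.010, ca=0.060, tol=1e-8, horizon=1e6,
                rtol=1e-8, atol=1e-12, y0=None):
    """Integrate the unstimulated system to its basal steady state.

    Runs increasingly long windows up to ``horizon`` seconds until the
    plateau criterion max_i |dc_i/dt| / max(c_i, 1 nM) < tol (s⁻¹) holds;
    raises with the worst offenders listed otherwise.  Slow compartment
    exchange makes the last decades of the horizon matter.
    """
    cm = CompiledModel(net, params)
    y = net.initial_state(params) if y0 is None else np.array(y0, dtype=float)
    da_fun = lambda t: da
    ca_fun = lambda t: ca
    t = 0.0
    for t_end in (1e3, 1e4, 1e5, horizon, 3 * horizon, 10 * horizon,
                  30 * horizon):
        if t_end <= t:
            continue
        sol = _solve(cm, y, t, t_end, da_fun, ca_fun, None, rtol, atol)
        y = sol.y[:, -1]
        t = t_end
        dy = cm.rhs(t, y, da_fun, ca_fun)
        rel = np.abs(dy) / np.maximum(np.abs(y), 1e-3)
        if float(rel.max()) < tol:
            return y
    order = np.argsort(rel)[::-1][:5]
    worst = ", ".join(f"{net.species[i].id}:{rel[i]:.2e}" for i in order)
    raise RuntimeError(f"no steady state within {horizon:g} s; worst rates: {worst}")


def simulate(net, params, y0, protocol: StimulusProtocol, scaling=None,
             genotype="WT", scheme=None, seed=None, dt=5.0,
             rtol=1e-6, atol=1e-12, train=None) -> Trajectory:
    """Run one protocol from an initial state (usually the equilibrated basal
    state).  The integrator restarts at every spike onset so the narrow Ca²⁺
    transients are never stepped over."""
    params = params.copy()
    if protocol.pp2b_inhibited:
        for rid in ("pp2b_34", "pp2b_3475"):
            params.constants[(rid, "kcat")] = 0.0
    cm = CompiledModel(net, params)
    nmdar_total = params.totals["NMDAR"]

    T = protocol.duration
    if train is None and protocol.spike_rate > 0:
        train = spike_train(protocol.spike_rate, T, protocol.spike_kind, seed)
    onsets = list(train.times) if train is not None else []
    onsets += [t0 for t0, _a in protocol.single_spikes]
    explicit = {t0: a for t0, a in protocol.single_spikes}
    onsets = sorted(set(onsets))

    da_fun = protocol.da_value
    base_amp = (protocol.spike.C_max - protocol.spike.C_b) \
        if protocol.spike is not None else 0.0
    k1 = protocol.spike.k1 if protocol.spike is not None else 1.0
    k2 = protocol.spike.k2 if protocol.spike is not None else 0.5
    tpk = np.log(k1 / k2) / (k1 - k2)
    norm = np.exp(-k2 * tpk) - np.exp(-k1 * tpk)
    # how long a spike contributes, and the step cap resolving its rise
    t_mem = np.log(max(base_amp, *(a for _t, a in protocol.single_spikes),
                       1e-3) / SPIKE_FLOOR) / k2
    spike_cap = max(tpk / 4.0, 0.01)

    active: list = []   # (onset, amplitude)

    def ca_fun(t):
        c = protocol.ca_level
        for t0, a in active:
            dtau = t - t0
            if 0.0 <= dtau <= t_mem:
                c += a * (np.exp(-k2 * dtau) - np.exp(-k1 * dtau)) / norm
        return c

    t_grid = np.unique(np.concatenate([
        np.arange(0.0, T + dt / 2, dt), np.asarray(protocol.readout_s, dtype=float)]))
    t_grid = t_grid[t_grid <= T + 1e-9]

    ts, ys = [np.array([0.0])], [np.array(y0, dtype=float)[:, None]]
    y = np.array(y0, dtype=float)
    t_prev = 0.0
    amps = []
    bounds = onsets + [T]

    def advance(y, t_from, t_to, cap):
        seg_eval = t_grid[(t_grid > t_from + 1e-9) & (t_grid <= t_to + 1e-9)]
        sol = _solve(cm, y, t_from, t_to, da_fun, ca_fun,
                     seg_eval if seg_eval.size else None, rtol, atol,
                     max_step=cap)
        if seg_eval.size:
            ts.append(sol.t)
            ys.append(sol.y)
        return sol.y[:, -1]

    for t_next in bounds:
        if t_next > t_prev + 1e-9:
            # resolve the just-started spike transient with capped steps,
            # then run free to the next onset
            t_cap_end = min(active[-1][0] + t_mem, t_next) if active else t_prev
            if active and t_cap_end > t_prev + 1e-9:
                y = advance(y, t_prev, t_cap_end, spike_cap)
                t_prev = t_cap_end
            if t_next > t_prev + 1e-9:
                y = advance(y, t_prev, t_next, np.inf)
            t_prev = t_next
        amp = explicit.get(t_next, base_amp)
        if t_next < T:
            f = 1.0
            if scaling is not None and protocol.scale_spikes:
                f = scaling.factor(nmdar_ratio(cm.net, y, scaling.mechanism,
                                               nmdar_total))
            active.append((t_next, amp * f))
            amps.append(amp * f)
            active[:] = [(t0, a) for t0, a in active if t_next - t0 < t_mem]

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    return Trajectory(t_all[keep], y_all[:, keep], net, params, protocol,
                      genotype=genotype, scheme=scheme,
                      mechanism=scaling.mechanism if scaling else None,
                      scaling=scaling,
                      spike_onsets=np.array(onsets),
                      spike_amplitudes=np.array(amps))


def calibrate_mechanism(net, params, basal_state, mechanism, target=2.5,
                        protocol_name="APA", tol=0.01, max_iter=8, seed=None):
    """Find the fold constant F so the peak scaling factor over the APA
    paradigm equals ``target`` (the common amplitude that makes the three
    mechanisms comparable).  Secant iteration on the peak normalised ratio,
    which depends only weakly on F through the Ca²⁺ feedback."""
    from .stimuli import protocol as make_protocol
    nmdar_total = params.totals["NMDAR"]
    r0 = nmdar_ratio(net, basal_state, mechanism, nmdar_total)

    def peak_factor(F):
        sc = ScalingState(mechanism, F, r0)
        proto = make_protocol(protocol_name, readout_s=(900.0,))
        traj = simulate(net, params, basal_state, proto, scaling=sc, seed=seed,
                        dt=15.0)
        ratios = np.array([nmdar_ratio(net, traj.y[:, i], mechanism, nmdar_total)
                           for i in range(traj.y.shape[1])])
        peak = float(ratios.max()) / r0
        return 1.0 + F * (peak - 1.0), peak

    # bracket the target, then bisect (the peak ratio itself shifts with F
    # through the Ca²⁺ feedback, so a plain secant step can oscillate)
    F_lo, F_hi = 0.0, target - 1.0
    f_hi, peak = peak_factor(F_hi)
    if peak <= 1.0 + 1e-9:
        raise RuntimeError(f"mechanism {mechanism}: no ratio excursion "
                           "under APA; cannot calibrate")
    it = 0
    while f_hi < target:
        F_lo, F_hi = F_hi, F_hi * 2.0
        f_hi, _ = peak_factor(F_hi)
        it += 1
        if it > max_iter:
            raise RuntimeError(f"calibration of {mechanism}: peak factor "
                               f"stuck at {f_hi:.3f} < {target}")
    for _ in range(max_iter * 2):
        F = 0.5 * (F_lo + F_hi)
        f_mid, _ = peak_factor(F)
        if abs(f_mid - target) <= tol * target:
            return ScalingState(mechanism, F, r0)
        if f_mid < target:
            F_lo = F
        else:
            F_hi = F
    raise RuntimeError(f"calibration of {mechanism} did not converge "
                       f"(last peak factor {f_mid:.3f})")
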