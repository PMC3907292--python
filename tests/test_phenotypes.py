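"""Marker readouts, immunoblot correction, fits and panel scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msnsig.phenotypes import (ib_correction, ib_forward, fit_hill,
                               fit_monoexp, marker_value, readout, wt_ratio,
                               load_panel, evaluate_panel, divergence,
                               PanelVariable)
from msnsig.stimuli import hill_curve, monoexp_curve


class TestIbCorrection:
    def test_homogeneous_sample_is_identity(self):
        assert ib_correction(6.0, 1.0, 1.0) == pytest.approx(6.0)

    def test_no_change_measured_gives_no_change(self):
        assert ib_correction(1.0, 0.5, 0.7) == pytest.approx(1.0)

    def test_fraction_validation(self):
        for fc, ft in ((0.0, 0.5), (0.5, 1.2), (-0.1, 0.5)):
            with pytest.raises(ValueError):
                ib_correction(2.0, fc, ft)
        with pytest.raises(ValueError):
            ib_correction(-1.0, 0.5, 0.5)

    @given(FC=st.floats(0.2, 50), fc=st.floats(0.05, 1.0),
           ft=st.floats(0.05, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_inverts_the_forward_mixture(self, FC, fc, ft):
        """Simulating the mixture (responders move FC-fold, the rest hold
        the basal level) and correcting the blotted fold change recovers the
        cell-specific fold change."""
        W = ib_forward(FC, fc, ft)
        assert ib_correction(W, fc, ft) == pytest.approx(FC, rel=1e-9)

    def test_two_population_simulation_oracle(self):
        rng = np.random.default_rng(0)
        n = 200000
        fc, ft, FC = 0.5, 0.8, 12.0
        responder_type = rng.random(n) < fc
        responds = responder_type & (rng.random(n) < ft)
        before = np.ones(n)
        after = np.where(responds, FC, 1.0)
        W = after.mean() / before.mean()
        assert ib_correction(W, fc, ft) == pytest.approx(FC, rel=0.02)


class TestFits:
    def test_flat_dose_response_rejected(self):
        with pytest.raises(RuntimeError):
            fit_hill(np.arange(1, 8), np.full(7, 3.0))
        with pytest.raises(ValueError):
            fit_hill([1, 2, 3], [0.1, 0.2, 0.3])

    def test_constant_time_series_flagged(self):
        out = fit_monoexp(np.linspace(0, 10, 8), np.zeros(8))
        assert out["k"] == 0.0 and out.get("flat")

    def test_non_monotone_warning(self):
        t = np.linspace(0, 10, 20)
        y = monoexp_curve(t, 1.0, 0.5)
        y[12:] *= 0.4
        assert "warning" in fit_monoexp(t, y)

    @pytest.mark.parametrize("sd", [0.0, 0.01, 0.05])
    def test_bias_vanishes_with_noise(self, sd):
        errs_h, errs_k = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.geomspace(0.1, 8.0, 12)
            y = hill_curve(x, 0, 1, 0.8, 4.1) + rng.normal(0, sd, 12)
            errs_h.append(fit_hill(x, y)["h"] - 4.1)
            t = np.linspace(0, 30, 12)
            v = monoexp_curve(t, 1.0, 0.15) + rng.normal(0, sd, 12)
            errs_k.append(fit_monoexp(t, v)["k"] - 0.15)
        assert abs(np.mean(errs_h)) < 0.05 + 25 * sd
        assert abs(np.mean(errs_k)) < 1e-6 + 2 * sd


class _FakeTraj:
    """Hand-built state carrier for marker arithmetic."""

    def __init__(self, net, params, state):
        self.net = net
        self.params = params
        self._state = np.asarray(state, dtype=float)
        self.scaling = None
        self.t = np.array([0.0, 1.0])
        self.y = np.tile(self._state[:, None], (1, 2))

    def state_at(self, t):
        return self._state


class TestMarkers:
    def test_stepact_is_one_when_nothing_phosphorylated(self, model):
        net, params = model
        state = np.zeros(net.n_species)
        state[net.index["STEP"]] = params.totals["STEP"] + params.totals["STEP2"]
        traj = _FakeTraj(net, params, state)
        assert marker_value(traj, "STEPact", state) == pytest.approx(1.0)

    def test_rasraf_fraction_of_fully_complexed_ras_is_one(self, model):
        net, params = model
        state = np.zeros(net.n_species)
        state[net.index["RASRAF"]] = params.totals["RAS"]
        traj = _FakeTraj(net, params, state)
        assert marker_value(traj, "RASRAF_fraction", state) == pytest.approx(1.0)

    def test_unknown_marker_raises(self, model):
        net, params = model
        traj = _FakeTraj(net, params, np.zeros(net.n_species))
        with pytest.raises(KeyError):
            marker_value(traj, "pCREB", traj._state)

    def test_wt_ratio_is_one_for_identical_trajectories(self, model):
        net, params = model
        state = np.zeros(net.n_species)
        state[net.index["GluR1@845"]] = 0.4
        traj = _FakeTraj(net, params, state)
        assert wt_ratio(traj, traj, traj, traj, "GluR1p845", 0.5) == 1.0


class TestPanel:
    def test_packaged_panel_has_seventeen_variables(self):
        panel = load_panel()
        assert len(panel) == 17
        assert {v.mode for v in panel} == {"absolute", "fold-over-basal",
                                           "ratio-to-WT", "fitted-parameter"}

    def test_perfect_simulation_scores_perfectly(self):
        panel = load_panel()
        sim = {v.name: (v.target if v.target_hi is None
                        else 0.5 * (v.target + v.target_hi)) for v in panel}
        df, r2 = evaluate_panel(sim, panel)
        assert np.allclose(df["divergence"], 0.0)
        assert r2 == pytest.approx(1.0)

    def test_range_targets_score_zero_inside_linear_outside(self):
        var = PanelVariable("basal-D32p34", 0.2, 0.5, "absolute")
        assert divergence(var, 0.35) == 0.0
        assert divergence(var, 0.2) == 0.0
        assert divergence(var, 0.75) == pytest.approx(0.5)
        assert divergence(var, 0.1) == pytest.approx(0.5)

    def test_r2_invariant_under_variable_ordering(self):
        panel = load_panel()
        rng = np.random.default_rng(1)
        sim = {v.name: v.target * (1 + 0.1 * rng.standard_normal())
               for v in panel}
        _df, r2a = evaluate_panel(sim, panel)
        _df, r2b = evaluate_panel(sim, panel[::-1])
        assert r2a == pytest.approx(r2b)

    def test_large_perturbation_is_flagged(self):
        panel = load_panel()
        sim = {v.name: (v.target if v.target_hi is None
                        else 0.5 * (v.target + v.target_hi)) for v in panel}
        sim["basal-cAMP"] *= 1.5
        df, _ = evaluate_panel(sim, panel)
        row = df.set_index("variable").loc["basal-cAMP"]
        assert row["divergence"] == pytest.approx(0.5)

    def test_missing_variable_raises(self):
        panel = load_panel()
        with pytest.raises(KeyError):
            evaluate_panel({}, panel)
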