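"""Forcing functions, spike trains, protocols and synthetic fixtures."""

import numpy as np
import pytest
from scipy import stats

from msnsig.stimuli import (TransientParams, CA_SPIKE, DA_TRANSIENT,
                            ca_spike_waveform, da_transient, spike_train,
                            train_waveform, protocol, StimulusProtocol,
                            synthetic_fit_fixtures, hill_curve, monoexp_curve)
from msnsig.phenotypes import fit_hill, fit_monoexp


class TestTransients:
    def test_boundaries_and_baseline(self):
        assert ca_spike_waveform(0.0) == pytest.approx(0.060)
        assert da_transient(0.0) == pytest.approx(0.010)
        assert ca_spike_waveform(1e4) == pytest.approx(0.060, abs=1e-9)
        assert da_transient(1e7) == pytest.approx(0.010, abs=1e-9)

    @pytest.mark.parametrize("params,cmax", [(CA_SPIKE, 0.5),
                                             (DA_TRANSIENT, 0.3)])
    def test_peak_matches_dense_grid_maximisation(self, params, cmax):
        t = np.linspace(0, 12 * params.t_peak, 200001)
        curve = params(t)
        assert curve.max() == pytest.approx(cmax, rel=1e-6)
        assert t[np.argmax(curve)] == pytest.approx(params.t_peak, rel=1e-3)

    def test_degenerate_rate_ordering_rejected(self):
        with pytest.raises(ValueError):
            TransientParams(C_b=0.1, C_max=0.5, k1=1.0, k2=1.0)
        with pytest.raises(ValueError):
            TransientParams(C_b=0.5, C_max=0.1, k1=2.0, k2=1.0)


class TestSpikeTrains:
    def test_regular_train_has_constant_interval(self):
        tr = spike_train(0.1, 100.0, "regular")
        assert len(tr.times) == 10
        assert np.allclose(np.diff(tr.times), 10.0)

    def test_poisson_count_near_mean(self):
        tr = spike_train(0.1, 10000.0, "poisson", seed=7)
        assert abs(len(tr.times) - 1000) < 3 * np.sqrt(1000)

    def test_seed_determinism_and_zero_rate(self):
        a = spike_train(0.1, 500.0, "poisson", seed=11)
        b = spike_train(0.1, 500.0, "poisson", seed=11)
        assert a.times == b.times
        assert spike_train(0.0, 500.0, "poisson", seed=1).times == ()
        with pytest.raises(ValueError):
            spike_train(-1.0, 10.0)
        with pytest.raises(ValueError):
            spike_train(0.1, 10.0, kind="fancy")

    def test_interspike_intervals_are_exponential(self):
        tr = spike_train(0.1, 1.2e5, "poisson", seed=3)
        isi = np.diff(tr.times)[:10000]
        stat, p = stats.kstest(isi, "expon", args=(0, 10.0))
        assert p > 0.01

    def test_superposed_waveform_never_below_baseline(self):
        tr = spike_train(0.1, 200.0, "poisson", seed=5)
        t = np.linspace(0, 200, 4001)
        wave = train_waveform(t, tr)
        assert np.all(wave >= CA_SPIKE.C_b - 1e-12)


class TestProtocols:
    def test_named_protocols(self):
        apa = protocol("APA")
        assert isinstance(apa.da, TransientParams)
        assert apa.da.C_max == pytest.approx(0.3)
        assert apa.spike_rate == 0.1
        da = protocol("DAslice")
        assert da.da == 10.0 and da.readout_s == (300.0,)
        nm = protocol("NMDAslice")
        assert nm.ca_level == 10.0 and nm.readout_s == (600.0,)
        pb = protocol("PP2B_inhibition", pp2b_inhibited=True)
        assert pb.ca_level == 10.0 and pb.pp2b_inhibited
        basal = protocol("basal")
        assert basal.da_value(0) == pytest.approx(0.010)
        assert basal.spike_rate == 0.1
        with pytest.raises(KeyError):
            protocol("icecream")

    def test_config_round_trip(self):
        apa = protocol("APA")
        clone = StimulusProtocol.from_config(apa.to_config())
        assert clone.da(100.0) == pytest.approx(apa.da(100.0))
        assert clone.readout_s == apa.readout_s
        assert clone.spike.k1 == apa.spike.k1


class TestSyntheticFixtures:
    def test_noiseless_hill_recovered_exactly(self):
        x, y = synthetic_fit_fixtures("hill", {"h": 4.1, "K": 0.8}, 9, 0.0)
        fit = fit_hill(x, y)
        assert fit["h"] == pytest.approx(4.1, rel=1e-6)
        assert fit["K"] == pytest.approx(0.8, rel=1e-6)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_monoexp_recovered_exactly(self):
        x, y = synthetic_fit_fixtures("monoexp", {"k": 0.15}, 12, 0.0)
        fit = fit_monoexp(x, y)
        assert fit["k"] == pytest.approx(0.15, rel=1e-8)

    def test_noise_reproducible_and_validated(self):
        a = synthetic_fit_fixtures("hill", {"h": 2.0, "K": 1.0}, 8, 0.05, seed=4)
        b = synthetic_fit_fixtures("hill", {"h": 2.0, "K": 1.0}, 8, 0.05, seed=4)
        assert np.allclose(a[1], b[1])
        with pytest.raises(ValueError):
            synthetic_fit_fixtures("hill", {"h": 2.0, "K": 1.0}, 8, -0.1)
        with pytest.raises(ValueError):
            synthetic_fit_fixtures("spline", {"k": 1.0}, 8, 0.0)

    def test_noisy_hill_estimator_matches_grid_search_oracle(self):
        """Least-squares fits agree with a brute-force (K, h) grid search on
        noisy data, and the spread shrinks with the noise level."""
        rng_spread = {}
        for sd in (0.01, 0.05):
            errs, gaps = [], []
            for seed in range(12):
                x, y = synthetic_fit_fixtures("hill", {"h": 4.1, "K": 0.8},
                                              11, sd, seed=seed)
                fit = fit_hill(x, y)
                Ks = np.geomspace(0.3, 2.0, 60)
                hs = np.linspace(1.5, 8.0, 60)
                best = None
                for K in Ks:
                    for h in hs:
                        resid = y - hill_curve(x, 0.0, 1.0, K, h)
                        ss = float(resid @ resid)
                        if best is None or ss < best[0]:
                            best = (ss, K, h)
                errs.append(abs(fit["h"] - 4.1))
                gaps.append(abs(fit["h"] - best[2]))
            rng_spread[sd] = np.mean(errs)
            assert np.mean(gaps) < 0.5          # grid pitch tolerance
        assert rng_spread[0.01] < rng_spread[0.05]
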