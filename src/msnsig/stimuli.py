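"""Forcing functions and synthetic data.

Dopamine and calcium are prescribed inputs.  Single transients are
difference-of-exponential pulses

    C(t) = C_b + (C_max - C_b) · (e^{-k₂ t} - e^{-k₁ t}) / n,   k₁ > k₂ > 0,

normalised by n so the maximum equals C_max.  A synaptically evoked Ca²⁺
spike uses Ca_b = 60 nM, Ca_max = 500 nM, k₁ = 17.2 s⁻¹, k₂ = 15.7 s⁻¹; the
psychostimulant dopamine overflow uses DA_b = 10 nM, DA_max = 300 nM,
k₁ = 0.15 min⁻¹, k₂ = 0.055 min⁻¹ (converted to s⁻¹ internally).

Glutamatergic drive is a train of Ca²⁺ spikes, Poisson or regularly spaced,
at 0.1 s⁻¹ during activity.  The amplitude term (C_max − C_b) of each spike
is multiplied by the DA-dependent NMDAR enhancement factor evaluated at
spike onset; the baseline is never scaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class TransientParams:
    """Double-exponential transient parameters (µM, s⁻¹)."""
    C_b: float
    C_max: float
    k1: float
    k2: float

    def __post_init__(self):
        if not (self.C_max > self.C_b >= 0):
            raise ValueError("need C_max > C_b >= 0")
        if not (self.k1 > self.k2 > 0):
            raise ValueError("need k1 > k2 > 0 (rise faster than decay)")

    @property
    def t_peak(self) -> float:
        return np.log(self.k1 / self.k2) / (self.k1 - self.k2)

    @property
    def _norm(self) -> float:
        t = self.t_peak
        return np.exp(-self.k2 * t) - np.exp(-self.k1 * t)

    def __call__(self, t):
        """Concentration at time t (s) after onset; baseline for t < 0."""
        t = np.asarray(t, dtype=float)
        pulse = np.where(t >= 0,
                         np.exp(-self.k2 * np.maximum(t, 0.0))
                         - np.exp(-self.k1 * np.maximum(t, 0.0)), 0.0)
        return self.C_b + (self.C_max - self.C_b) * pulse / self._norm

    def pulse_shape(self, t):
        """Unit-peak pulse shape (0 before onset, max 1 at t_peak)."""
        t = np.asarray(t, dtype=float)
        return np.where(t >= 0,
                        (np.exp(-self.k2 * np.maximum(t, 0.0))
                         - np.exp(-self.k1 * np.maximum(t, 0.0))) / self._norm,
                        0.0)


#: synaptically evoked Ca²⁺ spike
CA_SPIKE = TransientParams(C_b=0.060, C_max=0.500, k1=17.2, k2=15.7)
#: consensus psychostimulant dopamine overflow
DA_TRANSIENT = TransientParams(C_b=0.010, C_max=0.300,
                               k1=0.15 / SEC_PER_MIN, k2=0.055 / SEC_PER_MIN)


def ca_spike_waveform(t, params: TransientParams = CA_SPIKE):
    return params(t)


def da_transient(t, params: TransientParams = DA_TRANSIENT):
    return params(t)


@dataclass(frozen=True)
class SpikeTrain:
    times: tuple
    rate: float
    kind: str
    duration: float
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must be strictly increasing in [0, duration]")


def spike_train(rate, duration, kind="regular", seed=None) -> SpikeTrain:
    """Spike onset times for a regular or Poisson train.

    Regular trains place spikes at i/rate, i = 1, 2, ...; Poisson trains draw
    exponential inter-spike intervals with a seeded generator.
    """
    if rate < 0 or duration < 0:
        raise ValueError("rate and duration must be non-negative")
    if kind not in ("regular", "poisson"):
        raise ValueError(f"unknown train kind {kind!r}")
    if rate == 0:
        return SpikeTrain((), rate, kind, duration, seed)
    if kind == "regular":
        n = int(np.floor(duration * rate))
        times = tuple((np.arange(1, n + 1) / rate).tolist())
    else:
        rng = np.random.default_rng(seed)
        times = []
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate)
            if t > duration:
                break
            times.append(t)
        times = tuple(times)
    return SpikeTrain(times, rate, kind, duration, seed)


def train_waveform(t, train: SpikeTrain, spike: TransientParams = CA_SPIKE,
                   amplitudes=None):
    """Baseline + superposed spikes; ``amplitudes`` scales (C_max − C_b) per
    spike (default 1 each)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t.shape, spike.C_b)
    amp0 = spike.C_max - spike.C_b
    if amplitudes is None:
        amplitudes = np.ones(len(train.times))
    for t0, a in zip(train.times, amplitudes):
        out += a * amp0 * spike.pulse_shape(t - t0)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class StimulusProtocol:
    """Fully specified forcing for one simulated experiment.

    ``da`` is either a constant (µM) or a TransientParams; calcium is a
    constant baseline plus an optional spike train whose amplitudes are
    scaled by the NMDAR-enhancement mechanism.  ``readout_s`` are the times
    (s after stimulus onset) at which phenotypic markers are sampled.
    """
    name: str
    da: object = 0.010
    ca_level: float = 0.060
    spike: TransientParams | None = None
    spike_rate: float = 0.0
    spike_kind: str = "regular"
    single_spikes: tuple = ()          # explicit (onset, amplitude_µM) pulses
    duration: float = 1800.0
    readout_s: tuple = (900.0,)
    pp2b_inhibited: bool = False
    scale_spikes: bool = True

    def da_value(self, t):
        if isinstance(self.da, TransientParams):
            return self.da(t)
        return float(self.da)

    def to_config(self) -> dict:
        d = asdict(self)
        for k in ("da", "spike"):
            v = d[k]
            if isinstance(getattr(self, k), TransientParams):
                d[k] = {"transient": v}
        return d

    @classmethod
    def from_config(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        for k in ("da", "spike"):
            v = d.get(k)
            if isinstance(v, dict) and "transient" in v:
                d[k] = TransientParams(**v["transient"])
        d["single_spikes"] = tuple(map(tuple, d.get("single_spikes", ())))
        d["readout_s"] = tuple(d.get("readout_s", ()))
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_config(), indent=1)


#: tonic Ca²⁺ level standing in for bath NMDA/glutamate on slices or cultures
NMDA_TONIC_CA = 10.0

PROTOCOL_NAMES = ("basal", "DAslice", "NMDAslice", "APA", "DA_only",
                  "Ca_only", "culture_sensitization", "PP2B_inhibition",
                  "saline")


def protocol(name: str, **over) -> StimulusProtocol:
    """Named experimental paradigms.

    basal                 resting: DA 10 nM, basal Ca spiking at 0.1 s⁻¹
    DAslice               tonic 10 µM DA on striatal slices, sampled at 5′
    NMDAslice             bath NMDA as tonic elevated Ca²⁺, sampled at 10′
    APA                   psychostimulant DA transient + 0.1 s⁻¹ spike train
    DA_only / Ca_only     the two single-input arms of the AND-gate test
    culture_sensitization DA 3 µM, one scaled Ca²⁺ pulse, ERK read at 8′
    PP2B_inhibition       tonic 10 µM Ca²⁺; pair with pp2b_inhibited=True
    saline                APA control: DA stays at baseline, spiking intact
    """
    if name == "basal":
        p = StimulusProtocol("basal", spike=CA_SPIKE, spike_rate=0.1,
                             duration=900.0, readout_s=(900.0,))
    elif name == "DAslice":
        p = StimulusProtocol("DAslice", da=10.0, duration=300.0,
                             readout_s=(300.0,))
    elif name == "NMDAslice":
        p = StimulusProtocol("NMDAslice", ca_level=NMDA_TONIC_CA,
                             duration=600.0, readout_s=(600.0,))
    elif name == "APA":
        p = StimulusProtocol("APA", da=DA_TRANSIENT, spike=CA_SPIKE,
                             spike_rate=0.1, duration=2700.0,
                             readout_s=(900.0,))
    elif name == "saline":
        p = StimulusProtocol("saline", spike=CA_SPIKE, spike_rate=0.1,
                             duration=2700.0, readout_s=(900.0,))
    elif name == "DA_only":
        p = StimulusProtocol("DA_only", da=DA_TRANSIENT, duration=2700.0,
                             readout_s=(900.0,))
    elif name == "Ca_only":
        p = StimulusProtocol("Ca_only", spike=CA_SPIKE, spike_rate=0.1,
                             duration=2700.0, readout_s=(900.0,))
    elif name == "culture_sensitization":
        # bath-applied NMDA in culture: one slow Ca²⁺ elevation (tens of
        # seconds rise, ~2 min decay), scaled by the DA-driven enhancement
        p = StimulusProtocol("culture_sensitization", da=3.0,
                             spike=TransientParams(C_b=0.060, C_max=1.060,
                                                   k1=0.05, k2=0.004),
                             single_spikes=((60.0, 1.0),),
                             duration=540.0, readout_s=(540.0,))
    elif name == "PP2B_inhibition":
        p = StimulusProtocol("PP2B_inhibition", ca_level=NMDA_TONIC_CA,
                             duration=600.0, readout_s=(600.0,))
    else:
        raise KeyError(f"unknown protocol {name!r}")
    for k, v in over.items():
        setattr(p, k, v)
    return p


# ---------------------------------------------------------------------------
# synthetic fixtures for the fitting layer
# ---------------------------------------------------------------------------

def hill_curve(x, C_min, C_max, K, h):
    x = np.asarray(x, dtype=float)
    return C_min + (C_max - C_min) * x ** h / (K ** h + x ** h)


def monoexp_curve(t, A, k):
    t = np.asarray(t, dtype=float)
    return A * (1.0 - np.exp(-k * t))


def synthetic_fit_fixtures(model, true_params, n_points, noise_sd, seed=0):
    """Noisy synthetic dose-response (hill) or time-series (monoexp) data
    with known generating parameters, for exercising the fitting layer."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if model == "hill":
        K = true_params["K"]
        if n_points < 4:
            raise ValueError("need at least 4 dose points")
        x = np.geomspace(K / 10, K * 10, n_points)
        y = hill_curve(x, true_params.get("C_min", 0.0),
                       true_params.get("C_max", 1.0), K, true_params["h"])
    elif model == "monoexp":
        k = true_params["k"]
        if n_points < 2:
            raise ValueError("need at least 2 time points")
        x = np.linspace(0, 4.0 / k, n_points)
        y = monoexp_curve(x, true_params.get("A", 1.0), k)
    else:
        raise ValueError(f"unknown model {model!r}")
    y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return x, y
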