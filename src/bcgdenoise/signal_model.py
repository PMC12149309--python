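"""Synthetic ballistocardiogram (BCG) signals, calibrated noise, and SNR.

The synthetic BCG is a sum of six cardiac sinusoids (1.5–9 Hz) plus a
0.2 Hz respiratory sinusoid, sampled at 100 Hz.  Gaussian white noise is
injected at a nominal SNR referenced to the full (cardiac + respiratory)
signal.  These signals are the shared currency of parameter tuning and
denoising benchmarks: every experiment in :mod:`bcgdenoise.tuning` starts
from :func:`simulate`.

Seeding convention: every stochastic routine takes a single integer seed
plus an optional stream tuple; realization ``r`` of an experiment draws
from ``rng_for(seed, r)`` and is therefore reproducible independently of
realizations ``0..r-1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "TimeSeries",
    "SyntheticSpec",
    "NoisySignal",
    "rng_for",
    "generate_synthetic_bcg",
    "add_gaussian_noise",
    "simulate",
    "measure_snr",
    "generate_beat_train",
    "write_bundle",
    "read_bundle",
    "SNR_CAP_DB",
]

#: SNR reported when the residual power is exactly zero (avoids infinities
#: in heatmaps and serialized matrices).
SNR_CAP_DB = 300.0


def rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Counter-style RNG: an independent Generator per (seed, stream) key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(s) for s in stream)))


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values
        Amplitude samples (arbitrary units).  Stored as float64.
    rate
        Sampling rate in Hz; must be positive.
    start_time
        Time of the first sample in seconds.  Sample ``n`` sits at
        ``start_time + n / rate``.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("TimeSeries requires a 1-D array with at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.rate > 0):
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(values, self.rate, self.start_time)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.values**2)))


# Cardiac component frequencies (Hz) and amplitudes (a.u.) of the default
# six-sinusoid model; respiratory component at 0.2 Hz, amplitude 2.
DEFAULT_CARDIAC_FREQS = (1.5, 3.0, 4.5, 6.0, 7.5, 9.0)
DEFAULT_CARDIAC_AMPS = (0.1, 0.2, 0.1, 0.4, 0.3, 0.6)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic BCG generator.

    Defaults are the study conditions: six cardiac sinusoids at
    1.5/3/4.5/6/7.5/9 Hz with amplitudes 0.1/0.2/0.1/0.4/0.3/0.6 a.u.,
    a 0.2 Hz respiratory sinusoid of amplitude 2 a.u., 30 s at 100 Hz,
    Gaussian white noise at a nominal SNR of 0 dB referenced to the full
    synthetic signal.
    """

    cardiac_freqs: tuple[float, ...] = DEFAULT_CARDIAC_FREQS
    cardiac_amps: tuple[float, ...] = DEFAULT_CARDIAC_AMPS
    resp_freq: float = 0.2
    resp_amp: float = 2.0
    duration: float = 30.0
    rate: float = 100.0
    nominal_snr_db: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cardiac_freqs", tuple(float(f) for f in self.cardiac_freqs))
        object.__setattr__(self, "cardiac_amps", tuple(float(a) for a in self.cardiac_amps))
        if len(self.cardiac_freqs) != len(self.cardiac_amps):
            raise ValueError("cardiac_freqs and cardiac_amps must have the same length")
        if any(a < 0 for a in self.cardiac_amps) or self.resp_amp < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not (self.rate > 0 and self.duration > 0):
            raise ValueError("rate and duration must be positive")
        nyquist = self.rate / 2.0
        bad = [f for f in (*self.cardiac_freqs, self.resp_freq) if f >= nyquist]
        if bad:
            raise ValueError(
                f"frequencies {bad} are at or above the Nyquist limit {nyquist} Hz for rate {self.rate} Hz"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["cardiac_freqs"] = tuple(d["cardiac_freqs"])
        d["cardiac_amps"] = tuple(d["cardiac_amps"])
        return cls(**d)


@dataclass(frozen=True)
class NoisySignal:
    """A noisy synthetic BCG with its exact decomposition.

    Invariant (asserted in tests): ``noisy == clean_cardiac +
    clean_respiratory + noise`` sample-wise; the four series share rate
    and length.
    """

    noisy: TimeSeries
    clean_cardiac: TimeSeries
    clean_respiratory: TimeSeries
    noise: TimeSeries
    nominal_snr_db: float

    @property
    def clean(self) -> TimeSeries:
        """Cardiac + respiratory components (the noise-free signal)."""
        return self.clean_cardiac.with_values(self.clean_cardiac.values + self.clean_respiratory.values)


def generate_synthetic_bcg(spec: SyntheticSpec) -> tuple[TimeSeries, TimeSeries]:
    """Deterministic cardiac and respiratory components of the model.

    Returns ``(cardiac, respiratory)`` where cardiac(t) = Σ_k A_k sin(2π f_k t)
    and respiratory(t) = A_r sin(2π f_r t).
    """
    t = np.arange(spec.n_samples) / spec.rate
    cardiac = np.zeros_like(t)
    for f, a in zip(spec.cardiac_freqs, spec.cardiac_amps):
        cardiac += a * np.sin(2 * np.pi * f * t)
    resp = spec.resp_amp * np.sin(2 * np.pi * spec.resp_freq * t)
    return TimeSeries(cardiac, spec.rate), TimeSeries(resp, spec.rate)


def add_gaussian_noise(
    clean_reference: TimeSeries, nominal_snr_db: float, seed: int, *stream: int
) -> TimeSeries:
    """i.i.d. zero-mean Gaussian noise calibrated against a reference.

    The noise standard deviation is ``RMS(clean_reference) * 10**(-SNR/20)``
    so that the expected power ratio of reference to noise is the nominal
    SNR.  Reproducible for identical ``(seed, stream)``.
    """
    rms = clean_reference.rms()
    if rms == 0.0:
        raise ValueError("reference signal has zero power; SNR-calibrated noise is undefined")
    sigma = rms * 10.0 ** (-nominal_snr_db / 20.0)
    rng = rng_for(seed, *stream)
    noise = rng.normal(0.0, sigma, clean_reference.n)
    return clean_reference.with_values(noise)


def simulate(spec: SyntheticSpec, *stream: int) -> NoisySignal:
    """Generate one noisy realization of the synthetic BCG.

    Noise is calibrated against the FULL synthetic signal (cardiac +
    respiratory), matching how noise is added to the composite waveform;
    denoising quality is judged elsewhere against the cardiac component
    alone (see :func:`bcgdenoise.tuning.grid_search`).
    """
    cardiac, resp = generate_synthetic_bcg(spec)
    clean = cardiac.with_values(cardiac.values + resp.values)
    noise = add_gaussian_noise(clean, spec.nominal_snr_db, spec.seed, *stream)
    noisy = clean.with_values(clean.values + noise.values)
    return NoisySignal(noisy, cardiac, resp, noise, spec.nominal_snr_db)


def measure_snr(estimate: TimeSeries, reference: TimeSeries, cap_db: float = SNR_CAP_DB) -> float:
    """Signal-to-noise ratio of an estimate against a reference, in dB.

    ``10 * log10(P(reference) / P(estimate - reference))``, capped at
    ``cap_db`` when the residual power is zero.
    """
    if estimate.n != reference.n:
        raise ValueError(f"length mismatch: estimate has {estimate.n} samples, reference {reference.n}")
    if estimate.rate != reference.rate:
        raise ValueError("sampling-rate mismatch between estimate and reference")
    p_ref = float(np.mean(reference.values**2))
    if p_ref == 0.0:
        raise ValueError("reference signal has zero power; SNR is undefined")
    p_res = float(np.mean((estimate.values - reference.values) ** 2))
    if p_res == 0.0:
        return cap_db
    return min(cap_db, 10.0 * math.log10(p_ref / p_res))


def _gaussian_bump(fs: float, width_s: float = 0.03, half_support_s: float = 0.15) -> tuple[np.ndarray, int]:
    """Symmetric Gaussian bump template; returns (samples, argmax offset)."""
    half = int(round(half_support_s * fs))
    tt = (np.arange(2 * half + 1) - half) / fs
    w = np.exp(-(tt**2) / (2 * width_s**2))
    return w, half


def _biphasic(fs: float, width_s: float = 0.03, half_support_s: float = 0.15) -> tuple[np.ndarray, int]:
    """Biphasic (derivative-of-Gaussian) template, peak-normalized."""
    half = int(round(half_support_s * fs))
    tt = (np.arange(2 * half + 1) - half) / fs
    w = -tt / width_s * np.exp(-(tt**2) / (2 * width_s**2))
    w /= np.max(np.abs(w))
    return w, int(np.argmax(w))


_TEMPLATES = {"gaussian-bump": _gaussian_bump, "biphasic": _biphasic}


def generate_beat_train(
    rate_bpm: float,
    duration: float,
    fs: float,
    jitter_sd: float = 0.0,
    template: str = "gaussian-bump",
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[TimeSeries, np.ndarray]:
    """A train of beat-shaped pulses with known ground-truth peak times.

    One template instance is centred at each (jittered) beat time; the
    returned peak times are the true locations of the template maxima,
    independent of amplitude.  A test fixture for peak detection, not a
    physiological simulator.
    """
    if rate_bpm <= 0:
        raise ValueError("rate_bpm must be positive")
    if fs < 50:
        raise ValueError("fs must be at least 50 Hz to resolve beat morphology")
    if template not in _TEMPLATES:
        raise ValueError(f"unknown template {template!r}; choose from {sorted(_TEMPLATES)}")
    period = 60.0 / rate_bpm
    centres = np.arange(period / 2, duration - period / 4, period)
    if jitter_sd > 0:
        rng = rng_for(seed, 0)
        centres = centres + rng.normal(0.0, jitter_sd, centres.size)
        centres = np.sort(centres)
    tmpl, peak_off = _TEMPLATES[template](fs)
    half = (tmpl.size - 1) // 2
    min_gap = tmpl.size / fs
    if centres.size > 1 and np.min(np.diff(centres)) < min_gap:
        raise ValueError(
            f"jitter too large: adjacent beats closer than the template support ({min_gap:.3f} s)"
        )
    n = int(round(duration * fs))
    x = np.zeros(n)
    peak_times = []
    for c in centres:
        start = int(round(c * fs)) - half
        lo, hi = max(start, 0), min(start + tmpl.size, n)
        if hi <= lo:
            continue
        x[lo:hi] += amplitude * tmpl[lo - start : hi - start]
        peak_times.append((start + peak_off) / fs)
    return TimeSeries(x, fs), np.asarray(peak_times)


# -- bundle I/O ---------------------------------------------------------------
# 4-column CSV (time_s, cardiac, respiratory, noise) + JSON sidecar of the
# generating spec; round-trips bit-exactly at full float precision.


def write_bundle(directory: str | Path, sig: NoisySignal, spec: SyntheticSpec) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "synthetic_bundle.csv"
    json_path = directory / "synthetic_spec.json"
    t = sig.noisy.times
    cols = (t, sig.clean_cardiac.values, sig.clean_respiratory.values, sig.noise.values)
    with open(csv_path, "w") as fh:
        fh.write("time_s,cardiac,respiratory,noise\n")
        for row in zip(*cols):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    json_path.write_text(json.dumps(spec.to_dict(), indent=2))
    return csv_path, json_path


def read_bundle(directory: str | Path) -> tuple[NoisySignal, SyntheticSpec]:
    directory = Path(directory)
    spec = SyntheticSpec.from_dict(json.loads((directory / "synthetic_spec.json").read_text()))
    data = np.loadtxt(directory / "synthetic_bundle.csv", delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError(f"expected 4 columns in bundle CSV, found {data.shape[1]}")
    cardiac = TimeSeries(data[:, 1], spec.rate)
    resp = TimeSeries(data[:, 2], spec.rate)
    noise = TimeSeries(data[:, 3], spec.rate)
    noisy = TimeSeries(data[:, 1] + data[:, 2] + data[:, 3], spec.rate)
    return NoisySignal(noisy, cardiac, resp, noise, spec.nominal_snr_db), spec
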