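"""Beat fiducials, heart-rate estimation, and BCG-vs-ECG agreement.

The R-peak (ECG) and J-peak (BCG) mark the same cardiac cycle in the
electrical and mechanical domains; pairing heart rates derived from each
quantifies how well the unobtrusive BCG tracks the clinical reference.
Agreement is summarized Bland–Altman style: bias = mean(BCG - ECG),
limits of agreement = bias +/- 1.96 * sample SD of the differences,
alongside Pearson r, RMSE, and MAE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .signal_model import TimeSeries

__all__ = ["PeakAnnotations", "AgreementStats", "detect_peaks", "annotations_to_hr", "agreement"]


@dataclass(frozen=True)
class PeakAnnotations:
    """Peak positions as 0-based sample indices with matching times (s)."""

    indices: np.ndarray
    times: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        if idx.size != t.size:
            raise ValueError("indices and times must have equal length")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if idx.size and np.max(np.abs(idx / self.rate - t)) > 0.5 / self.rate + 1e-9:
            raise ValueError("times are inconsistent with indices/rate beyond half a sample")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "times", t)

    @classmethod
    def from_indices(cls, indices: np.ndarray, rate: float) -> "PeakAnnotations":
        idx = np.asarray(indices, dtype=np.int64)
        return cls(idx, idx / rate, rate)

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class AgreementStats:
    """Paired heart-rate agreement metrics (all in bpm except r)."""

    pearson_r: float  # NaN when either input is constant (r undefined)
    rmse: float
    mae: float
    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int


# Band-pass edges (Hz) applied before thresholding, per fiducial type.
_BANDS = {"ecg-r": (5.0, 25.0), "bcg-j": (1.0, 12.0)}


def detect_peaks(
    x: TimeSeries,
    refractory_s: float = 0.35,
    mode: str = "bcg-j",
    mad_k: float = 3.0,
    baseline_window_s: float = 2.0,
) -> PeakAnnotations:
    """Adaptive-threshold peak detection for R- or J-peaks.

    The signal is zero-phase band-pass filtered (5–25 Hz for ``ecg-r``,
    1–12 Hz for ``bcg-j``), then local maxima exceeding a rolling
    ``median + mad_k * MAD`` threshold and separated by at least
    ``refractory_s`` are kept.  A flat signal yields zero peaks; NaNs are
    rejected.
    """
    if mode not in _BANDS:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(_BANDS)}")
    if np.any(np.isnan(x.values)):
        raise ValueError("signal contains NaNs")
    if x.n <= 2 * refractory_s * x.rate:
        raise ValueError("signal shorter than two refractory periods")
    if np.ptp(x.values) == 0.0:
        return PeakAnnotations.from_indices(np.array([], dtype=np.int64), x.rate)

    lo, hi = _BANDS[mode]
    hi = min(hi, 0.45 * x.rate)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=x.rate, output="sos")
    filt = scipy.signal.sosfiltfilt(sos, x.values)

    win = max(3, int(round(baseline_window_s * x.rate)) | 1)  # odd window
    med = scipy.ndimage.median_filter(filt, size=win, mode="nearest")
    mad = scipy.ndimage.median_filter(np.abs(filt - med), size=win, mode="nearest")
    threshold = med + mad_k * mad

    distance = max(1, int(round(refractory_s * x.rate)))
    peaks, _ = scipy.signal.find_peaks(filt, distance=distance)
    peaks = peaks[filt[peaks] > threshold[peaks]]
    return PeakAnnotations.from_indices(peaks, x.rate)


def annotations_to_hr(ann: PeakAnnotations, method: str = "mean-interval") -> float | np.ndarray:
    """Heart rate from peak annotations.

    ``mean-interval``: 60 / mean(successive intervals in s), one scalar per
    record.  ``per-beat``: 60 / each interval, one value per beat pair.
    """
    if len(ann) < 2:
        raise ValueError("need at least 2 peaks to estimate heart rate")
    intervals = np.diff(ann.times)
    if method == "mean-interval":
        return 60.0 / float(np.mean(intervals))
    if method == "per-beat":
        return 60.0 / intervals
    raise ValueError(f"unknown method {method!r}; use 'mean-interval' or 'per-beat'")


def agreement(hr_a: np.ndarray, hr_b: np.ndarray) -> AgreementStats:
    """Paired agreement between two heart-rate series (diff = a - b).

    With the BCG rates first and the ECG reference second, a positive
    bias means the BCG reads high.  LOA uses the 1.96 multiplier with the
    sample (n-1) standard deviation.  Pearson r is NaN (flagged missing)
    when either input is constant; the remaining statistics are still
    computed.
    """
    a = np.asarray(hr_a, dtype=np.float64)
    b = np.asarray(hr_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("hr_a and hr_b must be equal-length 1-D arrays")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs for agreement statistics")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        r = math.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return AgreementStats(
        pearson_r=r,
        rmse=float(np.sqrt(np.mean(diff**2))),
        mae=float(np.mean(np.abs(diff))),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=n,
    )
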