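"""Force-plate signal chain: bandpass filter, RMS, segmentation, COP features.

Two parallel streams are computed from each trial:

* the *cleaned* stream — channels band-limited to 10-50 Hz with a zero-phase
  Butterworth filter, summarized per channel by RMS over the scored window;
* the *raw* stream — COP trajectory, 95% ellipse area, total force (TF) and
  total moment (MT), computed from the unfiltered channels. A 10-50 Hz
  bandpass removes DC, which would make the moment/force ratio defining the
  COP meaningless and drive TF to ~0 during quiet standing, so these
  load-bearing quantities always come from the raw signals.

Scored windows: static trials (SLB/TBT) drop the first and last 3 s of the
nominal 16 to avoid set-up peaks and end-of-trial fatigue; YBT trials keep
the initial 4 s containing the reach movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import chi2

from imep.types import PlateTrial

#: Fz below this (N) means the plate is effectively unloaded; such samples
#: carry no COP information and are dropped (and counted).
DEFAULT_MIN_FZ = 20.0

#: chi-square(2 df) quantile defining the 95% prediction ellipse.
CHI2_95_2DF = float(chi2.ppf(0.95, df=2))


@dataclass
class PlateFeatures:
    """Summary features of one trial over its scored window."""

    window: tuple[int, int]  # half-open sample index range
    window_seconds: tuple[float, float]
    tf: float  # total force, N (RMS of resultant magnitude, unfiltered)
    mt: float  # total moment, N·m
    cop_x: np.ndarray  # cm
    cop_y: np.ndarray  # cm
    cop_a: float  # 95% ellipse area, cm²
    rms_per_channel: dict[str, float]  # of the 10-50 Hz cleaned stream
    dropped_samples: int = 0


def bandpass(
    series: np.ndarray,
    fs: float,
    low: float = 10.0,
    high: float = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output has the input's length.

    Applied forward and backward (``filtfilt``) so band-limited features stay
    aligned in time with the raw record. Requires ``fs > 2*high`` (Nyquist)
    and a series comfortably longer than the filter order.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 2.0 * high:
        raise ValueError(
            f"sampling rate {fs} Hz cannot represent a {high} Hz band edge "
            "(need fs > 2*high)"
        )
    if series.ndim != 1 or len(series) <= 3 * order:
        raise ValueError(f"series too short to filter (need > {3 * order} samples)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series)


def segment_window(
    test_type: str, nominal_duration: float, fs: float, n_samples: int
) -> tuple[int, int]:
    """Half-open 0-based sample range of the scored window.

    Static tests keep [3 s, duration − 3 s); YBT keeps [0 s, 4 s). The
    recording must match its nominal duration within 5%.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    actual = n_samples / fs
    if nominal_duration > 0 and abs(actual - nominal_duration) > 0.05 * nominal_duration:
        raise ValueError(
            f"recording length {actual:.2f} s inconsistent with nominal "
            f"{nominal_duration:.2f} s (>5% off)"
        )
    if test_type == "YBT":
        stop = min(int(round(4.0 * fs)), n_samples)
        return 0, stop
    if actual <= 6.0:
        raise ValueError(
            f"window empty: static trial of {actual:.2f} s leaves nothing "
            "after removing 3 s from each end"
        )
    start = int(round(3.0 * fs))
    stop = n_samples - int(round(3.0 * fs))
    return start, stop


def rms(series: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x²))."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("rms of empty series")
    return float(np.sqrt(np.mean(series**2)))


def cop_path(
    trial: PlateTrial,
    window: tuple[int, int],
    min_fz: float = DEFAULT_MIN_FZ,
) -> tuple[np.ndarray, np.ndarray, int]:
    """COP trajectory in cm over the window, from unfiltered channels.

    For a plate with its origin at the surface, cop_x = −My/Fz and
    cop_y = Mx/Fz (metres, converted to cm). Samples with Fz ≤ ``min_fz``
    are dropped and counted; returns ``(cop_x, cop_y, n_dropped)``.
    """
    start, stop = window
    fz = trial.fz[start:stop]
    mx = trial.mx[start:stop]
    my = trial.my[start:stop]
    loaded = fz > min_fz
    n_dropped = int(np.sum(~loaded))
    if not loaded.any():
        raise ValueError(f"no loaded samples: Fz never exceeds {min_fz} N in window")
    cop_x = -my[loaded] / fz[loaded] * 100.0
    cop_y = mx[loaded] / fz[loaded] * 100.0
    return cop_x, cop_y, n_dropped


def cop_area_95(cop_x: np.ndarray, cop_y: np.ndarray, coverage: float = 0.95) -> float:
    """Area (cm²) of the prediction ellipse covering ``coverage`` of COP points.

    For a bivariate Gaussian cloud the ellipse
    ``(p − μ)ᵀ Σ⁻¹ (p − μ) ≤ χ²₂(coverage)`` contains that fraction of the
    distribution; its area is ``π · χ²₂ · sqrt(det Σ)`` with Σ the sample
    covariance. Degenerate clouds (identical or collinear points) give 0.
    """
    x = np.asarray(cop_x, dtype=float)
    y = np.asarray(cop_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("cop_x and cop_y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 COP points for a covariance")
    cov = np.cov(np.vstack([x, y]))
    det = float(np.linalg.det(cov))
    if det <= 0:
        return 0.0
    q = float(chi2.ppf(coverage, df=2))
    return float(np.pi * q * np.sqrt(det))


def _resultant_rms(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   window: tuple[int, int]) -> float:
    start, stop = window
    if stop <= start:
        raise ValueError("empty window")
    mag = np.sqrt(a[start:stop] ** 2 + b[start:stop] ** 2 + c[start:stop] ** 2)
    return rms(mag)


def total_force(trial: PlateTrial, window: tuple[int, int]) -> float:
    """TF: RMS over the window of |F| = sqrt(Fx²+Fy²+Fz²), unfiltered, in N."""
    return _resultant_rms(trial.fx, trial.fy, trial.fz, window)


def total_moment(trial: PlateTrial, window: tuple[int, int]) -> float:
    """MT: RMS over the window of |M| = sqrt(Mx²+My²+Mz²), unfiltered, in N·m."""
    return _resultant_rms(trial.mx, trial.my, trial.mz, window)


def compute_features(
    trial: PlateTrial,
    min_fz: float = DEFAULT_MIN_FZ,
    bandpass_low: float = 10.0,
    bandpass_high: float = 50.0,
) -> PlateFeatures:
    """Run the full chain on one trial: segment, filter+RMS, COP, TF, MT."""
    window = segment_window(
        trial.test_type, trial.nominal_duration, trial.sampling_rate, trial.n_samples
    )
    start, stop = window
    rms_clean = {}
    for name, series in trial.channels().items():
        cleaned = bandpass(series, trial.sampling_rate, bandpass_low, bandpass_high)
        rms_clean[name] = rms(cleaned[start:stop])
    cop_x, cop_y, n_dropped = cop_path(trial, window, min_fz)
    return PlateFeatures(
        window=window,
        window_seconds=(start / trial.sampling_rate, stop / trial.sampling_rate),
        tf=total_force(trial, window),
        mt=total_moment(trial, window),
        cop_x=cop_x,
        cop_y=cop_y,
        cop_a=cop_area_95(cop_x, cop_y),
        rms_per_channel=rms_clean,
        dropped_samples=n_dropped,
    )
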