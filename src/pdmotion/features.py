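"""Bradykinesia feature engineering on scaled kinematic channels.

Three custom symptom measures target the cardinal bradykinetic phenomena:

* **sequence effect** — the dominant (largest-magnitude non-DC) Fourier
  frequency of a 6.6-s sliding window is regressed against time; a negative
  slope means the movement is slowing over repetitions;
* **amplitude decrement** — the topographic prominence of each signal peak
  is regressed against peak time; a negative slope means shrinking
  excursions;
* **Pause Metric** — the cumulative distance below a kinematic threshold
  T, P = Σ_t (T − |x_t|)·1[|x_t| < T], evaluated on the max-abs-scaled
  signal over the threshold grid T ∈ {0.05, 0.10, …, 0.95}; larger values
  mean more time spent in low-motion states.

These are complemented by whole-signal Fourier coefficient magnitudes per
frequency bin and a pluggable set of generic time-series descriptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

from .kinematics import ChannelKey, ChannelSet

logger = logging.getLogger(__name__)

#: Pause Metric threshold grid (19 values, 0.05 … 0.95).
PAUSE_THRESHOLD_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))

DEFAULT_WINDOW_S = 6.6
DEFAULT_MIN_PROMINENCE = 0.01   # on the [−1, 1] scale; suppresses numerical ripple


class FreqSeries(NamedTuple):
    """Window-center times (s) and dominant frequencies (Hz); NaN = undefined."""

    time: np.ndarray
    freq_hz: np.ndarray


@dataclass
class FeatureVector:
    """Named feature values for one video, with per-feature provenance.

    ``values`` maps feature name → float (NaN encodes missing).
    ``provenance`` maps feature name → (channel name, feature type, detail).
    """

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def add(self, name: str, value: float, channel: str, ftype: str, detail: str = "") -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        v = float(value)
        self.values[name] = v if math.isfinite(v) else float("nan")
        self.provenance[name] = (channel, ftype, detail)

    def __len__(self) -> int:
        return len(self.values)


def _window_dominant_freqs(windows: np.ndarray, fps: float) -> np.ndarray:
    """Dominant non-DC DFT frequency per row of a (n_win, win) window stack."""
    win = windows.shape[-1]
    mags = np.abs(np.fft.rfft(windows, axis=-1))[..., 1:]  # DC excluded
    freqs = np.fft.rfftfreq(win, d=1.0 / fps)[1:]
    # argmax returns the first (lowest-frequency) bin on ties.
    idx = np.argmax(mags, axis=-1)
    out = freqs[idx]
    # A window with no non-DC content (e.g. constant signal) has no peak.
    flat = np.max(mags, axis=-1) <= 1e-9 * win
    out = np.where(flat, np.nan, out)
    return out


def dominant_frequency_series(
    x: np.ndarray,
    fps: float,
    window_s: float = DEFAULT_WINDOW_S,
    hop_frames: int = 1,
) -> FreqSeries:
    """Sliding-window dominant-frequency series of one scalar signal.

    For each window position the discrete Fourier transform is taken and
    the frequency of the maximum-magnitude non-DC bin reported (ties break
    toward the lower frequency).  Times are window centers; frequency
    resolution is 1/window_s.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fps))
    if len(x) < win:
        raise ValueError("signal shorter than window")
    if hop_frames < 1:
        raise ValueError("hop_frames must be >= 1")
    windows = sliding_window_view(x, win)[::hop_frames]
    starts = np.arange(0, len(x) - win + 1, hop_frames)
    times = (starts + (win - 1) / 2.0) / fps
    return FreqSeries(time=times, freq_hz=_window_dominant_freqs(windows, fps))


def frequency_trend(freq_series: FreqSeries) -> tuple[float, float]:
    """OLS (slope Hz/s, intercept Hz) of dominant frequency vs window time.

    Returns (NaN, NaN) when fewer than two windows have a defined frequency.
    """
    t = np.asarray(freq_series.time, dtype=float)
    f = np.asarray(freq_series.freq_hz, dtype=float)
    ok = np.isfinite(f) & np.isfinite(t)
    if ok.sum() < 2:
        return (float("nan"), float("nan"))
    if np.ptp(t[ok]) == 0.0:
        return (float("nan"), float("nan"))
    slope, intercept = np.polyfit(t[ok], f[ok], 1)
    return (float(slope), float(intercept))


def amplitude_trend(
    x: np.ndarray, fps: float, min_prominence: float = DEFAULT_MIN_PROMINENCE
) -> tuple[float, float]:
    """OLS (slope 1/s, intercept) of peak prominence vs peak time.

    Peaks are strict local maxima with topographic prominence of at least
    ``min_prominence``; fewer than two peaks yields (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    peaks, props = find_peaks(x, prominence=min_prominence)
    if len(peaks) < 2:
        return (float("nan"), float("nan"))
    times = peaks / fps
    slope, intercept = np.polyfit(times, props["prominences"], 1)
    return (float(slope), float(intercept))


def pause_metric(x: np.ndarray, T: float) -> float:
    """Cumulative distance below threshold: P = Σ_t (T − |x_t|)·1[|x_t| < T].

    ``x`` must already be max-abs scaled to [−1, 1]; 0 < T < 1.
    """
    if not 0.0 < T < 1.0:
        raise ValueError("threshold T must lie strictly between 0 and 1")
    ax = np.abs(np.asarray(x, dtype=float))
    below = ax < T
    # fsum: correctly rounded independent of summation order
    return math.fsum((T - ax[below]).tolist())


def _pause_metrics_grid(x: np.ndarray, grid) -> np.ndarray:
    """Vectorized Pause Metric over a threshold grid."""
    ax = np.abs(np.asarray(x, dtype=float))
    T = np.asarray(grid, dtype=float)[:, None]
    diff = T - ax[None, :]
    return np.sum(np.where(diff > 0.0, diff, 0.0), axis=1)


@lru_cache(maxsize=64)
def _band_names(n: int, fps: float, max_freq_hz: float | None) -> tuple[str, ...]:
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    df = fps / n
    names = []
    for k in range(1, len(freqs)):
        lo = freqs[k]
        if max_freq_hz is not None and lo >= max_freq_hz:
            break
        names.append(f"{lo:.2f}-{lo + df:.2f}Hz")
    return tuple(names)


def fourier_band_features(
    x: np.ndarray, fps: float, max_freq_hz: float | None = None
) -> dict[str, float]:
    """Whole-signal DFT coefficient magnitudes per frequency bin (DC excluded).

    Bins are named by their edges, e.g. ``"0.47-0.52Hz"``; the bin at
    frequency k/D (D = signal duration) covers [k/D, (k+1)/D).
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty series")
    names = _band_names(len(x), fps, max_freq_hz)
    mags = np.abs(np.fft.rfft(x))[1 : 1 + len(names)]
    return dict(zip(names, mags.tolist()))


# ---------------------------------------------------------------------------
# Generic (non-symptom-specific) time-series descriptors


def _longest_strike_above_mean(x: np.ndarray) -> float:
    above = np.concatenate(([False], x > np.mean(x), [False]))
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    if len(edges) == 0:
        return 0.0
    return float(np.max(edges[1::2] - edges[::2]))


def _sum_of_recurring_values(x: np.ndarray) -> float:
    vals, counts = np.unique(x, return_counts=True)
    return float(np.sum(vals[counts > 1]))


def default_generic_features(x: np.ndarray, fps: float) -> dict[str, float]:
    """Bundled minimal descriptor set: mean, variance, longest run above the
    mean, relative position of the maximum, sum of recurring values, and the
    slope of a linear trend over time."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n >= 2:
        t = np.arange(n) / fps
        tc = t - t.mean()
        slope = float(np.dot(tc, x - x.mean()) / np.dot(tc, tc))
    else:
        slope = float("nan")
    return {
        "mean": float(np.mean(x)),
        "variance": float(np.var(x)),
        "longest_strike_above_mean": _longest_strike_above_mean(x),
        "first_position_of_maximum": float(np.argmax(x) / n),
        "sum_of_recurring_values": _sum_of_recurring_values(x),
        "linear_trend_slope": slope,
    }


GenericExtractor = Callable[[np.ndarray, float], dict[str, float]]


def extract_feature_vector(
    c: ChannelSet,
    generic_extractor: GenericExtractor | None = default_generic_features,
    window_s: float = DEFAULT_WINDOW_S,
    hop_frames: int = 1,
    pause_grid=PAUSE_THRESHOLD_GRID,
    max_freq_hz: float | None = 6.0,
) -> FeatureVector:
    """Compute every per-channel feature for one video.

    For each channel: frequency-trend slope and intercept, amplitude-trend
    slope and intercept, the Pause Metric at every grid threshold, Fourier
    bin magnitudes (band-limited by ``max_freq_hz``, which comfortably
    covers voluntary movement and rest tremor), and the pluggable generic
    descriptors.  Missing values (e.g. a channel shorter than the sliding
    window, or too few peaks) are preserved as NaN — they are data, not
    errors.
    """
    fv = FeatureVector()
    keys = sorted(c.channels)

    # Dominant-frequency series batched over channels of equal length: one
    # FFT call per length group instead of one per window.
    win = int(round(window_s * c.fps))
    by_length: dict[int, list[ChannelKey]] = {}
    for k in keys:
        by_length.setdefault(len(c.channels[k]), []).append(k)
    freq_trends: dict[ChannelKey, tuple[float, float]] = {}
    for length, group in by_length.items():
        if length < win:
            for k in group:
                freq_trends[k] = (float("nan"), float("nan"))
            continue
        stack = np.stack([c.channels[k] for k in group])
        windows = sliding_window_view(stack, win, axis=-1)[:, ::hop_frames, :]
        starts = np.arange(0, length - win + 1, hop_frames)
        times = (starts + (win - 1) / 2.0) / c.fps
        freqs = _window_dominant_freqs(
            windows.reshape(-1, win), c.fps
        ).reshape(len(group), -1)
        for k, f in zip(group, freqs):
            freq_trends[k] = frequency_trend(FreqSeries(time=times, freq_hz=f))

    for k in keys:
        x = c.channels[k]
        ch = k.name
        fslope, fint = freq_trends[k]
        fv.add(f"{ch}|freq_trend|slope", fslope, ch, "frequency_trend", "slope of frequency vs. time")
        fv.add(f"{ch}|freq_trend|intercept", fint, ch, "frequency_trend", "intercept of frequency vs. time")
        aslope, aint = amplitude_trend(x, c.fps)
        fv.add(f"{ch}|amp_trend|slope", aslope, ch, "amplitude_trend", "slope of amplitude vs. time")
        fv.add(f"{ch}|amp_trend|intercept", aint, ch, "amplitude_trend", "intercept of amplitude vs. time")
        for T, p in zip(pause_grid, _pause_metrics_grid(x, pause_grid)):
            fv.add(f"{ch}|pause|T={T:.2f}", p, ch, "pause_metric", f"T={T:.2f}")
        for band, mag in fourier_band_features(x, c.fps, max_freq_hz=max_freq_hz).items():
            fv.add(f"{ch}|fourier|{band}", mag, ch, "fourier_coefficient", band)
        if generic_extractor is not None:
            for gname, gval in generic_extractor(x, c.fps).items():
                fv.add(f"{ch}|generic|{gname}", gval, ch, "generic", gname)
    return fv
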