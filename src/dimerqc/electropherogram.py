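"""Adapter-dimer peak detection in cDNA-library electropherogram traces.

A contaminated library shows a discrete peak below the library peak size
(around 88 bp for Ion Torrent chemistry, around 120 bp for Illumina TruSeq
small-RNA libraries; instruments reporting migration time instead of bp are
handled through user-supplied windows).  The dimer-to-library signal ratio
``dimer_area / (dimer_area + library_area)`` quantifies the contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

__all__ = [
    "Trace",
    "PeakCall",
    "DEFAULT_WINDOWS",
    "detect_dimer_peak",
    "simulate_trace",
]

#: Default dimer / library windows (bp) per chemistry.
DEFAULT_WINDOWS = {
    "iontorrent": {"dimer": (80.0, 95.0), "library": (100.0, 130.0)},
    "illumina": {"dimer": (110.0, 130.0), "library": (135.0, 170.0)},
}

_SMOOTH_WIDTH = 5


@dataclass(frozen=True)
class Trace:
    """Electropherogram trace: strictly increasing x (bp or minutes) and a
    non-negative signal of the same length (>= 16 points)."""

    x: np.ndarray
    signal: np.ndarray
    units: str = "bp"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "signal", sig)
        if len(x) != len(sig) or len(x) < 16:
            raise ValueError("trace needs >= 16 (x, signal) pairs of equal length")
        if not (np.diff(x) > 0).all():
            raise ValueError("x must be strictly increasing")
        if (sig < 0).any():
            raise ValueError("signal must be non-negative")

    @staticmethod
    def from_csv(path: str | Path, units: str = "bp") -> "Trace":
        """Read a 2-column CSV (x, signal) with an optional header row."""
        first = open(path).readline().split(",")[0].strip()
        skip = 0
        try:
            float(first)
        except ValueError:
            skip = 1
        data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
        return Trace(data[:, 0], data[:, 1], units=units)


@dataclass(frozen=True)
class PeakCall:
    """One called peak: center and height in trace units, baseline-subtracted
    trapezoidal area over the search window."""

    center: float
    height: float
    area: float
    window: tuple[float, float]


def _window_area(trace: Trace, baseline: float, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (trace.x >= lo) & (trace.x <= hi)
    return float(
        np.trapezoid(np.clip(trace.signal[mask] - baseline, 0.0, None), trace.x[mask])
    )


def detect_dimer_peak(
    trace: Trace,
    dimer_window: tuple[float, float],
    library_window: tuple[float, float],
) -> tuple[PeakCall | None, PeakCall | None, float]:
    """Call the tallest qualifying peak per window and the dimer ratio.

    The signal is smoothed by a 5-point moving average; the baseline is the
    5th percentile of the smoothed signal, and a local maximum qualifies
    when it rises above baseline + 3 x MAD of the low-signal
    (bottom-quartile) region, both in height and in prominence — the
    prominence requirement rejects bare noise excursions that happen to
    clear the height bar.  MAD is scaled to the normal distribution.
    ``dimer_ratio = dimer.area / (dimer.area + library.area)``; 0 with no
    dimer peak, 1 with a dimer peak but no library peak.
    """
    for lo, hi in (dimer_window, library_window):
        if not (trace.x[0] <= lo < hi <= trace.x[-1]):
            raise ValueError(f"window ({lo}, {hi}) outside trace range")
    if min(dimer_window[1], library_window[1]) > max(
        dimer_window[0], library_window[0]
    ):
        raise ValueError("dimer and library windows must be disjoint")

    kernel = np.ones(_SMOOTH_WIDTH) / _SMOOTH_WIDTH
    smoothed = np.convolve(trace.signal, kernel, mode="same")
    baseline = float(np.percentile(smoothed, 5))
    # MAD of the full smoothed trace: peaks occupy a minority of points, so
    # the median absolute deviation tracks the baseline noise scale
    mad = float(stats.median_abs_deviation(smoothed, scale="normal"))
    threshold = baseline + 3.0 * mad
    peaks, _ = sp_signal.find_peaks(
        smoothed, height=max(threshold, baseline), prominence=6.0 * mad
    )
    if np.ptp(trace.signal) == 0 or len(peaks) == 0:
        if np.ptp(trace.signal) == 0:
            warnings.warn("flat trace: no peaks called")
        return None, None, 0.0

    def call(window: tuple[float, float]) -> PeakCall | None:
        lo, hi = window
        inside = peaks[(trace.x[peaks] >= lo) & (trace.x[peaks] <= hi)]
        if len(inside) == 0:
            return None
        best = inside[np.argmax(smoothed[inside])]
        return PeakCall(
            center=float(trace.x[best]),
            height=float(smoothed[best]),
            area=_window_area(trace, baseline, window),
            window=window,
        )

    dimer = call(dimer_window)
    library = call(library_window)
    if dimer is None:
        ratio = 0.0
    elif library is None:
        ratio = 1.0
    else:
        ratio = dimer.area / (dimer.area + library.area)
    return dimer, library, ratio


def simulate_trace(
    peaks: list[tuple[float, float, float]],
    noise_sd: float,
    x_grid: np.ndarray,
    seed: int = 0,
) -> Trace:
    """Sum of Gaussian peaks (center, sd, area) plus seeded noise, clipped at 0."""
    x = np.asarray(x_grid, dtype=float)
    sig = np.zeros_like(x)
    for center, sd, area in peaks:
        if not (x[0] <= center <= x[-1]):
            raise ValueError(f"peak center {center} outside the x grid")
        sig += area / (sd * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - center) / sd) ** 2
        )
    if noise_sd > 0:
        sig = sig + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return Trace(x, np.clip(sig, 0.0, None))
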