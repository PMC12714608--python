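"""XIC extraction and chromatographic peak detection.

Peak picking follows the common DIA-software recipe: smooth with a linear
weighted (triangular) moving average, find local maxima above a minimum
height, delimit each peak where the smoothed trace stops falling or drops to
baseline, require a minimum width, and integrate the *raw* trace between the
smoothed-trace bounds with the trapezoid rule. Defaults mirror widely used
settings (smoothing level 3, minimum height 1000 counts, minimum width 5 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .runio import ScanSeries

DEFAULT_SMOOTHING_LEVEL = 3
DEFAULT_MIN_HEIGHT = 1000.0
DEFAULT_MIN_WIDTH_S = 5.0


@dataclass(frozen=True)
class ChromPeak:
    """A detected chromatographic peak on one XIC."""

    mz: float
    rt_apex: float                 # minutes
    rt_bounds: tuple[float, float]  # minutes
    area: float                    # intensity * seconds
    height: float                  # smoothed apex intensity

    def __post_init__(self) -> None:
        lo, hi = self.rt_bounds
        if not lo <= self.rt_apex <= hi:
            raise ValueError("apex must lie within bounds")


def extract_xic(series: ScanSeries, mz: float, tol_ppm: float = 10.0) -> np.ndarray:
    """Intensity-vs-scan trace at ``mz`` with a +/- ``tol_ppm`` window.

    The trace value at each scan is the sum of all centroid intensities whose
    m/z lies within the window; its length equals the scan count.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    n = series.n_scans
    if n == 0:
        return np.empty(0)
    half = mz * tol_ppm * 1e-6
    sel = np.abs(series.mz - mz) <= half
    return np.bincount(series.scan_index[sel], weights=series.intensity[sel], minlength=n)


def smooth_lwma(trace: np.ndarray, level: int = DEFAULT_SMOOTHING_LEVEL) -> np.ndarray:
    """Linear weighted moving average (triangular kernel of half-width ``level``)."""
    if level <= 0:
        return np.asarray(trace, float)
    w = np.concatenate([np.arange(1, level + 2), np.arange(level, 0, -1)]).astype(float)
    w /= w.sum()
    pad = np.pad(np.asarray(trace, float), level, mode="edge")
    return np.convolve(pad, w, mode="valid")


def detect_chrom_peaks(
    trace: np.ndarray,
    times: np.ndarray,
    mz: float = 0.0,
    smoothing_level: int = DEFAULT_SMOOTHING_LEVEL,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_width: float = DEFAULT_MIN_WIDTH_S,
    baseline_frac: float = 0.005,
) -> list[ChromPeak]:
    """Detect peaks on a uniformly sampled trace.

    Bounds are walked outward from each apex while the smoothed trace keeps
    decreasing, stopping at a local minimum or when it falls below
    ``baseline_frac`` of the apex. Peaks narrower than ``min_width`` seconds
    (bound-to-bound) are rejected. Area integrates the raw trace.
    """
    trace = np.asarray(trace, float)
    times = np.asarray(times, float)
    if trace.size == 0:
        return []
    if trace.size != times.size:
        raise ValueError("trace and time axis must have equal length")
    sm = smooth_lwma(trace, smoothing_level)
    apex_idx, _ = find_peaks(sm, height=min_height)
    peaks: list[ChromPeak] = []
    n = len(sm)
    for a in apex_idx:
        floor = baseline_frac * sm[a]
        lo = a
        while lo > 0 and sm[lo - 1] <= sm[lo] and sm[lo] > floor:
            lo -= 1
        hi = a
        while hi < n - 1 and sm[hi + 1] <= sm[hi] and sm[hi] > floor:
            hi += 1
        # min-width gate on the *raw* trace: contiguous above-baseline span
        # around the apex (smoothing must not widen narrow spikes into peaks)
        raw_floor = baseline_frac * trace[lo: hi + 1].max()
        rl = a
        while rl > lo and trace[rl - 1] > raw_floor:
            rl -= 1
        rh = a
        while rh < hi and trace[rh + 1] > raw_floor:
            rh += 1
        if (times[rh] - times[rl]) * 60.0 < min_width:
            continue
        area = float(np.trapezoid(trace[lo: hi + 1], times[lo: hi + 1]) * 60.0)
        if area <= 0:
            continue
        peaks.append(
            ChromPeak(
                mz=float(mz),
                rt_apex=float(times[a]),
                rt_bounds=(float(times[lo]), float(times[hi])),
                area=area,
                height=float(sm[a]),
            )
        )
    return peaks


def detect_peaks_in_series(
    series: ScanSeries,
    tol_ppm: float = 10.0,
    min_points: int = 4,
    **peak_kwargs,
) -> list[ChromPeak]:
    """MS1/MS2-level peak detection: cluster centroids by m/z, then pick peaks.

    Centroids across the whole series are sorted by m/z and split wherever the
    gap to the next centroid exceeds the ppm tolerance; each cluster with at
    least ``min_points`` centroids yields an XIC (at the intensity-weighted
    mean m/z) that is passed to :func:`detect_chrom_peaks`.
    """
    if len(series.mz) == 0:
        return []
    order = np.argsort(series.mz)
    mz = series.mz[order]
    gaps = np.diff(mz) > mz[:-1] * tol_ppm * 1e-6
    bounds = np.concatenate(([0], np.flatnonzero(gaps) + 1, [len(mz)]))
    peaks: list[ChromPeak] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < min_points:
            continue
        sel = order[s:e]
        w = series.intensity[sel]
        centre = float(np.average(series.mz[sel], weights=w))
        trace = extract_xic(series, centre, tol_ppm)
        peaks.extend(detect_chrom_peaks(trace, series.times, mz=centre, **peak_kwargs))
    return peaks
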