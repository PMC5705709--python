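"""gCaMP calcium transient quantification: ROI placement, dF/F amplitude,
and transient timing/synchrony.

dF/F = (F_peak - F_base) / F_base.  F_base defaults to the mean of the
lowest-decile samples (a pre-flash window mode is available when event
timing is known); F_peak averages all detected transient peaks rather than
taking a single maximum.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter

from .datatypes import CaMetrics, MovieStack, ROISet


def roi_grid(
    movie: MovieStack,
    roi_size_um: float = 400.0,
    n_rois: int = 3,
    placement: str = "variance",
) -> ROISet:
    """Place ``n_rois`` non-overlapping square ROIs on a movie.

    ROI edge length is ``round(roi_size_um / pixel_size)`` pixels.  The
    default placement greedily picks windows of maximal temporal signal
    variance; ties resolve to top-left scan order, so placement on a uniform
    movie is deterministic.
    """
    px_um = movie.pixel_size * 1000.0
    size = int(round(roi_size_um / px_um))
    rows, cols = movie.frames.shape[1:]
    if size < 1 or size > rows or size > cols:
        raise ValueError(
            f"ROI of {roi_size_um} um is {size} px; image is {rows}x{cols} px"
        )
    if placement not in ("variance", "grid"):
        raise ValueError(f"unknown placement {placement!r}")

    if placement == "grid":
        rois = []
        r = c = 0
        for _ in range(n_rois):
            if c + size > cols:
                c = 0
                r += size
            if r + size > rows:
                raise ValueError("cannot place ROIs without overlap")
            rois.append((r, r + size, c, c + size))
            c += size
        return ROISet(rois=rois, pixel_size_um=px_um)

    var = movie.frames.var(axis=0)
    # Window score: summed variance over each size x size window.
    # Padding never matters: only centers whose window lies fully inside the
    # image are eligible below.
    score = uniform_filter(var, size=size, mode="constant", cval=0.0)
    half = size // 2
    blocked = np.zeros_like(var, dtype=bool)
    rois = []
    for _ in range(n_rois):
        masked = np.where(blocked, -np.inf, score)
        # Valid window centers only.
        valid = np.full_like(masked, -np.inf)
        r0, r1 = half, rows - (size - half) + 1
        c0, c1 = half, cols - (size - half) + 1
        valid[r0:r1, c0:c1] = masked[r0:r1, c0:c1]
        if not np.isfinite(valid).any():
            raise ValueError("cannot place ROIs without overlap")
        rc = np.unravel_index(np.argmax(valid), valid.shape)
        top, left = rc[0] - half, rc[1] - half
        rois.append((top, top + size, left, left + size))
        # Block every center whose window would overlap this ROI.
        br0 = max(0, top - size + 1 + half)
        br1 = min(rows, top + size + half)
        bc0 = max(0, left - size + 1 + half)
        bc1 = min(cols, left + size + half)
        blocked[br0:br1, bc0:bc1] = True
    return ROISet(rois=rois, pixel_size_um=px_um)


def roi_trace(movie: MovieStack, roi: tuple) -> np.ndarray:
    """Mean fluorescence over one rectangular ROI per frame."""
    r0, r1, c0, c1 = roi
    return movie.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))


def dff_amplitude(
    trace: np.ndarray,
    prominence_frac: float = 0.2,
    baseline: str = "decile",
    baseline_window: Optional[tuple] = None,
    dt: Optional[float] = None,
) -> tuple:
    """dF/F of one fluorescence trace.

    ``baseline="decile"`` takes F_base as the mean of the lowest 10 % of
    samples; ``baseline="window"`` uses the mean over the
    ``baseline_window`` (t0, t1) ms interval (requires ``dt``).  F_peak is
    the mean of detected transient peak values.  Returns ``(dff, flags)``;
    a trace with no detectable transients returns ``(0.0, ("no_transients",))``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 10:
        raise ValueError("trace must have at least 10 samples")
    if baseline == "window":
        if baseline_window is None or dt is None:
            raise ValueError("baseline='window' requires baseline_window and dt")
        t = np.arange(trace.size) * dt
        sel = (t >= baseline_window[0]) & (t < baseline_window[1])
        if not sel.any():
            raise ValueError("empty baseline window")
        f_base = float(trace[sel].mean())
    else:
        k = max(1, trace.size // 10)
        f_base = float(np.sort(trace)[:k].mean())
    if f_base <= 0:
        raise ValueError("F_base must be positive")

    span = np.ptp(trace)
    if span <= 0:
        return 0.0, ("no_transients",)
    peaks, _ = sps.find_peaks(trace, prominence=prominence_frac * span)
    if peaks.size == 0:
        return 0.0, ("no_transients",)
    f_peak = float(trace[peaks].mean())
    return (f_peak - f_base) / f_base, ()


def movie_dff(
    movie: MovieStack,
    rois: Optional[ROISet] = None,
    roi_size_um: float = 400.0,
    n_rois: int = 3,
    prominence_frac: float = 0.2,
) -> CaMetrics:
    """Per-movie dF/F: mean over per-ROI amplitudes, plus transient timing."""
    if rois is None:
        rois = roi_grid(movie, roi_size_um=roi_size_um, n_rois=n_rois)
    dffs, flags = [], set()
    for roi in rois.rois:
        d, fl = dff_amplitude(roi_trace(movie, roi), prominence_frac=prominence_frac)
        dffs.append(d)
        flags.update(fl)
    ref = roi_trace(movie, rois.rois[0])
    times, rate = transient_events(ref, movie.dt, prominence_frac=prominence_frac)
    return CaMetrics(
        dff_per_roi=np.asarray(dffs),
        mean_dff=float(np.mean(dffs)),
        transient_times=list(times),
        rate_per_min=rate,
        flags=tuple(sorted(flags)),
    )


def transient_events(
    trace: np.ndarray,
    dt: float,
    prominence_frac: float = 0.2,
) -> tuple:
    """Transient peak times (ms) and event rate (per minute)."""
    trace = np.asarray(trace, dtype=float)
    span = np.ptp(trace)
    if span <= 0:
        return np.array([]), 0.0
    peaks, _ = sps.find_peaks(trace, prominence=prominence_frac * span)
    times = peaks * dt
    duration_min = trace.size * dt / 60_000.0
    rate = peaks.size / duration_min if duration_min > 0 else 0.0
    return times, float(rate)
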