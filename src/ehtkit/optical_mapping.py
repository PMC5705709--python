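"""Activation mapping, conduction velocity, APD, arrhythmia classification,
and graft-host coupling assessment from fluorescence movies.

The default activation definition is the 50 % upstroke crossing with linear
sub-sample interpolation; a maximum-dV/dt alternative is exposed.  The choice
is recorded in result metadata since either convention is common.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .datatypes import (
    ActivationMap,
    ActivityTrace,
    APDMap,
    CVResult,
    EpisodeClassification,
    MovieStack,
)

SUSTAINED_BOUNDARY_S = 60.0  # episodes self-terminating within 1 min are unsustained


# ---------------------------------------------------------------------------
# Preprocessing


def condition(
    stack: MovieStack,
    detrend: bool = False,
    smooth_ms: float = 0.0,
    snr_threshold: float = 5.0,
    percentiles: tuple = (2.0, 98.0),
) -> MovieStack:
    """Detrend, smooth, and robustly normalize a movie to [0, 1] per pixel.

    Normalization maps the ``percentiles[0]``/``percentiles[1]`` percentile of
    each pixel trace to 0/1, which is invariant to per-movie gain and offset.
    Pixels whose peak-to-peak amplitude falls below ``snr_threshold`` times a
    robust per-pixel noise estimate are dropped from the mask.

    Raises ``ValueError`` if no pixel survives.
    """
    frames = stack.frames.astype(float, copy=True)
    if detrend:
        frames = sps.detrend(frames, axis=0, type="linear")
    if smooth_ms > 0:
        win = max(1, int(round(smooth_ms / stack.dt)))
        if win > 1:
            frames = uniform_filter1d(frames, size=win, axis=0, mode="nearest")

    lo = np.percentile(frames, percentiles[0], axis=0)
    hi = np.percentile(frames, percentiles[1], axis=0)
    amp = hi - lo

    # Robust noise: scaled median absolute first difference of the raw trace.
    diffs = np.abs(np.diff(stack.frames, axis=0))
    noise = np.median(diffs, axis=0) / (math.sqrt(2.0) * 0.6745)

    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, amp / noise, np.where(amp > 0, np.inf, 0.0))
    keep = stack.mask & (amp > 0) & (snr >= snr_threshold)
    if not keep.any():
        raise ValueError(
            f"conditioning removed every pixel (SNR threshold {snr_threshold})"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        norm = (frames - lo[None]) / amp[None]
    norm[:, ~keep] = np.nan
    out = MovieStack(
        frames=norm,
        dt=stack.dt,
        pixel_size=stack.pixel_size,
        channel=stack.channel,
        mask=keep,
        meta=dict(stack.meta),
    )
    out.meta.update(
        conditioned=True,
        snr_threshold=snr_threshold,
        percentiles=percentiles,
        smooth_ms=smooth_ms,
        detrend=detrend,
        n_removed=int(stack.mask.sum() - keep.sum()),
    )
    return out


# ---------------------------------------------------------------------------
# Activation


def _upward_crossing_time(trace: np.ndarray, dt: float, level: float) -> float:
    """First upward crossing of ``level`` with linear interpolation, or NaN."""
    above = trace >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.nan
    i = idx[0]
    frac = (level - trace[i]) / (trace[i + 1] - trace[i])
    return (i + frac) * dt


def activation_map(
    stack: MovieStack,
    method: str = "half_amplitude",
    level: float = 0.5,
    stimulus_rc: Optional[tuple] = None,
) -> ActivationMap:
    """Per-pixel activation time from a conditioned movie.

    ``half_amplitude``: first upward crossing of ``level`` of normalized
    amplitude, sub-sample interpolated.  ``max_dvdt``: time of the maximum
    temporal derivative (parabolic sub-sample refinement).

    Pixels with no crossing are left undefined (NaN); if more than half the
    masked pixels are undefined a warning is recorded in the result metadata.
    """
    if method not in ("half_amplitude", "max_dvdt"):
        raise ValueError(f"unknown activation method {method!r}")
    rows, cols = stack.frames.shape[1:]
    act = np.full((rows, cols), np.nan)
    for r, c in zip(*np.nonzero(stack.mask)):
        trace = stack.frames[:, r, c]
        if method == "half_amplitude":
            act[r, c] = _upward_crossing_time(trace, stack.dt, level)
        else:
            dv = np.gradient(trace)
            i = int(np.argmax(dv))
            # Parabolic refinement around the discrete derivative peak.
            if 0 < i < dv.size - 1:
                denom = dv[i - 1] - 2 * dv[i] + dv[i + 1]
                shift = 0.0 if denom == 0 else 0.5 * (dv[i - 1] - dv[i + 1]) / denom
                act[r, c] = (i + np.clip(shift, -0.5, 0.5)) * stack.dt
            else:
                act[r, c] = i * stack.dt

    meta = {"method": method, "level": level}
    n_masked = int(stack.mask.sum())
    n_undef = int(np.isnan(act[stack.mask]).sum())
    if n_masked and n_undef > 0.5 * n_masked:
        meta["warning"] = f"{n_undef}/{n_masked} masked pixels have no activation"
    return ActivationMap(
        act_time=act,
        pixel_size=stack.pixel_size,
        stimulus_rc=stimulus_rc,
        meta=meta,
    )


def isochrones(amap: ActivationMap, interval: float) -> np.ndarray:
    """Band activation times at fixed intervals.

    Returns an integer image: ``floor(act_time / interval)`` per defined
    pixel, -1 outside the defined set.
    """
    if interval <= 0:
        raise ValueError("isochrone interval must be positive")
    defined = amap.mask
    times = amap.act_time[defined]
    if times.size and np.unique(times).size < 2 and defined.sum() > 1:
        pass  # uniform map is allowed: single band
    bands = np.full(amap.act_time.shape, -1, dtype=int)
    bands[defined] = np.floor(amap.act_time[defined] / interval).astype(int)
    return bands


# ---------------------------------------------------------------------------
# Conduction velocity


def _plane_fit_gradient(patch_t: np.ndarray, patch_x: np.ndarray, patch_y: np.ndarray):
    """Least-squares plane fit T(x, y); returns (dT/dx, dT/dy) in ms/mm."""
    A = np.column_stack([patch_x, patch_y, np.ones_like(patch_x)])
    coef, *_ = np.linalg.lstsq(A, patch_t, rcond=None)
    return coef[0], coef[1]


def conduction_velocity(
    amap: ActivationMap,
    method: str = "local_plane",
    neighborhood="auto",
    neighborhood_mm: float = 0.8,
    exclusion_radius_px: float = 1.5,
    min_gradient: float = 1e-6,
    stimulus_rc: Optional[tuple] = None,
) -> CVResult:
    """Conduction velocity in cm/s from an activation map.

    ``local_plane`` (default): fit the activation time to a plane in each
    ``neighborhood x neighborhood`` window of defined pixels; local speed is
    ``1 / |grad T|``.  ``neighborhood="auto"`` picks the smallest odd window
    spanning at least ``neighborhood_mm`` (minimum 3x3), so fine camera
    pixels and coarse photodiode channels average over comparable tissue
    area.  The mean excludes pixels within ``exclusion_radius_px`` of the
    stimulus site and pixels with near-zero gradient.  ``radial_fit``:
    least-squares slope of activation time vs. Euclidean distance from the
    stimulus; speed is ``1 / slope``.
    """
    if method not in ("local_plane", "radial_fit"):
        raise ValueError(f"unknown CV method {method!r}")
    px = amap.pixel_size
    if neighborhood == "auto":
        neighborhood = max(3, 1 + 2 * math.ceil(neighborhood_mm / (2 * px)))
    neighborhood = int(neighborhood)
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be an odd integer >= 3")
    defined = amap.mask
    if defined.sum() < 9:
        raise ValueError("need at least a 3x3 defined neighborhood")
    stim = stimulus_rc if stimulus_rc is not None else amap.stimulus_rc

    if method == "radial_fit":
        if stim is None:
            # Fall back to the earliest-activating pixel.
            stim = np.unravel_index(np.nanargmin(amap.act_time), amap.act_time.shape)
        r, c = np.nonzero(defined)
        dist = np.hypot(r - stim[0], c - stim[1]) * px  # mm
        t = amap.act_time[defined]
        far = dist > exclusion_radius_px * px
        if far.sum() < 3:
            raise ValueError("no resolvable propagation: too few pixels beyond stimulus")
        A = np.column_stack([dist[far], np.ones(far.sum())])
        slope, _ = np.linalg.lstsq(A, t[far], rcond=None)[0]
        if slope <= min_gradient:
            raise ValueError("no resolvable propagation (near-simultaneous activation)")
        speed = 100.0 / slope  # mm/ms -> cm/s
        return CVResult(
            mean_cv=float(speed),
            speed_map=None,
            direction=None,
            method=method,
            n_pixels=int(far.sum()),
            meta={"slope_ms_per_mm": float(slope), "stimulus_rc": tuple(stim)},
        )

    half = neighborhood // 2
    rows, cols = amap.act_time.shape
    speed_map = np.full((rows, cols), np.nan)
    direction = np.full((rows, cols, 2), np.nan)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for r in range(half, rows - half):
        for c in range(half, cols - half):
            win = np.s_[r - half : r + half + 1, c - half : c + half + 1]
            if not defined[win].all():
                continue
            t = amap.act_time[win].ravel()
            x = (cc[win].ravel() * px).astype(float)
            y = (rr[win].ravel() * px).astype(float)
            gx, gy = _plane_fit_gradient(t, x, y)
            g = math.hypot(gx, gy)
            if g < min_gradient:
                continue
            speed_map[r, c] = 100.0 / g  # cm/s
            direction[r, c] = (gx / g, gy / g)

    use = np.isfinite(speed_map)
    if stim is not None:
        near = np.hypot(rr - stim[0], cc - stim[1]) <= exclusion_radius_px
        use &= ~near
    if not use.any():
        raise ValueError("no resolvable propagation (near-simultaneous activation)")
    mean_cv = float(np.mean(speed_map[use]))
    out_map = np.where(use, speed_map, np.nan)
    return CVResult(
        mean_cv=mean_cv,
        speed_map=out_map,
        direction=direction,
        method=method,
        n_pixels=int(use.sum()),
        meta={
            "neighborhood": neighborhood,
            "exclusion_radius_px": exclusion_radius_px,
        },
    )


# ---------------------------------------------------------------------------
# APD


def apd_map(
    stack: MovieStack,
    amap: ActivationMap,
    level: float = 0.8,
) -> APDMap:
    """Action potential duration at ``level`` repolarization.

    Per pixel: the time from activation to the first downward crossing of
    ``1 - level`` of normalized amplitude after the post-activation peak,
    linearly interpolated.  Pixels that never repolarize within the record
    are left undefined.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    thr = 1.0 - level
    rows, cols = stack.frames.shape[1:]
    apd = np.full((rows, cols), np.nan)
    for r, c in zip(*np.nonzero(stack.mask)):
        t_act = amap.act_time[r, c]
        if not np.isfinite(t_act):
            continue
        trace = stack.frames[:, r, c]
        i_act = int(t_act / stack.dt)
        i_peak = i_act + int(np.argmax(trace[i_act:]))
        below = trace <= thr
        idx = np.flatnonzero(~below[:-1] & below[1:])
        idx = idx[idx >= i_peak]
        if idx.size == 0:
            continue
        i = idx[0]
        frac = (thr - trace[i]) / (trace[i + 1] - trace[i])
        t_rep = (i + frac) * stack.dt
        if t_rep > t_act:
            apd[r, c] = t_rep - t_act
    return APDMap(apd=apd, level=level, meta={"activation": amap.meta.get("method")})


# ---------------------------------------------------------------------------
# Arrhythmia classification and pacing protocol


def burst_protocol() -> list:
    """Burst-pacing stimulation frequencies in Hz: 2 Hz, then 6-20 Hz in
    2 Hz steps (nine episodes)."""
    return [2, 6, 8, 10, 12, 14, 16, 18, 20]


def classify_episode(
    trace: ActivityTrace,
    pacing_offset_s: Optional[float] = None,
    threshold: float = 0.5,
    grace_s: float = 0.05,
) -> EpisodeClassification:
    """Classify post-pacing activity by the 60 s sustained boundary.

    Ectopic events are threshold crossings after the pacing offset (a short
    grace window immediately after the offset is excluded).  Verdicts:
    ``none`` if there are no events, ``unsustained`` if the last event falls
    short of 60 s after the offset, ``sustained`` otherwise.  If the record
    ends before the 60 s horizon while activity is still present, the verdict
    carries a ``capped`` flag.
    """
    offset = pacing_offset_s if pacing_offset_s is not None else trace.pacing_offset_s
    if offset is None:
        raise ValueError("pacing offset not provided")
    if not trace.time_s[0] <= offset <= trace.time_s[-1]:
        raise ValueError(
            f"pacing offset {offset} s outside record "
            f"[{trace.time_s[0]}, {trace.time_s[-1]}] s"
        )
    rel = np.ptp(trace.value)
    level = trace.value.min() + threshold * rel if rel > 0 else np.inf
    after = trace.time_s > offset + grace_s
    events = trace.time_s[after & (trace.value >= level)]
    horizon = trace.time_s[-1] - offset

    if events.size == 0:
        return EpisodeClassification(
            verdict="none",
            ectopic_duration_s=0.0,
            pacing_offset_s=float(offset),
            capped=horizon < SUSTAINED_BOUNDARY_S,
        )
    last = float(events[-1] - offset)
    if last >= SUSTAINED_BOUNDARY_S:
        verdict = "sustained"
        capped = False
    else:
        verdict = "unsustained"
        # Activity running into the end of a short record cannot be called
        # self-terminated.
        capped = horizon < SUSTAINED_BOUNDARY_S and last >= horizon - grace_s
    return EpisodeClassification(
        verdict=verdict,
        ectopic_duration_s=last,
        pacing_offset_s=float(offset),
        event_times_s=events - offset,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# Graft-host coupling


def assess_coupling(
    host_events: Sequence[float],
    graft_events: Sequence[float],
    latency_window: float = 50.0,
    coupled_fraction_threshold: float = 0.8,
) -> dict:
    """Assess functional coupling between host and graft event trains.

    A host event is coupled if a graft event occurs within ``latency_window``
    ms after it.  The verdict is ``"coupled"`` iff the coupled fraction
    reaches ``coupled_fraction_threshold``.
    """
    host = np.sort(np.asarray(host_events, dtype=float))
    if host.size == 0:
        raise ValueError("host_events must be non-empty")
    graft = np.sort(np.asarray(graft_events, dtype=float))
    if graft.size == 0:
        return {
            "verdict": "uncoupled",
            "fraction": 0.0,
            "latencies": np.array([]),
            "n_host": int(host.size),
        }
    idx = np.searchsorted(graft, host)
    latencies = np.full(host.size, np.nan)
    in_window = idx < graft.size
    lat = graft[np.clip(idx, 0, graft.size - 1)] - host
    ok = in_window & (lat >= 0) & (lat <= latency_window)
    latencies[ok] = lat[ok]
    fraction = float(ok.mean())
    verdict = "coupled" if fraction >= coupled_fraction_threshold else "uncoupled"
    return {
        "verdict": verdict,
        "fraction": fraction,
        "latencies": latencies[ok],
        "n_host": int(host.size),
    }
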