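"""Contractile readouts: twitch kinetics, force-length curves, passive
stiffness, specific force, force-frequency relationship, per-cell force."""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .datatypes import FFRResult, ForceLengthCurve, ForceTrace, TwitchMetrics

BASELINE_WINDOW_MS = 100.0  # pre-stimulus window used for the twitch baseline


# ---------------------------------------------------------------------------
# Twitch segmentation and kinetics


def segment_twitches(
    trace: ForceTrace,
    min_prominence_frac: float = 0.3,
    min_separation_frac: float = 0.5,
) -> list:
    """Locate twitch windows as (start, stop) sample-index pairs.

    When stimulation markers are present each window is anchored to its
    marker (from ``BASELINE_WINDOW_MS`` before the marker to the next
    marker).  Otherwise twitches are found by peak detection with a minimum
    prominence (fraction of the global amplitude) and minimum separation
    (fraction of the median inter-peak period); each window spans midpoints
    between neighbouring peaks.

    An empty list (with a warning) is returned if nothing is found.
    """
    t, f = trace.time, trace.force
    dt = trace.dt
    n = t.size

    if trace.stim_times is not None and len(trace.stim_times) > 0:
        markers = np.asarray(trace.stim_times, dtype=float)
        starts = np.searchsorted(t, markers - BASELINE_WINDOW_MS)
        ends = np.append(np.searchsorted(t, markers[1:]), n)
        return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= 3]

    amp = np.ptp(f)
    if amp <= 0:
        warnings.warn("flat trace: no twitches found")
        return []
    peaks, _ = sps.find_peaks(f, prominence=min_prominence_frac * amp)
    if peaks.size == 0:
        warnings.warn("no twitches found above prominence threshold")
        return []
    if peaks.size > 1:
        period = np.median(np.diff(peaks))
        peaks, _ = sps.find_peaks(
            f,
            prominence=min_prominence_frac * amp,
            distance=max(1, int(min_separation_frac * period)),
        )
    bounds = np.concatenate([[0], (peaks[:-1] + peaks[1:]) // 2, [n]])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(peaks.size)]


def _interp_up(t, y, level):
    above = y >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return None
    i = idx[0]
    if y[i + 1] == y[i]:
        return float(t[i])  # flat tie: earliest sample
    return float(t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i]))


def _interp_down(t, y, level, start=0):
    below = y <= level
    idx = np.flatnonzero(~below[:-1] & below[1:])
    idx = idx[idx >= start]
    if idx.size == 0:
        return None
    i = idx[0]
    if y[i + 1] == y[i]:
        return float(t[i])
    return float(t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i]))


def twitch_metrics(
    trace: ForceTrace,
    window: Optional[tuple] = None,
    stim_time: Optional[float] = None,
) -> TwitchMetrics:
    """Kinetics of a single twitch.

    Baseline is the mean over the ``BASELINE_WINDOW_MS`` preceding the
    stimulus (or the pre-rise samples when no marker is given); amplitude is
    peak minus baseline.  Rise time runs from the upward 10 % to 90 %
    amplitude crossings, decay from the downward 90 % to 10 % crossings, and
    total time from 10 % activation to 90 % relaxation (10 % of amplitude
    remaining).  Crossings are linearly interpolated; flat ties resolve to
    the earliest sample.
    """
    if window is not None:
        s, e = window
        t = trace.time[s:e]
        f = trace.force[s:e]
    else:
        t, f = trace.time, trace.force

    if stim_time is None and trace.stim_times is not None and len(trace.stim_times):
        inside = [m for m in trace.stim_times if t[0] <= m <= t[-1]]
        stim_time = inside[0] if inside else None

    if stim_time is not None:
        pre = (t >= stim_time - BASELINE_WINDOW_MS) & (t < stim_time)
        baseline = float(f[pre].mean()) if pre.any() else float(f[0])
    else:
        n_pre = max(1, int(0.05 * f.size))
        baseline = float(f[:n_pre].mean())

    y = f - baseline
    ipeak = int(np.argmax(y))
    amplitude = float(y[ipeak])
    if amplitude <= 0:
        raise ValueError("window contains no positive deflection above baseline")

    up10 = _interp_up(t, y, 0.1 * amplitude)
    up90 = _interp_up(t, y, 0.9 * amplitude)
    down90 = _interp_down(t, y, 0.9 * amplitude, ipeak)
    down10 = _interp_down(t, y, 0.1 * amplitude, ipeak)

    flags = []
    if up10 is None or up90 is None:
        raise ValueError("window does not contain a full rise")
    rise = up90 - up10
    if down10 is None:
        flags.append("decay_undefined")
        decay = np.nan
        total = None
    else:
        decay = down10 - down90 if down90 is not None else np.nan
        total = down10 - up10
    return TwitchMetrics(
        amplitude=amplitude,
        rise_time=float(rise),
        decay_time=float(decay),
        total_time=None if total is None else float(total),
        baseline=baseline,
        peak_time=float(t[ipeak]),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Force-length and stiffness


def force_length(
    traces_by_strain: Dict[float, ForceTrace],
    csa_mm2: float,
    baseline_windows: Optional[Dict[float, tuple]] = None,
) -> ForceLengthCurve:
    """Active/passive force at each strain level of a stretch protocol.

    ``traces_by_strain`` maps strain (% of culture length) to the recorded
    trace at that length.  Passive tension is the mean force over the
    non-stimulated baseline segment — ``baseline_windows[strain]`` as a
    (t0, t1) ms pair when given, otherwise the segment before the first
    stimulus marker.  Active force is the mean twitch amplitude above that
    passive level.  Levels without a usable baseline are skipped with a
    warning.
    """
    strains, passive, active = [], [], []
    for strain in sorted(traces_by_strain):
        trace = traces_by_strain[strain]
        if baseline_windows is not None and strain in baseline_windows:
            t0, t1 = baseline_windows[strain]
            seg = (trace.time >= t0) & (trace.time < t1)
        elif trace.stim_times is not None and len(trace.stim_times):
            seg = trace.time < trace.stim_times[0]
        else:
            warnings.warn(f"strain {strain}%: no baseline segment, level skipped")
            continue
        if not seg.any():
            warnings.warn(f"strain {strain}%: empty baseline segment, level skipped")
            continue
        p = float(trace.force[seg].mean())
        windows = segment_twitches(trace)
        if windows:
            amps = []
            for w in windows:
                try:
                    amps.append(twitch_metrics(trace, window=w).amplitude)
                except ValueError:
                    continue
            a = float(np.mean(amps)) if amps else 0.0
        else:
            a = 0.0
        strains.append(strain)
        passive.append(p)
        active.append(a)
    return ForceLengthCurve(
        strain_pct=np.asarray(strains),
        passive_mN=np.asarray(passive),
        active_mN=np.asarray(active),
        csa_mm2=csa_mm2,
    )


def stiffness(curve: ForceLengthCurve, min_strain_pct: float = 112.0) -> float:
    """Passive stiffness in kPa.

    Least-squares slope of passive tension (mN) against strain expressed as a
    dimensionless fraction over the three highest strain levels (all of which
    must be at least ``min_strain_pct``), divided by the cross-sectional area
    (mm^2).  1 mN/mm^2 = 1 kPa.
    """
    if curve.csa_mm2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    qual = curve.strain_pct >= min_strain_pct
    if qual.sum() < 3:
        raise ValueError(
            f"need three strain levels >= {min_strain_pct}%, found {int(qual.sum())}"
        )
    order = np.argsort(curve.strain_pct)
    top = order[-3:]
    x = curve.strain_pct[top] / 100.0  # dimensionless fraction
    y = curve.passive_mN[top]
    slope = np.polyfit(x, y, 1)[0]
    return float(slope / curve.csa_mm2)


def specific_force(active_mN: float, csa_mm2: float) -> float:
    """Active force normalized by cross-sectional area (mN/mm^2 = kPa)."""
    if csa_mm2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    return active_mN / csa_mm2


# ---------------------------------------------------------------------------
# Force-frequency relationship and per-cell force


def ffr(amplitudes_by_freq: Dict[float, float]) -> FFRResult:
    """Force-frequency relationship normalized to the 1 Hz amplitude.

    Returns amplitudes as percent of the 1 Hz value plus the least-squares
    slope (percent per Hz) of the normalized values against frequency.
    """
    if 1.0 not in amplitudes_by_freq:
        raise ValueError("the 1 Hz amplitude is required for normalization")
    freqs = np.array(sorted(amplitudes_by_freq))
    amps = np.array([amplitudes_by_freq[f] for f in freqs], dtype=float)
    ref = amplitudes_by_freq[1.0]
    if ref <= 0:
        raise ValueError("1 Hz amplitude must be positive")
    normalized = 100.0 * amps / ref
    slope = float(np.polyfit(freqs, normalized, 1)[0]) if freqs.size > 1 else 0.0
    return FFRResult(frequencies=freqs, normalized_pct=normalized, slope=slope)


def force_per_input_cm(
    active_mN: float, input_cells: float, cm_fraction: float
) -> float:
    """Contractile force per input cardiomyocyte in nN/cell.

    ``active_mN * 1e6 / (input_cells * cm_fraction)``.
    """
    if input_cells <= 0:
        raise ValueError("input_cells must be positive")
    if not 0 < cm_fraction <= 1:
        raise ValueError("cm_fraction must be in (0, 1]")
    if active_mN < 0:
        raise ValueError("active force must be non-negative")
    return active_mN * 1e6 / (input_cells * cm_fraction)
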