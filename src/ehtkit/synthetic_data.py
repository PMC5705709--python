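"""Ground-truth-known synthetic inputs for every analysis stage.

Waves are kinematic (no reaction-diffusion): each pixel replays a common
action-potential template delayed by its source-to-pixel travel time, which
makes activation times, conduction velocity, and APD available in closed form.
Twitches, vessel phantoms, calcium flashes, and arrhythmia episodes follow the
same philosophy: parametric waveforms whose summary metrics are computed
analytically or by dense numerical evaluation of the noiseless waveform.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; two calls with the same config are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    ActivationMap,
    ActivityTrace,
    ForceTrace,
    HyperspectralStack,
    MovieStack,
    VesselMask,
)
from .spectra import extinction_at

# ---------------------------------------------------------------------------
# Acquisition geometry presets.
#
# The photodiode array is modelled as a channel -> (x, y) coordinate table;
# the default is a full 24 x 21 grid (504 channels) at 1 mm effective
# resolution sampled at 1.2 kHz.  The camera preset is 80 um resolution at
# 125 Hz (field size free).
PHOTODIODE_GEOMETRY = {"rows": 24, "cols": 21, "pixel_size": 1.0, "dt": 1000.0 / 1200.0}
CAMERA_GEOMETRY = {"rows": 40, "cols": 40, "pixel_size": 0.08, "dt": 1000.0 / 125.0}


def photodiode_channel_table(rows: int = 24, cols: int = 21, pixel_size: float = 1.0):
    """Channel -> (x_mm, y_mm) coordinate table for the photodiode array.

    Returns an array of shape (rows*cols, 4): channel, row, col, x, y columns
    flattened in scan order.
    """
    ch = np.arange(rows * cols)
    r, c = np.divmod(ch, cols)
    return np.column_stack([ch, r, c, c * pixel_size, r * pixel_size])


# ---------------------------------------------------------------------------
# Action-potential template


@dataclass
class APTemplate:
    """Piecewise-linear action potential: linear upstroke, flat plateau,
    linear repolarization ramp back to rest."""

    upstroke: float = 10.0  # ms
    plateau: float = 300.0  # ms
    repol: float = 200.0  # ms
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("upstroke", "plateau", "repol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def support(self) -> float:
        """Total duration of the non-zero part of the template (ms)."""
        return self.upstroke + self.plateau + self.repol

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Template value at time ``t`` (ms) after wavefront arrival."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        if self.upstroke > 0:
            rising = (t >= 0) & (t < self.upstroke)
            v[rising] = t[rising] / self.upstroke
        high = (t >= self.upstroke) & (t < self.upstroke + self.plateau)
        v[high] = 1.0
        if self.repol > 0:
            t0 = self.upstroke + self.plateau
            falling = (t >= t0) & (t < t0 + self.repol)
            v[falling] = 1.0 - (t[falling] - t0) / self.repol
        return v * self.amplitude

    def apd(self, level: float = 0.8) -> float:
        """Analytic action potential duration at ``level`` repolarization,
        measured from the half-amplitude upstroke crossing (the activation
        reference used by the mapping module)."""
        return 0.5 * self.upstroke + self.plateau + level * self.repol


@dataclass
class WaveSimConfig:
    """Configuration for a propagating-wave fluorescence movie."""

    rows: int = 24
    cols: int = 21
    pixel_size: float = 1.0  # mm
    dt: float = 1000.0 / 1200.0  # ms
    duration: float = 700.0  # ms
    source: str = "plane"  # "plane" | "point"
    direction_deg: float = 0.0  # plane-wave travel direction (0 = +x)
    origin_rc: tuple = (0.0, 0.0)  # point-source location, fractional (row, col)
    cv_true: float = 25.0  # cm/s
    ap: APTemplate = field(default_factory=APTemplate)
    noise_sd: float = 0.0  # fraction of template amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cv_true <= 0:
            raise ValueError("cv_true must be positive")
        if self.dt <= 0 or self.pixel_size <= 0 or self.duration <= 0:
            raise ValueError("dt, pixel_size and duration must be positive")
        if self.source not in ("plane", "point"):
            raise ValueError(f"unknown source kind {self.source!r}")


def arrival_truth(config: WaveSimConfig) -> np.ndarray:
    """Closed-form wavefront arrival (upstroke onset) times in ms per pixel."""
    v_mm_ms = config.cv_true * 0.01  # 1 cm/s = 0.01 mm/ms
    r, c = np.mgrid[0 : config.rows, 0 : config.cols]
    x = c * config.pixel_size
    y = r * config.pixel_size
    if config.source == "plane":
        ang = math.radians(config.direction_deg)
        proj = x * math.cos(ang) + y * math.sin(ang)
        dist = proj - proj.min()
    else:
        oy = config.origin_rc[0] * config.pixel_size
        ox = config.origin_rc[1] * config.pixel_size
        dist = np.hypot(x - ox, y - oy)
    return dist / v_mm_ms


def gen_wave_movie(config: WaveSimConfig):
    """Simulate a propagating action-potential movie.

    Returns
    -------
    (MovieStack, ActivationMap, float)
        The movie, the ground-truth activation map, and the analytic APD80 of
        the template.  Truth activation times use the half-amplitude upstroke
        reference (wavefront arrival plus half the upstroke duration), the
        same convention the mapping module measures.

    Raises
    ------
    ValueError
        If ``duration`` is too short for the last-activating pixel to finish
        repolarizing.
    """
    arrival = arrival_truth(config)
    needed = arrival.max() + config.ap.support
    if config.duration < needed:
        rc = np.unravel_index(np.argmax(arrival), arrival.shape)
        raise ValueError(
            f"duration {config.duration:g} ms too short: pixel {tuple(int(i) for i in rc)} "
            f"activates last at {arrival.max():.1f} ms and needs {needed:.1f} ms "
            "to repolarize"
        )
    act = arrival + 0.5 * config.ap.upstroke
    t = np.arange(0.0, config.duration, config.dt)
    frames = config.ap(t[:, None, None] - arrival[None, :, :])
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        frames = frames + rng.normal(
            0.0, config.noise_sd * config.ap.amplitude, frames.shape
        )
    stim = config.origin_rc if config.source == "point" else None
    movie = MovieStack(
        frames=frames,
        dt=config.dt,
        pixel_size=config.pixel_size,
        channel="voltage",
        meta={"generator": "gen_wave_movie", "cv_true": config.cv_true},
    )
    truth = ActivationMap(act_time=act, pixel_size=config.pixel_size, stimulus_rc=stim)
    return movie, truth, config.ap.apd(0.8)


# ---------------------------------------------------------------------------
# Twitch trains


@dataclass
class TwitchSimConfig:
    """Configuration for a stimulated isometric twitch train.

    ``shape="biexp"`` uses a double-exponential waveform scaled to peak at
    ``amplitude``; ``shape="triangle"`` interprets ``tau_rise``/``tau_decay``
    as linear ramp durations (closed-form kinetics for oracle tests).
    """

    dt: float = 1.0  # ms
    n_twitches: int = 5
    stim_frequency: float = 1.0  # Hz
    amplitude: float = 4.0  # mN
    tau_rise: float = 30.0  # ms
    tau_decay: float = 150.0  # ms
    passive_offset: float = 1.0  # mN
    noise_sd: float = 0.0  # mN
    seed: int = 0
    shape: str = "biexp"
    lead_in: float = 200.0  # ms of baseline before the first stimulus
    allow_truncation: bool = False

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.shape not in ("biexp", "triangle"):
            raise ValueError(f"unknown twitch shape {self.shape!r}")


def _twitch_waveform(config: TwitchSimConfig):
    """Return (waveform fn of ms-from-stimulus, support in ms)."""
    A, tr, td = config.amplitude, config.tau_rise, config.tau_decay
    if config.shape == "triangle":
        support = tr + td

        def w(t):
            t = np.asarray(t, dtype=float)
            out = np.zeros_like(t)
            up = (t >= 0) & (t < tr)
            out[up] = A * t[up] / tr
            down = (t >= tr) & (t < tr + td)
            out[down] = A * (1.0 - (t[down] - tr) / td)
            return out

        return w, support

    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak_val = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    # Decayed below 1 % of the peak-normalized amplitude.
    support = td * math.log(100.0 / peak_val)

    def w(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0
        tp = t[pos]
        out[pos] = A / peak_val * (np.exp(-tp / td) - np.exp(-tp / tr))
        return out

    return w, support


def _crossing_up(t, y, level):
    """First upward crossing of ``level``, linearly interpolated."""
    above = y >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return None
    i = idx[0]
    return t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i])


def _crossing_down(t, y, level, start_index=0):
    """First downward crossing of ``level`` at or after ``start_index``."""
    below = y <= level
    idx = np.flatnonzero(~below[:-1] & below[1:])
    idx = idx[idx >= start_index]
    if idx.size == 0:
        return None
    i = idx[0]
    return t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i])


def twitch_truth(config: TwitchSimConfig, resolution: float = 0.01) -> dict:
    """Kinetic truth for one noiseless twitch by dense-grid evaluation.

    Rise time is the 10->90 % activation interval, decay the 90->10 %
    relaxation interval, total the 10 % activation to 90 % relaxation
    (10 % of amplitude remaining) interval.
    """
    w, support = _twitch_waveform(config)
    t = np.arange(0.0, support + resolution, resolution)
    y = w(t)
    A = y.max()
    ipeak = int(np.argmax(y))
    up10 = _crossing_up(t, y, 0.1 * A)
    up90 = _crossing_up(t, y, 0.9 * A)
    down90 = _crossing_down(t, y, 0.9 * A, ipeak)
    down10 = _crossing_down(t, y, 0.1 * A, ipeak)
    return {
        "amplitude": float(A),
        "baseline": float(config.passive_offset),
        "peak_time": float(t[ipeak]),
        "rise_time": float(up90 - up10),
        "decay_time": float(down10 - down90),
        "total_time": float(down10 - up10),
        "support": float(support),
    }


def gen_twitch_train(config: TwitchSimConfig):
    """Simulate an isometric twitch train.

    Returns ``(ForceTrace, truth)`` where ``truth`` is the dense-grid kinetic
    summary of the noiseless waveform (see :func:`twitch_truth`).
    """
    w, support = _twitch_waveform(config)
    period = 1000.0 / config.stim_frequency
    if period < support and not config.allow_truncation:
        raise ValueError(
            f"stimulation period {period:g} ms shorter than single-twitch support "
            f"{support:.1f} ms; set allow_truncation=True to overlap twitches"
        )
    stim_times = config.lead_in + period * np.arange(config.n_twitches)
    t_end = stim_times[-1] + min(support, period) + config.lead_in
    t = np.arange(0.0, t_end, config.dt)
    force = np.full_like(t, config.passive_offset)
    for s in stim_times:
        force += w(t - s)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        force = force + rng.normal(0.0, config.noise_sd, force.shape)
    trace = ForceTrace(
        time=t,
        force=force,
        stim_times=stim_times,
        frequency=config.stim_frequency,
        meta={"generator": "gen_twitch_train", "shape": config.shape},
    )
    return trace, twitch_truth(config)


# ---------------------------------------------------------------------------
# Hyperspectral vessel phantoms


@dataclass
class VesselSegment:
    """Straight vessel segment: end points in pixel (row, col) coordinates and
    a radius in pixels."""

    p0: tuple
    p1: tuple
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass
class VesselPhantomConfig:
    """Configuration for a Beer-Lambert hyperspectral vessel phantom."""

    rows: int = 96
    cols: int = 96
    pixel_size_um: float = 10.0
    wavelengths: Sequence[float] = field(
        default_factory=lambda: tuple(range(500, 601, 10))
    )
    vessels: Sequence[VesselSegment] = field(default_factory=tuple)
    hb_total: float = 2e-5  # relative concentration along vessels
    oxy_fraction: float = 0.7  # HbO2 share of total hemoglobin
    background_intensity: float = 1000.0
    noise_sd: float = 0.0  # fraction of background intensity
    seed: int = 0
    roi: Optional[np.ndarray] = None  # defaults to full image

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not 0 <= self.oxy_fraction <= 1:
            raise ValueError("oxy_fraction must be in [0, 1]")
        if self.hb_total < 0:
            raise ValueError("hb_total must be non-negative")


def rasterize_vessels(config: VesselPhantomConfig) -> np.ndarray:
    """Binary vessel footprint: pixels whose center lies within one radius of
    any segment center-line."""
    mask = np.zeros((config.rows, config.cols), dtype=bool)
    r, c = np.mgrid[0 : config.rows, 0 : config.cols]
    for seg in config.vessels:
        p0 = np.asarray(seg.p0, dtype=float)
        p1 = np.asarray(seg.p1, dtype=float)
        d = p1 - p0
        den = float(d @ d)
        if den == 0:
            dist = np.hypot(r - p0[0], c - p0[1])
        else:
            tt = ((r - p0[0]) * d[0] + (c - p0[1]) * d[1]) / den
            tt = np.clip(tt, 0.0, 1.0)
            dist = np.hypot(r - (p0[0] + tt * d[0]), c - (p0[1] + tt * d[1]))
        mask |= dist <= seg.radius
    return mask


def gen_hyperspectral_phantom(config: VesselPhantomConfig):
    """Simulate a hyperspectral brightfield stack of a vessel phantom.

    Transmitted intensity along vessel footprints follows Beer-Lambert
    attenuation, ``I = I0 * 10**-(eps_HbO2*c1 + eps_Hb*c2)`` with unit
    pathlength absorbed into the relative concentration; background pixels
    transmit at ``I0``.

    Returns ``(HyperspectralStack, VesselMask, bvd_truth)``.
    """
    footprint = rasterize_vessels(config)
    roi = (
        np.ones_like(footprint)
        if config.roi is None
        else np.asarray(config.roi, dtype=bool)
    )
    wl = np.asarray(config.wavelengths, dtype=float)
    eps1, eps2 = extinction_at(wl)
    c1 = np.where(footprint, config.oxy_fraction * config.hb_total, 0.0)
    c2 = np.where(footprint, (1.0 - config.oxy_fraction) * config.hb_total, 0.0)
    absorbance = eps1[:, None, None] * c1 + eps2[:, None, None] * c2
    i0 = config.background_intensity
    images = i0 * np.power(10.0, -absorbance)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        images = images + rng.normal(0.0, config.noise_sd * i0, images.shape)
        images = np.clip(images, 1e-6 * i0, None)
    stack = HyperspectralStack(
        images=images,
        wavelengths=wl,
        pixel_size_um=config.pixel_size_um,
        i_ref=np.full(wl.size, i0),
        roi=roi,
        meta={"generator": "gen_hyperspectral_phantom", "hb_total": config.hb_total},
    )
    truth_mask = VesselMask(
        mask=footprint & roi, roi=roi, provenance={"source": "phantom truth"}
    )
    bvd_truth = float((footprint & roi).sum() / roi.sum())
    return stack, truth_mask, bvd_truth


# ---------------------------------------------------------------------------
# Calcium flash movies


def gen_calcium_movie(
    dff_true: float,
    rows: int = 96,
    cols: int = 96,
    flash_rate_hz: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    f_base: float = 100.0,
    dt: float = 20.0,
    pixel_size: float = 0.016,
    duration: float = 10_000.0,
    rise: float = 60.0,
    hold: float = 60.0,
    decay: float = 200.0,
) -> MovieStack:
    """Simulate a gCaMP flash movie with a prescribed dF/F.

    Flashes are periodic at ``flash_rate_hz``; each flash ramps linearly to
    ``f_base * (1 + dff_true)``, holds there for ``hold`` ms, then ramps back.
    ``noise_sd`` is a fraction of ``f_base``.
    """
    if dff_true < 0:
        raise ValueError("dff_true must be non-negative")
    t = np.arange(0.0, duration, dt)
    period = 1000.0 / flash_rate_hz
    phase = np.mod(t - period / 2.0, period)  # first flash mid-way into the record
    shape = np.zeros_like(t)
    up = phase < rise
    shape[up] = phase[up] / rise
    flat = (phase >= rise) & (phase < rise + hold)
    shape[flat] = 1.0
    down = (phase >= rise + hold) & (phase < rise + hold + decay)
    shape[down] = 1.0 - (phase[down] - rise - hold) / decay
    trace = f_base * (1.0 + dff_true * shape)
    frames = np.repeat(trace[:, None, None], rows, axis=1)
    frames = np.repeat(frames, cols, axis=2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd * f_base, frames.shape)
    return MovieStack(
        frames=frames,
        dt=dt,
        pixel_size=pixel_size,
        channel="calcium",
        meta={
            "generator": "gen_calcium_movie",
            "dff_true": dff_true,
            "flash_rate_hz": flash_rate_hz,
        },
    )


# ---------------------------------------------------------------------------
# Arrhythmia episodes


def gen_arrhythmia_episode(
    kind: str,
    post_pacing_activity_duration_s: float = 0.0,
    dt_s: float = 0.005,
    pacing_duration_s: float = 2.0,
    pacing_rate_hz: float = 5.0,
    ectopic_rate_hz: float = 8.0,
    tail_s: float = 5.0,
) -> ActivityTrace:
    """Simulate an electrical-activity trace around a burst-pacing episode.

    The trace holds regular paced deflections up to the pacing-offset marker,
    then, depending on ``kind``, ectopic deflections lasting exactly
    ``post_pacing_activity_duration_s`` (the last deflection falls on the end
    of that interval).  Consistency of ``kind`` with the 60 s sustained /
    unsustained boundary is enforced.
    """
    dur = float(post_pacing_activity_duration_s)
    if kind == "none":
        if dur != 0:
            raise ValueError("kind='none' requires zero post-pacing activity")
    elif kind == "unsustained":
        if not 0 < dur < 60:
            raise ValueError("kind='unsustained' requires 0 < duration < 60 s")
    elif kind == "sustained":
        if dur < 60:
            raise ValueError("kind='sustained' requires duration >= 60 s")
    else:
        raise ValueError(f"unknown episode kind {kind!r}")

    offset = pacing_duration_s
    total = offset + max(dur, 60.0) + tail_s
    t = np.arange(0.0, total, dt_s)
    v = np.zeros_like(t)

    def add_spikes(times):
        idx = np.clip(np.round(np.asarray(times) / dt_s).astype(int), 0, t.size - 1)
        v[idx] = 1.0

    add_spikes(np.arange(0.0, offset, 1.0 / pacing_rate_hz))
    if dur > 0:
        ect = np.arange(0.0, dur, 1.0 / ectopic_rate_hz)
        ect = np.append(ect, dur)  # activity ends exactly at the marker
        add_spikes(offset + ect)
    return ActivityTrace(time_s=t, value=v, pacing_offset_s=offset)
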