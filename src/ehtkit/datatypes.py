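"""Shared data containers for movies, maps, traces, and tabular inputs.

Conventions used throughout the package:

* arrays are indexed ``[t, row, col]``, 0-based;
* the physical origin sits at the upper-left pixel center;
* times are milliseconds from recording start (episode-scale traces used
  for arrhythmia classification carry seconds and say so in field names);
* lengths are millimetres (micrometres where conventional for pixels),
  forces are millinewtons, conduction velocities are cm/s.

Undefined pixels are NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class MovieStack:
    """Fluorescence movie with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (t, rows, cols)
        Fluorescence in arbitrary units.
    dt : float
        Sampling interval in ms.
    pixel_size : float
        Pixel edge length in mm.
    channel : str
        ``"voltage"`` or ``"calcium"``.
    mask : ndarray of bool, shape (rows, cols), optional
        Valid-pixel mask; defaults to all-valid.
    """

    frames: np.ndarray
    dt: float
    pixel_size: float
    channel: str = "voltage"
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, rows, cols) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match frame shape "
                    f"{self.frames.shape[1:]}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Frame times in ms."""
        return np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        """Record duration in ms (time of last frame)."""
        return (self.n_frames - 1) * self.dt

    def copy(self) -> "MovieStack":
        return MovieStack(
            frames=self.frames.copy(),
            dt=self.dt,
            pixel_size=self.pixel_size,
            channel=self.channel,
            mask=self.mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ActivationMap:
    """Per-pixel activation time in ms; NaN outside the defined set."""

    act_time: np.ndarray
    pixel_size: float
    stimulus_rc: Optional[tuple] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.act_time = np.asarray(self.act_time, dtype=float)
        if self.act_time.ndim != 2:
            raise ValueError("act_time must be 2-D")
        defined = self.act_time[np.isfinite(self.act_time)]
        if defined.size and defined.min() < 0:
            raise ValueError("activation times must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.act_time)


@dataclass
class APDMap:
    """Per-pixel action potential duration (ms) at a repolarization level."""

    apd: np.ndarray
    level: float = 0.8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.apd = np.asarray(self.apd, dtype=float)
        if not 0 < self.level < 1:
            raise ValueError(f"repolarization level must be in (0, 1), got {self.level}")
        defined = self.apd[np.isfinite(self.apd)]
        if defined.size and defined.min() <= 0:
            raise ValueError("defined APD values must be positive")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.apd)


@dataclass
class CVResult:
    """Conduction velocity estimate in cm/s."""

    mean_cv: float
    speed_map: Optional[np.ndarray]
    direction: Optional[np.ndarray]
    method: str
    n_pixels: int
    meta: dict = field(default_factory=dict)


@dataclass
class EpisodeClassification:
    """Arrhythmia verdict for one post-pacing episode."""

    verdict: str  # "none" | "unsustained" | "sustained"
    ectopic_duration_s: float
    pacing_offset_s: float
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    capped: bool = False

    def __post_init__(self) -> None:
        if self.verdict not in ("none", "unsustained", "sustained"):
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass
class ActivityTrace:
    """Episode-scale electrical activity trace (seconds; used for arrhythmia
    classification, where the relevant horizon is a minute)."""

    time_s: np.ndarray
    value: np.ndarray
    pacing_offset_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape:
            raise ValueError("time and value must have matching shapes")


@dataclass
class ForceTrace:
    """Time-force series with optional protocol annotations."""

    time: np.ndarray  # ms
    force: np.ndarray  # mN
    stim_times: Optional[np.ndarray] = None  # ms
    frequency: Optional[float] = None  # Hz
    strain: Optional[float] = None  # percent of culture length
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have matching shapes")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.stim_times is not None:
            self.stim_times = np.asarray(self.stim_times, dtype=float)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class TwitchMetrics:
    """Kinetic summary of a single twitch."""

    amplitude: float  # mN above baseline
    rise_time: float  # ms, 10 -> 90 % activation
    decay_time: float  # ms, 90 -> 10 % relaxation
    total_time: Optional[float]  # ms, 10 % activation -> 90 % relaxation
    baseline: float  # mN
    peak_time: Optional[float] = None  # ms
    flags: tuple = ()


@dataclass
class ForceLengthCurve:
    """Active/passive force at each strain level of a stretch protocol."""

    strain_pct: np.ndarray  # percent of culture length, e.g. 100..120
    passive_mN: np.ndarray
    active_mN: np.ndarray
    csa_mm2: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain_pct = np.asarray(self.strain_pct, dtype=float)
        self.passive_mN = np.asarray(self.passive_mN, dtype=float)
        self.active_mN = np.asarray(self.active_mN, dtype=float)
        if not np.all(np.diff(self.strain_pct) > 0):
            raise ValueError("strain levels must be increasing")
        if np.any(self.passive_mN < 0):
            raise ValueError("passive tension must be non-negative")


@dataclass
class FFRResult:
    """Force-frequency relationship normalized to the 1 Hz amplitude."""

    frequencies: np.ndarray  # Hz
    normalized_pct: np.ndarray  # percent of 1 Hz force
    slope: float  # percent per Hz


@dataclass
class HyperspectralStack:
    """Wavelength-indexed brightfield image stack."""

    images: np.ndarray  # (n_wavelengths, rows, cols)
    wavelengths: np.ndarray  # nm, strictly increasing
    pixel_size_um: float
    i_ref: Optional[np.ndarray] = None  # per-wavelength scalar or image
    roi: Optional[np.ndarray] = None  # bool mask; default: whole image
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (wavelength, rows, cols)")
        if self.images.shape[0] != self.wavelengths.size:
            raise ValueError(
                f"{self.images.shape[0]} images but {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.roi is None:
            self.roi = np.ones(self.images.shape[1:], dtype=bool)
        else:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.images.shape[1:]:
                raise ValueError("ROI shape does not match image shape")


@dataclass
class HbMap:
    """Relative total-hemoglobin concentration per pixel."""

    thb: np.ndarray
    residual: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thb = np.asarray(self.thb, dtype=float)
        defined = self.thb[np.isfinite(self.thb)]
        if defined.size and defined.min() < -1e-9:
            raise ValueError("hemoglobin concentrations must be non-negative")


@dataclass
class VesselMask:
    """Binary vessel image restricted to a patch ROI."""

    mask: np.ndarray
    roi: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.mask.shape != self.roi.shape:
            raise ValueError("mask and ROI shapes differ")
        if np.any(self.mask & ~self.roi):
            raise ValueError("vessel mask must lie inside the ROI")


@dataclass
class ROISet:
    """Rectangular regions of interest, (r0, r1, c0, c1) half-open bounds."""

    rois: list
    pixel_size_um: float

    def __post_init__(self) -> None:
        for r0, r1, c0, c1 in self.rois:
            if r1 <= r0 or c1 <= c0:
                raise ValueError("degenerate ROI")

    @property
    def count(self) -> int:
        return len(self.rois)


@dataclass
class CaMetrics:
    """Calcium transient summary over a set of ROIs."""

    dff_per_roi: np.ndarray
    mean_dff: float
    transient_times: list
    rate_per_min: float
    flags: tuple = ()


@dataclass
class MorphometryRecord:
    """Group-level cells-per-field and thickness means."""

    label: str
    cells_per_fov: float
    thickness_um: float

    def __post_init__(self) -> None:
        if self.cells_per_fov <= 0 or self.thickness_um <= 0:
            raise ValueError("morphometry fields must be positive")
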