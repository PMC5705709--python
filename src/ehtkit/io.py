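"""Readers, writers, and reproducible stage runs.

Movies and hyperspectral stacks travel as multi-page TIFF plus a JSON
sidecar; traces as two-column CSV; maps as CSV grids with optional PNG
renders.  Metadata is never silently defaulted: a sidecar missing ``dt_ms``
or ``pixel_size_mm`` is an error.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .datatypes import ActivationMap, APDMap, ForceTrace, HyperspectralStack, MovieStack

# ---------------------------------------------------------------------------
# Movies


def write_movie(stack: MovieStack, tiff_path, sidecar_path=None) -> Path:
    """Write a movie as multi-page TIFF + JSON sidecar; returns the sidecar
    path."""
    tiff_path = Path(tiff_path)
    sidecar_path = (
        Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    )
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    meta = {
        "dt_ms": stack.dt,
        "pixel_size_mm": stack.pixel_size,
        "channel": stack.channel,
    }
    if not stack.mask.all():
        meta["mask"] = stack.mask.astype(int).tolist()
    sidecar_path.write_text(json.dumps(meta, indent=2))
    return sidecar_path


def read_movie(tiff_path, sidecar_path=None) -> MovieStack:
    """Read a multi-page TIFF movie with its JSON sidecar."""
    tiff_path = Path(tiff_path)
    sidecar_path = (
        Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    )
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        raise ValueError("movie TIFF must contain at least 2 pages")
    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("dt_ms", "pixel_size_mm"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing required key {key!r}")
    mask = np.asarray(meta["mask"], dtype=bool) if "mask" in meta else None
    if mask is not None and mask.shape != frames.shape[1:]:
        raise ValueError(
            f"sidecar mask shape {mask.shape} does not match frames {frames.shape[1:]}"
        )
    return MovieStack(
        frames=np.asarray(frames, dtype=float),
        dt=float(meta["dt_ms"]),
        pixel_size=float(meta["pixel_size_mm"]),
        channel=meta.get("channel", "voltage"),
        mask=mask,
    )


def read_photodiode_csv(
    signal_csv, coords_csv, dt_ms: float, pixel_size_mm: float
) -> MovieStack:
    """Assemble a masked grid movie from photodiode channel data.

    ``signal_csv`` is wide (one column per channel, one row per frame);
    ``coords_csv`` maps ``channel`` to integer grid ``row``/``col``.
    Channels absent from the coordinate table are an error; grid positions
    without a channel are masked out.
    """
    sig = pd.read_csv(signal_csv)
    coords = pd.read_csv(coords_csv)
    for col in ("channel", "row", "col"):
        if col not in coords.columns:
            raise ValueError(f"coordinate table missing column {col!r}")
    lookup = {str(ch): (int(r), int(c)) for ch, r, c in
              zip(coords["channel"], coords["row"], coords["col"])}
    missing = [c for c in sig.columns if str(c) not in lookup]
    if missing:
        raise ValueError(f"channels without coordinates: {missing[:5]}")
    rows = coords["row"].max() + 1
    cols = coords["col"].max() + 1
    frames = np.full((len(sig), rows, cols), np.nan)
    mask = np.zeros((rows, cols), dtype=bool)
    for ch in sig.columns:
        r, c = lookup[str(ch)]
        frames[:, r, c] = sig[ch].to_numpy(dtype=float)
        mask[r, c] = True
    frames[:, ~mask] = 0.0
    return MovieStack(
        frames=frames, dt=dt_ms, pixel_size=pixel_size_mm, channel="voltage", mask=mask
    )


# ---------------------------------------------------------------------------
# Hyperspectral stacks


def write_hyperspectral(stack: HyperspectralStack, tiff_path, sidecar_path=None) -> Path:
    tiff_path = Path(tiff_path)
    sidecar_path = (
        Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    )
    tifffile.imwrite(tiff_path, stack.images.astype(np.float32))
    meta = {
        "wavelengths_nm": stack.wavelengths.tolist(),
        "pixel_size_um": stack.pixel_size_um,
    }
    if stack.i_ref is not None:
        meta["i_ref"] = np.asarray(stack.i_ref).tolist()
    sidecar_path.write_text(json.dumps(meta, indent=2))
    return sidecar_path


def read_hyperspectral(tiff_path, sidecar_path=None, roi=None) -> HyperspectralStack:
    tiff_path = Path(tiff_path)
    sidecar_path = (
        Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    )
    images = tifffile.imread(tiff_path)
    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("wavelengths_nm", "pixel_size_um"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing required key {key!r}")
    i_ref = np.asarray(meta["i_ref"], dtype=float) if "i_ref" in meta else None
    return HyperspectralStack(
        images=np.asarray(images, dtype=float),
        wavelengths=np.asarray(meta["wavelengths_nm"], dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
        i_ref=i_ref,
        roi=roi,
    )


def roi_from_polygon(vertices, shape) -> np.ndarray:
    """Rasterize a polygon (list of (row, col) vertices) to a boolean mask."""
    from skimage.draw import polygon

    v = np.asarray(vertices, dtype=float)
    rr, cc = polygon(v[:, 0], v[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# Traces, maps


def write_trace(trace: ForceTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": trace.time, "value": trace.force}).to_csv(
        path, index=False
    )
    return path


def read_trace(path, **kwargs) -> ForceTrace:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise ValueError(f"trace CSV {path} missing 'time_ms' column")
    value_col = [c for c in df.columns if c != "time_ms"][0]
    return ForceTrace(
        time=df["time_ms"].to_numpy(),
        force=df[value_col].to_numpy(),
        **kwargs,
    )


def write_map_csv(arr: np.ndarray, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(arr, dtype=float), delimiter=",", fmt="%.6g")
    return path


def render_map_png(arr: np.ndarray, path, cmap: str = "viridis") -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(arr, dtype=float), cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Configuration and provenance


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(params: dict) -> str:
    """Stable hash of a parameter mapping (canonical JSON, sha256)."""
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance_record(stage: str, params: dict, seed: Optional[int]) -> dict:
    return {
        "package": "ehtkit",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(params),
        "parameters": params,
    }


def write_provenance(out_dir, stage: str, params: dict, seed: Optional[int]) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(provenance_record(stage, params, seed), indent=2))
    return path
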