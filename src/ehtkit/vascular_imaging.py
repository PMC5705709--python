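"""Hyperspectral hemoglobin unmixing, contrast enhancement, vessel
segmentation, and blood-vessel density (BVD).

The unmixing model is a per-pixel non-negative least-squares fit of the
Beer-Lambert absorbance to the packaged oxy/deoxy-hemoglobin extinction
spectra; total hemoglobin is the sum of the two fitted concentrations.
Scattering and pathlength are absorbed into relative concentration units —
no absolute quantification is claimed.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.optimize import nnls
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.measure import label

from .datatypes import HbMap, HyperspectralStack, VesselMask
from .spectra import extinction_at


def absorbance(stack: HyperspectralStack, i_ref=None) -> np.ndarray:
    """Per-pixel absorbance ``A(lambda) = -log10(I / I_ref)``.

    ``i_ref`` defaults to the stack's reference intensities; when those are
    absent, the per-wavelength median over the pixels outside the ROI (an
    avascular background region) is used.  Non-positive intensities come out
    NaN.
    """
    if i_ref is None:
        i_ref = stack.i_ref
    if i_ref is None:
        bg = ~stack.roi
        if not bg.any():
            raise ValueError(
                "no reference intensities and no background region outside the ROI"
            )
        i_ref = np.median(stack.images[:, bg], axis=1)
    i_ref = np.asarray(i_ref, dtype=float)
    if i_ref.ndim == 1:
        i_ref = i_ref[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        a = -np.log10(stack.images / i_ref)
    a[stack.images <= 0] = np.nan
    return a


def unmix_hemoglobin(
    stack: HyperspectralStack,
    i_ref=None,
    fit_offset: bool = False,
) -> HbMap:
    """Total-hemoglobin map by non-negative spectral unmixing.

    Fits ``A(lambda) ~ eps_HbO2*c1 + eps_Hb*c2 (+ c0)`` per pixel with
    ``c1, c2 >= 0`` (the optional offset is unconstrained, modelled as the
    difference of two non-negative columns).  Returns total hemoglobin
    ``c1 + c2`` and the per-pixel residual norm.
    """
    n_unknowns = 3 if fit_offset else 2
    if stack.wavelengths.size < n_unknowns:
        raise ValueError(
            f"need at least {n_unknowns} wavelengths for {n_unknowns} unknowns"
        )
    eps1, eps2 = extinction_at(stack.wavelengths)
    cols = [eps1, eps2]
    if fit_offset:
        ones = np.ones_like(eps1)
        cols += [ones, -ones]  # free-sign offset under NNLS
    design = np.column_stack(cols)

    a = absorbance(stack, i_ref=i_ref)
    rows, colsn = a.shape[1:]
    thb = np.full((rows, colsn), np.nan)
    resid = np.full((rows, colsn), np.nan)
    for r in range(rows):
        for c in range(colsn):
            spec = a[:, r, c]
            if not np.all(np.isfinite(spec)):
                continue
            coef, rnorm = nnls(design, spec)
            thb[r, c] = coef[0] + coef[1]
            resid[r, c] = rnorm
    return HbMap(
        thb=thb,
        residual=resid,
        meta={"fit_offset": fit_offset, "n_wavelengths": int(stack.wavelengths.size)},
    )


def unmix_components(stack: HyperspectralStack, i_ref=None) -> tuple:
    """As :func:`unmix_hemoglobin` but returning the (c1, c2) component maps."""
    eps1, eps2 = extinction_at(stack.wavelengths)
    design = np.column_stack([eps1, eps2])
    a = absorbance(stack, i_ref=i_ref)
    rows, cols = a.shape[1:]
    c1 = np.full((rows, cols), np.nan)
    c2 = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            spec = a[:, r, c]
            if not np.all(np.isfinite(spec)):
                continue
            coef, _ = nnls(design, spec)
            c1[r, c], c2[r, c] = coef
    return c1, c2


def enhance_contrast(
    hb: HbMap,
    tile_size: int = 8,
    clip_limit: float = 0.01,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an Hb map.

    Output lies in [0, 1].  Tiles larger than the image fall back to global
    histogram equalization with a warning; a constant image comes back
    constant.
    """
    img = np.asarray(hb.thb, dtype=float)
    if not np.all(np.isfinite(img)):
        img = np.nan_to_num(img, nan=0.0)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    scaled = (img - lo) / (hi - lo)
    ny, nx = img.shape
    if tile_size >= min(ny, nx):
        warnings.warn("tile larger than image; using global equalization")
        return exposure.equalize_hist(scaled)
    kernel = (max(1, ny // tile_size), max(1, nx // tile_size))
    return exposure.equalize_adapthist(scaled, kernel_size=kernel, clip_limit=clip_limit)


def segment_vessels(
    enhanced: np.ndarray,
    roi: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
    min_object_px: int = 0,
) -> VesselMask:
    """Threshold an enhanced Hb image to a binary vessel mask inside the ROI.

    ``method="otsu"`` computes the threshold from the ROI histogram only;
    ``method="fixed"`` uses the supplied ``threshold``.  Objects smaller than
    ``min_object_px`` are removed.  A degenerate (single-valued) ROI
    histogram yields an empty mask with a warning.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    values = np.asarray(enhanced, dtype=float)[roi]
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.unique(values).size < 2:
            warnings.warn("degenerate histogram within ROI; returning empty mask")
            return VesselMask(
                mask=np.zeros_like(roi),
                roi=roi,
                provenance={"method": method, "degenerate": True},
            )
        thr = float(threshold_otsu(values))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = (np.asarray(enhanced) > thr) & roi
    if min_object_px > 0:
        labels = label(mask)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_object_px)
        mask &= ~np.isin(labels, small[small > 0])
    return VesselMask(
        mask=mask,
        roi=roi,
        provenance={
            "method": method,
            "threshold": thr,
            "min_object_px": min_object_px,
        },
    )


def bvd(mask: VesselMask) -> float:
    """Blood-vessel density: vessel pixels / ROI pixels, in [0, 1]."""
    roi_area = int(mask.roi.sum())
    if roi_area == 0:
        raise ValueError("ROI area is zero")
    return float(mask.mask.sum() / roi_area)


def bvd_fold_change(bvd_t1: float, bvd_t0: float) -> float:
    """Fold change in BVD between two time points (t1 relative to t0)."""
    if bvd_t0 <= 0:
        raise ValueError("baseline BVD must be positive for a fold change")
    return bvd_t1 / bvd_t0
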