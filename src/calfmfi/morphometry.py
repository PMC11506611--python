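"""Mask-based morphometry: subcutaneous fat thickness and marrow area.

The subcutaneous fat thickness (SFT) of a slice is the annulus area divided
by the mean of its inner and outer boundary lengths,

    SFT_i = 2 A_i / (L1_i + L2_i),

which for an annulus of constant thickness t equals t exactly.  Boundary
lengths are measured sub-pixel: contours are traced at the 0.5 iso-level of
a lightly Gaussian-smoothed mask (plain pixel-edge perimeters overestimate a
circle's length by several percent and would bias SFT low).  The subject
value averages the seven central slices (slices 2-8 of 9, 1-based).  The
fibula bone-marrow area (BMA) is the marrow-mask pixel count times the pixel
area, averaged over the same seven slices.

The peripheral calf-muscle ROI used for fat-infiltration histograms is the
muscle mask restricted to rows strictly inferior to the fibula centroid row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "MorphometryResult",
    "CENTRAL_SLICES",
    "boundary_lengths",
    "compute_sft",
    "compute_bma",
    "derive_muscle_roi",
    "perturb_mask",
    "measure_subject",
]

#: 1-based numbers of the seven central slices of a nine-slice stack
CENTRAL_SLICES = (2, 3, 4, 5, 6, 7, 8)

_CONTOUR_SMOOTH_PX = 1.0


@dataclass
class MorphometryResult:
    """Per-subject SFT/BMA with per-slice detail (slices 2-8)."""

    subject_id: str
    sft_mm: float
    bma_mm2: float
    sft_per_slice: dict  # slice number -> mm
    bma_per_slice: dict  # slice number -> mm^2
    area_per_slice: dict  # annulus area, mm^2
    boundary_per_slice: dict  # slice number -> (L1, L2) mm


class MaskTopologyError(ValueError):
    """Mask does not have the expected topology (e.g. not a 1-hole annulus)."""


def _count_components(mask: np.ndarray) -> int:
    _, n = ndimage.label(mask)
    return int(n)


def _contour_length(blob: np.ndarray, pixel_size: float) -> float:
    """Sub-pixel boundary length of a filled blob, in mm."""
    padded = np.pad(blob.astype(float), 2)
    smooth = ndimage.gaussian_filter(padded, _CONTOUR_SMOOTH_PX)
    contours = measure.find_contours(smooth, 0.5)
    if not contours:
        raise MaskTopologyError("no contour found at the 0.5 level")
    best = max(contours, key=len)
    d = np.diff(best, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum() * pixel_size)


def boundary_lengths(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Inner and outer boundary lengths (mm) of an annular mask.

    The outer boundary is traced on the hole-filled mask, the inner boundary
    on the hole itself, so arbitrarily thin annuli remain measurable.

    Raises
    ------
    MaskTopologyError
        If the mask is not a single connected component with exactly one hole.
    """
    mask = np.asarray(mask, dtype=bool)
    n_comp = _count_components(mask)
    if n_comp != 1:
        raise MaskTopologyError(f"expected 1 connected component, found {n_comp}")
    filled = ndimage.binary_fill_holes(mask)
    hole = filled & ~mask
    n_holes = _count_components(hole)
    if n_holes != 1:
        raise MaskTopologyError(f"expected exactly 1 hole, found {n_holes}")
    l_outer = _contour_length(filled, pixel_size)
    l_inner = _contour_length(hole, pixel_size)
    return l_inner, l_outer


def _as_slice_map(masks, expected=CENTRAL_SLICES) -> dict:
    if isinstance(masks, Mapping):
        m = dict(masks)
    else:
        m = dict(zip(expected, masks))
    if tuple(sorted(m)) != tuple(expected):
        raise ValueError(
            f"expected masks for slices {expected}, got {tuple(sorted(m))}"
        )
    return m


def compute_sft(sf_masks, pixel_size: float):
    """Subject SFT (mm): mean of per-slice 2A/(L1+L2) over slices 2-8.

    ``sf_masks`` is a mapping {slice number: annulus mask} for the seven
    central slices, or a sequence of seven masks taken as slices 2-8.

    Returns ``(sft_mm, detail)`` where ``detail`` maps slice number to a
    ``(sft, area, L1, L2)`` tuple.
    """
    m = _as_slice_map(sf_masks)
    detail = {}
    for s, mask in m.items():
        try:
            l1, l2 = boundary_lengths(mask, pixel_size)
        except MaskTopologyError as err:
            raise MaskTopologyError(f"slice {s}: {err}") from err
        area = float(np.count_nonzero(mask)) * pixel_size**2
        detail[s] = (2.0 * area / (l1 + l2), area, l1, l2)
    sft = float(np.mean([v[0] for v in detail.values()]))
    return sft, detail


def compute_bma(marrow_masks, pixel_size: float):
    """Subject BMA (mm^2): mean marrow area over slices 2-8.

    Returns ``(bma_mm2, {slice: area})``.
    """
    m = _as_slice_map(marrow_masks)
    detail = {}
    for s, mask in m.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(np.count_nonzero(mask))
        if n == 0:
            raise ValueError(f"slice {s}: empty marrow mask")
        if _count_components(mask) != 1:
            raise MaskTopologyError(f"slice {s}: marrow mask is not one component")
        detail[s] = n * pixel_size**2
    return float(np.mean(list(detail.values()))), detail


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def derive_muscle_roi(
    muscle_mask: np.ndarray, fibula_mask: np.ndarray, min_pixels: int = 100
) -> np.ndarray:
    """Peripheral calf-muscle ROI: muscle strictly inferior to the fibula.

    The dividing line is the horizontal row through the fibula centroid
    (computed over the full fibula mask, cortex plus marrow; rounded half
    down); only muscle pixels on rows strictly below it are kept.  A small
    (< ``min_pixels``) or empty ROI triggers a warning but is still returned.
    """
    fibula_mask = np.asarray(fibula_mask, dtype=bool)
    if not fibula_mask.any():
        raise ValueError("empty fibula mask")
    rows = np.nonzero(fibula_mask)[0]
    centroid_row = _round_half_down(float(rows.mean()))
    roi = np.asarray(muscle_mask, dtype=bool).copy()
    roi[: centroid_row + 1, :] = False
    if roi.sum() < min_pixels:
        warnings.warn(
            f"muscle ROI has only {int(roi.sum())} pixels "
            f"(inferior to row {centroid_row})",
            stacklevel=2,
        )
    return roi


def perturb_mask(
    mask: np.ndarray,
    magnitude: float,
    rng: np.random.Generator,
    smooth_px: float = 4.0,
    max_retries: int = 5,
) -> np.ndarray:
    """Emulate manual-redraw variability by jittering a mask boundary.

    The boundary is displaced along its normal by a smooth zero-mean random
    field with standard deviation ``magnitude`` pixels, implemented by
    thresholding the perturbed signed distance transform.  Topology
    (component and hole counts) is preserved; degenerate perturbations are
    retried up to ``max_retries`` times.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if magnitude == 0:
        return mask.copy()
    signed = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(
        ~mask
    )
    n_comp = _count_components(mask)
    n_holes = _count_components(ndimage.binary_fill_holes(mask) & ~mask)
    for _ in range(max_retries):
        noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), smooth_px)
        noise *= magnitude / max(noise.std(), 1e-12)
        new = (signed + noise) > 0
        new_holes = _count_components(ndimage.binary_fill_holes(new) & ~new)
        if _count_components(new) == n_comp and new_holes == n_holes:
            return new
    raise MaskTopologyError(
        f"perturbation destroyed mask topology in {max_retries} attempts"
    )


def measure_subject(mask_stack, subject_id: str = "") -> MorphometryResult:
    """SFT and BMA of one subject from its truth masks (slices 2-8)."""
    sf = {s: mask_stack.slice_mask("subcutaneous", s) for s in CENTRAL_SLICES}
    marrow = {s: mask_stack.slice_mask("marrow", s) for s in CENTRAL_SLICES}
    sft, sft_detail = compute_sft(sf, mask_stack.pixel_size)
    bma, bma_detail = compute_bma(marrow, mask_stack.pixel_size)
    return MorphometryResult(
        subject_id=subject_id,
        sft_mm=sft,
        bma_mm2=bma,
        sft_per_slice={s: v[0] for s, v in sft_detail.items()},
        bma_per_slice=bma_detail,
        area_per_slice={s: v[1] for s, v in sft_detail.items()},
        boundary_per_slice={s: (v[2], v[3]) for s, v in sft_detail.items()},
    )
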