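"""Endpoint-image uptake quantification and high-content dot counting.

Per-cell integrated fluid-phase (dextran) fluorescence from sum-projected
images: the cell outline is segmented from a plasma-membrane marker
channel (or supplied as a mask), a background estimate is taken from a
cell-free ROI, and the integrated intensity is
(mean in-cell - background) x cell area.  Dot counting segments connected
components above an intensity threshold and keeps those larger than a
pixel-area floor (default > 30 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class UptakeMeasurement:
    """Per-cell background-corrected integrated intensity."""

    cell_id: int
    cell_area_px: int
    cell_area_um2: float
    mean_in_cell: float
    background: float
    integrated_intensity: float
    flags: tuple[str, ...] = ()


def segment_cell_mask(
    membrane: np.ndarray,
    smooth_sigma: float = 2.0,
    qc_border: bool = True,
    min_area_px: int = 200,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Cell mask from a plasma-membrane marker image.

    Smoothed Otsu threshold followed by hole filling; small specks are
    dropped.  QC flags mark masks touching the image border or below the
    area floor (candidates for a manually supplied mask).
    """
    img = ndimage.gaussian_filter(np.asarray(membrane, dtype=float), smooth_sigma)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool), ("empty_segmentation",)
    thr = threshold_otsu(img)
    mask = ndimage.binary_fill_holes(img > thr)
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(img.shape, dtype=bool), ("empty_segmentation",)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = np.argmax(sizes) + 1
    mask = labels == keep
    flags = []
    if sizes[keep - 1] < min_area_px:
        flags.append("mask_too_small")
    if qc_border:
        border = np.zeros_like(mask)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (mask & border).any():
            flags.append("mask_touches_border")
    return mask, tuple(flags)


def quantify_uptake(
    dextran: np.ndarray,
    membrane_or_mask: np.ndarray,
    background_roi: np.ndarray | tuple[slice, slice],
    pixel_size_um: float = 1.0,
) -> list[UptakeMeasurement]:
    """Per-cell integrated dextran intensity, background corrected.

    ``membrane_or_mask`` is either a boolean mask (used as-is, labelled
    into cells) or a membrane-marker image (segmented).  The background is
    the mean dextran value over ``background_roi`` (boolean mask or slice
    pair), which must not overlap any cell mask.  Integrated intensity is
    (mean in-cell - background) x cell area in pixels, floored at zero
    with a flag when negative.
    """
    dex = np.asarray(dextran, dtype=float)
    seg_flags: tuple[str, ...] = ()
    mm = np.asarray(membrane_or_mask)
    if mm.dtype == bool:
        mask = mm
    else:
        mask, seg_flags = segment_cell_mask(mm)

    if isinstance(background_roi, tuple):
        bg_mask = np.zeros(dex.shape, dtype=bool)
        bg_mask[background_roi] = True
    else:
        bg_mask = np.asarray(background_roi, dtype=bool)
    if not bg_mask.any():
        raise ValueError("background ROI is empty")
    if (bg_mask & mask).any():
        raise ValueError("background ROI overlaps a cell mask")
    background = float(dex[bg_mask].mean())

    labels, n_cells = ndimage.label(mask)
    out: list[UptakeMeasurement] = []
    for cid in range(1, n_cells + 1):
        region = labels == cid
        area_px = int(region.sum())
        mean_in = float(dex[region].mean())
        integrated = (mean_in - background) * area_px
        flags = list(seg_flags)
        if integrated < 0:
            flags.append("negative_integral_floored")
            integrated = 0.0
        out.append(
            UptakeMeasurement(
                cell_id=cid,
                cell_area_px=area_px,
                cell_area_um2=area_px * pixel_size_um**2,
                mean_in_cell=mean_in,
                background=background,
                integrated_intensity=integrated,
                flags=tuple(flags),
            )
        )
    return out


def robust_dot_threshold(
    image: np.ndarray, mask: np.ndarray | None = None, z: float = 4.0
) -> float:
    """Default dot threshold: mean + z x robust SD of the (in-cell) background."""
    img = np.asarray(image, dtype=float)
    vals = img[mask] if mask is not None else img.ravel()
    med = float(np.median(vals))
    robust_sd = 1.4826 * float(np.median(np.abs(vals - med)))
    return float(vals.mean()) + z * robust_sd


def count_dots(
    image: np.ndarray,
    threshold: float,
    min_dot_area_px: int = 30,
    cell_masks: np.ndarray | None = None,
) -> pd.DataFrame:
    """Count bright dots per cell.

    Connected components (8-connectivity) of ``image > threshold`` with
    area strictly greater than ``min_dot_area_px`` are counted; with
    ``cell_masks`` (a label image) each dot is assigned to the cell under
    its centroid, otherwise everything is one cell.  Returns
    ``cell_id, n_dots``.
    """
    img = np.asarray(image, dtype=float)
    labels, n = ndimage.label(img > threshold, structure=np.ones((3, 3), dtype=int))
    dots = []
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        centroids = ndimage.center_of_mass(img > threshold, labels, range(1, n + 1))
        for size, (cy, cx) in zip(sizes, centroids):
            if size > min_dot_area_px:
                dots.append((int(round(cy)), int(round(cx))))
    if cell_masks is None:
        return pd.DataFrame({"cell_id": [1], "n_dots": [len(dots)]})
    cell_masks = np.asarray(cell_masks)
    cells = sorted(int(c) for c in np.unique(cell_masks) if c != 0)
    counts = {c: 0 for c in cells}
    for cy, cx in dots:
        c = int(cell_masks[cy, cx])
        if c != 0:
            counts[c] = counts.get(c, 0) + 1
    return pd.DataFrame(
        {"cell_id": list(counts), "n_dots": [counts[c] for c in counts]}
    )
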