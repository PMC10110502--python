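"""Cell masks, cortex ring masks, cell centers and nuclei density."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InputError

__all__ = [
    "CellMaskSeries",
    "NucleiDensityResult",
    "segment_cell",
    "cortex_mask",
    "cell_center",
    "nuclei_density",
    "CROSS_ELEMENT",
    "SQUARE_ELEMENT",
]

# 3x3 cross (4-connectivity) is the default structuring element; Fiji's
# default erode uses the full 3x3 square — pass SQUARE_ELEMENT to match it.
CROSS_ELEMENT = ndimage.generate_binary_structure(2, 1)
SQUARE_ELEMENT = ndimage.generate_binary_structure(2, 2)


@dataclass
class CellMaskSeries:
    """Per-frame binary cell masks with derived cortex rings and centers."""

    masks: np.ndarray  # (T, Y, X) bool
    centers: np.ndarray = None  # (T, 2) float, (y, x)
    cortex_masks: np.ndarray = None  # (T, Y, X) bool
    erosion_count: int = 4
    degenerate_frames: list = field(default_factory=list)

    @classmethod
    def from_masks(cls, masks, erosions: int = 4, element=CROSS_ELEMENT) -> "CellMaskSeries":
        masks = np.asarray(masks, dtype=bool)
        centers = np.array([cell_center(m) for m in masks])
        rings = np.empty_like(masks)
        degenerate = []
        for t, m in enumerate(masks):
            rings[t], flagged = cortex_mask(m, erosions=erosions, element=element, return_flag=True)
            if flagged:
                degenerate.append(t)
        return cls(masks, centers, rings, erosions, degenerate)


@dataclass
class NucleiDensityResult:
    """Mean distance to the k closest neighbours, one value per nucleus."""

    per_nucleus_mean_distance: np.ndarray  # um
    k: int = 5


def segment_cell(frame: np.ndarray, threshold="otsu") -> np.ndarray:
    """Threshold a frame, keep the largest connected component, fill holes.

    ``threshold`` is either an intensity value or ``"otsu"``.  An all-false
    mask is a valid outcome when nothing passes the threshold.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise InputError("empty frame")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InputError(f"unknown threshold method {threshold!r}")
        from skimage.filters import threshold_otsu

        if np.ptp(frame) == 0:
            return np.ones_like(frame, dtype=bool)  # uniform image: all foreground
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold)
    binary = frame > thr if isinstance(threshold, str) else frame >= thr
    if not binary.any():
        return binary
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(binary)


def cortex_mask(mask: np.ndarray, erosions: int = 4, element=CROSS_ELEMENT, return_flag: bool = False):
    """Ring mask: ``mask AND NOT erode^n(mask)``.

    If ``erosions`` passes of the structuring element empty the mask, the
    whole input mask is returned and flagged (degenerate-size rule), so that
    batch runs survive tiny cells.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty mask")
    eroded = ndimage.binary_erosion(mask, structure=element, iterations=erosions) if erosions > 0 else mask
    if erosions > 0 and not eroded.any():
        ring, flagged = mask.copy(), True
    else:
        ring, flagged = mask & ~eroded, False
    return (ring, flagged) if return_flag else ring


def cell_center(mask: np.ndarray) -> tuple:
    """Unweighted centroid ``(y, x)`` of the foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty mask")
    ys, xs = np.nonzero(mask)
    return float(ys.mean()), float(xs.mean())


def nuclei_density(centroids, k: int = 5) -> NucleiDensityResult:
    """Mean Euclidean distance from each nucleus to its ``k`` nearest others.

    ``centroids`` is an ``(n, 3)`` array or a DataFrame with columns
    ``x_um, y_um, z_um``; distances are in the input units (micrometers).
    """
    if hasattr(centroids, "columns"):
        centroids = centroids[["x_um", "y_um", "z_um"]].to_numpy()
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2:
        raise InputError("centroids must be a 2D point table")
    if len(pts) < k + 1:
        raise InputError(f"need at least {k + 1} points for k={k} neighbours")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)
    return NucleiDensityResult(per_nucleus_mean_distance=dists[:, 1:].mean(axis=1), k=k)
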