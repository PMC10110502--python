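"""Ratiometric (biosensor) quantification and projection-based stain intensity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .stats import normalize_by_group_mean

__all__ = [
    "RatioMap",
    "StainMeasurement",
    "ratio_map",
    "whole_cell_value",
    "normalize_per_day",
    "front_back_ratio",
    "quantify_stain",
    "DEFAULT_AVERAGE_SLICES",
]

DEFAULT_AVERAGE_SLICES = 10  # slices combined by the average projection


@dataclass
class RatioMap:
    """Per-pixel acceptor/donor ratio inside a cell mask.

    ``valid`` marks masked pixels whose donor signal exceeded the floor;
    only valid pixels enter any mean.
    """

    ratio: np.ndarray
    mask: np.ndarray
    valid: np.ndarray
    donor_floor: float


@dataclass
class StainMeasurement:
    """Projection-based stain readout with background subtraction."""

    projection_mode: str  # {"average", "sum"}
    n_slices: int
    cell_mean: float
    background_mean: float
    corrected_mean: float
    negative_flag: bool = False


def ratio_map(donor, acceptor, mask, donor_floor: float | None = None) -> RatioMap:
    """Per-pixel acceptor/donor inside ``mask`` where donor is above the floor.

    The default floor is 5% of the in-mask donor median, guarding against
    division blow-ups at dim pixels.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if donor.shape != acceptor.shape or donor.shape != mask.shape:
        raise InputError("donor, acceptor and mask shapes must match")
    if donor_floor is None:
        in_mask = donor[mask]
        donor_floor = 0.05 * float(np.median(in_mask)) if in_mask.size else 0.0
    valid = mask & (donor > donor_floor)
    ratio = np.full(donor.shape, np.nan)
    np.divide(acceptor, donor, out=ratio, where=valid)
    return RatioMap(ratio=ratio, mask=mask, valid=valid, donor_floor=float(donor_floor))


def whole_cell_value(rmap: RatioMap) -> float:
    """Mean ratio over the valid masked pixels."""
    if not rmap.valid.any():
        raise InputError("no valid pixels (donor below floor everywhere)")
    return float(rmap.ratio[rmap.valid].mean())


def normalize_per_day(df, value_col: str = "value", repeat_col: str = "repeat", group_col: str = "group", reference_group: str = "mesoderm"):
    """Per repeat (imaging day), divide all values by the reference-group mean."""
    return normalize_by_group_mean(df, value_col, repeat_col, group_col, reference_group)


def _principal_axis(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    coords = np.column_stack([ys - ys.mean(), xs - xs.mean()])
    cov = coords.T @ coords / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, np.argmax(evals)]  # (uy, ux), unit length


def front_back_ratio(rmap: RatioMap, movement_axis=None) -> float:
    """Mean ratio of the front quarter over the back quarter of the cell.

    The cell's longest axis is the principal second-moment axis of the mask
    (overridable by ``movement_axis``, a ``(dy, dx)`` direction); the mask's
    extent along it is split into four equal-length sections, front = the
    quarter in the axis direction, back = the opposite quarter.
    """
    mask = rmap.mask
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise InputError("empty mask")
    axis = _principal_axis(mask)
    if movement_axis is not None:
        mv = np.asarray(movement_axis, dtype=float)
        mv = mv / np.linalg.norm(mv)
        if abs(float(axis @ mv)) < 1e-12:
            axis = mv  # override: axis orthogonal to movement is ambiguous
        elif float(axis @ mv) < 0:
            axis = -axis
    proj = (ys - ys.mean()) * axis[0] + (xs - xs.mean()) * axis[1]
    pmin, pmax = proj.min(), proj.max()
    extent = pmax - pmin
    if extent <= 4:
        raise InputError("mask extent along the axis is degenerate (<= 4 px)")
    section = np.minimum((4 * (proj - pmin) / extent).astype(int), 3)
    vals = rmap.ratio[ys, xs]
    ok = rmap.valid[ys, xs]
    front = vals[(section == 3) & ok]
    back = vals[(section == 0) & ok]
    if front.size == 0 or back.size == 0:
        raise InputError("front or back quarter has no valid pixels")
    return float(front.mean() / back.mean())


def quantify_stain(
    stack,
    cell_region,
    background_regions,
    projection: str = "average",
    slice_start: int = 0,
    n_slices: int = DEFAULT_AVERAGE_SLICES,
) -> StainMeasurement:
    """Project a z-stack and measure a background-subtracted region mean.

    ``projection="average"`` averages ``n_slices`` consecutive slices from
    ``slice_start`` (default 10 slices); ``projection="sum"`` sums all
    slices.  ``cell_region`` and each of the (two) ``background_regions``
    are boolean masks over the projected frame; background is the mean of
    the per-region means.  A negative corrected value is kept but flagged.
    """
    data = np.asarray(stack.data) if hasattr(stack, "data") else np.asarray(stack)
    if data.ndim == 4:  # (T, Z, Y, X): use the first time point
        data = data[0]
    if data.ndim != 3:
        raise InputError("expected a (Z, Y, X) stack")
    if projection == "average":
        if slice_start < 0 or slice_start + n_slices > data.shape[0]:
            raise InputError("requested slices fall outside the stack")
        proj = data[slice_start : slice_start + n_slices].mean(axis=0)
        used = n_slices
    elif projection == "sum":
        proj = data.sum(axis=0)
        used = data.shape[0]
    else:
        raise InputError(f"unknown projection mode {projection!r}")

    cell = np.asarray(cell_region, dtype=bool)
    if cell.shape != proj.shape or not cell.any():
        raise InputError("cell region must be a non-empty mask over the frame")
    if len(background_regions) < 1:
        raise InputError("at least one background region is required")
    bg_means = []
    for bg in background_regions:
        bg = np.asarray(bg, dtype=bool)
        if bg.shape != proj.shape or not bg.any():
            raise InputError("each background region must be a non-empty mask")
        if (bg & cell).any():
            raise InputError("background region overlaps the cell region")
        bg_means.append(float(proj[bg].mean()))
    cell_mean = float(proj[cell].mean())
    background_mean = float(np.mean(bg_means))
    corrected = cell_mean - background_mean
    return StainMeasurement(
        projection_mode=projection,
        n_slices=used,
        cell_mean=cell_mean,
        background_mean=background_mean,
        corrected_mean=corrected,
        negative_flag=corrected < 0,
    )
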