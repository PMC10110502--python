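"""Core data containers and small shared utilities.

Conventions used throughout the package:

* pixel grid is 0-based, ``(row, col) == (y, x)``, pixel centers at integers;
* angles are degrees, counterclockwise from the +x axis of the image
  (``atan2(dy, dx)``), reported in ``[0, 360)``;
* physical units are micrometers and seconds unless a name says otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ImageStack",
    "circular_difference_deg",
    "wrap_angle_deg",
    "save_stack",
    "load_stack",
    "tracks_to_frame",
]


@dataclass
class ImageStack:
    """A time-lapse intensity stack with physical calibration.

    ``data`` is ``(T, Y, X)`` for planar movies or ``(T, Z, Y, X)`` for
    volumetric ones.  Single images are stored as a one-frame movie.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise InputError(
                f"ImageStack expects (T,Y,X) or (T,Z,Y,X) data, got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise InputError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def wrap_angle_deg(angle) -> np.ndarray | float:
    """Wrap an angle (degrees) into ``[0, 360)``."""
    return np.mod(angle, 360.0)


def circular_difference_deg(a, b) -> np.ndarray | float:
    """Signed circular difference ``a - b`` in degrees, in ``[-180, 180)``."""
    return (np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0


def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32))
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "meta": _jsonable(stack.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`save_stack`."""
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    pixel_size, interval, meta = 1.0, 1.0, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = sidecar.get("pixel_size_um", 1.0)
        interval = sidecar.get("frame_interval_s", 1.0)
        meta = sidecar.get("meta", {})
    return ImageStack(data, pixel_size, interval, meta)


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Flatten a list of :class:`pgcprot.kinetics.Track` into a tidy table."""
    rows = []
    for i, tr in enumerate(tracks):
        for t, pos in zip(tr.t_s, tr.positions_um):
            row = {"track_id": i, "t_s": float(t), "x_um": float(pos[0]), "y_um": float(pos[1])}
            if len(pos) > 2:
                row["z_um"] = float(pos[2])
            row["cell_class"] = tr.cell_class
            rows.append(row)
    return pd.DataFrame(rows)


def _jsonable(obj):
    """Best-effort conversion of numpy scalars/arrays for JSON sidecars."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
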