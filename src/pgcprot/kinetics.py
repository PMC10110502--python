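"""Track kinetics (speed, straightness, drift correction) and kymograph flow."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError
from .stats import normalize_by_group_mean

__all__ = [
    "Track",
    "Kymograph",
    "FlowEstimate",
    "drift_correct",
    "track_speed",
    "track_straightness",
    "per_repeat_normalize",
    "build_kymograph",
    "flow_speed",
]


@dataclass
class Track:
    """Ordered positions of one cell: times in seconds, positions in um."""

    t_s: np.ndarray
    positions_um: np.ndarray  # (n, 2) or (n, 3)
    cell_class: str = "pgc"

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.t_s) < 2 or len(self.t_s) != len(self.positions_um):
            raise InputError("a track needs >= 2 timestamped positions")
        if np.any(np.diff(self.t_s) <= 0):
            raise InputError("timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def path_length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.positions_um, axis=0), axis=1)))

    def net_displacement_um(self) -> float:
        return float(np.linalg.norm(self.positions_um[-1] - self.positions_um[0]))


@dataclass
class Kymograph:
    """Time x position intensity matrix sampled along a fixed line."""

    image: np.ndarray  # (n_frames, n_samples)
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    line: tuple = None  # ((y0, x0), (y1, x1))


@dataclass
class FlowEstimate:
    """Median streak velocity; positive = rearward along the sampling line."""

    v_um_min: float
    per_pair_displacements_px: np.ndarray
    low_confidence: bool = False
    method: dict = field(default_factory=dict)


def track_speed(track: Track) -> float:
    """Total path length divided by total duration, in um/min."""
    if track.duration_s <= 0:
        raise InputError("track duration must be positive")
    return track.path_length_um() / track.duration_s * 60.0


def track_straightness(track: Track) -> float:
    """Net displacement over path length; 1 for straight monotone motion."""
    path = track.path_length_um()
    if path <= 0:
        raise InputError("track has zero path length")
    return track.net_displacement_um() / path


def _interp_positions(track: Track, times: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.interp(times, track.t_s, track.positions_um[:, d]) for d in range(track.positions_um.shape[1])]
    )


def drift_correct(track: Track, somatic_tracks, k_neighbors: int = 5) -> Track:
    """Subtract local tissue drift estimated from nearby somatic tracks.

    For each interval of the cell track, the mean displacement of the
    ``k_neighbors`` somatic tracks nearest to the cell (at the interval
    start) is subtracted from the cell displacement, and positions are
    re-integrated from the original start point.  Somatic tracks must cover
    the cell track's time span (linear interpolation in between).
    """
    usable = [
        s
        for s in somatic_tracks
        if s.t_s[0] <= track.t_s[0] + 1e-9 and s.t_s[-1] >= track.t_s[-1] - 1e-9
    ]
    if not usable:
        raise InputError("no somatic track overlaps the cell track in time")
    k = min(k_neighbors, len(usable))
    som_pos = np.stack([_interp_positions(s, track.t_s) for s in usable])  # (S, n, d)

    corrected = [track.positions_um[0].copy()]
    for i in range(len(track.t_s) - 1):
        cell_disp = track.positions_um[i + 1] - track.positions_um[i]
        dists = np.linalg.norm(som_pos[:, i, :] - track.positions_um[i], axis=1)
        nearest = np.argsort(dists)[:k]
        drift = (som_pos[nearest, i + 1, :] - som_pos[nearest, i, :]).mean(axis=0)
        corrected.append(corrected[-1] + cell_disp - drift)
    return Track(t_s=track.t_s.copy(), positions_um=np.array(corrected), cell_class=track.cell_class)


def per_repeat_normalize(df, value_col: str, repeat_col: str = "repeat", group_col: str = "group", control_group: str = "control"):
    """Divide each value by its own repeat's control-group mean."""
    return normalize_by_group_mean(df, value_col, repeat_col, group_col, control_group)


def build_kymograph(movie, start, end) -> Kymograph:
    """Sample each frame along the segment ``start -> end`` (both (y, x)).

    Rows are frames; columns are ``ceil(length) + 1`` bilinear samples evenly
    spaced along the line.  Endpoints must lie inside the image.
    """
    stack = np.asarray(movie.data) if hasattr(movie, "data") else np.asarray(movie)
    if stack.ndim != 3:
        raise InputError("expected a (T, Y, X) movie")
    h, w = stack.shape[1:]
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for p in (start, end):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise InputError(f"line endpoint {tuple(p)} outside image bounds")
    length = float(np.linalg.norm(end - start))
    n_samples = int(np.ceil(length)) + 1
    ys = np.linspace(start[0], end[0], n_samples)
    xs = np.linspace(start[1], end[1], n_samples)
    rows = np.stack([ndimage.map_coordinates(frame, [ys, xs], order=1) for frame in stack])
    return Kymograph(
        image=rows,
        pixel_size_um=getattr(movie, "pixel_size_um", 1.0),
        frame_interval_s=getattr(movie, "frame_interval_s", 1.0),
        line=(tuple(start), tuple(end)),
    )


def _pair_displacement(row_a: np.ndarray, row_b: np.ndarray, max_lag: int) -> float | None:
    """Sub-pixel displacement of row_b relative to row_a via cross-correlation.

    Positive displacement means the pattern moved toward larger positions.
    Uses the biased (overlap-unnormalized) correlation so the smallest-lag
    peak of a periodic pattern dominates; refines the integer argmax with a
    parabolic fit.
    """
    a = row_a - row_a.mean()
    b = row_b - row_b.mean()
    if np.all(a == 0) or np.all(b == 0):
        return None
    n = len(row_a)
    max_lag = min(max_lag, (n - 1) // 2)
    # Hann-windowed circular cross-correlation via FFT, normalized by the
    # window's own autocorrelation: the windowing suppresses wrap-around
    # artifacts and the normalization removes the taper it introduces
    w = np.hanning(n)
    c = np.fft.irfft(np.fft.rfft(b * w) * np.conj(np.fft.rfft(a * w)), n)
    wf = np.fft.rfft(w)
    cw = np.fft.irfft(wf * np.conj(wf), n)
    lags = np.arange(-max_lag, max_lag + 1)
    window = c[lags % n] / np.maximum(cw[lags % n], 1e-12 * cw[0])
    # a periodic pattern repeats its peak every period; take the local
    # maximum nearest zero lag (slow-flow assumption)
    is_peak = np.r_[False, (window[1:-1] >= window[:-2]) & (window[1:-1] >= window[2:]), False]
    peaks = np.nonzero(is_peak)[0]
    i = int(peaks[np.argmin(np.abs(lags[peaks]))]) if peaks.size else int(np.argmax(window))
    lag = float(lags[i])
    if 0 < i < len(window) - 1:
        denom = window[i - 1] - 2 * window[i] + window[i + 1]
        if denom < 0:
            lag = lag + 0.5 * (window[i - 1] - window[i + 1]) / denom
    return float(lag)


def flow_speed(kymo: Kymograph, max_lag: int | None = None) -> FlowEstimate:
    """Median streak velocity of a kymograph, in um/min.

    Each consecutive row pair contributes the argmax of its 1D
    cross-correlation (parabolically refined); the median across pairs is
    converted with the pixel size and frame interval.  Constant rows give
    ``V = 0`` with ``low_confidence=True``.
    """
    img = np.asarray(kymo.image, dtype=float)
    if img.shape[0] < 2:
        raise InputError("kymograph needs at least 2 rows")
    if max_lag is None:
        max_lag = max(1, img.shape[1] // 3)
    disps = []
    for t in range(img.shape[0] - 1):
        d = _pair_displacement(img[t], img[t + 1], max_lag)
        if d is not None:
            disps.append(d)
    if not disps:
        return FlowEstimate(0.0, np.array([]), low_confidence=True, method={"max_lag": max_lag})
    disps = np.asarray(disps)
    v = float(np.median(disps)) * kymo.pixel_size_um / kymo.frame_interval_s * 60.0
    return FlowEstimate(v, disps, low_confidence=False, method={"max_lag": max_lag, "subpixel": "parabolic"})
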