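"""Synthetic microscopy generators with machine-readable ground truth.

Every generator is a pure function of ``(params, seed)``: calling it twice
with the same arguments yields bit-identical pixel data and truth records.
The cell model is deliberately simple — a star-convex radial contour
``r(theta, t)`` around a moving center, with blebs as transient Gaussian
bumps on ``r`` — chosen so that angular ground truth is exact by
construction rather than physically realistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from .core import ImageStack, circular_difference_deg, wrap_angle_deg
from .errors import ParameterError

__all__ = [
    "BlebTruth",
    "CellMovieParams",
    "CellMovieTruth",
    "SyntheticScene",
    "generate_cell_movie",
    "generate_nuclei_field",
    "generate_ratio_stack",
    "generate_stripe_movie",
    "generate_tracks",
    "generate_gel_encounter_movie",
]


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


@dataclass
class BlebTruth:
    """One scripted bleb event."""

    start_frame: int
    max_expansion_frame: int
    end_frame: int
    apex_angle_deg: float
    max_area_px2: float
    cell_area_px2: float = float("nan")  # mask area at max expansion

    @property
    def relative_size(self) -> float:
        return self.max_area_px2 / self.cell_area_px2


@dataclass
class CellMovieTruth:
    """Ground truth accompanying a generated cell movie."""

    contour_per_frame: list  # list of (n_vertices, 2) float arrays in (row, col)
    masks: np.ndarray  # (T, Y, X) bool; rasterization of the contours
    bleb_events: list  # list[BlebTruth]
    polarity_angle_per_frame: np.ndarray  # degrees in [0, 360)
    front_type_per_frame: list  # labels in {actin_rich, bleb, unpolarized}
    cortical_profile_params: tuple  # (A, mu_deg, sigma_deg, c)
    pixel_size_um: float
    frame_interval_s: float
    seed: int
    noise_sd: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def duration_min(self) -> float:
        return len(self.front_type_per_frame) * self.frame_interval_s / 60.0


@dataclass
class SyntheticScene:
    """One or two image channels plus whatever truth the generator produced."""

    stacks: dict  # channel name -> ImageStack
    truth: object

    def stack(self, name: str | None = None) -> ImageStack:
        if name is None:
            name = next(iter(self.stacks))
        return self.stacks[name]


# ---------------------------------------------------------------------------
# cell movies
# ---------------------------------------------------------------------------


@dataclass
class CellMovieParams:
    """Settings for :func:`generate_cell_movie`.

    Intensity layout: background 0, cell body ``body_level``, and a cortical
    ring of width ``ring_width_px`` whose intensity at angle ``theta`` is
    ``c + A * exp(-d(theta, mu)^2 / (2 sigma^2))`` with circular ``d``.
    """

    shape: tuple = (64, 64)
    n_frames: int = 24
    frame_interval_s: float = 5.0
    pixel_size_um: float = 0.5
    radius_px: float = 16.0
    center: tuple = (32.0, 32.0)  # (row, col)
    speed_px_per_frame: float = 0.0
    polarity_angle_deg: float = 90.0
    profile_amplitude: float = 0.65  # A
    profile_sigma_deg: float = 40.0  # sigma
    profile_offset: float = 0.35  # c
    profile_mu_deg: float | None = None  # defaults to polarity_angle_deg
    ring_width_px: float = 4.0
    body_level: float = 0.3
    bleb_rate_per_min: float = 0.0
    bleb_area_px2: float = 60.0
    bleb_width_deg: float = 25.0
    bleb_rise_s: float = 15.0
    bleb_fall_s: float = 15.0
    cortex_lag_s: float = 10.0  # time the bleb cap stays free of cortical signal
    min_event_gap_s: float = 0.0  # >0 thins the Poisson process (bounded rate)
    noise_sd: float = 0.0
    n_contour_vertices: int = 720
    render: bool = True  # False: truth bookkeeping only, no pixels


def _validate_cell_params(p: CellMovieParams) -> None:
    if p.n_frames < 2:
        raise ParameterError("movie length must be at least 2 frames")
    if p.bleb_rate_per_min < 0:
        raise ParameterError("bleb rate must be >= 0 events/min")
    if not (0.0 < p.profile_sigma_deg < 180.0):
        raise ParameterError("profile sigma must lie in (0, 180) degrees")
    if p.profile_amplitude < 0:
        raise ParameterError("profile amplitude must be non-negative")
    if p.radius_px <= 0:
        raise ParameterError("cell radius must be positive")
    if p.frame_interval_s <= 0 or p.pixel_size_um <= 0:
        raise ParameterError("frame interval and pixel size must be positive")


def _draw_bleb_events(p: CellMovieParams, rng: np.random.Generator) -> list[BlebTruth]:
    duration_min = p.n_frames * p.frame_interval_s / 60.0
    n_events = int(rng.poisson(p.bleb_rate_per_min * duration_min))
    rise_frames = max(1, round(p.bleb_rise_s / p.frame_interval_s))
    fall_frames = max(1, round(p.bleb_fall_s / p.frame_interval_s))
    starts = np.sort(rng.uniform(0, duration_min * 60.0, size=n_events))
    start_frames = np.minimum(
        (starts / p.frame_interval_s).astype(int), p.n_frames - 2
    )
    events: list[BlebTruth] = []
    gap_frames = p.min_event_gap_s / p.frame_interval_s
    for sf in start_frames:
        if gap_frames > 0 and events and sf - events[-1].end_frame < gap_frames:
            continue  # thinning: drop events violating the minimum gap
        mf = min(sf + rise_frames, p.n_frames - 1)
        ef = min(mf + fall_frames, p.n_frames - 1)
        apex = wrap_angle_deg(p.polarity_angle_deg + rng.uniform(-60.0, 60.0))
        events.append(BlebTruth(int(sf), int(mf), int(ef), float(apex), float(p.bleb_area_px2)))
    return events


def _polygon_area(verts: np.ndarray) -> float:
    y, x = verts[:, 0], verts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _bump_amplitude(p: CellMovieParams) -> float:
    # first-order area of a Gaussian radial bump: dA ~ R * a * w * sqrt(2*pi)
    w_rad = math.radians(p.bleb_width_deg)
    return p.bleb_area_px2 / (p.radius_px * w_rad * math.sqrt(2.0 * math.pi))


def _radius_at(p: CellMovieParams, events: list[BlebTruth], t: int, theta_deg: np.ndarray) -> np.ndarray:
    """Radial function r(theta) of frame ``t`` including active bleb bumps."""
    r = np.full_like(np.asarray(theta_deg, dtype=float), p.radius_px)
    a_max = _bump_amplitude(p)
    for ev in events:
        if not (ev.start_frame <= t <= ev.end_frame):
            continue
        if t <= ev.max_expansion_frame:
            denom = max(ev.max_expansion_frame - ev.start_frame, 1)
            envelope = (t - ev.start_frame) / denom
        else:
            denom = max(ev.end_frame - ev.max_expansion_frame, 1)
            envelope = 1.0 - (t - ev.max_expansion_frame) / denom
        if envelope <= 0:
            continue
        d = circular_difference_deg(theta_deg, ev.apex_angle_deg)
        r = r + envelope * a_max * np.exp(-(d**2) / (2.0 * p.bleb_width_deg**2))
    return r


def generate_cell_movie(params: CellMovieParams | None = None, seed: int = 0, **overrides) -> SyntheticScene:
    """Generate a single-channel movie of one motile cell with a bright cortex.

    The cortical ring intensity at angle ``theta`` about the cell center is
    ``c + A * exp(-d(theta, mu)^2 / (2 sigma^2))`` before noise.  Blebs appear
    as circular-cap contour expansions; while a bleb is younger than
    ``cortex_lag_s`` its cap carries body-level (not cortical) intensity.
    The returned truth lists every event, the per-frame contour polygon and
    its pixel-exact rasterization.
    """
    p = params if params is not None else CellMovieParams()
    if overrides:
        p = CellMovieParams(**{**asdict_shallow(p), **overrides})
    _validate_cell_params(p)
    rng = np.random.default_rng(seed)

    events = _draw_bleb_events(p, rng)
    active = np.zeros(p.n_frames, dtype=bool)
    for ev in events:
        active[ev.start_frame : ev.end_frame + 1] = True
    front_types = ["bleb" if active[t] else "actin_rich" for t in range(p.n_frames)]
    polarity = np.full(p.n_frames, wrap_angle_deg(p.polarity_angle_deg), dtype=float)
    mu = p.profile_mu_deg if p.profile_mu_deg is not None else p.polarity_angle_deg

    theta_v = np.linspace(0.0, 360.0, p.n_contour_vertices, endpoint=False)
    step = p.speed_px_per_frame * np.array(
        [math.sin(math.radians(p.polarity_angle_deg)), math.cos(math.radians(p.polarity_angle_deg))]
    )  # (drow, dcol)

    contours: list[np.ndarray] = []
    masks = np.zeros((p.n_frames, *p.shape), dtype=bool) if p.render else None
    movie = np.zeros((p.n_frames, *p.shape), dtype=float) if p.render else None

    yy, xx = np.mgrid[0 : p.shape[0], 0 : p.shape[1]]
    lag_frames = p.cortex_lag_s / p.frame_interval_s

    for t in range(p.n_frames):
        cy, cx = np.asarray(p.center, dtype=float) + t * step
        r_v = _radius_at(p, events, t, theta_v)
        verts = np.column_stack(
            [cy + r_v * np.sin(np.radians(theta_v)), cx + r_v * np.cos(np.radians(theta_v))]
        )
        contours.append(verts)
        if not p.render:
            continue
        mask = polygon2mask(p.shape, verts)
        masks[t] = mask

        dy = yy - cy
        dx = xx - cx
        rho = np.hypot(dy, dx)
        theta_p = wrap_angle_deg(np.degrees(np.arctan2(dy, dx)))
        r_p = _radius_at(p, events, t, theta_p)

        frame = np.zeros(p.shape, dtype=float)
        frame[mask] = p.body_level
        ring = mask & (rho >= r_p - p.ring_width_px)
        d_mu = circular_difference_deg(theta_p, mu)
        cortical = p.profile_offset + p.profile_amplitude * np.exp(
            -(d_mu**2) / (2.0 * p.profile_sigma_deg**2)
        )
        frame[ring] = cortical[ring]
        # young bleb caps lack cortical signal (from the first expansion
        # frame, for cortex_lag_s thereafter)
        for ev in events:
            if ev.start_frame < t <= ev.end_frame and (t - ev.start_frame) <= lag_frames:
                cap = ring & (
                    np.abs(circular_difference_deg(theta_p, ev.apex_angle_deg))
                    < 2.0 * p.bleb_width_deg
                )
                frame[cap] = p.body_level
        if p.noise_sd > 0:
            frame = frame + rng.normal(0.0, p.noise_sd, size=p.shape)
        movie[t] = frame

    # analytic (shoelace) polygon area: truth bookkeeping independent of
    # rasterization, available also on the truth-only fast path
    for ev in events:
        ev.cell_area_px2 = _polygon_area(contours[ev.max_expansion_frame])

    truth = CellMovieTruth(
        contour_per_frame=contours,
        masks=masks,
        bleb_events=events,
        polarity_angle_per_frame=polarity,
        front_type_per_frame=front_types,
        cortical_profile_params=(p.profile_amplitude, wrap_angle_deg(float(mu)), p.profile_sigma_deg, p.profile_offset),
        pixel_size_um=p.pixel_size_um,
        frame_interval_s=p.frame_interval_s,
        seed=seed,
        noise_sd=p.noise_sd,
        extras={"params": asdict_shallow(p)},
    )
    stacks = {}
    if p.render:
        stacks["cortical"] = ImageStack(movie, p.pixel_size_um, p.frame_interval_s)
    return SyntheticScene(stacks=stacks, truth=truth)


def asdict_shallow(p) -> dict:
    """`dataclasses.asdict` without deep-copying array-valued fields."""
    return {f: getattr(p, f) for f in p.__dataclass_fields__}


# ---------------------------------------------------------------------------
# nuclei fields
# ---------------------------------------------------------------------------


def generate_nuclei_field(
    mode: str = "uniform_random",
    n: int | None = None,
    spacing_um: float | None = None,
    box_um: tuple = (100.0, 100.0, 100.0),
    seed: int = 0,
) -> SyntheticScene:
    """Generate a 3D nuclei centroid table (micrometers).

    ``cubic_lattice`` lays points on an axis-aligned lattice with the given
    ``spacing_um`` filling ``box_um``; ``uniform_random`` draws ``n`` i.i.d.
    uniform points.  At least 6 points are required so that 5 neighbours
    exist downstream.
    """
    rng = np.random.default_rng(seed)
    if mode == "cubic_lattice":
        if spacing_um is None or spacing_um <= 0:
            raise ParameterError("cubic_lattice requires a positive spacing_um")
        axes = [np.arange(0.0, b + 1e-9, spacing_um) for b in box_um]
        pts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
        truth = {"mode": mode, "spacing_um": spacing_um, "seed": seed}
    elif mode == "uniform_random":
        if n is None:
            raise ParameterError("uniform_random requires n")
        pts = rng.uniform(0.0, np.asarray(box_um, dtype=float), size=(int(n), 3))
        truth = {"mode": mode, "n": int(n), "seed": seed}
    else:
        raise ParameterError(f"unknown nuclei field mode {mode!r}")
    if len(pts) < 6:
        raise ParameterError("need at least 6 nuclei (5 neighbours must exist)")
    table = pd.DataFrame(pts, columns=["x_um", "y_um", "z_um"])
    truth["centroids"] = table
    return SyntheticScene(stacks={}, truth=truth)


# ---------------------------------------------------------------------------
# ratio stacks
# ---------------------------------------------------------------------------


def generate_ratio_stack(
    ratio: float | tuple = 2.0,
    gradient_axis: int = 1,
    donor_level: float = 100.0,
    mask_shape: str = "rectangle",
    shape: tuple = (64, 64),
    mask_extent: tuple = (20, 40),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Two-channel single-frame scene whose acceptor/donor ratio is known.

    ``ratio`` is either a constant or ``(lo, hi)`` for a linear gradient
    along ``gradient_axis`` (0 = rows, 1 = cols) across the mask's bounding
    extent, evaluated at pixel centers with the half-pixel convention
    ``lo + (hi - lo) * (i + 0.5) / extent``.
    """
    if donor_level <= 0:
        raise ParameterError("donor level must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    mh, mw = mask_extent
    if mh <= 0 or mw <= 0 or mh > h or mw > w:
        raise ParameterError("mask extent must be positive and fit inside the frame")
    y0, x0 = (h - mh) // 2, (w - mw) // 2
    mask = np.zeros(shape, dtype=bool)
    if mask_shape == "rectangle":
        mask[y0 : y0 + mh, x0 : x0 + mw] = True
    elif mask_shape == "ellipse":
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((yy - (h - 1) / 2) / (mh / 2)) ** 2 + ((xx - (w - 1) / 2) / (mw / 2)) ** 2 <= 1.0
    else:
        raise ParameterError(f"unknown mask shape {mask_shape!r}")
    if not mask.any():
        raise ParameterError("mask is empty")

    ratio_field = np.zeros(shape, dtype=float)
    if np.isscalar(ratio):
        ratio_field[mask] = float(ratio)
    else:
        lo, hi = ratio
        idx = np.indices(shape)[gradient_axis]
        ax_min = idx[mask].min()
        extent = idx[mask].max() - ax_min + 1
        ratio_field[mask] = lo + (hi - lo) * (idx[mask] - ax_min + 0.5) / extent

    donor = np.zeros(shape, dtype=float)
    donor[mask] = donor_level
    acceptor = donor * ratio_field
    if noise_sd > 0:
        donor = donor + rng.normal(0, noise_sd, shape)
        acceptor = acceptor + rng.normal(0, noise_sd, shape)
    truth = {
        "ratio": ratio,
        "gradient_axis": gradient_axis,
        "ratio_field": ratio_field,
        "mask": mask,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return SyntheticScene(
        stacks={
            "donor": ImageStack(donor[None]),
            "acceptor": ImageStack(acceptor[None]),
        },
        truth=truth,
    )


# ---------------------------------------------------------------------------
# stripe movies (kymograph / flow input)
# ---------------------------------------------------------------------------


def generate_stripe_movie(
    speed_px_per_frame: float = 1.0,
    period_px: float = 24.0,
    shape: tuple = (16, 128),
    n_frames: int = 12,
    amplitude: float = 50.0,
    offset: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Movie of a sinusoidal stripe pattern translating along +x.

    The pattern translates by exactly ``speed_px_per_frame`` pixels per frame
    along the column axis; stripes are uniform along rows.
    """
    if n_frames < 2:
        raise ParameterError("movie needs at least 2 frames")
    if period_px <= 0:
        raise ParameterError("stripe period must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(shape[1], dtype=float)
    movie = np.empty((n_frames, *shape), dtype=float)
    for t in range(n_frames):
        row = offset + amplitude * np.cos(2 * np.pi * (x - speed_px_per_frame * t) / period_px)
        movie[t] = np.broadcast_to(row, shape)
        if noise_sd > 0:
            movie[t] = movie[t] + rng.normal(0, noise_sd, shape)
    truth = {"speed_px_per_frame": speed_px_per_frame, "period_px": period_px, "noise_sd": noise_sd, "seed": seed}
    return SyntheticScene(stacks={"stripes": ImageStack(movie)}, truth=truth)


# ---------------------------------------------------------------------------
# cell tracks in a drifting tissue
# ---------------------------------------------------------------------------


def generate_tracks(
    n_tracks: int = 10,
    mean_speed_um_min: float = 3.0,
    persistence: float = 0.8,
    tissue_drift_um_min: tuple = (0.0, 0.0),
    duration_s: float = 3600.0,
    interval_s: float = 120.0,
    n_somatic: int = 20,
    box_um: tuple = (200.0, 200.0),
    turn_sd_rad: float = 1.0,
    seed: int = 0,
) -> SyntheticScene:
    """Biased-random-walk cell tracks embedded in a uniformly drifting tissue.

    Cell headings evolve as ``phi += (1 - persistence) * N(0, turn_sd)``; the
    per-step displacement magnitude is exactly ``mean_speed * interval``, so
    path length over duration is exact.  Companion ``somatic`` tracks carry
    the drift only.
    """
    from .kinetics import Track

    if interval_s <= 0:
        raise ParameterError("interval must be positive")
    if duration_s < 2 * interval_s:
        raise ParameterError("duration must cover at least two intervals")
    if not (0.0 <= persistence <= 1.0):
        raise ParameterError("persistence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 1e-9, interval_s)
    n_steps = len(times) - 1
    drift = np.asarray(tissue_drift_um_min, dtype=float) / 60.0  # um/s
    step_len = mean_speed_um_min / 60.0 * interval_s

    pgc_tracks = []
    for _ in range(n_tracks):
        pos = rng.uniform(0, box_um, size=2)
        phi = rng.uniform(0, 2 * np.pi)
        pts = [pos.copy()]
        for _ in range(n_steps):
            phi = phi + (1.0 - persistence) * rng.normal(0.0, turn_sd_rad)
            pos = pos + step_len * np.array([np.cos(phi), np.sin(phi)]) + drift * interval_s
            pts.append(pos.copy())
        pgc_tracks.append(Track(t_s=times.copy(), positions_um=np.array(pts), cell_class="pgc"))

    somatic_tracks = []
    for _ in range(n_somatic):
        start = rng.uniform(0, box_um, size=2)
        pts = start[None, :] + np.outer(times, drift)
        somatic_tracks.append(Track(t_s=times.copy(), positions_um=pts, cell_class="somatic"))

    truth = {
        "mean_speed_um_min": mean_speed_um_min,
        "persistence": persistence,
        "tissue_drift_um_min": tuple(tissue_drift_um_min),
        "interval_s": interval_s,
        "duration_s": duration_s,
        "seed": seed,
        "pgc_tracks": pgc_tracks,
        "somatic_tracks": somatic_tracks,
    }
    return SyntheticScene(stacks={}, truth=truth)


# ---------------------------------------------------------------------------
# gel encounters
# ---------------------------------------------------------------------------


def generate_gel_encounter_movie(
    behavior: str = "no_change",
    turn_angle_deg: float = 90.0,
    encounter_frame: int = 20,
    response_lag_s: float = 60.0,
    n_frames: int = 120,
    frame_interval_s: float = 5.0,
    initial_polarity_deg: float = 0.0,
    gel_center: tuple = (32.0, 100.0),
    gel_radius_px: float = 14.0,
    shape: tuple = (64, 128),
    render: bool = False,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Scripted encounter of a polarized cell with a static stiff disk.

    ``behavior`` selects the post-encounter polarity trajectory: ``turn``
    rotates the polarity angle by ``turn_angle_deg`` at ``encounter_frame +
    response_lag``, ``loss_of_polarity`` switches the front type to
    ``unpolarized`` at that frame, ``no_change`` keeps everything constant.
    The window precondition (>= 1 min before and >= 5 min after the
    encounter) mirrors the downstream 6-minute scoring window.
    """
    if behavior not in ("turn", "loss_of_polarity", "no_change"):
        raise ParameterError(f"unknown behavior {behavior!r}")
    before_s = encounter_frame * frame_interval_s
    after_s = (n_frames - 1 - encounter_frame) * frame_interval_s
    if before_s < 60.0 or after_s < 300.0:
        raise ParameterError(
            "encounter must leave >= 1 min before and >= 5 min after within the movie"
        )
    lag_frames = max(1, round(response_lag_s / frame_interval_s))
    response_frame = encounter_frame + lag_frames
    if response_frame >= n_frames:
        raise ParameterError("response lag exceeds the movie")

    polarity = np.full(n_frames, wrap_angle_deg(initial_polarity_deg), dtype=float)
    front_type = ["actin_rich"] * n_frames
    if behavior == "turn":
        polarity[response_frame:] = wrap_angle_deg(initial_polarity_deg + turn_angle_deg)
    elif behavior == "loss_of_polarity":
        for t in range(response_frame, n_frames):
            front_type[t] = "unpolarized"

    stacks = {}
    if render:
        rng = np.random.default_rng(seed)
        movie = np.zeros((n_frames, *shape), dtype=float)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        gel = np.hypot(yy - gel_center[0], xx - gel_center[1]) <= gel_radius_px
        cell_r = 10.0
        start = np.array([shape[0] / 2.0, 20.0])
        approach = (np.asarray(gel_center) - np.array([0.0, gel_radius_px + cell_r]) - start) / max(
            encounter_frame, 1
        )
        for t in range(n_frames):
            c = start + approach * min(t, encounter_frame)
            cell = np.hypot(yy - c[0], xx - c[1]) <= cell_r
            frame = np.zeros(shape, dtype=float)
            frame[cell] = 0.6
            frame[gel] = 1.0
            if noise_sd > 0:
                frame = frame + rng.normal(0, noise_sd, shape)
            movie[t] = frame
        stacks["cell"] = ImageStack(movie, frame_interval_s=frame_interval_s)

    truth = {
        "behavior": behavior,
        "turn_angle_deg": turn_angle_deg,
        "encounter_frame": int(encounter_frame),
        "response_frame": int(response_frame),
        "response_lag_s": lag_frames * frame_interval_s,
        "polarity_angle_per_frame": polarity,
        "front_type_per_frame": front_type,
        "frame_interval_s": frame_interval_s,
        "gel_center": tuple(gel_center),
        "gel_radius_px": gel_radius_px,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return SyntheticScene(stacks=stacks, truth=truth)
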