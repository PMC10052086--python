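"""Synthetic top-down RGB-D scenes of a growing, periodically spaced lettuce
batch, with full per-plant ground truth.

The generator emulates a fixed depth camera about 1 m above hydroponic
lettuce in a greenhouse compartment: each head is a spherical cap (dome)
standing on a slightly tilted ground plane, heads grow logistically in
base radius and cap height, and the batch is stepped down a density ladder
by re-laying the heads on a regular grid at every spacing event.  Frames
are rendered by exact ray casting through the pinhole intrinsics, so the
depth raster, the ground-truth mask and the analytic cap geometry are
mutually consistent and every downstream stage (segmentation, plane
fitting, heights, volume, indicators) can be tested against closed-form
oracles without external data.

Spacing-day selection supports three policies:

``balanced``
    space on the day the light-loss indicator is predicted to balance
    (post-spacing floor loss equals pre-spacing overlap loss), i.e. at
    canopy closure; the prediction rasterises the ground-truth disc union.
``tangency``
    space on the first day neighbouring discs touch (strict rigid-disc
    tangency) — this reads as "too early" under the light-loss indicator.
``coverage``
    space when ground-truth coverage crosses a threshold (default 98%).

A fixed seed reproduces the batch byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .economics import classify_weight
from .frames import FrameRGBD
from .geometry import CameraIntrinsics, GroundPlane
from .schedule import LADDER, DensitySchedule, ScheduleError
from .segmentation import SegMask


class SyntheticSceneError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spherical-cap geometry (closed forms used as oracles throughout the tests)


def cap_sphere_radius(a_mm: float, h_mm: float) -> float:
    """Radius of the sphere whose cap has base radius a and height h."""
    if a_mm <= 0 or h_mm <= 0:
        raise SyntheticSceneError("cap radius and height must be positive")
    if h_mm > a_mm:
        raise SyntheticSceneError("cap height must not exceed base radius (dome-like head)")
    return (a_mm * a_mm + h_mm * h_mm) / (2.0 * h_mm)


def cap_volume_mm3(a_mm: float, h_mm: float) -> float:
    """Volume of a spherical cap: pi*h*(3a^2 + h^2)/6."""
    cap_sphere_radius(a_mm, h_mm)  # validation
    return math.pi * h_mm * (3.0 * a_mm * a_mm + h_mm * h_mm) / 6.0


def cap_height_field(
    plant: "PlantGT | tuple[float, float]",
    shape: tuple[int, int],
    gsd_mm: float,
    centre_xy_mm: tuple[float, float] | None = None,
) -> np.ndarray:
    """Orthographic elevation raster (mm) of one spherical-cap plant.

    The raster covers ``shape`` pixels of ``gsd_mm`` ground sampling,
    centred on the optical axis; the field is the cap elevation inside the
    base disc and 0 outside, peaking at the cap height over the centre.
    """
    if isinstance(plant, PlantGT):
        a, h = plant.radius_mm, plant.height_mm
        cx, cy = plant.centre_mm
    else:
        a, h = plant
        cx, cy = centre_xy_mm if centre_xy_mm is not None else (0.0, 0.0)
    R = cap_sphere_radius(a, h)
    rows, cols = shape
    x = (np.arange(cols) - (cols - 1) / 2.0) * gsd_mm - cx
    y = (np.arange(rows) - (rows - 1) / 2.0) * gsd_mm - cy
    r2 = x[None, :] ** 2 + y[:, None] ** 2
    out = np.zeros(shape, dtype=np.float64)
    inside = r2 <= a * a
    out[inside] = np.sqrt(R * R - r2[inside]) - (R - h)
    return out


# ---------------------------------------------------------------------------
# configuration and ground truth types


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth of base radius and cap height, mm and 1/day.

    Defaults give a ~6-week cycle: heads of ~3 cm radius at transplant
    reaching ~15 cm radius and ~13 cm height at harvest, which traverses
    the full density ladder and crosses the 250 g target around day 36.
    """

    radius0_mm: float = 30.0
    radius_max_mm: float = 190.0
    radius_rate: float = 0.08
    height0_mm: float = 20.0
    height_max_mm: float = 160.0
    height_rate: float = 0.08

    def radius(self, day: float) -> float:
        c = (self.radius_max_mm - self.radius0_mm) / self.radius0_mm
        return self.radius_max_mm / (1.0 + c * math.exp(-self.radius_rate * day))

    def height(self, day: float) -> float:
        c = (self.height_max_mm - self.height0_mm) / self.height0_mm
        return self.height_max_mm / (1.0 + c * math.exp(-self.height_rate * day))


@dataclass(frozen=True)
class AllometryParams:
    """Ground-truth fresh weight as a quadratic in the area*height indicator.

    weight [g] = c0 + c1*x + c2*x^2 (+ Gaussian noise), x in cm^3.
    Defaults place the 250 g crossing at an indicator of ~7845 cm^3.
    """

    c0: float = 5.0
    c1: float = 0.0234
    c2: float = 1.0e-6
    noise_sd_g: float = 20.0

    def mean_weight(self, indicator_cm3) -> np.ndarray:
        x = np.asarray(indicator_cm3, dtype=np.float64)
        return self.c0 + self.c1 * x + self.c2 * x * x

    def true_threshold(self, target_g: float = 250.0) -> float:
        """Indicator at which the noiseless weight reaches the target."""
        a, b, c = self.c2, self.c1, self.c0 - target_g
        if a == 0:
            return -c / b
        disc = b * b - 4 * a * c
        return (-b + math.sqrt(disc)) / (2 * a)


def allometric_weight(area_cm2, hmax_cm, params: AllometryParams, rng=None):
    """Fresh weight in grams from the area*height indicator, clamped at 0."""
    area = np.asarray(area_cm2, dtype=np.float64)
    h = np.asarray(hmax_cm, dtype=np.float64)
    if np.any(area < 0) or np.any(h < 0):
        raise SyntheticSceneError("area and height must be non-negative")
    w = params.mean_weight(area * h)
    if rng is not None and params.noise_sd_g > 0:
        w = w + rng.normal(0.0, params.noise_sd_g, size=np.shape(w))
    return np.maximum(w, 0.0) if np.ndim(w) else float(max(w, 0.0))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic greenhouse scene.

    The camera hangs ``camera_height_mm`` above the crop looking straight
    down; the ground plane is tilted by ``plane_tilt_deg`` to emulate
    skew in camera mounting.  ``gsd_mm`` is the ground sampling distance
    at the ground plane (mm/pixel); focal lengths follow as height/gsd.
    """

    seed: int = 0
    days: int = 42
    frames_per_day: int = 1
    image_size: tuple[int, int] = (256, 256)
    gsd_mm: float = 2.0
    camera_height_mm: float = 1000.0
    plane_tilt_deg: float = 2.0
    plane_tilt_azimuth_deg: float = 30.0
    depth_noise_sd_mm: float = 2.0
    rgb_noise_sd: float = 2.0
    depth_scale_mm: float = 0.1
    growth: GrowthParams = field(default_factory=GrowthParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    trait_jitter_sd: float = 0.03
    density_schedule: DensitySchedule | None = None
    spacing_policy: Literal["balanced", "tangency", "coverage"] = "balanced"
    coverage_trigger_pct: float = 98.0
    spacing_delay_days: int = 0
    ladder: tuple[float, ...] = LADDER

    def __post_init__(self) -> None:
        if self.gsd_mm <= 0:
            raise SyntheticSceneError("gsd must be positive")
        if not 0.0 <= self.plane_tilt_deg < 10.0:
            raise SyntheticSceneError("plane tilt must be in [0, 10) degrees")
        if self.days < 1 or self.frames_per_day < 1:
            raise SyntheticSceneError("days and frames_per_day must be >= 1")
        if any(b >= a for a, b in zip(self.ladder, self.ladder[1:])):
            raise ScheduleError("ladder densities must be strictly decreasing")

    @property
    def intrinsics(self) -> CameraIntrinsics:
        rows, cols = self.image_size
        f = self.camera_height_mm / self.gsd_mm
        return CameraIntrinsics(
            fx=f, fy=f, cx=(cols - 1) / 2.0, cy=(rows - 1) / 2.0,
            width=cols, height=rows, depth_scale=self.depth_scale_mm,
        )

    @property
    def ground_area_m2(self) -> float:
        rows, cols = self.image_size
        return rows * cols * self.gsd_mm**2 / 1e6

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the imaged ground area in mm."""
        rows, cols = self.image_size
        return cols * self.gsd_mm, rows * self.gsd_mm

    def ground_plane(self) -> GroundPlane:
        """The true tilted ground plane, normal toward the camera."""
        t = math.radians(self.plane_tilt_deg)
        ph = math.radians(self.plane_tilt_azimuth_deg)
        n = np.array([math.sin(t) * math.cos(ph), math.sin(t) * math.sin(ph), -math.cos(t)])
        return GroundPlane(n, float(n @ np.array([0.0, 0.0, self.camera_height_mm])))


@dataclass(frozen=True)
class PlantGT:
    """Ground truth of one lettuce head at one moment.

    ``scale_radius``/``scale_height`` are the head's persistent trait
    multipliers (biological head-to-head variation); ``weight_noise_g`` its
    persistent deviation from the allometric mean weight.
    """

    id: int
    centre_mm: tuple[float, float]
    radius_mm: float
    height_mm: float
    scale_radius: float = 1.0
    scale_height: float = 1.0
    weight_noise_g: float = 0.0
    color: tuple[int, int, int] = (45, 140, 45)

    @property
    def projected_area_cm2(self) -> float:
        return math.pi * self.radius_mm**2 / 100.0

    @property
    def height_cm(self) -> float:
        return self.height_mm / 10.0

    @property
    def indicator_cm3(self) -> float:
        """Ground-truth area*height harvest indicator."""
        return self.projected_area_cm2 * self.height_cm

    @property
    def volume_cm3(self) -> float:
        return cap_volume_mm3(self.radius_mm, self.height_mm) / 1000.0

    def fresh_weight_g(self, allometry: AllometryParams) -> float:
        w = float(allometry.mean_weight(self.indicator_cm3)) + self.weight_noise_g
        return max(w, 0.0)

    def quality_class(self, allometry: AllometryParams) -> str:
        return classify_weight(self.fresh_weight_g(allometry))


# ---------------------------------------------------------------------------
# layout


def grid_layout(n_plants: int, extent_mm: tuple[float, float]) -> np.ndarray:
    """Regular near-square grid of ``n_plants`` centres over the imaged area.

    Rows are evenly spaced; when the count does not factor into equal rows
    the remainder is spread over the first rows, keeping the layout as
    close to a square lattice as the count allows.  Returns (n, 2) centre
    coordinates in mm, origin at the optical axis.
    """
    if n_plants < 1:
        raise SyntheticSceneError("need at least one plant")
    w, h = extent_mm
    ny = max(1, round(math.sqrt(n_plants * h / w)))
    ny = min(ny, n_plants)
    base, rem = divmod(n_plants, ny)
    counts = [base + 1 if j < rem else base for j in range(ny)]
    centres = []
    for j, nj in enumerate(counts):
        if nj == 0:
            continue
        y = (j + 0.5) * h / ny - h / 2.0
        for i in range(nj):
            x = (i + 0.5) * w / nj - w / 2.0
            centres.append((x, y))
    return np.asarray(centres, dtype=np.float64)


def union_coverage_pct(
    centres: np.ndarray, radii: np.ndarray, shape: tuple[int, int], gsd_mm: float
) -> float:
    """Coverage (%) of the union of ground discs, rasterised orthographically."""
    rows, cols = shape
    covered = np.zeros((rows, cols), dtype=bool)
    x0, y0 = (cols - 1) / 2.0, (rows - 1) / 2.0
    for (cx, cy), a in zip(centres, radii):
        u, v = cx / gsd_mm + x0, cy / gsd_mm + y0
        pr = a / gsd_mm
        c0, c1 = max(0, int(u - pr) - 1), min(cols, int(u + pr) + 2)
        r0, r1 = max(0, int(v - pr) - 1), min(rows, int(v + pr) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        uu = np.arange(c0, c1) - u
        vv = np.arange(r0, r1) - v
        covered[r0:r1, c0:c1] |= uu[None, :] ** 2 + vv[:, None] ** 2 <= pr * pr
    return 100.0 * covered.mean()


# ---------------------------------------------------------------------------
# rendering

_BACKGROUND_GREY = 90


def render_frame(
    plants: Sequence[PlantGT],
    plane: GroundPlane,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    timestamp: int | str = 0,
) -> tuple[FrameRGBD, SegMask, list[PlantGT]]:
    """Ray-cast one top-down RGB-D frame of the scene.

    Every pixel ray is intersected with the tilted ground plane and each
    plant's cap sphere; the nearest hit wins, which resolves overlap by
    per-pixel maximum elevation (occluded leaves do not contribute).  Depth
    is the z coordinate of the hit, plus optional Gaussian noise, quantised
    to the storage unit.  The ground-truth mask marks pixels whose winning
    surface is a plant.
    """
    cam = cfg.intrinsics
    rows, cols = cfg.image_size
    half_w, half_h = cols * cfg.gsd_mm / 2.0, rows * cfg.gsd_mm / 2.0
    for p in plants:
        if not (-half_w <= p.centre_mm[0] <= half_w and -half_h <= p.centre_mm[1] <= half_h):
            raise SyntheticSceneError(f"plant {p.id} centre outside the imaged area")

    u = (np.arange(cols) - cam.cx) / cam.fx
    v = (np.arange(rows) - cam.cy) / cam.fy
    dx = np.broadcast_to(u[None, :], (rows, cols))
    dy = np.broadcast_to(v[:, None], (rows, cols))
    n = plane.normal
    denom = n[0] * dx + n[1] * dy + n[2]
    depth = plane.offset / denom  # ray-plane hit, z-depth since d_z = 1
    label = np.zeros((rows, cols), dtype=np.int32)

    for k, p in enumerate(plants, start=1):
        a, h = p.radius_mm, p.height_mm
        if a <= 0 or h <= 0:
            continue
        R = cap_sphere_radius(a, h)
        # base point on the plane below the nominal centre
        bx, by = p.centre_mm
        bz = (plane.offset - n[0] * bx - n[1] * by) / n[2]
        base = np.array([bx, by, bz])
        centre = base + (h - R) * n  # sphere centre; n points toward the camera
        # conservative pixel bounding box of the sphere
        zc = centre[2]
        pr = R / max(zc - R, 1.0) * cam.fx + 3.0
        uc = centre[0] / zc * cam.fx + cam.cx
        vc = centre[1] / zc * cam.fy + cam.cy
        c0, c1 = max(0, int(uc - pr)), min(cols, int(uc + pr) + 1)
        r0, r1 = max(0, int(vc - pr)), min(rows, int(vc + pr) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        sdx, sdy = dx[r0:r1, c0:c1], dy[r0:r1, c0:c1]
        A = sdx * sdx + sdy * sdy + 1.0
        B = -2.0 * (sdx * centre[0] + sdy * centre[1] + centre[2])
        C = float(centre @ centre - R * R)
        disc = B * B - 4.0 * A * C
        hit = disc >= 0.0
        t = np.where(hit, (-B - np.sqrt(np.where(hit, disc, 0.0))) / (2.0 * A), 0.0)
        # restrict to the cap: hit point above the base plane
        px, py, pz = t * sdx, t * sdy, t
        above = (px - base[0]) * n[0] + (py - base[1]) * n[1] + (pz - base[2]) * n[2] >= -1e-9
        win = hit & above & (t > 0) & (t < depth[r0:r1, c0:c1])
        depth[r0:r1, c0:c1] = np.where(win, t, depth[r0:r1, c0:c1])
        label[r0:r1, c0:c1] = np.where(win, k, label[r0:r1, c0:c1])

    if rng is not None and cfg.depth_noise_sd_mm > 0:
        depth = depth + rng.normal(0.0, cfg.depth_noise_sd_mm, size=depth.shape)
    depth = np.round(depth / cfg.depth_scale_mm) * cfg.depth_scale_mm
    np.clip(depth, 0.0, 65535 * cfg.depth_scale_mm, out=depth)

    rgb = np.empty((rows, cols, 3), dtype=np.float64)
    rgb[..., :] = _BACKGROUND_GREY
    for k, p in enumerate(plants, start=1):
        sel = label == k
        if sel.any():
            rgb[sel] = p.color
    if rng is not None and cfg.rgb_noise_sd > 0:
        rgb = rgb + rng.normal(0.0, cfg.rgb_noise_sd, size=rgb.shape)
    rgb8 = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    frame = FrameRGBD(rgb=rgb8, depth_mm=depth, cam=cam, timestamp=timestamp)
    mask = SegMask(label > 0, provenance="ground-truth")
    return frame, mask, list(plants)


# ---------------------------------------------------------------------------
# batch simulation


@dataclass
class BatchState:
    """Mutable state of the growing batch between days."""

    cfg: SimConfig
    plants: list[PlantGT]
    n_current: int
    ladder_idx: int
    events_nominal: list[tuple[int, float]]
    events_realized: list[tuple[int, float]]
    pending_spacing: int | None = None  # day on which a triggered spacing lands
    rng: np.random.Generator | None = None


def _traits_on(cfg: SimConfig, plant: PlantGT, day: float) -> PlantGT:
    a = cfg.growth.radius(day) * plant.scale_radius
    h = cfg.growth.height(day) * plant.scale_height
    # the cap model needs dome-like heads (h <= a)
    return replace(plant, radius_mm=a, height_mm=min(h, a))


def _new_batch_state(cfg: SimConfig, rng: np.random.Generator) -> BatchState:
    if cfg.density_schedule is not None:
        first = cfg.density_schedule.events[0][1]
    else:
        first = cfg.ladder[0]
    n0 = max(1, round(first * cfg.ground_area_m2))
    centres = grid_layout(n0, cfg.extent_mm)
    plants = []
    for i, (x, y) in enumerate(centres):
        sr = float(np.exp(rng.normal(0.0, cfg.trait_jitter_sd)))
        sh = float(np.exp(rng.normal(0.0, cfg.trait_jitter_sd)))
        wn = float(rng.normal(0.0, cfg.allometry.noise_sd_g))
        g = int(np.clip(rng.normal(140, 18), 90, 210))
        r = int(np.clip(rng.normal(45, 8), 20, 80))
        b = int(np.clip(rng.normal(45, 8), 20, 80))
        plants.append(
            _traits_on(
                cfg,
                PlantGT(
                    id=i, centre_mm=(float(x), float(y)),
                    radius_mm=1.0, height_mm=1.0,
                    scale_radius=sr, scale_height=sh,
                    weight_noise_g=wn, color=(r, g, b),
                ),
                0.0,
            )
        )
    realized = n0 / cfg.ground_area_m2
    return BatchState(
        cfg=cfg, plants=plants, n_current=n0, ladder_idx=0,
        events_nominal=[(0, first)], events_realized=[(0, realized)], rng=rng,
    )


def _keep_indices(n_current: int, n_new: int) -> np.ndarray:
    """Evenly thinned subset, as spacing staff remove every k-th head."""
    return np.unique(np.round(np.linspace(0, n_current - 1, n_new)).astype(int))


def _space_to(state: BatchState, day: int, nominal_density: float) -> None:
    """Re-lay the surviving plants on a grid at the new (lower) density."""
    cfg = state.cfg
    n_new = max(1, round(nominal_density * cfg.ground_area_m2))
    if n_new >= state.n_current:
        raise ScheduleError(
            f"spacing to {nominal_density} heads/m^2 would not reduce the plant count"
        )
    kept = [state.plants[i] for i in _keep_indices(state.n_current, n_new)]
    centres = grid_layout(n_new, cfg.extent_mm)
    state.plants = [
        replace(p, centre_mm=(float(x), float(y))) for p, (x, y) in zip(kept, centres)
    ]
    state.n_current = n_new
    state.ladder_idx += 1
    state.events_nominal.append((day, nominal_density))
    state.events_realized.append((day, n_new / cfg.ground_area_m2))
    state.pending_spacing = None


def _gt_coverage_of(plants: Sequence[PlantGT], cfg: SimConfig) -> float:
    """Ground-truth coverage a noiseless rendered mask would report."""
    _, mask, _ = render_frame(plants, cfg.ground_plane(), cfg, rng=None)
    return 100.0 * float(mask.data.mean())


def _predicted_light_loss(
    state: BatchState, radii_prev: np.ndarray, radii_now: np.ndarray, next_density: float
) -> float:
    """Light loss the indicator would report if spacing happened now.

    Predicts with the same measurement operator and timing the pipeline
    uses: the "before" coverage comes from the previous day's frame
    (``radii_prev``), the "after" coverage from today's radii re-laid at
    the new density.
    """
    cfg = state.cfg
    prev = [replace(p, radius_mm=float(a)) for p, a in zip(state.plants, radii_prev)]
    cov_before = _gt_coverage_of(prev, cfg)
    n_new = max(1, round(next_density * cfg.ground_area_m2))
    centres_after = grid_layout(n_new, cfg.extent_mm)
    keep = _keep_indices(state.n_current, n_new)
    after = [
        replace(state.plants[i], centre_mm=(float(x), float(y)), radius_mm=float(radii_now[i]))
        for i, (x, y) in zip(keep, centres_after)
    ]
    cov_after = _gt_coverage_of(after, cfg)
    q = n_new / state.n_current
    return (100.0 - cov_after) - (cov_after - cov_before * q)


def _policy_triggers(state: BatchState, day: int) -> bool:
    cfg = state.cfg
    if state.ladder_idx + 1 >= len(cfg.ladder):
        return False
    next_density = cfg.ladder[state.ladder_idx + 1]
    radii_today = np.array([p.radius_mm for p in state.plants])
    if cfg.spacing_policy == "tangency":
        centres = np.array([p.centre_mm for p in state.plants])
        d = np.linalg.norm(centres[:, None, :] - centres[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        gaps = d - (radii_today[:, None] + radii_today[None, :])
        return bool(gaps.min() <= 0.0)
    if cfg.spacing_policy == "coverage":
        centres = np.array([p.centre_mm for p in state.plants])
        cov = union_coverage_pct(centres, radii_today, cfg.image_size, cfg.gsd_mm)
        return cov >= cfg.coverage_trigger_pct
    if cfg.spacing_policy == "balanced":
        scale = np.array([p.scale_radius for p in state.plants])
        radii_yesterday = cfg.growth.radius(day - 1) * scale
        radii_tomorrow = cfg.growth.radius(day + 1) * scale
        f_today = _predicted_light_loss(state, radii_yesterday, radii_today, next_density)
        if f_today <= 0.0:
            return True
        f_tomorrow = _predicted_light_loss(state, radii_today, radii_tomorrow, next_density)
        return f_tomorrow < 0.0 and f_today < -f_tomorrow
    raise SyntheticSceneError(f"unknown spacing policy {cfg.spacing_policy!r}")


def grow_and_space(state: BatchState, day: int) -> BatchState:
    """Advance the batch to ``day``: logistic growth, then any spacing event.

    With an explicit schedule, spacing happens on the scheduled days; with a
    policy, the trigger is evaluated daily and the event lands
    ``spacing_delay_days`` later.  Re-laying preserves per-plant state.
    """
    cfg = state.cfg
    state.plants = [_traits_on(cfg, p, float(day)) for p in state.plants]
    if cfg.density_schedule is not None:
        for d, dens in cfg.density_schedule.events[1:]:
            if d == day:
                _space_to(state, day, dens)
    else:
        if state.pending_spacing is None and _policy_triggers(state, day):
            state.pending_spacing = day + cfg.spacing_delay_days
        if state.pending_spacing is not None and day >= state.pending_spacing:
            if state.ladder_idx + 1 < len(cfg.ladder):
                _space_to(state, day, cfg.ladder[state.ladder_idx + 1])
            else:
                state.pending_spacing = None
    return state


@dataclass
class SyntheticBatch:
    """A rendered batch: frames, ground-truth masks and per-plant truth."""

    cfg: SimConfig
    frames: list[FrameRGBD]
    masks: list[SegMask]
    plants_per_frame: list[list[PlantGT]]
    schedule_nominal: DensitySchedule
    schedule_realized: DensitySchedule
    plane_true: GroundPlane

    @property
    def days(self) -> list[int]:
        return sorted({int(f.timestamp) for f in self.frames})

    def frame_index(self, day: int, frame_of_day: int = 0) -> int:
        return day * self.cfg.frames_per_day + frame_of_day

    def gt_coverage_pct(self, day: int) -> float:
        return 100.0 * self.masks[self.frame_index(day)].data.mean()

    def gt_mean_weight_g(self, day: int) -> float:
        plants = self.plants_per_frame[self.frame_index(day)]
        return float(np.mean([p.fresh_weight_g(self.cfg.allometry) for p in plants]))

    def gt_table(self):
        """Per-day ground-truth summary as a DataFrame."""
        import pandas as pd

        rows = []
        for day in self.days:
            i = self.frame_index(day)
            plants = self.plants_per_frame[i]
            weights = [p.fresh_weight_g(self.cfg.allometry) for p in plants]
            rows.append(
                {
                    "day": day,
                    "density_nominal": self.schedule_nominal.density_on(day),
                    "density_realized": self.schedule_realized.density_on(day),
                    "n_plants": len(plants),
                    "coverage_gt_pct": self.gt_coverage_pct(day),
                    "mean_radius_mm": float(np.mean([p.radius_mm for p in plants])),
                    "mean_height_cm": float(np.mean([p.height_cm for p in plants])),
                    "mean_indicator_cm3": float(np.mean([p.indicator_cm3 for p in plants])),
                    "mean_weight_g": float(np.mean(weights)),
                }
            )
        return pd.DataFrame(rows)

    def calibration_pairs(
        self, every_days: int = 7, n_samples: int = 6, seed: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Weekly destructive samples: (ground-truth indicator cm^3, weight g)."""
        rng = np.random.default_rng(seed)
        xs, ws = [], []
        for day in self.days[::every_days]:
            plants = self.plants_per_frame[self.frame_index(day)]
            take = rng.choice(len(plants), size=min(n_samples, len(plants)), replace=False)
            for i in take:
                xs.append(plants[i].indicator_cm3)
                ws.append(plants[i].fresh_weight_g(self.cfg.allometry))
        return np.asarray(xs), np.asarray(ws)


def simulate_batch(cfg: SimConfig) -> SyntheticBatch:
    """Run the full growth/spacing/rendering loop for ``cfg.days`` days."""
    rng = np.random.default_rng(cfg.seed)
    plane = cfg.ground_plane()
    state = _new_batch_state(cfg, rng)
    frames, masks, per_frame = [], [], []
    for day in range(cfg.days):
        if day > 0:
            state = grow_and_space(state, day)
        for _ in range(cfg.frames_per_day):
            noise_rng = rng if (cfg.depth_noise_sd_mm > 0 or cfg.rgb_noise_sd > 0) else None
            frame, mask, snapshot = render_frame(
                state.plants, plane, cfg, rng=noise_rng, timestamp=day
            )
            frames.append(frame)
            masks.append(mask)
            per_frame.append(snapshot)
    return SyntheticBatch(
        cfg=cfg,
        frames=frames,
        masks=masks,
        plants_per_frame=per_frame,
        schedule_nominal=DensitySchedule.from_pairs(state.events_nominal),
        schedule_realized=DensitySchedule.from_pairs(state.events_realized),
        plane_true=plane,
    )
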