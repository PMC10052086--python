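"""Depth-image geometry: pinhole back-projection, RANSAC ground-plane
fitting, per-pixel canopy heights and per-plant volume.

Conventions: 0-based (row, col) pixel indices; camera coordinates in mm
with +z pointing from the camera into the scene (down, for a top-down rig);
the ground plane is fitted once on the planting-day frame through the
non-lettuce pixels and reused for the whole batch (static camera).  The
plane normal is oriented toward the camera, so canopy heights — signed
point-to-plane distances — are positive above the ground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    pass


class PlaneFitError(GeometryError):
    """Degenerate or unsupported plane fit."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels plus the stored-depth unit scale (mm/unit)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise GeometryError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise GeometryError("principal point must lie inside the image")
        if self.depth_scale <= 0:
            raise GeometryError("depth_scale must be positive")


def backproject(
    depth_mm: np.ndarray, cam: CameraIntrinsics, *, return_pixels: bool = False
):
    """Back-project a depth raster (mm, 0 = invalid) to camera-frame points.

    Pixel (row v, col u) at depth z maps to
    ((u − cx)·z/fx, (v − cy)·z/fy, z) in mm.  Invalid (zero or non-finite)
    pixels are omitted.  With ``return_pixels`` the (v, u) indices of the
    retained pixels are returned alongside the (N, 3) point array.
    """
    depth = np.asarray(depth_mm, dtype=np.float64)
    if depth.ndim != 2:
        raise GeometryError("depth raster must be 2-D")
    valid = np.isfinite(depth) & (depth > 0)
    if not valid.any():
        raise GeometryError("no valid depth pixels")
    v, u = np.nonzero(valid)
    z = depth[v, u]
    pts = np.column_stack(((u - cam.cx) * z / cam.fx, (v - cam.cy) * z / cam.fy, z))
    if return_pixels:
        return pts, (v, u)
    return pts


def project(points: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame points (mm) to continuous (u, v) pixel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    z = pts[:, 2]
    if np.any(z <= 0):
        raise GeometryError("points must have positive depth")
    return np.column_stack((pts[:, 0] * cam.fx / z + cam.cx, pts[:, 1] * cam.fy / z + cam.cy))


@dataclass(frozen=True)
class GroundPlane:
    """Plane n·p = d in mm camera coordinates, ‖n‖ = 1, n toward the camera."""

    normal: np.ndarray
    offset: float
    inliers: int = 0
    residual_mm: float = 0.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        nrm = float(np.linalg.norm(n))
        if not np.isclose(nrm, 1.0, atol=1e-9):
            if nrm == 0:
                raise GeometryError("zero plane normal")
            n = n / nrm
            object.__setattr__(self, "offset", self.offset / nrm)
        # camera sits at the origin looking along +z: "toward the camera"
        # means the normal's z component is negative.
        if n[2] > 0:
            n = -n
            object.__setattr__(self, "offset", -self.offset)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance along the normal; positive on the camera side (above ground)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.normal - self.offset

    def tilt_deg(self) -> float:
        """Angle between the plane normal and the optical axis, degrees."""
        return float(np.degrees(np.arccos(np.clip(abs(self.normal[2]), -1.0, 1.0))))


def _lstsq_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through points via SVD on the centred cloud."""
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if points.shape[0] < 3 or s[1] < 1e-9 * max(s[0], 1.0):
        raise PlaneFitError("degenerate (collinear) plane support")
    n = vt[2]
    return n, float(n @ centroid)


def fit_ground_plane(
    points: np.ndarray,
    *,
    iterations: int = 1000,
    inlier_threshold_mm: float = 5.0,
    seed: int | np.random.Generator = 0,
    max_support: int = 20000,
) -> GroundPlane:
    """Fit the ground plane to background points with seeded RANSAC.

    Random minimal (3-point) hypotheses are scored by the count of points
    within ``inlier_threshold_mm`` of the hypothesis plane; the best
    consensus set is refined by a total-least-squares fit.  With more than
    ``max_support`` points a deterministic subsample is scored, but the
    final refinement uses every inlier.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise PlaneFitError(f"need >= 3 points of dim 3, got shape {pts.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    score_pts = pts
    if pts.shape[0] > max_support:
        score_pts = pts[rng.choice(pts.shape[0], size=max_support, replace=False)]

    idx = rng.integers(0, score_pts.shape[0], size=(iterations, 3))
    p0, p1, p2 = (score_pts[idx[:, k]] for k in range(3))
    normals = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-9
    if not ok.any():
        raise PlaneFitError("all RANSAC hypotheses degenerate")
    normals = normals[ok] / norms[ok, None]
    offsets = np.einsum("ij,ij->i", normals, p0[ok])

    # distance of every scored point to every hypothesis, chunked over
    # hypotheses to bound memory.
    best_count, best = -1, 0
    chunk = max(1, int(5e7) // max(score_pts.shape[0], 1))
    counts = np.empty(normals.shape[0], dtype=np.int64)
    for start in range(0, normals.shape[0], chunk):
        sl = slice(start, min(start + chunk, normals.shape[0]))
        d = np.abs(score_pts @ normals[sl].T - offsets[sl])
        counts[sl] = (d <= inlier_threshold_mm).sum(axis=0)
    best = int(np.argmax(counts))
    best_count = int(counts[best])
    if best_count < 3:
        raise PlaneFitError("no consensus set found")

    # refine on the full point set's inliers
    dist = np.abs(pts @ normals[best] - offsets[best])
    inliers = pts[dist <= inlier_threshold_mm]
    n, d0 = _lstsq_plane(inliers)
    plane = GroundPlane(n, d0, inliers=int(inliers.shape[0]))
    residual = float(np.sqrt(np.mean(plane.signed_distance(inliers) ** 2)))
    return GroundPlane(plane.normal, plane.offset, plane.inliers, residual)


@dataclass(frozen=True)
class HeightMap:
    """Per-pixel canopy height (cm) over lettuce pixels, NaN elsewhere.

    ``pixel_area_cm2`` optionally carries each lettuce pixel's ground
    footprint (from its depth and the intrinsics); when present it is used
    for volume integration instead of a constant ground-sampling distance.
    """

    heights_cm: np.ndarray
    pixel_area_cm2: np.ndarray | None = None
    timestamp: int | str | None = None

    def lettuce_values(self) -> np.ndarray:
        vals = self.heights_cm[np.isfinite(self.heights_cm)]
        return vals


def heights(
    depth_mm: np.ndarray,
    plane: GroundPlane,
    mask,
    cam: CameraIntrinsics,
    *,
    mode: str = "point-to-plane",
    timestamp: int | str | None = None,
) -> HeightMap:
    """Per-pixel canopy height above the ground plane, in cm.

    Heights are signed point-to-plane distances of the back-projected
    lettuce pixels (positive toward the camera), or plain depth differences
    along the optical axis with ``mode="vertical"``.  Negative heights
    (sensor noise below the plane) are clipped to 0.  Only lettuce pixels
    are populated.
    """
    from .segmentation import SegMask

    mask = mask if isinstance(mask, SegMask) else SegMask(mask)
    depth = np.asarray(depth_mm, dtype=np.float64)
    if depth.shape != mask.shape:
        raise GeometryError(f"depth {depth.shape} and mask {mask.shape} shapes differ")
    out = np.full(depth.shape, np.nan)
    area = np.full(depth.shape, np.nan)
    sel = mask.data & np.isfinite(depth) & (depth > 0)
    if sel.any():
        v, u = np.nonzero(sel)
        z = depth[v, u]
        pts = np.column_stack(((u - cam.cx) * z / cam.fx, (v - cam.cy) * z / cam.fy, z))
        if mode == "point-to-plane":
            h_mm = plane.signed_distance(pts)
        elif mode == "vertical":
            # depth of the plane along each pixel ray minus the measured depth
            dirs = np.column_stack(
                ((u - cam.cx) / cam.fx, (v - cam.cy) / cam.fy, np.ones_like(z))
            )
            t = plane.offset / (dirs @ plane.normal)
            h_mm = t - z
        else:
            raise GeometryError(f"unknown height mode {mode!r}")
        out[v, u] = np.clip(h_mm, 0.0, None) / 10.0
        area[v, u] = _pixel_footprints(depth, cam)[v, u] / 100.0  # mm^2 -> cm^2
    return HeightMap(out, area, timestamp)


def _pixel_footprints(depth: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Ground footprint (mm^2) of every pixel from the local Jacobian of the
    back-projected (x, y) coordinate maps.

    Using a constant per-pixel area z^2/(fx*fy) underestimates canopy volume
    by ~3R/4z for a dome of radius R, because pixels near the silhouette are
    foreshortened on the sloped surface and cover more ground; the finite-
    difference Jacobian captures that slope term.  The maps are lightly
    smoothed first so sensor noise does not dominate the derivatives.
    """
    from scipy.ndimage import uniform_filter

    rows, cols = depth.shape
    z = np.where(np.isfinite(depth) & (depth > 0), depth, np.nan)
    uu = (np.arange(cols) - cam.cx) / cam.fx
    vv = (np.arange(rows) - cam.cy) / cam.fy
    x = uu[None, :] * z
    y = vv[:, None] * z
    if min(rows, cols) >= 3:
        fill = np.nanmedian(z)
        x = uniform_filter(np.where(np.isnan(x), uu[None, :] * fill, x), size=3)
        y = uniform_filter(np.where(np.isnan(y), vv[:, None] * fill, y), size=3)
    xv, xu = np.gradient(x)
    yv, yu = np.gradient(y)
    return np.abs(xu * yv - xv * yu)


def volume_per_plant(
    hm: HeightMap,
    gsd_mm: float,
    density_heads_m2: float,
    ground_area_m2: float,
) -> float:
    """Canopy volume per plant in cm^3.

    Integrates height over the lettuce pixels (each pixel's ground footprint
    from its depth when available, else gsd^2) and divides by the number of
    heads in the imaged area, density * area.
    """
    if density_heads_m2 <= 0:
        raise GeometryError("density must be positive")
    if gsd_mm <= 0:
        raise GeometryError("gsd must be positive")
    sel = np.isfinite(hm.heights_cm)
    if not sel.any():
        return 0.0
    h = hm.heights_cm[sel]
    if hm.pixel_area_cm2 is not None and np.isfinite(hm.pixel_area_cm2[sel]).all():
        a = hm.pixel_area_cm2[sel]
    else:
        a = np.full(h.shape, (gsd_mm / 10.0) ** 2)
    heads = density_heads_m2 * ground_area_m2
    return float(np.sum(h * a) / heads)


def max_height(hm: HeightMap, quantile: float = 1.0) -> float:
    """Maximum (or upper-quantile) canopy height over lettuce pixels, cm."""
    vals = hm.lettuce_values()
    if vals.size == 0:
        raise GeometryError("empty lettuce region")
    if not 0.0 < quantile <= 1.0:
        raise GeometryError("quantile must be in (0, 1]")
    if quantile == 1.0:
        return float(vals.max())
    return float(np.quantile(vals, quantile))
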