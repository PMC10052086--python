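"""Decision indicators for spacing and harvest.

Two indicators are assembled from the per-frame canopy traits:

* the *light-loss* indicator scores a spacing event after the fact by
  comparing the floor-light loss just after spacing (100 − coverage) with
  the light lost to overlapping leaves just before it (measured coverage
  minus the density-scaled projection of the pre-spacing coverage);
  values near zero mark well-timed spacing, negative values late spacing,
  large positive values early spacing;

* the *harvest* indicator, area per plant × maximum canopy height (cm^3),
  is a non-destructive fresh-weight proxy; a quadratic calibration against
  destructive weighings converts a target head weight (250 g by default)
  into an indicator threshold, ~7840 cm^3 for the published calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import geometry
from .frames import FrameRGBD
from .geometry import GroundPlane, HeightMap
from .schedule import DensitySchedule, next_ladder_density
from .segmentation import SegMask, coverage

logger = logging.getLogger(__name__)

#: Published indicator threshold (cm^3) equivalent to the 250 g target.
DEFAULT_HARVEST_THRESHOLD_CM3 = 7840.0
DEFAULT_TARGET_WEIGHT_G = 250.0
DEFAULT_COVERAGE_TRIGGER_PCT = 98.0
NEAR_OPTIMAL_LIGHT_LOSS = 5.0


class IndicatorError(ValueError):
    pass


@dataclass(frozen=True)
class TraitRecord:
    """Per-frame canopy traits at one timestamp.

    Area per plant follows from coverage and density
    (area = coverage/100 / density, in cm^2 via the 10^4 factor), and the
    harvest indicator is area per plant times maximum height.
    """

    timestamp: int | str
    coverage_pct: float
    max_height_cm: float
    area_per_plant_cm2: float
    volume_per_plant_cm3: float
    indicator_cm3: float
    density: float


def area_per_plant_cm2(coverage_pct: float, density: float) -> float:
    """Projected ground area per head, cm^2: (coverage/100)/density * 10^4."""
    if density <= 0:
        raise IndicatorError("density must be positive")
    return coverage_pct / 100.0 / density * 1e4


def trait_record(
    frame: FrameRGBD,
    mask: SegMask,
    plane: GroundPlane,
    density: float,
    *,
    gsd_mm: float,
    ground_area_m2: float,
    height_quantile: float = 1.0,
) -> TraitRecord:
    """Assemble one TraitRecord from a frame, its mask and the ground plane."""
    if plane is None:
        raise IndicatorError("missing ground plane")
    cov = coverage(mask, timestamp=frame.timestamp, density=density).percent
    hm: HeightMap = geometry.heights(
        frame.depth_mm, plane, mask, frame.cam, timestamp=frame.timestamp
    )
    if mask.lettuce_pixels() == 0:
        hmax, vol = 0.0, 0.0
    else:
        hmax = geometry.max_height(hm, quantile=height_quantile)
        vol = geometry.volume_per_plant(hm, gsd_mm, density, ground_area_m2)
    area = area_per_plant_cm2(cov, density)
    return TraitRecord(
        timestamp=frame.timestamp,
        coverage_pct=cov,
        max_height_cm=hmax,
        area_per_plant_cm2=area,
        volume_per_plant_cm3=vol,
        indicator_cm3=area * hmax,
        density=density,
    )


@dataclass(frozen=True)
class SpacingEvaluation:
    """Light-loss bookkeeping of one spacing event."""

    event_time: int | str
    coverage_prev_pct: float
    coverage_curr_pct: float
    density_prev: float
    density_curr: float
    light_loss_current: float
    light_loss_before_spacing: float
    light_loss: float

    @property
    def near_optimal(self) -> bool:
        return abs(self.light_loss) < NEAR_OPTIMAL_LIGHT_LOSS

    @property
    def verdict(self) -> str:
        if self.near_optimal:
            return "near-optimal"
        return "too late" if self.light_loss < 0 else "too early"


def light_loss(
    coverage_prev_pct: float,
    coverage_curr_pct: float,
    density_prev: float,
    density_curr: float,
    event_time: int | str = 0,
) -> SpacingEvaluation:
    """Score one spacing event.

    floor loss  = 100 − coverage_t
    overlap loss = coverage_t − coverage_{t−1} · density_t / density_{t−1}
    light loss  = floor loss − overlap loss

    Negative light loss means spacing came too late (the hidden-overlap
    term dominates); a large positive value means too early.
    """
    if density_curr >= density_prev:
        raise IndicatorError(
            f"spacing must reduce density ({density_prev} -> {density_curr})"
        )
    for c in (coverage_prev_pct, coverage_curr_pct):
        if not 0.0 <= c <= 100.0:
            raise IndicatorError(f"coverage {c} outside [0, 100]")
    ll_current = 100.0 - coverage_curr_pct
    theoretical = coverage_prev_pct * density_curr / density_prev
    ll_before = coverage_curr_pct - theoretical
    return SpacingEvaluation(
        event_time=event_time,
        coverage_prev_pct=coverage_prev_pct,
        coverage_curr_pct=coverage_curr_pct,
        density_prev=density_prev,
        density_curr=density_curr,
        light_loss_current=ll_current,
        light_loss_before_spacing=ll_before,
        light_loss=ll_current - ll_before,
    )


def evaluate_schedule(
    traits: Sequence[TraitRecord], schedule: DensitySchedule
) -> list[SpacingEvaluation]:
    """One SpacingEvaluation per density transition in the schedule.

    The last trait record before the event and the first at/after it
    provide the two coverages; events without flanking records are skipped
    with a warning.
    """
    records = sorted(traits, key=lambda r: r.timestamp)
    times = [r.timestamp for r in records]
    out = []
    for day, dens_prev, dens_curr in schedule.transitions:
        before = [r for r, t in zip(records, times) if t < day]
        after = [r for r, t in zip(records, times) if t >= day]
        if not before or not after:
            logger.warning("spacing event at %s lacks flanking frames; skipped", day)
            continue
        out.append(
            light_loss(
                before[-1].coverage_pct,
                after[0].coverage_pct,
                dens_prev,
                dens_curr,
                event_time=day,
            )
        )
    return out


def recommend_spacing(
    coverage_pct: float,
    current_density: float,
    threshold_pct: float = DEFAULT_COVERAGE_TRIGGER_PCT,
    ladder: Sequence[float] | None = None,
) -> float | None:
    """Spacing decision from current coverage: the next ladder density, or None.

    Space when coverage has reached the trigger threshold and a lower
    ladder density exists; otherwise hold.
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise IndicatorError("threshold must be in (0, 100]")
    if coverage_pct < threshold_pct:
        return None
    if ladder is None:
        return next_ladder_density(current_density)
    return next_ladder_density(current_density, ladder)


@dataclass(frozen=True)
class WeightModel:
    """Quadratic map indicator (cm^3) -> fresh weight (g), with the
    indicator threshold at which the predicted weight reaches the target."""

    c0: float
    c1: float
    c2: float
    threshold_cm3: float = DEFAULT_HARVEST_THRESHOLD_CM3
    target_weight_g: float = DEFAULT_TARGET_WEIGHT_G
    mae_g: float = float("nan")
    rmse_g: float = float("nan")

    def predict(self, indicator_cm3) -> np.ndarray:
        x = np.asarray(indicator_cm3, dtype=np.float64)
        return self.c0 + self.c1 * x + self.c2 * x * x


def _threshold_crossing(c0: float, c1: float, c2: float, target: float, x_hint: float) -> float:
    """Smallest non-negative indicator where the quadratic reaches target.

    Returns inf when the fitted model never reaches the target (e.g. a
    constant fit below the target weight): such a batch is never harvested.
    """
    if c0 >= target:
        return 0.0
    # solve c2 x^2 + c1 x + (c0 - target) = 0
    if abs(c2) < 1e-15:
        if abs(c1) < 1e-15 or (target - c0) / c1 < 0:
            return float("inf")
        return (target - c0) / c1
    disc = c1 * c1 - 4.0 * c2 * (c0 - target)
    if disc < 0:
        return float("inf")
    roots = sorted(
        r for r in ((-c1 - np.sqrt(disc)) / (2 * c2), (-c1 + np.sqrt(disc)) / (2 * c2))
    )
    # the crossing where predicted weight is increasing through the target
    candidates = [r for r in roots if r >= 0 and (c1 + 2 * c2 * r) >= 0]
    if not candidates:
        return float("inf")
    # prefer the crossing nearest the data range when both qualify
    return min(candidates, key=lambda r: abs(r - x_hint))


def fit_weight_model(
    indicators_cm3: Sequence[float],
    weights_g: Sequence[float],
    target_weight_g: float = DEFAULT_TARGET_WEIGHT_G,
) -> WeightModel:
    """Least-squares quadratic calibration of fresh weight on the indicator.

    Requires at least three distinct indicator values.  The harvest
    threshold is the smallest increasing crossing of the target weight;
    MAE and RMSE are reported on the fitting pairs.
    """
    x = np.asarray(indicators_cm3, dtype=np.float64)
    w = np.asarray(weights_g, dtype=np.float64)
    if x.shape != w.shape or x.ndim != 1:
        raise IndicatorError("indicators and weights must be equal-length 1-D")
    if np.unique(x).size < 3:
        raise IndicatorError("need >= 3 distinct indicator values")
    # guard the normal equations at indicator scales of ~10^4
    scale = max(float(np.abs(x).max()), 1.0)
    coef = np.polynomial.polynomial.polyfit(x / scale, w, deg=2)
    c0, c1, c2 = float(coef[0]), float(coef[1] / scale), float(coef[2] / scale**2)
    pred = c0 + c1 * x + c2 * x * x
    mae = float(np.mean(np.abs(pred - w)))
    rmse = float(np.sqrt(np.mean((pred - w) ** 2)))
    thr = _threshold_crossing(c0, c1, c2, target_weight_g, x_hint=float(np.median(x)))
    return WeightModel(
        c0=c0, c1=c1, c2=c2, threshold_cm3=thr,
        target_weight_g=target_weight_g, mae_g=mae, rmse_g=rmse,
    )


def harvest_date(
    traits: Sequence[TraitRecord], model: WeightModel | None = None
) -> int | str | None:
    """First timestamp whose harvest indicator reaches the model threshold.

    Returns None when the threshold is never crossed (as can happen for a
    batch kept at high density, where occlusion depresses the indicator).
    """
    if not traits:
        raise IndicatorError("empty trait series")
    threshold = (model or WeightModel(0.0, 0.0, 0.0)).threshold_cm3
    for rec in sorted(traits, key=lambda r: r.timestamp):
        if rec.indicator_cm3 >= threshold:
            return rec.timestamp
    return None
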