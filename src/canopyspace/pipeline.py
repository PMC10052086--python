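"""End-to-end pipeline: frames -> masks -> ground plane -> daily traits ->
spacing evaluations -> harvest date -> economics.

The pipeline mirrors greenhouse practice: the ground plane is fitted once,
by RANSAC through the non-lettuce pixels of the planting-day frame, and
reused for the whole batch; each daily frame then contributes one trait
record; every density transition is scored with the light-loss indicator;
and the harvest date is the first day the area×height indicator crosses
the weight-model threshold.  Identical config and seed reproduce the
report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry, indicators, io, segmentation
from .economics import EconomicLedger, Tariffs, average_crop_density, net_profit
from .frames import FrameRGBD
from .geometry import GroundPlane
from .indicators import TraitRecord, WeightModel
from .schedule import DensitySchedule
from .segmentation import SegMask

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RansacParams:
    iterations: int = 1000
    inlier_threshold_mm: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    """File-based pipeline configuration (see ``run_pipeline``)."""

    frames_dir: str
    intrinsics_file: str
    schedule_file: str
    output_dir: str
    masks_dir: str | None = None  # None -> built-in excess-green segmenter
    calibration_file: str | None = None  # CSV: day, fresh_weight_g
    ledger_file: str | None = None  # JSON economics ledger
    gsd_mm: float = 2.0
    ground_area_m2: float | None = None
    segmentation_threshold: float | str = 20
    coverage_trigger_pct: float = indicators.DEFAULT_COVERAGE_TRIGGER_PCT
    harvest_threshold_cm3: float = indicators.DEFAULT_HARVEST_THRESHOLD_CM3
    target_weight_g: float = indicators.DEFAULT_TARGET_WEIGHT_G
    ransac: RansacParams = field(default_factory=RansacParams)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, default=lambda o: o.__dict__, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class BatchReport:
    """Everything the pipeline derives from one batch."""

    traits: list[TraitRecord]
    evaluations: list
    plane: GroundPlane
    weight_model: WeightModel
    harvest_day: int | str | None
    economics: dict | None
    provenance: dict

    def traits_frame(self) -> pd.DataFrame:
        return io.traits_to_frame(self.traits)

    def evaluations_frame(self) -> pd.DataFrame:
        return io.evaluations_to_frame(self.evaluations)


def fit_plane_for_batch(
    frame: FrameRGBD, mask: SegMask, ransac: RansacParams, seed: int
) -> GroundPlane:
    """RANSAC ground plane through the planting-day background pixels."""
    background = SegMask(~mask.data, provenance=mask.provenance)
    pts = geometry.backproject(np.where(background.data, frame.depth_mm, 0.0), frame.cam)
    return geometry.fit_ground_plane(
        pts,
        iterations=ransac.iterations,
        inlier_threshold_mm=ransac.inlier_threshold_mm,
        seed=seed,
    )


def run_frames(
    frames: Sequence[FrameRGBD],
    masks: Sequence[SegMask],
    schedule: DensitySchedule,
    *,
    gsd_mm: float,
    ground_area_m2: float,
    ransac: RansacParams | None = None,
    seed: int = 0,
    calibration: tuple[Sequence[int], Sequence[float]] | None = None,
    harvest_threshold_cm3: float = indicators.DEFAULT_HARVEST_THRESHOLD_CM3,
    target_weight_g: float = indicators.DEFAULT_TARGET_WEIGHT_G,
    ledger: EconomicLedger | None = None,
    tariffs: Tariffs | None = None,
    provenance: dict | None = None,
) -> BatchReport:
    """Run the full trait/indicator pipeline on in-memory frames.

    ``calibration`` is an optional pair (days, destructive weights in g);
    when given, a quadratic weight model is fitted against the measured
    indicator on those days and its threshold replaces the default.
    """
    if len(frames) != len(masks) or not frames:
        raise PipelineError("need equally many frames and masks (>= 1)")
    ransac = ransac or RansacParams()
    plane = fit_plane_for_batch(frames[0], masks[0], ransac, seed)
    logger.info("ground plane: tilt %.2f deg, %d inliers", plane.tilt_deg(), plane.inliers)

    traits: list[TraitRecord] = []
    for frame, mask in zip(frames, masks):
        density = schedule.density_on(int(frame.timestamp))
        traits.append(
            indicators.trait_record(
                frame, mask, plane, density,
                gsd_mm=gsd_mm, ground_area_m2=ground_area_m2,
            )
        )
    evaluations = indicators.evaluate_schedule(traits, schedule)

    if calibration is not None:
        days, weights = calibration
        by_day = {int(t.timestamp): t.indicator_cm3 for t in traits}
        xs = [by_day[int(d)] for d in days]
        model = indicators.fit_weight_model(xs, list(weights), target_weight_g)
    else:
        model = WeightModel(
            0.0, 0.0, 0.0,
            threshold_cm3=harvest_threshold_cm3, target_weight_g=target_weight_g,
        )
    harvest = indicators.harvest_date(traits, model)

    econ = None
    if ledger is not None:
        total_days = max(int(f.timestamp) for f in frames)
        avg_density = average_crop_density(schedule, max(total_days, 1))
        econ = {
            "average_density": avg_density,
            "income": ledger.income,
            "operational_costs": ledger.operational_costs(),
            "intervention_costs": ledger.intervention_costs(tariffs),
            "net_profit": net_profit(ledger, tariffs),
        }

    prov = {"seed": seed, **(provenance or {})}
    return BatchReport(
        traits=traits, evaluations=evaluations, plane=plane,
        weight_model=model, harvest_day=harvest, economics=econ, provenance=prov,
    )


def run_pipeline(cfg: RunConfig) -> BatchReport:
    """File-based end-to-end run; writes CSV/JSON outputs to the output dir."""
    logging.basicConfig(level=cfg.log_level)
    frames_dir = Path(cfg.frames_dir)
    cam = io.read_intrinsics(cfg.intrinsics_file)
    sched_df = io.read_versioned_csv(cfg.schedule_file)
    schedule = DensitySchedule.from_pairs(
        zip(sched_df["day"].astype(int), sched_df["density"].astype(float))
    )

    frames, masks = [], []
    for depth_path in sorted(frames_dir.glob("*_depth.png")):
        stamp = depth_path.stem.replace("_depth", "")
        rgb_path = frames_dir / f"{stamp}_rgb.png"
        if not rgb_path.exists():
            raise PipelineError(f"missing RGB for {depth_path}")
        frame = io.read_frame(depth_path, rgb_path, cam)
        if cfg.masks_dir is not None:
            mask = io.read_mask(Path(cfg.masks_dir) / f"{stamp}_mask.png")
        else:
            mask = segmentation.exg_segment(frame.rgb, cfg.segmentation_threshold)
        frames.append(frame)
        masks.append(mask)
    if not frames:
        raise PipelineError(f"no frames found in {frames_dir}")

    calibration = None
    if cfg.calibration_file is not None:
        cal = pd.read_csv(cfg.calibration_file)
        calibration = (cal["day"].tolist(), cal["fresh_weight_g"].tolist())
    ledger = None
    if cfg.ledger_file is not None:
        ledger = EconomicLedger(**json.loads(Path(cfg.ledger_file).read_text()))

    rows, cols = frames[0].shape
    area = cfg.ground_area_m2
    if area is None:
        area = rows * cols * cfg.gsd_mm**2 / 1e6

    report = run_frames(
        frames, masks, schedule,
        gsd_mm=cfg.gsd_mm, ground_area_m2=area,
        ransac=cfg.ransac, seed=cfg.seed, calibration=calibration,
        harvest_threshold_cm3=cfg.harvest_threshold_cm3,
        target_weight_g=cfg.target_weight_g, ledger=ledger,
        provenance={"config_hash": cfg.config_hash()},
    )

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tdf = report.traits_frame()
    edf = report.evaluations_frame()
    tdf.insert(1, "config_hash", cfg.config_hash())
    if len(edf):
        edf.insert(1, "config_hash", cfg.config_hash())
    tdf.to_csv(out / "traits.csv", index=False)
    edf.to_csv(out / "spacing_evaluations.csv", index=False)
    io.write_weight_model(report.weight_model, out / "weight_model.json")
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "harvest_day": report.harvest_day,
        "plane_tilt_deg": report.plane.tilt_deg(),
        "plane_inliers": report.plane.inliers,
        "economics": report.economics,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return report
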