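"""Reusable study routines: the experiments the analysis drivers, the test
suite and the acceptance script all run.

Each function generates its own synthetic inputs from a seed, runs the
relevant pipeline stages and returns plain numbers, so results are
reproducible from a single integer.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import geometry as geo
from .economics import COMPARTMENT_LEDGERS, net_profit
from .pipeline import BatchReport, run_frames
from .segmentation import exg_segment, miou
from .synth import (
    AllometryParams,
    PlantGT,
    SimConfig,
    SyntheticBatch,
    cap_volume_mm3,
    render_frame,
    simulate_batch,
)
from .indicators import fit_weight_model


def economics_table() -> pd.DataFrame:
    """Net-profit breakdown of the six published compartment ledgers."""
    rows = []
    for name, led in COMPARTMENT_LEDGERS.items():
        rows.append(
            {
                "compartment": name,
                "income": led.income,
                "component_sum": led.fixed + led.heating + led.electricity + led.co2,
                "operational_costs": led.operational_costs(),
                "intervention_costs": led.intervention_costs(),
                "net_profit": net_profit(led),
            }
        )
    return pd.DataFrame(rows)


def run_batch(batch: SyntheticBatch, *, seed: int = 0, use_gt_masks: bool = True,
              calibration: tuple | None = None) -> BatchReport:
    """Run the standard pipeline over a rendered batch."""
    cfg = batch.cfg
    masks = batch.masks if use_gt_masks else [exg_segment(f.rgb) for f in batch.frames]
    return run_frames(
        batch.frames, masks, batch.schedule_realized,
        gsd_mm=cfg.gsd_mm, ground_area_m2=cfg.ground_area_m2, seed=seed,
        calibration=calibration,
    )


def segmentation_study(seed: int = 0, every_days: int = 7) -> dict:
    """Excess-green segmentation vs ground truth on a noiseless batch."""
    cfg = SimConfig(seed=seed, depth_noise_sd_mm=0.0, rgb_noise_sd=0.0)
    batch = simulate_batch(cfg)
    vals = [
        miou(exg_segment(f.rgb), gt)
        for f, gt in zip(batch.frames[::every_days], batch.masks[::every_days])
    ]
    return {"min_miou": float(np.min(vals)), "mean_miou": float(np.mean(vals)), "n": len(vals)}


def height_regression_study(seed: int = 0, noiseless: bool = True) -> dict:
    """Estimated vs true daily maximum plant height over a full batch."""
    cfg = SimConfig(seed=seed)
    if noiseless:
        cfg = replace(cfg, depth_noise_sd_mm=0.0, rgb_noise_sd=0.0)
    batch = simulate_batch(cfg)
    report = run_batch(batch, seed=seed + 1)
    true_h, est_h = [], []
    for day in batch.days:
        i = batch.frame_index(day)
        true_h.append(max(p.height_cm for p in batch.plants_per_frame[i]))
        est_h.append(report.traits[i].max_height_cm)
    x, y = np.asarray(true_h), np.asarray(est_h)
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    r2 = 1.0 - np.sum((y - A @ [slope, intercept]) ** 2) / np.sum((y - y.mean()) ** 2)
    return {"slope": float(slope), "intercept_cm": float(intercept), "r2": float(r2),
            "n": len(x)}


def volume_oracle_study(seed: int = 0) -> dict:
    """Pipeline volume of isolated caps vs the closed-form cap volume."""
    cfg = SimConfig(seed=seed, depth_noise_sd_mm=0.0, rgb_noise_sd=0.0, days=1)
    plane = cfg.ground_plane()
    cases = [((0.0, 0.0), 50.0, 50.0), ((150.0, 100.0), 60.0, 40.0), ((-120.0, 130.0), 70.0, 65.0)]
    plants = [PlantGT(id=i, centre_mm=c, radius_mm=a, height_mm=h)
              for i, (c, a, h) in enumerate(cases)]
    frame, mask, _ = render_frame(plants, plane, cfg, rng=None)
    pts = geo.backproject(np.where(~mask.data, frame.depth_mm, 0.0), cfg.intrinsics)
    fitted = geo.fit_ground_plane(pts, seed=seed)
    hm = geo.heights(frame.depth_mm, fitted, mask, cfg.intrinsics)
    measured_total = geo.volume_per_plant(hm, cfg.gsd_mm, 1.0 / cfg.ground_area_m2,
                                          cfg.ground_area_m2)
    true_total = sum(cap_volume_mm3(a, h) for _, a, h in cases) / 1000.0
    return {
        "measured_total_cm3": float(measured_total),
        "analytic_total_cm3": float(true_total),
        "rel_error_pct": float(100.0 * (measured_total / true_total - 1.0)),
    }


def plane_normal_study(n_trials: int = 100, seed: int = 0,
                       depth_noise_sd_mm: float = 2.0) -> dict:
    """RANSAC plane-normal error over random tilts 0-5 deg with sensor noise.

    Each trial renders a planting-day frame, fits the plane through the
    background pixels and measures the angle to the true normal.
    """
    rng = np.random.default_rng(seed)
    errors = []
    for k in range(n_trials):
        cfg = SimConfig(
            seed=seed + 1000 + k, days=1, image_size=(128, 128),
            plane_tilt_deg=float(rng.uniform(0.0, 5.0)),
            plane_tilt_azimuth_deg=float(rng.uniform(0.0, 360.0)),
            depth_noise_sd_mm=depth_noise_sd_mm, rgb_noise_sd=0.0,
        )
        batch = simulate_batch(cfg)
        frame, mask = batch.frames[0], batch.masks[0]
        pts = geo.backproject(np.where(~mask.data, frame.depth_mm, 0.0), cfg.intrinsics)
        fitted = geo.fit_ground_plane(
            pts, iterations=300, inlier_threshold_mm=5.0, seed=int(rng.integers(2**31))
        )
        cosang = abs(float(fitted.normal @ batch.plane_true.normal))
        errors.append(math.degrees(math.acos(min(cosang, 1.0))))
    return {
        "median_error_deg": float(np.median(errors)),
        "max_error_deg": float(np.max(errors)),
        "n_trials": n_trials,
    }


def _gt_calibration_pairs(cfg: SimConfig, rng: np.random.Generator,
                          every_days: int = 7, n_samples: int = 6):
    """Weekly destructive samples straight from the growth/allometry model."""
    xs, ws = [], []
    for day in range(0, cfg.days, every_days):
        for _ in range(n_samples):
            sr = math.exp(rng.normal(0.0, cfg.trait_jitter_sd))
            sh = math.exp(rng.normal(0.0, cfg.trait_jitter_sd))
            a = cfg.growth.radius(day) * sr
            h = min(cfg.growth.height(day) * sh, a)
            x = (math.pi * a * a / 100.0) * (h / 10.0)
            w = float(cfg.allometry.mean_weight(x)) + rng.normal(0.0, cfg.allometry.noise_sd_g)
            xs.append(x)
            ws.append(max(w, 0.0))
    return np.asarray(xs), np.asarray(ws)


def threshold_recovery_study(n_trials: int = 100, seed: int = 0,
                             weight_noise_sd_g: float = 20.0) -> dict:
    """Harvest-threshold recovery from noisy weekly calibration pairs.

    The generator's allometry defines the true indicator value at which
    mean weight reaches 250 g; each trial fits the quadratic calibration
    on noisy destructive samples and recovers the threshold.
    """
    cfg = SimConfig(allometry=AllometryParams(noise_sd_g=weight_noise_sd_g))
    true_thr = cfg.allometry.true_threshold(250.0)
    rng = np.random.default_rng(seed)
    rel_errors = []
    for _ in range(n_trials):
        xs, ws = _gt_calibration_pairs(cfg, rng)
        model = fit_weight_model(xs, ws, 250.0)
        rel_errors.append(abs(model.threshold_cm3 - true_thr) / true_thr)
    return {
        "true_threshold_cm3": float(true_thr),
        "median_rel_error": float(np.median(rel_errors)),
        "max_rel_error": float(np.max(rel_errors)),
        "n_trials": n_trials,
    }


def weight_recovery_study(seed: int = 0) -> dict:
    """Noiseless quadratic calibration must reproduce the generator's allometry."""
    al = AllometryParams(noise_sd_g=0.0)
    x = np.linspace(50.0, 11000.0, 60)
    model = fit_weight_model(x, al.mean_weight(x), 250.0)
    return {
        "max_coef_error": float(
            max(abs(model.c0 - al.c0), abs(model.c1 - al.c1), abs(model.c2 - al.c2))
        ),
        "mae_g": model.mae_g,
        "threshold_cm3": model.threshold_cm3,
        "true_threshold_cm3": al.true_threshold(250.0),
    }


def light_loss_study(seed: int = 0, policy: str = "balanced",
                     delay_days: int = 0) -> dict:
    """Measured light loss at every spacing event of a constructed batch."""
    cfg = SimConfig(seed=seed, spacing_policy=policy, spacing_delay_days=delay_days)
    batch = simulate_batch(cfg)
    report = run_batch(batch, seed=seed + 1)
    lls = [e.light_loss for e in report.evaluations]
    return {
        "light_losses": [float(v) for v in lls],
        "max_abs": float(np.max(np.abs(lls))) if lls else float("nan"),
        "n_events": len(lls),
    }


def harvest_study(seed: int = 0) -> dict:
    """Pipeline harvest date (measured indicator, calibrated threshold) vs
    the day the true mean weight crosses the 250 g target."""
    cfg = SimConfig(seed=seed)
    batch = simulate_batch(cfg)
    days, weights = [], []
    rng = np.random.default_rng(seed + 17)
    # weekly destructive samples plus the final-day weighing
    sample_days = list(batch.days[::7])
    if batch.days[-1] not in sample_days:
        sample_days.append(batch.days[-1])
    for day in sample_days:
        plants = batch.plants_per_frame[batch.frame_index(day)]
        for i in rng.choice(len(plants), size=min(6, len(plants)), replace=False):
            days.append(day)
            weights.append(plants[int(i)].fresh_weight_g(cfg.allometry))
    report = run_batch(batch, seed=seed + 1, calibration=(days, weights))
    true_day = next(
        (d for d in batch.days if batch.gt_mean_weight_g(d) >= 250.0), None
    )
    return {
        "harvest_day_pipeline": report.harvest_day,
        "harvest_day_true": true_day,
        "calibration_mae_g": report.weight_model.mae_g,
        "calibration_rmse_g": report.weight_model.rmse_g,
        "calibrated_threshold_cm3": report.weight_model.threshold_cm3,
    }
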