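"""Trait records, light loss, spacing recommendation, weight calibration
and harvest date."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyspace.indicators import (
    DEFAULT_HARVEST_THRESHOLD_CM3,
    IndicatorError,
    TraitRecord,
    WeightModel,
    area_per_plant_cm2,
    evaluate_schedule,
    fit_weight_model,
    harvest_date,
    light_loss,
    recommend_spacing,
)
from canopyspace.schedule import DensitySchedule


def record(day, coverage, height, density):
    area = area_per_plant_cm2(coverage, density)
    return TraitRecord(
        timestamp=day, coverage_pct=coverage, max_height_cm=height,
        area_per_plant_cm2=area, volume_per_plant_cm3=0.0,
        indicator_cm3=area * height, density=density,
    )


class TestTraitArithmetic:
    def test_published_row_arithmetic(self):
        # coverage 87.2% at 15 heads/m^2, max height 15.7 cm
        area = area_per_plant_cm2(87.2, 15.0)
        assert area == pytest.approx(581.33, abs=0.01)
        assert area * 15.7 == pytest.approx(9127, abs=2)

    def test_zero_coverage_zero_indicator(self):
        rec = record(0, 0.0, 12.0, 20.0)
        assert rec.indicator_cm3 == 0.0

    def test_full_coverage_example(self):
        rec = record(0, 100.0, 10.0, 20.0)
        assert rec.indicator_cm3 == pytest.approx(5000.0)


class TestLightLoss:
    def test_each_loss_term_vanishes_at_its_optimum(self):
        # full post-spacing coverage -> no floor loss
        ev = light_loss(90.0, 100.0, 60.0, 45.0)
        assert ev.light_loss_current == 0.0
        # post-spacing coverage equal to the projection -> no overlap loss
        ev = light_loss(100.0, 75.0, 60.0, 45.0)
        assert ev.light_loss_before_spacing == pytest.approx(0.0)
        assert ev.light_loss == pytest.approx(25.0)

    def test_direct_evaluation_example(self):
        ev = light_loss(98.0, 80.0, 60.0, 45.0)
        assert ev.light_loss_before_spacing == pytest.approx(6.5)
        assert ev.light_loss_current == pytest.approx(20.0)
        assert ev.light_loss == pytest.approx(13.5)
        assert ev.verdict == "too early"

    def test_late_spacing_example(self):
        ev = light_loss(99.0, 95.0, 92.0, 60.0)
        assert ev.light_loss == pytest.approx(5.0 - 30.43, abs=0.01)
        assert ev.verdict == "too late"

    def test_density_increase_rejected(self):
        with pytest.raises(IndicatorError):
            light_loss(90.0, 80.0, 45.0, 60.0)

    def test_coverage_range_enforced(self):
        with pytest.raises(IndicatorError):
            light_loss(101.0, 80.0, 60.0, 45.0)

    @settings(deadline=None, max_examples=100)
    @given(
        cov_prev=st.floats(0.0, 100.0),
        cov_curr=st.floats(0.0, 100.0),
        d_prev=st.floats(20.0, 92.0),
        ratio=st.floats(0.3, 0.95),
    )
    def test_decomposition_identity_and_enumeration(self, cov_prev, cov_curr, d_prev, ratio):
        d_curr = d_prev * ratio
        ev = light_loss(cov_prev, cov_curr, d_prev, d_curr)
        # the indicator is exactly floor loss minus overlap loss
        assert ev.light_loss == ev.light_loss_current - ev.light_loss_before_spacing
        # independent arithmetic enumeration
        expected = (100.0 - cov_curr) - (cov_curr - cov_prev * d_curr / d_prev)
        assert ev.light_loss == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_pre_spacing_overlap(self):
        """More hidden overlap released at spacing pushes light loss down."""
        base = light_loss(95.0, 80.0, 60.0, 45.0).light_loss
        more_overlap = light_loss(95.0, 88.0, 60.0, 45.0).light_loss
        assert more_overlap < base


class TestEvaluateSchedule:
    def test_no_transitions_gives_empty_list(self):
        sched = DensitySchedule.from_pairs([(0, 60.0)])
        traits = [record(d, 80.0, 10.0, 60.0) for d in range(5)]
        assert evaluate_schedule(traits, sched) == []

    def test_one_evaluation_per_transition(self):
        sched = DensitySchedule.from_pairs([(0, 92.0), (3, 60.0), (6, 45.0)])
        traits = [record(d, 90.0, 10.0, sched.density_on(d)) for d in range(9)]
        evals = evaluate_schedule(traits, sched)
        assert [e.event_time for e in evals] == [3, 6]
        assert evals[0].density_prev == 92.0
        assert evals[0].density_curr == 60.0

    def test_missing_flanking_frames_skipped_with_warning(self, caplog):
        sched = DensitySchedule.from_pairs([(0, 92.0), (3, 60.0)])
        traits = [record(d, 90.0, 10.0, 60.0) for d in (4, 5)]  # nothing before day 3
        with caplog.at_level(logging.WARNING):
            evals = evaluate_schedule(traits, sched)
        assert evals == []
        assert any("skipped" in r.message for r in caplog.records)


class TestRecommendSpacing:
    def test_below_threshold_holds(self):
        assert recommend_spacing(97.9, 60.0) is None

    def test_at_threshold_steps_down_ladder(self):
        assert recommend_spacing(98.3, 60.0) == 45.0

    def test_ladder_exhausted_holds(self):
        assert recommend_spacing(99.0, 15.0) is None

    def test_threshold_domain(self):
        with pytest.raises(IndicatorError):
            recommend_spacing(50.0, 60.0, threshold_pct=0.0)


class TestWeightModel:
    def test_known_quadratic_recovered(self):
        x = np.linspace(100, 10000, 25)
        w = 12.0 + 0.03 * x + 1.5e-6 * x**2
        m = fit_weight_model(x, w)
        assert m.c0 == pytest.approx(12.0, abs=1e-6)
        assert m.c1 == pytest.approx(0.03, abs=1e-9)
        assert m.c2 == pytest.approx(1.5e-6, abs=1e-12)
        assert m.mae_g == pytest.approx(0.0, abs=1e-8)

    def test_threshold_is_increasing_crossing_of_target(self):
        x = np.linspace(100, 10000, 25)
        w = 12.0 + 0.03 * x + 1.5e-6 * x**2
        m = fit_weight_model(x, w, target_weight_g=250.0)
        assert m.predict(m.threshold_cm3) == pytest.approx(250.0, abs=1e-6)
        assert m.predict(m.threshold_cm3 * 1.01) > 250.0

    def test_constant_weights_degenerate_fit(self):
        x = np.array([100.0, 200.0, 300.0, 400.0])
        m = fit_weight_model(x, np.full(4, 150.0))
        assert m.c0 == pytest.approx(150.0, abs=1e-8)
        assert abs(m.c1) < 1e-10 and abs(m.c2) < 1e-12
        assert m.threshold_cm3 == np.inf  # 150 g never reaches 250 g

    def test_fewer_than_three_distinct_x_rejected(self):
        with pytest.raises(IndicatorError):
            fit_weight_model([1.0, 1.0, 2.0], [10.0, 11.0, 12.0])

    def test_noisy_threshold_recovery_within_ten_percent(self):
        from canopyspace.studies import threshold_recovery_study

        result = threshold_recovery_study(n_trials=20, seed=3)
        assert result["median_rel_error"] < 0.10


class TestHarvestDate:
    def test_series_below_threshold_reports_absence(self):
        traits = [record(d, 50.0, 5.0, 30.0) for d in range(5)]
        assert harvest_date(traits, WeightModel(0, 0, 0, threshold_cm3=1e5)) is None

    def test_monotone_series_crossing_day(self):
        traits = [record(d, 60.0 + 5 * d, 10.0 + d, 15.0) for d in range(10)]
        model = WeightModel(0, 0, 0, threshold_cm3=traits[4].indicator_cm3)
        assert harvest_date(traits, model) == 4

    def test_default_threshold_is_published_value(self):
        assert WeightModel(0, 0, 0).threshold_cm3 == DEFAULT_HARVEST_THRESHOLD_CM3

    def test_empty_series_rejected(self):
        with pytest.raises(IndicatorError):
            harvest_date([], WeightModel(0, 0, 0))

    def test_pipeline_harvest_within_two_days_of_truth(self):
        from canopyspace.studies import harvest_study

        result = harvest_study(seed=21)
        assert result["harvest_day_true"] is not None
        assert abs(result["harvest_day_pipeline"] - result["harvest_day_true"]) <= 2

    def test_indicator_monotone_under_monotone_growth(self, noiseless_batch):
        """Between spacings the harvest indicator is non-decreasing."""
        from canopyspace.studies import run_batch

        report = run_batch(noiseless_batch, seed=2)
        event_days = {d for d, _, _ in noiseless_batch.schedule_realized.transitions}
        series = sorted(report.traits, key=lambda r: r.timestamp)
        for a, b in zip(series, series[1:]):
            if b.timestamp not in event_days:
                assert b.indicator_cm3 >= a.indicator_cm3 - 1e-6


class TestIndicatorVsVolumeCorrelation:
    def test_indicator_beats_volume_under_overlap(self):
        """Area x height correlates with true weight better than volume when
        leaves overlap: occlusion suppresses measured volume twice (hidden
        area and hidden height), while the maximum height stays visible."""
        from canopyspace.studies import run_batch
        from canopyspace.synth import SimConfig, simulate_batch

        # a batch never spaced: overlap grows unchecked at 92 heads/m^2
        cfg = SimConfig(seed=7, density_schedule=DensitySchedule.from_pairs([(0, 92.0)]))
        batch = simulate_batch(cfg)
        report = run_batch(batch, seed=8)
        days = batch.days
        truth = np.array([batch.gt_mean_weight_g(d) for d in days])
        ind = np.array([report.traits[batch.frame_index(d)].indicator_cm3 for d in days])
        vol = np.array(
            [report.traits[batch.frame_index(d)].volume_per_plant_cm3 for d in days]
        )
        sel = slice(10, None)  # the crowded phase
        r_ind = np.corrcoef(ind[sel], truth[sel])[0, 1]
        r_vol = np.corrcoef(vol[sel], truth[sel])[0, 1]
        assert r_ind > r_vol
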