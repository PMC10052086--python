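"""Synthetic scene generator: cap geometry, rendering, growth and spacing."""

import numpy as np
import pytest

from canopyspace.schedule import DensitySchedule, ScheduleError
from canopyspace.synth import (
    AllometryParams,
    GrowthParams,
    PlantGT,
    SimConfig,
    SyntheticSceneError,
    allometric_weight,
    cap_height_field,
    cap_volume_mm3,
    grid_layout,
    render_frame,
    simulate_batch,
    union_coverage_pct,
)


def tiny_cfg(**kw):
    defaults = dict(seed=5, days=2, image_size=(96, 96), depth_noise_sd_mm=0.0,
                    rgb_noise_sd=0.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestCapGeometry:
    def test_peak_equals_cap_height(self):
        field = cap_height_field((50.0, 50.0), (101, 101), 1.0)
        assert field[50, 50] == pytest.approx(50.0)

    def test_zero_outside_base_disc(self):
        field = cap_height_field((50.0, 50.0), (101, 101), 1.0)
        assert field[50, 0] == 0.0  # 50 mm from the centre, on the rim

    def test_hemisphere_volume_oracle(self):
        # fine-grid integral of the field vs (2/3) pi a^3
        field = cap_height_field((50.0, 50.0), (512, 512), 0.25)
        integral = field.sum() * 0.25**2
        assert integral == pytest.approx(2 / 3 * np.pi * 50**3, rel=0.01)

    def test_field_integral_matches_closed_form_for_shallow_cap(self):
        field = cap_height_field((60.0, 25.0), (512, 512), 0.25)
        assert field.sum() * 0.25**2 == pytest.approx(cap_volume_mm3(60, 25), rel=0.01)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(SyntheticSceneError):
            cap_height_field((0.0, 10.0), (32, 32), 1.0)

    def test_taller_than_wide_heads_rejected(self):
        with pytest.raises(SyntheticSceneError):
            cap_volume_mm3(30.0, 50.0)


class TestRenderFrame:
    def test_zero_plants_is_all_background_at_plane_depth(self):
        cfg = tiny_cfg(plane_tilt_deg=0.0)
        frame, mask, _ = render_frame([], cfg.ground_plane(), cfg, rng=None)
        assert not mask.data.any()
        np.testing.assert_allclose(frame.depth_mm, cfg.camera_height_mm, atol=0.1)

    def test_single_plant_mask_matches_disc_area(self):
        cfg = tiny_cfg(plane_tilt_deg=0.0)
        plant = PlantGT(id=0, centre_mm=(0.0, 0.0), radius_mm=40.0, height_mm=30.0)
        _, mask, _ = render_frame([plant], cfg.ground_plane(), cfg, rng=None)
        expected_px = np.pi * 40.0**2 / cfg.gsd_mm**2
        perimeter_px = 2 * np.pi * 40.0 / cfg.gsd_mm
        assert abs(mask.lettuce_pixels() - expected_px) < perimeter_px

    def test_overlap_strictly_reduces_union(self):
        cfg = tiny_cfg(plane_tilt_deg=0.0)
        p1 = PlantGT(id=0, centre_mm=(-30.0, 0.0), radius_mm=40.0, height_mm=30.0)
        p2 = PlantGT(id=1, centre_mm=(30.0, 0.0), radius_mm=40.0, height_mm=30.0)
        _, both, _ = render_frame([p1, p2], cfg.ground_plane(), cfg, rng=None)
        _, only1, _ = render_frame([p1], cfg.ground_plane(), cfg, rng=None)
        _, only2, _ = render_frame([p2], cfg.ground_plane(), cfg, rng=None)
        assert both.lettuce_pixels() < only1.lettuce_pixels() + only2.lettuce_pixels()

    def test_depth_peak_consistent_with_plant_height(self):
        cfg = tiny_cfg(plane_tilt_deg=0.0)
        plant = PlantGT(id=0, centre_mm=(0.0, 0.0), radius_mm=40.0, height_mm=35.0)
        frame, mask, _ = render_frame([plant], cfg.ground_plane(), cfg, rng=None)
        min_depth = frame.depth_mm[mask.data].min()
        assert cfg.camera_height_mm - min_depth == pytest.approx(35.0, abs=0.2)

    def test_centre_outside_area_rejected(self):
        cfg = tiny_cfg()
        plant = PlantGT(id=0, centre_mm=(5000.0, 0.0), radius_mm=40.0, height_mm=30.0)
        with pytest.raises(SyntheticSceneError):
            render_frame([plant], cfg.ground_plane(), cfg, rng=None)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_batch(self):
        cfg = SimConfig(seed=9, days=3, image_size=(96, 96))
        b1, b2 = simulate_batch(cfg), simulate_batch(cfg)
        for f1, f2, m1, m2 in zip(b1.frames, b2.frames, b1.masks, b2.masks):
            np.testing.assert_array_equal(f1.depth_mm, f2.depth_mm)
            np.testing.assert_array_equal(f1.rgb, f2.rgb)
            np.testing.assert_array_equal(m1.data, m2.data)
        assert b1.schedule_realized.events == b2.schedule_realized.events

    def test_different_seed_changes_frames(self):
        b1 = simulate_batch(SimConfig(seed=1, days=1, image_size=(96, 96)))
        b2 = simulate_batch(SimConfig(seed=2, days=1, image_size=(96, 96)))
        assert (b1.frames[0].rgb != b2.frames[0].rgb).any()


class TestGrowthAndSpacing:
    def test_logistic_limit_reaches_asymptote(self):
        g = GrowthParams()
        assert g.radius(10000.0) == pytest.approx(g.radius_max_mm, rel=1e-6)
        assert g.height(10000.0) == pytest.approx(g.height_max_mm, rel=1e-6)

    def test_zero_growth_rate_keeps_traits_constant(self):
        g = GrowthParams(radius_rate=0.0, height_rate=0.0)
        assert g.radius(0.0) == g.radius(40.0)
        assert g.height(0.0) == g.height(40.0)

    def test_spacing_reduces_count_and_preserves_radii(self, noiseless_batch):
        sched = noiseless_batch.schedule_realized
        day = sched.events[1][0]
        before = noiseless_batch.plants_per_frame[noiseless_batch.frame_index(day - 1)]
        after = noiseless_batch.plants_per_frame[noiseless_batch.frame_index(day)]
        assert len(after) < len(before)
        # kept plants carry their per-plant trait scales across the event
        scales_before = {p.id: p.scale_radius for p in before}
        assert all(p.scale_radius == scales_before[p.id] for p in after)

    def test_radii_nondecreasing_for_every_plant(self, noiseless_batch):
        by_id: dict[int, list[float]] = {}
        for plants in noiseless_batch.plants_per_frame:
            for p in plants:
                by_id.setdefault(p.id, []).append(p.radius_mm)
        for radii in by_id.values():
            assert all(b >= a for a, b in zip(radii, radii[1:]))

    def test_gt_coverage_monotone_between_events_and_drops_at_events(self, noiseless_batch):
        days = noiseless_batch.days
        cov = [noiseless_batch.gt_coverage_pct(d) for d in days]
        event_days = {d for d, _, _ in noiseless_batch.schedule_realized.transitions}
        for d0, d1, c0, c1 in zip(days, days[1:], cov, cov[1:]):
            if d1 in event_days:
                assert c1 < c0
            else:
                assert c1 >= c0

    def test_schedule_densities_strictly_decreasing(self, noiseless_batch):
        dens = [x for _, x in noiseless_batch.schedule_realized.events]
        assert all(b < a for a, b in zip(dens, dens[1:]))

    def test_explicit_increasing_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            DensitySchedule.from_pairs([(0, 45.0), (3, 60.0)])

    def test_explicit_schedule_followed(self):
        sched = DensitySchedule.from_pairs([(0, 92.0), (1, 60.0)])
        cfg = tiny_cfg(density_schedule=sched)
        batch = simulate_batch(cfg)
        assert [d for d, _ in batch.schedule_nominal.events] == [0, 1]
        assert len(batch.plants_per_frame[1]) < len(batch.plants_per_frame[0])


class TestConservation:
    def test_isolated_plant_area_matches_mask(self):
        """Per-plant ground-truth area equals mask area within a pixel perimeter."""
        cfg = tiny_cfg(plane_tilt_deg=2.0)
        plant = PlantGT(id=0, centre_mm=(10.0, -20.0), radius_mm=45.0, height_mm=40.0)
        _, mask, _ = render_frame([plant], cfg.ground_plane(), cfg, rng=None)
        mask_area_cm2 = mask.lettuce_pixels() * cfg.gsd_mm**2 / 100.0
        perimeter_cm2 = 2 * np.pi * 45.0 / cfg.gsd_mm * cfg.gsd_mm**2 / 100.0
        assert abs(mask_area_cm2 - plant.projected_area_cm2) < perimeter_cm2


class TestAllometricWeight:
    def test_zero_area_gives_intercept(self):
        params = AllometryParams(noise_sd_g=0.0)
        assert allometric_weight(0.0, 10.0, params) == pytest.approx(params.c0)

    def test_noiseless_polynomial_value(self):
        params = AllometryParams(c0=10.0, c1=0.02, c2=2e-6, noise_sd_g=0.0)
        x = 500.0 * 12.0
        assert allometric_weight(500.0, 12.0, params) == pytest.approx(
            10.0 + 0.02 * x + 2e-6 * x * x
        )

    def test_weight_never_negative(self, rng):
        params = AllometryParams(c0=1.0, c1=0.0, c2=0.0, noise_sd_g=50.0)
        w = np.array([allometric_weight(0.0, 0.0, params, rng) for _ in range(200)])
        assert (w >= 0).all()

    def test_negative_area_rejected(self):
        with pytest.raises(SyntheticSceneError):
            allometric_weight(-1.0, 5.0, AllometryParams())

    def test_polynomial_interpolation_recovery(self):
        """Fitting noiseless samples recovers the generator coefficients."""
        from canopyspace.studies import weight_recovery_study

        result = weight_recovery_study()
        assert result["max_coef_error"] < 1e-6
        assert result["mae_g"] < 1e-6


class TestLayout:
    def test_grid_count_and_extent(self):
        centres = grid_layout(12, (512.0, 512.0))
        assert centres.shape == (12, 2)
        assert np.abs(centres).max() < 256.0

    def test_union_coverage_of_disjoint_discs(self):
        centres = np.array([[-100.0, 0.0], [100.0, 0.0]])
        cov = union_coverage_pct(centres, np.array([40.0, 40.0]), (128, 128), 4.0)
        expected = 100 * 2 * np.pi * 40**2 / (512.0 * 512.0)
        assert cov == pytest.approx(expected, rel=0.05)
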