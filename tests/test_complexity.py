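"""Aperture geometry, MU-weighted aggregation and dynamic indices."""

import numpy as np
import pytest

from helpers import (
    make_beam,
    make_cp,
    make_plan,
    oracle_area_perimeter,
    random_control_point,
    segment_beam,
    translate_plan_x,
)

from vmatqa import (
    UndefinedMetricError,
    aperture_area,
    aperture_irregularity,
    aperture_perimeter,
    beam_aggregates,
    clipped_openings,
    compute_features,
    dynamics_variations,
    leaf_travel_per_al,
    plan_aggregates,
)
from vmatqa.complexity import FEATURE_COLUMNS, beam_table, control_point_table
from vmatqa.synthetic import PlanGeneratorConfig, generate_plan

# Millennium120 pair 30 spans y in [0, 5]; pair 0 spans [-200, -190] (10 mm).
MID, WIDE = 30, 0


class TestClippedOpenings:
    def test_single_open_pair_is_one_rectangle(self, millennium):
        shape = clipped_openings(make_cp(millennium, {MID: (-5.0, 5.0)}), millennium)
        assert shape.n_open == 1
        np.testing.assert_allclose(
            [shape.x_lo[0], shape.x_hi[0], shape.y_lo[0], shape.y_hi[0]],
            [-5.0, 5.0, 0.0, 5.0],
        )

    def test_jaws_clip_the_x_extent(self, millennium):
        cp = make_cp(millennium, {MID: (-5.0, 5.0)}, jaws=(-1.0, 3.0, -210, 210))
        shape = clipped_openings(cp, millennium)
        assert shape.x_hi[0] - shape.x_lo[0] == pytest.approx(4.0)

    def test_sub_min_gap_pair_is_dropped(self, millennium):
        cp = make_cp(millennium, {MID: (0.0, 0.4)})
        assert clipped_openings(cp, millennium).n_open == 0

    def test_y_jaws_exclude_out_of_field_pairs(self, millennium):
        cp = make_cp(millennium, {MID: (-5, 5), 50: (-5, 5)}, jaws=(-100, 100, -1, 8))
        shape = clipped_openings(cp, millennium)
        assert list(shape.pair_index) == [MID]


class TestAreaPerimeterIrregularity:
    def test_single_rectangle(self, millennium):
        shape = clipped_openings(make_cp(millennium, {MID: (0.0, 10.0)}), millennium)
        assert aperture_area(shape) == pytest.approx(50.0)  # 10 x 5 mm
        assert aperture_perimeter(shape) == pytest.approx(30.0)

    def test_stacked_identical_intervals_merge(self, millennium):
        cp = make_cp(millennium, {30: (0.0, 10.0), 31: (0.0, 10.0)})
        shape = clipped_openings(cp, millennium)
        assert aperture_area(shape) == pytest.approx(100.0)
        assert aperture_perimeter(shape) == pytest.approx(40.0)

    def test_island_openings_bound_separate_polygons(self, millennium):
        cp = make_cp(millennium, {30: (0.0, 10.0), 32: (0.0, 10.0)})
        shape = clipped_openings(cp, millennium)
        assert aperture_perimeter(shape) == pytest.approx(60.0)

    def test_square_irregularity_is_four_over_pi(self, millennium):
        shape = clipped_openings(make_cp(millennium, {WIDE: (-5.0, 5.0)}), millennium)
        assert aperture_irregularity(shape) == pytest.approx(4.0 / np.pi)

    def test_empty_shape(self, millennium):
        shape = clipped_openings(make_cp(millennium, {}), millennium)
        assert aperture_area(shape) == 0.0
        assert aperture_perimeter(shape) == 0.0
        with pytest.raises(UndefinedMetricError):
            aperture_irregularity(shape)

    def test_matches_rectilinear_oracle(self, millennium, hd120):
        rng = np.random.default_rng(7)
        for machine in (millennium, hd120):
            for _ in range(200):
                shape = clipped_openings(random_control_point(machine, rng), machine)
                area, perim = oracle_area_perimeter(shape)
                assert aperture_area(shape) == pytest.approx(area, abs=1e-9)
                assert aperture_perimeter(shape) == pytest.approx(perim, abs=1e-9)

    def test_isoperimetric_lower_bound(self, millennium):
        rng = np.random.default_rng(11)
        for _ in range(200):
            shape = clipped_openings(random_control_point(millennium, rng), millennium)
            if shape.n_open:
                assert aperture_irregularity(shape) >= 4.0 / np.pi - 1e-12

    def test_shrinking_jaws_never_increases_area(self, millennium):
        rng = np.random.default_rng(13)
        for _ in range(100):
            cp = random_control_point(millennium, rng)
            wide = aperture_area(clipped_openings(cp, millennium))
            cp2 = make_cp(millennium, {}, jaws=(cp.jaw_x1 / 2, cp.jaw_x2 / 2,
                                                cp.jaw_y1 / 2, cp.jaw_y2 / 2))
            cp2.bank_a, cp2.bank_b = cp.bank_a, cp.bank_b
            narrow = aperture_area(clipped_openings(cp2, millennium))
            assert narrow <= wide + 1e-9


class TestAggregation:
    def _beam_with_areas(self, machine, cmw_steps, widths):
        # one open mid pair whose gap sets the per-control-point area
        cps = []
        cmw = np.concatenate([[0.0], np.cumsum(cmw_steps)])
        cmw /= cmw[-1]
        for k, w in enumerate(widths):
            cps.append(make_cp(machine, {MID: (0.0, w)}, gantry=2.0 * k,
                               cmw=float(cmw[k])))
        return make_beam(machine, cps, mu=100.0)

    def test_equal_weights_average_areas(self, millennium):
        beam = self._beam_with_areas(millennium, [1.0, 1.0], [10.0, 20.0, 5.0])
        ba, _ = beam_aggregates(beam, millennium)
        assert ba == pytest.approx(75.0)  # mean of 50 and 100; last cp unweighted

    def test_unequal_mu_weights(self, millennium):
        beam = self._beam_with_areas(millennium, [1.0, 3.0], [10.0, 20.0, 5.0])
        ba, _ = beam_aggregates(beam, millennium)
        assert ba == pytest.approx(87.5)

    def test_constant_aperture_identity(self, millennium):
        beam = self._beam_with_areas(millennium, [1.0, 1.0, 1.0], [10.0] * 4)
        shape = clipped_openings(beam.control_points[0], millennium)
        ba, bi = beam_aggregates(beam, millennium)
        assert ba == pytest.approx(aperture_area(shape))
        assert bi == pytest.approx(aperture_irregularity(shape))

    def test_all_closed_beam_is_undefined(self, millennium):
        cps = [make_cp(millennium, {}, cmw=0.0),
               make_cp(millennium, {}, gantry=2.0, cmw=1.0)]
        with pytest.raises(UndefinedMetricError):
            beam_aggregates(make_beam(millennium, cps), millennium)

    def test_plan_weighting_and_bounds(self, millennium):
        b1 = self._beam_with_areas(millennium, [1.0], [20.0, 20.0])  # BA 100
        b1.beam_mu = 100.0
        b2 = self._beam_with_areas(millennium, [1.0], [40.0, 40.0])  # BA 200
        b2.beam_mu = 300.0
        pa, pi = plan_aggregates(make_plan(millennium, [b1, b2]))
        assert pa == pytest.approx(175.0)
        ba1, bi1 = beam_aggregates(b1, millennium)
        ba2, bi2 = beam_aggregates(b2, millennium)
        assert min(ba1, ba2) <= pa <= max(ba1, ba2)
        assert min(bi1, bi2) <= pi <= max(bi1, bi2)

    def test_single_beam_identity(self, millennium):
        b = self._beam_with_areas(millennium, [2.0, 1.0], [10.0, 25.0, 5.0])
        assert plan_aggregates(make_plan(millennium, [b])) == pytest.approx(
            beam_aggregates(b, millennium)
        )


class TestLeafTravel:
    def _travel_beam(self, machine):
        # pair MID's B leaf sweeps 0 -> 10 -> 20 mm over a 60-degree arc
        cps = [
            make_cp(machine, {MID: (-30.0, 0.0)}, gantry=0.0, cmw=0.0),
            make_cp(machine, {MID: (-30.0, 10.0)}, gantry=30.0, cmw=0.5),
            make_cp(machine, {MID: (-30.0, 20.0)}, gantry=60.0, cmw=1.0),
        ]
        return make_beam(machine, cps)

    def test_per_leaf_mean_over_open_pairs(self, millennium):
        plan = make_plan(millennium, [self._travel_beam(millennium)])
        # both leaves of the open pair participate: (20 + 0) / 2 over 60 deg
        assert leaf_travel_per_al(plan) == pytest.approx(10.0 / 60.0)

    def test_all_leaves_convention(self, millennium):
        plan = make_plan(millennium, [self._travel_beam(millennium)])
        assert leaf_travel_per_al(plan, participation="all") == pytest.approx(
            20.0 / 120.0 / 60.0
        )

    def test_no_motion_is_zero_and_linearity(self, millennium):
        frozen = make_plan(
            millennium,
            [make_beam(millennium, [
                make_cp(millennium, {MID: (-5, 5)}, gantry=0.0, cmw=0.0),
                make_cp(millennium, {MID: (-5, 5)}, gantry=60.0, cmw=1.0),
            ])],
        )
        assert leaf_travel_per_al(frozen) == 0.0
        plan = make_plan(millennium, [self._travel_beam(millennium)])
        doubled_cps = [
            make_cp(millennium, {MID: (-30.0, 2 * w)}, gantry=g, cmw=c)
            for w, g, c in [(0.0, 0.0, 0.0), (10.0, 30.0, 0.5), (20.0, 60.0, 1.0)]
        ]
        doubled = make_plan(millennium, [make_beam(millennium, doubled_cps)])
        assert leaf_travel_per_al(doubled) == pytest.approx(2 * leaf_travel_per_al(plan))

    def test_static_gantry_beam_is_an_error(self, millennium):
        cps = [make_cp(millennium, {MID: (-5, 5)}, gantry=10.0, cmw=0.0),
               make_cp(millennium, {MID: (-5, 5)}, gantry=10.0, cmw=1.0)]
        plan = make_plan(millennium, [make_beam(millennium, cps)])
        with pytest.raises(UndefinedMetricError):
            leaf_travel_per_al(plan)


class TestDynamicsVariations:
    def test_hand_computed_dose_rate_variation(self, millennium):
        # segments engineered to run at 600, 300, 600 MU/min over 120 deg
        dmu = [100.0, 300.0 * (40.0 / 4.8) / 60.0, 100.0]
        beam = segment_beam(millennium, dmu, [40.0, 40.0, 40.0])
        plan = make_plan(millennium, [beam])
        dr_var, gs_var = dynamics_variations(plan)
        assert dr_var == pytest.approx(600.0 / 120.0)

    def test_constant_dose_rate_gives_zero_variation(self, millennium):
        # every segment MU-limited at max dose rate
        beam = segment_beam(millennium, [50.0, 50.0, 50.0], [2.0, 2.0, 2.0])
        dr_var, gs_var = dynamics_variations(make_plan(millennium, [beam]))
        assert dr_var == 0.0

    def test_constant_gantry_speed_gives_zero_variation(self, millennium):
        # every segment gantry-limited at max speed
        beam = segment_beam(millennium, [1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        dr_var, gs_var = dynamics_variations(make_plan(millennium, [beam]))
        assert gs_var == 0.0


class TestFeatureAssembly:
    def test_generated_plan_features_are_finite_and_sane(self):
        plan = generate_plan(PlanGeneratorConfig.for_site("PROSTATE", seed=5))
        f = compute_features(plan)
        values = list(f.as_dict().values())
        assert np.all(np.isfinite(values))
        assert f.pa > 0 and f.pi >= 1.0
        assert f.total_mu == pytest.approx(plan.total_mu)

    def test_translation_invariance(self):
        plan = generate_plan(PlanGeneratorConfig.for_site("HN", seed=6))
        f0 = compute_features(plan).as_dict()
        f5 = compute_features(translate_plan_x(plan, 5.0)).as_dict()
        for k in FEATURE_COLUMNS:
            assert f5[k] == pytest.approx(f0[k], rel=1e-9)

    def test_beam_order_invariance(self):
        plan = generate_plan(PlanGeneratorConfig.for_site("HN", seed=8))
        f0 = compute_features(plan).as_dict()
        plan.beams = plan.beams[::-1]
        f1 = compute_features(plan).as_dict()
        for k in FEATURE_COLUMNS:
            assert f1[k] == pytest.approx(f0[k], rel=1e-12)

    def test_intermediate_tables_expose_per_cp_and_per_beam_rows(self):
        plan = generate_plan(
            PlanGeneratorConfig.for_site("PROSTATE", seed=5, n_control_points=11,
                                         gantry_span=20.0)
        )
        cp = control_point_table(plan)
        assert set(["AA_mm2", "AP_mm", "AI", "seg_MU"]) <= set(cp.columns)
        assert len(cp) == sum(len(b.control_points) for b in plan.beams)
        bt = beam_table(plan)
        assert set(["BA_mm2", "BI", "beam_MU", "arc_deg"]) <= set(bt.columns)
        assert len(bt) == len(plan.beams)
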