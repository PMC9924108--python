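"""Machine profiles, plan validation, arc length and segment dynamics."""

import numpy as np
import pytest

from helpers import make_beam, make_cp, make_plan, segment_beam

from vmatqa import MachineModel, arc_length, derive_segment_dynamics, validate_plan
from vmatqa.plan_model import gantry_steps
from vmatqa.synthetic import PlanGeneratorConfig, generate_plan


class TestMachineProfiles:
    @pytest.mark.parametrize(
        "profile,pattern,half_span",
        [
            ("HD120", (14, 5.0, 32, 2.5, 14, 5.0), 110.0),
            ("Millennium120", (10, 10.0, 40, 5.0, 10, 10.0), 200.0),
        ],
    )
    def test_builtin_profiles(self, profile, pattern, half_span):
        m = MachineModel.from_profile(profile)
        n1, w1, n2, w2, n3, w3 = pattern
        assert m.n_leaf_pairs == 60
        assert list(m.leaf_widths) == [w1] * n1 + [w2] * n2 + [w3] * n3
        b = m.leaf_boundaries
        assert np.all(np.diff(b) > 0)
        np.testing.assert_allclose(np.diff(b), m.leaf_widths)
        np.testing.assert_allclose([b[0], b[-1]], [-half_span, half_span])

    def test_energy_selects_max_dose_rate(self):
        assert MachineModel.from_profile("HD120", "6FFF").max_dose_rate == 1400.0
        assert MachineModel.from_profile("HD120", "10X").max_dose_rate == 600.0
        m = MachineModel.from_profile("HD120", "6FFF", max_dose_rate=500.0)
        assert m.max_dose_rate == 500.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            MachineModel.from_profile("Halcyon")
        with pytest.raises(ValueError):
            MachineModel(name="bad", leaf_widths=(5.0, -5.0))


class TestArcLength:
    def test_full_arc_through_zero(self, millennium):
        cps = [make_cp(millennium, {}, gantry=181.0, cmw=0.0),
               make_cp(millennium, {}, gantry=179.0, cmw=1.0)]
        assert arc_length(make_beam(millennium, cps, direction="CW")) == pytest.approx(358.0)

    def test_static_gantry_is_zero(self, millennium):
        cps = [make_cp(millennium, {}, gantry=90.0, cmw=0.0),
               make_cp(millennium, {}, gantry=90.0, cmw=1.0)]
        assert arc_length(make_beam(millennium, cps)) == 0.0

    def test_partial_arcs_report_their_own_span(self, millennium):
        beam = segment_beam(millennium, [1.0] * 89, [2.0] * 89, start_angle=181.0)
        assert arc_length(beam) == pytest.approx(178.0)

    def test_ccw_unwrap(self):
        steps = gantry_steps([1.0, 359.0, 357.0], "CCW")
        np.testing.assert_allclose(steps, [2.0, 2.0])


class TestSegmentDynamics:
    def test_mu_limited_segment(self, millennium):
        # 10 MU over 2 deg at 600 MU/min, 4.8 deg/s: MU is limiting (1 s)
        beam = segment_beam(millennium, [10.0], [2.0])
        (seg,) = derive_segment_dynamics(beam, millennium)
        assert seg.delta_t == pytest.approx(1.0)
        assert seg.dose_rate == pytest.approx(600.0)
        assert seg.gantry_speed == pytest.approx(2.0)

    def test_zero_mu_segment_runs_at_max_gantry_speed(self, millennium):
        cps = [make_cp(millennium, {30: (-10, 10)}, gantry=0.0, cmw=0.0),
               make_cp(millennium, {30: (-10, 10)}, gantry=2.0, cmw=0.0),
               make_cp(millennium, {30: (-10, 10)}, gantry=4.0, cmw=1.0)]
        segs = derive_segment_dynamics(make_beam(millennium, cps, mu=50.0), millennium)
        assert segs[0].dose_rate == 0.0
        assert segs[0].gantry_speed == pytest.approx(4.8)

    def test_machine_limits_and_one_active_constraint(self, millennium):
        plan = generate_plan(PlanGeneratorConfig.for_site("PROSTATE", seed=9))
        for beam in plan.beams:
            segs = derive_segment_dynamics(beam, plan.machine)
            for s in segs:
                assert s.dose_rate <= plan.machine.max_dose_rate * (1 + 1e-12)
                assert s.gantry_speed <= plan.machine.max_gantry_speed * (1 + 1e-12)
                if s.delta_mu > 0 or s.delta_theta > 0:
                    active = max(
                        s.dose_rate / plan.machine.max_dose_rate,
                        s.gantry_speed / plan.machine.max_gantry_speed,
                    )
                    assert active == pytest.approx(1.0)

    def test_segment_sums_match_beam_totals(self, millennium):
        plan = generate_plan(PlanGeneratorConfig.for_site("HN", seed=3))
        for beam in plan.beams:
            segs = derive_segment_dynamics(beam, plan.machine)
            assert sum(s.delta_mu for s in segs) == pytest.approx(beam.beam_mu)
            assert sum(s.delta_theta for s in segs) == pytest.approx(arc_length(beam))


class TestValidation:
    def test_generated_plans_are_valid(self):
        for site in ("IMRS", "HN", "MED_LUNG", "PROSTATE"):
            plan = generate_plan(PlanGeneratorConfig.for_site(site, seed=1))
            assert validate_plan(plan) == []

    def test_inverted_leaf_pair_is_one_violation(self, millennium):
        cps = [make_cp(millennium, {30: (-10, 10)}, cmw=0.0),
               make_cp(millennium, {30: (5, -5)}, gantry=2.0, cmw=1.0)]
        violations = validate_plan(make_plan(millennium, [make_beam(millennium, cps)]))
        assert len(violations) == 1
        assert "bank_B < bank_A" in violations[0]

    def test_incomplete_final_meterset_is_one_violation(self, millennium):
        cps = [make_cp(millennium, {30: (-10, 10)}, cmw=0.0),
               make_cp(millennium, {30: (-10, 10)}, gantry=2.0, cmw=0.98)]
        violations = validate_plan(make_plan(millennium, [make_beam(millennium, cps)]))
        assert len(violations) == 1
        assert "final cumulative meterset" in violations[0]

    def test_zero_mu_beam_is_rejected_not_averaged(self, millennium):
        plan = generate_plan(PlanGeneratorConfig.for_site("PROSTATE", seed=2))
        noop = make_beam(
            millennium,
            [make_cp(millennium, {30: (-10, 10)}, cmw=0.0),
             make_cp(millennium, {30: (-10, 10)}, gantry=2.0, cmw=1.0)],
            mu=0.0,
            beam_id="NOOP",
        )
        plan.beams.append(noop)
        assert any("NOOP" in v and "beam_mu" in v for v in validate_plan(plan))

    def test_leaf_count_mismatch_reported(self, millennium, hd120):
        plan = generate_plan(PlanGeneratorConfig.for_site("PROSTATE", seed=2))
        plan.machine = hd120  # same pair count; shrink banks instead
        cp = plan.beams[0].control_points[0]
        cp.bank_a = cp.bank_a[:40]
        assert any("leaf count mismatch" in v for v in validate_plan(plan))
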