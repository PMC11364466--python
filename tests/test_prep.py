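import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from camwm.prep import (
    FilterConfig,
    ScreenGeometry,
    assign_quadrant,
    cartesian_to_polar,
    compute_trial_errors,
    distance_to_boundary,
    filter_trials,
    polar_error,
    px_to_dva,
    summarize_bias,
    wrap_angle,
)


class TestPxToDva:
    def test_origin_maps_to_zero(self):
        geom = ScreenGeometry(1920, 1080, 57.6, 32.4, 60)
        assert px_to_dva(0, 0, geom) == (0.0, 0.0)

    def test_hand_arctangent(self):
        # 100 px at 0.03 cm/px viewed from 60 cm: atan(3/60) = 2.8624 deg
        geom = ScreenGeometry(1000, 1000, 30.0, 30.0, 60.0)
        x, y = px_to_dva(100, 0, geom)
        assert x == pytest.approx(2.8624, abs=1e-4)
        assert y == 0.0

    def test_farther_viewing_distance_shrinks_angle(self):
        near = ScreenGeometry(1000, 1000, 30.0, 30.0, 60.0)
        far = ScreenGeometry(1000, 1000, 30.0, 30.0, 120.0)
        assert abs(px_to_dva(250, 0, far)[0]) < abs(px_to_dva(250, 0, near)[0])

    def test_anisotropic_pitch_warns(self):
        with pytest.warns(UserWarning, match="anisotropic"):
            ScreenGeometry(1000, 1000, 30.0, 40.0, 60.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ScreenGeometry(1000, 1000, 30.0, 30.0, 0.0)


class TestPolarError:
    @pytest.mark.parametrize(
        "target,response,expected",
        [(30.0, 40.0, 10.0), (10.0, 355.0, -15.0), (350.0, 5.0, 15.0), (180.0, 180.0, 0.0)],
    )
    def test_signed_wrap(self, target, response, expected):
        err, _ = polar_error(target, 6.0, response, 6.0)
        assert err == pytest.approx(expected)

    def test_amplitude_ratio(self):
        _, ratio = polar_error(30.0, 6.0, 30.0, 3.0)
        assert ratio == pytest.approx(0.5)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            polar_error(30.0, 0.0, 30.0, 3.0)

    @given(st.floats(0, 360, allow_nan=False), st.integers(-3, 3))
    @settings(deadline=None, derandomize=True)
    def test_full_turn_invariance(self, angle, k):
        err, _ = polar_error(angle, 5.0, angle + 360.0 * k, 5.0)
        assert abs(err) < 1e-9

    @given(st.floats(-720, 720, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_wrap_range(self, x):
        w = float(wrap_angle(x))
        assert -180.0 < w <= 180.0


class TestAssignQuadrant:
    @pytest.mark.parametrize("angle,quadrant,proto", [
        (30.0, 1, 45.0), (100.0, 2, 135.0), (200.0, 3, 225.0), (350.0, 4, 315.0),
    ])
    def test_quadrants_and_prototypes(self, angle, quadrant, proto):
        q, p = assign_quadrant(angle)
        assert (q, p) == (quadrant, proto)

    @pytest.mark.parametrize("angle", [0.0, 90.0, 180.0, 270.0, 360.0, -90.0])
    def test_cardinal_axis_is_undefined(self, angle):
        with pytest.raises(ValueError):
            assign_quadrant(angle)

    def test_roundtrip_with_cartesian(self):
        ang, amp = cartesian_to_polar(1.0, 1.0)
        assert ang == pytest.approx(45.0)
        assert amp == pytest.approx(np.sqrt(2))

    def test_boundary_distance(self):
        assert distance_to_boundary(7.5) == pytest.approx(7.5)
        assert distance_to_boundary(85.0) == pytest.approx(5.0)
        assert distance_to_boundary(225.0) == pytest.approx(45.0)


class TestFilterTrials:
    def test_toy_table_counts_and_reasons(self, toy_trials):
        kept, report = filter_trials(compute_trial_errors(toy_trials))
        assert len(kept) == 9
        assert report.n_excluded == 3
        reasons = report.excluded_trials.set_index("trial")["exclusion_reasons"]
        assert "angular_error_gt_max" in reasons.loc[9]
        assert reasons.loc[10] == "amplitude_ratio_out_of_range"
        assert reasons.loc[11] == "response_outside_target_quadrant"

    def test_rules_are_not_mutually_subsuming(self, toy_trials):
        # a quadrant-only violation with small |error| and an angular violation
        # inside the quadrant must both exist in the toy construction
        _, report = filter_trials(compute_trial_errors(toy_trials))
        ex = report.excluded_trials
        quad_only = ex[ex["exclusion_reasons"] == "response_outside_target_quadrant"]
        ang = ex[ex["exclusion_reasons"].str.contains("angular_error_gt_max")]
        assert len(quad_only) == 1 and abs(quad_only["angular_error"].iloc[0]) <= 45
        assert len(ang) == 1 and (ang["quadrant"] == ang["response_quadrant"]).all()

    def test_boundary_ratio_is_kept(self):
        df = pd.DataFrame([dict(study_id="s", participant_id="p", trial=0,
                                target_angle_deg=30.0, target_amp_dva=6.0,
                                response_angle_deg=30.0, response_amp_dva=3.0)])
        kept, _ = filter_trials(compute_trial_errors(df))
        assert len(kept) == 1  # ratio exactly 0.5 -> closed interval keeps it

    def test_idempotent(self, toy_trials):
        kept, _ = filter_trials(compute_trial_errors(toy_trials))
        kept2, report2 = filter_trials(kept)
        assert report2.n_excluded == 0
        pd.testing.assert_frame_equal(
            kept.reset_index(drop=True), kept2.reset_index(drop=True))

    def test_counts_are_consistent_per_participant(self, small_cohort):
        trials, _ = small_cohort
        kept, report = filter_trials(trials)
        per = report.per_participant
        assert (per["n_input"] == per["n_excluded"]
                + kept.groupby(["study_id", "participant_id"]).size()
                .reindex(per.set_index(["study_id", "participant_id"]).index,
                         fill_value=0).to_numpy()).all()
        assert report.n_kept + report.n_excluded == report.n_input

    def test_all_compliant_reports_zero(self):
        df = pd.DataFrame([dict(study_id="s", participant_id="p", trial=i,
                                target_angle_deg=30.0 + i, target_amp_dva=6.0,
                                response_angle_deg=31.0 + i, response_amp_dva=6.0)
                           for i in range(5)])
        _, report = filter_trials(compute_trial_errors(df))
        assert report.mean_exclusion_pct == 0.0

    def test_empty_input_is_not_an_error(self):
        kept, report = filter_trials(pd.DataFrame(columns=[
            "study_id", "participant_id", "target_angle_deg", "target_amp_dva",
            "response_angle_deg", "response_amp_dva"]))
        assert len(kept) == 0 and report.n_input == 0

    def test_filterconfig_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(amplitude_ratio_range=(1.75, 0.5))


class TestSummarizeBias:
    def test_single_trial_equals_its_bias(self):
        df = pd.DataFrame([dict(study_id="s", participant_id="p", trial=0,
                                target_angle_deg=30.0, target_amp_dva=6.0,
                                response_angle_deg=35.0, response_amp_dva=6.0)])
        out = summarize_bias(compute_trial_errors(df))
        # target 30 -> prototype 45; +5 error points toward the prototype
        assert out["mean_bias_toward_prototype"].iloc[0] == pytest.approx(5.0)

    def test_bias_positive_and_grows_away_from_diagonal(self):
        # deterministic construction: responses exactly at lam*mu + (1-lam)*rho
        lam = 0.7
        rows = []
        for i, tgt in enumerate([10, 20, 30, 40, 50, 60, 70, 80]):
            _, rho = assign_quadrant(float(tgt))
            resp = lam * tgt + (1 - lam) * rho
            rows.append(dict(study_id="s", participant_id="p", trial=i,
                             target_angle_deg=float(tgt), target_amp_dva=6.0,
                             response_angle_deg=resp, response_amp_dva=6.0))
        out = summarize_bias(compute_trial_errors(pd.DataFrame(rows)))
        assert (out["mean_bias_toward_prototype"] >= 0).all()
        by_dist = out.assign(dist=np.abs(out["target_angle_deg"] - 45.0)).sort_values("dist")
        assert by_dist["mean_bias_toward_prototype"].is_monotonic_increasing

    def test_lambda_one_cohort_is_unbiased(self, quiet):
        from camwm.synth import CohortConfig, generate_behavior
        cfg = CohortConfig(n_studies=1, participants_per_study=(5,),
                           trials_per_participant=400, lambda_pop=(12.0, 0.0),
                           outlier_rate=0.0, nu_true=50.0, seed=5)
        trials, _ = generate_behavior(cfg)
        out = summarize_bias(compute_trial_errors(trials))
        overall = (out["mean_bias_toward_prototype"] * out["n_trials"]).sum() / out["n_trials"].sum()
        assert abs(overall) < 0.5
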