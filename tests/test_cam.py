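import numpy as np
import pandas as pd
import pytest
from scipy import stats

from camwm.cam import (
    CAMConfig,
    build_cam_model,
    derive_measures,
    fit_cam,
    lambda_from_sigmas,
    predictive_checks,
)
from camwm.prep import compute_trial_errors, wrap_angle
from camwm.sampling import EnsemblePosterior, convergence_report
from camwm.synth import CohortConfig, generate_behavior

QUICK = CAMConfig(chains=2, warmup=800, draws=800, thin=4, seed=7)


class TestLambdaIdentities:
    def test_identity_and_variance_identity_random_points(self):
        rng = np.random.default_rng(99)
        sm = rng.uniform(0.5, 20.0, 100)
        sp = rng.uniform(0.5, 40.0, 100)
        lam = lambda_from_sigmas(sm, sp)
        assert np.abs(lam - sp**2 / (sp**2 + sm**2)).max() < 1e-10
        # composed-response variance collapses: l^2 sm^2 + (1-l)^2 sp^2 = l sm^2
        lhs = lam**2 * sm**2 + (1 - lam) ** 2 * sp**2
        assert np.abs(lhs - lam * sm**2).max() < 1e-10

    def test_lambda_monotone_decreasing_in_sigma_m(self):
        sm = np.linspace(0.5, 30.0, 200)
        lam = lambda_from_sigmas(sm, 10.0)
        assert np.all(np.diff(lam) < 0)

    def test_equal_sigmas_give_half(self):
        assert lambda_from_sigmas(6.0, 6.0) == pytest.approx(0.5)


class TestModelBuild:
    def test_two_studies_rejected(self, small_cohort):
        trials, _ = small_cohort
        with pytest.raises(ValueError):
            build_cam_model(trials, QUICK)

    def test_few_trials_flagged_but_built(self, small_cohort, quiet):
        trials, _ = small_cohort
        sub = trials[trials["study_id"] == "study-01"]
        starved = pd.concat([
            sub[sub["participant_id"] != sub["participant_id"].iloc[0]],
            sub[sub["participant_id"] == sub["participant_id"].iloc[0]].head(2),
        ])
        with pytest.warns(UserWarning, match="< 3 kept trials"):
            model = build_cam_model(starved, QUICK)
        assert len(model.flags["few_trials"]) == 1

    def test_single_target_angle_flagged(self, quiet):
        df = pd.DataFrame([dict(study_id="s", participant_id="p", trial=i,
                                target_angle_deg=30.0, target_amp_dva=6.0,
                                response_angle_deg=30.0 + i, response_amp_dva=6.0)
                           for i in range(10)])
        with pytest.warns(UserWarning, match="single target angle"):
            model = build_cam_model(compute_trial_errors(df), QUICK)
        assert model.flags["single_target_angle"] == ["p"]


class TestFitRecovery:
    @pytest.fixture(scope="class")
    @classmethod
    def oracle_fit(cls, quiet_class):
        """Single participant, 4000 trials: OLS oracle vs posterior."""
        lam, sm = 0.7, 6.0
        cfg = CohortConfig(n_studies=1, participants_per_study=(1,),
                           trials_per_participant=4000,
                           lambda_pop=(np.log(lam / (1 - lam)), 0.0),
                           sigma_m_pop=(np.log(sm), 0.0),
                           nu_true=1000.0, outlier_rate=0.0, seed=7)
        trials, _ = generate_behavior(cfg)
        ann = compute_trial_errors(trials)
        post = fit_cam(ann, QUICK)
        y = np.asarray(wrap_angle(ann["response_angle_deg"] - ann["target_angle_deg"]))
        d = np.asarray(wrap_angle(ann["prototype_angle"] - ann["target_angle_deg"]))
        return post, y, d

    def test_posterior_matches_ols_oracle(self, oracle_fit):
        post, y, d = oracle_fit
        slope = (d @ y) / (d @ d)
        resid = y - slope * d
        se = resid.std(ddof=1) / np.sqrt(d @ d)
        pid = post.attrs["participant_ids"][0]
        assert 1 - post.mean(f"lambda[{pid}]") == pytest.approx(slope, abs=2 * se)
        scale = np.sqrt(post.draws[f"lambda[{pid}]"]) * post.draws[f"sigma_m[{pid}]"]
        nu = post.draws["nu"]
        implied_sd = float(np.mean(scale * np.sqrt(nu / (nu - 2))))
        assert implied_sd == pytest.approx(resid.std(ddof=1), rel=0.05)

    def test_lambda_identity_holds_drawwise(self, oracle_fit):
        post, _, _ = oracle_fit
        pid = post.attrs["participant_ids"][0]
        lam = post.draws[f"lambda[{pid}]"]
        sm = post.draws[f"sigma_m[{pid}]"]
        sp = post.draws[f"sigma_p[{pid}]"]
        assert np.abs(lam - sp**2 / (sp**2 + sm**2)).max() < 1e-10

    def test_nu_ordering_recovered(self, quiet):
        """Data generated with heavy vs light tails keep their df ordering."""
        posts = {}
        for nu_true in (3.0, 30.0):
            cfg = CohortConfig(n_studies=1, participants_per_study=(4,),
                               trials_per_participant=150, nu_true=nu_true,
                               outlier_rate=0.0, seed=29,
                               sigma_p_pop=(np.log(9.0), 0.3))
            trials, _ = generate_behavior(cfg)
            posts[nu_true] = fit_cam(compute_trial_errors(trials), QUICK)
        assert posts[3.0].mean("nu") < posts[30.0].mean("nu")


class TestDeriveMeasures:
    def _fake_post(self, lam, sm):
        post = EnsemblePosterior(draws={
            "lambda[p1]": np.asarray(lam, dtype=float),
            "sigma_m[p1]": np.asarray(sm, dtype=float),
        })
        post.attrs["participant_ids"] = ["p1"]
        post.attrs["study_id"] = "s1"
        return post

    def test_constant_draws(self):
        m = derive_measures(self._fake_post([[0.8, 0.8]], [[5.0, 5.0]]))
        assert m["prototype_bias"].iloc[0] == pytest.approx(0.2)

    def test_mean_of_draws(self):
        m = derive_measures(self._fake_post([[0.6, 0.8]], [[4.0, 6.0]]))
        assert m["memory_inexactness"].iloc[0] == pytest.approx(5.0)
        assert m["prototype_bias"].iloc[0] == pytest.approx(0.3)

    def test_single_draw_degenerate(self):
        m = derive_measures(self._fake_post([[0.9]], [[3.0]]))
        assert m["memory_inexactness"].iloc[0] == 3.0

    def test_missing_participant_errors(self):
        post = self._fake_post([[0.8]], [[5.0]])
        post.attrs["participant_ids"] = ["p1", "p2"]
        with pytest.raises(KeyError):
            derive_measures(post)


class TestConvergenceReport:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        report = convergence_report({"x": rng.standard_normal((4, 1000))})
        p = report["parameters"]["x"]
        assert p["pass"] and p["ess_bulk"] > 3000 and abs(p["rhat"] - 1) < 0.01

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 1000))
        chains[0] += 10.0
        report = convergence_report({"x": chains})
        assert not report["pass"]
        assert report["parameters"]["x"]["rhat"] > 1.01

    def test_low_ess_fails_at_400_threshold(self):
        rng = np.random.default_rng(0)
        # strongly autocorrelated AR(1) chains: effective draws << 400
        chains = np.empty((4, 500))
        for c in range(4):
            e = rng.standard_normal(500)
            chains[c, 0] = e[0]
            for t in range(1, 500):
                chains[c, t] = 0.995 * chains[c, t - 1] + 0.1 * e[t]
        report = convergence_report({"x": chains}, ess_threshold=400)
        assert not report["parameters"]["x"]["pass"]

    def test_single_chain_is_an_error(self):
        with pytest.raises(ValueError):
            convergence_report({"x": np.zeros((1, 100))})


class TestPredictiveChecks:
    def test_posterior_predictive_brackets_observed_sd(self, small_cohort, quiet):
        trials, _ = small_cohort
        sub = trials[trials["study_id"] == "study-01"]
        sub = sub[~sub["is_injected_outlier"]]
        model = build_cam_model(sub, QUICK)
        post = fit_cam(model)
        checks = predictive_checks(model, post, sub, n_rep=60, seed=1)
        lo, hi = np.percentile(checks["error_sd"], [2.5, 97.5])
        assert lo <= checks["observed_error_sd"].iloc[0] <= hi

    def test_prior_predictive_spans_observed_range(self, small_cohort, quiet):
        trials, _ = small_cohort
        sub = trials[trials["study_id"] == "study-01"]
        model = build_cam_model(sub, QUICK)
        checks = predictive_checks(model, None, sub, n_rep=60, seed=2)
        assert checks["error_sd"].min() < checks["observed_error_sd"].iloc[0] \
            < checks["error_sd"].max()

    def test_zero_replicates_empty(self, small_cohort, quiet):
        trials, _ = small_cohort
        model = build_cam_model(trials[trials["study_id"] == "study-01"], QUICK)
        assert predictive_checks(model, None, trials, n_rep=0).empty


@pytest.fixture(scope="class")
def quiet_class():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
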