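"""Hierarchical Bayesian category-adjustment model (CAM).

The response angle R on each trial is modeled as a precision-weighted
combination of a fine-grained memory of the target angle mu and the quadrant
prototype rho:

    R ~ StudentT(nu,  lambda_j * mu + (1 - lambda_j) * rho,  sqrt(lambda_j) * sigma_M_j)
    lambda_j = sigma_P_j^2 / (sigma_P_j^2 + sigma_M_j^2)

per participant j, fitted separately for each study.  The observation scale
sqrt(lambda) * sigma_M is both the posterior SD of the optimal cue combination
and the SD of lambda*M + (1-lambda)*P under the lambda identity, so the two
natural readings of the model's noise coincide (see docs/methods.md).

Participants' (log sigma_M, log sigma_P) are varying effects around study-level
means with a non-centered parameterization; lambda is deterministic, which
enforces positivity and the lambda identity draw-wise by construction.  One
Student-t degrees-of-freedom parameter nu is shared within a study, with a
Gamma(2, 0.1) prior on nu - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .prep import wrap_angle
from .sampling import EnsemblePosterior, SamplerConfig, convergence_report, run_ensembles

__all__ = [
    "CAMConfig",
    "CAMModel",
    "lambda_from_sigmas",
    "build_cam_model",
    "fit_cam",
    "fit_cam_by_study",
    "derive_measures",
    "convergence_report",
    "predictive_checks",
]


@dataclass(frozen=True)
class CAMConfig:
    """Fit settings: sampler sizes, the df prior, and the prior-width policy."""

    chains: int = 2
    warmup: int = 2500
    draws: int = 2500
    thin: int = 10
    walkers: int | None = None
    seed: int = 0
    df_prior: tuple[float, float] = (2.0, 0.1)  # Gamma(shape, rate) on nu - 1
    preliminary_fit: bool = True
    prior_sd_inflation: float = 10.0
    group_mean_prior_sd: float = 2.0  # log scale

    def sampler(self) -> SamplerConfig:
        return SamplerConfig(chains=self.chains, warmup=self.warmup, draws=self.draws,
                             thin=self.thin, walkers=self.walkers, seed=self.seed)


def lambda_from_sigmas(sigma_m, sigma_p):
    """Memory confidence lambda = sigma_P^2 / (sigma_P^2 + sigma_M^2)."""
    sigma_m = np.asarray(sigma_m, dtype=float)
    sigma_p = np.asarray(sigma_p, dtype=float)
    return sigma_p**2 / (sigma_p**2 + sigma_m**2)


def _student_t_loglik(y, loc, scale, nu):
    """Sum over the last axis of the Student-t log density; nu broadcasts."""
    z = (y - loc) / scale
    n = y.shape[-1]
    const = (special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0)
             - 0.5 * np.log(nu * np.pi))
    log_scale = np.log(np.broadcast_to(scale, z.shape)).sum(axis=-1)
    return (n * const - log_scale
            - 0.5 * (nu + 1.0) * np.log1p(z**2 / nu[..., None]).sum(axis=-1))


@dataclass
class CAMModel:
    """Built model: data arrays, parameter layout, and the log posterior."""

    study_id: str
    participant_ids: list[str]
    y: np.ndarray          # signed angular error, degrees
    d: np.ndarray          # prototype minus target, degrees
    pidx: np.ndarray       # participant index per trial
    cfg: CAMConfig
    prior_centers: tuple[float, float]  # (log sigma_M, log sigma_P)
    flags: dict

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def hierarchical(self) -> bool:
        # a single participant cannot identify group scales; fall back to a
        # flat parameterization with the same likelihood
        return self.n_participants > 1

    @property
    def param_names(self) -> list[str]:
        j = self.n_participants
        if not self.hierarchical:
            return ["log_sigma_m_flat", "log_sigma_p_flat", "log_nu_minus_1"]
        names = ["mu_log_sigma_m", "mu_log_sigma_p", "log_tau_m", "log_tau_p"]
        names += [f"z_m[{i}]" for i in range(j)]
        names += [f"z_p[{i}]" for i in range(j)]
        names += ["log_nu_minus_1"]
        return names

    def _unpack(self, theta: np.ndarray):
        j = self.n_participants
        mu_m = theta[:, 0]
        mu_p = theta[:, 1]
        tau_m = np.exp(theta[:, 2])
        tau_p = np.exp(theta[:, 3])
        z_m = theta[:, 4:4 + j]
        z_p = theta[:, 4 + j:4 + 2 * j]
        lnr = theta[:, 4 + 2 * j]
        lsm = mu_m[:, None] + tau_m[:, None] * z_m
        lsp = mu_p[:, None] + tau_p[:, None] * z_p
        return mu_m, mu_p, tau_m, tau_p, z_m, z_p, lnr, lsm, lsp

    def _log_prob_flat(self, theta: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):  # wild proposals become -inf below
            return self._log_prob_flat_impl(theta)

    def _log_prob_flat_impl(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        bad = np.any(np.abs(theta) > 40.0, axis=1)
        lsm, lsp, lnr = theta[:, 0], theta[:, 1], theta[:, 2]
        lam = special.expit(2.0 * (lsp - lsm))
        scale = np.sqrt(lam) * np.exp(lsm)
        nu = 1.0 + np.exp(lnr)
        loc = (1.0 - lam)[:, None] * self.d[None, :]
        ll = _student_t_loglik(self.y[None, :], loc, scale[:, None], nu)
        c_m, c_p = self.prior_centers
        sd0 = self.cfg.group_mean_prior_sd
        a, b = self.cfg.df_prior
        lp = (-0.5 * ((lsm - c_m) / sd0) ** 2 - 0.5 * ((lsp - c_p) / sd0) ** 2
              + a * lnr - b * np.exp(lnr))
        out = ll + lp
        out[bad] = -np.inf
        out[~np.isfinite(out)] = -np.inf
        return out

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        if not self.hierarchical:
            return self._log_prob_flat(theta)
        with np.errstate(all="ignore"):
            return self._log_prob_impl(theta)

    def _log_prob_impl(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        bad = np.any(np.abs(theta) > 40.0, axis=1)
        mu_m, mu_p, tau_m, tau_p, z_m, z_p, lnr, lsm, lsp = self._unpack(theta)

        lam = special.expit(2.0 * (lsp - lsm))          # (W, J)
        sigma_m = np.exp(lsm)
        scale = np.sqrt(lam) * sigma_m
        nu = 1.0 + np.exp(lnr)

        loc = (1.0 - lam)[:, self.pidx] * self.d[None, :]
        s = scale[:, self.pidx]
        ll = _student_t_loglik(self.y[None, :], loc, s, nu)

        c_m, c_p = self.prior_centers
        sd0 = self.cfg.group_mean_prior_sd
        lp = (-0.5 * ((mu_m - c_m) / sd0) ** 2
              - 0.5 * ((mu_p - c_p) / sd0) ** 2)
        # half-normal(1) on tau, sampled on the log scale (Jacobian included)
        lp += -0.5 * tau_m**2 + np.log(tau_m) - 0.5 * tau_p**2 + np.log(tau_p)
        lp += -0.5 * (z_m**2).sum(axis=1) - 0.5 * (z_p**2).sum(axis=1)
        a, b = self.cfg.df_prior
        lp += a * lnr - b * np.exp(lnr)

        out = ll + lp
        out[bad] = -np.inf
        out[~np.isfinite(out)] = -np.inf
        return out

    def init_center(self) -> np.ndarray:
        c_m, c_p = self.prior_centers
        if not self.hierarchical:
            return np.array([c_m, c_p, np.log(9.0)])
        j = self.n_participants
        center = np.zeros(4 + 2 * j + 1)
        center[0], center[1] = c_m, c_p
        center[2] = center[3] = np.log(0.3)
        center[4 + 2 * j] = np.log(9.0)
        return center


def _preliminary_pooled_fit(y: np.ndarray, d: np.ndarray,
                            df_prior: tuple[float, float]) -> tuple[float, float]:
    """One-level pooled Student-t fit; returns (log sigma_M, log sigma_P) to
    center the group-level priors (keeps sampling away from pathological
    regions without constraining it — prior SDs remain wide)."""

    def nll(theta):
        lsm, lsp, lnr = theta
        lam = special.expit(2.0 * (lsp - lsm))
        scale = np.sqrt(lam) * np.exp(lsm)
        nu = 1.0 + np.exp(lnr)
        ll = stats.t.logpdf(y, df=nu, loc=(1.0 - lam) * d, scale=scale).sum()
        a, b = df_prior
        return -(ll + a * lnr - b * np.exp(lnr))

    x0 = np.array([np.log(max(np.std(y), 1e-3)), np.log(2.0 * max(np.std(y), 1e-3)),
                   np.log(9.0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-6})
    lsm, lsp, _ = res.x
    return float(lsm), float(lsp)


def build_cam_model(trials: pd.DataFrame, cfg: CAMConfig | None = None) -> CAMModel:
    """Prepare the per-study model from a filtered trial table.

    The table must contain one study only (fits are run separately per study),
    with columns ``participant_id``, ``target_angle_deg``, ``prototype_angle``
    and ``response_angle_deg``.  Participants with fewer than 3 kept trials and
    participants whose kept trials all share one target angle (weak lambda
    identification) are flagged in ``model.flags`` with a warning, not dropped.
    """
    cfg = cfg or CAMConfig()
    studies = trials["study_id"].unique() if "study_id" in trials.columns else ["study"]
    if len(studies) != 1:
        raise ValueError(f"build_cam_model fits one study at a time, got {list(studies)}")
    if "prototype_angle" not in trials.columns:
        from .prep import compute_trial_errors
        trials = compute_trial_errors(trials)

    pids = sorted(trials["participant_id"].unique())
    pmap = {p: i for i, p in enumerate(pids)}
    pidx = trials["participant_id"].map(pmap).to_numpy()
    y = wrap_angle(trials["response_angle_deg"].to_numpy(dtype=float)
                   - trials["target_angle_deg"].to_numpy(dtype=float))
    d = wrap_angle(trials["prototype_angle"].to_numpy(dtype=float)
                   - trials["target_angle_deg"].to_numpy(dtype=float))

    flags = {"few_trials": [], "single_target_angle": []}
    for p, i in pmap.items():
        sel = pidx == i
        if sel.sum() < 3:
            flags["few_trials"].append(p)
        if trials.loc[sel, "target_angle_deg"].nunique() == 1:
            flags["single_target_angle"].append(p)
    if flags["few_trials"]:
        warnings.warn(f"participants with < 3 kept trials: {flags['few_trials']}")
    if flags["single_target_angle"]:
        warnings.warn("participants with a single target angle (lambda weakly "
                      f"identified): {flags['single_target_angle']}")

    if cfg.preliminary_fit:
        centers = _preliminary_pooled_fit(y, d, cfg.df_prior)
    else:
        centers = (np.log(5.0), np.log(10.0))

    return CAMModel(study_id=str(studies[0]), participant_ids=pids, y=y, d=d,
                    pidx=pidx, cfg=cfg, prior_centers=centers, flags=flags)


def _attach_derived(post: EnsemblePosterior, model: CAMModel) -> None:
    if not model.hierarchical:
        pid = model.participant_ids[0]
        lsm = post.draws["log_sigma_m_flat"]
        lsp = post.draws["log_sigma_p_flat"]
        post.draws[f"sigma_m[{pid}]"] = np.exp(lsm)
        post.draws[f"sigma_p[{pid}]"] = np.exp(lsp)
        post.draws[f"lambda[{pid}]"] = special.expit(2.0 * (lsp - lsm))
        post.draws["nu"] = 1.0 + np.exp(post.draws["log_nu_minus_1"])
        return
    j = model.n_participants
    mu_m = post.draws["mu_log_sigma_m"]
    mu_p = post.draws["mu_log_sigma_p"]
    tau_m = np.exp(post.draws["log_tau_m"])
    tau_p = np.exp(post.draws["log_tau_p"])
    for i, pid in enumerate(model.participant_ids):
        lsm = mu_m + tau_m * post.draws[f"z_m[{i}]"]
        lsp = mu_p + tau_p * post.draws[f"z_p[{i}]"]
        post.draws[f"sigma_m[{pid}]"] = np.exp(lsm)
        post.draws[f"sigma_p[{pid}]"] = np.exp(lsp)
        post.draws[f"lambda[{pid}]"] = special.expit(2.0 * (lsp - lsm))
    post.draws["nu"] = 1.0 + np.exp(post.draws["log_nu_minus_1"])


def _prior_inflation_check(post: EnsemblePosterior, model: CAMModel,
                           n_prior: int = 4000) -> dict:
    """Compare prior SD to posterior SD for the reported per-participant
    parameters; warn when the prior is not at least ``prior_sd_inflation``
    times wider."""
    cfg = model.cfg
    rng = np.random.default_rng(12345)
    c_m, c_p = model.prior_centers
    sd0 = cfg.group_mean_prior_sd
    if model.hierarchical:
        mu_m = rng.normal(c_m, sd0, n_prior)
        mu_p = rng.normal(c_p, sd0, n_prior)
        tau_m = np.abs(rng.standard_normal(n_prior))
        tau_p = np.abs(rng.standard_normal(n_prior))
        lsm = mu_m + tau_m * rng.standard_normal(n_prior)
        lsp = mu_p + tau_p * rng.standard_normal(n_prior)
    else:
        lsm = rng.normal(c_m, sd0, n_prior)
        lsp = rng.normal(c_p, sd0, n_prior)
    prior_sd = {
        "log_sigma_m": float(np.std(lsm)),
        "log_sigma_p": float(np.std(lsp)),
    }
    result = {"prior_sd": prior_sd, "violations": []}
    for i, pid in enumerate(model.participant_ids):
        post_sd_m = float(np.std(np.log(post.draws[f"sigma_m[{pid}]"])))
        post_sd_p = float(np.std(np.log(post.draws[f"sigma_p[{pid}]"])))
        if prior_sd["log_sigma_m"] < cfg.prior_sd_inflation * post_sd_m:
            result["violations"].append((pid, "log_sigma_m"))
        if prior_sd["log_sigma_p"] < cfg.prior_sd_inflation * post_sd_p:
            result["violations"].append((pid, "log_sigma_p"))
    if result["violations"]:
        warnings.warn(
            f"prior SD < {cfg.prior_sd_inflation}x posterior SD for: "
            f"{result['violations'][:5]}{'...' if len(result['violations']) > 5 else ''}")
    return result


def fit_cam(model: CAMModel | pd.DataFrame, cfg: CAMConfig | None = None) -> EnsemblePosterior:
    """Sample the CAM posterior for one study.

    Accepts a built :class:`CAMModel` or a trial table (built on the fly).
    Returns an :class:`EnsemblePosterior` with per-participant draws of
    ``sigma_m``, ``sigma_p`` and ``lambda`` attached, a convergence report and
    the prior-width check in ``diagnostics``.
    """
    if isinstance(model, pd.DataFrame):
        model = build_cam_model(model, cfg)
    cfg = cfg or model.cfg
    if cfg is not model.cfg:
        model = replace(model, cfg=cfg)

    post = run_ensembles(model.log_prob, model.init_center(), cfg.sampler(),
                         model.param_names, init_scale=0.05)
    _attach_derived(post, model)
    post.attrs["study_id"] = model.study_id
    post.attrs["participant_ids"] = model.participant_ids
    post.attrs["flags"] = model.flags
    if model.hierarchical:
        core = ["mu_log_sigma_m", "mu_log_sigma_p", "log_tau_m", "log_tau_p", "nu"]
    else:
        core = ["nu"]
    core += [f"lambda[{p}]" for p in model.participant_ids]
    core += [f"sigma_m[{p}]" for p in model.participant_ids]
    convergence_report(post, parameters=core)
    post.diagnostics["prior_inflation"] = _prior_inflation_check(post, model)
    return post


def fit_cam_by_study(trials: pd.DataFrame, cfg: CAMConfig | None = None
                     ) -> dict[str, EnsemblePosterior]:
    """Fit the model separately for each study and return a dict of posteriors."""
    cfg = cfg or CAMConfig()
    out = {}
    for k, (study, sub) in enumerate(sorted(trials.groupby("study_id"))):
        study_cfg = replace(cfg, seed=cfg.seed + 1000 * k)
        out[str(study)] = fit_cam(build_cam_model(sub, study_cfg))
    return out


def derive_measures(posteriors: EnsemblePosterior | dict[str, EnsemblePosterior]
                    ) -> pd.DataFrame:
    """Per-participant behavioral measures from the posterior.

    ``memory_inexactness`` is the posterior mean of sigma_M (degrees) and
    ``prototype_bias`` is 1 minus the posterior mean of lambda.
    """
    if isinstance(posteriors, EnsemblePosterior):
        posteriors = {posteriors.attrs.get("study_id", "study"): posteriors}
    rows = []
    for study, post in posteriors.items():
        for pid in post.attrs["participant_ids"]:
            if f"sigma_m[{pid}]" not in post.draws:
                raise KeyError(f"missing posterior draws for participant {pid}")
            rows.append(dict(
                study_id=study,
                participant_id=pid,
                memory_inexactness=post.mean(f"sigma_m[{pid}]"),
                prototype_bias=1.0 - post.mean(f"lambda[{pid}]"),
            ))
    return pd.DataFrame(rows)


def predictive_checks(model: CAMModel, post: EnsemblePosterior | None,
                      trials: pd.DataFrame, n_rep: int = 50,
                      seed: int = 0) -> pd.DataFrame:
    """Prior- or posterior-predictive summaries of replicated datasets.

    For each replicate, parameters are taken from the posterior (or drawn from
    the priors when ``post`` is None), responses are simulated at the observed
    (target, prototype) pairs, and the replicate's error SD and mean bias
    toward the prototype are recorded next to the observed values.  Zero
    replicates yield an empty frame.
    """
    cols = ["replicate", "source", "error_sd", "mean_bias_toward_prototype",
            "observed_error_sd", "observed_mean_bias"]
    if n_rep == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    y, d, pidx = model.y, model.d, model.pidx
    obs_sd = float(np.std(y))
    obs_bias = float(np.mean(y * np.sign(d)))

    rows = []
    for r in range(n_rep):
        if post is None:
            c_m, c_p = model.prior_centers
            sd0 = model.cfg.group_mean_prior_sd
            lsm = rng.normal(c_m, sd0) + abs(rng.standard_normal()) * rng.standard_normal(
                model.n_participants)
            lsp = rng.normal(c_p, sd0) + abs(rng.standard_normal()) * rng.standard_normal(
                model.n_participants)
            nu = 1.0 + rng.gamma(*_gamma_shape_scale(model.cfg.df_prior))
            source = "prior"
        else:
            n_chain, n_draw = post.draws["nu"].shape
            ci, di = rng.integers(n_chain), rng.integers(n_draw)
            lsm = np.array([np.log(post.draws[f"sigma_m[{p}]"][ci, di])
                            for p in model.participant_ids])
            lsp = np.array([np.log(post.draws[f"sigma_p[{p}]"][ci, di])
                            for p in model.participant_ids])
            nu = float(post.draws["nu"][ci, di])
            source = "posterior"
        lam = special.expit(2.0 * (lsp - lsm))
        scale = np.sqrt(lam) * np.exp(lsm)
        y_rep = (1.0 - lam)[pidx] * d + scale[pidx] * rng.standard_t(nu, size=len(d))
        rows.append(dict(replicate=r, source=source,
                         error_sd=float(np.std(y_rep)),
                         mean_bias_toward_prototype=float(np.mean(y_rep * np.sign(d))),
                         observed_error_sd=obs_sd, observed_mean_bias=obs_bias))
    return pd.DataFrame(rows, columns=cols)


def _gamma_shape_scale(shape_rate: tuple[float, float]) -> tuple[float, float]:
    shape, rate = shape_rate
    return shape, 1.0 / rate
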