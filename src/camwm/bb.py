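"""Bayesian brain-behavior association.

Network activity is regressed on standardized memory inexactness and prototype
bias with a Student-t likelihood and study-specific intercepts (non-centered
random effect across studies):

    beta_activity ~ StudentT(nu, alpha_study + b1 * z_inexactness + b2 * z_bias, sigma)

Priors: Normal(0, 10) on coefficients and the grand intercept, half-Cauchy(2.5)
on scales, Gamma(2, 0.1) on nu - 1.  All variables (activity and both
predictors) are standardized across participants, so coefficients are fully
standardized.  The headline summaries are posterior sign probabilities
P(b > 0) and P(b < 0) per coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .sampling import EnsemblePosterior, SamplerConfig, convergence_report, run_ensembles

__all__ = [
    "BBConfig",
    "standardize",
    "fit_brain_behavior",
    "fit_all_networks",
    "posterior_sign_probability",
    "correlate_measures",
    "summarize_bb",
]


@dataclass(frozen=True)
class BBConfig:
    """Priors and sampler settings for the association model."""

    beta_prior_sd: float = 10.0
    sd_prior_scale: float = 2.5   # half-Cauchy
    df_prior: tuple[float, float] = (2.0, 0.1)  # Gamma(shape, rate) on nu - 1
    chains: int = 2
    warmup: int = 3000
    draws: int = 5000
    thin: int = 10
    walkers: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_prior_sd <= 0 or self.sd_prior_scale <= 0:
            raise ValueError("prior scales must be positive")

    def sampler(self) -> SamplerConfig:
        return SamplerConfig(chains=self.chains, warmup=self.warmup, draws=self.draws,
                             thin=self.thin, walkers=self.walkers, seed=self.seed)


def standardize(values) -> np.ndarray:
    """Z-score across participants (population-SD convention: mean 0, SD 1 exactly)."""
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 2:
        raise ValueError("standardization needs >= 2 distinct values")
    return (v - v.mean()) / v.std()


def posterior_sign_probability(draws, direction: str = "+") -> float:
    """Fraction of posterior draws strictly above (``+``) or below (``-``) zero."""
    a = np.asarray(draws, dtype=float).reshape(-1)
    if a.size == 0:
        raise ValueError("no draws")
    if direction == "+":
        return float((a > 0).mean())
    if direction == "-":
        return float((a < 0).mean())
    raise ValueError("direction must be '+' or '-'")


def correlate_measures(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value (requires >= 3 pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _bb_log_prob_factory(y, x1, x2, sidx, n_studies, cfg: BBConfig):
    """Vectorized log posterior over walkers.

    Layout (hierarchical, n_studies >= 2):
      [b1, b2, alpha_bar, log_tau, z_s (S), log_sigma, log_nu_minus_1]
    Single-level (n_studies == 1): [b1, b2, alpha, log_sigma, log_nu_minus_1].
    """
    a_df, b_df = cfg.df_prior
    hc = cfg.sd_prior_scale
    bsd = cfg.beta_prior_sd
    hierarchical = n_studies >= 2

    def log_half_cauchy(x, logx):
        # density of |Cauchy(0, hc)| evaluated at x = exp(logx), plus Jacobian
        return np.log(2.0 / (np.pi * hc)) - np.log1p((x / hc) ** 2) + logx

    def log_prob(theta):
        with np.errstate(all="ignore"):  # wild proposals become -inf below
            return _impl(theta)

    def _impl(theta):
        theta = np.atleast_2d(theta)
        bad = np.any(np.abs(theta) > 40.0, axis=1)
        b1, b2 = theta[:, 0], theta[:, 1]
        if hierarchical:
            abar = theta[:, 2]
            log_tau = theta[:, 3]
            z = theta[:, 4:4 + n_studies]
            log_sigma = theta[:, 4 + n_studies]
            lnr = theta[:, 5 + n_studies]
            tau = np.exp(log_tau)
            alpha = abar[:, None] + tau[:, None] * z      # (W, S)
            prior = (-0.5 * (abar / bsd) ** 2
                     + log_half_cauchy(tau, log_tau)
                     - 0.5 * (z**2).sum(axis=1))
        else:
            alpha = theta[:, 2][:, None]
            log_sigma = theta[:, 3]
            lnr = theta[:, 4]
            prior = -0.5 * (alpha[:, 0] / bsd) ** 2
        sigma = np.exp(log_sigma)
        nu = 1.0 + np.exp(lnr)

        mu = alpha[:, sidx] + b1[:, None] * x1[None, :] + b2[:, None] * x2[None, :]
        zres = (y[None, :] - mu) / sigma[:, None]
        n = len(y)
        const = (special.gammaln((nu + 1) / 2) - special.gammaln(nu / 2)
                 - 0.5 * np.log(nu * np.pi))
        ll = (n * const - n * log_sigma
              - 0.5 * (nu + 1) * np.log1p(zres**2 / nu[:, None]).sum(axis=1))

        prior += (-0.5 * (b1 / bsd) ** 2 - 0.5 * (b2 / bsd) ** 2
                  + log_half_cauchy(sigma, log_sigma)
                  + a_df * lnr - b_df * np.exp(lnr))
        out = ll + prior
        out[bad] = -np.inf
        out[~np.isfinite(out)] = -np.inf
        return out

    return log_prob


def fit_brain_behavior(
    activity: pd.DataFrame,
    measures: pd.DataFrame,
    cfg: BBConfig | None = None,
    network: str | None = None,
    phase: str | None = None,
) -> EnsemblePosterior:
    """Fit the two-level association model for one (network, phase) slice.

    ``activity`` is a BetaTable (participant_id, study_id, unit-or-network,
    phase, beta); ``measures`` holds ``memory_inexactness`` and
    ``prototype_bias`` per participant.  Tables are joined on participant_id.
    With a single study the random intercept collapses to a single-level
    intercept with a warning.  Returns posterior draws of ``b_inexactness``,
    ``b_bias``, intercepts, ``sigma`` and ``nu`` plus sign probabilities in
    ``attrs``.
    """
    cfg = cfg or BBConfig()
    act = activity
    unit_col = "network" if "network" in act.columns else "unit"
    if network is not None:
        act = act[act[unit_col] == network]
    if phase is not None:
        act = act[act["phase"] == phase]
    if act.empty:
        raise ValueError("no activity rows for the requested network/phase")
    dup = act.duplicated(subset=["participant_id"]).any()
    if dup and not {"network", "phase"}.issubset(act.columns):
        raise ValueError("ambiguous activity slice; pass network=/phase=")

    if {"memory_inexactness", "prototype_bias"}.issubset(act.columns):
        merged = act.copy()  # measures already joined upstream
    else:
        merged = act.merge(
            measures[["participant_id", "memory_inexactness", "prototype_bias"]],
            on="participant_id", how="inner", validate="many_to_one")
    if merged["participant_id"].duplicated().any():
        raise ValueError("multiple activity rows per participant in the slice; "
                         "pass network=/phase= to disambiguate")

    y = standardize(merged["beta"])
    x1 = standardize(merged["memory_inexactness"])
    x2 = standardize(merged["prototype_bias"])
    studies = sorted(merged["study_id"].unique())
    sidx = merged["study_id"].map({s: i for i, s in enumerate(studies)}).to_numpy()
    n_studies = len(studies)
    if n_studies < 2:
        warnings.warn("single study in slice; fitting a single-level intercept")

    log_prob = _bb_log_prob_factory(y, x1, x2, sidx, n_studies, cfg)
    if n_studies >= 2:
        names = (["b_inexactness", "b_bias", "alpha_bar", "log_tau"]
                 + [f"z_alpha[{s}]" for s in studies] + ["log_sigma", "log_nu_minus_1"])
        center = np.zeros(len(names))
        center[names.index("log_tau")] = np.log(0.2)
    else:
        names = ["b_inexactness", "b_bias", "alpha", "log_sigma", "log_nu_minus_1"]
        center = np.zeros(len(names))
    center[names.index("log_nu_minus_1")] = np.log(9.0)

    post = run_ensembles(log_prob, center, cfg.sampler(), names, init_scale=0.05)
    post.draws["sigma"] = np.exp(post.draws["log_sigma"])
    post.draws["nu"] = 1.0 + np.exp(post.draws["log_nu_minus_1"])
    if n_studies >= 2:
        tau = np.exp(post.draws["log_tau"])
        for s in studies:
            post.draws[f"alpha[{s}]"] = (post.draws["alpha_bar"]
                                         + tau * post.draws[f"z_alpha[{s}]"])
    post.attrs.update(
        n_obs=len(y), studies=studies, network=network, phase=phase,
        predictor_correlation=float(np.corrcoef(x1, x2)[0, 1]),
        p_b_inexactness_pos=posterior_sign_probability(post.flat("b_inexactness"), "+"),
        p_b_inexactness_neg=posterior_sign_probability(post.flat("b_inexactness"), "-"),
        p_b_bias_pos=posterior_sign_probability(post.flat("b_bias"), "+"),
        p_b_bias_neg=posterior_sign_probability(post.flat("b_bias"), "-"),
    )
    convergence_report(post, parameters=["b_inexactness", "b_bias", "sigma", "nu"])
    return post


def fit_all_networks(activity: pd.DataFrame, measures: pd.DataFrame,
                     cfg: BBConfig | None = None) -> dict[tuple[str, str], EnsemblePosterior]:
    """One model per (network, phase) combination."""
    cfg = cfg or BBConfig()
    unit_col = "network" if "network" in activity.columns else "unit"
    out = {}
    for k, ((net, phase), _) in enumerate(sorted(activity.groupby([unit_col, "phase"]))):
        c = BBConfig(**{**cfg.__dict__, "seed": cfg.seed + 100 * k})
        out[(net, phase)] = fit_brain_behavior(activity, measures, c,
                                               network=net, phase=phase)
    return out


def summarize_bb(fits: dict[tuple[str, str], EnsemblePosterior]) -> pd.DataFrame:
    """Coefficient summary table: posterior mean, 95% interval, sign probabilities."""
    rows = []
    for (net, phase), post in sorted(fits.items()):
        for coef in ("b_inexactness", "b_bias"):
            lo, hi = post.interval(coef, 0.95)
            rows.append(dict(
                network=net, phase=phase, coefficient=coef,
                mean=post.mean(coef), ci_low=lo, ci_high=hi,
                p_positive=posterior_sign_probability(post.flat(coef), "+"),
                p_negative=posterior_sign_probability(post.flat(coef), "-"),
                predictor_correlation=post.attrs["predictor_correlation"],
            ))
    return pd.DataFrame(rows)
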