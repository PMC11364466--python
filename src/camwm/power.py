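"""Bootstrap power analysis for brain-behavior associations.

Participants are resampled with replacement at each target sample size, the
association model is refitted on every resample, and power is the proportion
of resamples in which at least 95% of the coefficient's posterior lies on one
side of zero.  The across-resample 2.5/97.5 percentiles of the posterior-mean
estimates give the stability interval; the smallest sample size from which
zero stays outside that interval for all larger sizes is the stability
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bb import BBConfig, fit_brain_behavior, posterior_sign_probability

__all__ = ["PowerConfig", "resample_power", "summarize_stability", "resampling_plan"]

COEFS = ("b_inexactness", "b_bias")


@dataclass(frozen=True)
class PowerConfig:
    """Resampling design.

    Defaults follow the published procedure (sizes 15..155, 1000 resamples);
    the inner sampler is deliberately small since each resample refits the
    model.  ``stratify_by_study`` guards degenerate tiny resamples; the default
    is plain unstratified resampling from the pooled sample.
    """

    sizes: tuple[int, ...] = tuple(range(15, 156, 10))
    n_resamples: int = 1000
    posterior_mass: float = 0.95
    inner: BBConfig = field(default_factory=lambda: BBConfig(
        chains=2, warmup=300, draws=300, thin=2))
    stratify_by_study: bool = False
    max_failure_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.sizes):
            raise ValueError("every sample size must be >= 2")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def resampling_plan(n_participants: int, cfg: PowerConfig) -> dict[int, np.ndarray]:
    """Deterministic with-replacement index plan: size -> (n_resamples, size)."""
    rng = np.random.default_rng(cfg.seed)
    return {size: rng.integers(0, n_participants, size=(cfg.n_resamples, size))
            for size in cfg.sizes}


def resample_power(
    activity: pd.DataFrame,
    measures: pd.DataFrame,
    network: str | None = None,
    phase: str | None = None,
    cfg: PowerConfig | None = None,
) -> pd.DataFrame:
    """Bootstrap the association model across sample sizes.

    Returns a PowerCurve table with one row per (size, coefficient):
    ``power``, across-resample mean of posterior-mean estimates (``est_mean``),
    the 2.5/97.5 percentile stability interval (``ci_low``, ``ci_hi``),
    ``n_failed_fits`` and a ``valid`` flag (False when the failure rate exceeds
    ``cfg.max_failure_rate``).  Duplicate participants within a resample are
    treated as independent rows (standard bootstrap).  Resamples containing a
    single study are fitted single-level rather than crashing.
    """
    cfg = cfg or PowerConfig()
    unit_col = "network" if "network" in activity.columns else "unit"
    act = activity
    if network is not None:
        act = act[act[unit_col] == network]
    if phase is not None:
        act = act[act["phase"] == phase]
    merged = act.merge(
        measures[["participant_id", "memory_inexactness", "prototype_bias"]],
        on="participant_id", how="inner")
    if merged["participant_id"].duplicated().any():
        raise ValueError("pass network=/phase= so the slice has one row per participant")
    merged = merged.reset_index(drop=True)
    n = len(merged)

    plan = resampling_plan(n, cfg)
    rows = []
    for size in cfg.sizes:
        est = {c: [] for c in COEFS}
        hit = {c: [] for c in COEFS}
        n_failed = 0
        for r in range(cfg.n_resamples):
            idx = plan[size][r]
            if cfg.stratify_by_study:
                idx = _stratified_indices(merged["study_id"], size, cfg.seed, size, r)
            sample = merged.iloc[idx].copy()
            sample["participant_id"] = np.arange(len(sample)).astype(str)  # bootstrap rows are i.i.d.
            inner = BBConfig(**{**cfg.inner.__dict__, "seed": cfg.inner.seed + 7919 * r + size})
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    post = fit_brain_behavior(sample, sample, inner)
            except Exception:
                n_failed += 1
                continue
            for c in COEFS:
                draws = post.flat(c)
                est[c].append(float(draws.mean()))
                mass = max(posterior_sign_probability(draws, "+"),
                           posterior_sign_probability(draws, "-"))
                hit[c].append(mass >= cfg.posterior_mass)
        n_ok = cfg.n_resamples - n_failed
        valid = n_ok > 0 and (n_failed / cfg.n_resamples) <= cfg.max_failure_rate
        for c in COEFS:
            e = np.asarray(est[c], dtype=float)
            rows.append(dict(
                size=size, coefficient=c,
                power=float(np.mean(hit[c])) if n_ok else np.nan,
                est_mean=float(e.mean()) if n_ok else np.nan,
                ci_low=float(np.percentile(e, 2.5)) if n_ok else np.nan,
                ci_hi=float(np.percentile(e, 97.5)) if n_ok else np.nan,
                n_failed_fits=n_failed, valid=valid,
            ))
    return pd.DataFrame(rows)


def _stratified_indices(study_ids: pd.Series, size: int, seed: int,
                        size_key: int, r: int) -> np.ndarray:
    rng = np.random.default_rng((seed, size_key, r))
    idx = []
    groups = list(study_ids.groupby(study_ids).groups.values())
    per = max(1, size // len(groups))
    for g in groups:
        g = np.asarray(g)
        idx.append(rng.choice(g, size=per, replace=True))
    idx = np.concatenate(idx)
    if len(idx) > size:
        idx = idx[:size]
    elif len(idx) < size:
        idx = np.concatenate([idx, rng.integers(0, len(study_ids), size - len(idx))])
    return idx


def summarize_stability(curve: pd.DataFrame) -> pd.DataFrame:
    """Smallest sample size from which zero stays outside the stability interval.

    For each coefficient, scans the increasing size grid and reports the
    smallest size such that every size from there on excludes zero from
    [ci_low, ci_hi]; ``"not reached"`` when no such size exists.
    """
    rows = []
    for coef, sub in curve.groupby("coefficient"):
        sub = sub.sort_values("size")
        excl = ((sub["ci_low"] > 0) | (sub["ci_hi"] < 0)).to_numpy()
        sizes = sub["size"].to_numpy()
        stable: object = "not reached"
        for i in range(len(excl)):
            if excl[i:].all():
                stable = int(sizes[i])
                break
        rows.append(dict(coefficient=coef, smallest_stable_n=stable))
    return pd.DataFrame(rows)
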