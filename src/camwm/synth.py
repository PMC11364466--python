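"""Synthetic multi-study cohorts with known ground truth.

Generates delayed-estimation spatial working-memory behavior under the
category-adjustment model, parcellated network activity linearly tied to the
behavioral measures, and simple BOLD time-series for the GLM stage — so every
downstream fitting stage has a recovery-testable input.

Generative model for behavior
-----------------------------
Each participant carries a memory inexactness sigma_M (degrees) and a memory
confidence lambda in (0,1); the prototype inexactness is derived from the
category-adjustment identity lambda = sigma_P^2 / (sigma_P^2 + sigma_M^2), so
the identity holds exactly by construction.  A response angle is drawn from a
Student-t with location ``lambda*mu + (1-lambda)*rho`` (mu target angle, rho
quadrant diagonal) and scale ``sqrt(lambda)*sigma_M``, the marginal implied by
optimally combining the fine-grained and prototype cues.  Across participants,
(log sigma_M, logit lambda) are bivariate Gaussian with the correlation chosen
so that sigma_M and prototype bias 1-lambda correlate at ``latent_corr``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import assign_quadrant, wrap_angle

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_target_angles",
    "generate_behavior",
    "generate_activity",
    "generate_timeseries",
]

NETWORKS = ("cingulo-opercular", "dorsal-attention", "frontoparietal", "default")
PHASES = ("encoding", "delay", "response")


def default_target_angles(n: int = 24, offset: float = 7.5) -> list[float]:
    """Evenly spread target angles avoiding the cardinal axes.

    Places ``n`` angles at ``offset + k*360/n``; raises if any lands on a
    cardinal axis.
    """
    angles = [float(np.mod(offset + k * 360.0 / n, 360.0)) for k in range(n)]
    if any(np.isclose(np.mod(a, 90.0), 0.0) for a in angles):
        raise ValueError("angle grid touches a cardinal axis; change offset or n")
    return angles


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and population parameters for a synthetic cohort.

    ``lambda_pop`` is (mean, SD) of logit(lambda) across participants and
    ``sigma_m_pop`` is (mean, SD) of log(sigma_M in degrees); ``latent_corr``
    is the target correlation between sigma_M and prototype bias 1-lambda.
    Alternatively ``sigma_p_pop`` (mean, SD of log sigma_P) specifies the
    population directly as independent log-normals on (sigma_M, sigma_P) —
    the population a hierarchical fit with independent varying effects
    assumes — in which case ``lambda_pop`` and ``latent_corr`` are ignored
    and lambda is derived.
    Defaults emulate a six-study cohort of 155 participants performing 20-80
    trials each at a constant per-study target amplitude, with targets never on
    the cardinal axes.
    """

    n_studies: int = 6
    participants_per_study: tuple[int, ...] = (25, 25, 25, 30, 25, 25)
    trials_per_participant: int = 60
    target_angles: tuple[tuple[float, ...], ...] | None = None
    target_amplitude: tuple[float, ...] | None = None
    lambda_pop: tuple[float, float] = (1.9, 0.8)
    sigma_m_pop: tuple[float, float] = (np.log(5.0), 0.35)
    sigma_p_pop: tuple[float, float] | None = None
    latent_corr: float = 0.66
    nu_true: float = 8.0
    outlier_rate: float = 0.02
    amp_ratio_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.participants_per_study) != self.n_studies:
            raise ValueError("participants_per_study length must equal n_studies")
        if self.trials_per_participant < 1:
            raise ValueError("trials_per_participant must be >= 1")
        if not -1.0 <= self.latent_corr <= 1.0:
            raise ValueError("latent_corr must lie in [-1, 1]")
        if self.nu_true <= 1:
            raise ValueError("nu_true must exceed 1")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.lambda_pop[1] < 0 or self.sigma_m_pop[1] < 0:
            raise ValueError("population SDs must be non-negative")
        for amp in self.resolved_amplitudes():
            if amp <= 0:
                raise ValueError("target amplitudes must be positive")
        for study_angles in self.resolved_angles():
            if not 1 <= len(study_angles):
                raise ValueError("each study needs at least one target angle")
            for a in study_angles:
                if np.isclose(np.mod(a, 90.0), 0.0):
                    raise ValueError(f"target angle {a} lies on a cardinal axis")

    def resolved_angles(self) -> tuple[tuple[float, ...], ...]:
        if self.target_angles is not None:
            return tuple(tuple(s) for s in self.target_angles)
        # 20-36 locations per study, alternating grids across studies
        out = []
        for s in range(self.n_studies):
            n = (20, 24, 28, 32, 36, 24)[s % 6]
            out.append(tuple(default_target_angles(n, offset=7.5 + 2.0 * (s % 3))))
        return tuple(out)

    def resolved_amplitudes(self) -> tuple[float, ...]:
        if self.target_amplitude is not None:
            return tuple(self.target_amplitude)
        return tuple(5.0 + 0.5 * (s % 3) for s in range(self.n_studies))


@dataclass
class GroundTruth:
    """True per-participant parameters and, after ``generate_activity``, the
    true activity model (per-network effects and study intercepts)."""

    participants: pd.DataFrame
    nu_by_study: dict
    activity_effects: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "participants": self.participants.to_dict(orient="records"),
            "nu_by_study": self.nu_by_study,
            "activity_effects": self.activity_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _calibrate_latent_corr(target: float, s_lsm: float, m_lam: float, s_lam: float,
                           m_lsm: float) -> float:
    """Find the Gaussian correlation between log sigma_M and logit lambda that
    yields corr(sigma_M, 1-lambda) == target, by bisection on a fixed
    quasi-random sample (deterministic)."""
    if s_lsm == 0 or s_lam == 0:
        return 0.0
    rng = np.random.default_rng(987654321)
    z = rng.standard_normal((20000, 2))

    def achieved(c: float) -> float:
        z2 = c * z[:, 0] + np.sqrt(max(0.0, 1 - c * c)) * z[:, 1]
        sig_m = np.exp(m_lsm + s_lsm * z[:, 0])
        lam = 1.0 / (1.0 + np.exp(-(m_lam + s_lam * z2)))
        return float(np.corrcoef(sig_m, 1.0 - lam)[0, 1])

    lo, hi = -0.999, 0.999
    # corr(sigma_M, 1-lambda) decreases as the Gaussian corr c increases
    # (higher lambda means lower bias), so bisect on -achieved
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if achieved(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_behavior(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a trial table and its ground truth.

    Response angles follow the category-adjustment Student-t; non-outlier
    response amplitudes scatter tightly around the target amplitude; outlier
    trials (rate ``config.outlier_rate``) get a uniform angle within +-180 deg
    of the target and a uniform amplitude in [0.3, 2] x target amplitude, and
    are flagged in the output.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m_lsm, s_lsm = config.sigma_m_pop
    m_lam, s_lam = config.lambda_pop
    c = _calibrate_latent_corr(config.latent_corr, s_lsm, m_lam, s_lam, m_lsm)

    angles = config.resolved_angles()
    amps = config.resolved_amplitudes()

    part_rows = []
    trial_rows = []
    for s in range(config.n_studies):
        study_id = f"study-{s + 1:02d}"
        nu = float(config.nu_true)
        for j in range(config.participants_per_study[s]):
            pid = f"{study_id}_p{j + 1:03d}"
            z1, zi = rng.standard_normal(2)
            sigma_m = float(np.exp(m_lsm + s_lsm * z1))
            if config.sigma_p_pop is not None:
                m_lsp, s_lsp = config.sigma_p_pop
                sigma_p = float(np.exp(rng.normal(m_lsp, s_lsp)))
                lam = float(sigma_p**2 / (sigma_p**2 + sigma_m**2))
            else:
                z2 = c * z1 + np.sqrt(max(0.0, 1 - c * c)) * zi
                lam = float(1.0 / (1.0 + np.exp(-(m_lam + s_lam * z2))))
                sigma_p = sigma_m * np.sqrt(lam / (1.0 - lam))
            part_rows.append(dict(
                study_id=study_id, participant_id=pid,
                sigma_M_true=sigma_m, sigma_P_true=float(sigma_p),
                lambda_true=lam, nu_true=nu,
            ))

            n = config.trials_per_participant
            mu = rng.choice(angles[s], size=n)
            _, rho = assign_quadrant(mu)
            amp = amps[s]
            is_outlier = rng.random(n) < config.outlier_rate

            loc = lam * mu + (1.0 - lam) * rho
            scale = np.sqrt(lam) * sigma_m
            resp_angle = loc + scale * rng.standard_t(nu, size=n)
            resp_amp = amp * np.exp(rng.normal(0.0, config.amp_ratio_sd, size=n))

            n_out = int(is_outlier.sum())
            if n_out:
                resp_angle[is_outlier] = mu[is_outlier] + rng.uniform(-180.0, 180.0, n_out)
                resp_amp[is_outlier] = amp * rng.uniform(0.3, 2.0, n_out)

            trial_rows.append(pd.DataFrame(dict(
                study_id=study_id, participant_id=pid, trial=np.arange(n),
                target_angle_deg=mu, target_amp_dva=amp,
                response_angle_deg=np.mod(resp_angle, 360.0),
                response_amp_dva=resp_amp,
                is_injected_outlier=is_outlier,
            )))

    trials = pd.concat(trial_rows, ignore_index=True)
    truth = GroundTruth(
        participants=pd.DataFrame(part_rows),
        nu_by_study={f"study-{s + 1:02d}": float(config.nu_true) for s in range(config.n_studies)},
    )
    return trials, truth


def generate_activity(
    truth: GroundTruth,
    b1: float | dict = 0.4,
    b2: float | dict = -0.2,
    noise_sd: float | dict = 1.0,
    networks: tuple[str, ...] = NETWORKS,
    phases: tuple[str, ...] = PHASES,
    nu_noise: float = 30.0,
    intercept_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-network, per-phase activity linearly tied to behavior.

    ``beta = a_study + b1 * z(sigma_M_true) + b2 * z(1 - lambda_true) + t-noise``
    with both predictors standardized across all participants.  ``b1``, ``b2``
    and ``noise_sd`` may be scalars or per-network dicts.  Effects and study
    intercepts are recorded in ``truth.activity_effects``.
    """
    part = truth.participants
    if len(part) < 2:
        raise ValueError("activity generation needs >= 2 participants to standardize")
    rng = np.random.default_rng(seed)

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    z_inex = z(part["sigma_M_true"])
    z_bias = z(1.0 - part["lambda_true"])
    studies = sorted(part["study_id"].unique())
    intercepts = {s: float(rng.normal(0.0, intercept_sd)) for s in studies}
    a = part["study_id"].map(intercepts).to_numpy()

    def per_net(v, net):
        return float(v[net]) if isinstance(v, dict) else float(v)

    rows = []
    effects = {}
    for net in networks:
        bb1, bb2, nsd = per_net(b1, net), per_net(b2, net), per_net(noise_sd, net)
        effects[net] = {"b1": bb1, "b2": bb2, "noise_sd": nsd}
        for phase in phases:
            noise = nsd * rng.standard_t(nu_noise, size=len(part)) if nsd > 0 else 0.0
            beta = a + bb1 * z_inex + bb2 * z_bias + noise
            rows.append(pd.DataFrame(dict(
                participant_id=part["participant_id"], study_id=part["study_id"],
                network=net, phase=phase, beta=beta,
            )))
    truth.activity_effects = {"per_network": effects, "study_intercepts": intercepts}
    return pd.concat(rows, ignore_index=True)


def generate_timeseries(
    events: pd.DataFrame,
    betas: dict,
    tr: float,
    n_frames: int,
    ar1: float = 0.0,
    noise_sd: float = 0.0,
    n_units: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Simulate BOLD as ``X @ beta`` plus AR(1) noise.

    ``X`` is built by :func:`camwm.glm.build_design` on the same events, so a
    noiseless series is recovered exactly by the GLM stage.  ``betas`` maps
    regressor label -> coefficient (per unit scalars; unlisted regressors get
    0).  Returns a ``n_frames x n_units`` matrix.
    """
    from .glm import build_design  # local import to avoid a cycle

    design = build_design(events, tr=tr, n_frames=n_frames)
    if np.any(events["onset"] + events["duration"] > tr * n_frames):
        raise ValueError("events extend past the end of the scan")
    b = np.array([betas.get(lab, 0.0) for lab in design.labels], dtype=float)
    signal = design.matrix @ b

    rng = np.random.default_rng(seed)
    y = np.tile(signal[:, None], (1, n_units))
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=(n_frames, n_units))
        if ar1 != 0.0:
            for t in range(1, n_frames):
                eps[t] += ar1 * eps[t - 1]
        y = y + eps
    return y
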