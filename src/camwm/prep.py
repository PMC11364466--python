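"""Behavioral preprocessing: screen-to-visual-angle conversion, polar error
decomposition, quadrant/prototype assignment, trial exclusion, and bias summaries.

Angle convention
----------------
All angles are in degrees, measured counter-clockwise from the positive x-axis
with the screen center as origin and the y-axis pointing up; stored angles live
in [0, 360).  Signed angular errors are wrapped to (-180, 180], positive =
counter-clockwise.  Quadrant 1 is the open interval (0, 90) with prototype 45,
quadrant 2 is (90, 180) with prototype 135, and so on.  Target locations on the
cardinal axes (0, 90, 180, 270) have no defined quadrant and raise an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "FilterConfig",
    "FilterReport",
    "wrap_angle",
    "px_to_dva",
    "polar_error",
    "assign_quadrant",
    "cartesian_to_polar",
    "compute_trial_errors",
    "filter_trials",
    "summarize_bias",
    "distance_to_boundary",
]

CARDINALS = (0.0, 90.0, 180.0, 270.0)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen description used to convert pixels to degrees of visual angle."""

    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")
        px, py = self.pitch_cm_per_px
        if abs(px - py) > 0.05 * max(px, py):
            warnings.warn(
                f"anisotropic pixel pitch: {px:.5f} cm/px (x) vs {py:.5f} cm/px (y)",
                stacklevel=2,
            )

    @property
    def pitch_cm_per_px(self) -> tuple[float, float]:
        return self.width_cm / self.width_px, self.height_cm / self.height_px


@dataclass(frozen=True)
class FilterConfig:
    """Trial-exclusion rules.

    A trial is excluded iff its absolute angular error exceeds
    ``max_abs_angular_error``, its response/target amplitude ratio falls outside
    the closed interval ``amplitude_ratio_range``, or (when ``quadrant_rule``)
    the response lies outside the target's quadrant.  Boundary values are kept:
    only strict violations exclude.
    """

    max_abs_angular_error: float = 45.0
    amplitude_ratio_range: tuple[float, float] = (0.5, 1.75)
    quadrant_rule: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_ratio_range
        if not lo < hi:
            raise ValueError("amplitude_ratio_range must be an increasing interval")
        if self.max_abs_angular_error <= 0:
            raise ValueError("max_abs_angular_error must be positive")


@dataclass
class FilterReport:
    """Per-rule and per-participant accounting of excluded trials."""

    n_input: int = 0
    n_kept: int = 0
    n_excluded: int = 0
    rule_counts: dict = field(default_factory=dict)
    per_participant: pd.DataFrame | None = None
    mean_exclusion_pct: float = float("nan")
    excluded_trials: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_excluded": self.n_excluded,
            "rule_counts": self.rule_counts,
            "mean_exclusion_pct": self.mean_exclusion_pct,
            "per_participant": (
                self.per_participant.to_dict(orient="records")
                if self.per_participant is not None
                else []
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


def px_to_dva(x_px, y_px, geom: ScreenGeometry):
    """Convert pixel offsets from screen center to degrees of visual angle.

    Each axis offset ``d_cm`` maps to ``atan(d_cm / viewing_distance)``; this is
    exact per axis (no small-angle approximation).
    """
    px, py = geom.pitch_cm_per_px
    x_cm = np.asarray(x_px, dtype=float) * px
    y_cm = np.asarray(y_px, dtype=float) * py
    d = geom.viewing_distance_cm
    return np.degrees(np.arctan2(x_cm, d)), np.degrees(np.arctan2(y_cm, d))


def polar_error(target_angle, target_amp, response_angle, response_amp):
    """Decompose a response into signed angular error and amplitude ratio.

    Returns ``(angular_error, amplitude_ratio)`` where the angular error is
    response minus target wrapped to (-180, 180] (positive = counter-clockwise)
    and the ratio is response amplitude over target amplitude.
    """
    target_amp = np.asarray(target_amp, dtype=float)
    response_amp = np.asarray(response_amp, dtype=float)
    if np.any(target_amp <= 0) or np.any(response_amp <= 0):
        raise ValueError("amplitudes must be positive")
    err = wrap_angle(np.asarray(response_angle, dtype=float) - np.asarray(target_angle, dtype=float))
    return err, response_amp / target_amp


def assign_quadrant(angle):
    """Map an angle to its screen quadrant and the quadrant's diagonal prototype.

    Quadrants are the four open sectors delimited by the cardinal axes,
    numbered counter-clockwise from the positive x-axis; the prototype is the
    quadrant diagonal (45, 135, 225 or 315 degrees).  Cardinal-axis angles have
    no quadrant and raise ``ValueError``.
    """
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if np.any(np.isclose(np.mod(a, 90.0), 0.0, atol=1e-9)):
        bad = a[np.isclose(np.mod(a, 90.0), 0.0, atol=1e-9)]
        raise ValueError(f"angle(s) on a cardinal axis have no quadrant: {np.unique(bad)}")
    quadrant = np.floor_divide(a, 90.0).astype(int) + 1
    prototype = 45.0 + 90.0 * (quadrant - 1)
    if scalar:
        return int(quadrant[0]), float(prototype[0])
    return quadrant, prototype


def cartesian_to_polar(x_dva, y_dva):
    """Convert °va screen coordinates (center origin, y up) to (angle in [0,360), amplitude)."""
    x = np.asarray(x_dva, dtype=float)
    y = np.asarray(y_dva, dtype=float)
    angle = np.mod(np.degrees(np.arctan2(y, x)), 360.0)
    return angle, np.hypot(x, y)


def distance_to_boundary(angle):
    """Angular distance (degrees) from an angle to the nearest cardinal axis."""
    m = np.mod(np.asarray(angle, dtype=float), 90.0)
    return np.minimum(m, 90.0 - m)


def compute_trial_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Annotate a trial table with polar errors, quadrants and prototypes.

    Expects columns ``target_angle_deg``, ``target_amp_dva``,
    ``response_angle_deg``, ``response_amp_dva``; adds ``angular_error``,
    ``amplitude_ratio``, ``quadrant``, ``prototype_angle``,
    ``response_quadrant`` (0 where the response sits on a cardinal axis) and
    ``boundary_distance``.
    """
    out = trials.copy()
    err, ratio = polar_error(
        out["target_angle_deg"], out["target_amp_dva"],
        out["response_angle_deg"], out["response_amp_dva"],
    )
    out["angular_error"] = err
    out["amplitude_ratio"] = ratio
    quadrant, prototype = assign_quadrant(out["target_angle_deg"].to_numpy())
    out["quadrant"] = quadrant
    out["prototype_angle"] = prototype
    resp = np.mod(out["response_angle_deg"].to_numpy(dtype=float), 360.0)
    on_axis = np.isclose(np.mod(resp, 90.0), 0.0, atol=1e-9)
    rq = np.floor_divide(resp, 90.0).astype(int) + 1
    rq[on_axis] = 0  # responses may land on an axis; that never matches any target quadrant
    out["response_quadrant"] = rq
    out["boundary_distance"] = distance_to_boundary(out["target_angle_deg"].to_numpy())
    return out


RULE_ANGULAR = "angular_error_gt_max"
RULE_AMPLITUDE = "amplitude_ratio_out_of_range"
RULE_QUADRANT = "response_outside_target_quadrant"


def filter_trials(trials: pd.DataFrame, cfg: FilterConfig | None = None):
    """Apply the exclusion rules and return ``(kept, FilterReport)``.

    Every rule is evaluated for every trial and all violated rules are recorded
    (semicolon-joined in ``exclusion_reasons``), so the report can separate
    e.g. pure quadrant misclassifications from large angular errors.
    An empty input yields an empty kept table and an empty report.
    """
    cfg = cfg or FilterConfig()
    if len(trials) == 0:
        empty = trials.copy()
        return empty, FilterReport(per_participant=pd.DataFrame(
            columns=["study_id", "participant_id", "n_input", "n_excluded", "exclusion_pct"]))

    if "angular_error" not in trials.columns:
        trials = compute_trial_errors(trials)
    df = trials.copy()

    viol_ang = np.abs(df["angular_error"].to_numpy()) > cfg.max_abs_angular_error
    lo, hi = cfg.amplitude_ratio_range
    ratio = df["amplitude_ratio"].to_numpy()
    viol_amp = (ratio < lo) | (ratio > hi)
    if cfg.quadrant_rule:
        viol_quad = df["response_quadrant"].to_numpy() != df["quadrant"].to_numpy()
    else:
        viol_quad = np.zeros(len(df), dtype=bool)

    reasons = []
    for a, m, q in zip(viol_ang, viol_amp, viol_quad):
        r = []
        if a:
            r.append(RULE_ANGULAR)
        if m:
            r.append(RULE_AMPLITUDE)
        if q:
            r.append(RULE_QUADRANT)
        reasons.append(";".join(r))
    excluded = viol_ang | viol_amp | viol_quad
    df["excluded"] = excluded
    df["exclusion_reasons"] = reasons

    keys = [k for k in ("study_id", "participant_id") if k in df.columns]
    if keys:
        per = (
            df.assign(n_excluded=excluded.astype(int))
            .groupby(keys, sort=True)
            .agg(n_input=("excluded", "size"), n_excluded=("n_excluded", "sum"))
            .reset_index()
        )
        per["exclusion_pct"] = 100.0 * per["n_excluded"] / per["n_input"]
        mean_pct = float(per["exclusion_pct"].mean())
    else:
        per = pd.DataFrame()
        mean_pct = 100.0 * excluded.mean()

    report = FilterReport(
        n_input=int(len(df)),
        n_kept=int((~excluded).sum()),
        n_excluded=int(excluded.sum()),
        rule_counts={
            RULE_ANGULAR: int(viol_ang.sum()),
            RULE_AMPLITUDE: int(viol_amp.sum()),
            RULE_QUADRANT: int(viol_quad.sum()),
        },
        per_participant=per,
        mean_exclusion_pct=mean_pct,
        excluded_trials=df.loc[excluded].copy(),
    )
    kept = df.loc[~excluded].drop(columns=["excluded", "exclusion_reasons"]).copy()
    return kept, report


def summarize_bias(kept: pd.DataFrame, by_study: bool = False) -> pd.DataFrame:
    """Mean signed bias toward the prototype per target angle.

    The bias on a trial is the angular error projected onto the
    target-to-prototype direction: positive when the response is displaced from
    the target toward the quadrant diagonal.  Returns a table with
    ``target_angle_deg``, ``n_trials``, ``mean_bias_toward_prototype`` and
    ``mean_angular_error`` (optionally per study).
    """
    df = kept if "angular_error" in kept.columns else compute_trial_errors(kept)
    toward = np.sign(wrap_angle(df["prototype_angle"] - df["target_angle_deg"]))
    bias = df["angular_error"].to_numpy() * toward
    work = df.assign(bias_toward_prototype=bias)
    keys = ["target_angle_deg"]
    if by_study and "study_id" in work.columns:
        keys = ["study_id"] + keys
    out = (
        work.groupby(keys, sort=True)
        .agg(
            n_trials=("bias_toward_prototype", "size"),
            mean_bias_toward_prototype=("bias_toward_prototype", "mean"),
            mean_angular_error=("angular_error", "mean"),
        )
        .reset_index()
    )
    return out
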