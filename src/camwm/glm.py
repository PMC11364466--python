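"""Task-phase GLM on parcellated time-series.

Builds design matrices with assumed-HRF phase regressors (double-gamma),
unassumed FIR columns for behaviorally flagged outlier trials, an 18-column
motion nuisance set (parameters, first derivatives, squares), intercept and
linear drift; estimates betas by ordinary least squares; averages region betas
into networks; and flags outlier participants by the correlation of their beta
maps with the group average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "double_gamma_hrf",
    "build_design",
    "estimate_betas",
    "aggregate_to_networks",
    "detect_outlier_participants",
]

PHASE_ORDER = ("encoding", "delay", "response", "cue")


def double_gamma_hrf(
    tr: float,
    length: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    oversample: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the canonical double-gamma HRF on a fine grid.

    The kernel is the difference of two gamma densities — response peak at
    ``peak_delay`` seconds and undershoot at ``undershoot_delay`` seconds (each
    with shape delay/dispersion and scale dispersion), mixed at
    ``ratio`` — normalized to a maximum of 1.  Returns ``(t, kernel)`` with
    ``t`` spaced at ``tr / oversample``.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    for name, v in (("peak_delay", peak_delay), ("undershoot_delay", undershoot_delay),
                    ("peak_disp", peak_disp), ("undershoot_disp", undershoot_disp)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    dt = tr / oversample
    t = np.arange(0.0, length + dt / 2, dt)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - ratio * under
    return t, h / np.max(h)


@dataclass
class DesignMatrix:
    """Frames x regressors matrix with column labels."""

    matrix: np.ndarray
    labels: list[str]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def _rank_check(x: np.ndarray, labels: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the offending columns via near-zero diagonal of R in a pivoted QR
        _, r, piv = _qr_pivoted(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [labels[piv[i]] for i in range(len(diag), x.shape[1])]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}")


def _qr_pivoted(x):
    from scipy.linalg import qr
    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_frames: int,
    motion: pd.DataFrame | np.ndarray | None = None,
    hrf_kwargs: dict | None = None,
    fir_post_s: float = 16.0,
    oversample: int = 16,
) -> DesignMatrix:
    """Construct the GLM design matrix.

    ``events`` needs columns ``phase``, ``onset`` (s), ``duration`` (s) and
    optionally ``is_outlier_trial``.  Non-outlier events become per-phase
    boxcars convolved with the double-gamma HRF; each outlier trial instead
    gets its own unassumed FIR set, one column per TR bin from trial onset to
    offset + ``fir_post_s``.  Motion (6 columns) expands to 18 nuisance
    regressors; an intercept and a linear drift close the matrix.
    """
    if tr <= 0 or n_frames < 1:
        raise ValueError("TR must be positive and n_frames >= 1")
    scan_end = tr * n_frames
    if len(events) and np.any(events["onset"].to_numpy() < 0):
        raise ValueError("event onsets must be non-negative")
    if len(events) and np.any(events["onset"].to_numpy() >= scan_end):
        raise ValueError("event onsets must fall within the scan")

    dt = tr / oversample
    hi_n = n_frames * oversample
    frame_idx = np.arange(n_frames) * oversample
    _, hrf = double_gamma_hrf(tr, oversample=oversample, **(hrf_kwargs or {}))

    cols: list[np.ndarray] = []
    labels: list[str] = []

    out_flag = (events["is_outlier_trial"].to_numpy(dtype=bool)
                if "is_outlier_trial" in events.columns
                else np.zeros(len(events), dtype=bool))

    phases = [p for p in PHASE_ORDER if p in set(events.loc[~out_flag, "phase"])]
    for phase in phases:
        sel = events.loc[(events["phase"] == phase) & ~out_flag]
        box = np.zeros(hi_n)
        for onset, dur in zip(sel["onset"], sel["duration"]):
            i0 = int(round(onset / dt))
            i1 = min(int(round((onset + dur) / dt)), hi_n)
            box[i0:max(i1, i0 + 1)] = 1.0
        conv = np.convolve(box, hrf)[:hi_n]
        cols.append(conv[frame_idx])
        labels.append(f"phase:{phase}")

    # unassumed (FIR) modeling per outlier trial: the trial contributes nothing
    # to the phase regressors above and is absorbed by its own bin indicators
    frame_times = np.arange(n_frames) * tr
    if out_flag.any():
        for tix, sub in events.loc[out_flag].groupby(
                events.loc[out_flag].get("trial_index", events.loc[out_flag].index)):
            t0 = float(sub["onset"].min())
            t1 = float((sub["onset"] + sub["duration"]).max()) + fir_post_s
            n_bins = int(np.ceil((t1 - t0) / tr))
            for k in range(n_bins):
                col = ((frame_times >= t0 + k * tr) & (frame_times < t0 + (k + 1) * tr)
                       ).astype(float)
                if col.any():
                    cols.append(col)
                    labels.append(f"fir:trial{tix}:bin{k}")

    if motion is not None:
        m = np.asarray(motion, dtype=float)
        if m.ndim != 2 or m.shape[0] != n_frames or m.shape[1] != 6:
            raise ValueError("motion must be an n_frames x 6 array")
        deriv = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
        for block, tag in ((m, "mot"), (deriv, "dmot"), (m**2, "mot2")):
            for i in range(6):
                cols.append(block[:, i])
                labels.append(f"{tag}:{i}")

    cols.append(np.ones(n_frames))
    labels.append("intercept")
    drift = np.linspace(-0.5, 0.5, n_frames) if n_frames > 1 else np.zeros(1)
    cols.append(drift)
    labels.append("drift")

    x = np.column_stack(cols)
    _rank_check(x, labels)
    return DesignMatrix(matrix=x, labels=labels)


def estimate_betas(bold: np.ndarray, design: DesignMatrix,
                   unit_labels: list[str] | None = None,
                   mask_nan: bool = False):
    """Ordinary least squares per unit.

    ``bold`` is frames x units.  Returns ``(betas, resid_var)``: a DataFrame of
    regressor x unit coefficients and the per-unit residual variance
    (denominator frames - rank).  NaNs raise unless ``mask_nan`` drops the
    offending frames per unit.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 1:
        bold = bold[:, None]
    if bold.shape[0] != design.n_frames:
        raise ValueError("BOLD frame count does not match the design")
    units = unit_labels or [f"unit{i}" for i in range(bold.shape[1])]
    x = design.matrix
    dof = x.shape[0] - x.shape[1]

    if np.isnan(bold).any():
        if not mask_nan:
            raise ValueError("NaNs in BOLD; pass mask_nan=True to drop those frames")
        b = np.empty((x.shape[1], bold.shape[1]))
        rv = np.empty(bold.shape[1])
        for k in range(bold.shape[1]):
            good = ~np.isnan(bold[:, k])
            bk, res, *_ = np.linalg.lstsq(x[good], bold[good, k], rcond=None)
            b[:, k] = bk
            resid = bold[good, k] - x[good] @ bk
            rv[k] = resid @ resid / max(good.sum() - x.shape[1], 1)
    else:
        b, _, _, _ = np.linalg.lstsq(x, bold, rcond=None)
        resid = bold - x @ b
        rv = (resid**2).sum(axis=0) / max(dof, 1)

    betas = pd.DataFrame(b, index=design.labels, columns=units)
    return betas, pd.Series(rv, index=units, name="resid_var")


def betas_to_table(betas: pd.DataFrame, participant_id: str, study_id: str) -> pd.DataFrame:
    """Long-form BetaTable (participant, study, unit, phase, beta) from the
    phase rows of an ``estimate_betas`` result."""
    rows = []
    for label in betas.index:
        if not label.startswith("phase:"):
            continue
        phase = label.split(":", 1)[1]
        for unit in betas.columns:
            rows.append(dict(participant_id=participant_id, study_id=study_id,
                             unit=unit, phase=phase, beta=float(betas.loc[label, unit])))
    return pd.DataFrame(rows)


def aggregate_to_networks(betas: pd.DataFrame, partition: dict[str, str]) -> pd.DataFrame:
    """Average region-level betas into networks (unweighted mean).

    ``betas`` is a long table with a ``unit`` column of region names; every
    region must appear in ``partition`` (region -> network) or an error lists
    the missing ones.
    """
    units = set(betas["unit"].unique())
    missing = sorted(units - set(partition))
    if missing:
        raise KeyError(f"regions missing from the partition: {missing}")
    out = betas.copy()
    out["unit"] = out["unit"].map(partition)
    keys = [c for c in ("participant_id", "study_id", "unit", "phase") if c in out.columns]
    return out.groupby(keys, sort=True, as_index=False)["beta"].mean()


def detect_outlier_participants(
    betas: pd.DataFrame,
    threshold_sd: float = 3.0,
    leave_one_out: bool = False,
):
    """Flag participants whose beta maps decorrelate from the group average.

    For each phase, each participant's unit-wise beta vector is correlated with
    the group-average vector (including the candidate unless
    ``leave_one_out``); a participant is excluded when any phase correlation
    deviates from that phase's mean correlation by more than ``threshold_sd``
    standard deviations.  Zero spread (all maps identical) excludes no one;
    zero-variance beta vectors make the correlation undefined and put the
    participant on a review list instead of silently dropping them.
    Returns ``(excluded, review, corr_table)``.
    """
    participants = sorted(betas["participant_id"].unique())
    if len(participants) < 3:
        raise ValueError("outlier detection needs at least 3 participants")
    rows = []
    review = set()
    for phase, sub in betas.groupby("phase"):
        mat = sub.pivot_table(index="participant_id", columns="unit", values="beta")
        mat = mat.loc[sorted(mat.index)]
        vals = mat.to_numpy()
        for i, pid in enumerate(mat.index):
            group = np.delete(vals, i, axis=0).mean(axis=0) if leave_one_out else vals.mean(axis=0)
            v = vals[i]
            if np.std(v) == 0 or np.std(group) == 0:
                review.add(pid)
                rows.append(dict(phase=phase, participant_id=pid, correlation=np.nan))
            else:
                rows.append(dict(phase=phase, participant_id=pid,
                                 correlation=float(np.corrcoef(v, group)[0, 1])))
    corr = pd.DataFrame(rows)

    excluded = set()
    if np.isfinite(threshold_sd):
        for phase, sub in corr.dropna().groupby("phase"):
            c = sub["correlation"].to_numpy()
            sd = c.std()
            if sd == 0:
                continue
            dev = np.abs(c - c.mean())
            for pid in sub.loc[dev > threshold_sd * sd, "participant_id"]:
                excluded.add(pid)
    return sorted(excluded), sorted(review), corr
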