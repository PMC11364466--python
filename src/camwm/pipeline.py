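"""End-to-end orchestration: simulate -> prep -> CAM -> GLM -> association ->
power -> report, with a manifest recording seeds, versions and file digests.

The global seed fans out to per-stage seeds as ``seed + STAGE_OFFSET[stage]``
so any stage can be rerun in isolation yet reproducibly.  All interchange is
TSV/JSON; every output table round-trips through ``pandas.read_csv``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bb import BBConfig, correlate_measures, fit_all_networks, summarize_bb
from .cam import CAMConfig, derive_measures, fit_cam_by_study
from .power import PowerConfig, resample_power, summarize_stability
from .prep import FilterConfig, compute_trial_errors, filter_trials, summarize_bias
from .synth import CohortConfig, generate_activity, generate_behavior

log = logging.getLogger("camwm")

STAGE_OFFSET = {"simulate": 11, "prep": 23, "cam": 37, "glm": 53,
                "associate": 71, "power": 97}

STAGES = ("simulate", "prep", "cam", "glm", "associate", "power", "report")


@dataclass
class RunConfig:
    """Declarative run description; see ``RunConfig.from_yaml``."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    cam: CAMConfig = field(default_factory=CAMConfig)
    bb: BBConfig = field(default_factory=BBConfig)
    power: PowerConfig = field(default_factory=PowerConfig)
    activity_b1: float = 0.4
    activity_b2: float = -0.2
    activity_noise_sd: float = 1.0
    activity_networks: tuple[str, ...] | None = None  # None -> all four default networks
    activity_phases: tuple[str, ...] | None = None
    power_network: str = "frontoparietal"
    power_phase: str = "delay"
    trials_path: Path | None = None   # skip simulate and read this table instead
    activity_path: Path | None = None  # skip glm/simulated activity
    bold_dir: Path | None = None       # per-participant BOLD + events for the glm stage
    partition_path: Path | None = None  # region -> network map (JSON) for aggregation

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        problems = []
        known = set(cls.__dataclass_fields__)
        for key in raw:
            if key not in known:
                problems.append(f"unknown config key: {key}")
        if "out_dir" not in raw:
            problems.append("missing required key: out_dir")
        for key in ("trials_path", "activity_path"):
            if raw.get(key) and not Path(raw[key]).exists():
                problems.append(f"{key} does not exist: {raw[key]}")
        if problems:
            raise ValueError("invalid run config:\n  " + "\n  ".join(problems))
        for name, sub_cls in (("cohort", CohortConfig), ("filters", FilterConfig),
                              ("cam", CAMConfig), ("bb", BBConfig), ("power", PowerConfig)):
            if name in raw and isinstance(raw[name], dict):
                raw[name] = sub_cls(**raw[name])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return int(self.seed + STAGE_OFFSET.get(stage, 0))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Each stage writes its tables before the next starts, so a failed run can
    resume by rerunning with a subset of stages against the same directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": list(config.stages), "outputs": {}}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256_16": _digest(path)}

    trials = truth = None
    if "simulate" in config.stages:
        log.info("stage simulate")
        cohort = CohortConfig(**{**config.cohort.__dict__,
                                 "seed": config.stage_seed("simulate")})
        trials, truth = generate_behavior(cohort)
        _write_tsv(trials, out / "trials.tsv")
        from .synth import NETWORKS, PHASES
        activity = generate_activity(
            truth, b1=config.activity_b1, b2=config.activity_b2,
            noise_sd=config.activity_noise_sd,
            networks=tuple(config.activity_networks or NETWORKS),
            phases=tuple(config.activity_phases or PHASES),
            seed=config.stage_seed("simulate") + 1)
        _write_tsv(activity, out / "activity.tsv")
        truth.to_json(out / "ground_truth.json")
        record("trials", out / "trials.tsv")
        record("activity", out / "activity.tsv")
        record("ground_truth", out / "ground_truth.json")
    elif config.trials_path is not None:
        trials = pd.read_csv(config.trials_path, sep="\t")

    kept = None
    if "prep" in config.stages:
        log.info("stage prep")
        if trials is None:
            trials = pd.read_csv(out / "trials.tsv", sep="\t")
        annotated = compute_trial_errors(trials)
        kept, report = filter_trials(annotated, config.filters)
        _write_tsv(kept, out / "trials_kept.tsv")
        report.to_json(out / "filter_report.json")
        _write_tsv(summarize_bias(kept, by_study=True), out / "bias_by_angle.tsv")
        record("trials_kept", out / "trials_kept.tsv")
        record("bias_by_angle", out / "bias_by_angle.tsv")

    measures = None
    if "cam" in config.stages:
        log.info("stage cam")
        if kept is None:
            kept = pd.read_csv(out / "trials_kept.tsv", sep="\t")
        cam_cfg = CAMConfig(**{**config.cam.__dict__, "seed": config.stage_seed("cam")})
        fits = fit_cam_by_study(kept, cam_cfg)
        measures = derive_measures(fits)
        _write_tsv(measures, out / "behavioral_measures.tsv")
        diag = {s: p.diagnostics.get("convergence", {}) for s, p in fits.items()}
        (out / "cam_diagnostics.json").write_text(json.dumps(diag, indent=2, default=str))
        # persist a compact draws file: study-level parameters at a 16-chain
        # subsample (per-participant posteriors are summarized in the measures
        # table; full draws stay in memory for interactive use)
        frames = []
        for s, p in fits.items():
            keep = [k for k in p.draws
                    if k in ("mu_log_sigma_m", "mu_log_sigma_p",
                             "log_tau_m", "log_tau_p", "nu")]
            sub = {k: p.draws[k][:16] for k in keep}
            from .sampling import EnsemblePosterior
            frames.append(EnsemblePosterior(draws=sub).to_dataframe().assign(study_id=s))
        pd.concat(frames, ignore_index=True).to_csv(out / "cam_draws.tsv",
                                                    sep="\t", index=False)
        record("behavioral_measures", out / "behavioral_measures.tsv")
        r, p = correlate_measures(measures["memory_inexactness"], measures["prototype_bias"])
        (out / "measure_correlation.json").write_text(
            json.dumps({"pearson_r": r, "p_value": p, "n": len(measures)}, indent=2))
        record("measure_correlation", out / "measure_correlation.json")

    if "glm" in config.stages and config.bold_dir is not None:
        log.info("stage glm")
        from .glm import aggregate_to_networks, betas_to_table, build_design, estimate_betas

        bold_dir = Path(config.bold_dir)
        tables = []
        for meta_path in sorted(bold_dir.glob("*_meta.json")):
            meta = json.loads(meta_path.read_text())
            pid = meta["participant_id"]
            bold = pd.read_csv(bold_dir / f"{pid}_bold.tsv", sep="\t")
            events = pd.read_csv(bold_dir / f"{pid}_events.tsv", sep="\t")
            motion_path = bold_dir / f"{pid}_motion.tsv"
            motion = (pd.read_csv(motion_path, sep="\t").to_numpy()
                      if motion_path.exists() else None)
            design = build_design(events, tr=meta["tr"], n_frames=len(bold), motion=motion)
            betas, _ = estimate_betas(bold.to_numpy(), design,
                                      unit_labels=list(bold.columns))
            tables.append(betas_to_table(betas, pid, meta.get("study_id", "study-01")))
        glm_activity = pd.concat(tables, ignore_index=True)
        if config.partition_path is not None:
            partition = json.loads(Path(config.partition_path).read_text())
            glm_activity = aggregate_to_networks(glm_activity, partition)
        glm_activity = glm_activity.rename(columns={"unit": "network"})
        _write_tsv(glm_activity, out / "activity.tsv")
        record("activity", out / "activity.tsv")

    activity = None
    if "associate" in config.stages:
        log.info("stage associate")
        if measures is None:
            measures = pd.read_csv(out / "behavioral_measures.tsv", sep="\t")
        apath = config.activity_path or out / "activity.tsv"
        activity = pd.read_csv(apath, sep="\t")
        bb_cfg = BBConfig(**{**config.bb.__dict__, "seed": config.stage_seed("associate")})
        fits = fit_all_networks(activity, measures, bb_cfg)
        summary = summarize_bb(fits)
        _write_tsv(summary, out / "brain_behavior_summary.tsv")
        record("brain_behavior_summary", out / "brain_behavior_summary.tsv")

    if "power" in config.stages:
        log.info("stage power")
        if measures is None:
            measures = pd.read_csv(out / "behavioral_measures.tsv", sep="\t")
        if activity is None:
            activity = pd.read_csv(config.activity_path or out / "activity.tsv", sep="\t")
        pw_cfg = PowerConfig(**{**config.power.__dict__, "seed": config.stage_seed("power")})
        curve = resample_power(activity, measures, network=config.power_network,
                               phase=config.power_phase, cfg=pw_cfg)
        _write_tsv(curve, out / "power_curve.tsv")
        _write_tsv(summarize_stability(curve), out / "power_stability.tsv")
        record("power_curve", out / "power_curve.tsv")
        record("power_stability", out / "power_stability.tsv")

    if "report" in config.stages:
        log.info("stage report")
        make_report(out)
        record("report", out / "report.md")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def make_report(run_dir) -> Path:
    """Assemble a Markdown report (with figures where matplotlib succeeds)
    from whatever stage outputs exist; missing outputs become notices."""
    run_dir = Path(run_dir)
    lines = ["# camwm run report", ""]

    def panel(title: str, fname: str, renderer) -> None:
        lines.append(f"## {title}")
        path = run_dir / fname
        if not path.exists():
            lines.append(f"_not available: {fname} missing_")
            lines.append("")
            return
        try:
            renderer(path)
        except Exception as exc:  # pragma: no cover - plotting best effort
            lines.append(f"_panel failed: {exc}_")
        lines.append("")

    def bias_panel(path):
        df = pd.read_csv(path, sep="\t")
        fig_path = run_dir / "fig_bias_by_angle.png"
        _plot_bias(df, fig_path)
        lines.append(f"![bias by angle]({fig_path.name})")
        lines.append(f"{len(df)} angle bins; mean bias toward prototype "
                     f"{df['mean_bias_toward_prototype'].mean():.2f} deg")

    def measures_panel(path):
        df = pd.read_csv(path, sep="\t")
        corr_path = run_dir / "measure_correlation.json"
        if corr_path.exists():
            corr = json.loads(corr_path.read_text())
            lines.append(f"n = {len(df)} participants; Pearson r between memory "
                         f"inexactness and prototype bias = {corr['pearson_r']:.3f} "
                         f"(p = {corr['p_value']:.2e})")
        fig_path = run_dir / "fig_measures.png"
        _plot_measures(df, fig_path)
        lines.append(f"![measures]({fig_path.name})")

    def bb_panel(path):
        df = pd.read_csv(path, sep="\t")
        fig_path = run_dir / "fig_brain_behavior.png"
        _plot_bb(df, fig_path)
        lines.append(f"![brain-behavior]({fig_path.name})")
        lines.append(df.to_markdown(index=False, floatfmt=".3f"))

    def power_panel(path):
        df = pd.read_csv(path, sep="\t")
        fig_path = run_dir / "fig_power.png"
        _plot_power(df, fig_path)
        lines.append(f"![power]({fig_path.name})")

    panel("Bias by target angle", "bias_by_angle.tsv", bias_panel)
    panel("Behavioral measures", "behavioral_measures.tsv", measures_panel)
    panel("Brain-behavior associations", "brain_behavior_summary.tsv", bb_panel)
    panel("Bootstrap power", "power_curve.tsv", power_panel)

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _plot_bias(df, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for study, sub in df.groupby("study_id") if "study_id" in df.columns else [("all", df)]:
        ax.plot(sub["target_angle_deg"], sub["mean_bias_toward_prototype"],
                "o-", ms=3, lw=0.8, label=str(study))
    for diag in (45, 135, 225, 315):
        ax.axvline(diag, color="red", lw=0.5, alpha=0.5)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("target angle (deg)")
    ax.set_ylabel("bias toward prototype (deg)")
    ax.legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_measures(df, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(df["memory_inexactness"], df["prototype_bias"], s=12, alpha=0.7)
    ax.set_xlabel("memory inexactness (deg)")
    ax.set_ylabel("prototype bias (1 - lambda)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_bb(df, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    ylabels, k = [], 0
    for _, row in df.iterrows():
        ax.errorbar(row["mean"], k, xerr=[[row["mean"] - row["ci_low"]],
                                          [row["ci_high"] - row["mean"]]],
                    fmt="o", ms=3, color="tab:blue" if "inex" in row["coefficient"] else "tab:orange")
        ylabels.append(f"{row['network']}/{row['phase']}/{row['coefficient']}")
        k += 1
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_yticks(range(k), ylabels, fontsize=5)
    ax.set_xlabel("standardized coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_power(df, path):
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for coef, sub in df.groupby("coefficient"):
        ax.plot(sub["size"], sub["power"], "o-", label=coef)
    ax.set_xlabel("sample size")
    ax.set_ylabel("power (95% posterior mass on one side of 0)")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
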