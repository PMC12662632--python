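"""End-to-end analysis pipeline: simulate -> thresholds -> DS profiles ->
shape comparison -> channel fits -> mixture fits -> psychometric fits ->
group statistics, with a versioned report directory of CSV/JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import channels as ch
from . import experiments as ex
from . import mixture as mx
from . import psychometric as psy
from . import shapes as sh
from . import stats as st


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 24
    n_participants_adj: int = 20
    n_participants_disc: int = 18
    profile: str = "mexican"          # generative DS shape
    tasks: tuple = ("OD", "SFD")
    fast_thresholds: bool = False     # Gaussian staircase-noise mode
    shape_starts: int = 32
    channel_starts: int = 12
    run_channels: bool = True
    run_adjustment: bool = True
    run_discrimination: bool = True


def _profile_stage(thresholds: pd.DataFrame, cfg: PipelineConfig) -> dict:
    out = {}
    for task in cfg.tasks:
        ds_tidy = sh.ds_table(thresholds, task)
        group = sh.compute_ds(thresholds, task, level="group")
        wide = ds_tidy.pivot(index="participant", columns="distance", values="ds")
        anova = st.rm_anova_oneway(wide.to_numpy())
        post_0 = st.paired_t(wide[20.0], wide[0.0])
        post_40 = st.paired_t(wide[20.0], wide[40.0])
        comp = sh.compare_shapes(group, n_starts=cfg.shape_starts, seed=cfg.seed)
        favored = []
        for pid, row in wide.iterrows():
            prof = sh.SensitivityProfile(wide.columns.to_numpy(float),
                                         row.to_numpy(), task, "participant")
            c = sh.compare_shapes(prof, n_starts=cfg.shape_starts, seed=cfg.seed)
            favored.append(c["favored"])
        out[task] = {
            "ds_table": ds_tidy, "group_profile": group, "anova": anova,
            "t_d20_vs_d0": post_0, "t_d20_vs_d40": post_40,
            "group_comparison": comp,
            "n_mexican_favored": int(sum(f == "mexican" for f in favored)),
            "n_participants": len(favored),
        }
    return out


def _channel_stage(thresholds: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Group-level channel fits per task and condition, plus phase changes."""
    out = {}
    for task in cfg.tasks:
        sub = thresholds[thresholds.task == task]
        mean_dt = sub.groupby(["condition", "orientation"], as_index=False).dt.mean()
        fits = {}
        for cond in ("B20", "B70", "E20", "E70"):
            rows = mean_dt[mean_dt.condition == cond]
            prof = ch.build_population_profile(rows.orientation.to_numpy(),
                                               rows.dt.to_numpy(), cond)
            fits[cond] = {
                "sharpening": ch.fit_sharpening(prof, cfg.channel_starts, cfg.seed),
                "shift": ch.fit_shift(prof, cfg.channel_starts, cfg.seed),
            }
        changes = {}
        for anchor in ("20", "70"):
            b, e = fits[f"B{anchor}"], fits[f"E{anchor}"]
            changes[f"E{anchor}"] = {
                "sharpening": ch.channel_changes(b["sharpening"], e["sharpening"]),
                "shift": ch.channel_changes(b["shift"], e["shift"]),
            }
        shift70 = changes["E70"]["shift"].expectward_shift
        shift20 = -changes["E20"]["shift"].expectward_shift  # toward 20 = negative
        out[task] = {"fits": fits, "changes": changes,
                     "mean_shift": ch.mean_shift(shift70, shift20)}
    return out


def _adjustment_stage(cfg: PipelineConfig, master: np.random.SeedSequence) -> dict:
    trials = []
    for i, child in enumerate(master.spawn(cfg.n_participants_adj)):
        rng = np.random.default_rng(child)
        obs = ex.make_observer(rng, profile=cfg.profile)
        trials.append(ex.simulate_adjustment_experiment(obs, f"P{i:02d}", rng))
    trials = pd.concat(trials, ignore_index=True)
    per_part = []
    for (pid,), part in trials.groupby(["participant"]):
        fits_b, fits_m = {}, {}
        for (phase, cond, group), tr in part.groupby(
                ["phase", "condition", "delta_group"]):
            fit = mx.fit_mixture(tr.adjust_error.to_numpy(),
                                 condition=f"{cond}-{group}")
            key = f"E{cond[1:]}-{group}"
            (fits_b if phase == "baseline" else fits_m)[key] = fit
        deltas = mx.condition_deltas(fits_b, fits_m)
        per_part.append({"participant": pid, **{
            k: v for k, v in deltas.items() if k != "per_condition"}})
    table = pd.DataFrame(per_part)
    tests = {col: st.one_sample_t(table[col]) for col in table.columns
             if col != "participant"}
    return {"trials": trials, "per_participant": table, "tests": tests}


def _discrimination_stage(cfg: PipelineConfig, master: np.random.SeedSequence) -> dict:
    per_part = []
    for i, child in enumerate(master.spawn(cfg.n_participants_disc)):
        rng = np.random.default_rng(child)
        obs = ex.make_observer(rng, profile=cfg.profile)
        counts = ex.simulate_discrimination_experiment(obs, f"P{i:02d}", rng)
        fits_b, fits_m = {}, {}
        for (phase, cond, group), sub in counts.groupby(
                ["phase", "condition", "delta_group"]):
            data = ex.psychometric_data_from_counts(sub, f"{cond}-{group}")
            key = f"E{cond[1:]}-{group}"
            (fits_b if phase == "baseline" else fits_m)[key] = psy.fit_cumnorm(data)
        deltas = psy.psych_deltas(fits_b, fits_m)
        per_part.append({"participant": f"P{i:02d}", **{
            k: v for k, v in deltas.items() if k != "per_condition"}})
    table = pd.DataFrame(per_part)
    tests = {col: st.one_sample_t(table[col]) for col in table.columns
             if col != "participant"}
    return {"per_participant": table, "tests": tests}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage; optionally write the report bundle to ``outdir``.

    Returns a dict of stage results keyed by stage name; with ``outdir`` the
    tables are written as CSV, the fits and statistics as JSON, plus a run
    manifest recording the seed and configuration.
    """
    master = np.random.SeedSequence(config.seed)
    seq_profile, seq_adj, seq_disc = master.spawn(3)

    thresholds = ex.simulate_profile_cohort(
        config.n_participants, config.tasks, config.profile,
        seed=config.seed, fast=config.fast_thresholds)
    report = {"thresholds": thresholds,
              "profile": _profile_stage(thresholds, config)}
    if config.run_channels:
        report["channels"] = _channel_stage(thresholds, config)
    if config.run_adjustment:
        report["adjustment"] = _adjustment_stage(config, seq_adj)
    if config.run_discrimination:
        report["discrimination"] = _discrimination_stage(config, seq_disc)
    if outdir is not None:
        write_report(report, config, Path(outdir))
    return report


def _jsonify(obj):
    if isinstance(obj, (st.StatResult, sh.ShapeFit, sh.SensitivityProfile,
                        ch.ChannelFit, ch.ChannelChange, mx.MixtureFit,
                        psy.PsychFit)):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report["thresholds"].to_csv(outdir / "thresholds.csv", index=False)
    summary = {}
    for stage, content in report.items():
        if stage == "thresholds":
            continue
        stage_json = {}
        for key, value in (content.items() if isinstance(content, dict) else []):
            if isinstance(value, pd.DataFrame):
                value.to_csv(outdir / f"{stage}_{key}.csv", index=False)
            elif isinstance(value, dict):
                stage_json[key] = _jsonify({
                    k: v for k, v in value.items()
                    if not isinstance(v, (pd.DataFrame, sh.SensitivityProfile))
                })
            else:
                stage_json[key] = _jsonify(value)
        summary[stage] = stage_json
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
    manifest = {"seed": config.seed, "config": asdict(config)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
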