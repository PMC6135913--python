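"""Orchestration: synthesis -> simulation -> gaze processing -> statistics.

One :class:`RunConfig` drives the whole pipeline reproducibly: a single
master seed deterministically derives per-stage sub-seeds, so identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_stats import (DesignError, correct_rate_cells, factorial_anova,
                             paired_t, pooled_two_sample_t, score_responses)
from .fixation_pipeline import SaccadeDetectorParams, process_dataset
from .stimulus_synth import build_stimulus_set, save_stimulus_set
from .synthetic_gaze import (EffectSpec, NoiseModel, ground_truth_dff_table,
                             simulate_experiment)

log = logging.getLogger("fggaze")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full configuration of one experiment run (seed is mandatory)."""

    seed: int
    out_dir: str = "fggaze_run"
    # stimulus synthesis
    n_bases: int = 38
    extent_deg: float = 9.0
    px_per_deg: float = 50.0
    alpha_front: float = 0.5
    alpha_back: float = 0.5
    write_images: bool = False
    # schedule
    n_participants: int = 6
    n_repeats: int = 3
    tasks: tuple = ("DOF", "FG")
    window_ms: float = 1000.0
    # simulation
    noise: NoiseModel = field(default_factory=NoiseModel)
    effects: EffectSpec = field(default_factory=EffectSpec)
    make_traces: bool = True
    # gaze processing
    detector: SaccadeDetectorParams = field(
        default_factory=SaccadeDetectorParams)
    exclusion_max_missing: int = 10
    region_mapping: str = "front-footprint"
    fixation_max_gap_samples: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "seed" not in d or d["seed"] is None:
            raise ConfigError("config must specify an integer 'seed'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = SaccadeDetectorParams(**d["detector"])
        if "effects" in d and isinstance(d["effects"], dict):
            eff = dict(d["effects"])
            for key in ("dff_means", "accuracy"):
                if key in eff and isinstance(eff[key], dict):
                    eff[key] = {tuple(k.split("/")): v
                                for k, v in eff[key].items()}
            d["effects"] = EffectSpec(**eff)
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"]["dff_means"] = {
            "/".join(k): v for k, v in d["effects"]["dff_means"].items()}
        d["effects"]["accuracy"] = {
            "/".join(k): v for k, v in d["effects"]["accuracy"].items()}
        d["tasks"] = list(d["tasks"])
        return d


@dataclass
class RunReport:
    n_stimuli: int
    n_trials_per_participant: int
    n_trials_total: int
    n_trials_kept: int
    n_trials_excluded: int
    files: Dict[str, str]
    summaries: Dict[str, object]
    config: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("synth")
def _synth(cfg: RunConfig, out: Path, seed: int):
    stimuli, manifest = build_stimulus_set(
        n_bases=cfg.n_bases, extent_deg=cfg.extent_deg,
        px_per_deg=cfg.px_per_deg,
        alphas=(cfg.alpha_front, cfg.alpha_back), seed=seed)
    if cfg.write_images:
        manifest = save_stimulus_set(stimuli, out, write_images=True)
    else:
        manifest.to_csv(out / "manifest.csv", index=False)
    return stimuli, manifest


@_stage("simulate")
def _simulate(cfg: RunConfig, out: Path, stimuli, seed: int):
    ds = simulate_experiment(
        cfg.effects, cfg.n_participants, stimuli=stimuli,
        n_repeats=cfg.n_repeats, tasks=cfg.tasks, noise=cfg.noise,
        seed=seed, make_traces=cfg.make_traces, window_ms=cfg.window_ms)
    ds.write(out)
    return ds


@_stage("process-gaze")
def _process(cfg: RunConfig, out: Path, stimuli, ds):
    if cfg.make_traces:
        stim_by_id = {s.meta.stimulus_id: s for s in stimuli}
        dff, events, n_excluded = process_dataset(
            ds.gaze, stim_by_id, ds.trials, params=cfg.detector,
            window_ms=cfg.window_ms,
            nominal_rate_hz=cfg.noise.sampling_rate,
            max_missing=cfg.exclusion_max_missing,
            mapping=cfg.region_mapping,
            max_gap_samples=cfg.fixation_max_gap_samples)
        events.to_csv(out / "events.csv", index=False)
    else:
        dff = ground_truth_dff_table(ds)
        n_excluded = 0
    dff.to_csv(out / "dff.csv", index=False)
    return dff, n_excluded


@_stage("analyze")
def _analyze(cfg: RunConfig, out: Path, manifest, ds, dff):
    summaries: Dict[str, object] = {}
    scored = score_responses(ds.trials, manifest)
    rates = correct_rate_cells(scored)
    rates.to_csv(out / "correct_rates.csv", index=False)

    ttest_rows = []
    wide = rates.pivot_table(index=["participant", "condition"],
                             columns="task", values="rate").reset_index()
    for cond, grp in wide.groupby("condition"):
        if {"DOF", "FG"} <= set(grp.columns) and len(grp) >= 2:
            try:
                res = paired_t(grp["DOF"], grp["FG"])
                ttest_rows.append({"contrast": f"rate DOF vs FG ({cond})",
                                   "variant": res.variant, "t": res.statistic,
                                   "df": res.df, "p": res.pvalue})
            except ValueError as exc:
                log.warning("paired t (%s) skipped: %s", cond, exc)

    anova_files = {}
    if cfg.n_participants >= 2 and len(cfg.tasks) >= 2:
        try:
            rate_tab = factorial_anova(rates, dv="rate",
                                       factors=("task", "condition"))
            rate_tab.to_csv(out / "anova_rates.csv")
            anova_files["anova_rates"] = str(out / "anova_rates.csv")
            summaries["rate_anova_task_F"] = float(rate_tab.loc["task", "F"])
        except DesignError as exc:
            log.warning("rate ANOVA skipped: %s", exc)
    for task in cfg.tasks:
        sub = dff[dff["task"] == task]
        factors = ("condition", "region", "participant")
        if cfg.n_participants < 2:
            factors = ("condition", "region")
        try:
            tab = factorial_anova(sub, dv="dff_ms", factors=factors)
        except DesignError as exc:
            log.warning("DFF ANOVA (%s) skipped: %s", task, exc)
            continue
        path = out / f"anova_dff_{task.lower()}.csv"
        tab.to_csv(path)
        anova_files[f"anova_dff_{task.lower()}"] = str(path)
        for factor in ("condition × region",):
            if factor in tab.index:
                summaries[f"{task}_CxF_p"] = float(tab.loc[factor, "p"])
                summaries[f"{task}_CxF_partial_eta_sq"] = float(
                    tab.loc[factor, "partial_eta_sq"])

    for task in cfg.tasks:
        sub = dff[dff["task"] == task]
        fig = sub.loc[sub["region"] == "figure", "dff_ms"]
        gnd = sub.loc[sub["region"] == "ground", "dff_ms"]
        if len(fig) >= 2 and len(gnd) >= 2:
            try:
                res = pooled_two_sample_t(fig, gnd)
                ttest_rows.append({"contrast": f"DFF figure vs ground ({task})",
                                   "variant": res.variant, "t": res.statistic,
                                   "df": res.df, "p": res.pvalue})
            except ValueError as exc:
                log.warning("DFF t-test (%s) skipped: %s", task, exc)
    pd.DataFrame(ttest_rows).to_csv(out / "ttests.csv", index=False)
    summaries["mean_rate_by_task"] = (
        rates.groupby("task")["rate"].mean().to_dict())
    return summaries, anova_files


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and persist every artifact.

    Deterministic under a fixed seed; each stage receives a sub-seed spawned
    from the master seed so stages can be re-run individually.
    """
    if not isinstance(config, RunConfig):
        raise ConfigError("run_pipeline expects a RunConfig")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(int(config.seed))
    synth_ss, sim_ss = root.spawn(2)
    synth_seed = int(synth_ss.generate_state(1)[0] % (2 ** 31))
    sim_seed = int(sim_ss.generate_state(1)[0] % (2 ** 31))

    stimuli, manifest = _synth(config, out, synth_seed)
    ds = _simulate(config, out, stimuli, sim_seed)
    dff, n_excluded = _process(config, out, stimuli, ds)
    summaries, anova_files = _analyze(config, out, manifest, ds, dff)

    n_total = len(ds.trials)
    files = {"manifest": str(out / "manifest.csv"),
             "trials": str(out / "trials.csv"),
             "gaze": str(out / "gaze.csv"),
             "truth": str(out / "truth.csv"),
             "dff": str(out / "dff.csv"),
             "correct_rates": str(out / "correct_rates.csv"),
             "ttests": str(out / "ttests.csv"),
             **anova_files}
    report = RunReport(
        n_stimuli=len(stimuli),
        n_trials_per_participant=(n_total // config.n_participants
                                  if config.n_participants else 0),
        n_trials_total=n_total,
        n_trials_kept=n_total - n_excluded,
        n_trials_excluded=n_excluded,
        files=files, summaries=summaries, config=config.echo())
    (out / "report.json").write_text(report.to_json())
    return report
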