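"""Simulation of tracker output and behavioral responses with known truth.

The simulator emulates a 60 Hz remote eye tracker: planned fixations become
stationary runs of samples (plus a per-trial systematic offset modelling
calibration accuracy and per-sample jitter), saccades are step transitions,
and samples drop out independently at a configurable rate (the effective
valid-sample rate is ``(1 - dropout_rate) * sampling_rate``; the default
0.14 reproduces ~51.6 valid samples/s at a 60 Hz nominal rate).

Behavioral 2AFC responses are drawn per trial from configurable per-cell
accuracies, and the first-fixation durations to the figure and ground
regions are sampled from per-cell means so that recovery of the injected
factorial structure can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .stimulus_synth import (BACK_ONLY, FRONT_ONLY, GROUND, OVERLAP,
                             TranslucentStimulus, stimulus_manifest)

GAZE_COLUMNS = ["trial_id", "participant", "t_ms", "x_deg", "y_deg", "valid"]

# sampled first-fixation durations below this are implausible and are redrawn
MIN_DFF_MS = 50.0


@dataclass(frozen=True)
class PlannedFixation:
    x: float
    y: float
    duration_ms: float


@dataclass
class ScanpathSpec:
    """Ordered planned fixations for one trial (trial onset at t = 0)."""

    fixations: Sequence[PlannedFixation]
    window_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not self.fixations:
            raise ValueError("scanpath must contain at least one fixation")
        for f in self.fixations:
            if f.duration_ms <= 0:
                raise ValueError("planned fixation durations must be > 0")

    @property
    def onsets_ms(self) -> np.ndarray:
        d = np.array([f.duration_ms for f in self.fixations])
        return np.concatenate([[0.0], np.cumsum(d)[:-1]])


@dataclass(frozen=True)
class NoiseModel:
    """Tracker noise: within-fixation jitter, per-trial systematic offset,
    independent sample dropout, and the nominal sampling rate."""

    jitter_sd: float = 0.3      # deg, per sample
    offset_sd: float = 0.74     # deg, one draw per trial (accuracy figure)
    dropout_rate: float = 0.14  # 60 Hz * (1 - 0.14) ~ 51.6 valid samples/s
    sampling_rate: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.jitter_sd < 0 or self.offset_sd < 0:
            raise ValueError("noise SDs must be >= 0")


ZERO_NOISE = NoiseModel(jitter_sd=0.0, offset_sd=0.0, dropout_rate=0.0)


@dataclass
class SimulatedTrial:
    """One simulated trial: the gaze trace plus its generating scanpath."""

    samples: pd.DataFrame
    spec: ScanpathSpec
    trial_id: str = "t0"
    participant: str = "sim"

    def true_dff(self, region_of: Callable[[float, float], str],
                 region: str) -> Optional[float]:
        """Ground-truth first-fixation duration for ``region``.

        The duration of the first planned fixation whose target lies in the
        region, clipped to the stimulus window; None when no planned
        fixation reaches the region within the window.
        """
        onsets = self.spec.onsets_ms
        for fix, onset in zip(self.spec.fixations, onsets):
            if onset >= self.spec.window_ms:
                break
            if region_of(fix.x, fix.y) == region:
                return min(fix.duration_ms, self.spec.window_ms - onset)
        return None


def _trace_arrays(spec: ScanpathSpec, noise: NoiseModel,
                  rng: np.random.Generator) -> tuple:
    n = int(round(spec.window_ms * noise.sampling_rate / 1000.0))
    dt = 1000.0 / noise.sampling_rate
    t = np.arange(n) * dt
    durations = np.array([f.duration_ms for f in spec.fixations])
    bounds = np.cumsum(durations)
    idx = np.minimum(np.searchsorted(bounds, t, side="right"),
                     len(durations) - 1)
    tx = np.array([f.x for f in spec.fixations])[idx]
    ty = np.array([f.y for f in spec.fixations])[idx]
    offset = rng.normal(0.0, noise.offset_sd, size=2)
    jitter = rng.normal(0.0, noise.jitter_sd, size=(n, 2))
    x = tx + offset[0] + jitter[:, 0]
    y = ty + offset[1] + jitter[:, 1]
    valid = rng.random(n) >= noise.dropout_rate
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return t, x, y, valid


def simulate_trace(spec: ScanpathSpec, noise: NoiseModel, seed,
                   trial_id: str = "t0",
                   participant: str = "sim") -> SimulatedTrial:
    """Simulate one gaze trace; bit-identical for identical inputs."""
    rng = np.random.default_rng(seed)
    t, x, y, valid = _trace_arrays(spec, noise, rng)
    samples = pd.DataFrame({
        "trial_id": trial_id,
        "participant": participant,
        "t_ms": t,
        "x_deg": x,
        "y_deg": y,
        "valid": valid.astype(int),
    })
    return SimulatedTrial(samples=samples, spec=spec, trial_id=trial_id,
                          participant=participant)


def _default_dff_means() -> Dict[tuple, float]:
    # FG task: figure dwell exceeds ground dwell, more so under
    # contradiction; DOF task: flat, slightly ground-favouring.
    return {
        ("FG", "consistent", "figure"): 320.0,
        ("FG", "consistent", "ground"): 230.0,
        ("FG", "contradictory", "figure"): 400.0,
        ("FG", "contradictory", "ground"): 170.0,
        ("DOF", "consistent", "figure"): 230.0,
        ("DOF", "consistent", "ground"): 250.0,
        ("DOF", "contradictory", "figure"): 230.0,
        ("DOF", "contradictory", "ground"): 250.0,
    }


def _default_accuracy() -> Dict[tuple, float]:
    # DOF discrimination easier than FG segregation in both conditions
    return {
        ("DOF", "consistent"): 0.95,
        ("DOF", "contradictory"): 0.92,
        ("FG", "consistent"): 0.80,
        ("FG", "contradictory"): 0.72,
    }


@dataclass
class EffectSpec:
    """Injected factorial structure: mean DFF per task x condition x region
    cell, participant and trial variability, and per-cell 2AFC accuracy."""

    dff_means: Dict[tuple, float] = field(default_factory=_default_dff_means)
    between_sd: float = 30.0  # participant-level offset SD, ms
    within_sd: float = 80.0   # trial-level SD within a cell, ms
    accuracy: Dict[tuple, float] = field(default_factory=_default_accuracy)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.dff_means.values()):
            raise ValueError("cell mean DFFs must be > 0")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be >= 0")
        if any(not 0.0 <= a <= 1.0 for a in self.accuracy.values()):
            raise ValueError("accuracies must lie in [0, 1]")

    def mean(self, task: str, condition: str, region: str) -> float:
        return self.dff_means[(task, condition, region)]

    def acc(self, task: str, condition: str) -> float:
        return self.accuracy[(task, condition)]


@dataclass
class SimulatedDataset:
    """Trial table, gaze log, and ground-truth sidecar of one experiment."""

    trials: pd.DataFrame
    gaze: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trials": out_dir / "trials.csv",
            "gaze": out_dir / "gaze.csv",
            "truth": out_dir / "truth.csv",
        }
        self.trials.to_csv(paths["trials"], index=False)
        self.gaze.to_csv(paths["gaze"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return {k: str(v) for k, v in paths.items()}


def region_target_points(stim: TranslucentStimulus,
                         max_ecc_deg: float = 3.2) -> Dict[str, tuple]:
    """Deep-interior target points for the figure and ground regions.

    Figure is the front surface's footprint (front-only plus overlap).
    The deepest interior pixel of each region (Euclidean distance
    transform argmax) is chosen among pixels within ``max_ecc_deg`` of the
    stimulus centre — observers inspect the ground near the shapes rather
    than the field edge, and a central target keeps jittered fixations on
    the stimulus.  Falls back to the global argmax when a region has no
    pixel inside that disk.
    """
    n = stim.n
    xs = (np.arange(n) + 0.5) / stim.px_per_deg - stim.extent_deg / 2
    ys = stim.extent_deg / 2 - (np.arange(n) + 0.5) / stim.px_per_deg
    X, Y = np.meshgrid(xs, ys)
    central = np.hypot(X, Y) <= max_ecc_deg
    fig = (stim.region_map == FRONT_ONLY) | (stim.region_map == OVERLAP)
    gnd = ~fig
    out = {}
    for name, mask in (("figure", fig), ("ground", gnd)):
        dist = ndimage.distance_transform_edt(mask)
        scoped = np.where(central, dist, 0.0)
        if scoped.max() == 0:
            scoped = dist
        row, col = np.unravel_index(int(np.argmax(scoped)), dist.shape)
        out[name] = (float(X[row, col]), float(Y[row, col]))
    return out


def _draw_duration(rng: np.random.Generator, mean: float, sd: float,
                   lo: float = MIN_DFF_MS, max_tries: int = 200) -> float:
    for _ in range(max_tries):
        d = rng.normal(mean, sd)
        if d >= lo:
            return float(d)
    return lo


def build_schedule(manifest: pd.DataFrame, tasks: Sequence[str],
                   n_repeats: int, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized trial order for one participant:
    every stimulus x task x repeat exactly once, uniformly shuffled."""
    reps = []
    for task in tasks:
        for rep in range(n_repeats):
            block = manifest[["stimulus_id", "condition", "dof_truth",
                              "figure_color_truth"]].copy()
            block["task"] = task
            block["repeat"] = rep
            reps.append(block)
    sched = pd.concat(reps, ignore_index=True)
    order = rng.permutation(len(sched))
    return sched.iloc[order].reset_index(drop=True)


def simulate_experiment(effects: EffectSpec, n_participants: int,
                        stimuli: Optional[Sequence[TranslucentStimulus]] = None,
                        manifest: Optional[pd.DataFrame] = None,
                        n_repeats: int = 3,
                        tasks: Sequence[str] = ("DOF", "FG"),
                        noise: Optional[NoiseModel] = None,
                        seed: int = 0,
                        make_traces: bool = True,
                        window_ms: float = 1000.0) -> SimulatedDataset:
    """Simulate the full trial schedule for ``n_participants`` observers.

    Each trial draws figure- and ground-region first-fixation durations from
    the cell means (participant offset plus trial noise, redrawn below
    ``MIN_DFF_MS``), visits the two regions in random order, pads the window
    with a return fixation, and draws a 2AFC response from the cell
    accuracy.  With ``make_traces=False`` only the trial table and
    ground-truth sidecar are produced (no per-sample gaze log).
    """
    if manifest is None:
        if not stimuli:
            raise ValueError("empty manifest: provide stimuli or a manifest")
        manifest = stimulus_manifest(stimuli)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if make_traces and not stimuli:
        raise ValueError("make_traces=True requires stimulus objects")
    noise = noise if noise is not None else NoiseModel()

    points: Dict[str, Dict[str, tuple]] = {}
    if stimuli:
        points = {s.meta.stimulus_id: region_target_points(s)
                  for s in stimuli}

    root = np.random.SeedSequence(int(seed))
    part_seeds = root.spawn(int(n_participants))
    trial_rows, truth_rows = [], []
    gaze_parts = []
    for p in range(int(n_participants)):
        rng = np.random.default_rng(part_seeds[p])
        pid = f"P{p}"
        b_p = rng.normal(0.0, effects.between_sd)
        sched = build_schedule(manifest, tasks, n_repeats, rng)
        for k, row in enumerate(sched.itertuples(index=False)):
            trial_id = f"{pid}_{k:05d}"
            task, cond = row.task, row.condition
            dur_fig = _draw_duration(rng, effects.mean(task, cond, "figure")
                                     + b_p, effects.within_sd)
            dur_gnd = _draw_duration(rng, effects.mean(task, cond, "ground")
                                     + b_p, effects.within_sd)
            first = "figure" if rng.random() < 0.5 else "ground"
            pts = points.get(row.stimulus_id,
                             {"figure": (0.0, 0.0), "ground": (4.0, 4.0)})
            order = ([("figure", dur_fig), ("ground", dur_gnd)]
                     if first == "figure"
                     else [("ground", dur_gnd), ("figure", dur_fig)])
            onset = 0.0
            for region, dur in order:
                true_dff = (min(dur, window_ms - onset)
                            if onset < window_ms else np.nan)
                truth_rows.append({"trial_id": trial_id, "participant": pid,
                                   "region": region,
                                   "true_dff_ms": true_dff,
                                   "true_response": ""})
                onset += dur
            filler = max(window_ms - onset, 1000.0 / noise.sampling_rate)
            planned = [PlannedFixation(*pts[r], d) for r, d in order]
            planned.append(PlannedFixation(*pts[first], filler))
            spec = ScanpathSpec(planned, window_ms=window_ms)

            truth_resp = (row.dof_truth if task == "DOF"
                          else row.figure_color_truth)
            truth_rows[-1]["true_response"] = truth_resp
            truth_rows[-2]["true_response"] = truth_resp
            alts = (("left", "right") if task == "DOF" else ("red", "green"))
            wrong = alts[0] if truth_resp == alts[1] else alts[1]
            correct = rng.random() < effects.acc(task, cond)
            response = truth_resp if correct else wrong

            if make_traces:
                t, x, y, valid = _trace_arrays(spec, noise, rng)
                m = len(t)
                gaze_parts.append(pd.DataFrame({
                    "trial_id": np.repeat(trial_id, m),
                    "participant": np.repeat(pid, m),
                    "t_ms": t, "x_deg": x, "y_deg": y,
                    "valid": valid.astype(int)}))

            trial_rows.append({
                "trial_id": trial_id, "participant": pid,
                "stimulus_id": row.stimulus_id, "task": task,
                "condition": cond, "repeat": row.repeat,
                "response": response, "response_correct_true": int(correct),
            })
    trials = pd.DataFrame(trial_rows)
    truth = pd.DataFrame(truth_rows)
    gaze = (pd.concat(gaze_parts, ignore_index=True) if gaze_parts
            else pd.DataFrame(columns=GAZE_COLUMNS))
    return SimulatedDataset(trials=trials, gaze=gaze, truth=truth)


def ground_truth_dff_table(dataset: SimulatedDataset) -> pd.DataFrame:
    """Ground-truth DFF records in the analysis schema
    (participant, trial_id, task, condition, region, dff_ms)."""
    merged = dataset.truth.merge(
        dataset.trials[["trial_id", "task", "condition"]], on="trial_id")
    out = merged.rename(columns={"true_dff_ms": "dff_ms"})
    out = out.dropna(subset=["dff_ms"])
    return out[["participant", "trial_id", "task", "condition", "region",
                "dff_ms"]].reset_index(drop=True)
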