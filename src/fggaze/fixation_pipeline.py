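"""From raw gaze samples to saccades, fixations and the DFF statistic.

Saccades are detected with a median-based velocity-threshold method:
velocities come from a centred moving-window finite difference (default
5-sample window), a per-axis noise scale is estimated robustly as
``sigma^2 = median(v^2) - median(v)^2``, and a sample is saccadic when

    (vx / (lambda * sigma_x))^2 + (vy / (lambda * sigma_y))^2 > 1

with threshold multiplier ``lambda = 6``.  Runs of saccadic samples form
saccade events; the successive small movements between saccades are one
fixation each.

Because the centred differentiator spreads an (effectively instantaneous)
saccade symmetrically over the window, fixation boundaries adjacent to a
saccade are placed at the temporal midpoint of the saccade event; this
removes the window-induced bias so that recovered fixation durations are
unbiased at the sampling resolution.  At trace edges (no adjacent saccade)
a fixation spans from its first member sample to one sample period past its
last member sample.

The duration of first fixation (DFF) to a region is the duration of the
earliest fixation whose location falls in that region, clipped to the
stimulus window; a fixation already ongoing at stimulus onset is counted
from the onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .stimulus_synth import (BACK_ONLY, FRONT_ONLY, GROUND, OVERLAP,
                             TranslucentStimulus)

GAZE_COLUMNS = ["trial_id", "participant", "t_ms", "x_deg", "y_deg", "valid"]

#: region-mapping modes: which labels count as the perceptual figure
REGION_MAPPINGS = {
    # figure = footprint of the physically front surface
    "front-footprint": frozenset({FRONT_ONLY, OVERLAP}),
    # figure = visible area of either surface; only the white ground is ground
    "both-surfaces": frozenset({FRONT_ONLY, OVERLAP, BACK_ONLY}),
}


class GazeParseError(ValueError):
    """A gaze log row could not be parsed; the message names the line."""


@dataclass(frozen=True)
class SaccadeDetectorParams:
    lambda_threshold: float = 6.0
    velocity_window: int = 5
    min_saccade_samples: int = 1

    def __post_init__(self) -> None:
        if self.lambda_threshold <= 0:
            raise ValueError("lambda_threshold must be > 0")
        if self.velocity_window < 3 or self.velocity_window % 2 == 0:
            raise ValueError("velocity_window must be odd and >= 3")
        if self.min_saccade_samples < 1:
            raise ValueError("min_saccade_samples must be >= 1")


@dataclass
class SaccadeEvent:
    onset_index: int       # first saccadic sample (inclusive)
    offset_index: int      # last saccadic sample (inclusive)
    onset_ms: float
    offset_ms: float
    displacement_deg: float

    def midpoint_ms(self, dt_ms: float) -> float:
        """Midpoint of the saccade interval [onset, offset + dt)."""
        return (self.onset_ms + self.offset_ms + dt_ms) / 2.0


@dataclass
class Fixation:
    onset_ms: float        # effective interval start (inclusive)
    offset_ms: float       # effective interval end (exclusive)
    centroid_x: float
    centroid_y: float
    first_index: int
    last_index: int
    region: Optional[str] = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class TrialTrace:
    """Time-ordered gaze samples of one trial."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    trial_id: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.t_ms.size

    @property
    def dt_ms(self) -> float:
        if len(self) < 2:
            return np.nan
        return float(np.median(np.diff(self.t_ms)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialTrace":
        df = df.sort_values("t_ms", kind="stable")
        return cls(t_ms=df["t_ms"].to_numpy(),
                   x=df["x_deg"].to_numpy(), y=df["y_deg"].to_numpy(),
                   valid=df["valid"].to_numpy().astype(bool),
                   trial_id=str(df["trial_id"].iloc[0]),
                   participant=str(df["participant"].iloc[0]))


def load_gaze_log(path) -> List[TrialTrace]:
    """Parse a gaze-log CSV into per-trial traces.

    Dialect: header ``trial_id,participant,t_ms,x_deg,y_deg,valid``; one row
    per sample; missing samples carry ``valid=0`` and empty coordinates.
    Samples are grouped by trial (file order of first appearance) and
    time-sorted; invalid rows are flagged, not dropped.  A malformed row
    raises :class:`GazeParseError` naming the offending line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeParseError(f"gaze log misses columns: {missing}")
    numeric: Dict[str, pd.Series] = {}
    for col in ("t_ms", "x_deg", "y_deg"):
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise GazeParseError(
                f"line {line}: non-numeric value {df[col].iloc[line - 2]!r} "
                f"in column {col}")
        numeric[col] = vals
    raw_valid = df["valid"].str.strip()
    if not raw_valid.isin({"0", "1"}).all():
        line = int(np.flatnonzero(~raw_valid.isin({"0", "1"}).to_numpy())[0]) + 2
        raise GazeParseError(f"line {line}: valid flag must be 0 or 1")
    if numeric["t_ms"].isna().any():
        line = int(np.flatnonzero(numeric["t_ms"].isna().to_numpy())[0]) + 2
        raise GazeParseError(f"line {line}: missing timestamp")
    clean = pd.DataFrame({
        "trial_id": df["trial_id"], "participant": df["participant"],
        "t_ms": numeric["t_ms"], "x_deg": numeric["x_deg"],
        "y_deg": numeric["y_deg"], "valid": raw_valid.astype(int)})
    traces = []
    for tid in clean["trial_id"].unique():
        traces.append(TrialTrace.from_dataframe(clean[clean["trial_id"] == tid]))
    return traces


def exclude_trial(trace: TrialTrace, window_ms: float = 1000.0,
                  nominal_rate_hz: float = 60.0,
                  max_missing: int = 10) -> bool:
    """Keep/exclude decision: True (keep) unless more than ``max_missing``
    samples are missing or invalid within the stimulus window."""
    in_win = (trace.t_ms >= 0) & (trace.t_ms < window_ms)
    n_valid = int(np.count_nonzero(trace.valid & in_win))
    n_expected = int(round(window_ms * nominal_rate_hz / 1000.0))
    n_missing = max(0, n_expected - n_valid)
    return n_missing <= max_missing


def _window_velocities(trace: TrialTrace, window: int) -> tuple:
    """Centred moving-window velocities (deg/s) per axis.

    ``v_i = sum_{k=1..h} (p_{i+k} - p_{i-k}) / (h (h+1) dt)`` with
    ``h = (window - 1) / 2``; undefined (NaN) at trace edges and wherever
    the window touches an invalid sample.
    """
    h = (window - 1) // 2
    n = len(trace)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    if n < window:
        return vx, vy
    dt_s = trace.dt_ms / 1000.0
    denom = h * (h + 1) * dt_s
    core = slice(h, n - h)
    num_x = np.zeros(n - 2 * h)
    num_y = np.zeros(n - 2 * h)
    for k in range(1, h + 1):
        num_x += trace.x[h + k: n - h + k] - trace.x[h - k: n - h - k]
        num_y += trace.y[h + k: n - h + k] - trace.y[h - k: n - h - k]
    ok = (np.convolve(trace.valid.astype(int), np.ones(window, dtype=int),
                      mode="valid") == window)
    with np.errstate(invalid="ignore"):
        vx[core] = np.where(ok, num_x / denom, np.nan)
        vy[core] = np.where(ok, num_y / denom, np.nan)
    return vx, vy


def _median_sigma(v: np.ndarray) -> float:
    med = float(np.median(v))
    s2 = float(np.median(v ** 2)) - med ** 2
    return float(np.sqrt(max(s2, 0.0)))


def _axis_term(v: np.ndarray, sigma: float, lam: float) -> np.ndarray:
    """Per-axis contribution to the elliptic threshold criterion.

    A degenerate axis (sigma = 0) contributes nothing for zero velocity and
    everything for nonzero velocity, so constant axes never trigger while
    genuine steps on an otherwise quiet axis still do.
    """
    if sigma > 0:
        return (v / (lam * sigma)) ** 2
    out = np.zeros_like(v)
    out[np.nan_to_num(v) != 0] = np.inf
    out[np.isnan(v)] = np.nan
    return out


def detect_saccades(trace: TrialTrace,
                    params: SaccadeDetectorParams = SaccadeDetectorParams()
                    ) -> List[SaccadeEvent]:
    """Median-based velocity-threshold saccade detection.

    Invalid samples (and samples whose velocity window touches one) cannot
    be saccadic and break runs.  An all-invalid trial yields an empty list
    with a warning.
    """
    if not trace.valid.any():
        warnings.warn(f"trial {trace.trial_id!r}: all samples invalid",
                      stacklevel=2)
        return []
    vx, vy = _window_velocities(trace, params.velocity_window)
    defined = ~np.isnan(vx) & ~np.isnan(vy)
    if not defined.any():
        return []
    sx = _median_sigma(vx[defined])
    sy = _median_sigma(vy[defined])
    lam = params.lambda_threshold
    with np.errstate(invalid="ignore"):
        crit = _axis_term(vx, sx, lam) + _axis_term(vy, sy, lam)
        saccadic = defined & (crit > 1.0)

    events: List[SaccadeEvent] = []
    n = len(trace)
    i = 0
    while i < n:
        if not saccadic[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and saccadic[j + 1]:
            j += 1
        if j - i + 1 >= params.min_saccade_samples:
            a = i - 1 if i > 0 and trace.valid[i - 1] else i
            b = j + 1 if j + 1 < n and trace.valid[j + 1] else j
            disp = float(np.hypot(trace.x[b] - trace.x[a],
                                  trace.y[b] - trace.y[a]))
            events.append(SaccadeEvent(onset_index=i, offset_index=j,
                                       onset_ms=float(trace.t_ms[i]),
                                       offset_ms=float(trace.t_ms[j]),
                                       displacement_deg=disp))
        i = j + 1
    return events


def segment_fixations(trace: TrialTrace, saccades: Sequence[SaccadeEvent],
                      dt_ms: Optional[float] = None,
                      max_gap_samples: int = 3) -> List[Fixation]:
    """Segment valid, non-saccadic samples into fixations.

    Each maximal run of non-saccadic valid samples becomes one fixation;
    its centroid is the mean member position.  Brief data-loss gaps of at
    most ``max_gap_samples`` invalid samples do not interrupt a fixation
    (tracker dropout does not end a dwell; set 0 for strict run-breaking).
    Boundaries adjacent to a saccade sit at the saccade's temporal
    midpoint; free boundaries span first-sample time to one sample period
    past the last member.
    """
    n = len(trace)
    dt = float(dt_ms) if dt_ms is not None else trace.dt_ms
    sacc_member = np.zeros(n, dtype=bool)
    start_of: Dict[int, SaccadeEvent] = {}
    end_of: Dict[int, SaccadeEvent] = {}
    for e in saccades:
        sacc_member[e.onset_index:e.offset_index + 1] = True
        start_of[e.onset_index] = e
        end_of[e.offset_index] = e
    member = trace.valid & ~sacc_member

    fixations: List[Fixation] = []
    i = 0
    while i < n:
        if not member[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            if member[j + 1]:
                j += 1
                continue
            # bridge a short invalid gap that continues into a member run
            k = j + 1
            while k < n and not trace.valid[k]:
                k += 1
            if 0 < k - (j + 1) <= max_gap_samples and k < n and member[k]:
                j = k
                continue
            break
        prev_sacc = end_of.get(i - 1)
        next_sacc = start_of.get(j + 1)
        onset = (prev_sacc.midpoint_ms(dt) if prev_sacc is not None
                 else float(trace.t_ms[i]))
        offset = (next_sacc.midpoint_ms(dt) if next_sacc is not None
                  else float(trace.t_ms[j]) + dt)
        members = np.arange(i, j + 1)[trace.valid[i:j + 1]]
        fixations.append(Fixation(
            onset_ms=onset, offset_ms=offset,
            centroid_x=float(np.mean(trace.x[members])),
            centroid_y=float(np.mean(trace.y[members])),
            first_index=i, last_index=j))
        i = j + 1
    return fixations


def assign_region(fix: Fixation, stim: TranslucentStimulus,
                  mapping: str = "front-footprint",
                  samples: Optional[tuple] = None) -> str:
    """Map a fixation to 'figure', 'ground' or 'off-stimulus'.

    By default the fixation centroid is looked up in the region map;
    passing ``samples=(x_array, y_array)`` switches to a per-sample
    majority vote over the member samples.
    """
    figure_labels = REGION_MAPPINGS[mapping]

    def classify(x: float, y: float) -> str:
        lab = stim.region_label_at(x, y)
        if lab is None:
            return "off-stimulus"
        return "figure" if lab in figure_labels else "ground"

    if samples is None:
        return classify(fix.centroid_x, fix.centroid_y)
    votes = pd.Series([classify(x, y) for x, y in zip(*samples)])
    return votes.mode().iloc[0]


def first_fixation_duration(fixations: Sequence[Fixation],
                            stim: TranslucentStimulus, region: str,
                            window_ms: float = 1000.0,
                            mapping: str = "front-footprint"
                            ) -> Optional[float]:
    """DFF: duration of the earliest fixation assigned to ``region``,
    clipped to [0, window]; None when the region is never fixated within
    the stimulus window."""
    for fix in fixations:
        if fix.onset_ms >= window_ms:
            break
        r = fix.region if fix.region else assign_region(fix, stim, mapping)
        if r != region:
            continue
        start = max(fix.onset_ms, 0.0)
        end = min(fix.offset_ms, window_ms)
        if end <= start:
            continue
        return end - start
    return None


@dataclass
class TrialResult:
    trial_id: str
    participant: str
    kept: bool
    saccades: List[SaccadeEvent]
    fixations: List[Fixation]
    dff: Dict[str, Optional[float]]


def process_trial(trace: TrialTrace, stim: TranslucentStimulus,
                  params: SaccadeDetectorParams = SaccadeDetectorParams(),
                  window_ms: float = 1000.0,
                  nominal_rate_hz: float = 60.0,
                  max_missing: int = 10,
                  mapping: str = "front-footprint",
                  max_gap_samples: int = 3) -> TrialResult:
    """Exclusion check, saccade detection, fixation segmentation, region
    assignment and DFF for one trial."""
    kept = exclude_trial(trace, window_ms, nominal_rate_hz, max_missing)
    saccades: List[SaccadeEvent] = []
    fixations: List[Fixation] = []
    dff: Dict[str, Optional[float]] = {"figure": None, "ground": None}
    if kept:
        saccades = detect_saccades(trace, params)
        fixations = segment_fixations(trace, saccades,
                                      max_gap_samples=max_gap_samples)
        for f in fixations:
            f.region = assign_region(f, stim, mapping)
        for region in ("figure", "ground"):
            dff[region] = first_fixation_duration(fixations, stim, region,
                                                  window_ms, mapping)
    return TrialResult(trial_id=trace.trial_id,
                       participant=trace.participant, kept=kept,
                       saccades=saccades, fixations=fixations, dff=dff)


def process_dataset(gaze: pd.DataFrame, stimuli_by_id: Dict[str, TranslucentStimulus],
                    trials: pd.DataFrame,
                    params: SaccadeDetectorParams = SaccadeDetectorParams(),
                    window_ms: float = 1000.0,
                    nominal_rate_hz: float = 60.0,
                    max_missing: int = 10,
                    mapping: str = "front-footprint",
                    max_gap_samples: int = 3) -> tuple:
    """Run the pipeline over a whole gaze log.

    Returns ``(dff_df, events_df, n_excluded)`` where ``dff_df`` follows the
    analysis schema (participant, trial_id, task, condition, region, dff_ms)
    with one row per observed (trial, region).
    """
    meta = trials.set_index("trial_id")
    dff_rows, event_rows = [], []
    n_excluded = 0
    for tid, g in gaze.groupby("trial_id", sort=False):
        trace = TrialTrace.from_dataframe(g)
        if tid not in meta.index:
            raise KeyError(f"gaze log references unknown trial {tid!r}")
        info = meta.loc[tid]
        stim = stimuli_by_id[info["stimulus_id"]]
        res = process_trial(trace, stim, params, window_ms, nominal_rate_hz,
                            max_missing, mapping, max_gap_samples)
        if not res.kept:
            n_excluded += 1
            continue
        for e in res.saccades:
            event_rows.append({"trial_id": tid, "participant": trace.participant,
                               "kind": "saccade", "onset_ms": e.onset_ms,
                               "offset_ms": e.offset_ms,
                               "x": np.nan, "y": np.nan,
                               "displacement_deg": e.displacement_deg,
                               "region": ""})
        for f in res.fixations:
            event_rows.append({"trial_id": tid, "participant": trace.participant,
                               "kind": "fixation", "onset_ms": f.onset_ms,
                               "offset_ms": f.offset_ms,
                               "x": f.centroid_x, "y": f.centroid_y,
                               "displacement_deg": np.nan,
                               "region": f.region or ""})
        for region, val in res.dff.items():
            if val is not None:
                dff_rows.append({"participant": trace.participant,
                                 "trial_id": tid, "task": info["task"],
                                 "condition": info["condition"],
                                 "region": region, "dff_ms": val})
    dff_df = pd.DataFrame(dff_rows, columns=["participant", "trial_id",
                                             "task", "condition", "region",
                                             "dff_ms"])
    events_df = pd.DataFrame(event_rows)
    return dff_df, events_df, n_excluded
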