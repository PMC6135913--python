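# fggaze

Figure-ground (FG) segregation assigns a global image region to an object;
border ownership gives only the local *direction of figure* (DOF) along a
contour. `fggaze` is a reusable, tested pipeline for psychophysics of the
interaction between the two, built around translucent two-surface displays
in which the two cues can be put in conflict: a translucent front surface
partially occludes a back surface, and the composite is translated so that
the contour at the stimulus centre belongs either to the front surface
(local DOF and global FG **consistent**) or to the occluded back surface
(**contradictory**).

The package is aimed at vision scientists who want to (a) generate such
stimuli with exact ground truth, (b) analyse 60 Hz eye-tracking data with a
robust velocity-threshold event detector, and (c) run the factorial
statistics on the *duration of first fixation* (DFF) — the time gaze dwells
in the figure or ground region for the first time after stimulus onset.
Because no raw data from the original study are deposited, a synthetic-gaze
module simulates tracker output and 2AFC responses with known ground truth,
so every stage of the pipeline is testable end to end.

## The model in brief

**Stimuli.** Two filled natural-shape patches are layered by alpha
blending over a white ground `W` (per channel, permeation rates
`α_front`, `α_back`):

```
I'_back       = α_back  · I_back  + (1 − α_back)  · W
S_superimpose = α_front · I_front + (1 − α_front) · I'_back
S_front       = α_front · I_front + (1 − α_front) · W
S_back        = α_back  · I_back  + (1 − α_back)  · W
```

Each base pair expands into 8 factorial variants (2 mirror × 2 depth
order/color × 2 translation targets); 38 bases give the full 304-stimulus
set, and 2 tasks × 3 repeats give 1824 trials per participant.

**Event detection.** Velocities come from a centred 5-sample moving-window
differentiator; the per-axis noise scale is the median-based estimator
`σ² = median(v²) − median(v)²`, and a sample is saccadic when
`(vx/λσx)² + (vy/λσy)² > 1` with `λ = 6`. Successive small movements
between saccades form single fixations; fixation boundaries adjacent to a
saccade sit at the saccade's temporal midpoint, which makes recovered
durations unbiased at the sampling resolution.

**Statistics.** Correct rates per task × condition cell; paired and pooled
Student t-tests; fixed-effects crossed ANOVA (Type III, sum-to-zero
contrasts — classical sums of squares on balanced data) with partial
eta squared `η²_p = SS_effect / (SS_effect + SS_error)`.

## Worked example

```python
import fggaze as fg

cfg = fg.RunConfig(seed=1, out_dir="demo", n_bases=10, px_per_deg=20,
                   n_participants=4, n_repeats=2)
report = fg.run_pipeline(cfg)
print(report.n_stimuli, report.n_trials_total, report.n_trials_excluded)
print(report.summaries)
```

prints (80 stimuli = 10 bases × 8 variants; 1280 trials = 80 × 2 tasks ×
2 repeats × 4 participants; 284 trials excluded by the >10-missing-samples
rule at 14% sample dropout):

```
80 1280 284
{'rate_anova_task_F': 95.36986301369863,
 'DOF_CxF_p': 0.3429877755227872,
 'DOF_CxF_partial_eta_sq': 0.0011034197425012148,
 'FG_CxF_p': 2.4933038965878364e-07,
 'FG_CxF_partial_eta_sq': 0.03318085927789342,
 'mean_rate_by_task': {'DOF': 0.9390625, 'FG': 0.7546875}}
```

Read this as: DOF discrimination is easier than FG segregation (mean
correct rate 0.94 vs 0.75, task effect F = 95.4), and the
condition × fixation-region interaction on DFF — the signature of the
contradiction modulating figure-ground processing — is detected in the FG
task (p ≈ 2.5e-7, η²_p ≈ 0.033) but absent in the DOF task (p = 0.34),
exactly the asymmetry the synthetic generator injects. The accompanying
`ttests.csv` shows the same pattern at the contrast level: DFF to figure
exceeds DFF to ground under the FG task (t(803) = 7.60, p ≈ 8e-14) but not
under the DOF task (t(829) = −1.95, p = 0.052).

The run directory also contains `manifest.csv` (stimulus ground truth),
`gaze.csv`/`truth.csv` (simulated tracker log and sidecar), `dff.csv`,
`events.csv`, `correct_rates.csv`, per-task ANOVA tables and
`report.json`.

A CLI mirrors the stages:

```
fg-gaze run-all --config config.yaml
fg-gaze synth --config config.yaml            # stimuli + label rasters + manifest
fg-gaze process-gaze --gaze gaze.csv --manifest manifest.csv --trials trials.csv
fg-gaze analyze --dff dff.csv --task FG
```

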