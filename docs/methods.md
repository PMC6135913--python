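# Methods

This note records the scientific and numerical choices behind `fggaze`:
what each stage models, which parameters matter, and what the synthetic
data do and do not establish about real eye-tracking data.

## Stimulus synthesis

A stimulus is a 9° × 9° raster (default 50 px/deg) containing two
overlapping filled shapes: a translucent *front* surface over a *back*
surface on a white ground. Coordinates are degrees of visual angle with
the origin at the stimulus centre, x rightward, y upward; pixel centres
sit at half-integer offsets.

**Shape source.** The original displays were built from natural-image
patches; here each patch is a procedural blob — a disk (radius 2.4°,
centred at ±1.2° horizontally) perturbed by low-pass Gaussian noise
(smoothing 0.8°, amplitude 0.45 of the radial profile), reduced to its
largest connected component with holes filled. This preserves the
topological requirements the analysis needs (one closed, naturalistic
contour per patch that crosses the horizontal midline, nonzero overlap
between the pair) without shipping any image data. Degenerate draws are
retried with a derived sub-seed (bounded budget, then an error).

**Blending.** The four region intensities follow the two-layer alpha
blend exactly (see README); they are computed per region in float64 and
quantized to 8 bit only on PNG export, so the analytic invariants (alpha
limits, conservation when all intensities coincide, per-channel
monotonicity in `α_front`) hold exactly on the analysis raster. Default
permeation rates are `α_front = α_back = 0.5`; per-observer α values are a
config field (the original per-participant transparency calibration is out
of scope).

**Factorial variants and ground truth.** Each base pair expands to
2 (mirror) × 2 (depth order, i.e. which color is in front) × 2
(translation target) = 8 variants. The whole composite is translated
horizontally so that a contour crossing of the target surface lands
between the two columns flanking x = 0 on the centre row (the crossing
nearest the centre is chosen). `condition` is *consistent* when the front
surface's own contour is centred and *contradictory* when the back
surface's is; `dof_truth` is the side on which the target surface's
interior lies at the centre, determined from the interior run lengths
within a 0.5° window (longer run wins on ties); `figure_color_truth` is
the front surface's color. Mirroring balances left/right DOF across the
set; the full set is 38 × 8 = 304 stimuli, half consistent and half
contradictory by construction.

## Synthetic gaze and behavior

The simulator emulates a 60 Hz remote tracker. A trial is a planned
scanpath (ordered target points with durations); samples within a planned
fixation are target + per-trial systematic offset (SD 0.74° per axis,
modelling calibration accuracy) + per-sample jitter (SD 0.3°); saccades
are instantaneous steps between samples, which at 60 Hz is as sharp as
real saccades appear; samples drop out independently with probability
0.14, reproducing the reported ~51.6 valid samples/s at a 60 Hz nominal
rate. Everything is driven by a single seed (bit-identical traces for
identical inputs).

Per trial, the figure- and ground-region first-fixation durations are
drawn from task × condition × region cell means plus a per-participant
offset (SD 30 ms) and trial noise (SD 80 ms), redrawn below 50 ms (below
plausible fixation duration and below detector resolution). The two
regions are visited in random order and the window is padded with a
return fixation. Default cell means encode the qualitative structure the
statistics should recover — FG task: figure/ground 320/230 ms consistent,
400/170 ms contradictory (a condition × region interaction); DOF task:
flat 230/250 ms — and default 2AFC accuracies make DOF discrimination
easier than FG segregation (0.95/0.92 vs 0.80/0.72). No numeric DFF means
are published, so these are the package's own choices of plausible
magnitudes; they are fixed defaults, not fitted quantities.

Scanpath targets are the deepest interior pixel of each region within
3.2° of the centre (distance-transform argmax restricted to a central
disk; global argmax as fallback). The restriction reflects how observers
inspect such displays — the ground is sampled near the shapes, not at the
screen edge — and keeps offset-jittered fixations on the stimulus field.

**What the simulator does not model:** main-sequence saccade kinematics,
smooth pursuit, microsaccades, blinks as structured (bursty) loss — blinks
are folded into independent dropout — pupil signals, and any dependence of
gaze strategy on the task instruction beyond the injected DFF means.
Passing recovery tests therefore shows that the *pipeline* is unbiased and
the *statistics* have the right operating characteristics under this
generative model; it does not validate the detector against human
saccades.

## Fixation pipeline

**Exclusion.** A trial is excluded when more than 10 samples are missing
or invalid within the 1000 ms stimulus window (nominal 60 expected; at the
default dropout ~8 missing is typical, so >10 flags atypical loss). The
threshold is configurable.

**Saccade detection.** Velocities: centred moving-window finite
difference, `v_i = Σ_{k=1..h}(p_{i+k} − p_{i−k}) / (h(h+1)Δt)` with
window 5 (h = 2). Noise scale per axis: `σ² = median(v²) − (median v)²`.
Threshold: a sample is saccadic when `(vx/λσx)² + (vy/λσy)² > 1`, λ = 6.
Runs of saccadic samples (length ≥ 1) form events; velocities are
undefined wherever the window touches an invalid sample, so data loss
breaks runs. Degenerate axes: if σ = 0 and the axis velocity is zero the
axis contributes nothing (a constant trace yields no saccades); if σ = 0
but a velocity is nonzero that sample is saccadic — otherwise noiseless
step traces, whose median velocity is zero, would hide real saccades.

**Fixation segmentation.** Maximal runs of valid, non-saccadic samples
form fixations (centroid = mean member position). Two timing conventions:
at trace edges a fixation spans from its first sample to one sample
period past its last (a full quiet 1000 ms trace is one 1000 ms
fixation); at saccade-adjacent boundaries the fixation ends/starts at the
*temporal midpoint of the saccade event*. The centred differentiator
spreads an instantaneous step symmetrically over ~4 samples, so the
midpoint is an unbiased estimate of the true transition time; using the
member-sample span instead would lose two samples (~33 ms) per boundary
systematically. Brief data-loss gaps of up to `max_gap_samples` invalid
samples (default 3 ≈ 50 ms) do not interrupt a fixation, the standard
gap-fill-in used by I-VT-style filters; set 0 for strict run-breaking.

**Region assignment and DFF.** A fixation is assigned through the region
label under its centroid (a per-sample majority mode is available).
By default *figure* is the front surface's footprint (front-only ∪
overlap) and everything else visible is *ground*; an alternative mapping
(`both-surfaces`) counts the back surface's visible area as figure, since
the original definition is ambiguous on this point. Points outside the
9° × 9° field are *off-stimulus*. The DFF for a region is the duration of
the earliest fixation assigned to it, clipped to the stimulus window; a
fixation already ongoing at onset counts from the onset. Absent when the
region is never fixated within the window.

## Statistics

Correct responses: DOF task — the response matches the side toward the
surface owning the centre contour; FG task — the response names the color
of the physically front surface. t-tests are Student: paired on
participant-level values (df = n − 1) and pooled two-sample on trial-level
values (df = n_a + n_b − 2, matching the printed integer dfs; Welch is
deliberately not used). Sidedness is explicit and configurable because
the published participant-level comparison is only consistent with a
one-sided reading. Inputs with zero-variance differences are degenerate
(error), except exactly identical inputs, which return t = 0.

The ANOVA is fixed-effects and fully crossed with a single residual error
term; participant is a fixed factor tested against that residual, matching
how the reference tables are laid out. Sums of squares are Type III with
sum-to-zero contrasts (statsmodels OLS + `anova_lm`), which equals the
classical decomposition on balanced data and is the closest conventional
match for post-exclusion unbalanced data. Partial eta squared is
`SS_effect / (SS_effect + SS_error)`. No multiplicity correction is
applied by default (none is used in the reference analysis); a Holm
helper exists.

**Reference-table audit.** `fggaze.reference_tables` stores the published
three-way decompositions; the audit recomputes MS, F and η²_p from the
printed SS/df. The FG-task table reproduces to ~1% (three-significant-
figure rounding), with one exception: the printed three-way-interaction
η²_p (0.0110) lies outside the interval implied by any rounding of its
printed SS ([0.0108, 0.0109]) and is off by 1.3%. The DOF-task table's
printed η²_p values disagree with their own printed SS by ~20% across the
board while its F values reproduce to <1%; the audit reports this
inconsistency rather than resolving it.

## Problem sizes and numerical tolerances

Counts and condition metadata are raster-independent, so test fixtures
build the full 304-stimulus set at 16 px/deg and single stimuli at
20 px/deg; production default stays 50 px/deg. Blend identities are
asserted exactly at the alpha limits and to 1e-12 at interior alphas
(1e-9 under arbitrary non-dyadic floats). Detector equivalence against a
literal per-sample oracle is exact on 150 random traces of ≤120 samples.
DFF recovery uses 1000 zero-noise and 1000 jittered trials; ANOVA
operating characteristics use 100 null and 100 interaction replicates of
the full single-task schedule via the traceless fast path (ground-truth
DFF records). ANOVA sums of squares match the projection oracle to 1e-8
relative; t statistics match closed forms to 1e-12.

## Known limitations

- Independent per-sample dropout understates the burstiness of real data
  loss; with the default rate the >10-missing rule excludes ~20% of
  simulated trials, more than a tracker with blink-dominated loss would
  see.
- The per-trial offset model makes region misassignment (and hence DFF
  cross-contamination between figure and ground) more severe for thin
  regions; measured cell means are biased upward by occasional long
  misassigned fixations even though the factorial structure survives.
- Fixed-factor participant terms mean generalization is to these
  participants only; no mixed-effects option is provided.
- The procedural shapes match the published displays topologically, not
  visually; effects that depend on natural-image statistics are outside
  what the simulation can show.
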