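import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fggaze as fg
from fggaze.fixation_pipeline import (Fixation, GazeParseError,
                                      SaccadeDetectorParams, TrialTrace,
                                      assign_region, detect_saccades,
                                      exclude_trial, first_fixation_duration,
                                      load_gaze_log, segment_fixations)
from fggaze.stimulus_synth import BACK_ONLY, FRONT_ONLY, GROUND, OVERLAP
from fggaze.synthetic_gaze import (NoiseModel, PlannedFixation, ScanpathSpec,
                                   ZERO_NOISE, region_target_points,
                                   simulate_trace)
from oracles import brute_force_saccades

DT = 1000.0 / 60.0


def make_trace(x, y=None, valid=None, dt=DT):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(len(x), bool) if valid is None else np.asarray(valid, bool)
    return TrialTrace(t_ms=np.arange(len(x)) * dt, x=x, y=y, valid=valid,
                      trial_id="t", participant="p")


def random_trace(rng):
    """A random plausible trace: 1-4 fixations, optional jitter/dropout."""
    n = int(rng.integers(20, 121))
    n_fix = int(rng.integers(1, 5))
    bounds = np.sort(rng.choice(np.arange(2, n - 2), size=n_fix - 1,
                                replace=False)) if n_fix > 1 else []
    targets = rng.uniform(-4, 4, size=(n_fix, 2))
    idx = np.searchsorted(bounds, np.arange(n), side="right")
    x = targets[idx, 0]
    y = targets[idx, 1]
    jitter = rng.choice([0.0, 0.05, 0.3])
    x = x + rng.normal(0, jitter, n)
    y = y + rng.normal(0, jitter, n)
    dropout = rng.choice([0.0, 0.1])
    valid = rng.random(n) >= dropout
    x[~valid] = np.nan
    y[~valid] = np.nan
    return make_trace(x, y, valid)


class TestLoadGazeLog:
    def test_roundtrip_two_trials(self, tmp_path):
        path = tmp_path / "gaze.csv"
        path.write_text(
            "trial_id,participant,t_ms,x_deg,y_deg,valid\n"
            "a,P0,0,0.1,0.2,1\n"
            "a,P0,16.7,,,0\n"
            "b,P0,0,1.0,-1.0,1\n"
            "b,P0,16.7,1.1,-0.9,1\n"
            "b,P0,33.3,1.2,-0.8,1\n")
        trials = load_gaze_log(path)
        assert [t.trial_id for t in trials] == ["a", "b"]
        assert len(trials[0]) == 2 and len(trials[1]) == 3
        assert not trials[0].valid[1]
        assert np.isnan(trials[0].x[1])

    def test_shuffled_timestamps_sorted(self, tmp_path):
        path = tmp_path / "gaze.csv"
        path.write_text(
            "trial_id,participant,t_ms,x_deg,y_deg,valid\n"
            "a,P0,33.3,3,0,1\n"
            "a,P0,0,1,0,1\n"
            "a,P0,16.7,2,0,1\n")
        (trace,) = load_gaze_log(path)
        assert np.array_equal(trace.t_ms, [0, 16.7, 33.3])
        assert np.array_equal(trace.x, [1, 2, 3])

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        path = tmp_path / "gaze.csv"
        path.write_text(
            "trial_id,participant,t_ms,x_deg,y_deg,valid\n"
            "a,P0,0,0.1,0.2,1\n"
            "a,P0,16.7,oops,0.2,1\n")
        with pytest.raises(GazeParseError, match="line 3"):
            load_gaze_log(path)


class TestExclusion:
    def test_complete_trial_kept(self):
        trace = make_trace(np.zeros(60))
        assert exclude_trial(trace)

    def test_boundary_ten_missing_kept(self):
        valid = np.ones(60, bool)
        valid[:10] = False
        assert exclude_trial(make_trace(np.zeros(60), valid=valid))

    def test_eleven_missing_excluded(self):
        valid = np.ones(60, bool)
        valid[:11] = False
        assert not exclude_trial(make_trace(np.zeros(60), valid=valid))

    def test_fifteen_missing_excluded(self):
        valid = np.ones(60, bool)
        valid[10:25] = False
        assert not exclude_trial(make_trace(np.zeros(60), valid=valid))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 59), min_size=0, max_size=25, unique=True),
           st.integers(0, 59))
    def test_exclusion_monotone_in_missingness(self, drop, extra):
        """Invalidating one more sample can flip keep -> exclude but never
        exclude -> keep."""
        valid = np.ones(60, bool)
        valid[drop] = False
        before = exclude_trial(make_trace(np.zeros(60), valid=valid))
        valid2 = valid.copy()
        valid2[extra] = False
        after = exclude_trial(make_trace(np.zeros(60), valid=valid2))
        assert after <= before


class TestDetectSaccades:
    def test_constant_trace_no_saccades(self):
        assert detect_saccades(make_trace(np.zeros(60))) == []

    def test_single_step_yields_one_saccade(self):
        x = np.concatenate([np.zeros(30), np.full(30, 4.0)])
        events = detect_saccades(make_trace(x))
        assert len(events) == 1
        assert events[0].displacement_deg == pytest.approx(4.0)

    def test_pure_jitter_rarely_triggers(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            trace = make_trace(rng.normal(0, 0.3, 60),
                               rng.normal(0, 0.3, 60))
            if detect_saccades(trace):
                hits += 1
        assert hits <= 2  # zero saccades in >= 95% of seeds

    def test_all_invalid_warns_and_returns_empty(self):
        trace = make_trace(np.full(20, np.nan), valid=np.zeros(20, bool))
        with pytest.warns(UserWarning):
            assert detect_saccades(trace) == []

    def test_invalid_samples_break_runs(self):
        x = np.concatenate([np.zeros(30), np.full(30, 4.0)])
        valid = np.ones(60, bool)
        valid[29] = False
        x = x.copy()
        x[29] = np.nan
        events = detect_saccades(make_trace(x, valid=valid))
        for e in events:
            assert not (e.onset_index <= 29 <= e.offset_index)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_bruteforce_oracle(self, window):
        rng = np.random.default_rng(2024)
        params = SaccadeDetectorParams(velocity_window=window)
        for _ in range(60):
            trace = random_trace(rng)
            got = [(e.onset_index, e.offset_index)
                   for e in detect_saccades(trace, params)]
            expected = brute_force_saccades(trace.t_ms, trace.x, trace.y,
                                            trace.valid, lam=6.0,
                                            window=window)
            assert got == expected

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SaccadeDetectorParams(velocity_window=4)
        with pytest.raises(ValueError):
            SaccadeDetectorParams(lambda_threshold=0)


class TestSegmentFixations:
    def test_full_quiet_trace_single_fixation(self):
        trace = make_trace(np.zeros(60))
        (fix,) = segment_fixations(trace, [])
        assert fix.duration_ms == pytest.approx(1000.0)
        assert (fix.centroid_x, fix.centroid_y) == (0.0, 0.0)

    def test_one_saccade_two_fixations(self):
        x = np.concatenate([np.zeros(24), np.full(36, 4.0)])
        trace = make_trace(x)
        events = detect_saccades(trace)
        fixations = segment_fixations(trace, events)
        assert len(fixations) == 2
        a, b = fixations
        assert a.offset_ms <= b.onset_ms
        assert a.duration_ms == pytest.approx(400.0, abs=DT)
        assert b.duration_ms == pytest.approx(600.0, abs=DT)

    def test_every_valid_sample_in_exactly_one_event(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            trace = random_trace(rng)
            events = detect_saccades(trace)
            fixations = segment_fixations(trace, events)
            owner = np.zeros(len(trace), dtype=int)
            for e in events:
                owner[e.onset_index:e.offset_index + 1] += 1
            for f in fixations:
                seg = np.arange(f.first_index, f.last_index + 1)
                owner[seg[trace.valid[seg]]] += 1
            assert np.all(owner[trace.valid] == 1)
            assert np.all(owner[~trace.valid] == 0)

    def test_short_dropout_gap_bridged(self):
        """A brief data-loss gap does not end a dwell; strict mode does."""
        x = np.zeros(60)
        valid = np.ones(60, bool)
        valid[30:32] = False
        x[30:32] = np.nan
        trace = make_trace(x, valid=valid)
        bridged = segment_fixations(trace, [], max_gap_samples=3)
        assert len(bridged) == 1
        assert bridged[0].duration_ms == pytest.approx(1000.0)
        strict = segment_fixations(trace, [], max_gap_samples=0)
        assert len(strict) == 2

    def test_long_dropout_gap_breaks_fixation(self):
        x = np.zeros(60)
        valid = np.ones(60, bool)
        valid[28:34] = False
        x[28:34] = np.nan
        trace = make_trace(x, valid=valid)
        assert len(segment_fixations(trace, [], max_gap_samples=3)) == 2

    def test_fixations_ordered_nonoverlapping(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            trace = random_trace(rng)
            fixations = segment_fixations(trace, detect_saccades(trace))
            for a, b in zip(fixations, fixations[1:]):
                assert a.offset_ms <= b.onset_ms
                assert a.duration_ms > 0 and b.duration_ms > 0


class TestRegionsAndDFF:
    def test_overlap_centroid_is_figure(self, one_stimulus):
        rows, cols = np.nonzero(one_stimulus.region_map == OVERLAP)
        r, c = rows.mean(), cols.mean()
        ppd = one_stimulus.px_per_deg
        x = (c + 0.5) / ppd - one_stimulus.extent_deg / 2
        y = one_stimulus.extent_deg / 2 - (r + 0.5) / ppd
        fix = Fixation(0, 100, x, y, 0, 5)
        if one_stimulus.region_label_at(x, y) in (FRONT_ONLY, OVERLAP):
            assert assign_region(fix, one_stimulus) == "figure"

    def test_region_mapping_modes(self, one_stimulus):
        rows, cols = np.nonzero(one_stimulus.region_map == BACK_ONLY)
        ppd = one_stimulus.px_per_deg
        k = len(rows) // 2
        x = (cols[k] + 0.5) / ppd - one_stimulus.extent_deg / 2
        y = one_stimulus.extent_deg / 2 - (rows[k] + 0.5) / ppd
        fix = Fixation(0, 100, x, y, 0, 5)
        assert assign_region(fix, one_stimulus, "front-footprint") == "ground"
        assert assign_region(fix, one_stimulus, "both-surfaces") == "figure"

    def test_white_background_is_ground(self, one_stimulus):
        fix = Fixation(0, 100, 4.3, 4.3, 0, 5)
        assert one_stimulus.region_label_at(4.3, 4.3) == GROUND
        assert assign_region(fix, one_stimulus) == "ground"

    def test_outside_field_is_off_stimulus(self, one_stimulus):
        fix = Fixation(0, 100, 10.0, 0.0, 0, 5)
        assert assign_region(fix, one_stimulus) == "off-stimulus"

    def test_single_central_fixation_dff(self, one_stimulus):
        pts = region_target_points(one_stimulus)
        fix = Fixation(0.0, 1000.0, *pts["figure"], 0, 59)
        assert first_fixation_duration([fix], one_stimulus,
                                       "figure") == 1000.0
        assert first_fixation_duration([fix], one_stimulus, "ground") is None

    def test_fixation_spanning_onset_clipped(self, one_stimulus):
        pts = region_target_points(one_stimulus)
        fix = Fixation(-200.0, 400.0, *pts["figure"], 0, 30)
        assert first_fixation_duration([fix], one_stimulus,
                                       "figure") == 400.0

    def test_two_region_scanpath_dffs(self, one_stimulus):
        pts = region_target_points(one_stimulus)
        spec = ScanpathSpec([PlannedFixation(*pts["ground"], 300.0),
                             PlannedFixation(*pts["figure"], 500.0),
                             PlannedFixation(*pts["ground"], 200.0)])
        trial = simulate_trace(spec, ZERO_NOISE, seed=0)
        trace = TrialTrace.from_dataframe(trial.samples)
        fixations = segment_fixations(trace, detect_saccades(trace))
        for f in fixations:
            f.region = assign_region(f, one_stimulus)
        dff_g = first_fixation_duration(fixations, one_stimulus, "ground")
        dff_f = first_fixation_duration(fixations, one_stimulus, "figure")
        assert dff_g == pytest.approx(300.0, abs=DT)
        assert dff_f == pytest.approx(500.0, abs=DT)


class TestProcessTrial:
    def test_excluded_trial_produces_no_dff(self, one_stimulus):
        x = np.zeros(60)
        valid = np.ones(60, bool)
        valid[:20] = False
        x[:20] = np.nan
        trace = make_trace(x, valid=valid)
        res = fg.process_trial(trace, one_stimulus)
        assert not res.kept
        assert res.dff == {"figure": None, "ground": None}

    def test_kept_trial_reports_regions(self, one_stimulus):
        pts = region_target_points(one_stimulus)
        spec = ScanpathSpec([PlannedFixation(*pts["figure"], 600.0),
                             PlannedFixation(*pts["ground"], 400.0)])
        trial = simulate_trace(spec, ZERO_NOISE, seed=0)
        trace = TrialTrace.from_dataframe(trial.samples)
        res = fg.process_trial(trace, one_stimulus)
        assert res.kept
        assert res.dff["figure"] == pytest.approx(600.0, abs=DT)
        assert res.dff["ground"] == pytest.approx(400.0, abs=DT)


class TestDFFRecovery:
    def _run(self, n_trials, noise, stim, seed0):
        pts = region_target_points(stim)
        rng = np.random.default_rng(seed0)
        errors = []
        for i in range(n_trials):
            d1 = float(rng.uniform(150, 450))
            d2 = float(rng.uniform(200, 500))
            first, second = (("ground", "figure") if rng.random() < 0.5
                             else ("figure", "ground"))
            spec = ScanpathSpec([
                PlannedFixation(*pts[first], d1),
                PlannedFixation(*pts[second], d2),
                PlannedFixation(*pts[first], max(1000 - d1 - d2, DT))])
            trial = simulate_trace(spec, noise, seed=seed0 + i)
            trace = TrialTrace.from_dataframe(trial.samples)
            fixations = segment_fixations(trace, detect_saccades(trace))
            for f in fixations:
                f.region = assign_region(f, stim)
            region_of = lambda x, y: assign_region(
                Fixation(0, 1, x, y, 0, 0), stim)
            for region in (first, second):
                truth = trial.true_dff(region_of, region)
                got = first_fixation_duration(fixations, stim, region)
                if truth is not None and got is not None:
                    errors.append(abs(got - truth))
                else:
                    errors.append(np.inf)
        return np.array(errors)

    def test_zero_jitter_recovery_within_one_sample(self, one_stimulus):
        errors = self._run(200, ZERO_NOISE, one_stimulus, seed0=100)
        assert np.mean(errors <= DT + 1e-9) >= 0.95

    def test_jittered_recovery_median_within_two_samples(self, one_stimulus):
        noise = NoiseModel(jitter_sd=0.3, offset_sd=0.0, dropout_rate=0.0)
        errors = self._run(200, noise, one_stimulus, seed0=300)
        assert np.median(errors) <= 2 * DT
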