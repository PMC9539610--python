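"""Window-wise mixed models, cluster rule, CV localization, follow-ups."""

import numpy as np
import pandas as pd
import pytest

from pupilwm.pupil import preprocess_traces, windowed_frame
from pupilwm.synth import (SimConfig, simulate_delayed_estimation,
                           simulate_pupil)
from pupilwm.timeseries import (TimeSeriesTestConfig, _fold_assignment,
                                contiguous_significance,
                                crossval_localize_test, followup_by_load,
                                run_time_series_analysis, windowed_lmm)

from conftest import fast_pupil_spec, null_pupil_spec

FAST_TS = dict(window_ms=100.0, random_structure="intercept")


def windowed(structure, trials, spec, seed, bin_ms=100.0):
    traces = simulate_pupil(trials, spec, seed=seed)
    return windowed_frame(preprocess_traces(traces, bin_ms=bin_ms), trials)


def brute_force_clusters(starts, pvals, alpha, min_windows, window_ms):
    """Independent oracle: check every possible run explicitly."""
    sig = [(p < alpha) if np.isfinite(p) else False for p in pvals]
    out, n = [], len(sig)
    i = 0
    while i < n:
        if sig[i] and (i == 0 or not sig[i - 1]):
            j = i
            while j < n and sig[j]:
                j += 1
            if j - i >= min_windows:
                out.append((starts[i], starts[j - 1] + window_ms))
            i = j
        else:
            i += 1
    return out


class TestContiguousSignificance:
    @pytest.mark.parametrize("n_sig, n_clusters", [(25, 1), (20, 1), (19, 0)])
    def test_run_length_threshold(self, n_sig, n_clusters):
        p = np.ones(100)
        p[40:40 + n_sig] = 0.01
        starts = np.arange(100) * 10.0
        clusters = contiguous_significance(starts, p)
        assert len(clusters) == n_clusters
        if n_clusters:
            assert clusters[0] == (400.0, 400.0 + n_sig * 10.0)

    def test_interrupted_runs_stay_separate(self):
        p = np.ones(100)
        p[10:30] = 0.01
        p[31:51] = 0.01      # one non-significant window between runs
        clusters = contiguous_significance(np.arange(100) * 10.0, p)
        assert len(clusters) == 2

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        cfg = TimeSeriesTestConfig()
        starts = np.arange(250) * 10.0
        for _ in range(200):
            p = rng.random(250) ** 3      # plenty of sub-alpha windows
            got = contiguous_significance(starts, p, cfg)
            want = brute_force_clusters(starts, p, cfg.alpha,
                                        cfg.min_windows, cfg.window_ms)
            assert got == want


class TestFoldAssignment:
    def test_partition_and_interleaving(self, small_trials):
        meta = small_trials[["participant", "trial", "memory_load",
                             "color_type"]]
        folds = _fold_assignment(meta, 4)
        assert folds.shape == (len(meta),)
        # every trial in exactly one fold, balanced within participant
        df = meta.assign(fold=folds)
        for _, grp in df.groupby("participant"):
            counts = grp.fold.value_counts()
            assert counts.max() - counts.min() <= 1
            in_order = grp.sort_values("trial").fold.to_numpy()
            assert np.array_equal(in_order[:8], np.tile([0, 1, 2, 3], 2))


class TestWindowedLmm:
    def test_recovers_injected_load_slope(self, structure7, small_trials):
        spec = null_pupil_spec(load_slope=10.0, noise_sd=1.0, blink_rate=0.0,
                               baseline_sd_between_trial=0.0)
        wf = windowed(structure7, small_trials, spec, seed=1)
        res = windowed_lmm(wf, TimeSeriesTestConfig(**FAST_TS))
        load = res[res.term == "load"].set_index("window_start_ms")
        post = load.loc[load.index >= 500, "coef"].to_numpy()
        assert post == pytest.approx(10.0, rel=0.05)
        pre = load.loc[(load.index >= 100) & (load.index < 500), "coef"]
        assert np.abs(pre).max() < 0.5

    def test_permuting_color_type_kills_interaction(self, structure7,
                                                    small_trials):
        spec = fast_pupil_spec(blink_rate=0.0)
        wf = windowed(structure7, small_trials, spec, seed=2)
        cfg = TimeSeriesTestConfig(**FAST_TS)
        res = windowed_lmm(wf, cfg)
        inter = res[res.term == "load:color_type"]
        inside = inter[(inter.window_start_ms >= 1300)
                       & (inter.window_start_ms < 2100)]
        real_strength = np.abs(inside.z).mean()

        rng = np.random.default_rng(3)
        shuffled = wf.copy()
        for pp, grp in shuffled.groupby("participant"):
            trial_ids = grp.trial.unique()
            mapping = dict(zip(trial_ids, rng.permutation(trial_ids)))
            orig = shuffled.loc[shuffled.participant == pp]
            lookup = (small_trials[small_trials.participant == pp]
                      .set_index("trial").color_type)
            shuffled.loc[shuffled.participant == pp, "color_type"] = \
                orig.trial.map(mapping).map(lookup).to_numpy()
        res_p = windowed_lmm(shuffled, cfg)
        inter_p = res_p[res_p.term == "load:color_type"]
        inside_p = inter_p[(inter_p.window_start_ms >= 1300)
                           & (inter_p.window_start_ms < 2100)]
        assert np.abs(inside_p.z).mean() < real_strength / 2
        assert np.abs(inside_p.z).mean() < 2.5

    def test_failed_windows_reported_not_dropped(self):
        # two participants, degenerate DV in one window
        rng = np.random.default_rng(0)
        rows = []
        for pp in range(4):
            for trial in range(16):
                for start in (0.0, 10.0):
                    rows.append({"participant": pp, "trial": trial,
                                 "window_start_ms": start,
                                 "pupil": np.nan if start == 0.0
                                 else rng.normal(),
                                 "memory_load": trial % 4 + 1,
                                 "color_type": ["prototypical", "ambiguous"]
                                 [trial % 2]})
        res = windowed_lmm(pd.DataFrame(rows),
                           TimeSeriesTestConfig(window_ms=10,
                                                min_duration_ms=20,
                                                random_structure="intercept"))
        w0 = res[res.window_start_ms == 0.0]
        assert len(w0) == 4 and w0.failed.all()
        assert not res[res.window_start_ms == 10.0].failed.any()


class TestCrossValLocalization:
    def test_winning_windows_and_sign_with_strong_effect(self, structure7,
                                                         small_trials):
        spec = fast_pupil_spec(noise_sd=5.0, blink_rate=0.0,
                               baseline_sd_between_trial=0.0)
        wf = windowed(structure7, small_trials, spec, seed=4)
        win, z, p = crossval_localize_test(
            wf, TimeSeriesTestConfig(**FAST_TS))
        assert all(1200.0 <= w < 2140.0 for w in win)
        # amplitudes fall with load for ambiguous -> negative interaction
        assert z < 0 and p < 0.01

    def test_full_analysis_report(self, structure7, small_trials):
        spec = fast_pupil_spec(blink_rate=0.0)
        wf = windowed(structure7, small_trials, spec, seed=5)
        res = run_time_series_analysis(wf, TimeSeriesTestConfig(**FAST_TS))
        assert set(res.clusters) == {"load", "color_type", "load:color_type"}
        for start, end in res.clusters["load"]:
            assert end - start >= 200.0
        assert len(res.cv_winning_samples) == 4
        assert set(res.followups) <= {1, 2, 3, 4}


class TestFollowupByLoad:
    def test_load1_only_effect_is_localized(self, structure7, small_trials):
        spec = null_pupil_spec(
            noise_sd=20.0, blink_rate=0.0,
            interaction_amplitude_by_load={1: 40.0, 2: 0.0, 3: 0.0, 4: 0.0})
        wf = windowed(structure7, small_trials, spec, seed=6)
        fu = followup_by_load(wf, (1290.0, 2140.0),
                              TimeSeriesTestConfig(**FAST_TS))
        assert fu[1]["z"] > 0 and fu[1]["p"] < 0.05
        for load in (2, 3, 4):
            assert abs(fu[load]["z"]) < 3.0

    def test_window_without_effect_is_null(self, structure7, small_trials):
        spec = null_pupil_spec(noise_sd=20.0, blink_rate=0.0)
        wf = windowed(structure7, small_trials, spec, seed=7)
        fu = followup_by_load(wf, (1290.0, 2140.0),
                              TimeSeriesTestConfig(**FAST_TS))
        assert all(abs(v["z"]) < 3.5 for v in fu.values())
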