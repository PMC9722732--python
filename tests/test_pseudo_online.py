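"""Sliding windows, double-threshold CMC onset, and pseudo-online scoring.

The onset scanner and the TP/FP/FN assignment are checked against exhaustive
brute-force enumeration over every binary window string up to length 12.
"""

import itertools
import math

import numpy as np
import pytest

from cmcdetect.pseudo_online import (CMCTrajectory, SlidingWindowConfig,
                                     cmc_onset, cmc_trajectory,
                                     compare_onsets, detection_summary,
                                     metric_table, required_run_length,
                                     rest_threshold, score_prediction_string,
                                     sliding_windows)

SHIFTS = (0.125, 0.25, 0.5)


def _traj(bits, shift):
    bits = np.asarray(bits, float)
    end_times = 1.0 + shift * np.arange(bits.size)
    return CMCTrajectory(0, ("C3", "ED_R"), end_times, bits, shift)


def _all_bitstrings(max_len):
    for length in range(1, max_len + 1):
        yield from itertools.product((0, 1), repeat=length)


class TestSlidingWindows:
    @pytest.mark.parametrize("dur,shift,expected", [
        (8.0, 0.125, 57), (8.0, 0.25, 29), (8.0, 0.5, 15),
        (4.0, 0.125, 25), (4.0, 0.25, 13), (4.0, 0.5, 7),
    ])
    def test_window_counts(self, dur, shift, expected):
        fs = 1000.0
        wins = sliding_windows(int(dur * fs), fs, SlidingWindowConfig(shift))
        assert len(wins) == expected
        assert wins[0][2] == pytest.approx(1.0)  # first END time
        assert wins[-1][1] <= dur * fs

    def test_count_formula_matches_enumeration(self):
        fs = 1000.0
        for dur in (1.0, 2.5, 4.0, 8.0):
            for shift in SHIFTS:
                wins = sliding_windows(int(dur * fs), fs,
                                       SlidingWindowConfig(shift))
                assert len(wins) == math.floor((dur - 1.0) / shift + 1e-9) + 1

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_windows(800, 1000.0)


def test_required_run_length_per_shift():
    assert [required_run_length(s) for s in SHIFTS] == [4, 2, 1]


class TestCMCOnset:
    def test_brute_force_equivalence(self):
        """Scanner agrees with naive enumeration on every string <= length 12."""
        for shift in SHIFTS:
            k = required_run_length(shift)
            for bits in _all_bitstrings(12):
                traj = _traj(bits, shift)
                got = cmc_onset(traj, 0.5)
                # oracle: first position opening k consecutive supra windows
                expected = None
                for i in range(len(bits) - k + 1):
                    if all(bits[i:i + k]):
                        expected = traj.end_times[i]
                        break
                assert got == expected, (bits, shift)

    def test_no_suprathreshold_window_gives_no_onset(self):
        assert cmc_onset(_traj([0] * 20, 0.125), 0.5) is None

    def test_single_window_qualifies_at_500ms_shift(self):
        # one 500-ms step already spans the persistence requirement
        traj = _traj([0, 0, 1, 0], 0.5)
        assert cmc_onset(traj, 0.5) == pytest.approx(2.0)


class TestRestThreshold:
    def test_constant_pool(self):
        assert rest_threshold([_traj([0.3] * 10, 0.125)]) == 0.3

    def test_linear_interpolation_percentile(self):
        vals = np.arange(0.01, 1.005, 0.01)
        thr = rest_threshold([_traj(vals, 0.125)])
        assert thr == pytest.approx(np.percentile(vals, 95))
        assert thr == pytest.approx(0.9505)

    def test_threshold_within_pool_range(self, rng):
        trajs = [_traj(rng.uniform(0, 1, 25), 0.125) for _ in range(5)]
        pool = np.concatenate([t.values for t in trajs])
        assert pool.min() <= rest_threshold(trajs) <= pool.max()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            rest_threshold([])


class TestCompareOnsets:
    @pytest.mark.parametrize("cmc,emg,expected", [
        (4.4, 4.0, "TD"), (3.5, 4.0, "FD"), (None, 4.0, "ND"),
        (4.0, 4.0, "TD"),  # exact coincidence is not an anticipation
    ])
    def test_categories(self, cmc, emg, expected):
        assert compare_onsets(cmc, emg) == expected


class TestDetectionSummary:
    def test_rates_and_delay(self):
        cats = ["TD"] * 8 + ["FD", "ND"]
        out = detection_summary(cats, [0.3, 0.5, 0.2, 0.4, 0.3, 0.5, 0.2,
                                       0.4, np.nan, np.nan])
        assert (out["td_rate"], out["fd_rate"], out["nd_rate"]) == \
            (0.8, 0.1, 0.1)
        assert out["td_rate"] + out["fd_rate"] + out["nd_rate"] == 1.0
        out2 = detection_summary(["TD", "TD"], [0.3, 0.5])
        assert out2["md"] == pytest.approx(0.4)

    def test_no_td_gives_absent_delay(self):
        assert detection_summary(["ND"], [np.nan])["md"] is None


def _score_oracle(preds, end_times, onset, m):
    """Slice-based reference: FP when an all-task M-slice lies fully before
    the onset, else TP at the first all-task M-slice fully after it."""
    after = [t > onset for t in end_times]
    for i in range(len(preds) - m + 1):
        if all(preds[i:i + m]) and not any(after[i:i + m]):
            return "FP", None
    for i in range(len(preds) - m + 1):
        if all(preds[i:i + m]) and all(after[i:i + m]):
            return "TP", end_times[i + m - 1]
    return "FN", None


class TestScorePredictionString:
    def test_brute_force_equivalence(self):
        for shift in SHIFTS:
            for m in (1, 2, 3):
                for bits in _all_bitstrings(12):
                    ends = [1.0 + shift * i for i in range(len(bits))]
                    onset = 1.0 + shift * (len(bits) // 2) + shift / 2
                    got = score_prediction_string(np.array(bits, bool),
                                                  np.array(ends), onset, m)
                    assert got == _score_oracle(bits, ends, onset, m)

    def test_all_rest_predictions_is_false_negative(self):
        out = score_prediction_string(np.zeros(10, bool),
                                      1 + 0.125 * np.arange(10), 4.0, 2)
        assert out == ("FN", None)

    def test_detection_time_is_mth_window_end(self):
        ends = 1.0 + 0.125 * np.arange(57)
        preds = np.zeros(57, bool)
        preds[26] = preds[27] = True  # end times 4.250 and 4.375 s
        outcome, t_m = score_prediction_string(preds, ends, 4.0, 2)
        assert outcome == "TP"
        assert t_m == pytest.approx(4.375)

    def test_any_preonset_task_window_is_fp_at_m1(self):
        preds = np.zeros(57, bool)
        preds[0] = True  # ends at 1.0 s, long before the onset
        preds[30:] = True  # a clean post-onset run exists too
        out = score_prediction_string(preds, 1 + 0.125 * np.arange(57), 4.0, 1)
        assert out == ("FP", None)

    def test_detection_time_monotone_in_m(self):
        # whenever a trial is TP at both M and M+1, T_{M+1} >= T_M
        ends = np.arange(1.0, 13.0)
        for bits in _all_bitstrings(12):
            preds = np.array(bits + (0,) * (12 - len(bits)), bool)
            prev = None
            for m in (1, 2, 3):
                out, t_m = score_prediction_string(preds, ends, 3.5, m)
                if out == "TP" and prev is not None:
                    assert t_m >= prev
                prev = t_m if out == "TP" else prev

    def test_fp_count_nonincreasing_in_m(self, rng):
        ends = 1 + 0.125 * np.arange(25)
        strings = rng.random((200, 25)) < 0.3
        counts = []
        for m in (1, 2, 3):
            counts.append(sum(score_prediction_string(s, ends, 2.0, m)[0]
                              == "FP" for s in strings))
        assert counts[0] >= counts[1] >= counts[2]


class TestOnPipelineRun:
    def test_trajectory_values_and_length(self, pipeline_report):
        trials = pipeline_report.trials
        t = trials.kept("task")[0]
        traj = cmc_trajectory(t, ("C3", "ED_R"), 20.0, trials,
                              SlidingWindowConfig(0.125))
        assert traj.values.size == 57
        assert np.all((traj.values >= 0) & (traj.values <= 1))
        assert np.allclose(np.diff(traj.end_times), 0.125)

    def test_outcome_exclusivity_and_metric_identity(self, pipeline_report):
        for res in pipeline_report.classification:
            assert set(res.outcomes.values()) <= {"TP", "FP", "FN"}
            assert len(res.outcomes) == res.n_task_trials
            assert res.hit_rate + res.fpr + res.fnr == pytest.approx(1.0)
            for d in res.delays.values():
                assert d >= 0.0  # end-time convention makes delays nonnegative

    def test_metric_table_shape_and_identity(self, pipeline_report):
        table = pipeline_report.table
        assert len(table) == 9  # 3 shifts x 3 M
        assert table["n_sessions"].eq(1).all()
        assert (table["hit_rate_se"] == 0).all()
        np.testing.assert_allclose(
            table[["hit_rate", "fpr", "fnr"]].sum(axis=1), 1.0)

    def test_aggregated_table_across_sessions(self, pipeline_report):
        rows = []
        for res in pipeline_report.classification:
            for sess in (0, 1):
                row = res.summary()
                row.update(movement="ext", side="R", shift=res.shift,
                           M=res.m)
                rows.append(row)
        tab = metric_table(rows)
        assert (tab["n_sessions"] == 2).all()
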