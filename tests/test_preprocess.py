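"""Filtering, epoching, and the three trial-screening rules."""

import numpy as np
import pytest

from cmcdetect.preprocess import (KEPT, REJECTED_ARTIFACT,
                                  REJECTED_NONCOMPLIANT,
                                  SENSORIMOTOR_CHANNELS, epoch, filter_eeg,
                                  filter_emg, screen_compliance,
                                  screen_eeg_artifacts, screen_emg_artifacts,
                                  spherical_spline_interpolate,
                                  _montage_positions)
from cmcdetect.session import Session
from cmcdetect.synth import inject_artifacts

FS = 1000.0


def _tone(freq, fs=FS, dur=4.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _rms_mid(x):
    n = x.size
    return np.sqrt(np.mean(x[n // 4: 3 * n // 4] ** 2))


class TestFilterEEG:
    def test_notch_kills_line_frequency(self):
        out = filter_eeg(_tone(50.0), FS)
        assert _rms_mid(out) < 0.05 * _rms_mid(_tone(50.0))

    def test_stopband_attenuates_slow_drift(self):
        out = filter_eeg(_tone(1.0, dur=16.0), FS)
        assert _rms_mid(out) < 0.1 * _rms_mid(_tone(1.0, dur=16.0))  # >= 20 dB

    def test_passband_preserves_beta(self):
        out = filter_eeg(_tone(20.0), FS)
        assert abs(_rms_mid(out) / _rms_mid(_tone(20.0)) - 1) < 0.05

    def test_idempotent_in_passband(self):
        once = filter_eeg(_tone(20.0), FS)
        twice = filter_eeg(once, FS)
        assert abs(_rms_mid(twice) / _rms_mid(once) - 1) < 0.05

    def test_rejects_too_low_sampling_rate(self):
        with pytest.raises(ValueError):
            filter_eeg(_tone(20.0, fs=100.0), 100.0)


class TestFilterEMG:
    def test_aliasing_guard(self):
        x = _tone(900.0, fs=2000.0)
        out = filter_emg(x, 2000.0, 1000.0)
        assert _rms_mid(out) < 0.01 * _rms_mid(x)  # >= 40 dB

    def test_dc_removed(self):
        x = 5.0 + 0.1 * np.random.default_rng(0).standard_normal(8000)
        out = filter_emg(x, 2000.0, 1000.0)
        assert abs(np.mean(out)) < 0.01 * 5.0

    def test_output_length_halved(self):
        out = filter_emg(np.zeros(8000), 2000.0, 1000.0)
        assert out.shape[-1] == 4000

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            filter_emg(np.zeros(3000), 1500.0, 1000.0)


class TestEpoch:
    def test_epoch_counts_and_lengths(self, small_trials):
        task = [t for t in small_trials.trials if t.label == "task"]
        rest = [t for t in small_trials.trials if t.label == "rest"]
        assert len(task) == 10 and len(rest) == 10
        assert all(t.eeg.shape == (28, 8000) for t in task)
        assert all(t.eeg.shape == (28, 4000) for t in rest)
        assert all(t.emg.shape[0] == 16 for t in task)
        assert all(t.emg.shape[1] == t.eeg.shape[1] for t in task + rest)

    def test_empty_subset_rejected(self, small_session):
        with pytest.raises(ValueError):
            epoch(small_session, subset=[])

    def test_cue_sample_alignment(self):
        # impulse planted at the cue sample must be the epoch's first sample
        fs = 1000.0
        eeg = np.zeros((len(SENSORIMOTOR_CHANNELS), 10000))
        cue = 2.5
        eeg[:, int(cue * fs)] = 1.0
        ses = Session(eeg, np.zeros((1, 10000)), fs, fs,
                      list(SENSORIMOTOR_CHANNELS), ["ED_R"],
                      np.array([cue]), ["rest"])
        ts = epoch(ses, prefiltered=True)
        assert ts.trials[0].eeg[0, 0] == 1.0
        assert not np.any(ts.trials[0].eeg[0, 1:])

    def test_cue_beyond_recording_end(self, small_session):
        ses = small_session.copy()
        ses.cue_times = ses.cue_times.copy()
        ses.cue_times[-1] = ses.eeg.shape[1] / ses.fs_eeg - 1.0
        with pytest.raises(ValueError, match="trial"):
            epoch(ses)


class TestEEGArtifactScreening:
    def test_clean_session_untouched(self, small_trials):
        out = screen_eeg_artifacts(small_trials)
        assert all(t.status == KEPT for t in out.trials)
        assert all(not t.interpolated_channels for t in out.trials)

    def test_single_channel_artifact_interpolated(self, small_session):
        bad, records = inject_artifacts(small_session, eeg_rate=0.1, seed=5)
        out = screen_eeg_artifacts(epoch(bad))
        planted = {(r.trial, r.channels[0]) for r in records}
        found = {(t.index, c) for t in out.trials
                 for c in t.interpolated_channels}
        assert found == planted
        assert all(t.status == KEPT for t in out.trials)

    def test_two_channel_artifact_rejects_trial(self, small_session):
        bad, records = inject_artifacts(small_session, eeg_rate=0.1, seed=6,
                                        eeg_channels_per_trial=2)
        out = screen_eeg_artifacts(epoch(bad))
        rejected = {t.index for t in out.trials
                    if t.status == REJECTED_ARTIFACT}
        assert rejected == {r.trial for r in records}

    def test_no_suprathreshold_samples_after_interpolation(self, small_session):
        bad, _ = inject_artifacts(small_session, eeg_rate=0.1, seed=5)
        out = screen_eeg_artifacts(epoch(bad))
        for t in out.trials:
            if t.status == KEPT:
                assert np.abs(t.eeg).max() <= 100.0


class TestSphericalSpline:
    def test_reconstructs_smooth_scalp_field(self):
        # a field linear in scalp position is a low-order harmonic the
        # spline must reproduce almost exactly
        pos = _montage_positions(SENSORIMOTOR_CHANNELS)
        t = np.linspace(0, 1, 200)
        wave = np.sin(2 * np.pi * 5 * t)
        data = (1.0 + pos[:, 0] + 0.5 * pos[:, 1])[:, None] * wave
        rec = spherical_spline_interpolate(data, SENSORIMOTOR_CHANNELS, "C3")
        truth = data[SENSORIMOTOR_CHANNELS.index("C3")]
        err = np.linalg.norm(rec - truth) / np.linalg.norm(truth)
        assert err < 0.05

    def test_interpolated_variance_within_neighbor_range(self, small_session):
        bad, records = inject_artifacts(small_session, eeg_rate=0.1, seed=5)
        out = screen_eeg_artifacts(epoch(bad))
        for t in out.trials:
            for c in t.interpolated_channels:
                ci = out.channel_labels.index(c)
                others = np.var(np.delete(t.eeg, ci, axis=0), axis=1)
                assert np.var(t.eeg[ci]) <= others.max()


class TestEMGStatisticalScreening:
    def test_identical_statistics_no_flags(self, small_trials):
        out, review = screen_emg_artifacts(small_trials, "ED_R")
        assert review == []

    def test_burst_flagged(self, small_session):
        bad, records = inject_artifacts(small_session, emg_rate=0.1, seed=7,
                                        emg_mode="burst")
        out, review = screen_emg_artifacts(epoch(bad), "ED_R")
        assert {r[0] for r in review} == {r.trial for r in records}
        for trial, _ in review:
            assert out.trials[trial].status == REJECTED_ARTIFACT

    def test_flatline_flagged(self, small_session):
        bad, records = inject_artifacts(small_session, emg_rate=0.1, seed=8,
                                        emg_mode="flatline")
        _, review = screen_emg_artifacts(epoch(bad), "ED_R",
                                         auto_reject=False)
        assert {r.trial for r in records} <= {r[0] for r in review}

    def test_too_few_trials_warns_and_skips(self, small_trials):
        for t in small_trials.trials:
            if t.label == "task" and t.index > 2:
                t.status = REJECTED_ARTIFACT
        with pytest.warns(UserWarning, match="skipped"):
            screen_emg_artifacts(small_trials, "ED_R")


class TestCompliance:
    def test_nominal_session_fully_compliant(self, small_trials):
        out = screen_compliance(small_trials, "ED_R")
        assert all(t.status == KEPT for t in out.trials)

    def test_rest_trial_with_movement_rejected(self, small_trials):
        rest = [t for t in small_trials.trials if t.label == "rest"][0]
        mi = small_trials.muscle_labels.index("ED_R")
        rest.emg[mi, 1000:2500] *= 8.0  # 1.5 s of task-level activity
        out = screen_compliance(small_trials, "ED_R")
        assert out.trials[rest.index].status == REJECTED_NONCOMPLIANT

    def test_task_trial_without_movement_rejected(self, small_trials):
        task = [t for t in small_trials.trials if t.label == "task"][0]
        mi = small_trials.muscle_labels.index("ED_R")
        scale = 0.2 * np.abs(task.emg[mi, :3500]).mean() / \
            np.abs(task.emg[mi, 4000:]).mean()
        task.emg[mi, 4000:] *= scale  # silence the movement period
        out = screen_compliance(small_trials, "ED_R")
        assert out.trials[task.index].status == REJECTED_NONCOMPLIANT


def test_status_bookkeeping_partitions_trials(small_session):
    bad, _ = inject_artifacts(small_session, eeg_rate=0.1, emg_rate=0.1,
                              seed=13, eeg_channels_per_trial=2)
    ts = epoch(bad)
    ts = screen_eeg_artifacts(ts)
    ts, _ = screen_emg_artifacts(ts, "ED_R")
    ts = screen_compliance(ts, "ED_R")
    counts = ts.counts()
    assert sum(counts.values()) == len(ts.trials) == 20
    assert all(t.reason for t in ts.trials if t.status != KEPT)
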