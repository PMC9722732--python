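"""Synthetic EEG+EMG sessions with planted beta-band cortico-muscular coupling.

The generator emulates the block-design study the pipeline targets: 8-s task
trials (4-s preparatory period, then movement held at ~15% MVC) interleaved
with 4-s rest trials under pseudo-random sequencing constraints (never more
than two consecutive trials of the same condition; a run never opens with two
rest trials).

Coupling model
--------------
The target-muscle EMG is a broadband carrier (band-limited white noise) whose
amplitude envelope ramps from a resting level to ``activation_level · MVC`` at
the true onset (cue + preparatory period + jitter). Beta-band coupling enters
*multiplicatively* on that envelope: post-onset the envelope is scaled by
``1 + m·sin(2π·f0·t + φ_trial)``, so that rectification demodulates the
modulation back into the beta band where coherence is measured (additive
coupling on the raw EMG would be destroyed by rectification). The coupled EEG
channels receive the same sinusoid (same per-trial random phase) added to a
1/f + white + 50 Hz line background during the post-onset period only. All
other channels and muscles are coupling-free, so across-trial coherence
reflects within-trial phase locking, not a global phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import signal

from cmcdetect._rng import substream
from cmcdetect.session import Session, SessionTruth

__all__ = [
    "SimulationConfig",
    "InfeasibleSequenceError",
    "generate_trial_sequence",
    "generate_session",
    "synthesize_task_emg",
    "inject_artifacts",
    "ArtifactRecord",
    "DEFAULT_MUSCLES",
]

#: 16 bipolar surface-EMG sites: 8 upper-limb/shoulder muscles × both sides.
DEFAULT_MUSCLES = [
    f"{m}_{s}"
    for m in ("ED", "FD", "TRI", "BIC", "PEC", "Lat_DELT", "Ant_DELT", "TRAP")
    for s in ("L", "R")
]

# 28 sensorimotor-strip channels (extended 10-20); duplicated in preprocess to
# keep module import graphs acyclic.
_SENSORIMOTOR_28 = [
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
]


class SimulationConfig(BaseModel):
    """Parameters of one synthetic session.

    Defaults reproduce the study conditions: 20 task + 20 rest trials, EEG at
    1 kHz / EMG at 2 kHz, 8-s task and 4-s rest trials with a 4-s preparatory
    period, activation held at 15% MVC, and beta-band coupling at 20 Hz.
    """

    model_config = ConfigDict(extra="forbid")

    n_task_trials: int = Field(20, ge=1)
    n_rest_trials: int = Field(20, ge=1)
    fs_eeg: float = Field(1000.0, gt=120.0)  # both rates must resolve 60 Hz
    fs_emg: float = Field(2000.0, gt=120.0)
    task_dur: float = Field(8.0, gt=0)
    rest_dur: float = Field(4.0, gt=0)
    prep_dur: float = Field(4.0, gt=0)
    iti: float = Field(3.0, ge=0)  # inter-trial interval (fixation cross)
    coupling_freq: float = Field(20.0, ge=13.0, le=30.0)
    coupling_strength: float = Field(0.5, ge=0.0, le=1.0)  # modulation depth m
    eeg_snr_db: float = -6.0  # coupled sinusoid amplitude vs background RMS
    activation_level: float = Field(0.15, gt=0, le=1.0)  # fraction of MVC
    rest_activation_level: float = Field(0.02, ge=0, le=1.0)
    onset_jitter_sd: float = Field(0.05, ge=0)  # s
    ramp_dur: float = Field(0.05, gt=0)  # raised-cosine onset ramp, s
    coupled_eeg_channels: list[str] = ["C3"]
    target_muscle: str = "ED_R"
    channel_labels: list[str] = list(_SENSORIMOTOR_28)
    muscle_labels: list[str] = list(DEFAULT_MUSCLES)
    mvc_mv: float = Field(1.0, gt=0)  # per-muscle MVC (mV RMS)
    pink_std_uv: float = Field(8.0, ge=0)
    white_std_uv: float = Field(3.0, gt=0)
    line_freq: float = 50.0
    line_amp_uv: float = Field(2.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.prep_dur >= self.task_dur:
            raise ValueError("prep_dur must be shorter than task_dur")
        for ch in self.coupled_eeg_channels:
            if ch not in self.channel_labels:
                raise ValueError(f"coupled channel {ch!r} not in channel_labels")
        if self.target_muscle not in self.muscle_labels:
            raise ValueError(f"target muscle {self.target_muscle!r} unknown")
        return self


class InfeasibleSequenceError(ValueError):
    """No trial ordering satisfies the sequencing constraints."""


@lru_cache(maxsize=None)
def _n_completions(t: int, r: int, last: str, run: int, no_rest: bool) -> int:
    """Count valid orderings of t task + r rest labels continuing (last, run).

    Constraints: no run of 3 equal labels; ``no_rest`` forbids a rest at the
    next position (used to ban two rests at the start of a run).
    """
    if t == 0 and r == 0:
        return 1
    total = 0
    if t > 0 and not (last == "task" and run >= 2):
        total += _n_completions(t - 1, r, "task", run + 1 if last == "task" else 1,
                                False)
    if r > 0 and not no_rest and not (last == "rest" and run >= 2):
        total += _n_completions(t, r - 1, "rest", run + 1 if last == "rest" else 1,
                                False)
    return total


def generate_trial_sequence(n_task: int, n_rest: int,
                            seed: int | np.random.Generator = 0) -> list[str]:
    """Draw a pseudo-random task/rest ordering under the run constraints.

    The sequence contains exactly ``n_task`` 'task' and ``n_rest`` 'rest'
    labels, never holds three consecutive equal labels, and never begins with
    two rest trials. Sampling is uniform over all valid orderings (labels are
    chosen stepwise with probability proportional to the number of valid
    completions), deterministic given the seed.

    Raises
    ------
    InfeasibleSequenceError
        If no ordering satisfies the constraints
        (e.g. ``n_task > 2·(n_rest + 1)``).
    """
    if n_task < 1 or n_rest < 1:
        raise ValueError("need at least one trial of each condition")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    seq: list[str] = []
    t, r = n_task, n_rest
    last, run = "", 0
    for pos in range(n_task + n_rest):
        # two rests may never open the sequence
        no_rest = pos == 1 and seq[0] == "rest"
        weights = {}
        if t > 0 and not (last == "task" and run >= 2):
            weights["task"] = _n_completions(
                t - 1, r, "task", run + 1 if last == "task" else 1, False)
        if r > 0 and not no_rest and not (last == "rest" and run >= 2):
            nr = pos == 0  # a leading rest forbids rest at position 1
            weights["rest"] = _n_completions(
                t, r - 1, "rest", run + 1 if last == "rest" else 1, nr)
        weights = {k: v for k, v in weights.items() if v > 0}
        if not weights:
            raise InfeasibleSequenceError(
                f"no valid ordering of {n_task} task / {n_rest} rest trials")
        labels = sorted(weights)
        probs = np.array([weights[k] for k in labels], float)
        choice = rng.choice(labels, p=probs / probs.sum())
        seq.append(str(choice))
        run = run + 1 if choice == last else 1
        last = str(choice)
        if choice == "task":
            t -= 1
        else:
            r -= 1
    return seq


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                std: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, normalized to the given SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = 1.0 / np.sqrt(f[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    s = x.std()
    return x * (std / s) if s > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited white noise (broadband EMG carrier)."""
    hi = min(band[1], 0.45 * fs)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _raised_cosine_gate(t: np.ndarray, start: float, stop: float,
                        ramp: float) -> np.ndarray:
    """0→1 gate with raised-cosine edges of the given ramp duration."""
    g = np.zeros_like(t)
    g[(t >= start + ramp) & (t <= stop - ramp)] = 1.0
    up = (t >= start) & (t < start + ramp)
    g[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    down = (t > stop - ramp) & (t <= stop)
    g[down] = 0.5 * (1 - np.cos(np.pi * (stop - t[down]) / ramp))
    return g


def synthesize_task_emg(config: SimulationConfig, rng: np.random.Generator,
                        phase: float | None = None,
                        onset: float | None = None
                        ) -> tuple[np.ndarray, float, float]:
    """Synthesize one task trial of target-muscle EMG at ``fs_emg``.

    Returns ``(emg_mv, onset_s, phase)`` with time 0 at the cue. Used
    internally by :func:`generate_session` and directly by validation studies
    that need many independent trials without whole-session overhead.
    """
    fs = config.fs_emg
    n = int(round(config.task_dur * fs))
    t = np.arange(n) / fs
    if onset is None:
        jit = rng.normal(0.0, config.onset_jitter_sd) if \
            config.onset_jitter_sd > 0 else 0.0
        jit = float(np.clip(jit, -3 * config.onset_jitter_sd,
                            3 * config.onset_jitter_sd))
        onset = config.prep_dur + jit
        onset = float(np.clip(onset, config.ramp_dur,
                              config.task_dur - 1.0))
    if phase is None:
        phase = float(rng.uniform(0, 2 * np.pi))
    carrier = _band_noise(rng, n, fs, (30.0, 450.0))
    gate = _raised_cosine_gate(t, onset, config.task_dur, config.ramp_dur)
    base = config.rest_activation_level * config.mvc_mv
    act = config.activation_level * config.mvc_mv
    env = base + (act - base) * gate
    mod = 1.0 + config.coupling_strength * gate * np.sin(
        2 * np.pi * config.coupling_freq * t + phase)
    return carrier * env * mod, onset, phase


def generate_session(config: SimulationConfig) -> Session:
    """Generate a full synthetic session from a validated configuration.

    Bit-identical output for identical configurations (all randomness flows
    from ``config.seed`` through named substreams).
    """
    seq_rng = substream(config.seed, "sequencer")
    eeg_rng = substream(config.seed, "eeg-noise")
    emg_rng = substream(config.seed, "emg-noise")
    trial_rng = substream(config.seed, "trial-params")

    labels = generate_trial_sequence(config.n_task_trials,
                                     config.n_rest_trials, seq_rng)
    durs = [config.task_dur if l == "task" else config.rest_dur for l in labels]
    cues = []
    tcur = config.iti
    for d in durs:
        cues.append(tcur)
        tcur += d + config.iti
    total = tcur + 1.0
    cue_times = np.array(cues)

    n_eeg = int(round(total * config.fs_eeg))
    n_emg = int(round(total * config.fs_emg))
    n_ch = len(config.channel_labels)
    n_mus = len(config.muscle_labels)

    # EEG background: per-channel independent 1/f + white + line noise
    eeg = np.empty((n_ch, n_eeg))
    t_eeg = np.arange(n_eeg) / config.fs_eeg
    for c in range(n_ch):
        x = _pink_noise(eeg_rng, n_eeg, config.fs_eeg, config.pink_std_uv)
        x += config.white_std_uv * eeg_rng.standard_normal(n_eeg)
        if config.line_amp_uv > 0:
            x += config.line_amp_uv * np.sin(
                2 * np.pi * config.line_freq * t_eeg +
                eeg_rng.uniform(0, 2 * np.pi))
        eeg[c] = x

    # EMG baseline: every muscle idles at the resting activation level
    emg = np.empty((n_mus, n_emg))
    base = config.rest_activation_level * config.mvc_mv
    for m in range(n_mus):
        emg[m] = base * _band_noise(emg_rng, n_emg, config.fs_emg, (30.0, 450.0))

    sigma_bg = np.sqrt(config.pink_std_uv**2 + config.white_std_uv**2 +
                       config.line_amp_uv**2 / 2.0)
    alpha = 10.0 ** (config.eeg_snr_db / 20.0) * sigma_bg
    coupled_idx = [config.channel_labels.index(c)
                   for c in config.coupled_eeg_channels]
    mus_idx = config.muscle_labels.index(config.target_muscle)

    onsets: dict[int, float] = {}
    for i, (lab, cue) in enumerate(zip(labels, cue_times)):
        if lab != "task":
            continue
        trial, onset, phase = synthesize_task_emg(config, trial_rng)
        onsets[i] = onset
        s0 = int(round(cue * config.fs_emg))
        emg[mus_idx, s0:s0 + trial.size] = trial[:n_emg - s0]
        # matching cortical component, same phase, gated post-onset only
        s0e = int(round(cue * config.fs_eeg))
        ne = int(round(config.task_dur * config.fs_eeg))
        tt = np.arange(ne) / config.fs_eeg
        gate = _raised_cosine_gate(tt, onset, config.task_dur, config.ramp_dur)
        comp = alpha * gate * np.sin(
            2 * np.pi * config.coupling_freq * tt + phase)
        for c in coupled_idx:
            eeg[c, s0e:s0e + ne] += comp[:n_eeg - s0e]

    truth = SessionTruth(
        onsets=onsets,
        coupled_pairs=[(c, config.target_muscle)
                       for c in config.coupled_eeg_channels],
        coupling_freq=config.coupling_freq,
    )
    mvc = {m: config.mvc_mv for m in config.muscle_labels}
    return Session(eeg, emg, config.fs_eeg, config.fs_emg,
                   list(config.channel_labels), list(config.muscle_labels),
                   cue_times, labels, mvc, truth)


@dataclass
class ArtifactRecord:
    """One planted artifact: which trial, what kind, which channels/muscle."""

    trial: int
    kind: str  # 'eeg' | 'emg_burst' | 'emg_flatline'
    channels: list[str] = field(default_factory=list)


def inject_artifacts(session: Session, eeg_rate: float = 0.0,
                     emg_rate: float = 0.0, seed: int = 0,
                     eeg_channels_per_trial: int = 1,
                     emg_mode: str = "burst",
                     task_dur: float = 8.0, rest_dur: float = 4.0,
                     ) -> tuple[Session, list[ArtifactRecord]]:
    """Corrupt a fraction of trials with EEG excursions or EMG bursts/flatlines.

    ``round(rate · n_trials)`` trials are drawn without replacement for each
    signal type. EEG artifacts are 200 µV 10-Hz bursts (they survive the 3–60
    Hz band-pass and trip the 100 µV screening rule) on
    ``eeg_channels_per_trial`` random channels; EMG artifacts either multiply
    a 1-s stretch of the target muscle's trace by 10 ('burst') or zero the
    whole trial ('flatline'). Returns a corrupted copy plus the truth list.
    """
    if not 0 <= eeg_rate <= 1 or not 0 <= emg_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = session.copy()
    records: list[ArtifactRecord] = []
    n = session.n_trials

    n_eeg_bad = int(round(eeg_rate * n))
    if n_eeg_bad:
        for trial in sorted(rng.choice(n, size=n_eeg_bad, replace=False)):
            trial = int(trial)
            dur = task_dur if session.trial_labels[trial] == "task" else rest_dur
            cue = session.cue_times[trial]
            chans = rng.choice(len(session.channel_labels),
                               size=eeg_channels_per_trial, replace=False)
            s0 = int(round((cue + 0.4 * dur) * session.fs_eeg))
            nb = int(round(0.3 * session.fs_eeg))
            tb = np.arange(nb) / session.fs_eeg
            burst = 200.0 * np.sin(2 * np.pi * 10.0 * tb) * \
                signal.windows.tukey(nb, 0.4)
            for c in chans:
                out.eeg[int(c), s0:s0 + nb] += burst
            records.append(ArtifactRecord(
                trial, "eeg", [session.channel_labels[int(c)] for c in chans]))

    n_emg_bad = int(round(emg_rate * n))
    if n_emg_bad:
        mus = session.muscle_labels.index(
            session.truth.coupled_pairs[0][1]) if session.truth and \
            session.truth.coupled_pairs else 0
        for trial in sorted(rng.choice(n, size=n_emg_bad, replace=False)):
            trial = int(trial)
            dur = task_dur if session.trial_labels[trial] == "task" else rest_dur
            cue = session.cue_times[trial]
            s0 = int(round(cue * session.fs_emg))
            ns = int(round(dur * session.fs_emg))
            if emg_mode == "flatline":
                out.emg[mus, s0:s0 + ns] = 0.0
                kind = "emg_flatline"
            else:
                b0 = s0 + int(round(0.25 * dur * session.fs_emg))
                nb = int(round(1.0 * session.fs_emg))
                out.emg[mus, b0:b0 + nb] *= 10.0
                kind = "emg_burst"
            records.append(ArtifactRecord(trial, kind,
                                          [session.muscle_labels[mus]]))
    return out, records
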