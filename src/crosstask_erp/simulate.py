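"""Synthetic EEG cohort generator for the color-oddball study.

Emulates continuous 65-channel recordings (62 scalp + 2 mastoids + 1 EOG,
1000 Hz) of participants viewing pseudo-random color sequences under three
attention tasks (C: count targets, A: arithmetic on all stimuli, M:
memorize target positions).  The forward model is additive:

* every stimulus evokes shared early visual activity (non-discriminative),
* targets evoke a late centroparietal positivity (P300-like) with Gaussian
  time course, per-epoch latency jitter and a fixed spatial pattern,
* distractors evoke the same component at a condition-specific (smaller)
  amplitude,
* plus 1/f background noise with spatial correlation, occipital alpha,
  50 Hz line noise, sub-0.5 Hz drift, and stereotyped blink transients on
  the EOG that leak into frontal channels.

Condition defaults encode the qualitative contrasts of the study: the
largest target-distractor amplitude difference under silent counting (C),
an elevated distractor positivity under arithmetic (A), and larger latency
jitter under A and M.  A master seed fixes the whole cohort bit-exactly;
per-participant/condition/repetition substreams are derived determinis-
tically, so any sub-unit is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import montage as mont
from .behavior import BehavioralRecord, score_correct
from .containers import ContinuousRecording
from .events import (
    CONDITIONS,
    SOA_MS,
    SequenceDesign,
    StimulusEvent,
    generate_sequence,
)


@dataclass(frozen=True)
class ErpComponentSpec:
    """One additive ERP component: Gaussian time course, fixed topography."""

    peak_latency_ms: float
    peak_amplitude_uV: float
    temporal_sd_ms: float
    latency_jitter_sd_ms: float = 0.0
    #: per-channel spatial weights, unit peak
    topography: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.latency_jitter_sd_ms < 0:
            raise ValueError("latency jitter SD must be >= 0")
        if self.temporal_sd_ms <= 0:
            raise ValueError("temporal SD must be > 0")
        if not all(math.isfinite(w) for w in self.topography.values()):
            raise ValueError("topography weights must be finite")


@dataclass(frozen=True)
class ConditionSpec:
    """Target and distractor components of one experimental condition.

    ``shared`` components are evoked by every stimulus regardless of class
    (early visual activity); they carry no class information.
    """

    target: ErpComponentSpec
    distractor: ErpComponentSpec
    shared: tuple[ErpComponentSpec, ...] = ()


@dataclass(frozen=True)
class NoiseSpec:
    """Background-activity model (all amplitudes in uV)."""

    pink_rms_uV: float = 10.0
    spatial_corr_length_m: float = 0.05
    alpha_amplitude_uV: float = 4.0
    alpha_freq_hz: float = 10.0
    line_amplitude_uV: float = 1.5
    line_freq_hz: float = 50.0
    drift_amplitude_uV: float = 5.0
    eog_noise_rms_uV: float = 8.0


@dataclass(frozen=True)
class BlinkSpec:
    """Ocular-artifact model: Poisson blink times, Gaussian transients."""

    rate_per_min: float = 5.0
    amplitude_range_uV: tuple[float, float] = (150.0, 300.0)
    width_sd_ms: float = 100.0
    frontal_leak: float = 0.4  # EOG-to-frontal-scalp propagation at Fpz


@dataclass(frozen=True)
class SubjectVariabilitySpec:
    """Between-participant variability of the evoked components."""

    amplitude_log_sd: float = 0.2
    latency_shift_sd_ms: float = 25.0
    topography_log_sd: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 13
    sequence_design: SequenceDesign = field(default_factory=SequenceDesign)
    conditions: dict[str, ConditionSpec] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    blink: BlinkSpec = field(default_factory=BlinkSpec)
    subject_variability: SubjectVariabilitySpec = field(default_factory=SubjectVariabilitySpec)
    behavioral_error_rate: float = 0.05
    sampling_rate: float = 1000.0
    lead_in_s: float = 2.0
    inter_repetition_gap_s: float = 2.5
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.behavioral_error_rate <= 1.0):
            raise ValueError("behavioral_error_rate must lie in [0, 1]")
        for name, val in (
            ("pink_rms_uV", self.noise.pink_rms_uV),
            ("alpha_amplitude_uV", self.noise.alpha_amplitude_uV),
            ("line_amplitude_uV", self.noise.line_amplitude_uV),
            ("drift_amplitude_uV", self.noise.drift_amplitude_uV),
            ("eog_noise_rms_uV", self.noise.eog_noise_rms_uV),
            ("blink rate", self.blink.rate_per_min),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        self.sequence_design.validate()
        for spec in self.conditions.values():
            spec.target.validate()
            spec.distractor.validate()
            for sh in spec.shared:
                sh.validate()


# ---------------------------------------------------------------------------
# default study configuration

def _late_positivity(amplitude_uV: float, jitter_sd_ms: float) -> ErpComponentSpec:
    """Late centroparietal positivity (P300-like), peak near 450 ms."""
    return ErpComponentSpec(
        peak_latency_ms=450.0,
        peak_amplitude_uV=amplitude_uV,
        temporal_sd_ms=80.0,
        latency_jitter_sd_ms=jitter_sd_ms,
        topography=mont.gaussian_topography("Pz", 0.06),
    )


def _early_visual() -> ErpComponentSpec:
    """Occipital response to any flash; identical for targets and distractors."""
    return ErpComponentSpec(
        peak_latency_ms=120.0,
        peak_amplitude_uV=3.0,
        temporal_sd_ms=30.0,
        latency_jitter_sd_ms=0.0,
        topography=mont.gaussian_topography("Oz", 0.05),
    )


def default_conditions() -> dict[str, ConditionSpec]:
    """Condition-specific morphology defaults.

    C: large target-distractor contrast, tight latency (jitter 30 ms).
    A: distractors also elicit a sizeable positivity (2.5 uV) because every
       stimulus requires arithmetic; latency jitter 60 ms.
    M: target contrast as in C but latency jitter 60 ms (memory encoding
       more variable in time).
    """
    shared = (_early_visual(),)
    return {
        "C": ConditionSpec(target=_late_positivity(5.0, 30.0),
                           distractor=_late_positivity(0.5, 30.0), shared=shared),
        "A": ConditionSpec(target=_late_positivity(5.0, 60.0),
                           distractor=_late_positivity(2.5, 60.0), shared=shared),
        "M": ConditionSpec(target=_late_positivity(5.0, 60.0),
                           distractor=_late_positivity(0.5, 60.0), shared=shared),
    }


def default_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """The study's default cohort: 13 participants, 3 conditions, 20
    repetitions of 47-50 stimuli each."""
    cfg = SimulationConfig(conditions=default_conditions(), master_seed=master_seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def null_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """A label-exchangeable cohort: target and distractor components are
    identical, so true discriminability is nil (chance-level control)."""
    shared = (_early_visual(),)
    same = {
        c: ConditionSpec(target=_late_positivity(2.0, 40.0),
                         distractor=_late_positivity(2.0, 40.0), shared=shared)
        for c in CONDITIONS
    }
    cfg = SimulationConfig(conditions=same, master_seed=master_seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def noiseless_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """Deterministic forward model: no noise, no blinks, no jitter, no
    subject variability.  Epochs equal the template superposition exactly."""
    conds = {}
    for c, spec in default_conditions().items():
        conds[c] = ConditionSpec(
            target=replace(spec.target, latency_jitter_sd_ms=0.0),
            distractor=replace(spec.distractor, latency_jitter_sd_ms=0.0),
            shared=spec.shared,
        )
    cfg = SimulationConfig(
        conditions=conds,
        noise=NoiseSpec(pink_rms_uV=0.0, alpha_amplitude_uV=0.0, line_amplitude_uV=0.0,
                        drift_amplitude_uV=0.0, eog_noise_rms_uV=0.0),
        blink=BlinkSpec(rate_per_min=0.0),
        subject_variability=SubjectVariabilitySpec(0.0, 0.0, 0.0),
        master_seed=master_seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# seeding

_SUBJECT_STREAM, _RECORDING_STREAM, _BEHAVIOR_STREAM = 1, 2, 3


def _rng(config: SimulationConfig, stream: int, *key: int) -> np.random.Generator:
    """Deterministic substream derived from the master seed and a key."""
    ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(stream, *key))
    return np.random.default_rng(ss)


def participant_label(participant: int) -> str:
    return f"P{participant + 1:02d}"


@dataclass(frozen=True)
class _SubjectParams:
    amplitude_scale: float
    latency_shift_ms: float
    topography_gain: dict[str, float]


def _draw_subject_params(config: SimulationConfig, participant: int) -> _SubjectParams:
    sv = config.subject_variability
    rng = _rng(config, _SUBJECT_STREAM, participant)
    amp = float(np.exp(rng.normal(0.0, sv.amplitude_log_sd)))
    lat = float(rng.normal(0.0, sv.latency_shift_sd_ms))
    gains = {
        ch: float(np.exp(rng.normal(0.0, sv.topography_log_sd)))
        for ch in mont.SCALP_CHANNELS
    }
    return _SubjectParams(amp, lat, gains)


# ---------------------------------------------------------------------------
# forward model

def component_timecourse(spec: ErpComponentSpec, times_ms: np.ndarray,
                         latency_shift_ms: float = 0.0,
                         amplitude_scale: float = 1.0) -> np.ndarray:
    """Gaussian voltage time course of one component on a time grid (ms
    relative to stimulus onset)."""
    tau = spec.peak_latency_ms + latency_shift_ms
    return (spec.peak_amplitude_uV * amplitude_scale
            * np.exp(-((times_ms - tau) ** 2) / (2.0 * spec.temporal_sd_ms**2)))


def erp_template(
    specs: tuple[ErpComponentSpec, ...] | list[ErpComponentSpec],
    times_ms: np.ndarray,
    channels: list[str],
    latency_shift_ms: float = 0.0,
    amplitude_scale: float = 1.0,
    topography_gain: dict[str, float] | None = None,
) -> np.ndarray:
    """Superpose components into a channels x time template (uV)."""
    out = np.zeros((len(channels), times_ms.size))
    for spec in specs:
        tc = component_timecourse(spec, times_ms, latency_shift_ms, amplitude_scale)
        w = np.array([
            spec.topography.get(ch, 0.0)
            * (topography_gain.get(ch, 1.0) if topography_gain else 1.0)
            for ch in channels
        ])
        out += w[:, None] * tc[None, :]
    return out


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float, floor_hz: float = 0.5) -> np.ndarray:
    """Unit-RMS 1/f noise per channel (power spectral density ~ 1/f above
    ``floor_hz``, flat below)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = (1.0 / np.sqrt(np.maximum(freqs, floor_hz))).astype(np.float32)
    scale[0] = 0.0
    re = rng.standard_normal((n_channels, freqs.size), dtype=np.float32)
    im = rng.standard_normal((n_channels, freqs.size), dtype=np.float32)
    x = np.fft.irfft((re + 1j * im) * scale, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _spatial_mixing(channels: list[str], corr_length_m: float) -> np.ndarray:
    """Cholesky factor of a squared-exponential inter-channel correlation."""
    pos = mont.channel_positions(tuple(channels))
    P = np.array([pos[c] for c in channels])
    d2 = np.sum((P[:, None, :] - P[None, :, :]) ** 2, axis=-1)
    C = np.exp(-d2 / (2.0 * corr_length_m**2)) + 1e-9 * np.eye(len(channels))
    return np.linalg.cholesky(C)


def _layout_events(config: SimulationConfig, condition: str,
                   rng: np.random.Generator) -> tuple[list[StimulusEvent], int]:
    """Generate all repetitions' sequences and place them on the recording
    timeline.  Returns (events, total n_samples)."""
    sfreq = config.sampling_rate
    gap_ms = int(round(config.inter_repetition_gap_s * 1000))
    t_ms = int(round(config.lead_in_s * 1000))
    events: list[StimulusEvent] = []
    for rep in range(1, config.sequence_design.n_repetitions_per_condition + 1):
        seq = generate_sequence(config.sequence_design, condition, rep, rng, start_ms=t_ms)
        events.extend(seq)
        t_ms = seq[-1].onset_ms + SOA_MS + gap_ms
    total_ms = t_ms  # gap after the final repetition serves as tail
    return events, int(round(total_ms * sfreq / 1000.0))


def simulate_recording(config: SimulationConfig, participant: int,
                       condition: str) -> ContinuousRecording:
    """Simulate one participant's continuous recording in one condition.

    Deterministic given (config.master_seed, participant, condition).
    """
    config.validate()
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"configured: {sorted(config.conditions)}")
    sfreq = config.sampling_rate
    channels = list(mont.ALL_CHANNELS)
    n_eeg = len(channels) - 1  # all but EOG
    eog_idx = channels.index(mont.EOG_CHANNEL)
    cond_idx = sorted(config.conditions).index(condition)
    rng = _rng(config, _RECORDING_STREAM, participant, cond_idx)
    subject = _draw_subject_params(config, participant)

    events, n_samples = _layout_events(config, condition, rng)
    data = np.zeros((len(channels), n_samples))

    # --- background activity -------------------------------------------------
    noise = config.noise
    if noise.pink_rms_uV > 0:
        indep = _pink_noise(rng, n_eeg, n_samples, sfreq)
        L = _spatial_mixing(channels[:n_eeg], noise.spatial_corr_length_m)
        data[:n_eeg] += noise.pink_rms_uV * (L @ indep)
    t = np.arange(n_samples) / sfreq
    if noise.alpha_amplitude_uV > 0:
        phase = rng.uniform(0, 2 * np.pi)
        env = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t
                                 + rng.uniform(0, 2 * np.pi))
        src = noise.alpha_amplitude_uV * env * np.sin(2 * np.pi * noise.alpha_freq_hz * t + phase)
        topo = mont.gaussian_topography("Oz", 0.08)
        w = np.array([topo.get(c, 0.0) for c in channels[:n_eeg]])
        data[:n_eeg] += w[:, None] * src[None, :]
    if noise.line_amplitude_uV > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data[:n_eeg] += noise.line_amplitude_uV * np.sin(
            2 * np.pi * noise.line_freq_hz * t + phase)[None, :]
    if noise.drift_amplitude_uV > 0:
        f = (2 * np.pi * rng.uniform(0.02, 0.4, size=(n_eeg, 2))).astype(np.float32)
        p = rng.uniform(0, 2 * np.pi, size=(n_eeg, 2)).astype(np.float32)
        a = (noise.drift_amplitude_uV
             * rng.uniform(0.3, 1.0, size=(n_eeg, 2))).astype(np.float32)
        t32 = t.astype(np.float32)
        for k in range(2):
            data[:n_eeg] += a[:, k, None] * np.sin(
                f[:, k, None] * t32[None, :] + p[:, k, None])
    if noise.eog_noise_rms_uV > 0:
        data[eog_idx] += noise.eog_noise_rms_uV * _pink_noise(rng, 1, n_samples, sfreq)[0]

    # --- blinks --------------------------------------------------------------
    blink = config.blink
    if blink.rate_per_min > 0:
        duration_min = n_samples / sfreq / 60.0
        n_blinks = rng.poisson(blink.rate_per_min * duration_min)
        leak_topo = mont.gaussian_topography("Fpz", 0.045)
        w_leak = np.array([blink.frontal_leak * leak_topo.get(c, 0.0)
                           for c in channels[:n_eeg]])
        sd = blink.width_sd_ms / 1000.0
        for _ in range(n_blinks):
            t0 = rng.uniform(0, n_samples / sfreq)
            amp = rng.uniform(*blink.amplitude_range_uV)
            lo = max(0, int((t0 - 4 * sd) * sfreq))
            hi = min(n_samples, int((t0 + 4 * sd) * sfreq))
            if hi <= lo:
                continue
            bump = amp * np.exp(-((t[lo:hi] - t0) ** 2) / (2 * sd**2))
            data[eog_idx, lo:hi] += bump
            data[:n_eeg, lo:hi] += w_leak[:, None] * bump[None, :]

    # --- evoked responses ----------------------------------------------------
    spec = config.conditions[condition]
    # epoch-shaped injection window [-100, +900) ms tiles the 1000 ms SOA
    win_lo, win_hi = -100, 900
    s_lo = int(round(win_lo * sfreq / 1000.0))
    s_hi = int(round(win_hi * sfreq / 1000.0))
    rel_ms = np.arange(s_lo, s_hi) * (1000.0 / sfreq)
    for ev in events:
        s0 = int(round(ev.onset_ms * sfreq / 1000.0))
        lo = s0 + s_lo
        hi = s0 + s_hi
        if lo < 0 or hi > n_samples:
            continue
        comp = spec.target if ev.is_target else spec.distractor
        jitter = (rng.normal(0.0, comp.latency_jitter_sd_ms)
                  if comp.latency_jitter_sd_ms > 0 else 0.0)
        tmpl = erp_template(
            (comp, *spec.shared), rel_ms, channels[:n_eeg],
            latency_shift_ms=subject.latency_shift_ms + jitter,
            amplitude_scale=subject.amplitude_scale,
            topography_gain=subject.topography_gain,
        )
        data[:n_eeg, lo:hi] += tmpl

    return ContinuousRecording(
        data=data,
        sampling_rate=sfreq,
        channel_names=channels,
        events=events,
        participant=participant_label(participant),
        condition=condition,
        reference="left-mastoid",
    )


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(
    events: list[StimulusEvent],
    condition: str,
    error_rate: float,
    seed: int | np.random.Generator = 0,
    grid_size: int = 5,
):
    """Entered answer for one repetition: correct with probability
    1 - error_rate, otherwise perturbed (count +-1; sum +-1 or +-10; one
    memorized position displaced)."""
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    correct = score_correct(events, condition)
    if rng.uniform() >= error_rate:
        return correct
    if condition == "C":
        delta = int(rng.choice([-1, 1]))
        return max(0, correct + delta)
    if condition == "A":
        delta = int(rng.choice([-10, -1, 1, 10]))
        return max(0, correct + delta)
    # M: displace one position to a random cell not already entered
    entered = [tuple(p) for p in correct]
    if not entered:
        return entered
    i = int(rng.integers(len(entered)))
    cells = [(r, c) for r in range(1, grid_size + 1) for c in range(1, grid_size + 1)
             if (r, c) not in entered]
    if cells:
        entered[i] = cells[int(rng.integers(len(cells)))]
    return entered


def simulate_answers(config: SimulationConfig, participant: int,
                     events: list[StimulusEvent], condition: str) -> list[BehavioralRecord]:
    """Behavioral records for all repetitions of one recording."""
    cond_idx = sorted(config.conditions).index(condition)
    rng = _rng(config, _BEHAVIOR_STREAM, participant, cond_idx)
    reps = sorted({ev.repetition_index for ev in events})
    out = []
    for rep in reps:
        seq = [ev for ev in events if ev.repetition_index == rep]
        correct = score_correct(seq, condition)
        entered = simulate_behavior(seq, condition, config.behavioral_error_rate, rng,
                                    grid_size=config.sequence_design.grid_size)
        out.append(BehavioralRecord(condition=condition, repetition_index=rep,
                                    correct=correct, entered=entered))
    return out


def simulate_cohort(config: SimulationConfig):
    """Yield (participant_label, condition, recording, behavioral records)
    for the whole cohort, one recording at a time."""
    config.validate()
    for p in range(config.n_participants):
        for condition in sorted(config.conditions):
            rec = simulate_recording(config, p, condition)
            answers = simulate_answers(config, p, rec.events, condition)
            yield participant_label(p), condition, rec, answers
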