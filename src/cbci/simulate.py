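"""Synthetic experiment generator.

Produces complete simulated sessions -- shared trial sequences, per-observer
decisions and response times, and response-locked 64x24 EEG epochs (or,
for end-to-end pipeline tests, short 2048 Hz continuous segments) --
carrying the statistical structure the analysis pipeline assumes:

* 10 observers x 224 trials on one shared stimulus sequence;
* per-observer error rates spread over 5-20% (population mean 12.5%), with
  error probability rising with the degree of match on non-identical pairs
  and only 0-1 misses of the identical pairs per observer;
* log-normal response times with condition medians 690 ms (correct) and
  880 ms (incorrect), plus a small DoM-dependent shift (harder trials are
  answered more slowly, whatever the outcome) so that median decision
  weights fall monotonically with DoM as observed empirically;
* a response-locked P300-like half-sine deflection, strongest over
  centro-parietal sites, whose onset/peak precede the response by
  400/200 ms on correct trials and 600/400 ms on incorrect ones, with a
  further 15 ms-per-DoM latency shift, embedded in AR(1) coloured noise.

Amplitude (8 uV at Pz) and noise (8 uV sd) are calibrated so that the
out-of-fold neural feature separates conditions on the scale the reported
weight medians imply (median nf roughly -0.8 correct vs -0.6 incorrect).

Separate seeds control the trial sequence and the behaviour/EEG so the
"same stimuli, different observers" structure is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import task
from .montage import BIOSEMI64, centro_parietal_gains
from .preprocess import (
    EPOCH_SAMPLES,
    FINAL_RATE,
    RAW_RATE,
    RESPONSE_PRE_SAMPLES,
    ContinuousRecording,
)
from .task import TrialSpec, generate_experiment


@dataclass(frozen=True)
class ObserverProfile:
    """Behavioural parameters of one simulated observer."""

    participant_id: str
    error_rate: float  # overall target error rate, identical pairs included
    dom_slope: float = 0.4  # log-odds of error per DoM unit (non-identical pairs)
    identical_miss_count: int = 0  # 0 or 1 missed identical pairs per experiment
    rt_median_correct: float = 0.690  # s
    rt_median_incorrect: float = 0.880  # s
    rt_sigma: float = 0.25  # log-normal shape
    rt_dom_slope: float = 0.030  # s per DoM unit, centred at DoM 3

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.identical_miss_count not in (0, 1):
            raise ValueError("identical_miss_count must be 0 or 1")


def default_profiles(n: int = 10) -> list[ObserverProfile]:
    """Observers with error rates evenly spread over 5-20% (mean 12.5%)."""
    rates = np.linspace(0.05, 0.20, n)
    return [
        ObserverProfile(
            participant_id=f"P{i + 1:02d}", error_rate=float(r), identical_miss_count=i % 2
        )
        for i, r in enumerate(rates)
    ]


@dataclass(frozen=True)
class ERPTemplateConfig:
    """Response-locked P300-like template parameters."""

    amplitude: float = 8.0  # uV at unit channel gain
    onset_pre_response_ms: tuple = (400.0, 600.0)  # (correct, incorrect)
    peak_pre_response_ms: tuple = (200.0, 400.0)
    dom_latency_slope_ms: float = 15.0  # extra pre-response shift per DoM unit
    noise_sd: float = 8.0  # uV, stationary sd of the AR(1) noise
    ar_coef: float = 0.9  # at 16 Hz
    channel_gains: tuple = tuple(centro_parietal_gains())

    def __post_init__(self) -> None:
        for onset, peak in zip(self.onset_pre_response_ms, self.peak_pre_response_ms):
            if onset <= peak:
                raise ValueError("template onset must precede its peak")
        if any(g < 0 for g in self.channel_gains):
            raise ValueError("channel gains must be nonnegative")

    def latencies_ms(self, condition: str, dom: int = 3) -> tuple[float, float]:
        """(onset, peak) in ms before the response, DoM shift applied."""
        i = {"correct": 0, "incorrect": 1}[condition]
        shift = self.dom_latency_slope_ms * (dom - 3)
        return self.onset_pre_response_ms[i] + shift, self.peak_pre_response_ms[i] + shift


def template_waveform(times_ms: np.ndarray, cfg: ERPTemplateConfig, condition: str, dom: int = 3) -> np.ndarray:
    """Unit-gain half-sine P300 on an arbitrary response-locked time axis (ms)."""
    onset, peak = cfg.latencies_ms(condition, dom)
    duration = 2.0 * (onset - peak)
    phase = (times_ms + onset) / duration  # 0 at onset, 0.5 at peak, 1 at offset
    wave = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    return cfg.amplitude * wave


def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, coef: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis, independent per channel."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, sd, shape[:-1])
    eps = rng.normal(0.0, innov_sd, shape[:-1] + (shape[-1] - 1,))
    for t in range(1, shape[-1]):
        out[..., t] = coef * out[..., t - 1] + eps[..., t - 1]
    return out


def simulate_eeg_epoch(
    condition: str,
    rt: float,
    template: ERPTemplateConfig,
    rng: np.random.Generator,
    dom: int = 3,
) -> np.ndarray:
    """One response-locked 64x24 epoch: gained template plus AR(1) noise."""
    if condition not in ("correct", "incorrect"):
        raise ValueError("condition must be 'correct' or 'incorrect'")
    if rt <= 0:
        raise ValueError("rt must be positive")
    times_ms = (np.arange(EPOCH_SAMPLES) - RESPONSE_PRE_SAMPLES) * 1000.0 / FINAL_RATE
    wave = template_waveform(times_ms, template, condition, dom)
    gains = np.asarray(template.channel_gains)
    epoch = np.outer(gains, wave)
    epoch += _ar1_noise(rng, epoch.shape, template.noise_sd, template.ar_coef)
    return epoch


# ---------------------------------------------------------------------------
# Sessions and populations


@dataclass
class Session:
    """One observer's simulated experiment."""

    participant_id: str
    behaviour: pd.DataFrame  # trial, block, dom, truth, decision, correct, rt
    epochs: np.ndarray | None = None  # (n_trials, 64, 24) response-locked

    @property
    def labels(self) -> np.ndarray:
        """+1 for incorrect trials, -1 for correct (the regression targets)."""
        return np.where(self.behaviour["correct"].to_numpy(), -1.0, 1.0)


@dataclass
class Population:
    """A set of observers who all saw the same trial sequence."""

    trials: list[TrialSpec]
    sessions: list[Session]

    @property
    def trials_frame(self) -> pd.DataFrame:
        return task.trials_to_frame(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _error_probabilities(trials: list[TrialSpec], profile: ObserverProfile) -> np.ndarray:
    """Per-trial error probability on non-identical pairs (0 for identical).

    The base log-odds is solved so the expected error count over the
    non-identical trials, plus the forced identical misses, hits the
    profile's overall target rate.
    """
    doms = np.array([t.dom for t in trials])
    nonident = doms < task.MAX_DOM
    target = profile.error_rate * len(trials) - profile.identical_miss_count
    if not 0 < target < nonident.sum():
        raise ValueError("unattainable error_rate for this trial sequence")
    x = profile.dom_slope * (doms[nonident] - 2.5)

    lo, hi = logit(1e-6), logit(1 - 1e-6)
    theta = brentq(lambda th: expit(th + x).sum() - target, lo - x.max(), hi - x.min())
    p = np.zeros(len(trials))
    p[nonident] = expit(theta + x)
    return p


def _simulate_behaviour(
    trials: list[TrialSpec], profile: ObserverProfile, rng: np.random.Generator
) -> pd.DataFrame:
    doms = np.array([t.dom for t in trials])
    identical = doms == task.MAX_DOM
    p_err = _error_probabilities(trials, profile)
    correct = rng.random(len(trials)) >= p_err
    correct[identical] = True
    if profile.identical_miss_count:
        miss = rng.choice(np.flatnonzero(identical), size=profile.identical_miss_count, replace=False)
        correct[miss] = False
    # errors on non-identical pairs are false matches ("yes"); misses are "no"
    decision = np.where(correct == identical, "yes", "no")
    median = (
        np.where(correct, profile.rt_median_correct, profile.rt_median_incorrect)
        + profile.rt_dom_slope * (doms - 3)
    )
    rt = median * np.exp(profile.rt_sigma * rng.standard_normal(len(trials)))
    return pd.DataFrame(
        {
            "trial": [t.trial_index for t in trials],
            "block": [t.block_index for t in trials],
            "dom": doms,
            "truth": [t.truth for t in trials],
            "decision": decision,
            "correct": correct,
            "rt": rt,
        }
    )


def simulate_population(
    n_participants: int = 10,
    trial_seed: int = 0,
    behaviour_seed: int = 1,
    profiles: list[ObserverProfile] | None = None,
    template: ERPTemplateConfig | None = None,
    n_blocks: int = task.BLOCKS_PER_EXPERIMENT,
    with_eeg: bool = True,
) -> Population:
    """Simulate a full experiment: one trial sequence, many observers.

    The trial sequence is generated once from ``trial_seed`` and shared by
    every session; behaviour and EEG derive from ``behaviour_seed`` with an
    independent substream per observer.
    """
    if profiles is None:
        profiles = default_profiles(n_participants)
    if len(profiles) != n_participants:
        raise ValueError("profiles length must match n_participants")
    template = template or ERPTemplateConfig()
    trials = generate_experiment(trial_seed, n_blocks=n_blocks)
    sessions = []
    for i, profile in enumerate(profiles):
        rng = np.random.default_rng([behaviour_seed, i])
        behaviour = _simulate_behaviour(trials, profile, rng)
        epochs = None
        if with_eeg:
            epochs = np.stack(
                [
                    simulate_eeg_epoch(
                        "correct" if row.correct else "incorrect",
                        row.rt,
                        template,
                        rng,
                        dom=row.dom,
                    )
                    for row in behaviour.itertuples()
                ]
            )
        sessions.append(Session(profile.participant_id, behaviour, epochs))
    return Population(trials, sessions)


def expected_condition_counts(
    n_participants: int = 10,
    n_trials: int = task.TRIALS_PER_EXPERIMENT,
    error_rate: float = 0.125,
) -> tuple[int, int]:
    """Pooled (correct, incorrect) epoch counts at a given mean error rate."""
    total = n_participants * n_trials
    incorrect = round(total * error_rate)
    return total - incorrect, incorrect


# ---------------------------------------------------------------------------
# Continuous 2048 Hz segments (for end-to-end pipeline tests)

_TRIAL_SETUP_S = (
    task.STIMULUS_TIMING_MS["fixation"]
    + task.STIMULUS_TIMING_MS["set1"]
    + task.STIMULUS_TIMING_MS["mask"]
    + task.STIMULUS_TIMING_MS["delay"]
) / 1000.0  # fixation -> set2 onset


def simulate_continuous_session(
    trials: list[TrialSpec],
    profile: ObserverProfile,
    template: ERPTemplateConfig,
    seed: int,
    rate: float = RAW_RATE,
    lead_in_s: float = 4.0,
    inter_trial_s: float = 1.0,
) -> tuple[ContinuousRecording, pd.DataFrame]:
    """A raw-rate recording with set2/response markers and embedded templates.

    The AR(1) noise coefficient is raised to ``ar_coef ** (16 / rate)`` so
    its low-frequency content matches the 16 Hz epoch noise after the
    decimation chain.
    """
    rng = np.random.default_rng(seed)
    behaviour = _simulate_behaviour(trials, profile, rng)
    onsets = []
    t = lead_in_s
    for rt in behaviour["rt"]:
        t += _TRIAL_SETUP_S
        onsets.append(t)
        t += rt + inter_trial_s
    n_samples = int(np.ceil((t + lead_in_s) * rate))
    coef = template.ar_coef ** (FINAL_RATE / rate)
    data = _ar1_noise(rng, (len(BIOSEMI64), n_samples), template.noise_sd, coef)
    gains = np.asarray(template.channel_gains)
    events = []
    times_all = np.arange(n_samples) / rate
    for row, onset in zip(behaviour.itertuples(), onsets):
        resp_t = onset + row.rt
        onset_sample = int(round(onset * rate))
        resp_sample = int(round(resp_t * rate))
        events.append({"sample": onset_sample, "kind": "set2_onset", "trial": row.trial})
        events.append({"sample": resp_sample, "kind": "response", "trial": row.trial})
        cond = "correct" if row.correct else "incorrect"
        lo = max(0, resp_sample - int(1.2 * rate))
        hi = min(n_samples, resp_sample + int(0.7 * rate))
        rel_ms = (times_all[lo:hi] - resp_t) * 1000.0
        data[:, lo:hi] += np.outer(gains, template_waveform(rel_ms, template, cond, dom=row.dom))
    recording = ContinuousRecording(
        data=data, rate=rate, channel_names=list(BIOSEMI64), events=pd.DataFrame(events)
    )
    return recording, behaviour


def end_to_end_fixture(seed: int = 0, with_eeg: bool = True) -> Population:
    """Miniature deterministic experiment: 4 observers x 2 blocks (56 trials)."""
    return simulate_population(
        n_participants=4,
        trial_seed=seed,
        behaviour_seed=seed + 1,
        profiles=default_profiles(4),
        n_blocks=2,
        with_eeg=with_eeg,
    )


def blink_waveform(n_samples: int, rate: float, peak_uv: float = 100.0) -> np.ndarray:
    """A single eye-blink-like transient (raised cosine, ~300 ms wide)."""
    t = np.arange(n_samples) / rate
    centre, width = t[n_samples // 2], 0.3
    phase = np.clip((t - centre + width / 2) / width, 0, 1)
    return peak_uv * 0.5 * (1 - np.cos(2 * np.pi * phase))
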