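"""EEG preprocessing chain: band-pass, ocular correction, decimation, epoching.

The chain reproduces a classic offline ERP pipeline: 64-channel data sampled
at 2048 Hz are band-pass filtered 0.15–40 Hz with a 14677-tap windowed FIR
filter, corrected for ocular artifacts by regressing out a surrogate EOG
built from frontal channel differences, low-pass filtered with an 820-tap
equiripple (Remez) filter passing 0–6 Hz, and decimated to 16 Hz.  Epochs of
1500 ms (24 samples x 64 channels) are then cut either stimulus-locked
(from the onset of the second stimulus set) or response-locked (from 1 s
before the response to 500 ms after it).

All filters are applied zero-phase so that ERP latencies are preserved:
the odd-length band-pass by delay-compensated convolution, the even-length
decimation low-pass forward-backward.  Edges are reflect-padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin, remez

from .montage import BIOSEMI64

logger = logging.getLogger(__name__)

RAW_RATE = 2048.0
FINAL_RATE = 16.0
DECIM = int(RAW_RATE / FINAL_RATE)  # 128

BANDPASS_TAPS = 14677
BANDPASS_LO_HZ = 0.15
BANDPASS_HI_HZ = 40.0
DECIM_TAPS = 820
DECIM_PASS_HZ = 6.0
DECIM_STOP_HZ = 8.0

EPOCH_MS = 1500.0
EPOCH_SAMPLES = 24  # at 16 Hz
RESPONSE_PRE_MS = 1000.0
RESPONSE_PRE_SAMPLES = 16  # 1000 ms at 16 Hz; the response falls on sample 16


@dataclass
class ContinuousRecording:
    """Multi-channel voltage data (µV) with event markers.

    ``events`` has columns ``sample`` (index into ``data``), ``kind``
    (``set2_onset`` or ``response``) and ``trial`` (0-based trial index).
    """

    data: np.ndarray  # (n_channels, n_samples)
    rate: float
    channel_names: list[str] = field(default_factory=lambda: list(BIOSEMI64))
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample", "kind", "trial"]))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class Epoch:
    """A 64-channel x 24-sample voltage matrix at 16 Hz (1500 ms)."""

    voltages: np.ndarray  # (n_channels, EPOCH_SAMPLES)
    locking: str  # "stimulus" | "response"
    trial_index: int
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape[1] != EPOCH_SAMPLES:
            raise ValueError(f"epochs have exactly {EPOCH_SAMPLES} samples per channel")
        if self.locking not in ("stimulus", "response"):
            raise ValueError("locking must be 'stimulus' or 'response'")


@lru_cache(maxsize=4)
def design_bandpass(
    rate: float = RAW_RATE,
    lo: float = BANDPASS_LO_HZ,
    hi: float = BANDPASS_HI_HZ,
    numtaps: int = BANDPASS_TAPS,
    lowpass_taps: int = 1025,
) -> np.ndarray:
    """Band-pass FIR: a windowed low-pass convolved with a windowed high-pass.

    The high-pass carries most of the length (its 0.15 Hz edge needs a very
    long filter); tap counts are chosen so the convolution has ``numtaps``
    coefficients, both factors odd (type-I) so the product is zero-phase
    after an integer delay.
    """
    hp_taps = numtaps - lowpass_taps + 1
    lp = firwin(lowpass_taps, hi, fs=rate, window="hamming")
    # spectral-inversion high-pass (delta minus low-pass): nulls DC exactly,
    # which a direct windowed design cannot do when the transition lobe is
    # wider than the 0.15 Hz cutoff itself
    hp = -firwin(hp_taps, lo, fs=rate, window="hamming")
    hp[(hp_taps - 1) // 2] += 1.0
    return np.convolve(lp, hp)


@lru_cache(maxsize=4)
def design_decimation_lowpass(rate: float = RAW_RATE, numtaps: int = DECIM_TAPS) -> np.ndarray:
    """Equiripple low-pass (Remez): pass 0-6 Hz, stop 8 Hz-Nyquist."""
    return remez(numtaps, [0, DECIM_PASS_HZ, DECIM_STOP_HZ, rate / 2], [1, 0], fs=rate)


def _zero_phase_filter(data: np.ndarray, h: np.ndarray, passes: int = 1) -> np.ndarray:
    """Apply a linear-phase FIR zero-phase with reflect padding.

    ``passes=1`` requires odd-length (integer-delay) ``h``; ``passes=2``
    applies the filter forward-backward (h is symmetric up to reversal, so
    two passes give an integer total delay for any length).
    """
    ntaps = len(h)
    if passes == 1 and ntaps % 2 == 0:
        raise ValueError("single-pass zero-phase needs an odd-length filter")
    pad = ntaps  # generous reflect padding, > total group delay
    padded = np.pad(data, [(0, 0), (pad, pad)], mode="reflect")
    out = padded
    for _ in range(passes):
        out = fftconvolve(out, h[None, :], mode="full", axes=1)
    delay = passes * (ntaps - 1) // 2
    start = pad + delay
    return out[:, start : start + data.shape[1]]


def bandpass_filter(recording: ContinuousRecording) -> ContinuousRecording:
    """Zero-phase 0.15-40 Hz band-pass at 2048 Hz."""
    if recording.rate != RAW_RATE:
        raise ValueError(f"band-pass chain is specified at {RAW_RATE:g} Hz input")
    h = design_bandpass(recording.rate)
    if recording.n_samples <= len(h):
        raise ValueError("recording shorter than the band-pass filter")
    return replace(recording, data=_zero_phase_filter(recording.data, h, passes=1))


def ocular_correction(recording: ContinuousRecording) -> ContinuousRecording:
    """Regress a surrogate EOG out of every channel.

    The surrogate is e(t) = mean[(Fp1-F1), (Fp2-F2)]; each channel c has
    b_c = cov(c, e)/var(e) estimated over the whole recording subtracted
    times e(t).
    """
    for name in ("Fp1", "F1", "Fp2", "F2"):
        if name not in recording.channel_names:
            raise ValueError(f"ocular correction requires channel {name}")
    e = 0.5 * (
        (recording.channel("Fp1") - recording.channel("F1"))
        + (recording.channel("Fp2") - recording.channel("F2"))
    )
    ec = e - e.mean()
    var = ec @ ec
    if var == 0:
        logger.warning("surrogate EOG has zero variance; no ocular correction applied")
        return replace(recording, data=recording.data.copy())
    dc = recording.data - recording.data.mean(axis=1, keepdims=True)
    b = dc @ ec / var  # (n_channels,)
    return replace(recording, data=recording.data - np.outer(b, e))


def lowpass_decimate(recording: ContinuousRecording) -> ContinuousRecording:
    """Equiripple 0-6 Hz low-pass (forward-backward) then keep every 128th sample."""
    if recording.rate != RAW_RATE:
        raise ValueError(f"decimation chain requires {RAW_RATE:g} Hz input")
    h = design_decimation_lowpass(recording.rate)
    filtered = _zero_phase_filter(recording.data, h, passes=2)
    data = filtered[:, ::DECIM]
    events = recording.events.copy()
    if len(events):
        events["sample"] = np.rint(events["sample"].to_numpy() / DECIM).astype(int)
    return ContinuousRecording(
        data=data, rate=FINAL_RATE, channel_names=list(recording.channel_names), events=events
    )


def preprocess_chain(recording: ContinuousRecording) -> ContinuousRecording:
    """Full chain: band-pass -> ocular correction -> low-pass + decimate."""
    return lowpass_decimate(ocular_correction(bandpass_filter(recording)))


def extract_epochs(recording: ContinuousRecording, locking: str) -> tuple[list[Epoch], list[int]]:
    """Cut 24-sample epochs from a 16 Hz recording.

    Stimulus-locked epochs run [set2 onset, onset+1500 ms); response-locked
    epochs run [response-1000 ms, response+500 ms), so the response falls on
    within-epoch sample 16.  Trials whose window leaves the recording, or
    (for response locking) with no response marker, are excluded; their
    indices are returned alongside the epochs.
    """
    if recording.rate != FINAL_RATE:
        raise ValueError("epochs are extracted from the 16 Hz post-chain recording")
    if locking not in ("stimulus", "response"):
        raise ValueError("locking must be 'stimulus' or 'response'")
    kind = "set2_onset" if locking == "stimulus" else "response"
    ev = recording.events
    trials = sorted(ev["trial"].unique()) if len(ev) else []
    epochs: list[Epoch] = []
    excluded: list[int] = []
    for trial in trials:
        rows = ev[(ev["trial"] == trial) & (ev["kind"] == kind)]
        if len(rows) == 0:
            excluded.append(int(trial))
            continue
        anchor = int(rows["sample"].iloc[0])
        start = anchor if locking == "stimulus" else anchor - RESPONSE_PRE_SAMPLES
        stop = start + EPOCH_SAMPLES
        if start < 0 or stop > recording.n_samples:
            excluded.append(int(trial))
            continue
        epochs.append(
            Epoch(voltages=recording.data[:, start:stop], locking=locking, trial_index=int(trial))
        )
    if excluded:
        logger.warning("excluded %d trial(s) without a usable %s window", len(excluded), locking)
    return epochs, excluded
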