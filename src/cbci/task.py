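"""Visual-matching task model.

Each trial briefly shows two sets of three shaded shapes and the observer
reports whether they are identical.  The similarity of the two sets is
summarised by the *degree of match* (DoM): the number of positionwise
shape/shade features they share, from 0 (nothing in common) to 6 (identical).
Experiments are built from blocks with equal numbers of trials at every DoM,
and the same trial sequence is shown to every observer so that their
decisions can later be fused offline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

SHAPES = ("triangle", "square", "pentagon")
SHADES = ("white", "grey")

_SHAPE_CODE = {"triangle": "T", "square": "S", "pentagon": "P"}
_SHADE_CODE = {"white": "w", "grey": "g"}
_CODE_SHAPE = {v: k for k, v in _SHAPE_CODE.items()}
_CODE_SHADE = {v: k for k, v in _SHADE_CODE.items()}

#: Nominal shade luminances (normalised RGB), metadata only.
SHADE_RGB = {"white": (1.0, 1.0, 1.0), "grey": (0.65, 0.65, 0.65)}

#: On-screen event durations in ms, metadata only (the simulator does not
#: model the mask or fixation psychophysically).
STIMULUS_TIMING_MS = {"fixation": 1000, "set1": 83, "mask": 250, "delay": 1000, "set2": 100}

N_POSITIONS = 3
N_FEATURES = 2 * N_POSITIONS  # shape + shade per position
MAX_DOM = N_FEATURES

TRIALS_PER_BLOCK = 28
BLOCKS_PER_EXPERIMENT = 8
TRIALS_PER_EXPERIMENT = TRIALS_PER_BLOCK * BLOCKS_PER_EXPERIMENT

# Response-time measurement jitter budget: USB mouse polling at 125 Hz,
# a 5 ms sleep in the event-capture loop, and 1 ms to mark the EEG status
# channel.  Worst case is the sum of the three.
USB_POLL_RATE_HZ = 125
LOOP_SLEEP_MS = 5.0
MARKER_JITTER_MS = 1.0


def max_rt_jitter_ms() -> float:
    """Worst-case jitter (ms) on a response-time measurement."""
    return 1000.0 / USB_POLL_RATE_HZ + LOOP_SLEEP_MS + MARKER_JITTER_MS


@dataclass(frozen=True)
class StimulusSet:
    """An ordered triple of (shape, shade) elements."""

    elements: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.elements) != N_POSITIONS:
            raise ValueError(f"a stimulus set has exactly {N_POSITIONS} elements")
        for shape, shade in self.elements:
            if shape not in SHAPES:
                raise ValueError(f"unknown shape {shape!r}")
            if shade not in SHADES:
                raise ValueError(f"unknown shade {shade!r}")

    def code(self) -> str:
        """Compact 'Tw Sw Pg' style code."""
        return " ".join(_SHAPE_CODE[sh] + _SHADE_CODE[sd] for sh, sd in self.elements)

    @classmethod
    def from_code(cls, code: str) -> "StimulusSet":
        parts = code.split()
        if len(parts) != N_POSITIONS or any(len(p) != 2 for p in parts):
            raise ValueError(f"malformed stimulus-set code {code!r}")
        try:
            elems = tuple((_CODE_SHAPE[p[0]], _CODE_SHADE[p[1]]) for p in parts)
        except KeyError as exc:
            raise ValueError(f"malformed stimulus-set code {code!r}") from exc
        return cls(elems)


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the matching task (0-based indices)."""

    trial_index: int
    block_index: int
    set1: StimulusSet
    set2: StimulusSet
    dom: int
    truth: str  # "identical" | "different"

    def __post_init__(self) -> None:
        if not 0 <= self.dom <= MAX_DOM:
            raise ValueError("dom out of range")
        if (self.truth == "identical") != (self.dom == MAX_DOM):
            raise ValueError("truth must be 'identical' iff dom == 6")


def degree_of_match(set1: StimulusSet, set2: StimulusSet) -> int:
    """Count the positionwise shape and shade features shared by two sets.

    A feature only counts as shared when it occurs at the same position in
    both sets; an off-position repeat of a shape contributes nothing.
    Range 0–6, with 6 meaning a perfect match.
    """
    dom = 0
    for (sh1, sd1), (sh2, sd2) in zip(set1.elements, set2.elements):
        dom += (sh1 == sh2) + (sd1 == sd2)
    return dom


def enumerate_all_sets() -> list[StimulusSet]:
    """All (2*3)^3 = 216 distinct stimulus sets."""
    elems = list(itertools.product(SHAPES, SHADES))
    return [StimulusSet(combo) for combo in itertools.product(elems, repeat=N_POSITIONS)]


def _random_set(rng: np.random.Generator) -> StimulusSet:
    return StimulusSet(
        tuple((SHAPES[rng.integers(3)], SHADES[rng.integers(2)]) for _ in range(N_POSITIONS))
    )


def _set_with_dom(set1: StimulusSet, dom: int, rng: np.random.Generator) -> StimulusSet:
    """Build a second set sharing exactly `dom` features with `set1`.

    Which of the 6 feature slots match is drawn uniformly at random;
    non-matching features are resampled uniformly from the alternatives.
    """
    if not 0 <= dom <= MAX_DOM:
        raise ValueError("dom must be in 0..6")
    matching = set(rng.choice(N_FEATURES, size=dom, replace=False).tolist())
    elems = []
    for pos, (shape, shade) in enumerate(set1.elements):
        if pos in matching:  # slots 0..2: shapes
            new_shape = shape
        else:
            others = [s for s in SHAPES if s != shape]
            new_shape = others[rng.integers(len(others))]
        if pos + N_POSITIONS in matching:  # slots 3..5: shades
            new_shade = shade
        else:
            new_shade = SHADES[0] if shade == SHADES[1] else SHADES[1]
        elems.append((new_shape, new_shade))
    return StimulusSet(tuple(elems))


def generate_balanced_block(
    rng_seed: int | np.random.Generator,
    block_index: int,
    n_trials: int = TRIALS_PER_BLOCK,
) -> list[TrialSpec]:
    """One block of trials with equal numbers at every DoM, shuffled.

    `rng_seed` may be an int or an already-seeded Generator (used by
    :func:`generate_experiment` so blocks draw from one stream).
    """
    if n_trials % (MAX_DOM + 1) != 0:
        raise ValueError("block size must be divisible by 7")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    per_dom = n_trials // (MAX_DOM + 1)
    doms = np.repeat(np.arange(MAX_DOM + 1), per_dom)
    rng.shuffle(doms)
    trials = []
    for i, dom in enumerate(doms):
        s1 = _random_set(rng)
        s2 = _set_with_dom(s1, int(dom), rng)
        assert degree_of_match(s1, s2) == dom
        trials.append(
            TrialSpec(
                trial_index=block_index * n_trials + i,
                block_index=block_index,
                set1=s1,
                set2=s2,
                dom=int(dom),
                truth="identical" if dom == MAX_DOM else "different",
            )
        )
    return trials


def generate_experiment(
    rng_seed: int, n_blocks: int = BLOCKS_PER_EXPERIMENT, block_size: int = TRIALS_PER_BLOCK
) -> list[TrialSpec]:
    """A full experiment: `n_blocks` balanced blocks from one seeded stream.

    The returned sequence is intended to be shared verbatim by every
    simulated participant, mirroring the stored-sequence design.
    """
    rng = np.random.default_rng(rng_seed)
    trials: list[TrialSpec] = []
    for b in range(n_blocks):
        trials.extend(generate_balanced_block(rng, b, block_size))
    return trials


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "block": [t.block_index for t in trials],
            "set1": [t.set1.code() for t in trials],
            "set2": [t.set2.code() for t in trials],
            "dom": [t.dom for t in trials],
            "truth": [t.truth for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(
            trial_index=int(r.trial_index),
            block_index=int(r.block),
            set1=StimulusSet.from_code(r.set1),
            set2=StimulusSet.from_code(r.set2),
            dom=int(r.dom),
            truth=str(r.truth),
        )
        for r in frame.itertuples()
    ]


def write_trials_tsv(trials: list[TrialSpec], path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> list[TrialSpec]:
    return frame_to_trials(pd.read_csv(path, sep="\t"))
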