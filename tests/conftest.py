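"""Shared builders for item-level fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from mcogscore.scoring import COLOURS, MemoryItem, StroopTrial, SymbolTrial

WORDS = ("apple", "river", "candle", "garden", "mirror", "pencil", "window", "basket",
         "engine", "forest", "hammer", "island", "jacket", "kettle", "ladder", "magnet")


def make_stroop(n_correct: int = 18, per_trial_time: float | list[float] = 1.0,
                skip_indices: tuple[int, ...] = ()) -> list[StroopTrial]:
    """18 trials (6 congruent / 12 incongruent); the first ``n_correct`` are
    answered correctly, the rest wrongly; ``skip_indices`` get no response."""
    times = [per_trial_time] * 18 if np.isscalar(per_trial_time) else list(per_trial_time)
    trials = []
    for i in range(18):
        ink = COLOURS[i % 3]
        word = ink if i < 6 else COLOURS[(i + 1) % 3]
        if i in skip_indices:
            trials.append(StroopTrial(word, ink))
        else:
            chosen = ink if i < n_correct else COLOURS[(COLOURS.index(ink) + 1) % 3]
            trials.append(StroopTrial(word, ink, chosen, times[i]))
    return trials


def make_symbols(n_correct: int = 9, per_trial_time: float | list[float] = 1.0,
                 skip_indices: tuple[int, ...] = ()) -> list[SymbolTrial]:
    times = [per_trial_time] * 9 if np.isscalar(per_trial_time) else list(per_trial_time)
    trials = []
    for i in range(9):
        correct = i + 1
        if i in skip_indices:
            trials.append(SymbolTrial(i + 1, correct))
        else:
            entered = correct if i < n_correct else correct % 9 + 1
            trials.append(SymbolTrial(i + 1, correct, entered, times[i]))
    return trials


def make_memory(n_correct: int = 8, skip_indices: tuple[int, ...] = ()) -> list[MemoryItem]:
    """8 items; the first ``n_correct`` have correct delayed choices."""
    items = []
    for i in range(8):
        target = WORDS[i]
        distract = [w for w in WORDS if w != target]
        first = (target,) + tuple(distract[:3])
        second = (target,) + tuple(distract[:7])
        if i in skip_indices:
            items.append(MemoryItem(target, first, second))
        else:
            items.append(MemoryItem(target, first, second,
                                    first_choice=0,
                                    second_choice=0 if i < n_correct else 1))
    return items


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
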