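"""Subtest scoring and the z-composite cognitive score.

The composite screening score is the mean of three z-scores:

* Stroop colour-word test (18 trials): correct responses per second,
* symbol-digit substitution (9 trials): correct responses per second,
* two-stage cued recall of 8 words: number correct on the delayed trial
  (time deliberately excluded so the memory score is decorrelated from
  the two speeded scores).

Skipped sections never score zero: any absent response marks the subtest
incomplete and an incomplete triplet yields no composite at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DegenerateReferenceError, InvalidDesignError, InvalidResponseError

COLOURS = ("red", "green", "blue")

STROOP_N_TRIALS = 18
STROOP_N_CONGRUENT = 6
SYMBOLS_N_TRIALS = 9
MEMORY_N_ITEMS = 8
MEMORY_N_OPTIONS_IMMEDIATE = 4
MEMORY_N_OPTIONS_DELAYED = 8


@dataclass(frozen=True)
class StroopTrial:
    """One colour-word trial: a colour name shown in an ink colour.

    ``chosen_option`` / ``response_time`` are ``None`` when the trial was
    skipped. A trial is correct when the chosen option names the ink.
    """

    word_text: str
    ink_colour: str
    chosen_option: str | None = None
    response_time: float | None = None

    def __post_init__(self) -> None:
        if self.word_text not in COLOURS or self.ink_colour not in COLOURS:
            raise InvalidResponseError(
                f"stroop stimulus must use colours {COLOURS}: "
                f"{self.word_text!r}/{self.ink_colour!r}"
            )
        if self.chosen_option is not None and self.chosen_option not in COLOURS:
            raise InvalidResponseError(f"stroop response {self.chosen_option!r} not a colour option")
        if self.response_time is not None and not self.response_time > 0:
            raise InvalidDesignError(f"response time must be positive, got {self.response_time}")

    @property
    def is_congruent(self) -> bool:
        return self.word_text == self.ink_colour

    @property
    def answered(self) -> bool:
        return self.chosen_option is not None and self.response_time is not None

    @property
    def correct(self) -> bool:
        return self.chosen_option == self.ink_colour


@dataclass(frozen=True)
class SymbolTrial:
    """One symbol-digit substitution trial.

    The key maps the nine symbols one-to-one onto digits 1-9;
    ``correct_digit`` is the key's digit for ``target_symbol_id``.
    """

    target_symbol_id: int
    correct_digit: int
    entered_digit: int | None = None
    response_time: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.target_symbol_id <= 9:
            raise InvalidDesignError(f"symbol id {self.target_symbol_id} outside 1..9")
        if not 1 <= self.correct_digit <= 9:
            raise InvalidDesignError(f"key digit {self.correct_digit} outside 1..9")
        if self.entered_digit is not None and not 1 <= self.entered_digit <= 9:
            raise InvalidResponseError(f"entered digit {self.entered_digit} outside 1..9")
        if self.response_time is not None and not self.response_time > 0:
            raise InvalidDesignError(f"response time must be positive, got {self.response_time}")

    @property
    def answered(self) -> bool:
        return self.entered_digit is not None and self.response_time is not None

    @property
    def correct(self) -> bool:
        return self.entered_digit == self.correct_digit


@dataclass(frozen=True)
class MemoryItem:
    """One word of the two-stage cued recall list.

    The immediate trial offers the target among 3 distractors, the delayed
    trial among 7 distractors. Choices are indices into the option tuples,
    or ``None`` if that recall trial was skipped.
    """

    target_word: str
    first_options: tuple[str, ...]
    second_options: tuple[str, ...]
    first_choice: int | None = None
    second_choice: int | None = None

    def __post_init__(self) -> None:
        if len(self.first_options) != MEMORY_N_OPTIONS_IMMEDIATE:
            raise InvalidDesignError("immediate recall needs exactly 4 options (target + 3 distractors)")
        if len(self.second_options) != MEMORY_N_OPTIONS_DELAYED:
            raise InvalidDesignError("delayed recall needs exactly 8 options (target + 7 distractors)")
        for opts in (self.first_options, self.second_options):
            if opts.count(self.target_word) != 1 or len(set(opts)) != len(opts):
                raise InvalidDesignError("option set must contain the target exactly once, all options distinct")
        for choice, opts in ((self.first_choice, self.first_options), (self.second_choice, self.second_options)):
            if choice is not None and not 0 <= choice < len(opts):
                raise InvalidResponseError(f"choice index {choice} outside option set")

    @property
    def first_correct(self) -> bool:
        return self.first_choice is not None and self.first_options[self.first_choice] == self.target_word

    @property
    def second_correct(self) -> bool:
        return self.second_choice is not None and self.second_options[self.second_choice] == self.target_word


@dataclass(frozen=True)
class SubtestResult:
    """Item-level responses reduced to (n_correct, n_items, total_time).

    ``total_time`` is ``None`` for the untimed memory subtest, and whenever
    the subtest is incomplete. ``completed`` is False as soon as any single
    item response is absent.
    """

    subtest: str
    n_correct: int
    n_items: int
    total_time: float | None
    completed: bool

    def __post_init__(self) -> None:
        if self.n_correct < 0 or self.n_correct > self.n_items:
            raise InvalidDesignError(f"n_correct {self.n_correct} outside 0..{self.n_items}")

    @property
    def raw_score(self) -> float | None:
        """Correct-per-second for timed subtests, plain count for memory.

        ``None`` for incomplete subtests: a skip is missing data, not zero.
        """
        if not self.completed:
            return None
        if self.subtest == "memory":
            return float(self.n_correct)
        return self.n_correct / self.total_time


def score_stroop(trials: Sequence[StroopTrial]) -> SubtestResult:
    """Score 18 colour-word trials as (n correct, total seconds).

    The design requires 6 congruent and 12 incongruent trials; anything
    else raises :class:`InvalidDesignError`.
    """
    if len(trials) != STROOP_N_TRIALS:
        raise InvalidDesignError(f"stroop needs {STROOP_N_TRIALS} trials, got {len(trials)}")
    n_congruent = sum(t.is_congruent for t in trials)
    if n_congruent != STROOP_N_CONGRUENT:
        raise InvalidDesignError(
            f"stroop needs {STROOP_N_CONGRUENT} congruent / "
            f"{STROOP_N_TRIALS - STROOP_N_CONGRUENT} incongruent trials, got {n_congruent} congruent"
        )
    completed = all(t.answered for t in trials)
    n_correct = sum(t.answered and t.correct for t in trials)
    total_time = sum(t.response_time for t in trials) if completed else None
    if completed and not total_time > 0:
        raise InvalidDesignError("total response time must be positive")
    return SubtestResult("stroop", n_correct, STROOP_N_TRIALS, total_time, completed)


def score_symbols(trials: Sequence[SymbolTrial]) -> SubtestResult:
    """Score 9 symbol-digit trials as (n correct, total seconds)."""
    if len(trials) != SYMBOLS_N_TRIALS:
        raise InvalidDesignError(f"symbols needs {SYMBOLS_N_TRIALS} trials, got {len(trials)}")
    completed = all(t.answered for t in trials)
    n_correct = sum(t.answered and t.correct for t in trials)
    total_time = sum(t.response_time for t in trials) if completed else None
    if completed and not total_time > 0:
        raise InvalidDesignError("total response time must be positive")
    return SubtestResult("symbols", n_correct, SYMBOLS_N_TRIALS, total_time, completed)


def score_memory(
    items: Sequence[MemoryItem],
    trial: Literal["delayed", "immediate", "both"] = "delayed",
) -> SubtestResult:
    """Score the 8-word cued recall by number correct (untimed).

    By default only the delayed (second) recall trial counts, the standard
    diagnostic trial of two-stage recall batteries; ``trial`` may widen
    this to the immediate trial or the per-item conjunction of both.
    """
    if len(items) != MEMORY_N_ITEMS:
        raise InvalidDesignError(f"memory needs {MEMORY_N_ITEMS} items, got {len(items)}")
    if trial == "delayed":
        completed = all(it.second_choice is not None for it in items)
        n_correct = sum(it.second_correct for it in items)
    elif trial == "immediate":
        completed = all(it.first_choice is not None for it in items)
        n_correct = sum(it.first_correct for it in items)
    elif trial == "both":
        completed = all(it.first_choice is not None and it.second_choice is not None for it in items)
        n_correct = sum(it.first_correct and it.second_correct for it in items)
    else:
        raise ValueError(f"unknown trial selector {trial!r}")
    return SubtestResult("memory", n_correct, MEMORY_N_ITEMS, None, completed)


SUBTESTS = ("stroop", "symbols", "memory")


@dataclass(frozen=True)
class ZReference:
    """Per-subtest normalisation constants (mean, sample sd) fitted on a
    reference sample of participants with all three subtests complete."""

    means: dict[str, float]
    sds: dict[str, float]
    n: int

    def zscore(self, subtest: str, raw: float) -> float:
        return (raw - self.means[subtest]) / self.sds[subtest]


def fit_reference(raw_triplets: Iterable[tuple[float, float, float]]) -> ZReference:
    """Fit per-subtest mean and sample (n-1) sd over complete participants.

    ``raw_triplets`` holds (stroop, symbols, memory) raw scores, one per
    participant with a complete triplet. Needs n >= 2 and nonzero variance
    in every subtest.
    """
    arr = np.asarray(list(raw_triplets), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise DegenerateReferenceError("reference needs >= 2 complete participants with 3 raw scores each")
    if np.isnan(arr).any():
        raise DegenerateReferenceError("reference sample must be complete (no missing raw scores)")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [s for s, sd in zip(SUBTESTS, sds) if sd <= 0]
        raise DegenerateReferenceError(f"zero variance in subtest(s) {bad}: cannot standardise")
    return ZReference(
        means=dict(zip(SUBTESTS, means.tolist())),
        sds=dict(zip(SUBTESTS, sds.tolist())),
        n=arr.shape[0],
    )


@dataclass(frozen=True)
class CompositeScore:
    """Raw scores, z-scores and the mean-z composite for one participant.

    ``status`` is ``"incomplete"`` (and ``m_cogscore`` is ``None``) unless
    all three subtests were completed — a partial mean is never formed.
    """

    raw_stroop: float | None
    raw_symbols: float | None
    raw_memory: float | None
    z_stroop: float | None
    z_symbols: float | None
    z_memory: float | None
    m_cogscore: float | None
    status: Literal["complete", "incomplete"]


def composite_mcog(
    stroop: SubtestResult,
    symbols: SubtestResult,
    memory: SubtestResult,
    reference: ZReference,
) -> CompositeScore:
    """Combine a subtest triplet into the mean-of-z composite.

    Any incomplete subtest makes the whole composite incomplete; raw scores
    of the completed subtests are still reported for missing-data audits.
    """
    results = {"stroop": stroop, "symbols": symbols, "memory": memory}
    for name, res in results.items():
        if res.subtest != name:
            raise InvalidDesignError(f"expected {name} result, got {res.subtest}")
    raws = {name: res.raw_score for name, res in results.items()}
    if all(res.completed for res in results.values()):
        zs = {name: reference.zscore(name, raws[name]) for name in SUBTESTS}
        composite = math.fsum(zs.values()) / 3.0
        return CompositeScore(
            raw_stroop=raws["stroop"], raw_symbols=raws["symbols"], raw_memory=raws["memory"],
            z_stroop=zs["stroop"], z_symbols=zs["symbols"], z_memory=zs["memory"],
            m_cogscore=composite, status="complete",
        )
    return CompositeScore(
        raw_stroop=raws["stroop"], raw_symbols=raws["symbols"], raw_memory=raws["memory"],
        z_stroop=None, z_symbols=None, z_memory=None,
        m_cogscore=None, status="incomplete",
    )
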