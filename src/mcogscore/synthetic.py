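"""Synthetic case-control cohorts for the screening validation pipeline.

A single latent severity factor L ~ Normal(group shift, 1) drives everything
that distinguishes impaired from healthy participants: item accuracy falls
and response times grow with L, the MMSE-2 total falls with L (and is
rounded then clamped to [0, 30], which produces the healthy-group ceiling
effect), and the probability of skipping a test section rises with L, so
missing data is coupled to impairment as observed in the study population.

Subtest-specific ability is S_k = loading * L + noise * eps_k, so the
shared-factor loading controls cross-subtest correlation (loading 0 makes
the subtests mutually independent and removes all group separation).

Two missingness regimes are supported: a stochastic regime (per-subtest
Bernoulli skips, Bernoulli upload failures) and an exact participant-flow
regime mirroring the study's flow diagram — 108 consented, 1 revoked
consent, 2 screening failures with CDR > 1, 7 upload failures and 26
single-section skippers, leaving exactly 72 complete participants (38
healthy, 34 impaired). In the exact regime only WHO is excluded is random
(severity-weighted within group); the counts are fixed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import InvalidDesignError
from .scoring import (
    COLOURS,
    MEMORY_N_ITEMS,
    MEMORY_N_OPTIONS_DELAYED,
    MEMORY_N_OPTIONS_IMMEDIATE,
    STROOP_N_CONGRUENT,
    STROOP_N_TRIALS,
    SYMBOLS_N_TRIALS,
    MemoryItem,
    StroopTrial,
    SubtestResult,
    SymbolTrial,
    score_memory,
    score_stroop,
    score_symbols,
)

EDUCATION_LEVELS = ("none", "GCSE", "A-levels", "University")

# Fixed pool the 8-word recall lists and their distractors are drawn from.
WORD_POOL = (
    "apple", "river", "candle", "garden", "mirror", "pencil", "window", "basket",
    "engine", "forest", "hammer", "island", "jacket", "kettle", "ladder", "magnet",
    "needle", "orange", "pillow", "quarry", "rocket", "saddle", "tunnel", "valley",
    "wallet", "anchor", "bridge", "carpet", "donkey", "eagle", "feather", "guitar",
    "helmet", "iron", "jungle", "kitten", "lantern", "meadow", "nickel", "ocean",
)


@dataclass(frozen=True)
class GroupConfig:
    """Demographics and latent-severity location for one CDR-labelled group."""

    n: int
    severity_shift: float
    age_mean: float
    age_sd: float
    p_female: float
    edu_probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidDesignError("group size must be non-negative")
        if self.age_sd <= 0:
            raise InvalidDesignError("age sd must be positive")
        if not 0 <= self.p_female <= 1:
            raise InvalidDesignError("p_female must be a probability")
        if len(self.edu_probs) != 4 or abs(sum(self.edu_probs) - 1) > 1e-9 or min(self.edu_probs) < 0:
            raise InvalidDesignError("edu_probs must be 4 non-negative values summing to 1")


@dataclass(frozen=True)
class SpeededModel:
    """Accuracy and response-time model for a timed subtest.

    Accuracy per item is Bernoulli(expit(acc_base - acc_slope * S)); log
    response time per item is Normal(rt_log_mean + rt_slope * S, rt_log_sd),
    S being the participant's subtest-specific severity.
    """

    acc_base: float
    acc_slope: float
    rt_log_mean: float
    rt_log_sd: float
    rt_slope: float

    def __post_init__(self) -> None:
        if self.rt_log_sd <= 0:
            raise InvalidDesignError("response-time log-sd must be positive")


@dataclass(frozen=True)
class MemoryModel:
    """Cued-recall accuracy model with guessing floors.

    An unknowing participant guesses uniformly among the displayed options,
    so correctness probability is floor + (1 - floor) * expit(base - slope*S)
    with floor 1/4 on the immediate trial and 1/8 on the delayed trial.
    Response times are recorded but never scored.
    """

    acc_base: float
    acc_slope: float
    rt_log_mean: float = math.log(2.5)
    rt_log_sd: float = 0.4


@dataclass(frozen=True)
class MmseModel:
    """MMSE-2 total: clamp(round(intercept - slope * L + noise), 0, 30)."""

    intercept: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise InvalidDesignError("MMSE noise sd must be positive")


@dataclass(frozen=True)
class SkipModel:
    """Section-skip propensity: logit P(skip) = base + slope * L."""

    base: float
    slope: float


@dataclass(frozen=True)
class FlowCounts:
    """Exact participant-flow counts (who is excluded stays random)."""

    n_revoked: int = 1
    n_cdr_gt1: int = 2
    n_upload_failed: tuple[int, int] = (5, 2)   # (healthy, impaired)
    n_skippers: tuple[int, int] = (7, 19)       # (healthy, impaired)
    n_cdr1: tuple[int, int] = (1, 6)            # CDR=1 among (included, missing) impaired


@dataclass(frozen=True)
class SimConfig:
    """Full generative configuration for one synthetic cohort.

    ``healthy.n`` / ``impaired.n`` are the sizes of the complete analysis
    groups; with ``emulate_flow`` the generator adds the excluded
    participants on top so the consented roster reproduces the flow
    diagram's counts exactly.
    """

    healthy: GroupConfig
    impaired: GroupConfig
    loading: float
    subtest_noise_sd: float
    stroop: SpeededModel
    symbols: SpeededModel
    memory: MemoryModel
    mmse: MmseModel
    skip: dict[str, SkipModel]
    p_upload_failure: float
    p_cdr1_impaired: float
    emulate_flow: bool = False
    flow: FlowCounts = field(default_factory=FlowCounts)

    def __post_init__(self) -> None:
        if not 0 <= self.p_upload_failure <= 1:
            raise InvalidDesignError("p_upload_failure must be a probability")
        if not 0 <= self.p_cdr1_impaired <= 1:
            raise InvalidDesignError("p_cdr1_impaired must be a probability")
        if self.subtest_noise_sd < 0:
            raise InvalidDesignError("subtest noise sd must be non-negative")
        if set(self.skip) != {"stroop", "symbols", "memory"}:
            raise InvalidDesignError("skip models required for stroop, symbols, memory")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        return cls(
            healthy=GroupConfig(**{**d["healthy"], "edu_probs": tuple(d["healthy"]["edu_probs"])}),
            impaired=GroupConfig(**{**d["impaired"], "edu_probs": tuple(d["impaired"]["edu_probs"])}),
            loading=d["loading"],
            subtest_noise_sd=d["subtest_noise_sd"],
            stroop=SpeededModel(**d["stroop"]),
            symbols=SpeededModel(**d["symbols"]),
            memory=MemoryModel(**d["memory"]),
            mmse=MmseModel(**d["mmse"]),
            skip={k: SkipModel(**v) for k, v in d["skip"].items()},
            p_upload_failure=d["p_upload_failure"],
            p_cdr1_impaired=d["p_cdr1_impaired"],
            emulate_flow=d["emulate_flow"],
            flow=FlowCounts(
                n_revoked=d["flow"]["n_revoked"],
                n_cdr_gt1=d["flow"]["n_cdr_gt1"],
                n_upload_failed=tuple(d["flow"]["n_upload_failed"]),
                n_skippers=tuple(d["flow"]["n_skippers"]),
                n_cdr1=tuple(d["flow"]["n_cdr1"]),
            ),
        )


@dataclass
class ParticipantRecord:
    """One synthetic participant: demographics, labels, item responses."""

    participant_id: str
    cdr_global: float | None
    age: float | None
    sex: str | None
    education: str | None
    mmse2_total: int | None
    stroop_trials: list[StroopTrial] | None
    symbol_trials: list[SymbolTrial] | None
    memory_items: list[MemoryItem] | None
    uploaded: bool
    revoked_consent: bool
    latent_severity: float | None = None
    group: str | None = None

    @property
    def impaired(self) -> bool | None:
        if self.cdr_global is None:
            return None
        return self.cdr_global > 0

    def subtest_results(self) -> dict[str, SubtestResult] | None:
        """Score the three sections; None when no data was uploaded."""
        if self.revoked_consent or not self.uploaded or self.stroop_trials is None:
            return None
        return {
            "stroop": score_stroop(self.stroop_trials),
            "symbols": score_symbols(self.symbol_trials),
            "memory": score_memory(self.memory_items),
        }


# --------------------------------------------------------------------------
# calibrated defaults
#
# The generative parameters below were calibrated once (Monte-Carlo at
# n = 200,000 per group plus the exact discretised-normal MMSE moments) so
# the complete-cohort moments match the study population: MMSE-2 totals
# 28.6 +/- 1.2 (healthy) vs 26.1 +/- 2.8 (impaired) with the ceiling at 30,
# and self-referenced composite group means +0.47 / -0.52 at the 38:34 mix.

_DELTA = 2.0  # latent severity shift of the impaired group

_DEFAULTS = dict(
    loading=1.0,
    subtest_noise_sd=1.0,
    stroop=SpeededModel(acc_base=3.2, acc_slope=0.5198, rt_log_mean=0.30, rt_log_sd=0.30, rt_slope=0.1512),
    symbols=SpeededModel(acc_base=3.0, acc_slope=0.5198, rt_log_mean=1.30, rt_log_sd=0.30, rt_slope=0.1512),
    memory=MemoryModel(acc_base=2.4, acc_slope=0.7088),
    mmse=MmseModel(intercept=29.3761, slope=1.5930, noise_sd=2.1427),
    skip={
        # bases solved so the mixture-marginal skip rates are 9/98, 5/98 and
        # 12/98 (the observed 9:5:12 section split); the shared slope couples
        # skipping to impairment
        "stroop": SkipModel(base=-3.6004, slope=0.8),
        "symbols": SkipModel(base=-4.2875, slope=0.8),
        "memory": SkipModel(base=-3.2393, slope=0.8),
    },
    p_upload_failure=7.0 / 105.0,
    p_cdr1_impaired=7.0 / 55.0,
)


def default_config(emulate_flow: bool = True) -> SimConfig:
    """The study-condition configuration.

    Group sizes, demographics, sex and education marginals follow the
    study's demographic table (38 healthy / 34 impaired complete); with
    ``emulate_flow`` the excluded participants (12 healthy, 21 impaired,
    1 revoked consent, 2 CDR > 1) are generated too, for a consented
    roster of 108.
    """
    return SimConfig(
        healthy=GroupConfig(
            n=38, severity_shift=0.0, age_mean=69.1, age_sd=5.5,
            p_female=21 / 38, edu_probs=(2 / 38, 9 / 38, 6 / 38, 21 / 38),
        ),
        impaired=GroupConfig(
            n=34, severity_shift=_DELTA, age_mean=69.5, age_sd=6.6,
            p_female=19 / 34, edu_probs=(4 / 34, 4 / 34, 12 / 34, 14 / 34),
        ),
        emulate_flow=emulate_flow,
        **_DEFAULTS,
    )


# --------------------------------------------------------------------------
# item-level generation


def _gen_stroop(rng: np.random.Generator, model: SpeededModel, s: float, skip: bool) -> list[StroopTrial]:
    congruent = np.zeros(STROOP_N_TRIALS, dtype=bool)
    congruent[:STROOP_N_CONGRUENT] = True
    rng.shuffle(congruent)
    p_correct = expit(model.acc_base - model.acc_slope * s)
    trials = []
    for cong in congruent:
        ink = COLOURS[rng.integers(3)]
        if cong:
            word = ink
        else:
            word = COLOURS[(COLOURS.index(ink) + 1 + rng.integers(2)) % 3]
        if skip:
            trials.append(StroopTrial(word, ink))
            continue
        if rng.random() < p_correct:
            chosen = ink
        else:
            chosen = COLOURS[(COLOURS.index(ink) + 1 + rng.integers(2)) % 3]
        rt = float(np.exp(rng.normal(model.rt_log_mean + model.rt_slope * s, model.rt_log_sd)))
        trials.append(StroopTrial(word, ink, chosen, rt))
    return trials


def _gen_symbols(rng: np.random.Generator, model: SpeededModel, s: float, skip: bool) -> list[SymbolTrial]:
    key = rng.permutation(9) + 1  # symbol i -> digit key[i-1], a bijection
    order = rng.permutation(9) + 1
    p_correct = expit(model.acc_base - model.acc_slope * s)
    trials = []
    for sym in order:
        correct = int(key[sym - 1])
        if skip:
            trials.append(SymbolTrial(int(sym), correct))
            continue
        if rng.random() < p_correct:
            entered = correct
        else:
            entered = int(1 + (correct - 1 + 1 + rng.integers(8)) % 9)
        rt = float(np.exp(rng.normal(model.rt_log_mean + model.rt_slope * s, model.rt_log_sd)))
        trials.append(SymbolTrial(int(sym), correct, entered, rt))
    return trials


def _gen_memory(rng: np.random.Generator, model: MemoryModel, s: float, skip: bool) -> list[MemoryItem]:
    pool = np.array(WORD_POOL)
    targets = rng.choice(pool, size=MEMORY_N_ITEMS, replace=False)
    p_lin = expit(model.acc_base - model.acc_slope * s)
    items = []
    for target in targets:
        others = pool[pool != target]
        first_opts = np.concatenate([[target], rng.choice(others, MEMORY_N_OPTIONS_IMMEDIATE - 1, replace=False)])
        second_opts = np.concatenate([[target], rng.choice(others, MEMORY_N_OPTIONS_DELAYED - 1, replace=False)])
        rng.shuffle(first_opts)
        rng.shuffle(second_opts)
        first_opts = tuple(str(w) for w in first_opts)
        second_opts = tuple(str(w) for w in second_opts)
        if skip:
            items.append(MemoryItem(str(target), first_opts, second_opts))
            continue
        choices: list[int] = []
        for opts, floor in ((first_opts, 1 / MEMORY_N_OPTIONS_IMMEDIATE),
                            (second_opts, 1 / MEMORY_N_OPTIONS_DELAYED)):
            p = floor + (1 - floor) * p_lin
            if rng.random() < p:
                choices.append(opts.index(str(target)))
            else:
                distractors = [i for i, w in enumerate(opts) if w != target]
                choices.append(int(rng.choice(distractors)))
        items.append(MemoryItem(str(target), first_opts, second_opts,
                                first_choice=choices[0], second_choice=choices[1]))
    return items


def _gen_mmse(rng: np.random.Generator, model: MmseModel, latent: float) -> int:
    raw = model.intercept - model.slope * latent + rng.normal(0.0, model.noise_sd)
    return int(np.clip(np.round(raw), 0, 30))


def expected_mmse_moments(config: SimConfig, group: Literal["healthy", "impaired"]) -> tuple[float, float]:
    """Exact mean and sd of the discretised, clamped MMSE-2 total.

    The pre-clamp score is Normal(intercept - slope * shift,
    slope^2 + noise^2); rounding and clamping to [0, 30] makes the total a
    lattice variable whose pmf follows from the normal CDF.
    """
    g = config.healthy if group == "healthy" else config.impaired
    mu = config.mmse.intercept - config.mmse.slope * g.severity_shift
    sigma = math.hypot(config.mmse.slope, config.mmse.noise_sd)
    ks = np.arange(0, 31)
    upper = np.where(ks == 30, np.inf, ks + 0.5)
    lower = np.where(ks == 0, -np.inf, ks - 0.5)
    pmf = norm.cdf(upper, mu, sigma) - norm.cdf(lower, mu, sigma)
    mean = float((ks * pmf).sum())
    var = float(((ks - mean) ** 2 * pmf).sum())
    return mean, math.sqrt(var)


# --------------------------------------------------------------------------
# cohort assembly


def _draw_demographics(rng: np.random.Generator, g: GroupConfig) -> tuple[float, str, str]:
    age = float(np.round(max(45.0, rng.normal(g.age_mean, g.age_sd)), 1))
    sex = "F" if rng.random() < g.p_female else "M"
    education = EDUCATION_LEVELS[rng.choice(4, p=np.asarray(g.edu_probs))]
    return age, sex, education


def _severity_weighted_pick(rng: np.random.Generator, latents: np.ndarray,
                            candidates: np.ndarray, k: int, slope: float) -> np.ndarray:
    """Pick k of the candidate indices with probability tilted by severity."""
    if k == 0:
        return np.array([], dtype=int)
    w = expit(slope * latents[candidates])
    return rng.choice(candidates, size=k, replace=False, p=w / w.sum())


def simulate_cohort(config: SimConfig, seed: int | np.random.Generator) -> list[ParticipantRecord]:
    """Generate a full roster of participant records, reproducibly.

    With ``config.emulate_flow`` the roster contains the consented total
    (analysis groups plus the fixed numbers of revoked, CDR > 1, upload-
    failed and single-section-skipping participants); otherwise exactly
    ``healthy.n + impaired.n`` participants with stochastic missingness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flow = config.flow
    records: list[ParticipantRecord] = []

    groups = []
    for name, g in (("healthy", config.healthy), ("impaired", config.impaired)):
        extra = 0
        if config.emulate_flow:
            gi = 0 if name == "healthy" else 1
            extra = flow.n_upload_failed[gi] + flow.n_skippers[gi]
        groups.append((name, g, g.n + extra))

    lam, tau = config.loading, config.subtest_noise_sd
    for name, g, n_total in groups:
        latents = rng.normal(g.severity_shift, 1.0, size=n_total)
        gi = 0 if name == "healthy" else 1

        if config.emulate_flow:
            idx = np.arange(n_total)
            slope = config.skip["stroop"].slope
            missing = _severity_weighted_pick(
                rng, latents, idx, flow.n_upload_failed[gi] + flow.n_skippers[gi], slope)
            upload_failed_set = set(rng.choice(missing, size=flow.n_upload_failed[gi], replace=False).tolist())
            skipper_set = set(missing.tolist()) - upload_failed_set
        else:
            upload_failed_set, skipper_set = set(), set()

        for i in range(n_total):
            L = float(latents[i])
            age, sex, education = _draw_demographics(rng, g)
            s_sub = {k: lam * L + tau * rng.normal() for k in ("stroop", "symbols", "memory")}

            if config.emulate_flow:
                uploaded = i not in upload_failed_set
                if i in skipper_set:
                    # one section per skipper, chosen with the same relative
                    # propensities as the stochastic skip model
                    w = np.array([expit(config.skip[k].base + config.skip[k].slope * L)
                                  for k in ("stroop", "symbols", "memory")])
                    section = ("stroop", "symbols", "memory")[rng.choice(3, p=w / w.sum())]
                    skips = {k: k == section for k in ("stroop", "symbols", "memory")}
                else:
                    skips = {k: False for k in ("stroop", "symbols", "memory")}
            else:
                uploaded = rng.random() >= config.p_upload_failure
                skips = {
                    k: rng.random() < expit(config.skip[k].base + config.skip[k].slope * L)
                    for k in ("stroop", "symbols", "memory")
                }

            mmse = _gen_mmse(rng, config.mmse, L)
            stroop = _gen_stroop(rng, config.stroop, s_sub["stroop"], skips["stroop"])
            symbols = _gen_symbols(rng, config.symbols, s_sub["symbols"], skips["symbols"])
            memory = _gen_memory(rng, config.memory, s_sub["memory"], skips["memory"])

            if name == "healthy":
                cdr = 0.0
            else:
                cdr = 1.0 if rng.random() < config.p_cdr1_impaired else 0.5

            records.append(ParticipantRecord(
                participant_id="",  # assigned after shuffling
                cdr_global=cdr, age=age, sex=sex, education=education,
                mmse2_total=mmse, stroop_trials=stroop, symbol_trials=symbols,
                memory_items=memory, uploaded=uploaded, revoked_consent=False,
                latent_severity=L, group=name,
            ))

    if config.emulate_flow:
        for _ in range(flow.n_cdr_gt1):
            g = config.impaired
            age, sex, education = _draw_demographics(rng, g)
            records.append(ParticipantRecord(
                participant_id="", cdr_global=2.0, age=age, sex=sex, education=education,
                mmse2_total=None, stroop_trials=None, symbol_trials=None, memory_items=None,
                uploaded=True, revoked_consent=False, latent_severity=None, group="cdr_gt_1",
            ))
        for _ in range(flow.n_revoked):
            records.append(ParticipantRecord(
                participant_id="", cdr_global=None, age=None, sex=None, education=None,
                mmse2_total=None, stroop_trials=None, symbol_trials=None, memory_items=None,
                uploaded=False, revoked_consent=True, latent_severity=None, group="revoked",
            ))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    width = max(3, len(str(len(records))))
    for k, rec in enumerate(records, start=1):
        rec.participant_id = f"P{k:0{width}d}"
    return records


def missingness_report(roster: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Per-subtest counts of incomplete sections, split by group.

    Only uploaded, consenting participants with CDR <= 1 are audited
    (others have no item data at all).
    """
    rows = []
    for rec in roster:
        if rec.revoked_consent or not rec.uploaded or rec.cdr_global is None or rec.cdr_global > 1:
            continue
        results = rec.subtest_results()
        rows.append({
            "group": "impaired" if rec.impaired else "healthy",
            **{k: (not results[k].completed) for k in ("stroop", "symbols", "memory")},
        })
    frame = pd.DataFrame(rows, columns=["group", "stroop", "symbols", "memory"])
    if frame.empty:
        return pd.DataFrame(0, index=["healthy", "impaired"], columns=["stroop", "symbols", "memory"])
    out = frame.groupby("group").sum().reindex(["healthy", "impaired"]).fillna(0).astype(int)
    out.columns.name = "subtest"
    return out


# --------------------------------------------------------------------------
# tabular output (the pipeline's on-disk interface)

ROSTER_COLUMNS = ["participant_id", "cdr_global", "age", "sex", "education",
                  "mmse2_total", "uploaded", "revoked_consent"]
ITEM_COLUMNS = ["participant_id", "subtest", "item_index", "phase", "stimulus",
                "options", "correct_response", "response", "response_time_s"]


def roster_frame(roster: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in roster:
        rows.append({
            "participant_id": rec.participant_id,
            "cdr_global": rec.cdr_global,
            "age": rec.age,
            "sex": rec.sex,
            "education": rec.education,
            "mmse2_total": rec.mmse2_total,
            "uploaded": rec.uploaded,
            "revoked_consent": rec.revoked_consent,
        })
    return pd.DataFrame(rows, columns=ROSTER_COLUMNS)


def items_frame(roster: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """One row per item response (two per memory word: immediate, delayed)."""
    rows = []
    for rec in roster:
        if rec.stroop_trials is None:
            continue
        pid = rec.participant_id
        for i, t in enumerate(rec.stroop_trials, start=1):
            rows.append((pid, "stroop", i, "", t.word_text, "|".join(COLOURS),
                         t.ink_colour, t.chosen_option or "", t.response_time or ""))
        for i, t in enumerate(rec.symbol_trials, start=1):
            rows.append((pid, "symbols", i, "", t.target_symbol_id, "",
                         t.correct_digit, t.entered_digit if t.entered_digit is not None else "",
                         t.response_time or ""))
        for i, it in enumerate(rec.memory_items, start=1):
            rows.append((pid, "memory", i, "immediate", it.target_word, "|".join(it.first_options),
                         it.target_word,
                         it.first_options[it.first_choice] if it.first_choice is not None else "", ""))
            rows.append((pid, "memory", i, "delayed", it.target_word, "|".join(it.second_options),
                         it.target_word,
                         it.second_options[it.second_choice] if it.second_choice is not None else "", ""))
    return pd.DataFrame(rows, columns=ITEM_COLUMNS)


def write_cohort(roster: Sequence[ParticipantRecord], out_dir: str | Path,
                 config: SimConfig | None = None, seed: int | None = None) -> dict[str, Path]:
    """Write roster and item CSVs (plus config/seed metadata) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"roster": out / "roster.csv", "items": out / "items.csv"}
    roster_frame(roster).to_csv(paths["roster"], index=False)
    items_frame(roster).to_csv(paths["items"], index=False)
    if config is not None:
        meta = {"seed": seed, "config": json.loads(config.to_json())}
        paths["meta"] = out / "simulation_meta.json"
        paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths


# --------------------------------------------------------------------------
# binormal helpers (used for closed-form AUC checks and desk-scale reruns)


def binormal_auc(mean_healthy: float, sd_healthy: float,
                 mean_impaired: float, sd_impaired: float) -> float:
    """Closed-form AUC for normal scores where lower predicts impairment:
    Phi((mu_h - mu_i) / sqrt(sd_h^2 + sd_i^2))."""
    return float(norm.cdf((mean_healthy - mean_impaired) / math.hypot(sd_healthy, sd_impaired)))


def binormal_scores(n_healthy: int, n_impaired: int,
                    mean_healthy: float, sd_healthy: float,
                    mean_impaired: float, sd_impaired: float,
                    seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (scores, labels) from two normal score distributions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.concatenate([
        rng.normal(mean_healthy, sd_healthy, n_healthy),
        rng.normal(mean_impaired, sd_impaired, n_impaired),
    ])
    labels = np.concatenate([np.zeros(n_healthy, dtype=int), np.ones(n_impaired, dtype=int)])
    return scores, labels
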