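"""Empirical ROC analysis for screening scores where a LOW score flags
impairment: AUC by the rank (Mann-Whitney) formulation with half-weighted
ties, Youden-optimal cut-offs under the strict "score < c => impaired"
decision rule, stratified proportion-bootstrap percentile confidence
intervals, and the DeLong placement-value test for two paired AUCs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm, rankdata

from .errors import UndefinedStatisticError

Direction = Literal["lower", "higher"]


@dataclass(frozen=True)
class LabelledScores:
    """Scores with binary labels (1 = impaired, 0 = healthy).

    ``direction="lower"`` (the default, matching cognitive scores) means a
    lower score predicts impairment; ``"higher"`` flips the orientation.
    """

    scores: np.ndarray
    labels: np.ndarray
    direction: Direction = "lower"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float).ravel()
        labels = np.asarray(self.labels).ravel().astype(np.int8)
        if scores.size != labels.size:
            raise UndefinedStatisticError("scores and labels must have equal length")
        if np.isnan(scores).any():
            raise UndefinedStatisticError("scores contain NaN")
        if not set(np.unique(labels)) <= {0, 1}:
            raise UndefinedStatisticError("labels must be binary 0/1")
        if labels.min() == labels.max():
            raise UndefinedStatisticError("both classes must be present")
        if self.direction not in ("lower", "higher"):
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def risk(self) -> np.ndarray:
        """Scores re-oriented so that HIGHER values predict impairment."""
        return -self.scores if self.direction == "lower" else self.scores


def _rank_auc(risk: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(risk_impaired > risk_healthy) + 0.5 P(tie), via mid-ranks."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(risk, method="average")
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: one operating point per candidate threshold.

    Thresholds are on the original score scale, ascending, with a +inf
    sentinel (classify everyone impaired) under ``direction="lower"``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: Direction


def empirical_roc(data: LabelledScores) -> RocCurve:
    """Build the empirical ROC over all distinct score thresholds.

    Under ``direction="lower"`` a participant is called impaired when
    score < c (strict); sensitivity is the impaired fraction below c and
    specificity the healthy fraction at or above c. The AUC comes from the
    rank formulation, so between-class ties contribute 1/2.
    """
    scores, labels = data.scores, data.labels
    imp = scores[labels == 1]
    hea = scores[labels == 0]
    uniq = np.unique(scores)
    if data.direction == "lower":
        thresholds = np.concatenate([uniq, [np.inf]])
        # score < c  =>  impaired
        sens = np.searchsorted(np.sort(imp), thresholds, side="left") / imp.size
        spec = 1.0 - np.searchsorted(np.sort(hea), thresholds, side="left") / hea.size
    else:
        thresholds = np.concatenate([[-np.inf], uniq])
        # score > c  =>  impaired
        sens = 1.0 - np.searchsorted(np.sort(imp), thresholds, side="right") / imp.size
        spec = np.searchsorted(np.sort(hea), thresholds, side="right") / hea.size
    auc = _rank_auc(data.risk, labels)
    return RocCurve(thresholds, sens, spec, auc, data.direction)


@dataclass(frozen=True)
class CutoffResult:
    """A decision threshold with its operating characteristics."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_cutoff(roc: RocCurve) -> CutoffResult:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward higher sensitivity (screening favours
    detection), then toward the smaller threshold; fully deterministic.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[roc.sensitivity[best] >= roc.sensitivity[best].max() - 1e-12]
    idx = int(best[np.argmin(roc.thresholds[best])])
    return CutoffResult(
        threshold=float(roc.thresholds[idx]),
        sensitivity=float(roc.sensitivity[idx]),
        specificity=float(roc.specificity[idx]),
        youden_j=float(j[idx]),
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for an AUC."""

    lower: float
    upper: float
    point: float
    n_boot: int
    proportion: float
    alpha: float
    seed: int | None
    n_redrawn: int = 0


def _batch_auc(h: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Row-wise AUC for batched healthy/impaired risk samples.

    ``h`` is (B, n0) and ``m`` is (B, n1); returns B AUCs with mid-rank
    tie handling.
    """
    n1 = m.shape[1]
    combined = np.concatenate([h, m], axis=1)
    ranks = rankdata(combined, method="average", axis=1)
    u1 = ranks[:, h.shape[1]:].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u1 / (h.shape[1] * n1)


def bootstrap_auc_ci(
    data: LabelledScores,
    n_boot: int = 10_000,
    proportion: float = 0.75,
    alpha: float = 0.05,
    seed: int | None = None,
    replace: bool = True,
) -> BootstrapCI:
    """Stratified proportion-bootstrap percentile CI for the AUC.

    Each replicate draws ``ceil(proportion * n_g)`` participants per class,
    with replacement by default (``replace=False`` switches to subsampling
    without replacement). The interval is the (alpha/2, 1 - alpha/2)
    percentile range of the replicate AUCs. Stratification guarantees both
    classes in every replicate, so redraws only ever log as zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    risk, labels = data.risk, data.labels
    h = risk[labels == 0]
    m = risk[labels == 1]
    n0 = math.ceil(proportion * h.size)
    n1 = math.ceil(proportion * m.size)
    if n0 == 0 or n1 == 0:
        raise UndefinedStatisticError("a bootstrap replicate would lose a class entirely")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    # chunked so the (B, n0 + n1) rank matrix stays small
    chunk = max(1, min(n_boot, 2_000_000 // (n0 + n1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        if replace:
            hb = rng.choice(h, size=(b, n0), replace=True)
            mb = rng.choice(m, size=(b, n1), replace=True)
        else:
            hb = np.stack([rng.choice(h, size=n0, replace=False) for _ in range(b)])
            mb = np.stack([rng.choice(m, size=n1, replace=False) for _ in range(b)])
        aucs[done:done + b] = _batch_auc(hb, mb)
        done += b
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(
        lower=float(lo), upper=float(hi), point=_rank_auc(risk, labels),
        n_boot=n_boot, proportion=proportion, alpha=alpha, seed=seed,
    )


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two AUCs on the same participants."""

    auc_a: float
    auc_b: float
    var_delta: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_two_sided: float


def _placements(risk: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-participant placement values (structural components).

    For impaired i: fraction of healthy scored below (ties half). For
    healthy j: fraction of impaired scored above (ties half).
    """
    pos = risk[labels == 1]
    neg = risk[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]), method="average")
    pos_ranks = rankdata(pos, method="average")
    neg_ranks = rankdata(neg, method="average")
    v10 = (all_ranks[:m] - pos_ranks) / n          # impaired placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # healthy placements
    auc = float(v10.mean())
    return auc, v10, v01


def delong_paired(scores_a, scores_b, labels, direction: Direction = "lower") -> DeLongResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must cover the same participants in the same order.
    The variance of AUC_a - AUC_b is estimated from the empirical
    covariance of the placement values, respecting the pairing; z is
    referred to the standard normal, two-sided.
    """
    a = LabelledScores(np.asarray(scores_a, dtype=float), labels, direction)
    b = LabelledScores(np.asarray(scores_b, dtype=float), labels, direction)
    auc_a, v10_a, v01_a = _placements(a.risk, a.labels)
    auc_b, v10_b, v01_b = _placements(b.risk, b.labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    cov_ab = s10[0, 1] / m + s01[0, 1] / n
    var_delta = var_a + var_b - 2 * cov_ab
    delta = auc_a - auc_b
    if var_delta <= 0:
        if math.isclose(delta, 0.0, abs_tol=1e-15):
            z, p = 0.0, 1.0
        else:
            warnings.warn("degenerate DeLong variance with nonzero AUC difference", RuntimeWarning)
            z, p = math.copysign(math.inf, delta), 0.0
    else:
        z = delta / math.sqrt(var_delta)
        p = float(2 * norm.sf(abs(z)))
    return DeLongResult(
        auc_a=auc_a, auc_b=auc_b, var_delta=float(max(var_delta, 0.0)),
        var_a=float(var_a), var_b=float(var_b), cov_ab=float(cov_ab),
        z=float(z), p_two_sided=p,
    )
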