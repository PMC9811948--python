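"""Empirical ROC, Youden cut-offs, bootstrap CIs and the DeLong test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mcogscore.errors import UndefinedStatisticError
from mcogscore.roc import (
    LabelledScores,
    bootstrap_auc_ci,
    delong_paired,
    empirical_roc,
    youden_cutoff,
)


def pair_counting_auc(scores, labels):
    """Brute-force oracle: (#concordant + 0.5 #tied) / (n0 * n1), where a
    concordant pair has the impaired participant scoring lower."""
    imp = scores[labels == 1]
    hea = scores[labels == 0]
    total = 0.0
    for i in imp:
        for h in hea:
            total += (i < h) + 0.5 * (i == h)
    return total / (imp.size * hea.size)


def trapezoid_auc(roc):
    fpr = 1.0 - roc.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(roc.sensitivity[order], fpr[order]))


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        data = LabelledScores(np.r_[[5, 6, 7.0], [1, 2, 3.0]], np.r_[0, 0, 0, 1, 1, 1])
        assert empirical_roc(data).auc == 1.0

    def test_pure_ties(self):
        data = LabelledScores(np.ones(8), np.r_[0, 0, 0, 0, 1, 1, 1, 1])
        assert empirical_roc(data).auc == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_three_way_auc_agreement(self, seed):
        """Rank formulation, trapezoid over the curve, exhaustive pair
        counting and the external oracle all coincide to 1e-12."""
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 50))
        scores = np.round(r.normal(size=n), 1)  # rounding forces ties
        labels = r.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        data = LabelledScores(scores, labels)
        roc = empirical_roc(data)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        assert roc.auc == pytest.approx(trapezoid_auc(roc), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, -scores), abs=1e-12)

    def test_sensitivity_monotone_and_orientation_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        roc = empirical_roc(LabelledScores(scores, labels, direction="lower"))
        assert np.all(np.diff(roc.sensitivity) >= 0)  # thresholds ascend
        flipped = empirical_roc(LabelledScores(-scores, labels, direction="higher"))
        assert flipped.auc == pytest.approx(roc.auc, abs=1e-15)
        # strictly monotone transform leaves the AUC unchanged
        transformed = empirical_roc(LabelledScores(np.exp(scores), labels, direction="lower"))
        assert transformed.auc == pytest.approx(roc.auc, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            LabelledScores(np.arange(4.0), np.zeros(4, dtype=int))


class TestYouden:
    def test_perfect_separation_j_one(self):
        data = LabelledScores(np.r_[[10, 11, 12.0], [5, 6, 7.0]], np.r_[0, 0, 0, 1, 1, 1])
        cut = youden_cutoff(empirical_roc(data))
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.threshold == 10  # impaired iff score < 10

    def test_screening_like_integer_fixture_returns_27(self):
        """An MMSE-shaped fixture with impaired mass below 27 yields the
        cut-off 27 under the strict score < c rule; J enumerated by hand."""
        healthy = np.array([27, 28, 28, 29, 29, 30, 30, 30, 26, 27])
        impaired = np.array([20, 22, 23, 24, 25, 26, 26, 27, 24, 28])
        scores = np.concatenate([healthy, impaired])
        labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
        cut = youden_cutoff(empirical_roc(LabelledScores(scores, labels)))
        assert cut.threshold == 27
        # hand enumeration of J over every cut point peaks at 0.7
        assert cut.youden_j == pytest.approx(0.7)
        assert cut.sensitivity == pytest.approx((impaired < 27).mean())
        assert cut.specificity == pytest.approx((healthy >= 27).mean())

    def test_internal_consistency_and_equivariance(self, rng):
        scores = np.round(rng.normal(size=80), 1)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        data = LabelledScores(scores, labels)
        cut = youden_cutoff(empirical_roc(data))
        sens = (scores[labels == 1] < cut.threshold).mean()
        spec = (scores[labels == 0] >= cut.threshold).mean()
        assert cut.youden_j == pytest.approx(sens + spec - 1)
        # a strictly increasing transform maps the cut-off through itself
        t_cut = youden_cutoff(empirical_roc(LabelledScores(np.exp(scores), labels)))
        assert t_cut.threshold == pytest.approx(np.exp(cut.threshold))
        assert t_cut.youden_j == pytest.approx(cut.youden_j)


class TestBootstrap:
    def _separated(self):
        return LabelledScores(np.r_[np.arange(10, 20.0), np.arange(0, 10.0)],
                              np.r_[np.zeros(10), np.ones(10)].astype(int))

    def test_full_proportion_perfect_separation(self):
        ci = bootstrap_auc_ci(self._separated(), n_boot=200, proportion=1.0, seed=0)
        assert (ci.lower, ci.upper) == (1.0, 1.0)

    def test_seed_reproducibility(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        data = LabelledScores(scores, labels)
        a = bootstrap_auc_ci(data, n_boot=500, seed=7)
        b = bootstrap_auc_ci(data, n_boot=500, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (50, 200, 1000):
            r = np.random.default_rng(5)
            scores = np.concatenate([r.normal(1, 1, n), r.normal(0, 1, n)])
            labels = np.r_[np.zeros(n), np.ones(n)].astype(int)
            ci = bootstrap_auc_ci(LabelledScores(scores, labels), n_boot=1000, seed=3)
            widths.append(ci.upper - ci.lower)
        assert widths[0] > widths[1] > widths[2]

    def test_subsampling_variant(self):
        data = self._separated()
        ci = bootstrap_auc_ci(data, n_boot=200, proportion=0.75, seed=1, replace=False)
        assert (ci.lower, ci.upper) == (1.0, 1.0)


class TestDeLong:
    def test_identical_scores(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        res = delong_paired(scores, scores, labels)
        assert res.auc_a == res.auc_b
        assert res.p_two_sided == pytest.approx(1.0)

    def test_monotone_transform_gives_null(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        res = delong_paired(scores, np.exp(scores), labels)
        assert res.auc_a - res.auc_b == pytest.approx(0.0, abs=1e-15)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=50)
        b = 0.5 * a + rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        fwd = delong_paired(a, b, labels)
        rev = delong_paired(b, a, labels)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided, abs=1e-12)

    def test_matches_published_algorithm_shape(self, rng):
        """AUC from placements equals the rank AUC; variance positive for
        non-degenerate data."""
        a = rng.normal(size=60)
        b = 0.7 * a + rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = delong_paired(a, b, labels)
        assert res.auc_a == pytest.approx(
            empirical_roc(LabelledScores(a, labels)).auc, abs=1e-12)
        assert res.var_delta > 0


@settings(max_examples=30, deadline=None)
@given(st.data())
def test_auc_bounds_property(data):
    n = data.draw(st.integers(6, 30))
    scores = np.array(data.draw(st.lists(
        st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)))
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    auc = empirical_roc(LabelledScores(scores, labels)).auc
    assert 0.0 <= auc <= 1.0
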