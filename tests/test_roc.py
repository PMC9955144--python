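"""Tests for ROC construction, AUC, LR-threshold selection and the rank-sum test.

Brute-force counting oracles recompute every quantity from first principles:
sensitivity/specificity by looping over all observations, AUC by enumerating
all positive-negative pairs, the optimal cutoff by scanning every ROC point,
and rank-sum p-values by exhaustive permutation enumeration.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from avslat import (DegenerateLabelsError, Direction, LognormalParams, NoFiniteLRError,
                    auc_rank, auc_trapezoid, best_threshold_by_lr,
                    binormal_auc_lognormal, rank_sum_test, roc_curve, sens_spec_at)

# ---------------------------------------------------------------------------
# independent oracles


def brute_sens_spec(scores, labels, threshold, direction):
    tp = fn = tn = fp = 0
    for s, y in zip(scores, labels):
        pos_call = s >= threshold if direction is Direction.HIGHER_IS_POSITIVE else s <= threshold
        if y == 1:
            tp, fn = tp + pos_call, fn + (not pos_call)
        else:
            tn, fp = tn + (not pos_call), fp + pos_call
    return tp / (tp + fn), tn / (tn + fp)


def brute_auc(scores, labels, direction):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p == n:
                total += 0.5
            elif (p > n) == (direction is Direction.HIGHER_IS_POSITIVE):
                total += 1.0
    return total / (len(pos) * len(neg))


def brute_best_lr(curve):
    best = None
    for p in curve.points:
        if p.specificity < 1 and p.sensitivity > 0 and math.isfinite(p.lr_positive):
            if best is None or p.lr_positive > best.lr_positive + 1e-12:
                best = p
    return best


def exact_rank_sum_p(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n = len(pooled)
    mu = na * (n - na) / 2
    count = total = 0
    for comb in itertools.combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def random_instance(rng, n=12, ties=True):
    labels = np.zeros(n, dtype=int)
    labels[: rng.integers(1, n)] = 1
    rng.shuffle(labels)
    if ties:
        scores = rng.integers(0, 6, n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


# ---------------------------------------------------------------------------


class TestRocCurve:
    def test_perfect_separation_point_present(self):
        curve = roc_curve([1.0, 2.0, 3.0], [0, 0, 1], Direction.HIGHER_IS_POSITIVE)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in curve.points)

    def test_all_tied_scores_reduce_to_diagonal(self):
        curve = roc_curve([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert len(curve.points) == 3
        mid = curve.points[1]
        assert mid.sensitivity == 1.0 and mid.specificity == 0.0

    def test_endpoints_always_present(self, rng):
        scores, labels = random_instance(rng)
        curve = roc_curve(scores, labels)
        assert curve.points[0].sensitivity == 0.0 and curve.points[0].specificity == 1.0
        assert curve.points[-1].sensitivity == 1.0 and curve.points[-1].specificity == 0.0

    def test_sensitivity_monotone_as_threshold_loosens(self, rng):
        for direction in Direction:
            scores, labels = random_instance(rng, n=15)
            sens = [p.sensitivity for p in roc_curve(scores, labels, direction).points]
            assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_points_match_brute_force_counting(self, rng):
        for direction in Direction:
            for _ in range(25):
                scores, labels = random_instance(rng, n=14)
                curve = roc_curve(scores, labels, direction)
                for p in curve.points:
                    if math.isfinite(p.threshold):
                        sens, spec = brute_sens_spec(scores, labels, p.threshold, direction)
                        assert p.sensitivity == pytest.approx(sens)
                        assert p.specificity == pytest.approx(spec)


class TestSensSpecAt:
    def test_perfect_separation_value(self):
        curve = roc_curve([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert sens_spec_at(curve, 3.0) == (1.0, 1.0)

    def test_threshold_below_all_scores_lower_positive(self):
        curve = roc_curve([1.0, 2.0, 3.0], [1, 0, 0], Direction.LOWER_IS_POSITIVE)
        assert sens_spec_at(curve, 0.5) == (0.0, 1.0)

    def test_matches_brute_force_at_arbitrary_thresholds(self, rng):
        scores, labels = random_instance(rng, n=20)
        curve = roc_curve(scores, labels)
        for t in np.linspace(scores.min(), scores.max(), 11):
            assert sens_spec_at(curve, t) == pytest.approx(
                brute_sens_spec(scores, labels, t, curve.direction))


class TestAucRank:
    def test_perfect_separation(self):
        assert auc_rank([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_null_labels_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert auc_rank(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_enumeration_small_n(self, rng):
        for direction in Direction:
            for _ in range(40):
                scores, labels = random_instance(rng, n=8)
                assert auc_rank(scores, labels, direction) == pytest.approx(
                    brute_auc(scores, labels, direction))

    def test_equals_trapezoid_area(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng, n=rng.integers(4, 30))
            direction = Direction.LOWER_IS_POSITIVE if rng.random() < 0.5 \
                else Direction.HIGHER_IS_POSITIVE
            a1 = auc_rank(scores, labels, direction)
            a2 = auc_trapezoid(roc_curve(scores, labels, direction))
            assert a1 == pytest.approx(a2, abs=1e-12)

    def test_direction_reversal_complements(self, rng):
        scores, labels = random_instance(rng, n=25, ties=False)
        a_hi = auc_rank(scores, labels, Direction.HIGHER_IS_POSITIVE)
        a_lo = auc_rank(scores, labels, Direction.LOWER_IS_POSITIVE)
        assert a_hi + a_lo == pytest.approx(1.0)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores, labels = random_instance(rng, n=200)
        assert auc_rank(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


class TestBestThresholdByLr:
    def test_direct_formula_on_constructed_instance(self):
        # two interior operating points: (sens .95, spec .83) and (sens .5, spec .9)
        scores = np.concatenate([
            np.repeat(2.0, 50), np.repeat(1.0, 45), np.repeat(0.0, 5),       # positives
            np.repeat(2.0, 10), np.repeat(1.0, 7), np.repeat(0.0, 83)])      # negatives
        labels = np.array([1] * 100 + [0] * 100)
        curve = roc_curve(scores, labels)
        choice = best_threshold_by_lr(curve)
        assert choice.threshold == 1.0
        assert choice.sensitivity == pytest.approx(0.95)
        assert choice.specificity == pytest.approx(0.83)
        assert choice.lr_positive == pytest.approx(0.95 / 0.17)

    def test_infinite_lr_points_excluded(self):
        curve = roc_curve([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        choice = best_threshold_by_lr(curve)
        assert math.isfinite(choice.lr_positive)
        assert choice.specificity < 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(60):
            scores, labels = random_instance(rng, n=16)
            curve = roc_curve(scores, labels)
            try:
                choice = best_threshold_by_lr(curve)
            except NoFiniteLRError:
                assert brute_best_lr(curve) is None
                continue
            assert choice.lr_positive == pytest.approx(brute_best_lr(curve).lr_positive)

    def test_invariant_under_monotone_transform(self, rng):
        scores, labels = random_instance(rng, n=30, ties=False)
        c1 = best_threshold_by_lr(roc_curve(scores, labels))
        c2 = best_threshold_by_lr(roc_curve(np.exp(scores), labels))
        assert c2.threshold == pytest.approx(np.exp(c1.threshold))
        assert (c2.sensitivity, c2.specificity) == (c1.sensitivity, c1.specificity)

    def test_uninformative_tied_scores_give_diagonal_optimum(self):
        curve = roc_curve([1.0, 1.0], [0, 1])
        assert best_threshold_by_lr(curve).lr_positive == 1.0


class TestBinormalAuc:
    def test_identical_distributions_give_half(self):
        p = LognormalParams(0.3, 1.1)
        assert binormal_auc_lognormal(p, p) == pytest.approx(0.5)

    def test_large_separation_approaches_one(self):
        a = LognormalParams(20.0, 0.5)
        b = LognormalParams(0.0, 0.5)
        assert binormal_auc_lognormal(a, b) > 0.999999

    def test_direction_flips_sign(self):
        a, b = LognormalParams(1.0, 0.5), LognormalParams(0.0, 0.5)
        hi = binormal_auc_lognormal(a, b, Direction.HIGHER_IS_POSITIVE)
        lo = binormal_auc_lognormal(a, b, Direction.LOWER_IS_POSITIVE)
        assert hi + lo == pytest.approx(1.0)

    @given(mu1=st.floats(-1, 1), mu2=st.floats(-1, 1),
           s1=st.floats(0.2, 1.5), s2=st.floats(0.2, 1.5))
    def test_agrees_with_monte_carlo(self, mu1, mu2, s1, s2):
        rng = np.random.default_rng(7)
        n = 100_000
        pos = rng.lognormal(mu1, s1, n // 10)
        neg = rng.lognormal(mu2, s2, n // 10)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * len(pos) + [0] * len(neg))
        analytic = binormal_auc_lognormal(LognormalParams(mu1, s1), LognormalParams(mu2, s2))
        assert auc_rank(scores, labels) == pytest.approx(analytic, abs=0.01)

    def test_nonpositive_sigma_rejected(self):
        from types import SimpleNamespace
        with pytest.raises(ValueError):
            binormal_auc_lognormal(LognormalParams(0.0, 1.0),
                                   SimpleNamespace(mu=0.0, sigma=0.0))


class TestRankSumTest:
    def test_complete_separation_exact_p(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0])
        assert p == pytest.approx(2 / 70)

    def test_identical_groups_no_evidence(self):
        _, p = rank_sum_test([5.0, 5.1], [5.0, 5.1])
        assert p > 0.5

    def test_exact_mode_matches_enumeration(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 6)))
            b = rng.normal(size=int(rng.integers(3, 6)))
            _, p = rank_sum_test(a, b)
            assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)

    def test_normal_approximation_close_to_exact(self, rng):
        """The tie-corrected normal approximation tracks exhaustive enumeration."""
        worst = 0.0
        for _ in range(15):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            p_asym = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                              method="asymptotic").pvalue)
            worst = max(worst, abs(p_asym - exact_rank_sum_p(a, b)))
        assert worst < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
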