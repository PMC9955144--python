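"""ROC construction, rank-statistic AUC, and likelihood-ratio threshold selection.

The diagnostic-evaluation statistics used to assess a lateralization index:
empirical ROC curves with candidate thresholds at the observed score values,
AUC in both its rank-statistic (Mann–Whitney) and trapezoidal forms (they are
identical on the empirical curve), positive-likelihood-ratio-maximizing
cutoff selection (LR+ = sensitivity/(1 − specificity)), a closed-form
binormal AUC for lognormal score families (used as an analytic oracle), and
the Mann–Whitney rank-sum group comparison.

Thresholding is inclusive: a score at the threshold counts as a positive
call (score >= t for ``higher_is_positive``, score <= t for
``lower_is_positive``), matching the inclusive SI >= 5 / LI >= 4 clinical
conventions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Direction",
    "RocPoint",
    "RocCurve",
    "ThresholdChoice",
    "DegenerateLabelsError",
    "NoFiniteLRError",
    "roc_curve",
    "auc_rank",
    "auc_trapezoid",
    "best_threshold_by_lr",
    "sens_spec_at",
    "binormal_auc_lognormal",
    "rank_sum_test",
]


class Direction(str, enum.Enum):
    HIGHER_IS_POSITIVE = "higher_is_positive"
    LOWER_IS_POSITIVE = "lower_is_positive"


class DegenerateLabelsError(ValueError):
    """Scores contain only one class; ROC quantities are undefined."""


class NoFiniteLRError(ValueError):
    """No ROC point has a finite, positive likelihood ratio."""


@dataclass(frozen=True)
class RocPoint:
    threshold: float  # +/-inf at the degenerate endpoints
    sensitivity: float
    specificity: float
    lr_positive: float  # sens/(1-spec); inf when spec == 1 and sens > 0; nan at (0,1)


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    sensitivity: float
    specificity: float
    lr_positive: float


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: one point per distinct observed score plus the two
    degenerate endpoints, ordered by loosening threshold (sensitivity
    non-decreasing).  Raw scores/labels are retained so that sensitivity and
    specificity can be recounted at arbitrary thresholds."""

    direction: Direction
    points: tuple[RocPoint, ...]
    scores: tuple[float, ...]
    labels: tuple[int, ...]


def _validate(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateLabelsError("need at least one positive and one negative label")
    return s, y


def _lr(sens: float, spec: float) -> float:
    if spec < 1.0:
        return sens / (1.0 - spec)
    return math.inf if sens > 0 else math.nan


def _sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float,
               direction: Direction) -> tuple[float, float]:
    if Direction(direction) is Direction.HIGHER_IS_POSITIVE:
        call = scores >= threshold
    else:
        call = scores <= threshold
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    tp = int(np.sum(call & (labels == 1)))
    tn = int(np.sum(~call & (labels == 0)))
    return tp / n_pos, tn / n_neg


def roc_curve(scores: Sequence[float], labels: Sequence[int],
              direction: Direction = Direction.HIGHER_IS_POSITIVE) -> RocCurve:
    """Empirical ROC with candidate thresholds at the distinct observed scores.

    Tied scores are grouped at one threshold.  The two degenerate endpoints
    (sens 0 / spec 1 at an unattainable threshold, sens 1 / spec 0 at an
    all-inclusive one) are always present.
    """
    s, y = _validate(scores, labels)
    direction = Direction(direction)
    distinct = np.unique(s)
    # order thresholds from strictest (nothing positive beyond endpoint) to loosest
    if direction is Direction.HIGHER_IS_POSITIVE:
        ordered = distinct[::-1]
        strict_end, loose_end = math.inf, -math.inf
    else:
        ordered = distinct
        strict_end, loose_end = -math.inf, math.inf

    points = [RocPoint(strict_end, 0.0, 1.0, _lr(0.0, 1.0))]
    for t in ordered:
        sens, spec = _sens_spec(s, y, float(t), direction)
        points.append(RocPoint(float(t), sens, spec, _lr(sens, spec)))
    points.append(RocPoint(loose_end, 1.0, 0.0, _lr(1.0, 0.0)))
    return RocCurve(direction, tuple(points), tuple(s.tolist()), tuple(int(v) for v in y))


def auc_rank(scores: Sequence[float], labels: Sequence[int],
             direction: Direction = Direction.HIGHER_IS_POSITIVE) -> float:
    """AUC as the Mann–Whitney concordance: (concordant + ties/2)/(n_pos*n_neg).

    Identical to the trapezoidal area under the empirical ROC curve.
    """
    s, y = _validate(scores, labels)
    if Direction(direction) is Direction.LOWER_IS_POSITIVE:
        s = -s
    ranks = stats.rankdata(s)  # midranks for ties
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under an empirical ROC curve (over 1 − specificity)."""
    fpr = np.array([1.0 - p.specificity for p in curve.points])
    tpr = np.array([p.sensitivity for p in curve.points])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def best_threshold_by_lr(curve: RocCurve) -> ThresholdChoice:
    """The ROC point maximizing LR+ = sens/(1 − spec).

    Points with specificity 1 (infinite or undefined LR) or zero sensitivity
    are inadmissible.  Ties break toward higher sensitivity, then toward the
    less extreme (more inclusive) threshold.
    """
    admissible = [p for p in curve.points
                  if p.specificity < 1.0 and p.sensitivity > 0.0 and math.isfinite(p.lr_positive)]
    if not admissible:
        raise NoFiniteLRError("no ROC point with finite positive likelihood ratio")

    if curve.direction is Direction.HIGHER_IS_POSITIVE:
        # lower threshold = more inclusive = less extreme
        def extremeness(p: RocPoint) -> float:
            return -p.threshold
    else:
        def extremeness(p: RocPoint) -> float:
            return p.threshold

    best = max(admissible, key=lambda p: (p.lr_positive, p.sensitivity, extremeness(p)))
    return ThresholdChoice(best.threshold, best.sensitivity, best.specificity, best.lr_positive)


def sens_spec_at(curve: RocCurve, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity at an arbitrary threshold, inclusive calls."""
    s = np.asarray(curve.scores)
    y = np.asarray(curve.labels)
    return _sens_spec(s, y, threshold, curve.direction)


def binormal_auc_lognormal(params_pos, params_neg,
                           direction: Direction = Direction.HIGHER_IS_POSITIVE) -> float:
    """Closed-form AUC for two lognormal score distributions.

    If log-scores are N(mu_p, s_p^2) and N(mu_n, s_n^2), the probability that
    a positive outscores a negative is Phi((mu_p - mu_n)/sqrt(s_p^2 + s_n^2));
    the sign flips for ``lower_is_positive``.  Accepts any objects exposing
    ``mu`` and ``sigma`` attributes.
    """
    for name, p in (("params_pos", params_pos), ("params_neg", params_neg)):
        if not p.sigma > 0:
            raise ValueError(f"{name}.sigma must be > 0, got {p.sigma!r}")
    d = (params_pos.mu - params_neg.mu) / math.hypot(params_pos.sigma, params_neg.sigma)
    if Direction(direction) is Direction.LOWER_IS_POSITIVE:
        d = -d
    return float(stats.norm.cdf(d))


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test between two groups.

    For combined n <= 12 the two-sided p comes from exhaustive enumeration of
    all group assignments of the pooled midranks (valid with ties, where the
    classical exact null tables are not); larger samples use the normal
    approximation with midrank tie correction.  Returns (U statistic for
    group_a, two-sided p).
    """
    from itertools import combinations

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n = int(a.size), int(a.size + b.size)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:n_a].sum()) - n_a * (n_a + 1) / 2.0
    if n <= 12:
        mu = n_a * (n - n_a) / 2.0
        hits = total = 0
        for comb in combinations(range(n), n_a):
            u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
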