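"""Split conformal prediction: scores, calibration, sets, intervals.

Split conformal prediction turns a trained model's notion of uncertainty
into prediction sets (classification) or intervals (regression) with a
finite-sample marginal coverage guarantee: for exchangeable data and a
user-specified maximal error rate alpha,

    1 - alpha <= P(truth in C(x)) <= 1 - alpha + 1/(N_cal + 1).

All scores are oriented as *uncertainty* (high = unusual).  The calibration
threshold q-hat is the modified (1 - alpha)-quantile of the calibration
score distribution: the k-th smallest score with
k = ceil((N_cal + 1) (1 - alpha)).  When k exceeds N_cal, q-hat is the +inf
sentinel (full sets / unbounded intervals); when k <= 0 it is -inf.

Classification scores
---------------------
* True-class (TC): 1 - P(class | x), the estimated misclassification
  probability.
* Summation (Sum): cumulative vote mass over the descending-sorted classes
  up to and including the true class (adaptive-set style).
* Mondrian (Mon): the TC score calibrated separately per true class, giving
  class-conditional coverage.

Regression score
----------------
* Quantile (Qu): signed distance of the response to the nearest boundary of
  the base quantile interval [f_{alpha/2}, f_{1-alpha/2}]; the interval is
  widened (q-hat > 0) or narrowed (q-hat < 0) accordingly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "modified_quantile",
    "tc_score",
    "tc_set",
    "sum_score",
    "sum_set",
    "mondrian_calibrate",
    "mondrian_set",
    "quantile_score",
    "conformalize_interval",
    "PredictionInterval",
    "ConformalCalibrator",
    "CoverageReport",
    "evaluate_sets",
    "evaluate_intervals",
]

SCORE_KINDS = ("tc", "sum", "mondrian", "quantile")


# ------------------------------------------------------------- calibration


def modified_quantile(scores, alpha: float) -> float:
    """Finite-sample-corrected (1 - alpha)-quantile of calibration scores.

    Returns the k-th smallest score with k = ceil((N + 1)(1 - alpha)),
    +inf when k > N and -inf when k <= 0.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate on an empty score distribution")
    if not np.all(np.isfinite(scores)):
        raise ValueError("calibration scores must be finite")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n = scores.size
    # guard against float fuzz in (n+1)*(1-alpha), e.g. 10 * 0.9 -> 9.000...2
    k = math.ceil((n + 1) * (1.0 - alpha) - 1e-9)
    if k > n:
        return math.inf
    if k <= 0:
        return -math.inf
    return float(np.sort(scores)[k - 1])


# ------------------------------------------------------ classification part


def _check_votes(votes: np.ndarray) -> np.ndarray:
    votes = np.asarray(votes, dtype=float)
    if votes.ndim != 1 or not np.isclose(votes.sum(), 1.0, atol=1e-8):
        raise ValueError("class votes must be a 1-d vector summing to 1")
    return votes


def _label_index(labels, label) -> int:
    labels = list(labels)
    if label not in labels:
        raise ValueError(f"label {label!r} not in class scheme {labels}")
    return labels.index(label)


def tc_score(votes, labels, label) -> float:
    """True-class score: 1 - P(label | x)."""
    votes = _check_votes(votes)
    return float(1.0 - votes[_label_index(labels, label)])


def tc_set(votes, labels, q_hat: float) -> set:
    """Classes whose TC score is at most q-hat (possibly empty)."""
    votes = _check_votes(votes)
    return {c for c, v in zip(labels, votes) if 1.0 - v <= q_hat}


def _descending_order(votes: np.ndarray, labels) -> np.ndarray:
    """Indices sorting votes descending, probability ties by ascending code."""
    codes = np.asarray(list(labels))
    return np.lexsort((codes, -np.asarray(votes)))


def sum_score(votes, labels, label) -> float:
    """Cumulative vote mass down the descending-sorted classes up to the
    true class (inclusive)."""
    votes = _check_votes(votes)
    target = _label_index(labels, label)
    order = _descending_order(votes, labels)
    total = 0.0
    for idx in order:
        total += float(votes[idx])
        if idx == target:
            return total
    raise AssertionError("unreachable")


def sum_set(votes, labels, q_hat: float) -> set:
    """Top classes of the descending-sorted list whose cumulative mass first
    reaches q-hat; never empty (the top class is always included)."""
    votes = _check_votes(votes)
    order = _descending_order(votes, labels)
    cum = np.cumsum(np.asarray(votes)[order])
    n_below = int(np.sum(cum < q_hat))        # sup over empty set -> 0
    n_take = min(n_below + 1, len(order))
    return {list(labels)[i] for i in order[:n_take]}


def mondrian_calibrate(cal_votes, cal_labels, labels, alpha: float) -> dict:
    """Per-class thresholds: modified quantile of the TC scores of the
    calibration samples of each true class.  Classes absent from the
    calibration data get a +inf sentinel (always included) with a warning.
    """
    cal_votes = np.asarray(cal_votes, dtype=float)
    cal_labels = np.asarray(cal_labels)
    q_hats = {}
    for j, c in enumerate(labels):
        mask = cal_labels == c
        if not np.any(mask):
            warnings.warn(f"class {c!r} absent from calibration data; its "
                          "Mondrian threshold is +inf (always included)",
                          UserWarning)
            q_hats[c] = math.inf
            continue
        scores = 1.0 - cal_votes[mask, j]
        q_hats[c] = modified_quantile(scores, alpha)
    return q_hats


def mondrian_set(votes, labels, q_hats: dict) -> set:
    votes = _check_votes(votes)
    return {c for c, v in zip(labels, votes) if 1.0 - v <= q_hats[c]}


# ---------------------------------------------------------- regression part


@dataclass
class PredictionInterval:
    """A conformalized interval; ``degenerate`` flags upper < lower after
    narrowing (reported, not an error)."""

    lower: float
    upper: float
    degenerate: bool = False

    @property
    def width(self) -> float:
        return 0.0 if self.degenerate else self.upper - self.lower

    def contains(self, y: float) -> bool:
        return (not self.degenerate) and self.lower <= y <= self.upper


def quantile_score(lower: float, upper: float, y: float) -> float:
    """Signed distance of y to the nearest boundary of [lower, upper]:
    negative inside, positive outside, zero on a boundary."""
    if lower > upper:
        raise ValueError("lower quantile exceeds upper quantile")
    return float(max(lower - y, y - upper))


def conformalize_interval(lower: float, upper: float, q_hat: float) -> PredictionInterval:
    """Widen (q-hat > 0) or narrow (q-hat < 0) the base quantile interval."""
    if lower > upper:
        raise ValueError("lower quantile exceeds upper quantile")
    lo, hi = lower - q_hat, upper + q_hat
    return PredictionInterval(lo, hi, degenerate=hi < lo)


# -------------------------------------------------------------- calibrator


@dataclass
class ConformalCalibrator:
    """A calibrated score function: kind, calibration scores, threshold(s).

    ``q_hat`` is a float for the global scores and a per-class dict for the
    Mondrian score.
    """

    score_kind: str
    alpha: float
    labels: tuple | None = None
    cal_scores: np.ndarray | dict | None = None
    q_hat: float | dict = field(default=math.nan)

    @classmethod
    def calibrate_classification(cls, score_kind: str, cal_votes, cal_labels,
                                 labels, alpha: float) -> "ConformalCalibrator":
        labels = tuple(labels)
        cal_votes = np.asarray(cal_votes, dtype=float)
        cal_labels = np.asarray(cal_labels)
        if score_kind == "tc":
            scores = np.array([tc_score(v, labels, c)
                               for v, c in zip(cal_votes, cal_labels)])
            return cls("tc", alpha, labels, scores, modified_quantile(scores, alpha))
        if score_kind == "sum":
            scores = np.array([sum_score(v, labels, c)
                               for v, c in zip(cal_votes, cal_labels)])
            return cls("sum", alpha, labels, scores, modified_quantile(scores, alpha))
        if score_kind == "mondrian":
            q_hats = mondrian_calibrate(cal_votes, cal_labels, labels, alpha)
            per_class = {c: 1.0 - cal_votes[cal_labels == c, j]
                         for j, c in enumerate(labels)}
            return cls("mondrian", alpha, labels, per_class, q_hats)
        raise ValueError(f"unknown classification score kind {score_kind!r}")

    @classmethod
    def calibrate_regression(cls, cal_lower, cal_upper, cal_y,
                             alpha: float) -> "ConformalCalibrator":
        scores = np.array([quantile_score(lo, hi, y)
                           for lo, hi, y in zip(cal_lower, cal_upper, cal_y)])
        return cls("quantile", alpha, None, scores, modified_quantile(scores, alpha))

    def prediction_set(self, votes) -> set:
        if self.score_kind == "tc":
            return tc_set(votes, self.labels, self.q_hat)
        if self.score_kind == "sum":
            return sum_set(votes, self.labels, self.q_hat)
        if self.score_kind == "mondrian":
            return mondrian_set(votes, self.labels, self.q_hat)
        raise ValueError("not a classification calibrator")

    def prediction_interval(self, lower: float, upper: float) -> PredictionInterval:
        if self.score_kind != "quantile":
            raise ValueError("not a regression calibrator")
        return conformalize_interval(lower, upper, self.q_hat)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        doc = {"score_kind": self.score_kind, "alpha": self.alpha,
               "labels": list(self.labels) if self.labels else None}
        if self.score_kind == "mondrian":
            doc["q_hat"] = {str(c): q for c, q in self.q_hat.items()}
            doc["cal_scores"] = {str(c): np.asarray(s).tolist()
                                 for c, s in self.cal_scores.items()}
        else:
            doc["q_hat"] = self.q_hat
            doc["cal_scores"] = np.asarray(self.cal_scores).tolist()
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ConformalCalibrator":
        labels = tuple(doc["labels"]) if doc.get("labels") else None
        if doc["score_kind"] == "mondrian":
            q_hat = {int(c): float(q) for c, q in doc["q_hat"].items()}
            cal = {int(c): np.asarray(s, dtype=float)
                   for c, s in doc["cal_scores"].items()}
        else:
            q_hat = float(doc["q_hat"])
            cal = np.asarray(doc["cal_scores"], dtype=float)
        return cls(doc["score_kind"], float(doc["alpha"]), labels, cal, q_hat)


# -------------------------------------------------------------- diagnostics


@dataclass
class CoverageReport:
    """Coverage / efficiency diagnostics of a CP output on labelled data."""

    marginal_coverage: float
    per_class_coverage: dict | None = None
    efficiency: float | None = None          # fraction of single-class sets
    mean_relative_width: float | None = None  # interval width / training range


def evaluate_sets(sets, truths) -> CoverageReport:
    """Marginal and per-true-class coverage plus efficiency of CP sets."""
    sets = list(sets)
    truths = list(truths)
    if len(sets) == 0 or len(sets) != len(truths):
        raise ValueError("need one non-empty prediction set list matching truths")
    hits = [t in s for s, t in zip(sets, truths)]
    per_class = {}
    for c in sorted(set(truths)):
        idx = [i for i, t in enumerate(truths) if t == c]
        per_class[c] = float(np.mean([hits[i] for i in idx]))
    efficiency = float(np.mean([len(s) == 1 for s in sets]))
    return CoverageReport(float(np.mean(hits)), per_class, efficiency, None)


def evaluate_intervals(intervals, truths, training_range: float) -> CoverageReport:
    """Marginal coverage and mean width relative to the training range."""
    intervals = list(intervals)
    truths = list(truths)
    if len(intervals) == 0 or len(intervals) != len(truths):
        raise ValueError("need one non-empty interval list matching truths")
    if training_range <= 0:
        raise ValueError("training range must be positive")
    hits = [iv.contains(t) for iv, t in zip(intervals, truths)]
    widths = [iv.width for iv in intervals]
    return CoverageReport(float(np.mean(hits)), None, None,
                          float(np.mean(widths) / training_range))
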