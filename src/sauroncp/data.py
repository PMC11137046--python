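"""Core data containers shared across the package.

The central objects are a feature matrix (cell lines x molecular features),
a response bundle pairing a continuous drug response with its discretized
counterpart, and the train/calibration/test split specification used by the
conformal-prediction layer.

Class-label conventions follow drug-sensitivity usage: in the binary setting
resistant = 0 and sensitive = 1; in the ternary setting sensitive = 1,
ambiguous = 2, resistant = 3.  Because sensitivity corresponds to *low*
response values (low viability, low IC50), class labels are additionally
carried in ascending order of the response so that distance-based sample
weights can relate each class to its neighbouring thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureMatrix",
    "ClassScheme",
    "ResponseBundle",
    "SplitSpec",
    "BINARY_LABELS_ASCENDING",
    "TERNARY_LABELS_ASCENDING",
]

# labels listed in ascending order of the continuous response
BINARY_LABELS_ASCENDING = (1, 0)  # sensitive (low), resistant (high)
TERNARY_LABELS_ASCENDING = (1, 2, 3)  # sensitive, ambiguous, resistant


@dataclass
class FeatureMatrix:
    """A samples-by-features real matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
    sample_ids : sequence of unique sample identifiers
    feature_ids : sequence of feature identifiers
    """

    values: np.ndarray
    sample_ids: list
    feature_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("feature matrix must have at least one sample and one feature")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match number of columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: Sequence) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return FeatureMatrix(self.values[rows], list(sample_ids), self.feature_ids)


@dataclass
class ClassScheme:
    """The discrete class structure of a response.

    ``labels_ascending`` lists class codes in ascending order of the
    continuous response.  ``modal_class`` is the class holding the relative
    majority of the training samples (ties broken towards the lowest class
    code).
    """

    labels_ascending: tuple
    counts: dict
    modal_class: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.labels_ascending) < 2:
            raise ValueError("a class scheme needs at least two classes")
        if set(self.counts) != set(self.labels_ascending):
            raise ValueError("counts must cover exactly the scheme labels")
        # relative majority; ties resolved towards the lowest class code
        best = max(self.counts.values())
        self.modal_class = min(c for c, n in self.counts.items() if n == best)

    @property
    def k(self) -> int:
        return len(self.labels_ascending)

    @property
    def labels_sorted(self) -> tuple:
        """Class codes in ascending code order (the order used for votes)."""
        return tuple(sorted(self.labels_ascending))


@dataclass
class ResponseBundle:
    """Continuous response ``y``, discrete response ``d`` and thresholds.

    When ``thresholds`` is given, ``d`` must be consistent with thresholding
    ``y``: samples at or below a threshold belong to the more sensitive
    (lower-response) class.  ``thresholds`` may be ``None`` for externally
    discretized responses; distance-based sample weights then cannot be used.
    """

    y: np.ndarray
    d: np.ndarray
    labels_ascending: tuple
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.d = np.asarray(self.d)
        self.labels_ascending = tuple(self.labels_ascending)
        if self.y.ndim != 1 or self.d.ndim != 1 or len(self.y) != len(self.d):
            raise ValueError("y and d must be one-dimensional and of equal length")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("continuous response contains non-finite values")
        if not set(np.unique(self.d)) <= set(self.labels_ascending):
            raise ValueError("discrete response contains labels outside the class scheme")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if len(self.thresholds) != len(self.labels_ascending) - 1:
                raise ValueError("need k-1 thresholds for k classes")
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValueError("thresholds must be strictly increasing")
            expected = self.classify(self.y)
            if not np.array_equal(expected, self.d):
                raise ValueError("discrete response is inconsistent with thresholding y")

    @classmethod
    def from_continuous(
        cls,
        y: np.ndarray,
        thresholds: Sequence[float],
        labels_ascending: Sequence[int] | None = None,
    ) -> "ResponseBundle":
        """Build the bundle by thresholding ``y`` (ties go to the lower band)."""
        thresholds = np.asarray(thresholds, dtype=float)
        if labels_ascending is None:
            labels_ascending = (
                BINARY_LABELS_ASCENDING if len(thresholds) == 1 else TERNARY_LABELS_ASCENDING
            )
        labels = tuple(labels_ascending)
        bands = np.searchsorted(thresholds, np.asarray(y, dtype=float), side="left")
        d = np.asarray([labels[b] for b in bands])
        return cls(np.asarray(y, dtype=float), d, labels, thresholds)

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Map continuous values onto classes; boundary values go to the
        more sensitive (lower-response) class."""
        if self.thresholds is None:
            raise ValueError("bundle has no thresholds")
        bands = np.searchsorted(self.thresholds, np.asarray(values, dtype=float), side="left")
        return np.asarray([self.labels_ascending[b] for b in bands])

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def scheme(self) -> ClassScheme:
        counts = {c: int(np.sum(self.d == c)) for c in self.labels_ascending}
        return ClassScheme(self.labels_ascending, counts)

    def subset(self, rows: Sequence[int]) -> "ResponseBundle":
        rows = list(rows)
        return ResponseBundle(self.y[rows], self.d[rows], self.labels_ascending, self.thresholds)


@dataclass
class SplitSpec:
    """Disjoint train / calibration / test sample-id sets and the error rate."""

    train_ids: list
    cal_ids: list
    test_ids: list
    alpha: float = 0.1

    def __post_init__(self) -> None:
        train, cal, test = map(set, (self.train_ids, self.cal_ids, self.test_ids))
        if train & cal or train & test or cal & test:
            raise ValueError("train, calibration and test sets must be pairwise disjoint")
        if len(cal) < 1:
            raise ValueError("calibration set must contain at least one sample")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def n_cal(self) -> int:
        return len(self.cal_ids)


def make_split(sample_ids: Sequence, fractions=(0.70, 0.15, 0.15), alpha: float = 0.1,
               seed: int = 0) -> SplitSpec:
    """Randomly partition ``sample_ids`` into train/calibration/test sets.

    Fractions must be positive and sum to one; sizes are rounded so the three
    parts exactly cover the input.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive numbers summing to 1")
    ids = list(sample_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_cal = int(round(fractions[1] * n))
    n_cal = max(1, min(n_cal, n - n_train - 1))
    train = [ids[i] for i in order[:n_train]]
    cal = [ids[i] for i in order[n_train:n_train + n_cal]]
    test = [ids[i] for i in order[n_train + n_cal:]]
    return SplitSpec(train, cal, test, alpha)
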