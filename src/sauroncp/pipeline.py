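"""The split-CP pipeline on top of the SAURON forest.

The four steps: (1) train the forest on the training partition, (2) choose
score functions, (3) apply the model to the calibration partition and derive
thresholds from the score distributions, (4) turn test-set predictions into
prediction sets and intervals.  This module also carries the per-drug
orchestration used by the command-line interface and by the cell-line-centric
prioritization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformal import (ConformalCalibrator, CoverageReport, evaluate_intervals,
                        evaluate_sets)
from .data import FeatureMatrix, ResponseBundle, SplitSpec
from .forest import ForestParams, SauronForest, fit_forest
from .weights import compute_sample_weights

__all__ = ["CPOutput", "train_stage", "calibrate_stage", "predict_stage",
           "run_conformal_pipeline", "save_calibrators", "load_calibrators"]

CLASSIFICATION_SCORES = ("tc", "sum", "mondrian")


@dataclass
class CPOutput:
    """Test-set output of one pipeline run for one drug."""

    test_ids: list
    point_values: np.ndarray
    point_classes: np.ndarray
    class_votes: np.ndarray          # (n_test, k), label order = sorted codes
    quantile_pairs: np.ndarray       # (n_test, 2): base alpha/2, 1-alpha/2
    sets: dict                       # score kind -> list of sets
    intervals: list                  # conformalized PredictionIntervals
    reports: dict = field(default_factory=dict)   # score kind -> CoverageReport
    training_range: float = float("nan")

    def sets_for(self, kind: str) -> dict:
        return dict(zip(self.test_ids, self.sets[kind]))

    def intervals_by_id(self) -> dict:
        return dict(zip(self.test_ids, self.intervals))

    def values_by_id(self) -> dict:
        return dict(zip(self.test_ids, self.point_values))


def _rows(features: FeatureMatrix, ids) -> list[int]:
    index = {s: i for i, s in enumerate(features.sample_ids)}
    missing = [s for s in ids if s not in index]
    if missing:
        raise KeyError(f"sample ids not in feature matrix: {missing[:5]}")
    return [index[s] for s in ids]


def train_stage(features: FeatureMatrix, bundle: ResponseBundle, split: SplitSpec,
                weight_scheme: str = "simple", g: int | None = None,
                params: ForestParams | None = None) -> SauronForest:
    """Step 1: fit the SAURON forest on the training partition."""
    rows = _rows(features, split.train_ids)
    sub_bundle = bundle.subset(rows)
    weights = compute_sample_weights(sub_bundle, weight_scheme, g)
    return fit_forest(features.values[rows], sub_bundle, weights, params)


def calibrate_stage(forest: SauronForest, features: FeatureMatrix,
                    bundle: ResponseBundle, split: SplitSpec,
                    score_kinds=("tc",)) -> dict:
    """Steps 2-3: score the calibration partition, derive thresholds.

    Returns a dict mapping score kind to its :class:`ConformalCalibrator`;
    regression calibration (the quantile score) is always included under the
    key ``"quantile"``.
    """
    alpha = split.alpha
    rows = _rows(features, split.cal_ids)
    Xc = features.values[rows]
    yc = bundle.y[rows]
    dc = bundle.d[rows]
    _, _, votes, _ = forest.predict_batch(Xc)
    calibrators: dict[str, ConformalCalibrator] = {}
    for kind in score_kinds:
        if kind not in CLASSIFICATION_SCORES:
            raise ValueError(f"unknown classification score kind {kind!r}")
        calibrators[kind] = ConformalCalibrator.calibrate_classification(
            kind, votes, dc, forest.class_labels, alpha)
    q = forest.predict_quantile(Xc, [alpha / 2, 1 - alpha / 2])
    calibrators["quantile"] = ConformalCalibrator.calibrate_regression(
        q[:, 0], q[:, 1], yc, alpha)
    return calibrators


def predict_stage(forest: SauronForest, calibrators: dict,
                  features: FeatureMatrix, split: SplitSpec,
                  bundle: ResponseBundle | None = None) -> CPOutput:
    """Step 4: prediction sets and intervals for the test partition.

    When the true responses are supplied, coverage / efficiency / relative
    interval width diagnostics are attached.
    """
    alpha = split.alpha
    rows = _rows(features, split.test_ids)
    Xt = features.values[rows]
    values, classes, votes, _ = forest.predict_batch(Xt)
    q = forest.predict_quantile(Xt, [alpha / 2, 1 - alpha / 2])
    sets = {}
    for kind, cal in calibrators.items():
        if kind == "quantile":
            continue
        sets[kind] = [cal.prediction_set(v) for v in votes]
    qcal = calibrators["quantile"]
    intervals = [qcal.prediction_interval(lo, hi) for lo, hi in q]
    training_range = float(np.ptp(forest.y_train))
    out = CPOutput(list(split.test_ids), values, classes, votes, q, sets,
                   intervals, {}, training_range)
    if bundle is not None:
        dt = bundle.d[rows]
        yt = bundle.y[rows]
        for kind, s in sets.items():
            out.reports[kind] = evaluate_sets(s, dt)
        out.reports["quantile"] = evaluate_intervals(intervals, yt, training_range)
    return out


def run_conformal_pipeline(features: FeatureMatrix, bundle: ResponseBundle,
                           split: SplitSpec, score_kinds=("tc",),
                           weight_scheme: str = "simple", g: int | None = None,
                           params: ForestParams | None = None):
    """End-to-end CP run; returns (forest, calibrators, CPOutput)."""
    forest = train_stage(features, bundle, split, weight_scheme, g, params)
    calibrators = calibrate_stage(forest, features, bundle, split, score_kinds)
    output = predict_stage(forest, calibrators, features, split, bundle)
    return forest, calibrators, output


# ------------------------------------------------------------ serialization


def save_calibrators(calibrators: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: c.to_dict() for k, c in calibrators.items()}, fh)


def load_calibrators(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {k: ConformalCalibrator.from_dict(d) for k, d in doc.items()}


def coverage_table(reports: dict) -> pd.DataFrame:
    """One row per score kind: coverage, per-class coverage, efficiency,
    relative width (delimited-text-friendly)."""
    rows = []
    for kind, rep in reports.items():
        row = {"score": kind, "marginal_coverage": rep.marginal_coverage,
               "efficiency": rep.efficiency,
               "mean_relative_width": rep.mean_relative_width}
        if rep.per_class_coverage:
            for c, v in rep.per_class_coverage.items():
                row[f"coverage_class_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
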