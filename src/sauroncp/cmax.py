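"""CMax-viability drug-sensitivity measure and PAM-based discretization.

The CMax viability of a (drug, cell line) pair is the fraction of viable
cells at the drug's CMax concentration — the peak plasma concentration
reached at the highest clinically recommended dose.  Unlike IC50 or AUC it
lives on a common [0, 1] scale for every drug, which makes responses
comparable *across* drugs and enables prioritization.

The measure is computed by fitting a monotone dose-response curve to the raw
(concentration, viability) points of each pair and evaluating it at the CMax
concentration.  The curve model is a pluggable two-parameter logistic on
log10 concentration,

    v(c) = 1 / (1 + exp(h * (log10 c - log10 ec50))),    h >= 0,

which is monotonically nonincreasing in the concentration; evaluations are
clipped to [0, 1].  Constant-viability inputs fall back to a flat curve.

Across-drug discretization pools all CMax viabilities and clusters them with
one-dimensional k-medoids (PAM objective, solved exactly by a dynamic
program over contiguous segments, hence deterministic) into k = 2
(sensitive / resistant) or k = 3 (sensitive / ambiguous / resistant)
clusters; the midpoints between adjacent clusters are the discretization
thresholds applied identically to every drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data import (BINARY_LABELS_ASCENDING, TERNARY_LABELS_ASCENDING,
                   ResponseBundle, SplitSpec)

__all__ = [
    "DoseResponseCurve",
    "fit_dose_response",
    "cmax_viability",
    "build_cmax_matrix",
    "DiscretizationModel",
    "pam_discretize",
    "apply_thresholds",
    "filter_analyzable_drugs",
]


# ----------------------------------------------------------- curve fitting


def _logistic(log10_c: np.ndarray, log10_ec50: float, hill: float) -> np.ndarray:
    z = np.clip(hill * (log10_c - log10_ec50), -500, 500)
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class DoseResponseCurve:
    """A fitted monotone dose-response curve on log10 concentration."""

    kind: str                      # "logistic" or "flat"
    log10_ec50: float = np.nan
    hill: float = np.nan           # slope >= 0 (nonincreasing viability)
    level: float = np.nan          # flat curves only
    conc_range: tuple = (np.nan, np.nan)  # tested range, µM
    residual_norm: float = np.nan

    def viability(self, concentration) -> np.ndarray:
        """Predicted viability at the given concentration(s), clipped to [0,1]."""
        c = np.asarray(concentration, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.kind == "flat":
            v = np.full(c.shape, self.level)
        else:
            v = _logistic(np.log10(c), self.log10_ec50, self.hill)
        return np.clip(v, 0.0, 1.0)


def fit_dose_response(concentrations, viabilities) -> DoseResponseCurve:
    """Least-squares fit of the monotone logistic to raw dose-response points.

    Requires at least three distinct positive concentrations; replicates are
    allowed and enter the fit individually.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if conc.shape != viab.shape or conc.ndim != 1:
        raise ValueError("concentrations and viabilities must be aligned 1-d vectors")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not np.all(np.isfinite(viab)):
        raise ValueError("viabilities must be finite")
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least three distinct concentrations to fit a curve")
    log_c = np.log10(conc)
    crange = (float(conc.min()), float(conc.max()))

    if np.ptp(viab) < 1e-9:
        level = float(np.clip(viab[0], 0.0, 1.0))
        return DoseResponseCurve("flat", level=level, conc_range=crange,
                                 residual_norm=0.0)

    # initialization: midpoint at the concentration closest to viability 0.5,
    # slope from the spread of the viability drop over the tested range
    mid0 = log_c[int(np.argmin(np.abs(viab - 0.5)))]
    hill0 = max(1.0, 4.0 * np.ptp(viab) / max(np.ptp(log_c), 1e-6))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic, log_c, viab, p0=[mid0, hill0],
                bounds=([log_c.min() - 6.0, 0.0], [log_c.max() + 6.0, 50.0]),
                maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"dose-response fit did not converge: {exc}") from exc
    resid = viab - _logistic(log_c, *popt)
    return DoseResponseCurve("logistic", log10_ec50=float(popt[0]),
                             hill=float(popt[1]), conc_range=crange,
                             residual_norm=float(np.linalg.norm(resid)))


def cmax_viability(curve: DoseResponseCurve, cmax_concentration: float):
    """Evaluate the fitted curve at the CMax concentration.

    Returns ``(viability, extrapolated)``; ``extrapolated`` is True when the
    CMax concentration lies outside the tested concentration range.
    """
    cmax = float(cmax_concentration)
    if cmax <= 0:
        raise ValueError("CMax concentration must be strictly positive")
    value = float(curve.viability(cmax))
    lo, hi = curve.conc_range
    extrapolated = bool(np.isfinite(lo) and not (lo <= cmax <= hi))
    return value, extrapolated


def build_cmax_matrix(points: pd.DataFrame, cmax_table: pd.DataFrame):
    """CMax-viability matrix (cell lines x drugs) from raw dose-response data.

    ``points`` needs columns drug, cell_line, concentration_uM, viability;
    ``cmax_table`` needs drug, cmax_uM.  Returns (matrix, extrapolation
    flags) as DataFrames; pairs without dose-response data are NaN.
    """
    cmax_map = dict(zip(cmax_table["drug"], cmax_table["cmax_uM"].astype(float)))
    drugs = sorted(set(points["drug"]) & set(cmax_map))
    lines = sorted(set(points["cell_line"]))
    values = pd.DataFrame(np.nan, index=lines, columns=drugs)
    flags = pd.DataFrame(False, index=lines, columns=drugs)
    for (drug, line), grp in points.groupby(["drug", "cell_line"], sort=False):
        if drug not in cmax_map:
            continue
        curve = fit_dose_response(grp["concentration_uM"].to_numpy(),
                                  grp["viability"].to_numpy())
        v, ex = cmax_viability(curve, cmax_map[drug])
        values.loc[line, drug] = v
        flags.loc[line, drug] = ex
    values.index.name = "cell_line"
    flags.index.name = "cell_line"
    return values, flags


# ------------------------------------------------------------ discretization


def _segment_costs(values: np.ndarray, counts: np.ndarray):
    """For sorted distinct ``values`` with multiplicities, the k-medoids cost
    of every contiguous segment [i..j] served by its weighted median, as an
    (n x n) matrix (NaN below the diagonal), plus the medoid index matrix."""
    n = len(values)
    W = np.concatenate([[0.0], np.cumsum(counts)])          # W[l] = mass of x_<l
    S = np.concatenate([[0.0], np.cumsum(counts * values)])
    cost = np.full((n, n), np.nan)
    medoid = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        j = np.arange(i, n)
        half = W[i] + 0.5 * (W[j + 1] - W[i])
        m = np.searchsorted(W[1:], half)                    # weighted median index
        xm = values[m]
        left = xm * (W[m + 1] - W[i]) - (S[m + 1] - S[i])
        right = (S[j + 1] - S[m + 1]) - xm * (W[j + 1] - W[m + 1])
        cost[i, i:] = left + right
        medoid[i, i:] = m
    return cost, medoid


def _pam_1d(values: np.ndarray, counts: np.ndarray, k: int):
    """Exact, deterministic 1-D k-medoids on distinct values with
    multiplicities.  In one dimension the optimal clusters are contiguous in
    sorted order, so dynamic programming over segment boundaries yields the
    global optimum of the k-medoids objective.  Returns sorted medoid values.
    """
    n = len(values)
    cost, medoid = _segment_costs(values, counts)
    # D[q][j]: best cost of clustering values[0..j] into q+1 segments
    D = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=np.int64)
    D[0] = cost[0]
    for q in range(1, k):
        # candidate split: previous q segments end at i-1, new segment [i..j]
        cand = D[q - 1][:, None] + np.vstack([cost[1:], np.full(n, np.nan)])
        with np.errstate(invalid="ignore"):
            best = np.nanargmin(np.where(np.isnan(cand), np.inf, cand), axis=0)
        D[q] = cand[best, np.arange(n)]
        back[q] = best + 1
    # backtrack the segment starts
    medoids = []
    j = n - 1
    for q in range(k - 1, -1, -1):
        i = back[q, j] if q > 0 else 0
        medoids.append(values[medoid[i, j]])
        j = i - 1
    return np.sort(np.asarray(medoids))


@dataclass
class DiscretizationModel:
    """PAM-derived across-drug discretization thresholds.

    ``thresholds`` (k-1 ascending reals) apply identically to all drugs; the
    lowest-viability cluster is the sensitive class.  ``threshold_rule``
    records whether thresholds are midpoints between adjacent cluster
    boundaries (default) or between adjacent medoids.
    """

    k: int
    medoids: np.ndarray
    thresholds: np.ndarray
    threshold_rule: str = "boundary"
    labels_ascending: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.medoids = np.asarray(self.medoids, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if len(self.thresholds) != self.k - 1 or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("need k-1 strictly increasing thresholds")
        self.labels_ascending = (BINARY_LABELS_ASCENDING if self.k == 2
                                 else TERNARY_LABELS_ASCENDING)


def pam_discretize(all_viabilities, k: int, threshold_rule: str = "boundary") -> DiscretizationModel:
    """Cluster the pooled CMax viabilities of *all* drugs into k groups.

    Thresholds are midpoints between the maximum of each lower cluster and
    the minimum of the next cluster (``threshold_rule="boundary"``) or
    midpoints between adjacent medoids (``"medoid"``).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if threshold_rule not in ("boundary", "medoid"):
        raise ValueError("threshold_rule must be 'boundary' or 'medoid'")
    vals = np.asarray(all_viabilities, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) < k:
        raise ValueError(f"need at least {k} distinct viability values")
    medoids = _pam_1d(uniq, counts, k)
    # assign distinct values to the nearest medoid (ties to the lower medoid)
    assign = np.argmin(np.abs(uniq[:, None] - medoids[None, :]), axis=1)
    thresholds = []
    for j in range(k - 1):
        if threshold_rule == "medoid":
            thresholds.append(0.5 * (medoids[j] + medoids[j + 1]))
        else:
            lower_max = uniq[assign == j].max()
            upper_min = uniq[assign == j + 1].min()
            thresholds.append(0.5 * (lower_max + upper_min))
    return DiscretizationModel(k, medoids, np.asarray(thresholds), threshold_rule)


def apply_thresholds(values, model: DiscretizationModel) -> np.ndarray:
    """Map viabilities onto classes; boundary values go to the more
    sensitive (lower-viability) class.

    Binary: viability <= threshold -> sensitive (1), else resistant (0).
    Ternary: ascending viability bands map to sensitive (1), ambiguous (2),
    resistant (3).
    """
    vals = np.asarray(values, dtype=float)
    bands = np.searchsorted(model.thresholds, vals, side="left")
    labels = np.asarray(model.labels_ascending)
    return labels[bands]


# -------------------------------------------------------------- drug filter


def filter_analyzable_drugs(labels_by_drug: pd.DataFrame, split: SplitSpec,
                            min_per_class: int = 3):
    """Drop drugs whose discretized responses cannot support the pipeline.

    A drug is dropped when its labels contain a single class overall, or when
    any class present for that drug has fewer than ``min_per_class`` samples
    in any of the train / calibration / test partitions.  ``labels_by_drug``
    is a cell-lines x drugs label frame (NaN = unavailable pair).

    Returns ``(retained_drugs, report)`` where the report lists one row per
    drug with its status and reason.
    """
    parts = {"train": set(split.train_ids), "calibration": set(split.cal_ids),
             "test": set(split.test_ids)}
    rows = []
    retained = []
    for drug in labels_by_drug.columns:
        col = labels_by_drug[drug].dropna()
        classes = sorted(set(col))
        if len(classes) < 2:
            rows.append({"drug": drug, "status": "dropped", "reason": "single class"})
            continue
        reason = None
        for part, ids in parts.items():
            sub = col[col.index.isin(ids)]
            for c in classes:
                if int((sub == c).sum()) < min_per_class:
                    reason = (f"class {c} has fewer than {min_per_class} "
                              f"samples in {part}")
                    break
            if reason:
                break
        if reason:
            rows.append({"drug": drug, "status": "dropped", "reason": reason})
        else:
            retained.append(drug)
            rows.append({"drug": drug, "status": "retained", "reason": ""})
    return retained, pd.DataFrame(rows, columns=["drug", "status", "reason"])


def bundle_from_viabilities(viabilities: pd.Series, model: DiscretizationModel) -> ResponseBundle:
    """Pair a drug's CMax viabilities with their discretized labels."""
    y = viabilities.to_numpy(dtype=float)
    return ResponseBundle.from_continuous(y, model.thresholds, model.labels_ascending)
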