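"""Cell-line-centric drug prioritization from conformal predictions.

For one cell line, a drug is *effective* when its CP class set is exactly
the singleton {sensitive}.  Effective drugs are ranked ascendingly by the
upper limit of their CP regression interval — a CMax-viability value that is
unlikely to be exceeded, so a small upper limit means confidently strong
killing.  Evaluation compares the ranked list with the true CMax
viabilities: precision of the list, whether the truly most efficient drug is
contained, the rank of the predicted first drug in the true ordering, and
the viability gap between the predicted and the actual best drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "effective_drugs",
    "rank_drugs",
    "PrioritizedList",
    "PrioritizationEvaluation",
    "evaluate_prioritization",
    "aggregate_evaluations",
]

SENSITIVE = 1


@dataclass
class PrioritizedList:
    """Ordered effective drugs for one cell line (ascending upper CP limit)."""

    cell_line: object
    drugs: list
    upper_limits: list
    point_values: list


@dataclass
class PrioritizationEvaluation:
    """Per-cell-line quality of a prioritized list; ``defined`` is False for
    empty lists (their fields are NaN and excluded from aggregate medians)."""

    cell_line: object
    defined: bool
    precision: float
    contains_most_efficient: float
    rank_of_first: float
    first_is_tp: float
    viability_gap: float


def effective_drugs(sets_by_drug: Mapping, drugs: Sequence | None = None,
                    sensitive_label=SENSITIVE) -> list:
    """Drugs whose CP set is exactly the singleton sensitive class."""
    if drugs is not None:
        missing = [d for d in drugs if d not in sets_by_drug]
        if missing:
            raise ValueError(f"missing CP sets for drugs: {missing}")
    items = drugs if drugs is not None else list(sets_by_drug)
    return [d for d in items if set(sets_by_drug[d]) == {sensitive_label}]


def rank_drugs(effective: Sequence, intervals_by_drug: Mapping,
               point_values: Mapping | None = None,
               cell_line=None) -> PrioritizedList:
    """Sort effective drugs ascendingly by upper CP limit; ties broken by
    point value, then drug id."""
    missing = [d for d in effective if d not in intervals_by_drug]
    if missing:
        raise ValueError(f"missing CP intervals for drugs: {missing}")

    def key(d):
        iv = intervals_by_drug[d]
        upper = iv.upper if hasattr(iv, "upper") else float(iv)
        pv = point_values.get(d, 0.0) if point_values else 0.0
        return (upper, pv, str(d))

    ordered = sorted(effective, key=key)
    uppers = [intervals_by_drug[d].upper if hasattr(intervals_by_drug[d], "upper")
              else float(intervals_by_drug[d]) for d in ordered]
    pvs = [point_values.get(d, float("nan")) if point_values else float("nan")
           for d in ordered]
    return PrioritizedList(cell_line, ordered, uppers, pvs)


def evaluate_prioritization(ranked: PrioritizedList, true_viabilities: Mapping,
                            true_labels: Mapping,
                            sensitive_label=SENSITIVE) -> PrioritizationEvaluation:
    """Compare a prioritized list with the true CMax viabilities.

    ``true_viabilities`` and ``true_labels`` must cover the full drug panel
    (ranks are computed within that panel).
    """
    nan = float("nan")
    if len(ranked.drugs) == 0:
        return PrioritizationEvaluation(ranked.cell_line, False, nan, nan, nan,
                                        nan, nan)
    truly_sensitive = {d for d, lab in true_labels.items() if lab == sensitive_label}
    precision = float(np.mean([d in truly_sensitive for d in ranked.drugs]))
    # true ascending-viability ordering of the whole panel
    panel = sorted(true_viabilities, key=lambda d: (true_viabilities[d], str(d)))
    best = panel[0]
    first = ranked.drugs[0]
    rank_of_first = float(panel.index(first) + 1)
    gap = abs(true_viabilities[first] - true_viabilities[best])
    return PrioritizationEvaluation(
        ranked.cell_line, True, precision,
        float(best in ranked.drugs), rank_of_first,
        float(first in truly_sensitive), float(gap))


def aggregate_evaluations(evals: Sequence[PrioritizationEvaluation]) -> dict:
    """Medians (precision, rank, gap) and fractions (flags) over cell lines
    with a defined (non-empty) prioritized list; undefined lists are counted
    separately."""
    defined = [e for e in evals if e.defined]
    n = len(evals)
    out = {"n_cell_lines": n, "n_defined": len(defined),
           "fraction_undefined": (n - len(defined)) / n if n else float("nan")}
    if defined:
        out["median_precision"] = float(np.median([e.precision for e in defined]))
        out["median_rank_of_first"] = float(np.median([e.rank_of_first for e in defined]))
        out["median_viability_gap"] = float(np.median([e.viability_gap for e in defined]))
        out["fraction_contains_most_efficient"] = float(
            np.mean([e.contains_most_efficient for e in defined]))
        out["fraction_first_is_tp"] = float(np.mean([e.first_is_tp for e in defined]))
        out["fraction_gap_below_0.1"] = float(
            np.mean([e.viability_gap < 0.1 for e in defined]))
    else:
        for key in ("median_precision", "median_rank_of_first",
                    "median_viability_gap", "fraction_contains_most_efficient",
                    "fraction_first_is_tp", "fraction_gap_below_0.1"):
            out[key] = float("nan")
    return out


def evaluations_frame(evals: Sequence[PrioritizationEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in evals])
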