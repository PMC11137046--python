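"""Sample-weight schemes counteracting class imbalance.

Three schemes are available.  The *simple* scheme gives weight 1 to samples
of the modal (relative-majority) class and N_mode / N_c to samples of every
other class c, so each minority class contributes the same total weight as
the majority.  The *linear* and *quadratic* schemes instead emphasize samples
by their distance to the discretization threshold(s): a sample of class c
with continuous response y_i receives

    w_i* = dist_i^g / (k * sum_{n in c} dist_n^g),    g = 1 (linear) or 2,

where dist_i is |y_i - t| for the two outer classes (single neighbouring
threshold t) and the average of the distances to both neighbouring
thresholds for interior classes, and k is the number of classes.  Weights
are normalized within each class, so again every class carries equal total
weight (1/k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ResponseBundle

__all__ = ["SampleWeights", "compute_sample_weights"]

SCHEMES = ("simple", "linear", "quadratic")


@dataclass
class SampleWeights:
    """Per-sample weights ``w_star`` with the scheme that produced them."""

    w_star: np.ndarray
    scheme: str
    g: int | None = None

    def __post_init__(self) -> None:
        self.w_star = np.asarray(self.w_star, dtype=float)
        if np.any(self.w_star < 0) or not np.all(np.isfinite(self.w_star)):
            raise ValueError("weights must be finite and non-negative")


def compute_sample_weights(bundle: ResponseBundle, scheme: str = "simple",
                           g: int | None = None) -> SampleWeights:
    """Compute imbalance-countering sample weights for a response bundle.

    Parameters
    ----------
    bundle : ResponseBundle
        Continuous + discrete response.  Distance schemes require thresholds.
    scheme : {"simple", "linear", "quadratic"}
    g : {1, 2}, optional
        Distance exponent; implied by the scheme name and checked if given.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    if scheme == "simple":
        return SampleWeights(_simple_weights(bundle), "simple")

    implied = 1 if scheme == "linear" else 2
    if g is None:
        g = implied
    if g != implied:
        raise ValueError(f"scheme {scheme!r} implies g={implied}, got g={g}")
    return SampleWeights(_distance_weights(bundle, g), scheme, g)


def _simple_weights(bundle: ResponseBundle) -> np.ndarray:
    scheme = bundle.scheme
    counts = scheme.counts
    present = [c for c, n in counts.items() if n > 0]
    if len(present) < 2:
        raise ValueError("simple weights need at least two non-empty classes")
    mode = scheme.modal_class
    n_mode = counts[mode]
    w = np.empty(bundle.n_samples, dtype=float)
    for c in present:
        w[bundle.d == c] = 1.0 if c == mode else n_mode / counts[c]
    return w


def _distance_weights(bundle: ResponseBundle, g: int) -> np.ndarray:
    if bundle.thresholds is None:
        raise ValueError("distance-based weights require thresholds")
    t = bundle.thresholds
    labels = bundle.labels_ascending
    k = len(labels)
    y, d = bundle.y, bundle.d
    dist = np.empty(len(y), dtype=float)
    for j, c in enumerate(labels):
        mask = d == c
        if not np.any(mask):
            continue
        if j == 0:
            dist[mask] = np.abs(y[mask] - t[0]) ** g
        elif j == k - 1:
            dist[mask] = np.abs(y[mask] - t[-1]) ** g
        else:  # interior class: distances to both neighbouring thresholds
            dist[mask] = (np.abs(y[mask] - t[j - 1]) ** g
                          + np.abs(y[mask] - t[j]) ** g)
    w = np.zeros(len(y), dtype=float)
    for c in labels:
        mask = d == c
        if not np.any(mask):
            continue
        denom = k * float(np.sum(dist[mask]))
        if denom == 0.0:
            warnings.warn(
                f"all samples of class {c} lie exactly on their threshold; "
                "their distance weights are zero", UserWarning)
            continue
        w[mask] = dist[mask] / denom
    if np.any(w == 0.0) and np.any(dist == 0.0):
        warnings.warn("samples with zero distance to their threshold received "
                      "weight 0", UserWarning)
    return w
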