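"""Seeded generators emulating the inputs of the prediction pipeline.

Three generators cover the three input kinds the method consumes:

* expression-like feature matrices with a sparse informative subset and a
  continuous response carrying class structure and imbalance
  (:func:`make_regression_classification`),
* raw dose-response panels from known logistic curves with analytically
  known CMax viabilities (:func:`make_dose_response_panel`),
* multi-drug panels sharing one cell-line cohort and one
  train/calibration/test split, as the cell-line-centric prioritization
  requires (:func:`make_shared_panel`).

All randomness flows from a single master seed through per-stage and
per-drug substreams (``SeedSequence`` spawn keys), so adding drugs to a
panel does not perturb the data of existing drugs, and a fixed seed fully
determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import FeatureMatrix, ResponseBundle, SplitSpec, make_split

__all__ = [
    "GeneratorConfig",
    "make_regression_classification",
    "make_dose_response_panel",
    "make_shared_panel",
    "SharedPanel",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    ``class_fractions`` are listed in ascending order of the continuous
    response (sensitive class first) and must sum to 1; the default 30%
    sensitive / 70% resistant mirrors the typical imbalance of drug screens.
    ``noise_sd`` is the response noise level relative to the unit-variance
    noiseless signal (0.5 keeps the signal clearly learnable but noisy).
    Dose-response points use ``n_concentrations`` log-spaced doses (µM) in
    triplicate with Gaussian assay noise ``viability_noise_sd`` per point
    (3% of the untreated-control signal, a realistic luminescence-assay
    noise floor that keeps per-pair curve evaluations accurate to a few
    percent).
    """

    n_samples: int = 2000
    n_features: int = 20
    n_informative: int = 5
    noise_sd: float = 0.5
    class_fractions: tuple = (0.3, 0.7)
    n_drugs: int = 8
    n_concentrations: int = 9
    n_replicates: int = 3
    conc_low_uM: float = 1e-3
    conc_high_uM: float = 10.0
    viability_noise_sd: float = 0.03
    cmax_outside_fraction: float = 0.1
    panel_thresholds: tuple = (0.5,)
    split_fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.class_fractions, dtype=float)
        if len(fr) < 2 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must be positive and sum to 1")
        if not 1 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [1, n_features]")
        if self.n_samples < len(fr):
            raise ValueError("need at least one sample per class")

    def _rng(self, stage: int, item: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(stage, item))
        return np.random.default_rng(ss)


_STAGE_FEATURES = 0
_STAGE_RESPONSE = 1
_STAGE_DOSE = 2
_STAGE_SPLIT = 3
_STAGE_PANEL = 4


def _sparse_signal(cfg: GeneratorConfig, rng: np.random.Generator, X: np.ndarray):
    """Unit-variance sparse linear signal with random coefficient signs."""
    idx = rng.choice(cfg.n_features, size=cfg.n_informative, replace=False)
    beta = np.zeros(cfg.n_features)
    beta[idx] = rng.uniform(0.5, 1.5, size=cfg.n_informative) * rng.choice(
        [-1.0, 1.0], size=cfg.n_informative)
    beta /= np.linalg.norm(beta)  # features are iid N(0,1) -> Var(X beta) = 1
    return X @ beta, beta, np.sort(idx)


def _threshold_by_fractions(y: np.ndarray, fractions: Sequence[float]) -> np.ndarray:
    cum = np.cumsum(np.asarray(fractions, dtype=float))[:-1]
    return np.quantile(y, cum)


def make_regression_classification(cfg: GeneratorConfig):
    """Feature matrix + response bundle + truth record.

    Features are iid standard normal; the continuous response is a sparse
    linear signal plus Gaussian noise; the discrete response thresholds the
    response at the quantiles matching the requested class fractions (the
    same construction the drug pipeline uses: labels are derived from the
    observed continuous response).
    """
    rng_x = cfg._rng(_STAGE_FEATURES)
    X = rng_x.standard_normal((cfg.n_samples, cfg.n_features))
    rng_y = cfg._rng(_STAGE_RESPONSE)
    y0, beta, informative = _sparse_signal(cfg, rng_y, X)
    y = y0 + cfg.noise_sd * rng_y.standard_normal(cfg.n_samples)
    thresholds = _threshold_by_fractions(y, cfg.class_fractions)
    bundle = ResponseBundle.from_continuous(y, thresholds)
    fm = FeatureMatrix(X, [f"S{i:05d}" for i in range(cfg.n_samples)],
                       [f"gene_{j:04d}" for j in range(cfg.n_features)])
    truth = {"beta": beta, "informative": informative, "noiseless": y0,
             "thresholds": thresholds}
    return fm, bundle, truth


def make_dose_response_panel(cfg: GeneratorConfig):
    """Raw dose-response points per drug-cell line pair with known truth.

    Curves are logistic on log10 concentration with per-pair midpoints and
    slopes drawn within the tested range; replicate viabilities carry
    Gaussian assay noise.  CMax concentrations fall outside the tested range
    for a ``cmax_outside_fraction`` of drugs.  Returns
    ``(points, cmax_table, true_viabilities)`` with true CMax viabilities
    computed analytically from the generating curves.
    """
    n_lines = max(2, cfg.n_samples)
    lines = [f"CL{i:05d}" for i in range(n_lines)]
    log_lo, log_hi = np.log10(cfg.conc_low_uM), np.log10(cfg.conc_high_uM)
    concs = np.logspace(log_lo, log_hi, cfg.n_concentrations)
    rows = []
    cmax_rows = []
    truth_rows = []
    for d in range(cfg.n_drugs):
        rng = cfg._rng(_STAGE_DOSE, d)
        drug = f"drug_{d:03d}"
        if rng.uniform() < cfg.cmax_outside_fraction:
            # outside the tested range, up to one decade beyond either end
            side = rng.choice([-1.0, 1.0])
            log_cmax = (log_lo - rng.uniform(0, 1)) if side < 0 else (log_hi + rng.uniform(0, 1))
        else:
            log_cmax = rng.uniform(log_lo, log_hi)
        cmax = 10.0 ** log_cmax
        cmax_rows.append({"drug": drug, "cmax_uM": cmax})
        for line in lines:
            ec50 = rng.uniform(log_lo + 0.5, log_hi - 0.5)
            hill = rng.uniform(0.8, 2.5)
            true_v = 1.0 / (1.0 + np.exp(hill * (log_cmax - ec50)))
            truth_rows.append({"drug": drug, "cell_line": line,
                               "log10_ec50": ec50, "hill": hill,
                               "true_cmax_viability": true_v})
            clean = 1.0 / (1.0 + np.exp(hill * (np.log10(concs) - ec50)))
            for _ in range(cfg.n_replicates):
                noisy = clean + cfg.viability_noise_sd * rng.standard_normal(len(concs))
                for c, v in zip(concs, noisy):
                    rows.append({"drug": drug, "cell_line": line,
                                 "concentration_uM": c, "viability": v})
    points = pd.DataFrame(rows)
    cmax_table = pd.DataFrame(cmax_rows)
    truth = pd.DataFrame(truth_rows)
    return points, cmax_table, truth


@dataclass
class SharedPanel:
    """Multi-drug dataset with one cell-line cohort and one shared split."""

    features: FeatureMatrix
    bundles: dict
    split: SplitSpec
    truth: dict = field(default_factory=dict)

    @property
    def drugs(self) -> list:
        return list(self.bundles)


def make_shared_panel(cfg: GeneratorConfig, alpha: float = 0.1) -> SharedPanel:
    """Multi-drug viability panel on one cohort with a shared 70/15/15 split.

    Every drug has its own sparse signal and effect size but all drugs share
    the feature matrix and the train/calibration/test cell-line partition.
    Continuous responses are viability-like values in (0, 1) (a logistic
    squash of the per-drug signal), discretized by the across-drug
    ``panel_thresholds``.
    """
    rng_x = cfg._rng(_STAGE_FEATURES)
    X = rng_x.standard_normal((cfg.n_samples, cfg.n_features))
    lines = [f"CL{i:05d}" for i in range(cfg.n_samples)]
    fm = FeatureMatrix(X, lines, [f"gene_{j:04d}" for j in range(cfg.n_features)])
    split_seed = int(cfg._rng(_STAGE_SPLIT).integers(2**31 - 1))
    split = make_split(lines, cfg.split_fractions, alpha=alpha, seed=split_seed)
    bundles = {}
    truth = {}
    for d in range(cfg.n_drugs):
        rng = cfg._rng(_STAGE_PANEL, d)
        drug = f"drug_{d:03d}"
        y0, beta, informative = _sparse_signal(cfg, rng, X)
        shift = rng.uniform(-0.8, 0.8)        # per-drug potency offset
        scale = rng.uniform(1.0, 2.0)         # per-drug effect size
        lin = scale * y0 + shift
        noiseless = 1.0 / (1.0 + np.exp(-lin))
        noisy_lin = lin + cfg.noise_sd * rng.standard_normal(cfg.n_samples)
        viab = 1.0 / (1.0 + np.exp(-noisy_lin))
        bundles[drug] = ResponseBundle.from_continuous(viab, cfg.panel_thresholds)
        truth[drug] = {"beta": beta, "informative": informative,
                       "noiseless_viability": noiseless}
    return SharedPanel(fm, bundles, split, truth)
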