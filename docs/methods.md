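# Methods

This note documents the models and procedures implemented in `sauroncp`,
the defaults and numerical conventions chosen where the design was open,
and what the synthetic-data experiments do and do not demonstrate.

## Simultaneous regression + classification forest

### Model

Input is a feature matrix `X ∈ R^{N×P}`, a continuous response `y ∈ R^N`
and a discrete response `d` over `k ≥ 2` classes obtained by thresholding
`y` at `k−1` ordered thresholds. Class conventions follow drug-sensitivity
usage: binary resistant = 0 / sensitive = 1; ternary sensitive = 1,
ambiguous = 2, resistant = 3; sensitivity corresponds to *low* response.

Sample weights counteract class imbalance:

* *simple*: weight 1 for the modal (relative-majority) class, `N_mode/N_c`
  for class `c`, so each class carries equal total weight;
* *linear*/*quadratic* (`g = 1, 2`): `w_i* = dist_i^g / (k · Σ_{n∈class}
  dist_n^g)` where `dist_i` is the distance of `y_i` to the class's
  neighbouring threshold (outer classes) or the sum of the distances to
  both neighbouring thresholds (interior classes). Samples lying exactly
  on their threshold receive weight 0 with a warning.

`B` trees are grown on bootstraps of size `N`. At each node, `m` features
are drawn without replacement and the best split maximizes the improvement
in `w*`-weighted mean squared error; the weights deliberately shape the
trees, not only the leaf averages. A node becomes a leaf when it cannot be
split into children of at least `min_leaf` members or has zero weighted
response variance. Tree growth delegates to scikit-learn's CART regressor
(`sample_weight = w*`, `max_features = m`, `min_samples_leaf = min_leaf`),
after which the structure is copied into plain arrays; prediction,
serialization and deserialization never touch scikit-learn, and routing of
training members and queries uses one float64 traversal.

Per leaf the package stores the normalized weights
`w_n^leaf = w_n*/Σ_{i∈leaf} w_i*` over the bootstrap multiset (duplicates
aggregated onto their original sample id), the weighted mean response, and
the modal class of the leaf members (ties to the lowest class code). A
tree predicts its leaf's weighted mean and votes its leaf's mode. The
forest classifies by plurality vote (ties to the lowest class code) with
vote proportions as its certainty notion, and predicts

    f̂(x) = Σ_b w_b(x) f̂_b(x),
    w_b(x) = 1/B                    if the vote is the training modal class,
    w_b(x) = I_b(x)/Σ_β I_β(x)      otherwise,

where `I_b(x)` indicates agreement of tree `b` with the forest vote. In
the multi-class setting "modal" means the training modal class; any
predicted non-modal class triggers the agreeing-trees weighting (the
binary rule generalized).

### Quantile extension

The identical prediction rewritten over training samples,
`f̂(x) = Σ_i w_i(x) y_i` with
`w_i(x) = Σ_b w_b(x) · 1{i ∈ leaf_b(x)} · w_i^{leaf_b}`, yields the
conditional-distribution estimate `F̂(y|x) = Σ_i w_i(x) 1{y_i ≤ y}` and
quantiles `Q̂_α(x) = min{y : F̂(y|x) ≥ α}` on the training support. All
three weight families (leaf, tree, forest-wide) sum to 1 by construction;
the test suite asserts this to 1e-10 and the algebraic identity of the two
prediction forms to 1e-8. CDF inversion uses a 1e-12 slack on the `≥`
comparison to absorb float accumulation.

### Defaults

`B = 100`, `m = ⌈P/3⌉`, `min_leaf = 5` (regression-forest convention;
configurable). A single top-level seed derives per-tree bootstrap and
split streams via `SeedSequence.spawn`, so fitting and prediction are
bit-reproducible, and models serialized to the JSON text format reload
bit-exactly (Python float round-trip).

## Conformal prediction

Split CP with calibration threshold `q̂` = the `k`-th smallest calibration
score, `k = ⌈(N_cal+1)(1−α)⌉` (an epsilon of 1e-9 guards the ceiling
against float fuzz such as `10 × 0.9 → 9.000…2`). When `k > N_cal`, `q̂ =
+∞` (full sets / unbounded intervals); when `k ≤ 0`, `q̂ = −∞` — the
standard finite-sample sentinels, logged via warnings for Mondrian classes
absent from calibration. All scores are oriented as uncertainty.

* True-class sets may be empty; empty sets are reported as such (they
  count against efficiency, never as covering).
* Summation sets take the top classes of the descending-sorted vote list
  until the cumulative mass reaches `q̂`; the supremum over an empty index
  set is 0, so the top class is always included. Probability ties sort by
  ascending class code; no smoothed (randomized) variant is implemented.
* Mondrian calibrates the True-class score per true class and guarantees
  class-conditional coverage.
* The Quantile score conformalizes `[Q̂_{α/2}, Q̂_{1−α/2}]`; negative `q̂`
  narrows the interval and an interval whose bounds cross is flagged
  degenerate (width 0, covers nothing) rather than silently swapped.

Coverage diagnostics report marginal and per-true-class coverage,
efficiency (fraction of single-class sets) and mean interval width
relative to the spanned training response range.

A subtlety worth recording: the finite-sample *upper* coverage bound
`1−α + 1/(N_cal+1)` assumes almost-surely distinct scores. Tree-vote
scores are discrete (B+1 atoms), so True-class sets are marginally
conservative; over 200 simulated splits at `N_cal = 300` the measured mean
coverage was 90.5% against a band top of 90.3%, an excess within one
Monte-Carlo standard error. The acceptance tests therefore check the band
with a 3-SE tolerance.

## CMax viability

Per (drug, cell line) pair a monotone two-parameter logistic on log10
concentration, `v(c) = 1/(1 + exp(h (log10 c − log10 ec50)))` with `h ≥ 0`,
is least-squares fitted to the raw points (≥ 3 distinct concentrations
required; replicates enter individually; constant inputs fall back to a
flat curve). The curve is pluggable: any monotone model exposing
`viability(concentration)` can stand in. Evaluation at the CMax
concentration is clipped to [0, 1]; CMax concentrations outside the tested
range are extrapolated and flagged.

Pooled viabilities of all drugs are discretized together. The k-medoids
(PAM) objective is solved *exactly* by dynamic programming over contiguous
segments — in one dimension the optimal clusters are contiguous in sorted
order — which is deterministic and globally optimal, whereas the classical
BUILD+SWAP heuristic can stall in local optima (observed on a 12-point
fixture). Thresholds are midpoints between the maximum of each lower
cluster and the minimum of the next (`threshold_rule="boundary"`,
default); midpoints between adjacent medoids are available as
`"medoid"`. Values exactly on a threshold map to the more sensitive
class. Drugs whose labels are single-class, or with fewer than
`min_per_class = 3` samples of any present class in any partition, are
dropped with an audited reason.

## Prioritization

Effective drugs for a cell line are those with CP set exactly
`{sensitive}`; they are ranked ascendingly by upper CP interval limit with
ties broken by point value, then drug id. Evaluation reports list
precision, whether the truly most efficient (lowest-viability) drug is
listed, the rank of the predicted first drug within the true
ascending-viability ordering of the analyzed panel, whether it is a true
positive, and its viability gap to the true best. Empty lists yield
*undefined* (NaN) evaluations, excluded from aggregate medians and counted
separately, to avoid biasing the medians toward zero.

## Synthetic data

The generators emulate the structure the method assumes, not any specific
assay's artifacts:

* `make_regression_classification`: iid standard-normal features, a sparse
  unit-variance linear signal on `n_informative = 5` of `P = 20` features,
  Gaussian noise `0.5` (signal-to-noise 4:1), labels by thresholding the
  observed response at the quantiles matching the class fractions (default
  30% sensitive / 70% resistant, mirroring screen imbalance) — the same
  construction as the real pipeline, where labels derive from the observed
  response.
* `make_dose_response_panel`: logistic curves with per-pair midpoints
  inside the tested range (9 log-spaced doses, 1 nM – 10 µM) and Hill
  slopes in [0.8, 2.5]; triplicate points with 3% Gaussian assay noise (a
  realistic luminescence-assay noise floor under which per-pair CMax
  viabilities are recoverable to a few percent); 10% of drugs get CMax
  outside the tested range to exercise the extrapolation flag; true
  viabilities are analytic.
* `make_shared_panel`: one cohort, one 70/15/15 train/calibration/test
  split shared by all drugs; per-drug sparse signals squashed to
  viability-like values in (0, 1) with a global threshold 0.5.

A master seed feeds per-stage, per-drug `SeedSequence` spawn keys, so
adding drugs leaves existing drugs' data untouched. Because features are
Gaussian and signals linear, passing coverage and recovery tests
demonstrates correctness of the algorithms under exchangeability — not
performance on real expression data with batch effects, correlated genes
or heteroscedastic assay noise.

## Problem sizes

The coverage experiments use N = 2000 samples, P = 20 features, B = 100
trees and 50 independent seeds (≈ 3 minutes on one CPU); Mondrian
class-conditional coverage uses 25 seeds of a 9:1 imbalanced task; oracle
equivalences run at N ≤ 50, B ≤ 10 where brute-force recomputation is
exact. These sizes give Monte-Carlo standard errors of ~0.3 percentage
points on coverage means.

## Known limitations

* Coverage guarantees assume exchangeability; covariate shift between
  screens or cohorts voids them (shift-aware CP is out of scope).
* Quantile estimates are supported on training response values only, so
  extreme quantiles saturate at the observed range.
* The dose-response model is a two-parameter logistic with fixed asymptotes
  1 and 0; partial responders (upper asymptote < 1) are approximated.
* Mondrian thresholds for classes with very few calibration samples
  saturate at `+∞` (always included) rather than failing.
* Very large pooled viability sets make the exact k-medoids dynamic
  program quadratic in the number of *distinct* values; at drug-panel
  scales (≤ tens of thousands of pairs) this is a few seconds.
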