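# sauroncp

Reliable anti-cancer drug-sensitivity prediction and prioritization:
simultaneous regression + classification random forests (SAURON-RF) with a
quantile-regression extension, split conformal prediction with
user-specified certainty guarantees, the CMax-viability drug-sensitivity
measure, and a cell-line-centric drug-prioritization pipeline.

## The problem

Machine-learning models that predict how strongly a cancer sample responds
to a drug usually return *point* predictions — a class (sensitive /
resistant) or a continuous response value — with no statement about how much
an individual prediction can be trusted. For medical decision support that
is not enough: one needs predictions with explicit, finite-sample certainty
guarantees, and a response measure that allows *drugs* to be compared for
one sample, not only samples for one drug. This package is for
computational pharmacogenomics practitioners working with cell-line drug
screens (expression features, dose-response viability data) who want both.

## What is inside

**SAURON-RF.** A regression random forest whose leaves also carry the
discrete class labels of their training members. Class imbalance is
countered by sample weights `w*` — either `N_mode / N_c` per class
(*simple*) or threshold-distance-based (*linear* / *quadratic*) — that are
propagated through the split criterion and the leaf averages. Each tree `b`
predicts `f̂_b(x) = Σ_{n∈leaf} w_n^leaf · y_n` and votes with its leaf's
modal class; the forest classifies by plurality vote and predicts

`f̂(x) = Σ_b w_b(x) · f̂_b(x)`,

where `w_b(x) = 1/B` if the vote is the training modal class and otherwise
averages only the agreeing trees. Rewriting `f̂(x) = Σ_i w_i(x) · y_i` as a
weighted sum over training samples yields an estimate of the conditional
distribution `F̂(y|x) = Σ_i w_i(x) · 1{y_i ≤ y}` and hence conditional
quantiles `Q̂_α(x)` (quantile-regression-forest style).

**Conformal prediction.** Given disjoint train / calibration / test sets
and a maximal error rate α, a nonconformity score is computed on the
calibration set and thresholded at `q̂`, the `⌈(N_cal+1)(1−α)⌉ / N_cal`
quantile. Sets `{c : s(x, c) ≤ q̂}` (classification) and intervals
`[Q̂_{α/2}(x) − q̂, Q̂_{1−α/2}(x) + q̂]` (regression) then contain the truth
with probability in `[1−α, 1−α + 1/(N_cal+1)]` under exchangeability.
Scores: **True-class** `1 − P(c|x)`, **Summation** (cumulative vote mass
down the descending-sorted classes), **Mondrian** (True-class calibrated
per true class, giving class-conditional coverage), and **Quantile**
`max(Q̂_{α/2} − y, y − Q̂_{1−α/2})`.

**CMax viability.** The fraction of viable cells at a drug's CMax
concentration (peak plasma concentration at the highest clinically
recommended dose), read off a monotone logistic dose-response curve fitted
per (drug, cell line) pair. It lives in [0, 1] for every drug, so pooled
values can be discretized by one k-medoids threshold set (sensitive = 1 /
resistant = 0, or sensitive / ambiguous / resistant) applied to all drugs.

**Prioritization.** For one cell line, keep drugs whose CP set is exactly
`{sensitive}` and rank them ascendingly by the upper CP interval limit — a
viability value unlikely to be exceeded.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_conformal_prediction.py` prints

```
alpha = 0.1: sets/intervals cover ~90% of test truths on average over splits (a single split fluctuates by a few percent)
  tc        coverage 0.853  efficiency 0.95
  sum       coverage 1.000  efficiency 0.01
  mondrian  coverage 0.807  efficiency 1.00
  quantile  coverage 0.927  relative width 0.34
example test sample S00415: TC set {0}, interval [-0.52, +2.36]
```

Coverage is the fraction of test samples whose true class/value falls in
the CP set/interval; efficiency is the fraction of single-class sets (the
Summation score covers trivially by emitting two-class sets). Running
`python examples/04_prioritization.py` ranks effective drugs per test cell
line and aggregates:

```
across 45 test cell lines (43 with a non-empty list):
  median precision of the list: 1.00
  most efficient drug in list:  0.88
  median true rank of 1st drug: 2.0
  viability gap < 0.1:          0.70
```

so here every listed drug is truly sensitive for at least half the cell
lines, and the top-ranked drug's true viability is within 0.1 of the best
drug's for 70% of cell lines.

The same pipelines are scriptable from a shell via the `sauroncp` command
(`simulate`, `discretize`, `train`, `calibrate`, `predict`, `prioritize`,
`evaluate`); every stage reads and writes delimited text and serialized
models reload bit-exactly.

## Documentation

See `docs/methods.md` for the model details, numerical conventions,
defaults and known limitations.
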