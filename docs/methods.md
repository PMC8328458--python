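# Methods

## Model and assumptions

The package evaluates binary scorers on *positive-unlabeled* test sets.
A site has true occurrence y ∈ {0, 1}; a labeled site (s = 1) is always
a true presence; an unlabeled site (s = 0) may be either. Everything
rests on two assumptions:

1. **Uniform labeling.** Labeled presences are a uniform random
   subsample of presences — selection does not depend on the score.
   Then c = P(s=1 | y=1) is a single constant, recall estimated from
   labeled presences is unbiased (r′ = r), and the naive precision p′
   relates to the true precision p by
   p = (1−c)/c · p′/(1−p′) (case-control) or p = p′/c
   (single-training-set).
2. **A known sampling scenario.** *Case-control*: labeled presences are
   drawn from the presence stratum and unlabeled ("background") sites
   from the whole population; population quantities are then estimable
   from the unlabeled margin only, and c = n1/(n1 + n0·P(y=1)).
   *Single-training-set*: one random site sample in which each presence
   is detected with probability c; the whole sample is representative
   and c = n1/(t·P(y=1)).

The identities are exact at the confusion-table level only when the
labeled presences are rank-balanced with the unlabeled ones
(m1·m5 = m2·m4, equivalently r′ = r at that threshold) — true in
expectation under assumption 1, and exactly true on the balanced tables
the identity tests construct. On finite samples the per-threshold
deviation of r′ from r behaves like a correlated random walk along the
curve and is the dominant noise source in calibrated curves.

A consequence worth noting: p′ ≤ p at *every* threshold is guaranteed
only for c ≤ 1/2 (then (1−c)/c ≥ 1). For c > 1/2 the naive precision
can exceed the true precision at thresholds where p is small, even in
the population.

## Curve construction

A site is predicted present iff score ≥ threshold; thresholds are the
distinct observed scores in decreasing order (+∞ anchors the
all-negative prediction), and tied scores form one block. ROC curves
are anchored at (0,0) and (1,1); PR curves drop thresholds with no
predicted positives and extend the first defined precision to r = 0.
AUC integrates over the x axis after a stable sort; vertical runs
(duplicate x) contribute nothing, which makes the PA ROC area equal the
midrank Mann–Whitney statistic exactly, ties included. PR areas default
to the trapezoid; a step rule (each segment contributes the precision
at its right end, as in average precision) is available because the two
differ noticeably at small n and the literature is not uniform about
the choice.

Calibration replaces p′ by the corrected precision (PR) or recomputes
FPR from the corrected precision, the per-threshold predicted-positive
fraction and the prevalence (ROC). The predicted-positive fraction is
taken per threshold — (k1−m1)/n0 under case-control, k1/t under
single-training-set — never as one global value. Numerically, the
calibrated FPR is evaluated as a single integer-combination numerator
over a constant denominator, e.g. ((k1−m1) − m1(1−c)/c)/(n0(1−prev)),
so thresholds whose exact FPR coincides stay bitwise identical and
vertical runs survive the sort.

**Clipping.** Corrected precisions and FPRs can leave [0, 1] through
sampling noise or a mis-specified c. They are clipped and flagged, and
flag counts propagate to curve output and logs. Clipping is asymmetric:
at thresholds where the true precision is 1, noise can only be
truncated from above, so the calibrated PR curve is biased slightly
*downward* in the small-count (low recall) region. With 1,000 labeled
presences and 5× background this bias is roughly 0.05–0.10 in
precision below recall ≈ 0.3 and shows up as a ΔAUCPR of about 0.02–0.04
against the presence–absence benchmark; the calibrated ROC curve is
essentially unaffected (ΔAUCROC ~ 0.002) because the effect is diluted
by the true-negative mass. Users comparing PR curves at low recall
should expect this.

## Estimating c

`estimate_c` averages the naive precisions that fall inside a
percentile window of the p′ multiset — one value per distinct
threshold, linear-interpolation percentiles, inclusive bounds. The
default window (90th–99th) excludes the extreme top of the curve,
where tiny predicted-positive counts make p′ erratic, while staying in
the region where a well-discriminating model has p ≈ 1 and hence
p′ ≈ c. Diagnostics always report j (points averaged), the window
bounds, p′max and the spread of the selected values; a c estimate
without its j and spread is not interpretable. For weakly
discriminating models the assumption p ≈ 1 inside the window fails;
`max_fpr` restricts the multiset to thresholds with naive FPR below a
cutoff, which is the appropriate remedy *when such points exist* (see
limitations). Estimates feed `prevalence_from_c` to give a prevalence
estimate under either scenario.

When several candidate models are available, estimate c from the model
with the highest naive AUC — the naive ranking is generally
order-preserving even though the absolute values are biased.

## The virtual-species simulator

The simulator provides exact ground truth: a known occurrence
probability per cell, its Bernoulli realization, and samplers for both
scenarios that retain the hidden labels so that every naive and
calibrated quantity can be checked against the truth.

* **Environmental fields.** Three synthetic covariate layers on a
  square grid: Gaussian white noise smoothed at correlation lengths of
  6, 12 and 3 cells, restandardized, then shifted/scaled to means
  (0, 0.4, 0.2) and spreads (1.0, 0.4, 0.15). They emulate standardized
  climate/terrain layers with heterogeneous spatial structure. The
  scales were chosen once so that the five packaged coefficient sets
  produce realized prevalences from about 0.06 to 0.87 with usable
  discrimination (population AUC ≳ 0.9, ≈ 0.97 for `spec1`); realized
  prevalence is always computed from the surface, never assumed, since
  the same coefficients give different prevalences on different fields.
* **Species.** `spec1`…`spec5` are logistic occurrence models — linear
  or centered-quadratic in the three covariates — shipped as a YAML
  fixture; custom YAML files use the same layout. Quadratic models
  center on the field means unless explicit means are given.
* **Samplers.** Case-control: n1 labeled presences drawn without
  replacement from presence cells, round(bg_ratio·n1) background cells
  from all cells (without replacement when the grid allows; flagged in
  `meta` otherwise). Single-training-set: t cells without replacement,
  presences labeled independently with the detection probability. Both
  record the population-implied c and the realized in-set c; oracle
  comparisons use the realized value, for which the correction
  identities are exact. All samplers take explicit seeds and are
  bit-reproducible.
* **Degradation.** `degrade_model` swaps P(y=1|x) with 1 − P(y=1|x) at
  a uniformly random fraction of cells; a 40% swap takes a ~0.97-AUC
  scorer to the ~0.6 neighborhood, and a 100% swap inverts the ranking
  (AUC → 1 − AUC).

**What the simulator does not emulate.** Real covariates with
physically bounded, spatially correlated gradients; classifier training
(scores are the true or degraded conditional probabilities — the
evaluation method is agnostic to the scorer); landscape geometry.
Passing tests therefore demonstrate the statistical machinery under the
stated sampling assumptions, not robustness to violations of uniform
labeling or to classifier artifacts.

## Known limitations

* **Degraded scorers on saturated surfaces.** The smooth-field logistic
  surfaces saturate: most cells have p very near 0 or 1. After a
  uniform probability swap, the swapped absences (score 1 − p with
  p ≈ 0) outrank every genuine presence, so the top of the ranking
  carries no presence enrichment at any swap fraction ≥ ~10%: there is
  no high-p′ plateau and no near-zero-FPR region, and the
  percentile-window estimate of c collapses (relative errors of tens of
  percent) rather than degrading gracefully. The `max_fpr` remedy is
  inapplicable because the points it would select do not exist. This is
  a property of the degradation operator interacting with a saturated
  score distribution, not of the estimator's small-sample behavior; on
  less saturated score distributions a weak model can still yield
  usable estimates.
* The calibrated PR curve's low-recall clipping bias described above.
* c = 0 is rejected outright (nothing is estimable without labeled
  data); prevalence = 1 makes FPR undefined and is rejected in the ROC
  path.
* Percentile-window conventions (inclusive bounds, one p′ per
  threshold, linear interpolation) are stated choices; other
  conventions shift c_hat at the margin when j is small.

## Problem sizes used in the test suite

Simulation-backed tests run on one realized 100,000-cell map of
`spec1` (prevalence ≈ 0.125). Curve-agreement checks average ten
case-control draws of 6,000 records; estimator-recovery checks use 20
draws; the size-consistency check spans n1 = 100 to 5,000. The full
suite completes in a few seconds on one CPU.
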