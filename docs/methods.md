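# Methods

## Model and procedure

The classifier is an ensemble of RBF-kernel SVMs over pairwise Pearson
functional-connectivity (FC) features. For a parcellation with R regions,
a subject's feature vector has d = R(R−1)/2 entries; entry k is the
correlation of the two region signals given by the fixed row-major
upper-triangle pair ordering (0,1), (0,2), …, (1,2), … — index 0 is
always pair (0,1). Raw r is used: no Fisher z-transform, and no feature
standardisation by default (features already live in [−1, 1]); a config
switch enables per-feature z-scoring fit on the train+validation subjects
only.

Subjects are split 3:1 (train+validation vs test), stratified by class;
each base classifier then draws a fresh 2:1 train/validation partition of
the pool and m features uniformly without replacement from the active
feature pool. The per-member redraw is deliberate — it is what makes the
ensemble "random" over samples — and can be switched off by fixing the
inner split externally. Subject sampling is a partition (without
replacement), not a bootstrap. A member's weight W_l is its validation
accuracy; weak members (W_l < 0.5, strict) still vote at test time — the
vote is weighted, never censored.

One *evolution* accumulates, per feature, the total weight over the weak
members that sampled it (Tw_j), removes every feature with Tw_j > q
(strict), and rebuilds the ensemble from the reduced pool; removed
features never re-enter. The update is subtractive (pool minus the
over-threshold set) rather than "keep strong members' features": the
subtractive rule shrinks the pool gradually over tens of generations,
which matches the roughly linear pool decline this family of methods
exhibits at full scale, whereas the union rule would collapse the pool in
one or two generations. The generation with the highest held-out accuracy
is *optimal*; its surviving pool (configurably, the union of features its
members actually drew) is the optimal feature set. Region ranking counts,
for each region, the optimal features having it as an endpoint (so the
frequencies sum to exactly twice the optimal-set size), descending, ties
by region ordinal.

## Parameters

| parameter | default | meaning |
|---|---|---|
| n_members | 500 | base classifiers per generation |
| m | 62 | features per member (≈ √4005 at AAL-90 scale) |
| σ | 3 | RBF bandwidth, K(u,v) = exp(−‖u−v‖²/2σ²), i.e. γ = 1/2σ² |
| C | 10⁶ | SVM penalty; a large finite stand-in for a hard margin, which is numerically fragile |
| q | 7 | pruning threshold on Tw_j (full-scale default; see scaling below) |
| n_evolutions | 50 | pruning/rebuild iterations after generation 0 |
| outer / inner ratio | 3:1 / 2:1 | subject split ratios, nearest-integer rounded, both parts non-empty |

The bandwidth convention matters: "σ = 3" is realised as γ = 1/(2σ²) ≈
0.056. Split sizes round to the nearest integer with every part forced
non-empty, and stratification additionally bumps per-class counts so both
classes appear in every part (so a 2+2-subject cohort splits 2/2, not
3/1).

### Scaling q to the problem size

The expected total weight of an uninformative feature is roughly
p·m/|pool|·W̄_weak, where p is the weak-member count — about 250·62/4005·0.45
≈ 1.7 at the full AAL-90 scale, which is what makes q = 7 a meaningful
tail threshold there. At the desk scale used throughout the tests
(n = 100 members, m = 14, d = 190) that expectation is ~20× smaller and
q = 7 would never prune anything. The desk-scale studies therefore use
q = 0.3 (a feature is dropped as soon as the weak members leaning on it
accumulate more than 0.3 total weight) with up to 60 evolutions; the loop
stops early, with a logged reason, when fewer than m features remain or
pruning empties the pool.

## Selection of the optimal generation

Selecting the optimal generation on the test set follows the protocol the
full-scale defaults encode, but is optimistically biased — the test set has then been used
for model selection, and the reported optimal accuracy inherits a
max-of-generations bias (under a pure null with a 15-subject test set,
the max over six generations sits near 0.6, not 0.5). The package
documents this prominently: `selection="holdout"` carves a separate
selection split out of the test part so the final test set is never
selected on, and any chance-level calibration should be read from the
unselected per-generation accuracies, not the selected maximum.

Ties in the per-generation accuracy go to the earliest generation by
default. When accuracy saturates — which the strong-signal synthetic
regime provokes by design — every generation ties at the ceiling and
"earliest" degenerates to generation 0, i.e. no feature selection at all.
`tie_break="parsimonious"` instead takes, among the accuracy-maximal
generations, the one with the smallest surviving pool (earliest among
equal pools): among equally accurate models, prefer the one needing the
fewest features. The synthetic study conditions use this option; the
default remains "earliest".

## The synthetic-data generator

Each subject's T×R series is drawn i.i.d. over time from a zero-mean
multivariate Gaussian. Class −1 is the reference: correlation ρ₀
(default 0.1) between every region pair. Class +1 adds an effect Δ
(default 0.4) on a planted set of pairs only — by default 8 pairs
concentrated on 6 regions. The planted regions (ordinals 2, 5, 9, 11,
14, 18 at R = 20) are deliberately scattered across the ordinal range:
ranking ties break by ordinal, so planting the first six regions would
make "recovery" succeed even on pure noise, and the scattered choice
keeps the recovery score an honest measure. Defaults: 30 subjects per
class, R = 20 (190 features), T = 130 timepoints (a typical 140-volume
resting-state acquisition minus 10 discarded volumes), noise scale 1.

If a requested correlation matrix is not positive definite it is
projected (eigenvalues clipped at 10⁻⁶, diagonal re-normalised) and the
projection is logged. `recovery_score` is the fraction of planted regions
appearing in the top-k of the frequency ranking, k = number of planted
regions.

What the generator does *not* emulate: temporal autocorrelation, scanner
drift, motion and physiological confounds, site effects, or realistic FC
topology (hubs, modules). Pearson correlation is invariant to the
temporal structure omitted here, so the stationary model exercises
exactly the statistical structure the pipeline consumes — passing tests
show the algorithm recovers planted correlation differences under its own
assumptions, not that it is robust to fMRI artefacts. The `noise_scale`
parameter scales signal amplitude without changing correlations, and so
does not change task difficulty; difficulty is governed by Δ, ρ₀, T and
the cohort size.

## Numerical and degenerate-input choices

- Constant region signals make Pearson r undefined: hard error naming the
  region by default; a permissive mode writes 0 for the affected pairs
  with a warning. Silent NaN propagation is never an option.
- Computed correlations are clipped to [−1, 1] to absorb round-off.
- Vote ties: label of the single heaviest member; if the heaviest members
  disagree, +1. Weight comparisons are exact (weights are small rationals
  — counts over validation sets).
- Undefined ratio metrics (empty denominator) raise or report "n/a",
  never 0; the positive class is named in every report.
- Members whose random training part is single-class are discarded and
  redrawn (capped); under stratified inner splits this cannot occur.
- Every removed feature is checked against the implied occurrence bound
  (Tw_j > q with weak weights < 0.5 forces > q/max-weak-weight
  occurrences); a violation is a bookkeeping bug and raises.
- All randomness flows from one master seed through named substreams
  (outer split, per-generation member draws, simulation), so a (dataset,
  config, seed) triple is bit-reproducible, and fitted ensembles persist
  to JSON with their explicit decision state so reloaded ensembles
  predict identically.

## Problem sizes used by the test suite and acceptance script

Statistical checks run R = 20, T = 130, 30 subjects per class, 100
members with m = 14, over 20 seeds (tests) or 10 seeds (acceptance
script): large enough for the planted-signal and null-calibration
properties to be sharp, small enough that the whole suite completes in a
few minutes on one CPU. The full-scale defaults (500 members, m = 62,
q = 7, 50 evolutions) are exercised for correctness through the unit
contracts rather than end-to-end runs.

## Known limitations

- Binary classification only; multiclass voting is out of scope.
- Test-set selection bias of the default protocol (see above) — the
  headline "optimal" accuracy is an optimistic estimate unless
  `selection="holdout"` is used.
- The pruning dynamic stalls once the pool is small enough that nearly
  every member samples informative features (no weak members remain), so
  the pool does not converge to exactly the planted set; a residue of
  uninformative survivors is expected and visible in the recovery scores.
- Region frequencies count pool membership, not member usage or feature
  effect sizes; `optimal_set="drawn"` is the only alternative exposed.
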