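# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical conventions, and the design choices
that were genuinely open.

## Scoring model

Action grades are ordinal symbols `'=' '/' '-' '!' '+' '#'` from worst to
best; the serve scale moves `'/'` to second-best (a half-point serve).
The grade-to-score map is purely empirical: for each (action type, grade)
cell of a historical outcome table, score = 10 × (rallies won)/(rallies
observed). Cells absent from the table are an error rather than an
imputed zero — silent imputation would bias every downstream target. The
map is *expected* to be monotone in the grade order but is not forced to
be: empirical win rates from finite histories can invert, so a
non-monotone map triggers a warning only.

A performance target is the arithmetic mean of the mapped scores of one
player's actions of one type in one match, restricted to
position-relevant pairs (serve/setter; attack/outside hitter, middle
blocker, opposite; block/middle blocker; pass/libero, opposite). Rows
with zero relevant actions are never emitted, so no empty-mean artifacts
exist.

## Predictor construction

Windows are half-open intervals `[match_date − w, match_date)` for
w ∈ {7, 14, 28} days: predictors must be computable strictly before the
match, so match-day activity is excluded by construction (whether pre-match
activity on the match day should count is genuinely ambiguous; exclusion is
the conservative choice and is locked in by a regression test).

Three kinds of base series are distinguished because "no activity" and
"no data" mean different things:

* **count/load series** (daily jump counts per height category, daily
  session load and session counts per category) are 0 on activity-free
  days — an athlete who trained but did not jump genuinely had zero jumps;
* **per-event series** (daily mean jump height; per-set strength weights)
  contribute nothing on days without events — there is no height of a
  jump that did not happen;
* **holiday days** are missing for every variable, including wellness:
  no data were collected at all.

Jump categories use thresholds 50 and 65 cm with the boundary heights
assigned to the middle ("average") category; low is strictly below 50,
high strictly above 65, so the three categories partition all jumps (a
tested invariant: the category sums reproduce the all-jumps count for
every row, aggregate and window).

Strength-weight aggregates operate on the per-set weight observations
within the window, not on daily means: sets are the unit athletes log,
and quartiles of set weights are the natural reading of thresholds like
"first quartile ≥ 90 kg". The sum aggregate exists only for jump counts
and absolute-kg weights; %1-RM values are ratios and their sum has no
physical meaning (this split is also what reproduces the documented
81 = 45 + 12·3 column count).

Load metrics per window and session category (volleyball-specific —
which includes matches, since match exertion is logged the same way —,
strength, and all sessions): load is the sum of daily session loads
(RPE × minutes), monotony is mean/SD of the daily loads including zero
days, strain is load × monotony. Monotony of a constant or single-day
window is undefined and propagates as missing, never as infinity.

Numerical conventions, chosen once so goldens are bit-stable: SD always
uses the n−1 denominator; quartiles use linear interpolation; aggregates
drop missing values pairwise and an all-missing window is missing.

## Synthetic season generator

The generator emulates the season structure the analysis assumes: 24
weeks (5 preparation + 3 competition + 3 holiday + 10 preparation + 3
competition), 17 players covering all five positions (3/5/4/3/2
setters/outside hitters/middle blockers/opposites/liberos), sessions per
player-week drawn from N(6.1, 2.4²) truncated at 0, 31 matches of which
roughly 17 are friendlies placed in the preparation phases, and
per-action match participation calibrated so one season yields about
122/87/58/35 attack/pass/block/serve performance records.

Grades are drawn from per-action categorical distributions; a per-row
latent fluctuation tilts the distribution exponentially (the tilt
parameter is solved by bisection so the expected mapped score moves by
exactly the requested amount). Distributions are calibrated so the
per-action score means and SDs sit near the observed levels for elite
men's volleyball — attack ≈ 6.8 ± 1.7, serve ≈ 3.3 ± 0.9, block ≈ 2.7 ±
1.5, pass ≈ 8.6 ± 0.9 — and the surrogate historical-outcome table is
sampled binomially around the same win probabilities, so the full
scoring path (counts → map → targets) is exercised rather than bypassed.
Jump heights are lognormal (median ≈ 54 cm) so all three height
categories are populated; wellness items follow an AR(1) Likert process
(mean 7, autocorrelation 0.6); strength sessions draw 3–5 exercises from
a six-exercise catalogue with per-player 1-RMs and set weights around
80% of 1-RM.

Two deliberate simplifications matter for interpreting test results:

* **No per-player performance baseline.** Within an action type, targets
  are exchangeable across rows. This is what makes swap randomization an
  exact null on generated seasons and is the substrate of the
  false-discovery calibration test. Real data are player-clustered; if
  players differ systematically in both performance and training
  features, target permutation can be anti-conservative. This is a
  limitation of the swap-randomization design itself, not of the
  implementation, and the generator exposes it honestly rather than
  hiding it under a random effect the method cannot absorb.
* **No built-in feature–target coupling.** Null seasons carry no
  association between predictors and targets beyond sampling noise;
  signal exists only where `plant_effects` injects it, by re-drawing the
  grades of rows satisfying a feature condition with a tilted
  distribution (so planted data still flow through the scoring path).
  Planting warns when the condition covers <10% or >90% of rows — such
  effects are unrecoverable by design, because the search only considers
  subgroups in that size range.

What passing tests on these seasons show: the machinery (scoring,
windowing, search, null calibration, model protocol) is correct at the
study's scale. What they cannot show: that real training-load features
carry the cross-correlation structure of real seasons, or that effect
sizes found in real data transfer.

## Model evaluation protocol

The 70/30 split stratifies on action type crossed with within-action
target quartile (continuous targets have no canonical strata; quartiles
are the standard reproducible choice). The near-zero-variance filter
drops training columns with a single value, or with most-common /
second-most-common frequency ratio above 19 while distinct values are
fewer than 10% of rows — the convention of the dominant preprocessing
toolkit, stated explicitly for reproducibility. The same retained set is
applied to test data.

Reference hyperparameters: random forest with 500 trees, 10 candidate
features per split, minimum node size 5, variance split rule; XGBoost
with 50 rounds of depth-1 trees, learning rate 0.3, gamma 0. The tuning
grids are small neighbourhoods of these values (the original tuned
values are known; the grids are not), searched by 10-fold CV on mean
absolute error; a single-point grid skips the search.

MAE is reported with a 95% t-interval over per-row absolute errors; each
model is compared with the naive baseline by a paired t-test on per-row
absolute-error differences and Cohen's d of those paired differences
(d = mean/SD of differences, CI via d ± 1.96·√(1/n + d²/2n)). When
paired differences have zero variance (e.g. a model identical to the
baseline) the t-test is reported as not applicable rather than p = 0,
avoiding spurious significance. Effect-size labels: negligible < 0.20 ≤
small < 0.50 ≤ medium < 0.80 ≤ large.

## Subgroup discovery

The search space is every condition `feature ≥ t` or `feature ≤ t` with
t an observed value and subgroup size within [10%, 90%] of the action
type's rows — exhaustive for single numeric conditions, which is what
allows an independent brute-force oracle to verify the vectorised
implementation exactly. Rows with a missing feature value never satisfy
a condition on that feature, while the whole-collection mean and SD in
the z-quality always cover all rows. The z denominator is the
whole-collection SD (the standard z-score quality for numeric-target
subgroup discovery; the subgroup's own SD would reward small noisy
groups). Results are collapsed to the best threshold per (feature,
operator) before ranking, since neighbouring thresholds describe
essentially the same subgroup.

The null distribution permutes the target column only, keeping the
feature matrix — hence the candidate set — fixed, re-runs the full
search and records the maximum |z|; this adjusts the false-discovery
probability for the entire multiple-testing burden of the search. The
add-one estimator (1 + hits)/(runs + 1) never returns exactly zero.
Cohen's d is reported as a magnitude between subgroup and complement
(direction is carried by the z sign), with the complement rather than
the whole collection as the comparison group so the two groups are
disjoint.

A consequence of exhaustive observed-value enumeration worth knowing:
with ~240 predictors the null maximum |z| at n ≈ 120 concentrates around
3.1–3.7, so only subgroups whose |z| clears that bar can ever be
significant. A mean shift of 1.5 score units on a quarter of the rows of
a target with SD 1.7 sits right at this bar (z ≈ 3.5–3.7) and is
therefore detected in only about half of generated seasons; the same
shift on a low-variance target such as passes (SD ≈ 0.9) clears it
comfortably. Shrinking the candidate family (e.g. equal-frequency
threshold binning, as some subgroup-discovery toolchains do by default)
would lighten the null and raise power at the cost of threshold
resolution; exhaustive enumeration was kept because it is the choice the
oracle-equivalence guarantee depends on.

## Pipeline

A single user seed drives every stochastic stage through
`crc32(stage name) XOR seed` (below 2³¹), so one flag reproduces the
whole run; each run writes its resolved configuration and a config hash
next to its outputs. Stage failures raise errors naming the stage, with
earlier artifacts preserved. Report tables mirror the structure of the
analysis: per-action score distributions, model comparison, significant
subgroups per action (with an explicit "No significant results" row
where the search found none).

## Problem sizes used by the test suite

Unit and property tests run on handcrafted seasons of a few dozen days
or matrices of ≤ 50 rows. The statistical acceptance tests use full-size
seasons: false-discovery calibration over 100 generated seasons with 200
swap runs per action type; planted-effect recovery over 20 seasons at
the attack scale (n ≈ 122) and 20 at the serve scale (n = 35), 200 swap
runs each; the model-ordering check on one planted-signal season with
the reference hyperparameters. The acceptance script uses the full 1000
swap runs per action type.
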