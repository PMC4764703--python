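# Methods

## The abbreviation objective

A candidate short form is a binary mask over the instrument's items.
Its cost is

    cost(mask) = I·k + Σᵢ wᵢ (1 − Rᵢ²)

- `I` — fixed cost per retained item (default **0.05**). Raising `I`
  shortens the measure; lowering it favours explained variance.
- `k` — total number of retained items.
- `wᵢ` — per-subscale weight (default **1**, equal weighting).
- `Rᵢ²` — in-sample OLS R² (intercept included) of subscale *i*'s
  long-form score on retained item scores. The long-form target is the
  keyed **mean** of all of the subscale's items, computed once per
  dataset. Mean scoring (not sum) is the default throughout because it
  keeps long and short forms on the same response metric, which is what
  makes their subscale means directly comparable; sum scoring is
  available as an option.

By default each subscale is regressed only on its **own** retained
items. The alternative — regressing on all retained items — is
available (`regression_mode="all"`), but own-subscale regression is the
default because it is what gives the per-subscale retention cap `k_max`
its meaning: every subscale must be predictable from its own surviving
items. Reverse-keyed items are recoded (`min + max − response`) before
any regression, correlation or reliability computation.

R² values are computed from precomputed covariance blocks of
`[items | targets]`: the R² of any item subset reduces to solving a
linear system no larger than the subscale, so fitness evaluation cost is
independent of the number of respondents. Rank-deficient predictor sets
(duplicated or collinear items) use the minimum-norm least-squares
solution, which leaves R² well defined. Computed R² is clipped to
[0, 1] against floating-point overshoot.

## The evolutionary loop

Generational binary GA, fully reproducible from a single integer seed:

- **Initialization**: independent Bernoulli(0.5) bits, then repair.
- **Selection**: linear-rank (probability proportional to fitness rank),
  robust to the scale of the cost.
- **Crossover**: single-point on the bit-string, probability 0.8 per
  pair.
- **Mutation**: independent per-bit flips, probability 0.1.
- **Elitism**: the top 5% of each generation survives unchanged, which
  makes the best-cost history non-increasing.
- **Constraint handling**: *repair* — any subscale exceeding `k_max`
  retained items has random excess items deselected after every
  variation step. Repair (rather than a penalty) guarantees every
  evaluated individual is feasible, so the reported optimum never needs
  post-hoc fixing.
- **Termination**: fixed generation budget (default 200). No early
  stopping by default; an optional stall-based stop exists but is off.
- **Ties**: a new generation replaces the incumbent best only on a
  strict improvement, so the first mask attaining the minimum is
  reported — determinism under reruns.

Defaults (item cost 0.05, population 200, 200 generations, `k_max` 5,
crossover 0.8, mutation 0.1, elite 5%) are the standard settings for
GA scale abbreviation of a ~60-item six-subscale instrument.

`exhaustive_search` enumerates every feasible mask (guarded to ≤ 20
items), exploiting the fact that with own-subscale regression the cost
is additive over subscales; ties are broken by fewer items, then
lexicographic mask order. It exists as a ground-truth oracle: on random
small instances the best of three seeded GA runs attains its optimum.

## Consensus across runs

Because the GA is stochastic — and because multiply imputed copies of a
planned-missing matrix each yield a slightly different solution — the
final short form is built by selection-frequency ranking: count the runs
retaining each item, sort within subscale, keep the top *k*. Ties at
the cut are broken deterministically: (1) higher mean absolute
corrected item-total correlation with the item's own subscale across the
supplied datasets, (2) original item order; every applied tie-break is
recorded in the report's audit trail. If a subscale has fewer than *k*
ever-selected items, the deficit is filled from never-selected items by
the same item-total criterion, with a warning. Only item *selections*
are pooled across imputations; downstream statistics are computed per
dataset, never pooled by combining rules.

## Synthetic data generator

The generator emulates the target data situation: `s` correlated latent
factors (multivariate normal with a specified correlation matrix), each
item loading on exactly one factor (`latent = a·f + √(1−a²)·e`),
ordinal discretization at ordered thresholds (default: equal-probability
normal quantiles — a graded-threshold model rather than rounding, so
category frequencies are controllable), reverse-keyed items stored in
their raw reflected direction, and criterion variables constructed to
have specified correlations with the factors.

The 62-item preset has six subscales of (11, 11, 11, 10, 9, 10) items
on a 1–6 scale, factor correlations matching a published six-factor
experiential-avoidance solution (range −0.32 to 0.71), loadings drawn
once (seeded) from U[0.45, 0.75], one reverse-keyed item, and two
criterion variables (mental distress, life satisfaction). The planted
oracle instance has 3 subscales × 8 items with loadings 0.8 (five
items) vs 0.1 (three items), so a k = 5 selection has an unambiguous
ground truth.

Planned missingness is matrix sampling: each respondent sees a uniform
random subset of `items_per_respondent` positions out of a survey frame
of `frame_size` items (the instrument occupying the first positions), so
missingness is MCAR by construction; with 60 of 280 frame items shown,
each item is observed for ≈ 21% of respondents.

What the generator does **not** emulate: response styles (acquiescence,
straight-lining), cross-loadings, correlated item uniquenesses, local
dependence, and non-MCAR mechanisms. Tests passing on this generator
therefore demonstrate the machinery's correctness under a clean
measurement model, not robustness to the messiness of real survey data.

### Imputation stand-in

`simple_mi_impute` fits a single multivariate-normal model by EM on the
incomplete matrix (ridge-stabilized, convergence on max parameter change
< 1e-3, hard error with diagnostics if the iteration cap is reached)
and draws each respondent's missing cells from their conditional normal,
rounding and clipping to the response range. This is a deliberately
plain normal-model imputer — it does not bootstrap the EM parameters,
so between-imputation variability reflects only the conditional draws,
understating parameter uncertainty. That is acceptable here because the
GA consumes imputed matrices only as plausible complete datasets; it
would not be acceptable for pooled interval estimation.

## Validation statistics

- **Cronbach's α** from the variance formula on keyed items; listwise
  complete rows by default, a pairwise-covariance option for
  planned-missing data.
- **Average inter-item correlation**: mean over distinct item pairs;
  constant items are excluded with a warning.
- **Correlation tables** are pairwise-complete by default — under
  matrix sampling, listwise deletion would discard almost every
  respondent; cells with < 3 joint observations become NaN with a
  warning.
- **Convergent diagonal**: each subscale's long×short Pearson r. Note
  it is inflated by shared items (the short form is a subset of the long
  form), which is why criterion-correlation agreement is reported
  alongside.
- **MAD summaries**: mean absolute cell difference between two tables.
  `offdiagonal` compares the 15 distinct pairs of two symmetric 6×6
  matrices; `lower_vs_upper` handles the compact presentation that
  prints one form below and the other above the diagonal of a single
  table. Internal computation is full precision; rounding to 2 decimals
  happens only at presentation.
- **Train/test split**: seeded permutation; training size
  `round(fraction·n)` (7884 × 0.75 → 5913/1971).

## Problem sizes used in tests and the acceptance script

Small instances are used throughout so the full pipeline runs
comfortably on a laptop: oracle-equivalence checks use 8–14 items,
150 respondents, population 100 × 100 generations × 3 seeds;
planted-structure recovery uses 25 GA runs (population 80 × 80
generations) on independently simulated n = 2000 datasets, emulating
the one-run-per-imputed-dataset workflow; the 62-item preset examples
use n = 2000 with population 100–200. These sizes were chosen once as
representative desk-scale conditions.

A note on the planted instance: a 0.1-loading item still contributes
its unique variance to the mean-score target, worth ΔR² ≈ 0.047 against
an item cost of 0.05 — individually near-marginal by design. Single GA
runs therefore occasionally retain a poor item; it is the consensus
ranking across runs that separates the planted high-loading items
cleanly (observed: every high-loading item selected more often than any
poor item of its subscale, and 15/15 recovery of the planted set).

## Known limitations

- Own-subscale vs all-items regression changes the optimum when
  subscales are highly correlated; the choice is exposed but the
  exhaustive oracle supports only the own-subscale mode.
- The GA offers no optimality certificate beyond the small-instance
  oracle; for > 20 items the exhaustive check is unavailable by design.
- α assumes essential tau-equivalence; it equals the Spearman–Brown
  value only for standardized exchangeable items (property-tested).
- Confirmatory factor analysis / SEM fitting is intentionally out of
  scope; factor-level comparisons enter only through transcribed
  published tables.
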