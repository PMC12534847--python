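# Methods

## The death distribution

Every index operates on the discrete distribution of ages at death of a
life table's synthetic cohort: point masses at effective ages
`x̃ = x + a_x` with weights `d_x / Σ d_x`. Using `a_x`-adjusted rather than
integer ages avoids a systematic half-year bias in means and in the Gini
numerator. When a table does not supply `a_x`, the package fills the
standard demographic defaults: `a_0 = 0.3` (infant deaths cluster early in
the first year), `a_x = 0.5` for other closed single-year intervals, and
for the open terminal interval the table's own remaining life expectancy at
`ω` when present, else 0.5. All defaults are overridable, because producers'
conventions differ and the indices inherit whatever convention the points
carry.

Life expectancy at birth defaults to the cohort mean `Σ w_i x̃_i`, which is
internally consistent with the distribution the indices see. A table's own
`e_x[0]` can be preferred via `e0_source="table"`; the two disagree exactly
when the producer's within-interval conventions differ from the defaults
above.

## The modal-anchored normalized index

Perfect equality is the whole population dying at the modal age at death.
The mode is the `argmax` of the raw `d_x` column — no smoothing, ties to
the smallest age (deterministic, and conservative in that it favors
detecting an infant mode). The index is

    scale × Σ w_i (x̃_i − M̃)² / D²,   D = max(M̃, ω̃ − M̃)

the mean squared deviation from the modal point divided by its unconstrained
supremum on the support `[0, ω̃]`. Exact algebraic variants (variance about
the mean conditional on the mode, a mode-constrained maximal variance, other
reporting scales) are genuinely open design territory; this construction is
the most direct reading of "actual variance relative to the mode over
maximal possible variance", produces single-digit-to-low-teens values on
realistic schedules, and is isolated behind `HiniConfig` so an alternative
algebra can be swapped in without touching callers.

`ω̃` defaults to the effective age of the table's last (open) interval,
keeping each table self-contained; a fixed global bound (e.g. 110.5) is
available for strict cross-table comparability of the denominator. A table
whose support collapses to one point has an undefined ratio (0/0); the
default policy returns 0 with a warning — the equality limit of the defined
quantity — and an `"error"` policy is available instead.

Because the anchor is the mode, the index is *deliberately* discontinuous
in the underlying mortality parameters: when infancy stops being the most
common age at death the anchor jumps from 0 to an adult age and the index
drops sharply. Relatedly, among populations whose mode is still 0, rising
infant mortality concentrates mass at the anchor and can *lower* the index.
Both behaviors are asserted in the test suite rather than smoothed away.

## Lifespan Gini and Jamison index

The Gini is computed by the exact pairwise formula
`Σ_i Σ_j w_i w_j |x̃_i − x̃_j| / (2μ)`; the test suite keeps an independent
Lorenz-curve trapezoid construction and requires agreement to 1e-9, so the
two derivations guard each other.

The Jamison index is `1 − F(e_0)` with `F` the cumulative share of deaths
before life expectancy. "Before" is strict on the point masses: a
population dying entirely at exactly `e_0` scores a clean 1. For the point
mass sharing `e_0`'s calendar year, its weight enters through a linear ramp
from the mass's own location `x̃` to the end of that year. This choice
makes `F` continuous and nondecreasing in `e_0` (no one-year quantization
artifact when life expectancy crosses an age boundary) while preserving the
strict-before convention at the mass itself. An `e_0` outside the support
is clamped with a warning.

## Synthetic life tables

The generator integrates the Siler hazard
`μ(x) = a1·e^(−b1·x) + c + a3·e^(b3·x)` in closed form over each year of
age, so `q_x` carries no quadrature error and identical parameters give
bit-identical tables (radix 100 000). Survivors to `ω` die in the open
interval with mean time lived `1/μ(ω)`, capped at 5 years, which keeps `e_0`
finite and stable for flat old-age hazards. The two presets are fixed,
realistic anchors: `low-mortality` (a1=0.005, b1=1.0, c=4e-4, a3=2e-5,
b3=0.105, ω=110) gives an adult modal age near 81 and e0 ≈ 74.6;
`high-infant-mortality` (a1=0.5, b1=0.8, c=0.01, a3=5e-5, b3=0.09) forces
the mode to 0 with e0 ≈ 29. Degenerate (single-age) and two-point tables
supply hand-computable oracles and the equality extreme.

What the generator emulates: the gross shape of human mortality — an
infant spike with controllable depth, a background level, an old-age hump —
and therefore every qualitative regime the indices distinguish (infant vs
adult mode, narrow vs wide spread). What it does not emulate: young-adult
excess mortality humps, cohort effects, crisis years, age heaping, or the
statistical estimation error of real life tables. Passing tests therefore
demonstrate correctness of the index arithmetic and pipeline on clean
schedules, not robustness to real-data artifacts.

The multi-country fixture used in the comparative tests builds 236
locations along a smooth mortality gradient (55 of them below the 200 000
population threshold, so the microstate filter retains 181) for the years
1960 and 2021. Problem sizes throughout the suite — 1 000 random
distributions for the dual-oracle Gini check, 100 random matrices for the
screening enumeration, 10 seeds × 500-tree forests on 181×10 matrices —
were chosen to exercise each claim convincingly at desk scale.

## Comparative conventions

Ranks run from 1 = most equal (lowest index value); ties share the minimum
(competition) rank with alphabetical output order. Percentiles are
`100 (N − rank) / N`, emitted unrounded — reporting precision is the
caller's choice, since no single rounding rule is canonical. Income-group
trends are unweighted means over a *fixed* (classification-year) group
membership, so a group's trend reflects changing mortality rather than
countries migrating between groups; both mean index value and mean rank are
emitted because the two can tell different stories. The microstate filter
requires complete metadata coverage and errors on unmatched locations
rather than silently keeping or dropping them.

## Indicator screening and forest importance

Screening keeps indicators whose completeness strictly exceeds 90%, then
walks pairs with |Pearson r| > 0.85 (pairwise-complete observations) in
descending |r|, dropping from each pair the member with more missing
values; an exact missingness tie is resolved by a caller-supplied priority
list (a stand-in for "keep the more general indicator") and is an error
when no ruling exists, never an arbitrary choice. Processing order makes
the procedure deterministic and idempotent; the tests check its output
against a brute-force enumeration of every drop order.

Importance discretizes the inequality index into quantile classes (default
quartiles — "levels of inequality"), trains a random-forest classifier on a
70% stratified split, and measures permutation importance (mean decrease in
accuracy) on the 30% holdout, with the spread over repeats reported.
An accuracy-based importance metric implies classification, which is why the
continuous index is binned rather than regressed. Negative importances are
floored at zero before shares are computed, so shares are nonnegative and
sum to 100. The headline error rate is the holdout misclassification rate;
the forest's classic per-tree out-of-bag error is reported alongside for
transparency. Missing values in surviving indicators get per-column median
imputation — the least-assuming completion a forest needs. Rows are
canonically sorted before splitting, so results are invariant to input row
order and fully reproducible given a seed.

## Known limitations

- Only complete (single-year) life tables are supported; abridged tables,
  table construction from raw counts, and rate smoothing are out of scope.
- The normalized index's exact algebra is one committed choice among
  defensible variants (see above); comparisons against values computed
  under a different variant require matching `HiniConfig` settings.
- Sex-specific analysis is only implicit: a sex-specific table is just
  another location key.
- Forest importances are predictive, not causal, and correlated mortality
  indicators share importance in ways that depend on the screening step.
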