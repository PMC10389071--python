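# Methods

This note records the scientific conventions the package pins down, why
they were chosen, and what the synthetic-data experiments do and do not
establish.

## The task and its data shape

In the modified random-number-generation task each participant produces one
spoken stream of digits 1–10 for about one minute at roughly one digit per
second, under conditions designed to suppress auditory working memory.
Only the digit order survives (recordings are deleted after transcription),
so all analyses operate on ordered integer sequences of variable length
(roughly 40–75 items, group means near 59–62). Every metric therefore comes
with a length-relative normalisation.

## Randomness indices: pinned formulas

The classical indices are reported in the literature without standardised
formulas, so the package fixes one convention each and pins it with oracle
tests:

- **Redundancy** `R = 100(1 − H/log₂10)`,
  `H = log₂n − (1/n)Σ nᵢ log₂ nᵢ` over digit counts; clipped to [0, 100].
- **Evans RNG / RNG2** `100·(Σ n_ij log n_ij)/(Σ mᵢ log mᵢ)` on lag-1 /
  lag-2 digram counts with `0·log 0 ≡ 0`. The index is a ratio of entropy
  terms, hence log-base invariant (property-tested). When every digram
  first member occurs at most once the denominator vanishes and the index
  is reported as missing (NaN), never 0; downstream group tests exclude
  missing values pairwise.
- **NSQ** counts empty cells of the 10×10 lag-1 digram matrix out of the
  maximum 99 (one cell is always occupied).
- **Adjacency** has no wrap-around (10→1 is not a step of +1); combined =
  ascending + descending.
- **TPI** collapses runs of equal values, counts strict interior extrema,
  and divides by the random-series expectation `(2/3)(n−2)` with `n` the
  original length; range [0, 150].
- **r_RF and r_FOD divide by n** ("per sequence length"), so the 19
  relative FOD bins sum to `(n−1)/n`, which matches the published group
  profiles summing to ≈0.99.
- **r_Cf** is the fraction of all unordered position pairs holding the
  same digit (`Cf` divided by its maximum `n/2`); its chance level for 10
  equiprobable digits is 0.1, which is exactly what the published values
  (≈0.099) show.

## Categorical RQA conventions

Recurrence is exact digit match: embedding dimension 1, delay 1, radius 0 —
the canonical parameters for integer category data. The main diagonal is
excluded; no wider Theiler window. Minimum line length is 2 for diagonal
and vertical structures.

Two border conventions matter and are pinned by tests:

- **Vertical lines**: the excluded main-diagonal cell is spliced out of a
  column rather than treated as an interruption, so a constant sequence of
  length n yields one maximal vertical run of n−1 per column and laminarity
  exactly 1.
- **Determinism border correction**: the two corner diagonals of length 1
  can never hold a countable line, so recurrent points on them are removed
  from the determinism denominator. A fully recurrent plot then has
  DET = 1 exactly instead of `1 − 2/(n(n−1))`.

Relative line-length entropy divides the Shannon entropy of the ≥2
diagonal line-length distribution by `log`(number of distinct observed
lengths), and is 0 for degenerate distributions. Measures over empty line
sets are 0. The identity `RR ≡ r_Cf` (both count equal-digit pairs) is
enforced as a cross-module test.

## Moving windows

The 20-second window on a ~60-second task is mapped to items as
`w = max(round(n/3), 5)` because per-item timestamps were not retained and
pacing was ≈1 item/s. Windows advance by 1 item (maximal overlap; the
original step is unreported). Cross-participant alignment is by window
ordinal, since lengths differ; participants whose trajectory is shorter
than an ordinal drop out of that ordinal only. Group contrasts are
descriptive (per-ordinal means and their difference) — no per-window
inferential test is defined.

## Group comparisons

Per feature: Shapiro–Wilk at α = 0.05 in each group; if either group
rejects (or is too small or constant), the two-sided Mann–Whitney U test is
used, otherwise one-way ANOVA. Categorical margins use Pearson chi-square
without continuity correction, which reproduces the published gender-table
p = 0.842 for 30/6 vs 34/6. Raw p-values are the default output —
mirroring the original reporting of ~70 per-feature tests — and that is a
known multiplicity problem, so an optional Benjamini–Hochberg column is
available (`adjust=True`). Note the gate's small-sample behaviour:
Shapiro–Wilk has essentially no power below n ≈ 10, so tiny groups land in
ANOVA unless forced.

## Classifier subset search

The tree is CART (Gini) with the published final hyperparameters
`max_depth=5, max_features=1, min_samples_split=7, min_samples_leaf=1` and
seeded candidate-feature choice (`random_state=1` by default). Every
subset of 1–3 features is scored by leave-one-out accuracy; ranking ties
break toward smaller subsets, then lexicographic names. With
`max_features=1` induction is stochastic, so accuracies — not tree shapes —
are the comparable quantity across implementations.

Two statistical caveats are built into the test suite rather than hidden:

- **Selection optimism**: on label-permuted null data the best of 175
  subsets still reaches ≈0.7–0.9 LOO accuracy. A headline accuracy from an
  exhaustive search needs external validation.
- **LOO majority artifact**: an unsplittable feature degrades to majority
  vote, and with balanced groups leave-one-out then scores exactly 0, not
  0.5.

The hyperparameter grid search that originally produced these settings is
out of scope; the printed final values are fixed defaults. The full
descriptor pool (60 features, ≈36k subsets) runs in tens of minutes on one
CPU; the bounded `"fod"` pool (19 first-order-difference counts, 1,159
subsets, containing the published best subset FOD_8 + FOD_-8) is the
default for scripted runs.

## Synthetic cohort model

A first-order Markov chain: `P(next = j | current = i) ∝
pref_j · kernel_{j−i}`, renormalised over j ∈ 1..10, with fallback to
`pref` alone if all weights vanish; first digit ∝ `pref`; length =
rounded Gaussian truncated at 10. First-order structure is a deliberate
model choice: every analysed descriptor (FOD, digrams, adjacency,
frequencies) is first-order.

**Calibration.** Because steps beyond the digit range are unavailable near
the ends, the chain's realised step marginal is not the kernel (a uniform
kernel yields a triangular marginal `(10−|d|)/100`). Default parameters are
therefore produced by a deterministic fixed-point iteration that picks
kernel and preferences whose model-implied stationary marginals equal the
published group profiles: mean relative FOD (e.g., +1 step ≈ 0.32/0.30 for
the autism/comparison groups), mean relative digit frequencies (digit 1
≈ 0.15, digit 10 ≈ 0.06–0.08), lengths 59/62 with sd = IQR/1.349 from the
published interquartile ranges.

**Tilt gauge.** The transition law is exactly invariant under
`kernel_d → kernel_d e^{λd}`, `pref_j → pref_j e^{−λj}`, so (kernel, pref)
are identified only up to a geometric tilt. Calibration and recovery both
work in the same canonical gauge: the member whose log-preferences have no
linear trend against the (target or observed) digit marginal.

**Between-participant variability.** The published between-participant sd
of the digit frequencies (~0.04) is already explained by multinomial
sampling noise at n ≈ 60, so preferences are shared within a group; the sd
of the +1-step rate (0.09) exceeds its binomial part (≈0.06), so each
participant's kernel is drawn from a Dirichlet centred on the group kernel
with concentration 45, chosen once to close that gap. Set `jitter=None`
for exact parameter-recovery experiments.

**Recovery.** `recover_params` fits the structured model by maximum
likelihood on pooled transition counts plus first digits (L-BFGS on
log-weights), then canonicalises the tilt. It is consistent where the
naive pooled-marginal estimate is biased near the range ends; at the
76 × 60 cohort scale component errors are within ~3 Monte-Carlo standard
errors of the estimator.

**What a green test does not establish.** The generator reproduces
first-order marginal structure and length statistics. It does not model
higher-order habits (cycling through favourite triplets, drifting
strategies over the minute), response timing, or any cognitive mechanism;
windowed trajectories of synthetic data are stationary by construction,
unlike potentially fatiguing humans. Agreement of pipeline outputs on
synthetic cohorts validates the computations, not the psychological claims.

## Numerical choices

- `0·log 0 ≡ 0` throughout; undefined metrics are NaN, excluded pairwise
  downstream.
- Digit validation happens at cohort construction; metric code assumes
  digits in [1, 10].
- All simulation randomness flows through numpy `SeedSequence` spawn keys
  `(group, participant index)`, so cohorts are reproducible and inserting
  a participant never changes another's sequence.
- Mann–Whitney U uses scipy's tie-corrected two-sided test; an all-tied
  feature reports p = 1 with a warning rather than an error.

## Known limitations

- The classical indices have no published reference values to the digit:
  exact numeric agreement with the original study would require its
  deposited dataset, which ships separately; the printed group means were
  used only to calibrate the generator and sanity-check magnitudes.
- The adjacency and windowed-analysis conventions (no wrap-around; window
  as length fraction; step 1) are documented choices where the original
  report is silent; alternatives are configuration options, not defaults.
- Chi-square expected counts are not checked against the usual ≥5 rule;
  with the cohort sizes in scope (≈6 per cell minimum margin) this is
  acceptable, but tiny cohorts should prefer an exact test (not provided).
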