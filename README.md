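# randgen

Analysis toolkit for **human-produced random digit sequences**: the
random-number-generation (RNG) task, in which a participant speaks a stream
of digits 1–10 "as randomly as possible" for about a minute. The package
quantifies how far such sequences depart from ideal randomness, compares a
clinical group against a comparison group, and asks whether sequence
features alone can discriminate the groups — the full workflow used in
autism research on arbitrary decision making, reimplemented as a tested,
reusable library with a synthetic-cohort generator so the entire pipeline
runs without access to any participant data.

## What it computes

For one digit sequence `x_1 … x_n` (digits 1–10):

**Randomness indices**

- Redundancy `R = 100 (1 − H/log₂10)` with
  `H = log₂ n − (1/n) Σᵢ nᵢ log₂ nᵢ` over digit counts `nᵢ` — the
  entropy shortfall of digit usage.
- Evans' index `RNG = 100 · (Σᵢⱼ n_ij log n_ij) / (Σᵢ mᵢ log mᵢ)` over
  lag-1 digram counts `n_ij` with row sums `mᵢ`; `RNG2` is the same at
  lag 2 (interleaved pairs).
- Null-score quotient `NSQ = 100 · NS / 99`, the share of the 100 possible
  digrams never used.
- Adjacency: percentage of ±1 steps (ascending, descending, combined).
- Turning point index `TPI = 100 · TP / ((2/3)(n−2))`, observed local
  extrema against the random-series expectation.

**Sequence descriptors** — response frequencies `RF`/`r_RF = RF/n`,
first-order differences `FOD_d` for `d ∈ {−9…9}` with `r_FOD = FOD/n`, and
the correlation-function index `Cf` (equal-digit pairs over all lags) with
`r_Cf` = fraction of all equal-digit position pairs (expectation 0.1 for
uniform digits).

**Categorical recurrence quantification (RQA)** — recurrence rate, ­
determinism, laminarity, mean diagonal line length, relative line-length
entropy and trapping time of the exact-match recurrence plot
(`RR ≡ r_Cf` holds identically).

**Group analysis** — Shapiro–Wilk-gated Mann–Whitney U / one-way ANOVA per
feature (chi-square for categorical margins), overlapping moving-window
trajectories (default window: one third of the sequence), and an exhaustive
decision-tree search over all feature subsets of size ≤ 3 scored by
leave-one-out accuracy with the published hyperparameters
(`max_depth=5, max_features=1, min_samples_split=7, min_samples_leaf=1`).

**Synthetic cohorts** — a first-order Markov model of human digit
production (`P(j|i) ∝ pref_j · kernel_{j−i}`), calibrated so its stationary
step and digit marginals reproduce the published group profiles
(dominant +1 steps ≈ 0.3, suppressed repetitions, digit 1 over-used).
`recover_params` solves the inverse problem by maximum likelihood.

## Worked example

```python
import randgen as rg

cohort = rg.sample_cohort(rg.default_scenario(seed=1))   # 36 ASD / 40 CTRL
features = rg.feature_table(cohort.sequences)
print(features.groupby("group")[["n", "r_FOD_1", "r_Cf", "NSQ"]].mean().round(3))
```

prints

```
            n  r_FOD_1   r_Cf     NSQ
group
ASD    58.333    0.327  0.108  69.753
CTRL   63.025    0.303  0.104  64.394
```

i.e., the simulated autism group produces slightly shorter sequences with a
stronger +1-step habit and more unused digrams (higher NSQ), while the
repetition structure (`r_Cf`, close to the 0.1 chance level) is nearly
identical — the qualitative picture reported for the real cohorts. A full
report bundle (features, RQA, comparison table, window trajectories,
classifier ranking, best-subset tree in DOT) comes from

```bash
randgen run --seed 1 --out report/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on the calibrated synthetic
cohort — simulation, all sequence metrics and RQA measures, gated group
comparisons, window contrasts, and the exhaustive leave-one-out
decision-tree subset search — and writes the results JSON (no numeric
targets are registered, so the object is empty; the run is the check).
Pass `--keep DIR` to retain the intermediate CSV artifacts.

## Layout

- `randgen.cohort` — sequence/cohort types, CSV I/O with column mapping
- `randgen.metrics` — randomness indices and sequence descriptors
- `randgen.rqa` — categorical recurrence quantification
- `randgen.windows` — moving-window trajectories and group contrasts
- `randgen.compare` — normality-gated two-group tests
- `randgen.classify` — decision-tree feature-subset search (scikit-learn)
- `randgen.simulate` — calibrated Markov generator and parameter recovery
- `randgen.pipeline` / `randgen.cli` — orchestration and the `randgen` CLI

See `docs/methods.md` for the model conventions, calibration details and
known limitations.
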