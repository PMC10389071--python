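"""Synthetic cohorts of human-like random digit sequences.

Human digit production in the random-number-generation task is emulated
with a first-order Markov model: every descriptor the analysis computes
(first-order differences, digrams, adjacency, digit frequencies) is
first-order, so the generator carries exactly the structure the pipeline
measures — a strong +1-step preference, elevated -1 and +/-2 steps,
suppressed repetitions, digit 1 over-used and digit 10 under-used, and
variable sequence lengths.

Transition law: given current digit i, the next digit j is drawn with
probability proportional to digit_pref[j] * step_kernel[j - i], renormalised
over j in 1..10; if every candidate weight vanishes the draw falls back to
digit_pref alone, so the chain can always progress. Sequence length is a
rounded Gaussian truncated from below.

Because differences near the ends of the digit range are unavailable, the
realised (marginal) step distribution of the chain is not the kernel
itself. Default parameters are therefore *calibrated*: a fixed-point
iteration picks the kernel and preference weights whose model-implied
stationary step/digit marginals equal the published group-mean relative
first-order-difference and digit-frequency profiles (and the published mean
lengths, 59 for the autism group and 62 for the comparison group).
:func:`recover_params` solves the inverse problem from data by maximum
likelihood on the structured transition model.

Streams are split per participant, so inserting a participant never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize

from .cohort import Cohort, ParticipantMeta, ResponseSequence, normalize_group
from .metrics import FOD_DIFFS

#: Published group-mean relative first-order differences (d = -9..+9):
#: the calibration targets for the step marginals.
_RFOD_ASD = np.array(
    [0.013, 0.030, 0.020, 0.023, 0.028, 0.036, 0.046, 0.067, 0.128, 0.037,
     0.317, 0.088, 0.028, 0.033, 0.018, 0.012, 0.012, 0.007, 0.046]
)
_RFOD_CTRL = np.array(
    [0.018, 0.026, 0.020, 0.024, 0.032, 0.030, 0.040, 0.060, 0.159, 0.035,
     0.295, 0.079, 0.046, 0.031, 0.021, 0.015, 0.009, 0.007, 0.044]
)
#: Published group-mean relative response frequencies (digits 1..10):
#: the calibration targets for the digit marginals.
_RRF_ASD = np.array(
    [0.151, 0.114, 0.107, 0.080, 0.106, 0.082, 0.103, 0.095, 0.095, 0.062]
)
_RRF_CTRL = np.array(
    [0.144, 0.104, 0.099, 0.090, 0.103, 0.087, 0.093, 0.099, 0.096, 0.079]
)

#: Published sequence-length summaries: mean, and sd derived from the
#: printed interquartile ranges as IQR/1.349 (normal-quantile spacing).
_LENGTHS = {"ASD": (59.0, (74 - 40) / 1.349), "CTRL": (62.0, (72 - 49) / 1.349)}

#: Default between-participant step-kernel Dirichlet concentration: chosen
#: so that the simulated between-participant sd of r_FOD_1 matches the
#: published 0.09 once binomial sampling noise is added.
DEFAULT_JITTER = 45.0


@dataclass(frozen=True)
class GeneratorParams:
    """Parametric model of one group's digit production.

    step_kernel
        Nonnegative weights over differences -9..+9 (index d+9).
    digit_pref
        Nonnegative weights over digits 1..10 (index digit-1).
    jitter
        Between-participant variability of the step kernel: each
        participant's kernel is drawn from a Dirichlet centred on the group
        kernel with concentration ``jitter`` (larger = tighter). The digit
        preferences are shared — the published digit-frequency spread is
        already explained by sampling noise. ``None`` disables jitter.
    """

    length_mean: float = 60.0
    length_sd: float = 15.0
    length_min: int = 10
    step_kernel: tuple = tuple(np.full(19, 1.0 / 19))
    digit_pref: tuple = tuple(np.full(10, 0.1))
    jitter: float | None = None

    def __post_init__(self) -> None:
        kernel = np.asarray(self.step_kernel, dtype=float)
        pref = np.asarray(self.digit_pref, dtype=float)
        if kernel.shape != (19,) or pref.shape != (10,):
            raise ValueError("step_kernel must have 19 weights and digit_pref 10")
        if kernel.min() < 0 or pref.min() < 0:
            raise ValueError("weights must be nonnegative")
        if kernel.sum() <= 0 or pref.sum() <= 0:
            raise ValueError("weights must have positive sum")
        if self.length_min < 10:
            raise ValueError("length_min must be >= 10")
        object.__setattr__(self, "step_kernel", tuple(kernel))
        object.__setattr__(self, "digit_pref", tuple(pref))

    def transition_matrix(self, kernel=None, pref=None) -> np.ndarray:
        """Row-stochastic 10x10 matrix P[i-1, j-1] = P(next = j | current = i).

        Rows whose pref x kernel mass vanishes fall back to digit_pref.
        """
        kernel = np.asarray(self.step_kernel if kernel is None else kernel, float)
        pref = np.asarray(self.digit_pref if pref is None else pref, float)
        return _transition_matrix(kernel, pref)


def _transition_matrix(kernel: np.ndarray, pref: np.ndarray) -> np.ndarray:
    p = np.zeros((10, 10))
    for i in range(10):
        weights = pref * kernel[(np.arange(10) - i) + 9]
        total = weights.sum()
        p[i] = weights / total if total > 0 else pref / pref.sum()
    return p


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary digit distribution of a row-stochastic matrix."""
    values, vectors = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(values - 1.0)))
    pi = np.real(vectors[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def implied_marginals(kernel, pref) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied stationary digit marginal and step marginal.

    The step marginal m[d] = sum_i pi_i P[i, i+d] is what the pooled
    relative first-order differences of long sequences converge to.
    """
    kernel = np.asarray(kernel, float)
    pref = np.asarray(pref, float)
    transition = _transition_matrix(kernel, pref)
    pi = stationary_distribution(transition)
    m = np.zeros(19)
    for i in range(10):
        for j in range(10):
            m[(j - i) + 9] += pi[i] * transition[i, j]
    return pi, m


def _remove_tilt(
    kernel: np.ndarray, pref: np.ndarray, target_digit: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the tilt degeneracy of the transition model.

    Replacing kernel_d by kernel_d e^{lam d} and pref_j by pref_j e^{-lam j}
    leaves every transition probability unchanged, so (kernel, pref) are
    only identified up to a geometric tilt. Pick the member of the family
    whose log-preferences are closest (least squares) to the target's.
    """
    j = np.arange(10, dtype=float)
    b = np.log(np.maximum(pref, 1e-300)) - np.log(np.maximum(target_digit, 1e-300))
    lam = float(np.polyfit(j, b, 1)[0])
    d = np.arange(-9, 10, dtype=float)
    kernel = kernel * np.exp(lam * d)
    pref = pref * np.exp(-lam * j)
    return kernel / kernel.sum(), pref / pref.sum()


def calibrate_weights(
    target_step: np.ndarray,
    target_digit: np.ndarray,
    n_iter: int = 400,
    damping: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel and preference weights whose implied marginals match targets.

    Deterministic fixed-point iteration with multiplicative updates
    kernel <- kernel (target/implied)^damping (same for pref); the tilt
    degeneracy (see :func:`_remove_tilt`) is projected out at every step.
    Targets are renormalised to sum 1; zero target bins stay zero.
    """
    target_step = np.asarray(target_step, float)
    target_digit = np.asarray(target_digit, float)
    target_step = target_step / target_step.sum()
    target_digit = target_digit / target_digit.sum()
    kernel = target_step.copy()
    pref = target_digit.copy()
    for _ in range(n_iter):
        pi, m = implied_marginals(kernel, pref)
        with np.errstate(divide="ignore", invalid="ignore"):
            kernel = kernel * np.where(m > 0, (target_step / np.maximum(m, 1e-300)) ** damping, 0.0)
            pref = pref * np.where(pi > 0, (target_digit / np.maximum(pi, 1e-300)) ** damping, 0.0)
        kernel /= kernel.sum()
        pref /= pref.sum()
        kernel, pref = _remove_tilt(kernel, pref, target_digit)
    return kernel, pref


@dataclass(frozen=True)
class GroupScenario:
    """Two generator parameterisations plus group sizes (defaults: the
    published cohort, 36 ASD vs 40 comparison)."""

    params_asd: GeneratorParams
    params_ctrl: GeneratorParams
    n_asd: int = 36
    n_ctrl: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 1 or self.n_ctrl < 1:
            raise ValueError("both groups need at least one participant")


@lru_cache(maxsize=8)
def _calibrated_weights(group: str) -> tuple[tuple, tuple]:
    kernel_target = _RFOD_ASD if group == "ASD" else _RFOD_CTRL
    pref_target = _RRF_ASD if group == "ASD" else _RRF_CTRL
    kernel, pref = calibrate_weights(kernel_target, pref_target)
    return tuple(kernel), tuple(pref)


def default_paper_like_params(
    group: str, jitter: float | None = DEFAULT_JITTER
) -> GeneratorParams:
    """Generator parameters calibrated to the published group profiles."""
    group = normalize_group(group)
    mean, sd = _LENGTHS[group]
    kernel, pref = _calibrated_weights(group)
    return GeneratorParams(
        length_mean=mean,
        length_sd=sd,
        length_min=10,
        step_kernel=kernel,
        digit_pref=pref,
        jitter=jitter,
    )


def default_scenario(seed: int = 0, jitter: float | None = DEFAULT_JITTER) -> GroupScenario:
    return GroupScenario(
        params_asd=default_paper_like_params("ASD", jitter),
        params_ctrl=default_paper_like_params("CTRL", jitter),
        seed=seed,
    )


def null_scenario(seed: int = 0, n_asd: int = 36, n_ctrl: int = 40,
                  jitter: float | None = DEFAULT_JITTER) -> GroupScenario:
    """Identical generators in both groups (for calibration experiments)."""
    params = default_paper_like_params("CTRL", jitter)
    return GroupScenario(
        params_asd=replace(params),
        params_ctrl=replace(params),
        n_asd=n_asd,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def _participant_rng(seed: int, group: str, index: int) -> np.random.Generator:
    # spawn_key depends only on (seed, group, index): inserting a participant
    # never changes another participant's stream.
    group_key = 0 if normalize_group(group) == "ASD" else 1
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_key, index))
    )


def sample_sequence(
    params: GeneratorParams, rng: np.random.Generator
) -> tuple[int, ...]:
    """Draw one digit sequence from the production model."""
    n = max(int(round(rng.normal(params.length_mean, params.length_sd))),
            params.length_min)
    kernel = np.asarray(params.step_kernel)
    pref = np.asarray(params.digit_pref)
    if params.jitter is not None:
        kernel = rng.dirichlet(np.maximum(kernel / kernel.sum(), 1e-12) * params.jitter)
    transition = _transition_matrix(kernel, pref)
    cumulative = np.cumsum(transition, axis=1)
    start = np.cumsum(pref / pref.sum())
    digits = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    digits[0] = int(np.searchsorted(start, u[0], side="right")) + 1
    for t in range(1, n):
        row = cumulative[digits[t - 1] - 1]
        digits[t] = int(np.searchsorted(row, u[t] * row[-1], side="right")) + 1
    return tuple(int(d) for d in np.minimum(digits, 10))


def sample_cohort(scenario: GroupScenario) -> Cohort:
    """Simulate a full two-group cohort with placeholder demographics."""
    sequences: list[ResponseSequence] = []
    meta: dict[str, ParticipantMeta] = {}
    for group, n, params in (
        ("ASD", scenario.n_asd, scenario.params_asd),
        ("CTRL", scenario.n_ctrl, scenario.params_ctrl),
    ):
        for index in range(n):
            rng = _participant_rng(scenario.seed, group, index)
            pid = f"{group}{index + 1:03d}"
            responses = sample_sequence(params, rng)
            sequences.append(ResponseSequence(pid, group, responses))
            # placeholder demographics in the published ranges
            meta[pid] = ParticipantMeta(
                pid,
                group,
                age=float(max(np.round(rng.normal(27.0, 6.0), 1), 18.0)),
                gender="M" if rng.random() < 0.85 else "F",
                iq=float(max(np.round(rng.normal(109.0, 11.0), 1), 71.0)),
            )
    return Cohort(sequences, meta)


def _transition_counts(sequences) -> tuple[np.ndarray, np.ndarray]:
    counts = np.zeros((10, 10))
    first = np.zeros(10)
    for seq in sequences:
        x = np.asarray(seq.responses)
        np.add.at(counts, (x[:-1] - 1, x[1:] - 1), 1.0)
        first[x[0] - 1] += 1.0
    return counts, first


def _fit_structured_model(
    counts: np.ndarray, first: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood (kernel, pref) for the transition model
    P[i,j] = pref_j k_{j-i} / Z_i, plus first-digit draws from pref."""
    digit_marginal = counts.sum(axis=0) + counts.sum(axis=1) + first
    diffs = np.arange(10)[None, :] - np.arange(10)[:, None]  # j - i
    step_marginal = np.zeros(19)
    np.add.at(step_marginal, diffs + 9, counts)

    eps = 1e-8
    u0 = np.log(step_marginal / step_marginal.sum() + eps)
    v0 = np.log(digit_marginal / digit_marginal.sum() + eps)

    def unpack(theta):
        k = np.exp(theta[:19])
        p = np.exp(theta[19:])
        return k / k.sum(), p / p.sum()

    def nll(theta):
        kernel, pref = unpack(theta)
        transition = _transition_matrix(kernel, pref)
        logp = np.log(np.maximum(transition, 1e-300))
        value = -float(np.sum(counts * logp))
        value -= float(np.sum(first * np.log(np.maximum(pref, 1e-300))))
        return value

    res = optimize.minimize(
        nll,
        np.concatenate([u0, v0]),
        method="L-BFGS-B",
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 2000},
    )
    return unpack(res.x)


def recover_params(cohort: Cohort) -> dict[str, dict[str, np.ndarray]]:
    """Estimate each group's step kernel and digit preferences from data.

    ``step_kernel`` / ``digit_pref`` are maximum-likelihood estimates under
    the production model (consistent for the generating weights as
    participants x length grows). ``marginal_step`` / ``marginal_digit``
    are the naive pooled relative first-order-difference and digit
    histograms — descriptive, and biased for the weights near the digit
    range ends (a uniform kernel yields a triangular step marginal).
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for group in ("ASD", "CTRL"):
        sequences = cohort.subset(group)
        if not sequences:
            continue
        counts, first = _transition_counts(sequences)
        kernel, pref = _fit_structured_model(counts, first)
        digit_hist_all = counts.sum(axis=0) + first
        # canonical tilt gauge: transitions carry no information about the
        # geometric tilt (see _remove_tilt), so report the family member
        # anchored to the observed digit marginal — the same gauge
        # calibrate_weights uses when constructing parameters
        kernel, pref = _remove_tilt(kernel, pref, digit_hist_all / digit_hist_all.sum())
        diffs = np.arange(10)[None, :] - np.arange(10)[:, None]
        marginal_step = np.zeros(19)
        np.add.at(marginal_step, diffs + 9, counts)
        digit_hist = np.zeros(10)
        for seq in sequences:
            digit_hist += np.bincount(np.asarray(seq.responses), minlength=11)[1:]
        out[group] = {
            "step_kernel": kernel,
            "digit_pref": pref,
            "marginal_step": marginal_step / marginal_step.sum(),
            "marginal_digit": digit_hist / digit_hist.sum(),
            "diffs": FOD_DIFFS.copy(),
        }
    return out
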