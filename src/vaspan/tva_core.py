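"""Generative model of whole-report letter identification.

The model is an exponential race into a capacity-limited visual short-term
memory (VSTM) store.  Each of the ``n`` displayed letters accrues evidence
at rate ``C / n`` (the total processing rate ``C`` is divided equally among
the homogeneous letters).  A letter is encoded if its exponential finishing
time falls inside the *effective* exposure window; encoded letters occupy
VSTM slots in finishing order, up to the capacity ``K``.  The reported
score is the number of occupied slots.

Two nuisance parameters shape the effective exposure: ``t0``, the
perceptual threshold below which nothing is encoded, and ``mu``, the iconic
persistence that extends unmasked displays.  All durations are seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TVAParams",
    "DisplayCondition",
    "ScoreDistribution",
    "effective_exposure",
    "encoding_probability",
    "score_distribution",
    "expected_score",
    "simulate_trial",
    "simulate_scores",
]


@dataclass(frozen=True)
class TVAParams:
    """Visual attention capacity parameters for one observer.

    Attributes
    ----------
    C : float
        Visual processing speed, elements per second (total rate shared
        among displayed elements). Must be positive.
    K : float
        VSTM storage capacity in elements.  May be fractional, interpreted
        as a per-trial Bernoulli mixture of the two adjacent integer
        capacities.
    t0 : float
        Perceptual threshold in seconds; exposure below it encodes nothing.
    mu : float
        Iconic-memory persistence in seconds, added to the effective
        exposure of unmasked displays.
    """

    C: float
    K: float
    t0: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.K < 0:
            raise ValueError(f"K must be non-negative, got {self.K}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be non-negative, got {self.t0}")
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")


@dataclass(frozen=True)
class DisplayCondition:
    """One cell of the whole-report design.

    ``n`` letters shown for ``exposure`` seconds, followed by a pattern
    mask (``masked=True``) or a blank screen.
    """

    n: int
    exposure: float
    masked: bool

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"display size must be >= 1, got {self.n}")
        if not self.exposure > 0:
            raise ValueError(f"exposure must be positive, got {self.exposure}")


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability mass function over report scores 0..n."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    @property
    def scores(self) -> np.ndarray:
        return np.arange(len(self.probs))

    def mean(self) -> float:
        return float(self.scores @ self.probs)

    def pmf(self, score: int) -> float:
        return float(self.probs[score]) if 0 <= score < len(self.probs) else 0.0


def effective_exposure(cond: DisplayCondition, params: TVAParams) -> float:
    """Exposure available for encoding, in seconds.

    Masked displays yield ``exposure - t0`` (clamped at zero).  Unmasked
    displays additionally persist for ``mu`` seconds, but only if the
    nominal exposure exceeded the threshold at all.
    """
    tau = cond.exposure - params.t0
    if tau <= 0:
        return 0.0
    if not cond.masked:
        tau += params.mu
    return tau


def encoding_probability(n: int, tau: float, params: TVAParams) -> float:
    """Probability that one of ``n`` displayed letters finishes within ``tau``.

    Each letter races at rate ``C / n``, so the finishing time is
    exponential and ``P(encode) = 1 - exp(-(C/n) * tau)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return -math.expm1(-(params.C / n) * tau)


def _binom_pmf(n: int, p: float) -> np.ndarray:
    # display sizes are tiny (<= 6 in the standard design): direct evaluation
    # beats scipy's generic machinery inside the likelihood loop
    j = np.arange(n + 1)
    comb = np.array([math.comb(n, k) for k in j], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmf = comb * np.power(p, j) * np.power(1.0 - p, n - j)
    # guard 0**0 at the endpoints
    if p == 0.0:
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
    elif p == 1.0:
        pmf = np.zeros(n + 1)
        pmf[n] = 1.0
    return pmf


def _truncate_at_cap(pmf: np.ndarray, cap: int) -> np.ndarray:
    """Pile the upper tail of a score pmf onto the capacity cap."""
    n = len(pmf) - 1
    if cap >= n:
        return pmf
    out = np.zeros_like(pmf)
    out[:cap] = pmf[:cap]
    out[cap] = pmf[cap:].sum()
    return out


def score_distribution(cond: DisplayCondition, params: TVAParams) -> ScoreDistribution:
    """Distribution of the number of correctly reported letters.

    With encoding probability ``p`` the number of letters finishing the
    race is Binomial(n, p); the VSTM cap truncates it.  A fractional
    capacity ``K`` is the gamma-weighted mixture of the two adjacent
    integer caps, where ``gamma = K - floor(K)``.
    """
    tau = effective_exposure(cond, params)
    p = encoding_probability(cond.n, tau, params)
    pmf = _binom_pmf(cond.n, p)
    k_lo = math.floor(params.K)
    gamma = params.K - k_lo
    if gamma == 0.0:
        mix = _truncate_at_cap(pmf, k_lo)
    else:
        mix = (1.0 - gamma) * _truncate_at_cap(pmf, k_lo) + gamma * _truncate_at_cap(
            pmf, k_lo + 1
        )
    mix = mix / mix.sum()
    return ScoreDistribution(mix)


def expected_score(cond: DisplayCondition, params: TVAParams) -> float:
    """Mean number of correctly reported letters in a condition."""
    return score_distribution(cond, params).mean()


def simulate_scores(
    cond: DisplayCondition,
    params: TVAParams,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate report scores for ``n_trials`` trials of one condition.

    Per-element exponential finishing times at rate C/n race against the
    effective exposure; finishers occupy up to ``cap`` slots, with the cap
    drawn per trial for fractional K.  Returns an int array of scores.
    """
    if n_trials == 0:
        return np.zeros(0, dtype=int)
    tau = effective_exposure(cond, params)
    rate = params.C / cond.n
    times = rng.exponential(scale=1.0 / rate, size=(n_trials, cond.n))
    finished = (times < tau).sum(axis=1)
    k_lo = math.floor(params.K)
    gamma = params.K - k_lo
    if gamma == 0.0:
        cap = np.full(n_trials, k_lo)
    else:
        cap = k_lo + (rng.random(n_trials) < gamma).astype(int)
    return np.minimum(finished, cap).astype(int)


def simulate_trial(
    cond: DisplayCondition, params: TVAParams, rng: np.random.Generator
) -> int:
    """Simulate a single whole-report trial; returns the score."""
    return int(simulate_scores(cond, params, 1, rng)[0])
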