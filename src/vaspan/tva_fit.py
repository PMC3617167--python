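"""Maximum-likelihood estimation of the whole-report race-model parameters.

One observer's trials are grouped by design cell; the likelihood of a
parameter vector (C, K, t0, mu) is the product over trials of the model's
score probability in that trial's cell.  The surface is non-smooth in K
(the fractional-capacity mixture) and kinked in t0, so a bounded
Nelder-Mead simplex from a fixed grid of starting points is used; the best
of the starts is returned, which makes the fit deterministic for a given
data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .tva_core import DisplayCondition, TVAParams, score_distribution

__all__ = [
    "TrialRecord",
    "FitConfig",
    "FitResult",
    "negative_log_likelihood",
    "fit_tva",
    "fit_quality",
    "average_fit_quality",
    "bootstrap_fit",
]


@dataclass(frozen=True)
class TrialRecord:
    """One whole-report trial: who, which design cell, how many correct."""

    child_id: str
    condition: DisplayCondition
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= self.condition.n:
            raise ValueError(
                f"score {self.score} outside 0..{self.condition.n} "
                f"for child {self.child_id}"
            )


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_tva`.

    Bounds default to ranges comfortably containing values observed in
    school-age children: C in [1, 200] el/s, K in [0.5, max display size],
    t0 in [0, smallest exposure], mu in [0, 1] s.
    """

    c_bounds: tuple[float, float] = (1.0, 200.0)
    k_bounds: tuple[float, float] | None = None  # None -> (0.5, n_max)
    t0_bounds: tuple[float, float] | None = None  # None -> (0, min exposure)
    mu_bounds: tuple[float, float] = (0.0, 1.0)
    c_starts: tuple[float, ...] = (10.0, 25.0, 60.0)
    k_starts: tuple[float, ...] = (2.0, 3.5, 5.5)
    t0_starts: tuple[float, ...] = (0.001, 0.020)
    mu_starts: tuple[float, ...] = (0.10, 0.25)
    xatol: float = 1e-4
    fatol: float = 1e-6
    maxiter: int = 2000


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: TVAParams
    neg_log_likelihood: float
    conditions: list[DisplayCondition]
    empirical_means: np.ndarray
    fitted_means: np.ndarray
    converged: bool
    identifiable: bool = True
    bootstrap_sd: dict[str, float] | None = None
    bootstrap_quantiles: dict[str, np.ndarray] | None = None
    n_bootstrap_failures: int = 0


def _group_trials(
    trials: list[TrialRecord],
) -> list[tuple[DisplayCondition, np.ndarray]]:
    """Collapse trials to per-condition score histograms (sorted, stable)."""
    cells: dict[tuple, np.ndarray] = {}
    for t in trials:
        key = (t.condition.n, t.condition.exposure, t.condition.masked)
        if key not in cells:
            cells[key] = np.zeros(t.condition.n + 1, dtype=int)
        cells[key][t.score] += 1
    out = []
    for key in sorted(cells):
        n, exposure, masked = key
        out.append((DisplayCondition(n, exposure, masked), cells[key]))
    return out


def _score_pmf(n: int, p: float, K: float, comb: np.ndarray) -> np.ndarray:
    """Capacity-truncated binomial score pmf (fast inner-loop version).

    Matches :func:`vaspan.tva_core.score_distribution` exactly; ``comb``
    carries the precomputed binomial coefficients for display size n.
    """
    j = np.arange(n + 1)
    if p <= 0.0:
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
    elif p >= 1.0:
        pmf = np.zeros(n + 1)
        pmf[n] = 1.0
    else:
        pmf = comb * p**j * (1.0 - p) ** (n - j)
    k_lo = int(K)
    gamma = K - k_lo
    if k_lo >= n:
        return pmf
    out = np.zeros(n + 1)
    out[:k_lo] = pmf[:k_lo]
    out[k_lo] = pmf[k_lo:].sum()
    if gamma > 0.0 and k_lo + 1 <= n:
        hi = np.zeros(n + 1)
        hi[: k_lo + 1] = pmf[: k_lo + 1]
        hi[k_lo + 1] = pmf[k_lo + 1 :].sum()
        out = (1.0 - gamma) * out + gamma * hi
    return out


def _precompute_groups(groups):
    """(n, exposure, masked, counts, observed scores, comb) per cell."""
    pre = []
    for cond, counts in groups:
        comb = np.array([math.comb(cond.n, k) for k in range(cond.n + 1)], dtype=float)
        obs = np.nonzero(counts)[0]
        pre.append((cond.n, cond.exposure, cond.masked, counts[obs].astype(float), obs, comb))
    return pre


def _nll_fast(theta: np.ndarray, pre) -> float:
    C, K, t0, mu = theta
    if C <= 0 or K < 0 or t0 < 0 or mu < 0:
        return np.inf
    nll = 0.0
    for n, exposure, masked, counts, obs, comb in pre:
        tau = exposure - t0
        if tau <= 0:
            tau = 0.0
        elif not masked:
            tau += mu
        p = -math.expm1(-(C / n) * tau)
        pmf = _score_pmf(n, p, K, comb)
        probs = pmf[obs]
        if np.any(probs <= 0.0):
            return np.inf
        nll -= float(counts @ np.log(probs))
    return nll


def _nll_grouped(
    theta: np.ndarray, groups: list[tuple[DisplayCondition, np.ndarray]]
) -> float:
    return _nll_fast(theta, _precompute_groups(groups))


def negative_log_likelihood(params: TVAParams, trials: list[TrialRecord]) -> float:
    """Minus the summed log score-probability over trials.

    Infinite when any observed score has probability zero under the
    parameters (for instance a score above the capacity ceiling), which
    signals an infeasible region to the optimizer.
    """
    groups = _group_trials(trials)
    return _nll_grouped(
        np.array([params.C, params.K, params.t0, params.mu]), groups
    )


def fit_tva(trials: list[TrialRecord], config: FitConfig | None = None) -> FitResult:
    """Fit (C, K, t0, mu) to one observer's trials by maximum likelihood.

    Raises
    ------
    ValueError
        If the trials do not span at least two distinct (exposure, masked)
        cells, in which case the speed and threshold are not identifiable.
    """
    if config is None:
        config = FitConfig()
    groups = _group_trials(trials)
    exposures = {(c.exposure, c.masked) for c, _ in groups}
    if len(exposures) < 2:
        raise ValueError(
            "trials must span at least two distinct exposure conditions; "
            f"got {len(exposures)}"
        )

    n_max = max(c.n for c, _ in groups)
    min_exposure = min(c.exposure for c, _ in groups)
    max_score = max(
        int(np.max(np.nonzero(counts)[0])) for _, counts in groups if counts.sum()
    )
    k_bounds = config.k_bounds or (0.5, float(n_max))
    t0_bounds = config.t0_bounds or (0.0, min_exposure)

    # K starts below the largest observed score give zero likelihood; keep
    # the configured grid but clip into the feasible band
    k_feasible_lo = min(max_score + 0.5, k_bounds[1])
    k_starts = sorted({min(max(k, k_feasible_lo), k_bounds[1]) for k in config.k_starts})

    bounds = [config.c_bounds, k_bounds, t0_bounds, config.mu_bounds]
    pre = _precompute_groups(groups)
    best = None
    converged = False
    for c0 in config.c_starts:
        for k0 in k_starts:
            for t00 in config.t0_starts:
                for mu0 in config.mu_starts:
                    x0 = np.array(
                        [
                            np.clip(c0, *config.c_bounds),
                            np.clip(k0, *k_bounds),
                            np.clip(t00, *t0_bounds),
                            np.clip(mu0, *config.mu_bounds),
                        ]
                    )
                    res = optimize.minimize(
                        _nll_fast,
                        x0,
                        args=(pre,),
                        method="Nelder-Mead",
                        bounds=bounds,
                        options={
                            "xatol": config.xatol,
                            "fatol": config.fatol,
                            "maxiter": config.maxiter,
                        },
                    )
                    if best is None or res.fun < best.fun:
                        best = res
                        converged = bool(res.success)

    theta = best.x
    params = TVAParams(C=theta[0], K=theta[1], t0=theta[2], mu=theta[3])
    conds = [c for c, _ in groups]
    emp = np.array(
        [counts @ np.arange(len(counts)) / counts.sum() for _, counts in groups]
    )
    fitted = np.array([score_distribution(c, params).mean() for c in conds])
    # degenerate data (no letter ever reported) pins C at its lower bound
    # and identifies nothing
    identifiable = bool(emp.max() > 0.0)
    return FitResult(
        params=params,
        neg_log_likelihood=float(best.fun),
        conditions=conds,
        empirical_means=emp,
        fitted_means=fitted,
        converged=converged,
        identifiable=identifiable,
    )


def fit_quality(fit: FitResult) -> float:
    """Pearson correlation between empirical and fitted condition means.

    Returns NaN (flagged) when the empirical means are constant across
    conditions, where the correlation is undefined.
    """
    if len(fit.conditions) < 3:
        raise ValueError("fit quality needs at least 3 conditions")
    emp, fitted = fit.empirical_means, fit.fitted_means
    if np.std(emp) == 0.0 or np.std(fitted) == 0.0:
        return float("nan")
    return float(np.corrcoef(emp, fitted)[0, 1])


def average_fit_quality(rs: list[float] | np.ndarray) -> float:
    """Average correlations through Fisher's z transform.

    Coefficients at exactly |r| = 1 are clipped to 1 - 1e-7 before the
    transform.
    """
    r = np.clip(np.asarray(rs, dtype=float), -1 + 1e-7, 1 - 1e-7)
    return float(np.tanh(np.mean(np.arctanh(r))))


def bootstrap_fit(
    trials: list[TrialRecord],
    B: int = 500,
    rng: np.random.Generator | int | None = None,
    config: FitConfig | None = None,
    warm_start: bool = True,
) -> FitResult:
    """Assess parameter reliability by a within-condition trial bootstrap.

    Trials are resampled with replacement inside each design cell
    (preserving the balanced design), the model refitted B times, and the
    per-parameter bootstrap SDs and (2.5, 25, 50, 75, 97.5)% quantiles
    attached to the original fit.  Resamples whose refit fails are dropped
    and counted.  With ``warm_start`` the refits run a single simplex from
    the parent estimate instead of the full start grid, which is the usual
    economy for resampling loops.
    """
    from dataclasses import replace

    rng = np.random.default_rng(rng)
    base = fit_tva(trials, config)
    if B == 0:
        base.bootstrap_sd = {}
        base.bootstrap_quantiles = {}
        return base
    refit_config = config or FitConfig()
    if warm_start:
        est = base.params
        refit_config = replace(
            refit_config,
            c_starts=(est.C,),
            k_starts=(est.K,),
            t0_starts=(est.t0,),
            mu_starts=(est.mu,),
        )

    by_cell: dict[tuple, list[TrialRecord]] = {}
    for t in trials:
        key = (t.condition.n, t.condition.exposure, t.condition.masked)
        by_cell.setdefault(key, []).append(t)

    draws = {"C": [], "K": [], "t0": [], "mu": []}
    failures = 0
    for _ in range(B):
        resample: list[TrialRecord] = []
        for cell in sorted(by_cell):
            pool = by_cell[cell]
            idx = rng.integers(0, len(pool), size=len(pool))
            resample.extend(pool[i] for i in idx)
        try:
            fit = fit_tva(resample, refit_config)
        except ValueError:
            failures += 1
            continue
        draws["C"].append(fit.params.C)
        draws["K"].append(fit.params.K)
        draws["t0"].append(fit.params.t0)
        draws["mu"].append(fit.params.mu)

    qs = np.array([0.025, 0.25, 0.5, 0.75, 0.975])
    base.bootstrap_sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
                         for k, v in draws.items()}
    base.bootstrap_quantiles = {
        k: np.quantile(v, qs) if v else np.full(len(qs), np.nan)
        for k, v in draws.items()
    }
    base.n_bootstrap_failures = failures
    return base
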