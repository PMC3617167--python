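"""Mediation analysis: causal steps, bootstrapped indirect effect, kappa-squared.

The model asks whether a mediator M transmits the effect of X on Y, with
covariates (age, here) in every equation:

    y = i1 + c x  + covariates            (total effect)
    m = i2 + a x  + covariates            (X -> M path)
    y = i3 + c' x + b m + covariates      (direct + M -> Y paths)

The indirect effect is a*b, with the exact OLS identity a*b + c' = c.
Its sampling distribution is built by case resampling of whole child
rows, and 95% intervals are bias-corrected and accelerated (BCa):
the bias correction z0 comes from the bootstrap distribution's position
relative to the point estimate, the acceleration from a leave-one-out
jackknife.

kappa-squared is the observed indirect effect divided by the maximum
indirect effect attainable with the observed variances, holding the
non-path correlation r_xy fixed and pushing each path correlation to the
boundary of the positive-semidefinite region (Preacher & Kelley's
construction, each path maximized given the others at their observed
values).  Covariates are partialled out of x, m and y first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import ols_fit

__all__ = [
    "MediationPaths",
    "MediationResult",
    "causal_steps",
    "bootstrap_mediated_effect",
    "kappa_squared",
    "mediation_analysis",
    "bca_interval",
]


@dataclass(frozen=True)
class PathEstimate:
    coef: float
    se: float
    p: float

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


@dataclass
class MediationPaths:
    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate
    verdict: str  # "none" | "partial" | "total"
    alpha: float

    @property
    def indirect(self) -> float:
        return self.a.coef * self.b.coef


@dataclass
class MediationResult:
    paths: MediationPaths
    indirect: float
    indirect_ci: tuple[float, float] | None = None
    kappa2: float | None = None
    kappa2_ci: tuple[float, float] | None = None
    n_bootstrap: int = 0
    n_dropped: int = 0


def causal_steps(
    cohort: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> MediationPaths:
    """Three-regression mediation test.

    Verdict is "none" if any of c, a, b misses significance; "total"
    if c, a, b are significant and the direct path c' is not; "partial"
    when all four are significant.
    """
    covariates = covariates or []
    fit_c = ols_fit(cohort, y, covariates + [x])
    fit_a = ols_fit(cohort, m, covariates + [x])
    fit_b = ols_fit(cohort, y, covariates + [x, m])

    def path(fit, term) -> PathEstimate:
        return PathEstimate(
            coef=float(fit.params[term]),
            se=float(fit.bse[term]),
            p=float(fit.pvalues[term]),
        )

    a = path(fit_a, x)
    b = path(fit_b, m)
    c = path(fit_c, x)
    c_prime = path(fit_b, x)

    if c.p < alpha and a.p < alpha and b.p < alpha:
        verdict = "partial" if c_prime.p < alpha else "total"
    else:
        verdict = "none"
    return MediationPaths(a=a, b=b, c=c, c_prime=c_prime, verdict=verdict, alpha=alpha)


def _ab_statistic(Xc, xv, mv, yv) -> float:
    """Indirect effect a*b from raw arrays (Xc = covariate design w/ const)."""
    A = np.column_stack([Xc, xv])
    a = np.linalg.lstsq(A, mv, rcond=None)[0][-1]
    B = np.column_stack([Xc, xv, mv])
    b = np.linalg.lstsq(B, yv, rcond=None)[0][-1]
    return float(a * b)


def bca_interval(
    boot: np.ndarray,
    point: float,
    jackknife: np.ndarray,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval.

    ``boot`` is the bootstrap distribution of the statistic, ``point``
    the full-sample estimate and ``jackknife`` the leave-one-out
    estimates used for the acceleration constant.
    """
    boot = np.asarray(boot, dtype=float)
    B = len(boot)
    if B == 0:
        raise ValueError("empty bootstrap distribution")
    # bias correction; clamp away from 0/1 so z0 stays finite
    prop = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / B
    prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(prop)
    # acceleration from jackknife skewness
    jk = np.asarray(jackknife, dtype=float)
    d = jk.mean() - jk
    denom = 6.0 * (d**2).sum() ** 1.5
    acc = float((d**3).sum() / denom) if denom > 0 else 0.0

    alpha = 1.0 - level
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(q)
        adj = z0 + (z0 + z) / (1.0 - acc * (z0 + z))
        out.append(float(np.quantile(boot, stats.norm.cdf(adj))))
    return out[0], out[1]


def _prepare_arrays(cohort, x, m, y, covariates):
    xv = cohort[x].to_numpy(dtype=float)
    mv = cohort[m].to_numpy(dtype=float)
    yv = cohort[y].to_numpy(dtype=float)
    if covariates:
        Xc = np.column_stack(
            [np.ones(len(cohort))] + [cohort[c].to_numpy(dtype=float) for c in covariates]
        )
    else:
        Xc = np.ones((len(cohort), 1))
    return Xc, xv, mv, yv


def bootstrap_mediated_effect(
    cohort: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], int]:
    """Indirect effect a*b with a case-resampling BCa interval.

    Whole child rows are resampled with replacement B times; a and b are
    re-estimated on each resample.  Returns (point estimate, (lo, hi),
    number of degenerate resamples dropped).  The point estimate comes
    from the original sample and does not depend on B or the seed.
    """
    if len(cohort) < 10:
        raise ValueError("too few observations to bootstrap")
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(rng)
    covariates = covariates or []
    Xc, xv, mv, yv = _prepare_arrays(cohort, x, m, y, covariates)
    n = len(xv)
    point = _ab_statistic(Xc, xv, mv, yv)

    boot, dropped = _bootstrap_stat(
        lambda idx: _ab_statistic(Xc[idx], xv[idx], mv[idx], yv[idx]), n, B, rng
    )
    jack = np.array(
        [
            _ab_statistic(np.delete(Xc, i, 0), np.delete(xv, i), np.delete(mv, i), np.delete(yv, i))
            for i in range(n)
        ]
    )
    ci = bca_interval(boot, point, jack, level)
    return point, ci, dropped


def _bootstrap_stat(stat_of_idx, n, B, rng):
    boot = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            v = stat_of_idx(idx)
        except (np.linalg.LinAlgError, ValueError):
            dropped += 1
            continue
        if not np.isfinite(v):
            dropped += 1
            continue
        boot.append(v)
    return np.array(boot), dropped


def _residualize(Xc: np.ndarray, v: np.ndarray) -> np.ndarray:
    return v - Xc @ np.linalg.lstsq(Xc, v, rcond=None)[0]


def _kappa2_from_arrays(Xc, xv, mv, yv) -> float:
    """Preacher-Kelley kappa-squared with covariates partialled out."""
    rx = _residualize(Xc, xv)
    rm = _residualize(Xc, mv)
    ry = _residualize(Xc, yv)
    sx, sm_, sy = rx.std(ddof=1), rm.std(ddof=1), ry.std(ddof=1)
    if sx == 0 or sm_ == 0 or sy == 0:
        raise ValueError("degenerate variance after partialling covariates")
    r_xm = float(np.corrcoef(rx, rm)[0, 1])
    r_xy = float(np.corrcoef(rx, ry)[0, 1])
    r_my = float(np.corrcoef(rm, ry)[0, 1])
    if abs(r_xm) >= 1.0 or abs(r_xy) >= 1.0 or abs(r_my) >= 1.0:
        raise ValueError("perfectly correlated variables")

    a = r_xm * sm_ / sx
    b = (r_my - r_xm * r_xy) / (1.0 - r_xm**2) * sy / sm_
    ab = a * b
    if ab == 0.0:
        return 0.0

    # largest |a| keeping the correlation matrix PSD, r_my and r_xy fixed
    sa = 1.0 if a >= 0 else -1.0
    a_max = (r_xy * r_my + sa * np.sqrt((1 - r_xy**2) * (1 - r_my**2))) * sm_ / sx
    # largest |b| keeping PSD, r_xm and r_xy fixed
    sb = 1.0 if b >= 0 else -1.0
    b_max = sb * np.sqrt((1 - r_xy**2) / (1 - r_xm**2)) * sy / sm_
    denom = a_max * b_max
    if denom == 0.0:
        raise ValueError("degenerate maximum indirect effect")
    return float(ab / denom)


def kappa_squared(
    cohort: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], int]:
    """kappa-squared effect size with a bootstrap BCa interval.

    The observed indirect effect is divided by the maximum indirect
    effect admissible given the observed (covariate-partialled)
    variances; its sign follows the observed effect.  Returns
    (point, (lo, hi), dropped resamples).
    """
    rng = np.random.default_rng(rng)
    covariates = covariates or []
    Xc, xv, mv, yv = _prepare_arrays(cohort, x, m, y, covariates)
    n = len(xv)
    point = _kappa2_from_arrays(Xc, xv, mv, yv)

    boot, dropped = _bootstrap_stat(
        lambda idx: _kappa2_from_arrays(Xc[idx], xv[idx], mv[idx], yv[idx]), n, B, rng
    )
    jack = np.array(
        [
            _kappa2_from_arrays(
                np.delete(Xc, i, 0), np.delete(xv, i), np.delete(mv, i), np.delete(yv, i)
            )
            for i in range(n)
        ]
    )
    ci = bca_interval(boot, point, jack, level)
    return point, ci, dropped


def mediation_analysis(
    cohort: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> MediationResult:
    """Full mediation workup: causal steps + bootstrap a*b + kappa-squared.

    The two bootstrap stages use independent child streams spawned from
    ``rng`` so the a*b interval does not shift when kappa-squared is
    added or removed.
    """
    root = np.random.default_rng(rng)
    rng_ab, rng_k2 = root.spawn(2)
    paths = causal_steps(cohort, x, m, y, covariates, alpha=alpha)
    ab, ab_ci, dropped_ab = bootstrap_mediated_effect(
        cohort, x, m, y, covariates, B=B, rng=rng_ab
    )
    k2, k2_ci, dropped_k2 = kappa_squared(cohort, x, m, y, covariates, B=B, rng=rng_k2)
    return MediationResult(
        paths=paths,
        indirect=ab,
        indirect_ci=ab_ci,
        kappa2=k2,
        kappa2_ci=k2_ci,
        n_bootstrap=B,
        n_dropped=dropped_ab + dropped_k2,
    )
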