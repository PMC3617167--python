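"""Synthetic cohorts of school-age readers.

Two generators stand in for the unavailable child cohort:

* a *structural* generator that draws per-child race-model parameters,
  simulates the whole-report trials of the 10-condition design, scores a
  visual-attention-span task from simulated 5-letter 200 ms trials, and
  produces reading speed as a linear function of age and VA span plus
  noise — so that mediation of processing speed through VA span is true
  by construction;

* a *moment-exact* generator that manufactures an n-row table whose sample
  means, SDs and correlation matrix hit specified targets to numerical
  precision, which lets every regression and mediation quantity that is a
  function of first and second moments be recomputed from published
  summary tables alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tva_core import DisplayCondition, TVAParams, simulate_scores
from .tva_fit import TrialRecord

__all__ = [
    "ExposureDesign",
    "VASpanDesign",
    "CohortMoments",
    "CohortConfig",
    "d_min_analytic",
    "generate_cohort_structural",
    "generate_cohort_moment_exact",
    "sd_from_ci",
    "TABLE1_MOMENTS",
]


@dataclass(frozen=True)
class ExposureDesign:
    """The 10-cell whole-report design for one child.

    Five effective exposures per display size: the child's minimum
    exposure D_min masked and unmasked, D_min + 70 ms masked, and the
    200 ms maximum masked and unmasked, crossed with display sizes 3
    and 6.
    """

    d_min: float
    intermediate_offset: float = 0.070
    maximum: float = 0.200
    display_sizes: tuple[int, ...] = (3, 6)
    trials_per_condition: int = 15

    def __post_init__(self) -> None:
        inter = self.d_min + self.intermediate_offset
        if not self.d_min < inter < self.maximum:
            raise ValueError(
                f"need d_min < d_min+offset < maximum, got "
                f"{self.d_min} < {inter} < {self.maximum}"
            )

    def conditions(self) -> list[DisplayCondition]:
        cells = []
        for n in self.display_sizes:
            cells.append(DisplayCondition(n, self.d_min, masked=True))
            cells.append(DisplayCondition(n, self.d_min, masked=False))
            cells.append(
                DisplayCondition(n, self.d_min + self.intermediate_offset, masked=True)
            )
            cells.append(DisplayCondition(n, self.maximum, masked=True))
            cells.append(DisplayCondition(n, self.maximum, masked=False))
        return cells


@dataclass(frozen=True)
class VASpanDesign:
    """Visual-attention-span task: 20 unmasked 5-letter strings at 200 ms."""

    string_length: int = 5
    exposure: float = 0.200
    n_trials: int = 20


@dataclass(frozen=True)
class CohortMoments:
    """Target sample moments for the moment-exact generator."""

    variables: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = len(self.variables)
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("SDs must be positive")


def d_min_analytic(params: TVAParams) -> float:
    """Exposure at which a single letter is identified with probability 1/2.

    Under the masked model a lone letter races at the full rate C, so the
    50% threshold is ``t0 + ln(2)/C``.  This closed form replaces an
    adaptive staircase for setting each synthetic child's minimum
    exposure.
    """
    return params.t0 + math.log(2.0) / params.C


def sd_from_ci(mean: float, ci_low: float, ci_high: float, n: int) -> float:
    """Back out a sample SD from a normal-theory 95% CI of the mean."""
    if not ci_low < ci_high:
        if ci_low == ci_high:
            return 0.0
        raise ValueError("ci_low must not exceed ci_high")
    if n <= 1:
        raise ValueError("n must exceed 1")
    return (ci_high - ci_low) / 2.0 * math.sqrt(n) / 1.96


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions for the structural generator.

    Defaults are calibrated to descriptive statistics observed in 8-9
    year-old readers: processing speed C ~ N(24.6, 7.2) el/s truncated
    above 5; capacity K ~ N(3.6, 0.5) truncated to [1, 6]; threshold
    t0 ~ |N(0, 8 ms)|; iconic persistence mu ~ N(184, 60) ms truncated
    above 0; age uniform over 97-119 months.  ``latent_loading`` induces
    the C-K correlation through a shared standard-normal factor.

    The VA-span task is run on a horizontal letter string, which school
    children process with a reading-specific advantage absent from the
    circular-array task that identifies K; ``va_capacity_bonus`` adds that
    advantage (in elements) to the capacity used in VA-span trials.

    Reading speed is ``intercept + beta_age*age + beta_va*VA + eps`` with
    slopes of 19 wpm per letter of span and 0.8 wpm per month, and noise
    sized so the marginal SD lands near 21 wpm.
    """

    c_mean: float = 24.6
    c_sd: float = 7.2
    c_min: float = 5.0
    k_mean: float = 3.6
    k_sd: float = 0.5
    k_range: tuple[float, float] = (1.0, 6.0)
    t0_sd: float = 0.008
    mu_mean: float = 0.184
    mu_sd: float = 0.060
    age_range: tuple[float, float] = (97.0, 119.0)
    latent_loading: float = 0.75
    va_capacity_bonus: float = 1.0
    beta_va: float = 19.0
    beta_age: float = 0.8
    reading_intercept: float = 80.0 - 0.8 * 108.0 - 19.0 * 4.1
    noise_sd: float = 19.0
    d_min_jitter: float = 0.0  # relative staircase noise, e.g. 0.2 for +-20%
    exposure_design: ExposureDesign | None = None  # None -> per-child analytic
    va_design: VASpanDesign = field(default_factory=VASpanDesign)
    trials_per_condition: int = 15


def _truncate(draw, lo: float | None, hi: float | None, rng, redraw) -> np.ndarray:
    """Redraw out-of-range values (up to a cap, then clip)."""
    x = draw()
    for _ in range(100):
        bad = np.zeros(len(x), dtype=bool)
        if lo is not None:
            bad |= x < lo
        if hi is not None:
            bad |= x > hi
        if not bad.any():
            break
        x[bad] = redraw(bad.sum())
    return np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)


def generate_cohort_structural(
    config: CohortConfig | None = None,
    n_children: int = 47,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, list[TrialRecord]]:
    """Simulate a cohort: parameters, whole-report trials, VA span, reading.

    Returns the per-child table (true parameters, age, VA span, reading
    speed) and the flat list of simulated whole-report trials.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(rng)

    lam = config.latent_loading
    resid = math.sqrt(max(0.0, 1.0 - lam * lam))
    z = rng.standard_normal(n_children)

    def correlated(n=n_children):
        return lam * z[:n] + resid * rng.standard_normal(n)

    C = config.c_mean + config.c_sd * correlated()
    K = config.k_mean + config.k_sd * correlated()
    # redraw only the independent part for truncation violations
    for _ in range(100):
        bad = C < config.c_min
        if not bad.any():
            break
        C[bad] = config.c_mean + config.c_sd * (
            lam * z[bad] + resid * rng.standard_normal(bad.sum())
        )
    C = np.clip(C, config.c_min, None)
    K = np.clip(K, *config.k_range)
    t0 = np.abs(rng.normal(0.0, config.t0_sd, n_children))
    mu = np.clip(rng.normal(config.mu_mean, config.mu_sd, n_children), 1e-3, None)
    age = rng.uniform(*config.age_range, n_children)

    rows = []
    trials: list[TrialRecord] = []
    for i in range(n_children):
        cid = f"child{i:03d}"
        params = TVAParams(C=float(C[i]), K=float(K[i]), t0=float(t0[i]), mu=float(mu[i]))
        if config.exposure_design is not None:
            design = config.exposure_design
        else:
            d_min = d_min_analytic(params)
            if config.d_min_jitter > 0:
                d_min *= 1.0 + rng.uniform(-config.d_min_jitter, config.d_min_jitter)
            # keep the design ordering valid
            d_min = float(np.clip(d_min, 0.005, 0.200 - 0.071))
            design = ExposureDesign(
                d_min=d_min, trials_per_condition=config.trials_per_condition
            )
        for cond in design.conditions():
            scores = simulate_scores(cond, params, design.trials_per_condition, rng)
            trials.extend(TrialRecord(cid, cond, int(s)) for s in scores)

        va_params = TVAParams(
            C=params.C,
            K=min(params.K + config.va_capacity_bonus, config.va_design.string_length),
            t0=params.t0,
            mu=params.mu,
        )
        va_cond = DisplayCondition(
            config.va_design.string_length, config.va_design.exposure, masked=False
        )
        va_scores = simulate_scores(va_cond, va_params, config.va_design.n_trials, rng)
        va_span = float(va_scores.mean())

        reading = (
            config.reading_intercept
            + config.beta_age * age[i]
            + config.beta_va * va_span
            + rng.normal(0.0, config.noise_sd)
        )
        rows.append(
            dict(
                child_id=cid,
                age=float(age[i]),
                true_C=params.C,
                true_K=params.K,
                true_t0=params.t0,
                true_mu=params.mu,
                d_min=design.d_min,
                va_span=va_span,
                reading_speed=float(reading),
            )
        )
    cohort = pd.DataFrame(rows)
    return cohort, trials


def generate_cohort_moment_exact(
    moments: CohortMoments,
    rng: np.random.Generator | int | None = None,
    max_abs_z: float | None = None,
) -> pd.DataFrame:
    """Build an n-row table with exactly the requested sample moments.

    A random Gaussian matrix is centred and orthonormalized (QR), giving
    columns with zero mean, unit sample variance and zero pairwise sample
    correlation; the target correlation is imposed by its Cholesky factor
    and the columns rescaled and shifted.  The seed rotates the rows but
    cannot move the moments.

    ``max_abs_z`` emulates a cohort that has already passed an outlier
    screen: rotations are redrawn until no value sits more than that many
    sample SDs from its mean, so a downstream z screen at the same
    threshold excludes nobody.
    """
    rng = np.random.default_rng(rng)
    p = len(moments.variables)
    n = moments.n
    if n <= p:
        raise ValueError(f"need n > number of variables, got n={n}, p={p}")

    corr = np.asarray(moments.correlation, dtype=float)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        # suggest the nearest PSD repair rather than silently applying it
        w, V = np.linalg.eigh(corr)
        nearest = (V * np.maximum(w, 0)) @ V.T
        d = np.sqrt(np.diag(nearest))
        nearest = nearest / np.outer(d, d)
        raise ValueError(
            f"correlation matrix is not PSD (min eigenvalue {eigmin:.3e}); "
            f"nearest PSD candidate:\n{np.round(nearest, 4)}"
        )

    L = np.linalg.cholesky(corr + 1e-14 * np.eye(p))
    for _ in range(1000):
        # centred orthonormal basis orthogonal to the intercept
        Z = rng.standard_normal((n, p))
        Z -= Z.mean(axis=0)
        Q, _ = np.linalg.qr(Z)
        Y = Q * math.sqrt(n - 1)  # unit sample variance, zero correlation
        X = Y @ L.T  # standardized with the target correlation
        if max_abs_z is None or np.abs(X).max() <= max_abs_z:
            break
    else:
        raise ValueError(
            f"could not draw a rotation with all |z| <= {max_abs_z} in 1000 tries"
        )
    X = X * np.asarray(moments.sds) + np.asarray(moments.means)
    df = pd.DataFrame(X, columns=list(moments.variables))
    df.insert(0, "child_id", [f"child{i:03d}" for i in range(n)])
    return df


def _table1_moments() -> CohortMoments:
    """Published cohort summary: means and CI-derived SDs for n = 47,
    with the full correlation matrix over age, VA span, C, K and reading
    speed."""
    n = 47
    variables = ("age", "va_span", "C", "K", "reading_speed")
    means = np.array([108.0, 4.1, 24.6, 3.6, 80.0])
    sds = np.array(
        [
            sd_from_ci(108.0, 106.0, 110.0, n),
            sd_from_ci(4.1, 3.95, 4.25, n),  # printed 3.9-4.2; half-width 0.15
            sd_from_ci(24.6, 22.5, 26.6, n),
            sd_from_ci(3.6, 3.45, 3.75, n),  # printed 3.5-3.8; half-width 0.15
            sd_from_ci(80.0, 74.0, 86.0, n),
        ]
    )
    corr = np.array(
        [
            [1.00, 0.30, 0.39, 0.19, 0.40],
            [0.30, 1.00, 0.67, 0.67, 0.56],
            [0.39, 0.67, 1.00, 0.54, 0.50],
            [0.19, 0.67, 0.54, 1.00, 0.34],
            [0.40, 0.56, 0.50, 0.34, 1.00],
        ]
    )
    return CohortMoments(variables, means, sds, corr, n)


TABLE1_MOMENTS = _table1_moments()
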