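"""Causal steps, bootstrap BCa indirect effect, kappa-squared."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vaspan.mediation import (
    _kappa2_from_arrays,
    bca_interval,
    bootstrap_mediated_effect,
    causal_steps,
    kappa_squared,
    mediation_analysis,
)


def _chain_cohort(n=200, a=1.0, b=1.0, noise_m=1.0, noise_y=1.0, seed=0):
    """x -> m -> y chain with adjustable path strengths."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = a * x + noise_m * rng.normal(size=n)
    y = b * m + noise_y * rng.normal(size=n)
    return pd.DataFrame(dict(child_id=np.arange(n), x=x, m=m, y=y))


class TestCausalSteps:
    def test_independent_mediator_verdict_none(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame(
            dict(
                x=rng.normal(size=n),
                m=rng.normal(size=n),  # unrelated to everything
                y=rng.normal(size=n),
            )
        )
        df["y"] += 0.8 * df["x"]
        res = causal_steps(df, "x", "m", "y")
        assert not res.b.significant
        assert res.verdict == "none"

    def test_perfect_mediator_verdict_total(self):
        df = _chain_cohort(noise_y=0.3)
        df["y"] = df["m"] + 0.3 * np.random.default_rng(1).normal(size=len(df))
        res = causal_steps(df, "x", "m", "y")
        assert res.verdict == "total"
        assert abs(res.c_prime.coef) < abs(res.c.coef)

    def test_partial_mediation_detected(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(size=n)
        m = x + 0.7 * rng.normal(size=n)
        y = 0.5 * m + 0.5 * x + 0.5 * rng.normal(size=n)  # direct path too
        df = pd.DataFrame(dict(x=x, m=m, y=y))
        assert causal_steps(df, "x", "m", "y").verdict == "partial"

    def test_decomposition_identity(self, moment_cohort):
        # a*b + c' = c holds exactly for OLS with shared covariates
        res = causal_steps(
            moment_cohort, "C", "va_span", "reading_speed", ["age"]
        )
        assert res.indirect + res.c_prime.coef == pytest.approx(res.c.coef, abs=1e-10)

    def test_moment_cohort_total_mediation(self, moment_cohort):
        res = causal_steps(moment_cohort, "C", "va_span", "reading_speed", ["age"])
        assert res.a.significant and res.b.significant and res.c.significant
        assert not res.c_prime.significant
        assert res.verdict == "total"


class TestBootstrapIndirect:
    def test_null_effect_ci_contains_zero(self):
        rng = np.random.default_rng(4)
        n = 300
        df = pd.DataFrame(
            dict(x=rng.normal(size=n), m=rng.normal(size=n), y=rng.normal(size=n))
        )
        point, ci, _ = bootstrap_mediated_effect(df, "x", "m", "y", B=400, rng=0)
        assert ci[0] < 0 < ci[1]

    def test_point_estimate_independent_of_B_and_seed(self, moment_cohort):
        p1, _, _ = bootstrap_mediated_effect(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=100, rng=1
        )
        p2, _, _ = bootstrap_mediated_effect(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=200, rng=99
        )
        assert p1 == p2

    def test_seed_reproducible(self, moment_cohort):
        r1 = bootstrap_mediated_effect(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=200, rng=7
        )
        r2 = bootstrap_mediated_effect(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=200, rng=7
        )
        assert r1 == r2

    def test_matches_scipy_bca(self, moment_cohort):
        # independent BCa implementation from scipy on the same statistic
        from vaspan.mediation import _ab_statistic, _prepare_arrays

        Xc, xv, mv, yv = _prepare_arrays(
            moment_cohort, "C", "va_span", "reading_speed", ["age"]
        )
        idx = np.arange(len(xv))

        def stat(index):
            index = np.asarray(index, dtype=int)
            return _ab_statistic(Xc[index], xv[index], mv[index], yv[index])

        res = stats.bootstrap(
            (idx,),
            stat,
            n_resamples=1500,
            method="BCa",
            vectorized=False,
            random_state=np.random.default_rng(0),
        )
        _, ours, _ = bootstrap_mediated_effect(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=1500, rng=0
        )
        assert ours[0] == pytest.approx(res.confidence_interval.low, abs=0.12)
        assert ours[1] == pytest.approx(res.confidence_interval.high, abs=0.12)

    def test_too_small_sample_rejected(self):
        df = _chain_cohort(n=5)
        with pytest.raises(ValueError, match="too few"):
            bootstrap_mediated_effect(df, "x", "m", "y", B=200)


class TestBCaInterval:
    def test_monotone_in_level(self):
        rng = np.random.default_rng(0)
        boot = rng.normal(1.0, 0.3, 2000)
        jack = rng.normal(1.0, 0.05, 47)
        lo90, hi90 = bca_interval(boot, 1.0, jack, level=0.90)
        lo95, hi95 = bca_interval(boot, 1.0, jack, level=0.95)
        lo99, hi99 = bca_interval(boot, 1.0, jack, level=0.99)
        assert lo99 <= lo95 <= lo90 <= hi90 <= hi95 <= hi99

    def test_symmetric_case_near_percentile(self):
        rng = np.random.default_rng(1)
        boot = rng.normal(0.0, 1.0, 20000)
        jack = rng.normal(0.0, 1.0, 200)  # negligible skew
        lo, hi = bca_interval(boot, float(np.median(boot)), jack)
        assert lo == pytest.approx(-1.96, abs=0.12)
        assert hi == pytest.approx(1.96, abs=0.12)


class TestKappaSquared:
    def test_zero_indirect_gives_zero(self):
        n = 60
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        x -= x.mean()
        m = rng.normal(size=n)
        m -= m.mean()
        m -= x * (x @ m) / (x @ x)  # exactly uncorrelated: a = 0
        y = rng.normal(size=n)
        Xc = np.ones((n, 1))
        assert _kappa2_from_arrays(Xc, x, m, y) == pytest.approx(0.0, abs=1e-12)

    def test_increases_with_mediation_strength(self):
        # kappa-squared does not reach 1 even for a noiseless chain (a
        # known property of the construction), but it must grow as the
        # chain tightens and stay inside [0, 1]
        strong = _chain_cohort(n=400, noise_m=0.05, noise_y=0.05, seed=6)
        weak = _chain_cohort(n=400, noise_m=1.5, noise_y=1.5, seed=6)
        k2_strong, _, _ = kappa_squared(strong, "x", "m", "y", B=100, rng=0)
        k2_weak, _, _ = kappa_squared(weak, "x", "m", "y", B=100, rng=0)
        assert 0.0 < k2_weak < k2_strong <= 1.0
        assert k2_strong > 0.5

    def test_bounded(self, moment_cohort):
        k2, (lo, hi), _ = kappa_squared(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=200, rng=0
        )
        assert -1.0 <= lo <= k2 <= hi <= 1.0

    def test_scale_invariant(self, moment_cohort):
        k2a, _, _ = kappa_squared(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=100, rng=0
        )
        scaled = moment_cohort.copy()
        scaled["C"] = scaled["C"] * 3.7
        scaled["reading_speed"] = scaled["reading_speed"] / 60.0  # wpm -> wps
        k2b, _, _ = kappa_squared(
            scaled, "C", "va_span", "reading_speed", ["age"], B=100, rng=0
        )
        assert k2a == pytest.approx(k2b, abs=1e-10)

    def test_matches_grid_search_oracle(self, moment_cohort):
        # maximize each path by brute force over the PSD region and
        # compare with the analytic boundary values
        from vaspan.mediation import _prepare_arrays, _residualize

        Xc, xv, mv, yv = _prepare_arrays(
            moment_cohort, "C", "va_span", "reading_speed", ["age"]
        )
        rx, rm, ry = (_residualize(Xc, v) for v in (xv, mv, yv))
        sx, sm_, sy = (v.std(ddof=1) for v in (rx, rm, ry))
        r_xm = np.corrcoef(rx, rm)[0, 1]
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_my = np.corrcoef(rm, ry)[0, 1]

        def psd(rxm, rmy):
            M = np.array([[1, rxm, r_xy], [rxm, 1, rmy], [r_xy, rmy, 1]])
            return np.linalg.eigvalsh(M).min() >= -1e-12

        grid = np.linspace(-0.9999, 0.9999, 20001)
        a_grid = max(
            (g for g in grid if psd(g, r_my)), key=lambda g: g
        ) * sm_ / sx  # largest admissible positive a
        b_grid = max(
            ((g - r_xm * r_xy) / (1 - r_xm**2) for g in grid if psd(r_xm, g))
        ) * sy / sm_

        a = r_xm * sm_ / sx
        b = (r_my - r_xm * r_xy) / (1 - r_xm**2) * sy / sm_
        k2_grid = (a * b) / (a_grid * b_grid)
        k2 = _kappa2_from_arrays(Xc, xv, mv, yv)
        assert k2 == pytest.approx(k2_grid, abs=2e-4)


class TestMediationAnalysis:
    def test_full_workup_consistent(self, moment_cohort):
        res = mediation_analysis(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=300, rng=11
        )
        assert res.indirect == pytest.approx(res.paths.a.coef * res.paths.b.coef)
        assert res.paths.verdict == "total"
        assert res.indirect_ci[0] < res.indirect < res.indirect_ci[1]
        assert res.kappa2_ci[0] < res.kappa2 < res.kappa2_ci[1]

    def test_bit_reproducible(self, moment_cohort):
        r1 = mediation_analysis(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=200, rng=5
        )
        r2 = mediation_analysis(
            moment_cohort, "C", "va_span", "reading_speed", ["age"], B=200, rng=5
        )
        assert r1.indirect_ci == r2.indirect_ci
        assert r1.kappa2_ci == r2.kappa2_ci
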