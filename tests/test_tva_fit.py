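"""Maximum-likelihood fitting: likelihood, optimizer, fit quality, bootstrap."""

import math

import numpy as np
import pytest

from vaspan.recovery import parameter_recovery
from vaspan.tva_core import DisplayCondition, TVAParams, simulate_scores
from vaspan.tva_fit import (
    FitConfig,
    TrialRecord,
    average_fit_quality,
    bootstrap_fit,
    fit_quality,
    fit_tva,
    negative_log_likelihood,
)

P_REF = TVAParams(C=30.0, K=3.0, t0=0.010, mu=0.184)
COND_REF = DisplayCondition(n=6, exposure=0.110, masked=True)


def _two_condition_trials(scores_a=(0, 1, 2), scores_b=(2, 3, 3)):
    ca = DisplayCondition(6, 0.050, True)
    cb = DisplayCondition(6, 0.200, True)
    return [TrialRecord("x", ca, s) for s in scores_a] + [
        TrialRecord("x", cb, s) for s in scores_b
    ]


class TestNegativeLogLikelihood:
    def test_empty_is_zero(self):
        assert negative_log_likelihood(P_REF, []) == 0.0

    def test_single_trial_reference(self):
        # -ln P(score=3) at the reference setup, frozen from the
        # closed-form distribution
        nll = negative_log_likelihood(P_REF, [TrialRecord("x", COND_REF, 3)])
        assert nll == pytest.approx(0.8161, abs=5e-4)

    def test_score_above_cap_infeasible(self):
        nll = negative_log_likelihood(P_REF, [TrialRecord("x", COND_REF, 4)])
        assert math.isinf(nll)

    def test_additive_over_partitions(self):
        trials = _two_condition_trials()
        whole = negative_log_likelihood(P_REF, trials)
        parts = negative_log_likelihood(P_REF, trials[:2]) + negative_log_likelihood(
            P_REF, trials[2:]
        )
        assert whole == pytest.approx(parts, rel=1e-12)


@pytest.fixture(scope="module")
def simulated_child():
    truth = TVAParams(C=24.6, K=3.6, t0=0.004, mu=0.184)
    rng = np.random.default_rng(99)
    from vaspan.synthetic_data import ExposureDesign, d_min_analytic

    design = ExposureDesign(d_min=d_min_analytic(truth))
    trials = [
        TrialRecord("kid", cond, int(s))
        for cond in design.conditions()
        for s in simulate_scores(cond, truth, 15, rng)
    ]
    return truth, trials


class TestFitTVA:
    def test_single_exposure_unidentifiable(self):
        trials = [TrialRecord("x", COND_REF, s) for s in (1, 2, 2, 3)]
        with pytest.raises(ValueError, match="two distinct exposure"):
            fit_tva(trials)

    def test_all_zero_scores_flagged(self):
        trials = _two_condition_trials((0, 0, 0, 0), (0, 0, 0, 0))
        fit = fit_tva(trials)
        assert not fit.identifiable
        assert fit.params.C == pytest.approx(FitConfig().c_bounds[0], abs=1e-6)

    def test_order_invariance(self, simulated_child):
        _, trials = simulated_child
        f1 = fit_tva(trials)
        f2 = fit_tva(list(reversed(trials)))
        assert f1.params == f2.params

    def test_determinism(self, simulated_child):
        _, trials = simulated_child
        assert fit_tva(trials).params == fit_tva(trials).params

    def test_likelihood_beats_truth(self, simulated_child):
        # the ML optimum can never be worse than the generating parameters
        truth, trials = simulated_child
        fit = fit_tva(trials)
        assert fit.neg_log_likelihood <= negative_log_likelihood(truth, trials) + 1e-6

    def test_profile_sanity(self, simulated_child):
        # perturbing any single parameter away from the optimum cannot
        # improve the likelihood
        _, trials = simulated_child
        fit = fit_tva(trials)
        base = fit.neg_log_likelihood
        p = fit.params
        for dp in (
            dict(C=p.C * 1.05),
            dict(C=p.C * 0.95),
            dict(K=min(p.K + 0.2, 6.0)),
            dict(K=max(p.K - 0.2, 0.5)),
            dict(t0=p.t0 + 0.002),
            dict(mu=p.mu * 1.1),
        ):
            perturbed = TVAParams(**{**p.__dict__, **dp})
            assert negative_log_likelihood(perturbed, trials) >= base - 1e-6

    def test_recovers_generating_parameters(self, simulated_child):
        truth, trials = simulated_child
        fit = fit_tva(trials)
        assert fit.params.C == pytest.approx(truth.C, rel=0.35)
        assert fit.params.K == pytest.approx(truth.K, abs=0.5)


class TestRecoveryHarness:
    def test_median_errors_within_tolerance(self, recovery_50):
        # tolerances frozen from a pre-build recovery simulation: median
        # |error| in C below 20% of truth, in K below 0.4 elements
        est = recovery_50.estimates
        assert np.median(np.abs(est["C"] - 24.6)) / 24.6 < 0.20
        assert np.median(np.abs(est["K"] - 3.6)) < 0.4

    def test_median_fit_quality(self, recovery_50):
        assert np.median(recovery_50.estimates["fit_r"]) >= 0.75


class TestFitQuality:
    def test_perfect_fit(self, simulated_child):
        _, trials = simulated_child
        fit = fit_tva(trials)
        fit.fitted_means = fit.empirical_means.copy()
        assert fit_quality(fit) == pytest.approx(1.0)

    def test_anticorrelated(self, simulated_child):
        _, trials = simulated_child
        fit = fit_tva(trials)
        fit.empirical_means = np.array([1.0, 2.0, 3.0] * 4)[: len(fit.conditions)]
        fit.fitted_means = -fit.empirical_means
        assert fit_quality(fit) == pytest.approx(-1.0)

    def test_constant_empirical_flagged(self, simulated_child):
        _, trials = simulated_child
        fit = fit_tva(trials)
        fit.empirical_means = np.ones(len(fit.conditions))
        assert math.isnan(fit_quality(fit))


class TestAverageFitQuality:
    def test_equal_rs(self):
        assert average_fit_quality([0.8, 0.8, 0.8]) == pytest.approx(0.8)

    def test_zeros(self):
        assert average_fit_quality([0.0, 0.0]) == 0.0

    def test_fisher_mean(self):
        # tanh((atanh .6 + atanh .9)/2) evaluated directly
        expected = math.tanh((math.atanh(0.6) + math.atanh(0.9)) / 2.0)
        assert average_fit_quality([0.6, 0.9]) == pytest.approx(expected, abs=1e-9)
        assert average_fit_quality([0.6, 0.9]) == pytest.approx(0.7942, abs=5e-5)

    def test_boundary_clipped(self):
        assert average_fit_quality([1.0, 1.0]) < 1.0


class TestBootstrapFit:
    def test_zero_resamples(self, simulated_child):
        _, trials = simulated_child
        fit = bootstrap_fit(trials, B=0)
        assert fit.bootstrap_sd == {}

    def test_reproducible(self, simulated_child):
        _, trials = simulated_child
        f1 = bootstrap_fit(trials, B=25, rng=5)
        f2 = bootstrap_fit(trials, B=25, rng=5)
        assert f1.bootstrap_sd == f2.bootstrap_sd

    def test_sd_shrinks_with_data(self):
        truth = TVAParams(C=24.6, K=3.6, t0=0.004, mu=0.184)
        from vaspan.synthetic_data import ExposureDesign, d_min_analytic

        design = ExposureDesign(d_min=d_min_analytic(truth))
        rng = np.random.default_rng(3)
        sds = []
        for tpc in (15, 120):
            trials = [
                TrialRecord("kid", cond, int(s))
                for cond in design.conditions()
                for s in simulate_scores(cond, truth, tpc, rng)
            ]
            sds.append(bootstrap_fit(trials, B=30, rng=1).bootstrap_sd["C"])
        assert sds[1] < sds[0]

    def test_bootstrap_sd_calibrated(self, recovery_50):
        # bootstrap SD of C for one child should agree with the spread of
        # the estimator across replicate children within a factor of 2
        cid = recovery_50.estimates.index[0]
        fit = bootstrap_fit(recovery_50.trials_by_child[cid], B=100, rng=11)
        across = recovery_50.estimates["C"].std(ddof=1)
        assert across / 2 < fit.bootstrap_sd["C"] < across * 2
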