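"""Cox partial likelihood, penalized fitting and classical statistics."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from combocox import (
    CoxFitResult,
    DegenerateDataError,
    FittingError,
    InputError,
    fit_cox,
    gradient_and_hessian,
    kaplan_meier,
    likelihood_ratio_test,
    log_partial_likelihood,
    logrank_test,
)
from combocox.path import lambda_max
from combocox.survival import CoxPartialLikelihood, kkt_residual

from .oracles import km_by_hand, logrank_by_hand, naive_gradient, naive_loglik


def _design(fixture):
    return fixture.items.astype(float), fixture.time, fixture.event


class TestLogPartialLikelihood:
    def test_null_model_reduces_to_risk_set_sizes(self, small_fixture):
        """At beta = 0 with no ties each event contributes -log(risk-set size)."""
        X, time, event = _design(small_fixture)
        time = time + 1e-9 * np.arange(len(time))  # break any accidental ties
        beta = np.zeros(X.shape[1])
        expected = -sum(
            np.log((time >= t).sum()) for t in time[event == 1]
        )
        got = log_partial_likelihood(beta, X, time, event)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_subject_is_its_own_risk_set(self):
        ll = log_partial_likelihood(
            np.array([2.3]), np.array([[1.0]]), np.array([5.0]), np.array([1])
        )
        assert ll == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_naive_loop_implementation(self, tied_fixture, ties):
        X, time, event = _design(tied_fixture)
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.5, X.shape[1])
        got = log_partial_likelihood(beta, X, time, event, ties=ties)
        if ties == "breslow":
            assert got == pytest.approx(naive_loglik(beta, X, time, event),
                                        rel=1e-12)
        else:
            assert np.isfinite(got)

    def test_five_subject_breslow_tie_oracle(self):
        """Hand-checkable 5-subject dataset with one tied event time."""
        X = np.array([[1.0], [0.0], [1.0], [0.0], [1.0]])
        time = np.array([2.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 1])
        beta = np.array([0.7])
        got = log_partial_likelihood(beta, X, time, event, ties="breslow")
        assert got == pytest.approx(naive_loglik(beta, X, time, event), rel=1e-12)

    def test_errors(self, small_fixture):
        X, time, event = _design(small_fixture)
        with pytest.raises(InputError):
            log_partial_likelihood(np.zeros(X.shape[1] + 1), X, time, event)
        with pytest.raises(DegenerateDataError):
            log_partial_likelihood(np.zeros(X.shape[1]), X, time,
                                   np.zeros_like(event))

    def test_concavity_on_random_segments(self, small_fixture):
        """Midpoint value of the log PL is >= the mean of the endpoints."""
        X, time, event = _design(small_fixture)
        rng = np.random.default_rng(42)
        for _ in range(100):
            b1 = rng.normal(0, 1.0, X.shape[1])
            b2 = rng.normal(0, 1.0, X.shape[1])
            mid = log_partial_likelihood((b1 + b2) / 2, X, time, event)
            ends = (
                log_partial_likelihood(b1, X, time, event)
                + log_partial_likelihood(b2, X, time, event)
            ) / 2
            assert mid >= ends - 1e-9

    def test_sample_permutation_invariance(self, tied_fixture):
        X, time, event = _design(tied_fixture)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(time))
        beta = rng.normal(0, 0.4, X.shape[1])
        for ties in ("breslow", "efron"):
            a = log_partial_likelihood(beta, X, time, event, ties=ties)
            b = log_partial_likelihood(beta, X[perm], time[perm], event[perm],
                                       ties=ties)
            assert a == pytest.approx(b, rel=1e-12)


class TestDerivatives:
    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_gradient_matches_central_differences(self, tied_fixture, ties):
        X, time, event = _design(tied_fixture)
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 0.5, X.shape[1])
        grad, _ = gradient_and_hessian(beta, X, time, event, ties=ties)
        h = 1e-6
        for j in range(len(beta)):
            e = np.zeros_like(beta)
            e[j] = h
            fd = (
                log_partial_likelihood(beta + e, X, time, event, ties=ties)
                - log_partial_likelihood(beta - e, X, time, event, ties=ties)
            ) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_hessian_matches_gradient_differences(self, tied_fixture, ties):
        X, time, event = _design(tied_fixture)
        rng = np.random.default_rng(2)
        beta = rng.normal(0, 0.5, X.shape[1])
        _, H = gradient_and_hessian(beta, X, time, event, ties=ties)
        h = 1e-6
        for j in range(len(beta)):
            e = np.zeros_like(beta)
            e[j] = h
            g_plus, _ = gradient_and_hessian(beta + e, X, time, event, ties=ties)
            g_minus, _ = gradient_and_hessian(beta - e, X, time, event, ties=ties)
            fd = (g_plus - g_minus) / (2 * h)
            np.testing.assert_allclose(H[:, j], fd, rtol=1e-4, atol=1e-6)

    def test_hessian_negative_semidefinite(self, small_fixture):
        X, time, event = _design(small_fixture)
        _, H = gradient_and_hessian(np.full(X.shape[1], 0.3), X, time, event)
        eigs = np.linalg.eigvalsh(H)
        assert eigs.max() <= 1e-10

    def test_absent_covariate_has_zero_gradient(self, small_fixture):
        X, time, event = _design(small_fixture)
        X = np.column_stack([X, np.zeros(len(time))])
        grad, _ = gradient_and_hessian(np.zeros(X.shape[1]), X, time, event)
        assert grad[-1] == 0.0


class TestFitCox:
    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = (np.arange(n) % 2).astype(float)  # perfectly balanced, no effect
        time = rng.exponential(1.0, n)
        event = np.ones(n, dtype=int)
        res = fit_cox(x[:, None], time, event)
        se = np.sqrt(4 / n)  # binary balanced covariate, all events
        assert abs(res.beta[0]) < 3 * se

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = (rng.random((n, 2)) < 0.4).astype(float)
        true = np.array([1.0, -0.5])
        T = rng.exponential(1.0 / (0.2 * np.exp(X @ true)))
        C = rng.exponential(15.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        res = fit_cox(X, time, event)
        _, H = gradient_and_hessian(res.beta, X, time, event)
        se = np.sqrt(np.diag(np.linalg.inv(-H)))
        assert np.all(np.abs(res.beta - true) < 3 * se)

    def test_penalty_at_lambda_max_gives_null_model(self, small_fixture):
        lam_max, _ = lambda_max(small_fixture, max_order=1)
        X, time, event = _design(small_fixture)
        res = fit_cox(X, time, event, l1_lambda=lam_max * 1.0001)
        assert np.all(res.beta == 0.0)
        assert res.converged

    @pytest.mark.parametrize("lam", [0.0, 0.5, 2.0])
    def test_kkt_residual_certified(self, small_fixture, lam):
        """The returned optimum satisfies the subgradient conditions, checked
        against an independently computed gradient."""
        X, time, event = _design(small_fixture)
        res = fit_cox(X, time, event, l1_lambda=lam, tol=1e-9)
        g = -naive_gradient(res.beta, X, time, event)
        assert kkt_residual(g, res.beta, lam) < 1e-7

    def test_agrees_with_lifelines_unpenalized(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        n = 120
        X = (rng.random((n, 3)) < 0.4).astype(float)
        T = rng.exponential(1.0 / (0.2 * np.exp(X @ [0.8, -0.4, 0.0])))
        time, event = T, np.ones(n, dtype=int)
        ours = fit_cox(X, time, event, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["d"] = time, event
        ref = CoxPHFitter().fit(df, "t", "d")
        np.testing.assert_allclose(ours.beta, ref.params_.values, rtol=1e-4)
        assert ours.log_partial_likelihood == pytest.approx(
            ref.log_likelihood_, rel=1e-8
        )

    def test_agrees_with_r_coxph_breslow(self, tmp_path):
        """Breslow tie handling cross-checked against survival::coxph."""
        rng = np.random.default_rng(8)
        n = 40
        X = (rng.random((n, 2)) < 0.5).astype(float)
        time = rng.integers(1, 10, n).astype(float)
        event = (rng.random(n) < 0.7).astype(int)
        event[:2] = 1
        ours = fit_cox(X, time, event, ties="breslow")
        df = pd.DataFrame({"t": time, "d": event, "x1": X[:, 0], "x2": X[:, 1]})
        csv = tmp_path / "fix.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            f <- coxph(Surv(t, d) ~ x1 + x2, data=d, ties="breslow")
            cat(sprintf("%.14g", c(coef(f), f$loglik[2])), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        np.testing.assert_allclose(ours.beta, vals[:2], rtol=1e-5)
        assert ours.log_partial_likelihood == pytest.approx(vals[2], rel=1e-8)

    def test_warm_start_already_optimal_returns_quickly(self, small_fixture):
        X, time, event = _design(small_fixture)
        first = fit_cox(X, time, event, l1_lambda=1.0)
        second = fit_cox(X, time, event, l1_lambda=1.0, warm_start=first.beta)
        assert second.n_iter <= 2
        np.testing.assert_allclose(second.beta, first.beta, atol=1e-10)


class TestKaplanMeier:
    def test_reduces_to_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(9)
        time = rng.exponential(1.0, 50)
        event = np.ones(50, dtype=int)
        curve = kaplan_meier(time, event)[0]
        for t in np.sort(time):
            assert curve.at(t) == pytest.approx((time > t).mean(), abs=1e-12)

    def test_all_censored_is_flat_at_one(self):
        time = np.arange(1.0, 6.0)
        curve = kaplan_meier(time, np.zeros(5, dtype=int))[0]
        assert np.all(curve.survival == 1.0)

    def test_six_subject_product_limit_by_hand(self):
        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 0, 1])
        curve = kaplan_meier(time, event)[0]
        tl, sv = km_by_hand(time, event)
        for t, s in zip(tl[1:], sv[1:]):
            assert curve.at(t) == pytest.approx(s, rel=1e-12)

    def test_two_strata_and_empty_stratum_error(self, small_fixture):
        group = small_fixture.items[:, 0].astype(int)
        curves = kaplan_meier(small_fixture.time, small_fixture.event, group)
        assert set(curves) == {0, 1}
        with pytest.raises(InputError):
            kaplan_meier(small_fixture.time, small_fixture.event,
                         np.ones_like(group))


class TestLogrank:
    def test_identical_experience_gives_null_statistic(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1])
        stat, p = logrank_test(time, event, group)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_observed_minus_expected(self):
        rng = np.random.default_rng(10)
        time = rng.exponential(1.0, 30)
        event = (rng.random(30) < 0.8).astype(int)
        group = (rng.random(30) < 0.5).astype(int)
        stat, p = logrank_test(time, event, group)
        stat_h, p_h = logrank_by_hand(time, event, group)
        assert stat == pytest.approx(stat_h, rel=1e-9)
        assert p == pytest.approx(p_h, rel=1e-9)

    def test_type_one_error_under_label_permutation(self):
        """Empirical size at alpha = 0.05 stays within 0.05 +- 0.02."""
        rng = np.random.default_rng(11)
        n = 80
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.75).astype(int)
        group = np.array([0, 1] * (n // 2))
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            g = rng.permutation(group)
            _, p = logrank_by_hand(time, event, g)
            rejections += p <= 0.05
        assert abs(rejections / n_perm - 0.05) <= 0.02


class TestLikelihoodRatio:
    def test_identical_models_give_p_one(self):
        r = CoxFitResult(beta=np.zeros(1), log_partial_likelihood=-10.0,
                         n_iter=1, converged=True)
        assert likelihood_ratio_test(r, r, df=1) == pytest.approx(1.0)

    def test_chi_square_quantile_identity(self):
        full = CoxFitResult(beta=np.zeros(2), log_partial_likelihood=-10.0,
                            n_iter=1, converged=True)
        reduced = CoxFitResult(beta=np.zeros(1),
                               log_partial_likelihood=-10.0 - 3.841 / 2,
                               n_iter=1, converged=True)
        assert likelihood_ratio_test(full, reduced, df=1) == pytest.approx(
            0.05, abs=5e-4
        )

    def test_reduced_better_than_full_signals_failure(self):
        full = CoxFitResult(beta=np.zeros(2), log_partial_likelihood=-12.0,
                            n_iter=1, converged=True)
        reduced = CoxFitResult(beta=np.zeros(1), log_partial_likelihood=-10.0,
                               n_iter=1, converged=True)
        with pytest.raises(FittingError):
            likelihood_ratio_test(full, reduced, df=1)


class TestEfronVsBreslow:
    def test_agree_when_no_ties(self, small_fixture):
        X, time, event = _design(small_fixture)
        time = time + 1e-9 * np.arange(len(time))
        beta = np.full(X.shape[1], 0.2)
        a = log_partial_likelihood(beta, X, time, event, ties="breslow")
        b = log_partial_likelihood(beta, X, time, event, ties="efron")
        assert a == pytest.approx(b, rel=1e-12)

    def test_direction_weights_match_hessian_contraction(self, tied_fixture):
        """The per-sample step-search weights reproduce x^T H g exactly."""
        X, time, event = _design(tied_fixture)
        rng = np.random.default_rng(12)
        beta = rng.normal(0, 0.4, X.shape[1])
        g_dir = rng.normal(0, 1.0, len(time))
        for ties in ("breslow", "efron"):
            pl = CoxPartialLikelihood(time, event, ties)
            eta = X @ beta
            v = pl.direction_weights(eta, g_dir)
            # reference: full Hessian in an extended design with g as a column
            Xe = np.column_stack([X, g_dir])
            He = pl.hessian(eta, Xe)
            expected = He[:-1, -1]  # columns of X against the g direction
            np.testing.assert_allclose(X.T @ v, expected, rtol=1e-10, atol=1e-12)
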