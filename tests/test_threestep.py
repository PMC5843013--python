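"""Bias-adjusted three-step regression: D matrix, estimator and tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from trajlca.collapse import CompositePosterior
from trajlca.threestep import (
    ErrorMatrix,
    error_matrix,
    fit_threestep,
    modal_assign,
    omnibus_test,
    wald_intervals,
)


def make_posterior(probs):
    probs = np.asarray(probs, dtype=float)
    return CompositePosterior(probs, np.arange(probs.shape[0]))


class TestModalAssign:
    def test_clear_maximum(self):
        comp = make_posterior([[0.9, 0.05, 0.03, 0.02]])
        assert modal_assign(comp).tolist() == [0]

    def test_tie_breaks_to_less_severe_group(self):
        comp = make_posterior([[0.5, 0.5, 0, 0], [0, 0.3, 0.4, 0.3]])
        assert modal_assign(comp).tolist() == [0, 2]

    def test_agrees_with_argmax_oracle(self, rng):
        probs = rng.dirichlet(np.ones(4), size=200)
        comp = make_posterior(probs)
        np.testing.assert_array_equal(modal_assign(comp), probs.argmax(axis=1))


class TestErrorMatrix:
    def test_degenerate_posteriors_give_identity(self):
        probs = np.zeros((8, 4))
        probs[np.arange(8), np.arange(8) % 4] = 1.0
        np.testing.assert_allclose(error_matrix(make_posterior(probs)).D, np.eye(4))

    def test_uniform_posteriors_concentrate_on_normative(self):
        comp = make_posterior(np.full((10, 4), 0.25))
        d = error_matrix(comp).D
        np.testing.assert_allclose(d[:, 0], 1.0)
        np.testing.assert_allclose(d[:, 1:], 0.0)

    def test_five_child_hand_computation(self):
        probs = np.array(
            [
                [0.8, 0.1, 0.05, 0.05],
                [0.1, 0.7, 0.1, 0.1],
                [0.3, 0.3, 0.35, 0.05],
                [0.25, 0.25, 0.25, 0.25],
                [0.05, 0.05, 0.05, 0.85],
            ]
        )
        comp = make_posterior(probs)
        m = modal_assign(comp)  # [0, 1, 2, 0, 3]
        d = error_matrix(comp).D
        for t in range(4):
            for col in range(4):
                expected = probs[m == col, t].sum() / probs[:, t].sum()
                assert d[t, col] == pytest.approx(expected, abs=1e-12)

    def test_rows_sum_to_one(self, rng):
        comp = make_posterior(rng.dirichlet(np.ones(4), size=100))
        np.testing.assert_allclose(error_matrix(comp).D.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_mass_class_named_in_error(self):
        probs = np.zeros((5, 4))
        probs[:, 0] = 1.0
        with pytest.raises(ValueError, match="constipation_alone"):
            error_matrix(make_posterior(probs))


def simulate_labels(n, beta, rng, base=(0.745, 0.132, 0.075, 0.048)):
    """True class from a one-covariate multinomial logit; returns (x, t)."""
    x = (rng.random(n) < 0.5).astype(float)
    eta = np.log(base)[None, :] + x[:, None] * np.asarray(beta)[None, :]
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    t = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return x, t


def misclassify(t, D, rng):
    u = rng.random(t.size)
    return (D[t].cumsum(axis=1) < u[:, None]).sum(axis=1)


MODERATE_D = np.array(
    [
        [0.85, 0.05, 0.05, 0.05],
        [0.10, 0.80, 0.05, 0.05],
        [0.10, 0.05, 0.80, 0.05],
        [0.05, 0.10, 0.10, 0.75],
    ]
)


class TestFit:
    def test_identity_d_equals_statsmodels_mnlogit(self, rng):
        x, t = simulate_labels(3000, [0, 0.4, -0.3, 0.6], rng)
        cov = pd.DataFrame({"child_id": np.arange(x.size), "male": x})
        res = fit_threestep(t, np.eye(4), cov, ["male"])
        ref = sm.MNLogit(t, sm.add_constant(x)).fit(disp=0, method="newton", tol=1e-12)
        params = np.asarray(ref.params)
        np.testing.assert_allclose(res.coef, params, atol=1e-6)
        np.testing.assert_allclose(res.se, np.asarray(ref.bse), atol=1e-5)

    def test_gradient_norm_small_at_solution(self, rng):
        x, t = simulate_labels(2000, [0, 0.3, 0.2, -0.2], rng)
        m = misclassify(t, MODERATE_D, rng)
        cov = pd.DataFrame({"child_id": np.arange(x.size), "male": x})
        res = fit_threestep(m, MODERATE_D, cov, ["male"])
        assert res.gradient_norm < 1e-6
        assert res.converged

    def test_singular_d_rejected(self, rng):
        d = np.full((4, 4), 0.25)
        cov = pd.DataFrame({"child_id": [0, 1], "male": [0.0, 1.0]})
        with pytest.raises(ValueError, match="singular"):
            fit_threestep(np.array([0, 1]), d, cov, ["male"])

    def test_bias_adjustment_beats_naive_modal_regression(self):
        # with known misclassification, the adjusted estimator should be
        # closer to the generating log-OR than regression on modal labels
        rng = np.random.default_rng(99)
        beta_true = np.array([0, 0.5, 0.7, 0.4])
        bias_adj, bias_naive = [], []
        for _ in range(25):
            x, t = simulate_labels(3000, beta_true, rng)
            m = misclassify(t, MODERATE_D, rng)
            cov = pd.DataFrame({"child_id": np.arange(x.size), "male": x})
            adj = fit_threestep(m, MODERATE_D, cov, ["male"])
            naive = fit_threestep(m, np.eye(4), cov, ["male"])
            bias_adj.append(np.abs(adj.coef[1] - beta_true[1:]).mean())
            bias_naive.append(np.abs(naive.coef[1] - beta_true[1:]).mean())
        assert np.median(bias_adj) < np.median(bias_naive)

    def test_or_invariant_to_categorical_level_codes(self, rng):
        x, t = simulate_labels(2000, [0, 0.4, 0.1, -0.1], rng)
        levels = np.where(x > 0, "exposed", "ref_level")
        cov1 = pd.DataFrame(
            {
                "child_id": np.arange(x.size),
                "f": pd.Categorical(levels, categories=["ref_level", "exposed"]),
            }
        )
        levels2 = np.where(x > 0, "LEVEL_B", "LEVEL_A")
        cov2 = cov1.assign(
            f=pd.Categorical(levels2, categories=["LEVEL_A", "LEVEL_B"])
        )
        r1 = fit_threestep(t, np.eye(4), cov1, ["f"])
        r2 = fit_threestep(t, np.eye(4), cov2, ["f"])
        np.testing.assert_allclose(r1.coef, r2.coef, atol=1e-8)

    def test_listwise_deletion_of_missing_covariates(self, rng):
        x, t = simulate_labels(500, [0, 0.3, 0.1, 0.2], rng)
        xm = x.copy()
        xm[:50] = np.nan
        cov = pd.DataFrame({"child_id": np.arange(x.size), "male": xm})
        res = fit_threestep(t, np.eye(4), cov, ["male"])
        assert res.n_used == 450

    def test_separation_is_flagged(self):
        # covariate perfectly predicts class 1 membership
        t = np.array([0] * 50 + [1] * 50)
        x = (t == 1).astype(float)
        cov = pd.DataFrame({"child_id": np.arange(100), "male": x})
        res = fit_threestep(t, np.eye(4), cov, ["male"])
        assert res.separation


class TestWaldAndOmnibus:
    def _result_with(self, coef, se):
        from trajlca.threestep import ThreeStepResult

        coef = np.asarray(coef, dtype=float)
        p, km1 = coef.shape
        cov = np.diag(np.asarray(se, dtype=float).ravel(order="F") ** 2)
        return ThreeStepResult(
            coef=coef,
            cov=cov,
            term_names=["intercept", "male"][:p],
            class_labels=["normative", "a", "b", "c"][: km1 + 1],
            loglik=0.0,
            n_used=100,
            gradient_norm=0.0,
            converged=True,
            factor_terms={"male": [1]} if p > 1 else {"x": [0]},
        )

    def test_interval_closed_form(self):
        res = self._result_with(np.zeros((1, 3)), np.full((1, 3), 0.1))
        res.factor_terms = {"x": [0]}
        res.term_names = ["x"]
        table = wald_intervals(res)
        assert table["or"].tolist() == [1.0, 1.0, 1.0]
        np.testing.assert_allclose(table["ci_low"], np.exp(-1.959964 * 0.1), atol=1e-5)
        np.testing.assert_allclose(table["ci_high"], np.exp(1.959964 * 0.1), atol=1e-5)

    def test_zero_se_degenerate_interval(self):
        res = self._result_with(np.full((1, 3), np.log(2)), np.zeros((1, 3)))
        res.factor_terms = {"x": [0]}
        res.term_names = ["x"]
        table = wald_intervals(res)
        np.testing.assert_allclose(table["ci_low"], 2.0)
        np.testing.assert_allclose(table["ci_high"], 2.0)

    def test_omnibus_p_is_one_when_block_zero(self):
        res = self._result_with(np.zeros((2, 3)), np.ones((2, 3)))
        assert omnibus_test(res, "male") == pytest.approx(1.0)

    def test_single_coefficient_at_z_1_96(self):
        coef = np.zeros((1, 1))
        coef[0, 0] = 1.96 * 0.5
        res = self._result_with(coef, np.full((1, 1), 0.5))
        res.class_labels = ["normative", "a"]
        res.factor_terms = {"x": [0]}
        p = omnibus_test(res, "x")
        assert p == pytest.approx(stats.chi2.sf(1.96**2, 1), abs=1e-10)
        assert p == pytest.approx(0.05, abs=0.001)


def test_power_against_strong_simulated_effect():
    """A generating OR of 2 is detected (p < 0.001) in nearly all replicates."""
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(20):
        x, t = simulate_labels(8435, [0, np.log(2), np.log(2), np.log(2)], rng)
        m = misclassify(t, MODERATE_D, rng)
        cov = pd.DataFrame({"child_id": np.arange(x.size), "male": x})
        res = fit_threestep(m, MODERATE_D, cov, ["male"])
        hits += omnibus_test(res, "male") < 0.001
    assert hits >= 19
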