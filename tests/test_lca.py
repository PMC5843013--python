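"""Single-process LLCA: likelihood arithmetic, EM behaviour, ordering, BIC."""

import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit, logsumexp

from trajlca.lca import (
    LCAParams,
    canonical_order,
    compute_loglik,
    em_fit,
    enumerate_classes,
    label_classes,
    posterior_probs,
)
from trajlca.panel import ResponsePanel
from trajlca.simulate import GeneratorConfig, generate_cohort


def make_panel(values):
    values = np.asarray(values, dtype=float)
    return ResponsePanel(values, np.arange(values.shape[0]), "toy")


TOY_PARAMS = LCAParams(
    class_weights=[0.6, 0.4], item_probs=[[0.1, 0.1], [0.9, 0.9]]
)


class TestLoglik:
    def test_single_class_half_probabilities(self):
        params = LCAParams(class_weights=[1.0], item_probs=[[0.5] * 6])
        panel = make_panel([[1, 0, 1, 0, 1, 0]])
        assert compute_loglik(params, panel) == pytest.approx(6 * np.log(0.5))

    def test_two_class_pattern_enumeration(self):
        # 0.6*0.1*0.9 + 0.4*0.9*0.1 = 0.09
        panel = make_panel([[1, 0]])
        assert compute_loglik(TOY_PARAMS, panel) == pytest.approx(np.log(0.09))

    def test_missing_waves_contribute_nothing(self):
        panel = make_panel([[1, np.nan]])
        # only wave 0 observed: 0.6*0.1 + 0.4*0.9 = 0.42
        assert compute_loglik(TOY_PARAMS, panel) == pytest.approx(np.log(0.42))

    def test_contradicting_degenerate_probability_gives_neg_inf(self):
        params = LCAParams(class_weights=[1.0], item_probs=[[0.0, 0.5]])
        panel = make_panel([[1, 0]])
        assert compute_loglik(params, panel) == -np.inf

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_loglik(TOY_PARAMS, make_panel(np.empty((0, 2))))


class TestPosterior:
    def test_single_class_posterior_is_one(self):
        params = LCAParams(class_weights=[1.0], item_probs=[[0.3, 0.7]])
        post = posterior_probs(params, make_panel([[1, 0], [0, 0]]))
        np.testing.assert_array_equal(post.probs, 1.0)
        assert post.entropy_quality == 1.0

    def test_symmetric_model_symmetric_pattern(self):
        # mirror-image profiles with equal weights: a pattern invariant
        # under the class swap (here (1,1): 0.1*0.9 vs 0.9*0.1) splits 50/50
        params = LCAParams(
            class_weights=[0.5, 0.5], item_probs=[[0.1, 0.9], [0.9, 0.1]]
        )
        post = posterior_probs(params, make_panel([[1, 1]]))
        np.testing.assert_allclose(post.probs[0], [0.5, 0.5])

    def test_hand_bayes_rule(self):
        post = posterior_probs(TOY_PARAMS, make_panel([[1, 0]]))
        assert post.probs[0, 0] == pytest.approx(0.054 / 0.09)

    def test_zero_likelihood_child_is_reported(self):
        params = LCAParams(class_weights=[1.0], item_probs=[[0.0, 0.5]])
        with pytest.raises(ValueError, match="zero likelihood"):
            posterior_probs(params, make_panel([[1, 0]]))


def brute_force_two_class_loglik(panel):
    """Direct numerical maximisation over the 5 free parameters (C=2, T=2)."""

    def negll(theta):
        pi1 = expit(theta[0])
        rho = expit(theta[1:]).reshape(2, 2)
        params = LCAParams(class_weights=[pi1, 1 - pi1], item_probs=rho)
        return -compute_loglik(params, panel)

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(40):
        x0 = rng.normal(scale=2.0, size=5)
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return -best


class TestEM:
    def test_one_class_closed_form(self):
        panel = make_panel([[1, 0], [1, 1], [0, 0], [1, np.nan]])
        params, post = em_fit(panel, 1)
        assert params.class_weights.tolist() == [1.0]
        # observed means: wave0 3/4, wave1 1/3
        np.testing.assert_allclose(params.item_probs[0], [0.75, 1 / 3], atol=1e-9)
        np.testing.assert_array_equal(post.probs, 1.0)

    def test_matches_brute_force_oracle(self, two_wave_toy_panel):
        params, _ = em_fit(two_wave_toy_panel, 2, n_starts=20, seed=1)
        oracle = brute_force_two_class_loglik(two_wave_toy_panel)
        assert params.loglik == pytest.approx(oracle, abs=1e-6)

    def test_monotone_ascent_over_many_random_starts(self, two_wave_toy_panel):
        history = []
        em_fit(two_wave_toy_panel, 2, n_starts=100, seed=2, loglik_history=history)
        assert len(history) == 100
        for start in history:
            diffs = np.diff(start)
            assert (diffs >= -1e-9 * np.abs(start[1:])).all()

    def test_deleting_a_wave_equals_fitting_reduced_panel(self, rng):
        values = rng.integers(0, 2, size=(200, 4)).astype(float)
        full = values.copy()
        full[:, 2] = np.nan  # wave 2 unobserved for everyone
        init_full = LCAParams(
            class_weights=[0.5, 0.5],
            item_probs=[[0.2, 0.3, 0.5, 0.4], [0.7, 0.6, 0.5, 0.8]],
        )
        init_red = LCAParams(
            class_weights=[0.5, 0.5],
            item_probs=[[0.2, 0.3, 0.4], [0.7, 0.6, 0.8]],
        )
        pf, _ = em_fit(make_panel(full), 2, n_starts=0, init=init_full,
                       canonicalize=False)
        pr, _ = em_fit(make_panel(np.delete(values, 2, axis=1)), 2, n_starts=0,
                       init=init_red, canonicalize=False)
        assert pf.loglik == pytest.approx(pr.loglik, abs=1e-9)
        np.testing.assert_allclose(pf.class_weights, pr.class_weights, atol=1e-9)
        np.testing.assert_allclose(
            np.delete(pf.item_probs, 2, axis=1), pr.item_probs, atol=1e-9
        )

    def test_parameter_recovery_on_well_separated_cohort(self):
        # median recovered parameters over replicates are within 0.03 of truth
        weights, probs = [], []
        for rep in range(9):
            cfg = GeneratorConfig(n_children=10_000, seed=500 + rep)
            cohort = generate_cohort(cfg)
            params, _ = em_fit(cohort.constipation, 4, n_starts=10, seed=rep)
            weights.append(params.class_weights)
            probs.append(params.item_probs)
        truth_weights = cfg.joint_class_weights.sum(axis=0)  # constipation marginal
        np.testing.assert_allclose(
            np.median(weights, axis=0), truth_weights, atol=0.03
        )
        np.testing.assert_allclose(
            np.median(probs, axis=0), cfg.constipation_profiles, atol=0.03
        )

    def test_more_classes_than_patterns_warns(self):
        panel = make_panel([[0, 0]] * 10 + [[1, 1]] * 10)
        with pytest.warns(UserWarning, match="distinct"):
            em_fit(panel, 4, n_starts=3, seed=0)


class TestCanonicalOrder:
    def test_idempotent_on_ordered_params(self):
        params = LCAParams(
            class_weights=[0.7, 0.2, 0.1],
            item_probs=[[0.05, 0.05], [0.4, 0.5], [0.9, 0.9]],
        )
        out = canonical_order(params)
        np.testing.assert_array_equal(out.class_weights, params.class_weights)
        np.testing.assert_array_equal(out.item_probs, params.item_probs)

    def test_permutation_invariance(self, rng):
        params = LCAParams(
            class_weights=[0.1, 0.6, 0.3],
            item_probs=[[0.9, 0.8], [0.02, 0.04], [0.3, 0.6]],
        )
        base = canonical_order(params)
        for _ in range(5):
            perm = rng.permutation(3)
            shuffled = LCAParams(
                class_weights=params.class_weights[perm],
                item_probs=params.item_probs[perm],
            )
            out = canonical_order(shuffled)
            np.testing.assert_allclose(out.class_weights, base.class_weights)
            np.testing.assert_allclose(out.item_probs, base.item_probs)

    def test_early_and_late_labels_follow_profile_shape(self):
        cfg = GeneratorConfig(n_children=6000, seed=9)
        cohort = generate_cohort(cfg)
        params, _ = em_fit(cohort.constipation, 4, n_starts=10, seed=10)
        names = label_classes(params)
        assert names[0] == "normative"
        assert sorted(names[1:]) == ["early", "late", "persistent"]
        early = params.item_probs[names.index("early")]
        late = params.item_probs[names.index("late")]
        assert early[:3].mean() > early[3:].mean()
        assert late[:3].mean() < late[3:].mean()


class TestEnumeration:
    def test_single_pattern_panel_selects_one_class(self):
        panel = make_panel(np.zeros((60, 3)))
        table = enumerate_classes(panel, 1, 3, n_starts=5, seed=0)
        assert table.loc[table.best_bic, "n_classes"].item() == 1

    def test_bic_formula(self, two_wave_toy_panel):
        table = enumerate_classes(two_wave_toy_panel, 1, 2, n_starts=5, seed=0)
        row = table.iloc[1]
        expected = -2 * row.loglik + row.n_params * np.log(100)
        assert row.bic == pytest.approx(expected)

    def test_selects_four_classes_on_well_separated_data(self):
        hits = 0
        for rep in range(5):
            cfg = GeneratorConfig(n_children=4000, seed=100 + rep)
            cohort = generate_cohort(cfg)
            table = enumerate_classes(
                cohort.constipation, 3, 5, n_starts=8, seed=rep
            )
            hits += table.loc[table.best_bic, "n_classes"].item() == 4
        assert hits >= 4
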