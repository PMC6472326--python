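"""Cross-entropy SAM balancing and regularity-constrained AIDS estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from fiscalfood import (AIDSParameters, ElasticityPriors, InfeasibleBalanceError,
                        SAM, aids_elasticities, balance_sam, elasticities_to_aids,
                        estimate_aids)


def _sam(values, accounts=None):
    n = len(values)
    accounts = accounts or [f"a{i}" for i in range(n)]
    return SAM(pd.DataFrame(np.asarray(values, float), index=accounts,
                            columns=accounts))


def _balanced_prior():
    # a small balanced flow matrix (row sums equal column sums)
    q = np.array([[0.0, 4.0, 2.0],
                  [5.0, 0.0, 3.0],
                  [1.0, 4.0, 0.0]])
    assert np.allclose(q.sum(axis=1), q.sum(axis=0))
    return q


class TestBalanceSam:
    def test_balanced_prior_returned_unchanged(self):
        prior = _sam(_balanced_prior())
        out = balance_sam(prior)
        assert np.max(np.abs(out.values - prior.values)) < 1e-10

    def test_perturbed_cell_balances_and_matches_generic_optimizer(self):
        """The entropy-dual solution must agree with a generic constrained
        optimiser run on the identical program (independent oracle)."""
        q = _balanced_prior()
        q[0, 1] *= 1.3                      # one perturbed cell
        out = balance_sam(_sam(q))
        assert out.max_imbalance() < 1e-8

        mask = q > 0
        x0 = q[mask]

        def objective(x):
            a = np.zeros_like(q)
            a[mask] = x
            return float((x * np.log(x / x0) - x + x0).sum())

        def balance_cons(x):
            a = np.zeros_like(q)
            a[mask] = x
            return (a.sum(axis=1) - a.sum(axis=0))[:-1]

        res = optimize.minimize(objective, x0, method="SLSQP",
                                constraints={"type": "eq", "fun": balance_cons},
                                bounds=[(1e-9, None)] * mask.sum(),
                                options={"maxiter": 500, "ftol": 1e-14})
        oracle = np.zeros_like(q)
        oracle[mask] = res.x
        assert np.max(np.abs(out.values - oracle)) < 1e-5

    def test_structural_zero_row_with_positive_column_is_infeasible(self):
        q = np.array([[0.0, 2.0, 1.0],
                      [0.0, 0.0, 0.0],      # account pays nothing...
                      [1.0, 1.0, 0.0]])
        q[0, 1] = 2.0                       # ...but receives income
        with pytest.raises(InfeasibleBalanceError) as err:
            balance_sam(_sam(q, ["x", "dead", "z"]))
        assert "dead" in str(err.value)

    def test_idempotent_on_random_priors(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            q = rng.random((4, 4)) + 0.1
            np.fill_diagonal(q, 0.0)
            once = balance_sam(_sam(q))
            twice = balance_sam(once)
            assert np.max(np.abs(twice.values - once.values)) < 1e-9

    def test_margin_targets_are_met(self):
        q = _balanced_prior()
        targets = {"a0": 7.0, "a1": 9.0, "a2": 6.0}
        out = balance_sam(_sam(q), targets=targets)
        t = np.array([targets[a] for a in out.accounts])
        assert np.allclose(out.row_sums(), t, atol=1e-8)
        assert np.allclose(out.col_sums(), t, atol=1e-8)

    def test_noisy_sam_moves_toward_truth(self, noisy_bundle):
        truth, unbalanced, _ = noisy_bundle
        posterior = balance_sam(unbalanced)
        t = truth.balanced_sam.values
        assert (np.linalg.norm(posterior.values - t)
                < np.linalg.norm(unbalanced.values - t))


def _random_regular_params(n=4, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(n, 5.0))
    eta = 0.8 + 0.5 * rng.random(n)
    eta += 1.0 - w @ eta
    beta = w * (eta - 1.0)
    S = rng.random((n, n))
    S = 0.1 * (S + S.T) * np.outer(w, w)
    S = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    return AIDSParameters(["c%d" % i for i in range(n)], ["h"], w[None],
                          beta[None], S[None], np.array([np.log(10.0)])), w


class TestElasticityInversion:
    def test_roundtrip_on_consistent_system(self):
        """Forward elasticity formulas applied to the inverted parameters
        must reproduce the input elasticities (closed-form oracle)."""
        params, w = _random_regular_params(seed=3)
        eps, eta = aids_elasticities(params, w[None])
        priors = ElasticityPriors(params.commodities, params.households,
                                  eps, eta, w[None])
        inv = elasticities_to_aids(priors, np.array([10.0]))
        eps2, eta2 = aids_elasticities(inv, w[None])
        assert np.max(np.abs(eps2 - eps)) < 1e-10
        assert np.max(np.abs(eta2 - eta)) < 1e-10

    def test_homothetic_case_gives_zero_expenditure_coefficients(self):
        n = 4
        w = np.full(n, 0.25)
        priors = ElasticityPriors([f"c{i}" for i in range(n)], ["h"],
                                  -np.eye(n)[None], np.ones((1, n)), w[None])
        out = elasticities_to_aids(priors)
        assert np.allclose(out.beta, 0.0, atol=1e-14)

    def test_cobb_douglas_pattern_gives_zero_parameters(self):
        n = 3
        w = np.array([0.2, 0.3, 0.5])
        eps = -np.eye(n) + 0.0
        priors = ElasticityPriors([f"c{i}" for i in range(n)], ["h"],
                                  eps[None], np.ones((1, n)), w[None])
        out = elasticities_to_aids(priors)
        # Cobb-Douglas: gamma_ij = w_i w_j - w_i delta_ij + beta pattern = 0
        assert np.allclose(out.beta, 0.0, atol=1e-14)
        expected_gamma = np.zeros((n, n))
        got = out.gamma[0] - (np.outer(w, w) - np.diag(w) + np.eye(n) * w)
        # direct check: eps_ij reproduced as Cobb-Douglas
        eps2, eta2 = aids_elasticities(out, w[None])
        assert np.allclose(eps2[0], eps, atol=1e-12)
        assert np.allclose(eta2, 1.0, atol=1e-12)

    def test_zero_share_raises_per_commodity(self):
        w = np.array([[0.5, 0.5, 0.0]])
        with pytest.raises(ValueError):
            ElasticityPriors(["a", "b", "c"], ["h"], -np.eye(3)[None],
                             np.ones((1, 3)), w)


class TestEstimateAids:
    def test_regular_prior_is_fixed_point(self):
        params, _ = _random_regular_params(seed=5)
        post = estimate_aids(params)
        assert np.max(np.abs(post.gamma - params.gamma)) < 1e-8
        assert np.max(np.abs(post.beta - params.beta)) < 1e-8

    def test_symmetry_violation_resolves_to_midpoint(self):
        """Adding a doubly-centred antisymmetric perturbation leaves the
        projection at the symmetric part, i.e. each pair of cross terms at
        its midpoint; verified against a generic SLSQP solve."""
        params, w = _random_regular_params(n=3, seed=7)
        x = np.array([1.0, -0.5, -0.5])
        y = np.array([-0.5, 1.0, -0.5])
        A = 0.01 * (np.outer(x, y) - np.outer(y, x))     # antisymmetric, centred
        prior = AIDSParameters(params.commodities, params.households,
                               params.alpha, params.beta,
                               (params.gamma[0] + A)[None], params.anchor)
        post = estimate_aids(prior)
        mid = 0.5 * (prior.gamma[0] + prior.gamma[0].T)
        assert np.max(np.abs(post.gamma[0] - mid)) < 1e-6
        g = prior.gamma[0]
        assert np.allclose(post.gamma[0][0, 1],
                           0.5 * (g[0, 1] + g[1, 0]), atol=1e-6)

    def test_projection_matches_generic_optimizer(self):
        rng = np.random.default_rng(11)
        params, _ = _random_regular_params(n=3, seed=9)
        noisy = AIDSParameters(params.commodities, params.households,
                               params.alpha + 0.01 * rng.standard_normal((1, 3)),
                               params.beta + 0.01 * rng.standard_normal((1, 3)),
                               params.gamma + 0.01 * rng.standard_normal((1, 3, 3)),
                               params.anchor)
        post = estimate_aids(noisy)
        n = 3
        x0 = np.concatenate([noisy.alpha[0], noisy.beta[0], noisy.gamma[0].ravel()])

        def obj(x):
            return float(((x - x0) ** 2).sum())

        def cons(x):
            a, b = x[:n], x[n:2 * n]
            g = x[2 * n:].reshape(n, n)
            # row sums are implied by column sums plus symmetry; pass the
            # generic solver a full-rank constraint set
            return np.concatenate([[a.sum() - 1.0], [b.sum()],
                                   g.sum(axis=0),
                                   (g - g.T)[np.triu_indices(n, 1)]])

        res = optimize.minimize(obj, x0, method="SLSQP",
                                constraints={"type": "eq", "fun": cons},
                                options={"maxiter": 1000, "ftol": 1e-14})
        assert res.success
        assert np.max(np.abs(post.gamma[0].ravel() - res.x[2 * n:])) < 1e-5

    def test_invariant_to_commodity_ordering(self):
        params, _ = _random_regular_params(n=4, seed=13)
        rng = np.random.default_rng(2)
        noisy_gamma = params.gamma + 0.01 * rng.standard_normal(params.gamma.shape)
        prior = AIDSParameters(params.commodities, params.households,
                               params.alpha, params.beta, noisy_gamma,
                               params.anchor)
        post = estimate_aids(prior)
        perm = [2, 0, 3, 1]
        prior_p = AIDSParameters([params.commodities[i] for i in perm],
                                 params.households, prior.alpha[:, perm],
                                 prior.beta[:, perm],
                                 prior.gamma[:, perm][:, :, perm], params.anchor)
        post_p = estimate_aids(prior_p)
        assert np.allclose(post_p.gamma[:, :, :],
                           post.gamma[:, perm][:, :, perm], atol=1e-10)

    def test_posterior_satisfies_engel_aggregation(self, noisy_bundle):
        truth, _, priors = noisy_bundle
        prior = elasticities_to_aids(priors, np.exp(truth.aids_parameters.anchor))
        post = estimate_aids(prior)
        w = priors.shares
        _, eta = aids_elasticities(post, w)
        assert np.max(np.abs((w * eta).sum(axis=1) - 1.0)) < 1e-8
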