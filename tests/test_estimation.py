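"""Nodewise eLasso estimation: solver, EBIC selection and network assembly."""

import numpy as np
import pytest
import statsmodels.api as sm

import sevnet as sv


@pytest.fixture(scope="module")
def logit_fixture():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, (300, 3)).astype(float)
    eta = -0.5 + X @ np.array([1.0, -0.8, 0.4])
    y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, X


class TestLambdaSequence:
    def test_length_and_log_spacing(self, logit_fixture):
        y, X = logit_fixture
        lams = sv.lambda_sequence(y, X, n_lambda=30, lambda_ratio=0.05)
        assert lams.size == 30
        ratios = lams[1:] / lams[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)
        assert lams[-1] == pytest.approx(0.05 * lams[0])

    def test_first_lambda_zeroes_all_coefficients(self, logit_fixture):
        y, X = logit_fixture
        lams = sv.lambda_sequence(y, X, n_lambda=5, lambda_ratio=0.5)
        path = sv.logistic_lasso_path(y, X, lams)
        assert path.nnz[0] == 0
        assert np.all(path.coefs[0] == 0)

    def test_validation(self, logit_fixture):
        y, X = logit_fixture
        with pytest.raises(ValueError, match="n_lambda"):
            sv.lambda_sequence(y, X, n_lambda=1)
        with pytest.raises(ValueError, match="lambda_ratio"):
            sv.lambda_sequence(y, X, lambda_ratio=1.5)


class TestLogisticLassoPath:
    def test_unpenalized_limit_matches_irls_oracle(self, logit_fixture):
        """At lambda -> 0 the path solution equals the unpenalized MLE from
        an independent iteratively-reweighted fit (statsmodels)."""
        y, X = logit_fixture
        mle = np.asarray(sm.Logit(y, sm.add_constant(X)).fit(disp=0).params)
        path = sv.logistic_lasso_path(y, X, np.array([1.0, 1e-8]), tol=1e-14)
        fitted = np.r_[path.intercepts[-1], path.coefs[-1]]
        np.testing.assert_allclose(fitted, mle, atol=1e-6)

    def test_row_duplication_with_scaled_lambda_preserves_path(self, logit_fixture):
        """Duplicating every observation doubles the likelihood term, so
        doubling lambda leaves the coefficient path unchanged."""
        y, X = logit_fixture
        lams = sv.lambda_sequence(y, X, n_lambda=10, lambda_ratio=0.05)
        single = sv.logistic_lasso_path(y, X, lams, tol=1e-12)
        doubled = sv.logistic_lasso_path(
            np.tile(y, 2), np.tile(X, (2, 1)), 2 * lams, tol=1e-12
        )
        np.testing.assert_allclose(doubled.coefs, single.coefs, atol=1e-6)
        np.testing.assert_allclose(doubled.logliks, 2 * single.logliks, rtol=1e-8)

    def test_weights_equal_row_duplication(self, logit_fixture):
        y, X = logit_fixture
        lams = sv.lambda_sequence(y, X, n_lambda=8, lambda_ratio=0.1)
        weighted = sv.logistic_lasso_path(
            y, X, 2 * lams, weights=np.full(y.size, 2.0), tol=1e-12
        )
        doubled = sv.logistic_lasso_path(
            np.tile(y, 2), np.tile(X, (2, 1)), 2 * lams, tol=1e-12
        )
        np.testing.assert_allclose(weighted.coefs, doubled.coefs, atol=1e-8)

    def test_constant_response_or_predictor_is_an_error(self):
        X = np.random.default_rng(1).integers(0, 2, (50, 2)).astype(float)
        with pytest.raises(ValueError, match="constant"):
            sv.logistic_lasso_path(np.ones(50), X, np.array([1.0]))
        y = X[:, 0].copy()
        X2 = X.copy()
        X2[:, 1] = 1.0
        with pytest.raises(ValueError, match="constant"):
            sv.logistic_lasso_path(y, X2, np.array([1.0]))


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        assert sv.ebic(-50.0, 2, 200, 9, 0.0) == pytest.approx(
            100 + 2 * np.log(200)
        )

    def test_empty_model_is_minus_twice_loglik(self):
        assert sv.ebic(-123.4, 0, 50, 10, 0.25) == pytest.approx(246.8)

    def test_reference_value(self):
        # -2(-100) + 3 ln 100 + 2(0.25)(3) ln 10 = 217.269...
        assert sv.ebic(-100.0, 3, 100, 10, 0.25) == pytest.approx(
            200 + 3 * np.log(100) + 1.5 * np.log(10), abs=1e-9
        )
        assert sv.ebic(-100.0, 3, 100, 10, 0.25) == pytest.approx(217.269, abs=5e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            sv.ebic(-1.0, -1, 10, 5, 0.25)
        with pytest.raises(ValueError):
            sv.ebic(-1.0, 1, 0, 5, 0.25)
        with pytest.raises(ValueError):
            sv.ebic(-1.0, 1, 10, 5, -0.1)


class TestFitIsing:
    def test_weights_symmetric_zero_diagonal(self, chain6):
        net = sv.fit_ising(sv.sample_ising_exact(chain6, 800, seed=0))
        np.testing.assert_allclose(net.weights, net.weights.T, atol=1e-12)
        assert np.all(np.diag(net.weights) == 0)

    def test_node_relabeling_equivariance(self, chain6):
        x = sv.sample_ising_exact(chain6, 800, seed=1)
        perm = np.array([3, 0, 5, 1, 4, 2])
        net = sv.fit_ising(x, tol=1e-12)
        net_p = sv.fit_ising(x[:, perm], tol=1e-12)
        # update order differs under relabeling, so agreement is up to the
        # solver tolerance; the selected edge set must map exactly
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-4
        )
        mapped = {
            tuple(sorted((int(np.flatnonzero(perm == i)[0]),
                          int(np.flatnonzero(perm == j)[0]))))
            for i, j in net.edge_set()
        }
        assert net_p.edge_set() == mapped

    def test_row_order_invariance(self, chain6):
        x = sv.sample_ising_exact(chain6, 800, seed=2)
        shuffled = x[np.random.default_rng(3).permutation(x.shape[0])]
        np.testing.assert_allclose(
            sv.fit_ising(x).weights, sv.fit_ising(shuffled).weights, atol=1e-12
        )

    def test_and_rule_edge_set_subset_of_or_rule(self, chain6):
        x = sv.sample_ising_exact(chain6, 400, seed=4)
        and_net = sv.fit_ising(x, rule="AND")
        or_net = sv.fit_ising(x, rule="OR")
        assert and_net.edge_set() <= or_net.edge_set()

    def test_constant_node_error_lists_nodes(self):
        x = np.random.default_rng(5).integers(0, 2, (100, 4))
        x[:, 2] = 1
        with pytest.raises(ValueError, match="V3"):
            sv.fit_ising(x)

    def test_fewer_rows_than_nodes_warns(self):
        x = np.array(
            [
                [0, 1, 0, 1, 0, 1],
                [1, 0, 1, 0, 1, 0],
                [1, 1, 0, 0, 1, 1],
                [0, 0, 1, 1, 0, 0],
                [1, 0, 0, 1, 1, 0],
            ]
        )
        with pytest.warns(UserWarning, match="fewer observations"):
            sv.fit_ising(x)

    def test_nodewise_mle_converges_to_conditional_parameters(self):
        """Unpenalized nodewise logistic coefficients approach the true
        conditional parameters (tau_i, beta_ij) of the enumerated joint,
        with bias shrinking as n grows."""
        couplings = np.zeros((4, 4))
        couplings[0, 1] = couplings[1, 0] = 1.2
        couplings[2, 3] = couplings[3, 2] = -0.8
        net = sv.GroundTruthNetwork(couplings, np.array([-0.4, 0.2, 0.0, -0.6]))
        errs = []
        for n in (2000, 30000):
            x = sv.sample_ising_exact(net, n, seed=n)
            err = 0.0
            for j in range(4):
                cols = [k for k in range(4) if k != j]
                fit = sm.Logit(
                    x[:, j].astype(float), sm.add_constant(x[:, cols].astype(float))
                ).fit(disp=0)
                true = np.r_[net.thresholds[j], couplings[j, cols]]
                err = max(err, np.max(np.abs(np.asarray(fit.params) - true)))
            errs.append(err)
        assert errs[1] < errs[0]
        assert errs[1] < 0.1

    def test_drop_constant_embeds_isolated_nodes(self):
        x = np.random.default_rng(9).integers(0, 2, (200, 5))
        x[:, 1] = 0
        net, n_dropped = sv.fit_ising_drop_constant(x)
        assert n_dropped == 1
        assert net.dropped == ["V2"]
        assert np.all(net.weights[1] == 0) and np.all(net.weights[:, 1] == 0)
        assert net.n_nodes == 5


class TestGlobalStrength:
    def test_trivial_values(self):
        w = np.zeros((4, 4))
        assert sv.global_strength(w) == 0.0
        w[0, 1] = w[1, 0] = 0.7
        assert sv.global_strength(w) == pytest.approx(0.7)
        w[1, 2] = w[2, 1] = -0.3
        w[0, 3] = w[3, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.2
        # |0.7| + |-0.3| + |0.5| + |0.2| over unique pairs
        assert sv.global_strength(w) == pytest.approx(1.7)

    def test_invariant_to_relabeling_and_sign_flips(self):
        rng = np.random.default_rng(10)
        w = rng.normal(0, 1, (5, 5))
        w = np.triu(w, 1)
        w = w + w.T
        perm = rng.permutation(5)
        assert sv.global_strength(w[np.ix_(perm, perm)]) == pytest.approx(
            sv.global_strength(w)
        )
        flipped = w.copy()
        flipped[0, 1] *= -1
        flipped[1, 0] *= -1
        assert sv.global_strength(flipped) == pytest.approx(sv.global_strength(w))


class TestBinarizeNetwork:
    def test_zero_one_conversion_and_idempotence(self, chain6):
        net = sv.fit_ising(sv.sample_ising_exact(chain6, 1000, seed=6))
        unweighted = sv.binarize_network(net)
        assert set(np.unique(unweighted.weights)) <= {0.0, 1.0}
        assert unweighted.edge_set() == net.edge_set()
        again = sv.binarize_network(unweighted)
        np.testing.assert_array_equal(again.weights, unweighted.weights)

    def test_empty_network_stays_empty(self):
        net = sv.IsingNetwork(
            np.zeros((3, 3)), np.zeros(3), ["a", "b", "c"], 10, 0.25, "AND"
        )
        assert sv.binarize_network(net).edge_set() == set()
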