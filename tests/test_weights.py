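"""Composite weighting schemes and the composite covariance matrix."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import compositebias as cb
from tests.conftest import edges_of


class TestEqualWeights:
    def test_counterexample_unit_variance_values(self, counterexample,
                                                 counterexample_cov):
        W = cb.weights_equal(counterexample_cov, counterexample.blocks,
                             latent_order=counterexample.latent_names)
        wb = W.block_weights("eta_ind1", counterexample.blocks)
        assert np.allclose(wb, 1 / np.sqrt(12), atol=1e-10)

    def test_composite_correlation_attenuated(self, counterexample,
                                              counterexample_cov,
                                              counterexample_ewc):
        C = cb.composite_cov(counterexample_cov, counterexample_ewc)
        # latent correlation -2/3 attenuates to q^2 * (-2/3) = -1/2
        assert C.matrix[0, 1] == pytest.approx(-0.5, abs=1e-10)

    def test_single_indicator_block(self):
        cov = cb.CovarianceInput([[4.0]], None, ("x",))
        W = cb.weights_equal(cov, {"a": ("x",)})
        assert W.weights[0, 0] == pytest.approx(0.5)


class TestBartlettWeights:
    def test_parallel_block_proportional_to_equal_weights(self):
        cov = cb.CovarianceInput(np.eye(3) + 1.0, None, ("a", "b", "c"))
        W = cb.weights_bartlett({k: 1.0 for k in "abc"},
                                {k: 1.0 for k in "abc"},
                                {"f": ("a", "b", "c")}, cov)
        w = W.weights[:, 0]
        assert np.allclose(w, w[0])

    def test_loading_two_gets_double_weight(self):
        S = np.array([[2.0, 2.0], [2.0, 5.0]])  # lam=(1,2), Var(f)=1, Theta=I
        cov = cb.CovarianceInput(S, None, ("a", "b"))
        W = cb.weights_bartlett({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 1.0},
                                {"f": ("a", "b")}, cov)
        w = W.weights[:, 0]
        # raw Bartlett weights (0.2, 0.4): ratio 2 survives rescaling
        assert w[1] / w[0] == pytest.approx(2.0, abs=1e-12)

    def test_heteroscedastic_errors_downweight_noisy_indicator(self):
        S = np.array([[2.0, 1.0], [1.0, 5.0]])  # lam=(1,1), Theta=diag(1,4)
        cov = cb.CovarianceInput(S, None, ("a", "b"))
        W = cb.weights_bartlett({"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 4.0},
                                {"f": ("a", "b")}, cov)
        assert W.weights[0, 0] > W.weights[1, 0] > 0

    def test_zero_error_variance_rejected(self):
        cov = cb.CovarianceInput(np.eye(2), None, ("a", "b"))
        with pytest.raises(ValueError, match="invertible"):
            cb.weights_bartlett({"a": 1.0, "b": 1.0}, {"a": 0.0, "b": 1.0},
                                {"f": ("a", "b")}, cov)


class TestPlsWeights:
    @pytest.mark.parametrize("mode", ["A", "B", "B_A"])
    def test_parallel_measures_give_equal_weights(self, mode, counterexample,
                                                  counterexample_cov):
        W = cb.weights_pls(counterexample_cov, counterexample.blocks,
                           edges_of(counterexample), mode=mode,
                           latent_order=counterexample.latent_names)
        assert W.converged
        for name in counterexample.latent_names:
            wb = W.block_weights(name, counterexample.blocks)
            assert np.allclose(wb, wb[0], atol=1e-9)

    def test_tolerance_stability(self, random_model_cov):
        model, cov = random_model_cov
        kw = dict(blocks=model.blocks, edges=edges_of(model),
                  latent_order=model.latent_names)
        W1 = cb.weights_pls(cov, mode="A", tol=1e-10, **kw)
        W2 = cb.weights_pls(cov, mode="A", tol=1e-6, **kw)
        assert np.max(np.abs(W1.weights - W2.weights)) < 1e-5

    def test_single_indicator_blocks_all_modes_coincide(self):
        S = np.diag([4.0, 9.0, 1.0])
        S[0, 2] = S[2, 0] = 0.5
        S[1, 2] = S[2, 1] = 0.6
        cov = cb.CovarianceInput(S, None, ("x1", "x2", "y"))
        blocks = {"a": ("x1",), "b": ("x2",), "c": ("y",)}
        edges = [("a", "c"), ("b", "c")]
        results = [cb.weights_pls(cov, blocks, edges, mode=m,
                                  latent_order=("a", "b", "c")).weights
                   for m in ("A", "B", "B_A")]
        for W in results:
            assert np.allclose(np.diag(W), [0.5, 1 / 3, 1.0])
        assert np.allclose(results[0], results[1])

    def test_disconnected_latent_rejected(self, counterexample,
                                          counterexample_cov):
        with pytest.raises(ValueError, match="disconnected"):
            cb.weights_pls(counterexample_cov, counterexample.blocks,
                           [("eta_ind1", "eta_dep")],
                           latent_order=counterexample.latent_names)

    def test_moment_equivalence_with_raw_data_iteration(self):
        """Moment-based Mode A/B weights equal a raw-data PLS oracle."""
        model = cb.make_random_model(k_exo=2, k_endo=1,
                                     indicators_per_block=3, seed=5)
        design = cb.SimulationDesign(model=model, n=400, reps=1, seed=5)
        (cov, X) = cb.sample_data(design, return_raw=True)[0]
        X = X - X.mean(axis=0)
        edges = edges_of(model)
        blocks = model.blocks
        order = model.latent_names

        def raw_pls(mode):
            # independent implementation iterating on actual score vectors
            pos = {lab: i for i, lab in enumerate(cov.labels)}
            idx = {n: [pos[i] for i in blocks[n]] for n in order}
            m = len(order)
            adj = np.zeros((m, m))
            for s, d in edges:
                i, j = order.index(s), order.index(d)
                adj[i, j] = adj[j, i] = 1
            W = np.zeros((X.shape[1], m))
            for j, n in enumerate(order):
                w = np.ones(len(idx[n]))
                scores = X[:, idx[n]] @ w
                W[idx[n], j] = w / np.std(scores, ddof=1)
            for _ in range(500):
                eta = X @ W
                C = np.cov(eta, rowvar=False)
                E = C * adj
                Wn = np.zeros_like(W)
                for j, n in enumerate(order):
                    proxy = eta @ E[:, j]
                    xb = X[:, idx[n]]
                    cw = np.array([np.cov(xb[:, t], proxy, ddof=1)[0, 1]
                                   for t in range(xb.shape[1])])
                    if mode == "B":
                        cw = np.linalg.solve(np.cov(xb, rowvar=False), cw)
                    s = xb @ cw
                    cw = cw / np.std(s, ddof=1)
                    if np.sum(np.cov(xb, xb @ cw, rowvar=False, ddof=1)[-1, :-1]) < 0:
                        cw = -cw
                    Wn[idx[n], j] = cw
                if np.max(np.abs(Wn - W)) < 1e-12:
                    W = Wn
                    break
                W = Wn
            return W

        for mode in ("A", "B"):
            Wm = cb.weights_pls(cov, blocks, edges, mode=mode,
                                latent_order=order, tol=1e-13)
            assert np.max(np.abs(Wm.weights - raw_pls(mode))) < 1e-8


class TestCompositeCov:
    def test_unit_diagonal_for_any_scheme(self, counterexample,
                                          counterexample_cov):
        for mode in ("A", "B_A"):
            W = cb.weights_pls(counterexample_cov, counterexample.blocks,
                               edges_of(counterexample), mode=mode,
                               latent_order=counterexample.latent_names)
            C = cb.composite_cov(counterexample_cov, W)
            assert np.allclose(np.diag(C.matrix), 1.0, atol=1e-10)

    def test_identity_weights_on_single_indicators_standardize(self):
        S = np.array([[4.0, 1.0], [1.0, 9.0]])
        cov = cb.CovarianceInput(S, None, ("x", "y"))
        W = cb.weights_equal(cov, {"a": ("x",), "b": ("y",)})
        C = cb.composite_cov(cov, W)
        assert C.matrix[0, 1] == pytest.approx(1.0 / 6.0)


@given(seed=st.integers(min_value=0, max_value=3000))
def test_factor_wise_structure_for_all_schemes(seed):
    """Weight entries outside a latent's own block are exactly zero."""
    model = cb.make_random_model(k_exo=2, k_endo=1, indicators_per_block=2,
                                 seed=seed)
    cov = cb.implied_indicator_cov(model)
    schemes = [
        cb.weights_equal(cov, model.blocks, latent_order=model.latent_names),
        cb.weights_bartlett(model.loadings, model.error_variances,
                            model.blocks, cov,
                            latent_order=model.latent_names),
        cb.weights_pls(cov, model.blocks, edges_of(model), mode="A",
                       latent_order=model.latent_names),
        cb.weights_pls(cov, model.blocks, edges_of(model), mode="B_A",
                       latent_order=model.latent_names),
    ]
    pos = {lab: i for i, lab in enumerate(cov.labels)}
    for W in schemes:
        for j, name in enumerate(model.latent_names):
            own = {pos[i] for i in model.blocks[name]}
            outside = [i for i in range(cov.p) if i not in own]
            assert np.all(W.weights[outside, j] == 0.0)


def test_parallel_measures_collapse_all_schemes_identical(counterexample,
                                                          counterexample_cov):
    """Equal loadings/error variances make all four schemes coincide."""
    model, cov = counterexample, counterexample_cov
    ewc = cb.weights_equal(cov, model.blocks, latent_order=model.latent_names)
    bfs = cb.weights_bartlett(model.loadings, model.error_variances,
                              model.blocks, cov,
                              latent_order=model.latent_names)
    pls_a = cb.weights_pls(cov, model.blocks, edges_of(model), mode="A",
                           latent_order=model.latent_names)
    pls_ba = cb.weights_pls(cov, model.blocks, edges_of(model), mode="B_A",
                            latent_order=model.latent_names)
    for other in (bfs, pls_a, pls_ba):
        assert np.max(np.abs(ewc.weights - other.weights)) < 1e-9
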