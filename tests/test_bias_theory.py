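"""The probability-limit (reliability-matrix) machinery for composite OLS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import compositebias as cb


@pytest.fixture()
def raw_weights(counterexample, counterexample_cov):
    return cb.weights_equal(counterexample_cov, counterexample.blocks,
                            latent_order=counterexample.latent_names,
                            unit_variance=False)


class TestBiasMatrix:
    def test_counterexample_hand_computed_matrix(self, counterexample,
                                                 raw_weights):
        # (Sigma + (1/3)I)^{-1} Sigma with Sigma = [[1,-2/3],[-2/3,1]]
        M = cb.bias_matrix(counterexample, raw_weights, "eta_dep")
        assert np.allclose(M, [[2 / 3, -1 / 6], [-1 / 6, 2 / 3]], atol=1e-12)

    def test_uncorrelated_predictors_give_diagonal_bias(self):
        model = cb.make_null_model(rho=0.0, gamma2=0.7)
        S = cb.implied_indicator_cov(model)
        W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names)
        M = cb.bias_matrix(model, W, "eta_dep")
        assert abs(M[0, 1]) < 1e-12 and abs(M[1, 0]) < 1e-12

    def test_perfect_measurement_gives_identity(self):
        model = cb.PopulationModel(
            latent_names=("a", "b", "y"),
            blocks={"a": ("a1",), "b": ("b1",), "y": ("y1",)},
            loadings={"a1": 1.0, "b1": 1.0, "y1": 1.0},
            error_variances={"a1": 0.0, "b1": 0.0, "y1": 0.0},
            structural=(("a", "y", 0.3), ("b", "y", 0.4)),
            exo_cov=np.array([[1.0, 0.5], [0.5, 1.0]]),
            disturbance_variances={"y": 1.0})
        S = cb.implied_indicator_cov(model)
        p = len(model.indicator_names)
        W = cb.WeightMatrix(np.eye(p), model.indicator_names,
                            model.latent_names, "identity")
        M = cb.bias_matrix(model, W, "y")
        assert np.allclose(M, np.eye(2), atol=1e-12)


class TestPlimGamma:
    def test_counterexample_raw_weights(self, counterexample, raw_weights):
        plim = cb.plim_gamma(counterexample, raw_weights, "eta_dep")
        # sympy oracle: M gamma = (0, 5/8) for gamma = (1/4, 1)
        assert plim[0] == pytest.approx(0.0, abs=1e-12)
        assert plim[1] == pytest.approx(5 / 8, abs=1e-10)

    def test_counterexample_unit_variance_weights(self, counterexample,
                                                  counterexample_ewc):
        plim = cb.plim_gamma(counterexample, counterexample_ewc, "eta_dep")
        # sympy oracle: (0, 5 sqrt(11) / 33)
        assert plim[0] == pytest.approx(0.0, abs=1e-12)
        assert plim[1] == pytest.approx(5 * np.sqrt(11) / 33, abs=1e-9)

    def test_null_model_false_signal(self):
        model = cb.make_null_model(rho=-2 / 3, gamma2=1.0)
        S = cb.implied_indicator_cov(model)
        W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names,
                             unit_variance=False)
        plim = cb.plim_gamma(model, W, "eta_dep")
        assert plim[0] == pytest.approx(-1 / 6, abs=1e-10)

    def test_zero_gamma_gives_zero_plim(self):
        model = cb.make_null_model(rho=-0.5, gamma2=0.0)
        S = cb.implied_indicator_cov(model)
        W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names)
        assert np.allclose(cb.plim_gamma(model, W, "eta_dep"), 0.0, atol=1e-12)


class TestScalingCorrectable:
    def test_counterexample_not_correctable(self, counterexample, raw_weights):
        M = cb.bias_matrix(counterexample, raw_weights, "eta_dep")
        flag, D = cb.scaling_correctable(M)
        assert not flag and D is None

    def test_simple_regression_always_correctable(self):
        model = cb.PopulationModel(
            latent_names=("a", "y"),
            blocks={"a": ("a1", "a2"), "y": ("y1", "y2")},
            loadings={k: 1.0 for k in ("a1", "a2", "y1", "y2")},
            error_variances={k: 1.0 for k in ("a1", "a2", "y1", "y2")},
            structural=(("a", "y", 0.5),), exo_cov=np.eye(1),
            disturbance_variances={"y": 1.0})
        S = cb.implied_indicator_cov(model)
        W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names)
        M = cb.bias_matrix(model, W, "y")
        flag, D = cb.scaling_correctable(M)
        assert flag
        assert np.allclose(D @ M, np.eye(1), atol=1e-10)

    def test_identity_correctable_with_identity_correction(self):
        flag, D = cb.scaling_correctable(np.eye(3))
        assert flag and np.allclose(D, np.eye(3))


class TestSolveDegenerate:
    def test_counterexample_row_solution(self, counterexample, raw_weights):
        gamma = cb.solve_degenerate(counterexample, raw_weights, "eta_dep",
                                    "eta_ind1", value=0.25)
        assert gamma == pytest.approx([0.25, 1.0], abs=1e-12)

    def test_diagonal_bias_returns_none(self):
        model = cb.make_null_model(rho=0.0, gamma2=1.0)
        S = cb.implied_indicator_cov(model)
        W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names)
        assert cb.solve_degenerate(model, W, "eta_dep", "eta_ind1") is None

    def test_three_correlated_predictors_property(self):
        rho = 0.4
        exo = ("a", "b", "c")
        blocks = {name: tuple(f"{name}{i}" for i in range(1, 3))
                  for name in exo + ("y",)}
        inds = [i for b in blocks.values() for i in b]
        cov = np.full((3, 3), rho); np.fill_diagonal(cov, 1.0)
        model = cb.PopulationModel(
            latent_names=exo + ("y",), blocks=blocks,
            loadings={i: 1.0 for i in inds},
            error_variances={i: 1.0 for i in inds},
            structural=(("a", "y", 0.5), ("b", "y", 0.5), ("c", "y", 0.5)),
            exo_cov=cov, disturbance_variances={"y": 1.0})
        S = cb.implied_indicator_cov(model)
        W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names)
        gamma = cb.solve_degenerate(model, W, "y", "a", value=0.3)
        assert gamma is not None and gamma[0] == pytest.approx(0.3)
        model2 = model.with_structural(tuple(
            (src, "y", g) for src, g in zip(exo, gamma)))
        plim = cb.plim_gamma(model2, W, "y")
        assert abs(plim[0]) < 1e-12


# ---- properties -----------------------------------------------------------

@given(seed=st.integers(min_value=0, max_value=5000))
def test_plim_zero_pattern_invariant_under_rescaling(seed):
    """Zeros of the plim survive any positive rescaling of the weights."""
    model = cb.make_counterexample(gamma1=0.4)
    S = cb.implied_indicator_cov(model)
    W = cb.weights_equal(S, model.blocks, latent_order=model.latent_names)
    rng = np.random.default_rng(seed)
    factors = {name: float(rng.uniform(0.2, 5.0))
               for name in model.latent_names}
    plim = cb.plim_gamma(model, W.scaled(factors), "eta_dep")
    assert abs(plim[0]) < 1e-12


@given(seed=st.integers(min_value=0, max_value=5000))
def test_vanishing_measurement_error_removes_bias(seed):
    """As Theta -> 0 with w'lambda = 1, M -> I and the plim -> gamma."""
    rng = np.random.default_rng(seed)
    rho = float(rng.uniform(-0.8, 0.8))
    g1, g2 = rng.uniform(-1, 1, size=2)
    blocks = {"a": ("a1",), "b": ("b1",), "y": ("y1",)}
    model = cb.PopulationModel(
        latent_names=("a", "b", "y"), blocks=blocks,
        loadings={"a1": 1.0, "b1": 1.0, "y1": 1.0},
        error_variances={"a1": 1e-12, "b1": 1e-12, "y1": 1e-12},
        structural=(("a", "y", g1), ("b", "y", g2)),
        exo_cov=np.array([[1.0, rho], [rho, 1.0]]),
        disturbance_variances={"y": 1.0})
    W = cb.WeightMatrix(np.eye(3), model.indicator_names, model.latent_names,
                        "identity")
    M = cb.bias_matrix(model, W, "y")
    assert np.allclose(M, np.eye(2), atol=1e-9)
    assert np.allclose(cb.plim_gamma(model, W, "y"), [g1, g2], atol=1e-9)
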