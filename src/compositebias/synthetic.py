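"""Benchmark population models and multivariate-normal data generation.

The two named constructions mirror the study conditions used throughout
the package:

* :func:`make_counterexample` -- two correlated exogenous latent variables
  (variance 1, covariance rho, default -2/3) and one endogenous latent,
  each measured by three parallel indicators (loadings 1, error variances
  1), disturbance variance 1.  The structural coefficients are chosen by
  the degeneracy solver so that the composite-based plim of the first path
  is exactly 0 while the true coefficient is nonzero.
* :func:`make_null_model` -- the same measurement structure with a truly
  zero first path (gamma_1 = 0); with correlated exogenous latents the
  composite plim of that path is nonzero, the mechanism behind inflated
  type-I error rates of composite-score path analysis.

Random valid models and seeded multivariate-normal sampling round out the
module so every downstream stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bias as _bias
from . import weights as _weights
from .model import CovarianceInput, PopulationModel, implied_indicator_cov

__all__ = ["SimulationDesign", "make_counterexample", "make_null_model",
           "make_mediation_model", "make_random_model", "sample_data"]

DEP = "eta_dep"
IND1 = "eta_ind1"
IND2 = "eta_ind2"


def _three_block_model(rho: float, gamma1: float, gamma2: float) -> PopulationModel:
    if not abs(rho) < 1:
        raise ValueError("|rho| must be below 1")
    latents = (IND1, IND2, DEP)
    blocks = {IND1: ("x11", "x12", "x13"),
              IND2: ("x21", "x22", "x23"),
              DEP: ("y1", "y2", "y3")}
    inds = [i for b in blocks.values() for i in b]
    return PopulationModel(
        latent_names=latents,
        blocks=blocks,
        loadings={i: 1.0 for i in inds},
        error_variances={i: 1.0 for i in inds},
        structural=((IND1, DEP, gamma1), (IND2, DEP, gamma2)),
        exo_cov=np.array([[1.0, rho], [rho, 1.0]]),
        disturbance_variances={DEP: 1.0},
    )


def make_counterexample(gamma1: float = 0.25, rho: float = -2.0 / 3.0
                        ) -> PopulationModel:
    """Parallel-measures model whose composite plim of the first path is 0.

    gamma_2 is obtained from the degeneracy solver applied to the bias
    matrix of the first structural equation; with uncorrelated exogenous
    latents (rho = 0) the bias matrix is diagonal and no such degeneracy
    exists, which raises a ValueError.
    """
    if gamma1 == 0:
        raise ValueError("gamma1 must be nonzero")
    probe = _three_block_model(rho, gamma1, 0.0)
    S = implied_indicator_cov(probe)
    W = _weights.weights_equal(S, probe.blocks, latent_order=probe.latent_names)
    gamma = _bias.solve_degenerate(probe, W, DEP, IND1, value=gamma1)
    if gamma is None:
        raise ValueError(
            "no degeneracy: with uncorrelated exogenous latent variables the "
            "bias matrix is diagonal, so only gamma1 = 0 yields a zero plim")
    return probe.with_structural(((IND1, DEP, float(gamma[0])),
                                  (IND2, DEP, float(gamma[1]))))


def make_null_model(rho: float = -2.0 / 3.0, gamma2: float = 1.0
                    ) -> PopulationModel:
    """Same block structure, but the first path is truly zero (gamma_1 = 0)."""
    return _three_block_model(rho, 0.0, gamma2)


def make_mediation_model() -> PopulationModel:
    """A small mediation model xi -> eta1 -> eta2 with a direct xi -> eta2 path.

    All latent variances equal 1 by construction (loadings 0.9/0.8/0.7,
    disturbance variances set to one minus the explained variance), which
    makes the marker and unit-variance scalings genuinely different
    parameterizations of the same population.
    """
    blocks = {"xi": ("x1", "x2", "x3"),
              "eta1": ("m1", "m2", "m3"),
              "eta2": ("y1", "y2", "y3")}
    loadings = {}
    for b in blocks.values():
        for ind, lam in zip(b, (0.9, 0.8, 0.7)):
            loadings[ind] = lam
    inds = [i for b in blocks.values() for i in b]
    a, bcoef, c = 0.6, 0.5, 0.2
    # Var(eta1) = a^2 + psi1 = 1 ; Var(eta2) = Var(c xi + b eta1) + psi2 = 1
    psi1 = 1.0 - a ** 2
    pred_var = c ** 2 + bcoef ** 2 + 2 * bcoef * c * a
    return PopulationModel(
        latent_names=("xi", "eta1", "eta2"),
        blocks=blocks,
        loadings=loadings,
        error_variances={i: 0.5 for i in inds},
        structural=(("xi", "eta1", a), ("xi", "eta2", c), ("eta1", "eta2", bcoef)),
        exo_cov=np.array([[1.0]]),
        disturbance_variances={"eta1": psi1, "eta2": 1.0 - pred_var},
    )


def make_random_model(k_exo: int = 2, k_endo: int = 1,
                      indicators_per_block: int = 3,
                      seed: int = 0) -> PopulationModel:
    """A random valid recursive model (deterministic in ``seed``).

    Loadings are drawn uniformly on [0.5, 1.0], error variances on
    [0.3, 1.0], exogenous covariances form a random correlation matrix, and
    each endogenous latent regresses on a random nonempty subset of the
    preceding latents with coefficients on [-0.8, 0.8] \\ (-0.1, 0.1).
    """
    if min(k_exo, k_endo, indicators_per_block) < 1:
        raise ValueError("all size arguments must be positive")
    rng = np.random.default_rng(seed)
    exo = [f"xi{i + 1}" for i in range(k_exo)]
    endo = [f"eta{i + 1}" for i in range(k_endo)]
    latents = exo + endo
    blocks = {name: tuple(f"{name}_x{j + 1}" for j in range(indicators_per_block))
              for name in latents}
    inds = [i for b in blocks.values() for i in b]
    loadings = {i: float(rng.uniform(0.5, 1.0)) for i in inds}
    errvar = {i: float(rng.uniform(0.3, 1.0)) for i in inds}
    if k_exo == 1:
        exo_cov = np.array([[1.0]])
    else:
        A = rng.normal(size=(k_exo, k_exo))
        C = A @ A.T + 0.5 * k_exo * np.eye(k_exo)
        d = 1.0 / np.sqrt(np.diag(C))
        exo_cov = C * np.outer(d, d)
    edges: list[tuple[str, str, float]] = []

    def coef() -> float:
        c = rng.uniform(0.1, 0.8) * rng.choice([-1.0, 1.0])
        return float(c)

    for j, name in enumerate(endo):
        candidates = exo + endo[:j]
        chosen = [c for c in candidates if rng.uniform() < 0.7]
        if not chosen:
            chosen = [candidates[int(rng.integers(len(candidates)))]]
        edges.extend((src, name, coef()) for src in chosen)
    # every exogenous latent must reach the structural graph
    used = {src for src, _, _ in edges}
    for name in exo:
        if name not in used:
            tgt = endo[int(rng.integers(k_endo))]
            edges.append((name, tgt, coef()))
    psis = {name: float(rng.uniform(0.3, 1.0)) for name in endo}
    return PopulationModel(latents, blocks, loadings, errvar, tuple(edges),
                           exo_cov, psis)


@dataclass(frozen=True)
class SimulationDesign:
    """One Monte-Carlo condition: a population model, sample size per
    replication, replication count, and master seed."""

    model: PopulationModel
    n: int
    reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.n <= len(self.model.indicator_names):
            raise ValueError("n must exceed the number of indicators")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")


def sample_data(design: SimulationDesign, return_raw: bool = False):
    """Seeded multivariate-normal replications of a design.

    Yields one :class:`CovarianceInput` (sample covariance, divisor n-1)
    per replication, drawn from independent substreams spawned from the
    master seed.  With ``return_raw`` the n x p data matrix is attached.
    """
    pop = implied_indicator_cov(design.model)
    eigs = np.linalg.eigvalsh(pop.matrix)
    if eigs.min() <= 0:
        raise ValueError("implied indicator covariance is not positive definite")
    chol = np.linalg.cholesky(pop.matrix)
    streams = np.random.SeedSequence(design.seed).spawn(design.reps)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        X = rng.standard_normal(size=(design.n, pop.p)) @ chol.T
        S = np.cov(X, rowvar=False)
        cov = CovarianceInput(S, design.n, pop.labels)
        out.append((cov, X) if return_raw else cov)
    return out
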