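"""Linear latent-variable population models and their implied moments.

A :class:`PopulationModel` describes a recursive structural equation system

    eta_endo = B eta_endo + Gamma eta_exo + zeta,        x = Lambda eta + eps,

with a reflective measurement model in which every indicator loads on
exactly one latent variable and measurement errors are mutually
uncorrelated (diagonal Theta).  All latent variables have mean zero and no
intercepts appear anywhere.  The module computes the implied latent and
indicator covariance matrices and the attenuation decomposition of
factor-wise composite scores: a composite eta~ = w'x of a block decomposes
as eta~ = q eta + delta with q = w'lambda and Var(delta) = w'Theta w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PopulationModel",
    "CovarianceInput",
    "WeightMatrix",
    "AttenuationDecomposition",
    "implied_latent_cov",
    "implied_indicator_cov",
    "attenuation",
]


class ModelError(ValueError):
    """Raised when a model specification violates its invariants."""


def _as_tuple(seq: Sequence[str]) -> tuple[str, ...]:
    return tuple(str(s) for s in seq)


@dataclass(frozen=True)
class PopulationModel:
    """Full parameterization of a recursive latent-variable system.

    Parameters
    ----------
    latent_names
        Ordered labels of all latent variables (exogenous and endogenous).
    blocks
        Mapping latent -> ordered indicator labels; blocks are disjoint and
        every indicator belongs to exactly one block.
    loadings
        Loading lambda of each indicator on its own latent variable.
    error_variances
        Diagonal of Theta, the measurement-error covariance matrix.
    structural
        Edge list ``(source, target, coefficient)``; targets are the
        endogenous latent variables and the edge graph must be acyclic.
    exo_cov
        Covariance matrix of the exogenous latent variables, ordered as
        they appear in ``latent_names``.
    disturbance_variances
        Variance of the structural disturbance zeta per endogenous latent.
    """

    latent_names: tuple[str, ...]
    blocks: Mapping[str, tuple[str, ...]]
    loadings: Mapping[str, float]
    error_variances: Mapping[str, float]
    structural: tuple[tuple[str, str, float], ...]
    exo_cov: np.ndarray
    disturbance_variances: Mapping[str, float]

    def __init__(self, latent_names, blocks, loadings, error_variances,
                 structural, exo_cov, disturbance_variances):
        object.__setattr__(self, "latent_names", _as_tuple(latent_names))
        object.__setattr__(self, "blocks",
                           {str(k): _as_tuple(v) for k, v in dict(blocks).items()})
        object.__setattr__(self, "loadings",
                           {str(k): float(v) for k, v in dict(loadings).items()})
        object.__setattr__(self, "error_variances",
                           {str(k): float(v) for k, v in dict(error_variances).items()})
        object.__setattr__(self, "structural",
                           tuple((str(a), str(b), float(c)) for a, b, c in structural))
        object.__setattr__(self, "exo_cov", np.array(exo_cov, dtype=float))
        object.__setattr__(self, "disturbance_variances",
                           {str(k): float(v) for k, v in dict(disturbance_variances).items()})
        self._validate()

    # ---- structure -------------------------------------------------------

    @property
    def endo_names(self) -> tuple[str, ...]:
        targets = {dst for _, dst, _ in self.structural}
        targets |= set(self.disturbance_variances)
        return tuple(name for name in self.latent_names if name in targets)

    @property
    def exo_names(self) -> tuple[str, ...]:
        endo = set(self.endo_names)
        return tuple(name for name in self.latent_names if name not in endo)

    @property
    def indicator_names(self) -> tuple[str, ...]:
        # fixed canonical order: concatenation of blocks in latent order
        out: list[str] = []
        for name in self.latent_names:
            out.extend(self.blocks[name])
        return tuple(out)

    def parents(self, latent: str) -> tuple[str, ...]:
        """Predictors of ``latent``, in latent_names order."""
        srcs = {src for src, dst, _ in self.structural if dst == latent}
        return tuple(name for name in self.latent_names if name in srcs)

    def coefficients(self, latent: str) -> np.ndarray:
        """Structural coefficients of ``latent``'s equation, parent order."""
        lookup = {(s, d): c for s, d, c in self.structural}
        return np.array([lookup[(p, latent)] for p in self.parents(latent)])

    def causal_order(self) -> tuple[str, ...]:
        """Endogenous latents in a topological (causal) order."""
        g = nx.DiGraph()
        g.add_nodes_from(self.latent_names)
        g.add_edges_from((s, d) for s, d, _ in self.structural)
        order = list(nx.topological_sort(g))
        endo = set(self.endo_names)
        return tuple(n for n in order if n in endo)

    @property
    def lambda_matrix(self) -> np.ndarray:
        """p x m loading matrix in canonical indicator/latent order."""
        inds = self.indicator_names
        lam = np.zeros((len(inds), len(self.latent_names)))
        row = {ind: i for i, ind in enumerate(inds)}
        for j, name in enumerate(self.latent_names):
            for ind in self.blocks[name]:
                lam[row[ind], j] = self.loadings[ind]
        return lam

    @property
    def theta_matrix(self) -> np.ndarray:
        return np.diag([self.error_variances[i] for i in self.indicator_names])

    # ---- validation ------------------------------------------------------

    def _validate(self) -> None:
        names = self.latent_names
        if len(set(names)) != len(names):
            raise ModelError("duplicate latent names")
        if set(self.blocks) != set(names):
            raise ModelError("blocks must cover exactly the declared latents")
        seen: set[str] = set()
        for name in names:
            block = self.blocks[name]
            if not block:
                raise ModelError(f"latent {name!r} has an empty indicator block")
            for ind in block:
                if ind in seen:
                    raise ModelError(
                        f"indicator {ind!r} appears in more than one block")
                seen.add(ind)
                if ind not in self.loadings:
                    raise ModelError(f"missing loading for indicator {ind!r}")
                if ind not in self.error_variances:
                    raise ModelError(f"missing error variance for {ind!r}")
                if self.error_variances[ind] < 0:
                    raise ModelError(
                        f"negative measurement-error variance for {ind!r}")
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for src, dst, _ in self.structural:
            for end in (src, dst):
                if end not in self.blocks:
                    raise ModelError(f"structural edge uses unknown latent {end!r}")
            if src == dst:
                raise ModelError(f"self-loop on {src!r}")
            g.add_edge(src, dst)
        if not nx.is_directed_acyclic_graph(g):
            raise ModelError("structural system is not recursive (cycle found)")
        endo = self.endo_names
        if set(self.disturbance_variances) != set(endo):
            raise ModelError(
                "disturbance_variances must cover exactly the endogenous latents")
        for name, psi in self.disturbance_variances.items():
            if psi < 0:
                raise ModelError(f"negative disturbance variance for {name!r}")
        exo = self.exo_names
        cov = self.exo_cov
        if cov.shape != (len(exo), len(exo)):
            raise ModelError(
                f"exo_cov has shape {cov.shape}, expected {(len(exo), len(exo))}")
        if len(exo) and not np.allclose(cov, cov.T, atol=1e-10):
            raise ModelError("exo_cov must be symmetric")
        if len(exo) and np.linalg.eigvalsh(cov).min() <= 0:
            raise ModelError("exo_cov must be positive definite")

    # convenience ----------------------------------------------------------

    def with_structural(self, structural) -> "PopulationModel":
        """Copy of the model with a replaced structural edge list."""
        return PopulationModel(self.latent_names, self.blocks, self.loadings,
                               self.error_variances, structural, self.exo_cov,
                               self.disturbance_variances)


@dataclass(frozen=True)
class CovarianceInput:
    """A symmetric covariance matrix with labels and (optional) sample size.

    ``n is None`` marks a population matrix (no sampling variability).
    """

    matrix: np.ndarray
    n: int | None
    labels: tuple[str, ...]

    def __init__(self, matrix, n, labels):
        m = np.array(matrix, dtype=float)
        labels = _as_tuple(labels)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(labels):
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric (1e-10)")
        if n is not None:
            n = int(n)
            if n < m.shape[0] + 1:
                raise ValueError("sample size must exceed the number of variables")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "labels", labels)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class WeightMatrix:
    """Block-structured composite weights, one column per latent variable.

    Entries outside a latent's own indicator block are exactly zero
    (factor-wise composites).  ``scheme`` names the construction (EWC, BFS,
    PLS_A, PLS_BA, or a custom label).
    """

    weights: np.ndarray
    indicator_names: tuple[str, ...]
    latent_names: tuple[str, ...]
    scheme: str
    iterations: int = 0
    converged: bool = True

    def __init__(self, weights, indicator_names, latent_names, scheme,
                 iterations=0, converged=True):
        w = np.array(weights, dtype=float)
        indicator_names = _as_tuple(indicator_names)
        latent_names = _as_tuple(latent_names)
        if w.shape != (len(indicator_names), len(latent_names)):
            raise ValueError("weight matrix shape does not match labels")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "indicator_names", indicator_names)
        object.__setattr__(self, "latent_names", latent_names)
        object.__setattr__(self, "scheme", str(scheme))
        object.__setattr__(self, "iterations", int(iterations))
        object.__setattr__(self, "converged", bool(converged))

    def column(self, latent: str) -> np.ndarray:
        return self.weights[:, self.latent_names.index(latent)]

    def block_weights(self, latent: str, blocks: Mapping[str, Sequence[str]]) -> np.ndarray:
        idx = [self.indicator_names.index(i) for i in blocks[latent]]
        return self.column(latent)[idx]

    def scaled(self, factors: Mapping[str, float]) -> "WeightMatrix":
        """Multiply each latent's weight column by a positive constant."""
        w = self.weights.copy()
        for name, c in factors.items():
            w[:, self.latent_names.index(name)] *= float(c)
        return WeightMatrix(w, self.indicator_names, self.latent_names,
                            self.scheme, self.iterations, self.converged)


@dataclass(frozen=True)
class AttenuationDecomposition:
    """Per-composite attenuation terms for one structural equation.

    ``q`` and ``delta_var`` cover every latent in the model; ``Q`` and
    ``sigma_delta`` are the diagonal matrices over the predictors of the
    dependent latent variable, and ``q_dep`` is the dependent composite's
    own attenuation factor.
    """

    q: Mapping[str, float]
    delta_var: Mapping[str, float]
    predictors: tuple[str, ...]
    Q: np.ndarray = field(repr=False)
    sigma_delta: np.ndarray = field(repr=False)
    q_dep: float = 1.0


def _check_blocks_match(model: PopulationModel, W: WeightMatrix) -> None:
    if W.indicator_names != model.indicator_names:
        raise ValueError("weight matrix indicator order does not match model")
    if W.latent_names != model.latent_names:
        raise ValueError("weight matrix latent order does not match model")
    inds = model.indicator_names
    for j, name in enumerate(model.latent_names):
        own = set(model.blocks[name])
        outside = [inds[i] for i in range(len(inds))
                   if inds[i] not in own and W.weights[i, j] != 0.0]
        if outside:
            raise ValueError(
                f"weights for {name!r} are nonzero outside its block: {outside}")


def implied_latent_cov(model: PopulationModel) -> np.ndarray:
    """Covariance matrix of all latent variables, in latent_names order.

    Uses the reduced form eta_endo = (I-B)^{-1}(Gamma eta_exo + zeta); the
    recursive (acyclic) structure guarantees I-B is invertible.
    """
    names = list(model.latent_names)
    exo = list(model.exo_names)
    endo = list(model.endo_names)
    m = len(names)
    K = np.zeros((m, m))
    pos = {n: i for i, n in enumerate(names)}
    exo_idx = [pos[n] for n in exo]
    K[np.ix_(exo_idx, exo_idx)] = model.exo_cov
    if endo:
        ne = len(endo)
        epos = {n: i for i, n in enumerate(endo)}
        B = np.zeros((ne, ne))
        G = np.zeros((ne, len(exo)))
        xpos = {n: i for i, n in enumerate(exo)}
        for src, dst, coef in model.structural:
            if src in epos:
                B[epos[dst], epos[src]] = coef
            else:
                G[epos[dst], xpos[src]] = coef
        ImB = np.eye(ne) - B
        try:
            A = np.linalg.solve(ImB, np.eye(ne))  # (I-B)^{-1}
        except np.linalg.LinAlgError as exc:  # defensive; DAG keeps I-B unit-triangular
            raise ModelError("singular (I-B): check the structural ordering") from exc
        Psi = np.diag([model.disturbance_variances[n] for n in endo])
        Sig = model.exo_cov
        K_ee = A @ (G @ Sig @ G.T + Psi) @ A.T
        K_ex = A @ G @ Sig
        endo_idx = [pos[n] for n in endo]
        K[np.ix_(endo_idx, endo_idx)] = K_ee
        K[np.ix_(endo_idx, exo_idx)] = K_ex
        K[np.ix_(exo_idx, endo_idx)] = K_ex.T
    return (K + K.T) / 2.0


def implied_indicator_cov(model: PopulationModel) -> CovarianceInput:
    """Population indicator covariance Lambda Cov(eta) Lambda' + Theta."""
    lam = model.lambda_matrix
    K = implied_latent_cov(model)
    S = lam @ K @ lam.T + model.theta_matrix
    return CovarianceInput((S + S.T) / 2.0, None, model.indicator_names)


def attenuation(model: PopulationModel, W: WeightMatrix,
                dep: str) -> AttenuationDecomposition:
    """Attenuation decomposition of the composites entering ``dep``'s equation.

    For each block, q = w'lambda and Var(delta) = w'Theta w; Q and
    sigma_delta are assembled over the predictors of ``dep``.
    """
    _check_blocks_match(model, W)
    if dep not in model.endo_names:
        raise ValueError(f"{dep!r} is not an endogenous latent variable")
    q: dict[str, float] = {}
    dv: dict[str, float] = {}
    for name in model.latent_names:
        wb = W.block_weights(name, model.blocks)
        lam_b = np.array([model.loadings[i] for i in model.blocks[name]])
        th_b = np.array([model.error_variances[i] for i in model.blocks[name]])
        q[name] = float(wb @ lam_b)
        dv[name] = float(wb @ (th_b * wb))
    preds = model.parents(dep)
    Q = np.diag([q[pn] for pn in preds])
    Sd = np.diag([dv[pn] for pn in preds])
    return AttenuationDecomposition(q=q, delta_var=dv, predictors=preds,
                                    Q=Q, sigma_delta=Sd, q_dep=q[dep])
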