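"""Factor-wise composite weighting schemes.

Implements the four weighting schemes compared throughout the package:

* EWC   -- equally weighted composites,
* BFS   -- Bartlett factor scores computed from CB-SEM estimates,
* PLS Mode A / Mode B -- iterative partial-least-squares outer weights, and
* PLS Mode B_A -- a Mode-A fixed point finished with Mode-B outer step(s).

All schemes are factor-wise: a latent variable's weights are nonzero only
on its own indicator block.  Every scheme rescales its weights so each
composite has unit variance under the input covariance matrix, and all
PLS computation is moment-based: it runs directly on the indicator
variance-covariance matrix, so population matrices and sample covariance
matrices are handled identically.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import CovarianceInput, WeightMatrix

__all__ = ["weights_equal", "weights_bartlett", "weights_bartlett_from_fit",
           "weights_pls", "composite_cov"]


def _block_indices(labels: Sequence[str], blocks: Mapping[str, Sequence[str]],
                   latent_order: Sequence[str]) -> dict[str, list[int]]:
    pos = {lab: i for i, lab in enumerate(labels)}
    out = {}
    for name in latent_order:
        try:
            out[name] = [pos[i] for i in blocks[name]]
        except KeyError as exc:
            raise ValueError(f"indicator {exc.args[0]!r} not found in covariance "
                             f"labels for block {name!r}") from exc
    return out


def _normalize_and_sign(S: np.ndarray, idx: Mapping[str, list[int]],
                        W: np.ndarray) -> np.ndarray:
    """Rescale each column to unit composite variance; fix sign so the sum
    of covariances between the composite and its own indicators is positive."""
    for name, rows in idx.items():
        j = list(idx).index(name)
        w = W[rows, j]
        Sbb = S[np.ix_(rows, rows)]
        var = float(w @ Sbb @ w)
        if var <= 0:
            raise ValueError(f"composite for {name!r} has non-positive variance")
        w = w / np.sqrt(var)
        if float(np.sum(Sbb @ w)) < 0:
            w = -w
        W[rows, j] = w
    return W


def weights_equal(S: CovarianceInput, blocks: Mapping[str, Sequence[str]],
                  latent_order: Sequence[str] | None = None,
                  unit_variance: bool = True) -> WeightMatrix:
    """Equally weighted composites.

    With ``unit_variance=False`` the raw weights 1/m_b per indicator are
    returned (so a parallel block with loadings 1 has q = 1); otherwise the
    equal weights are rescaled to give each composite unit variance under S.
    """
    order = tuple(latent_order) if latent_order is not None else tuple(blocks)
    idx = _block_indices(S.labels, blocks, order)
    W = np.zeros((S.p, len(order)))
    for j, name in enumerate(order):
        rows = idx[name]
        W[rows, j] = 1.0 / len(rows)
    if unit_variance:
        W = _normalize_and_sign(S.matrix, idx, W)
    return WeightMatrix(W, S.labels, order, "EWC")


def weights_bartlett(loadings: Mapping[str, float],
                     error_variances: Mapping[str, float],
                     blocks: Mapping[str, Sequence[str]],
                     S: CovarianceInput,
                     latent_order: Sequence[str] | None = None) -> WeightMatrix:
    """Bartlett factor-score weights w = Theta^{-1} lam (lam' Theta^{-1} lam)^{-1}.

    ``loadings`` and ``error_variances`` are typically CB-SEM estimates.
    The raw Bartlett weights are then rescaled to unit composite variance
    under S, which leaves z-statistics of downstream path regressions
    unchanged.
    """
    order = tuple(latent_order) if latent_order is not None else tuple(blocks)
    idx = _block_indices(S.labels, blocks, order)
    W = np.zeros((S.p, len(order)))
    for j, name in enumerate(order):
        rows = idx[name]
        lam = np.array([loadings[i] for i in blocks[name]])
        th = np.array([error_variances[i] for i in blocks[name]])
        if np.any(th <= 0):
            bad = [i for i in blocks[name] if error_variances[i] <= 0]
            raise ValueError(
                f"Bartlett weights need invertible Theta; non-positive error "
                f"variance for {bad}")
        wt = (lam / th) / float(lam @ (lam / th))
        W[rows, j] = wt
    W = _normalize_and_sign(S.matrix, idx, W)
    return WeightMatrix(W, S.labels, order, "BFS")


def weights_bartlett_from_fit(fit, S: CovarianceInput) -> WeightMatrix:
    """Bartlett weights from a converged :class:`~compositebias.sem.SemFit`."""
    return weights_bartlett(fit.loading_estimates(), fit.error_variance_estimates(),
                            fit.model.blocks, S,
                            latent_order=fit.model.latent_names)


def _inner_weights(C: np.ndarray, adj: np.ndarray, scheme: str,
                   parents: list[list[int]]) -> np.ndarray:
    """Inner weighting matrix E: column j holds the weights of the other
    composites in the inner proxy of latent j."""
    m = C.shape[0]
    E = np.zeros((m, m))
    if scheme == "factorial":
        E = C * adj
    elif scheme == "centroid":
        E = np.sign(C) * adj
    elif scheme == "path":
        for j in range(m):
            pj = parents[j]
            if pj:
                E[pj, j] = np.linalg.solve(C[np.ix_(pj, pj)], C[pj, j])
            for k in range(m):
                if adj[k, j] and k not in pj:
                    E[k, j] = C[k, j]
    else:
        raise ValueError(f"unknown inner scheme {scheme!r}")
    np.fill_diagonal(E, 0.0)
    return E


def weights_pls(S: CovarianceInput, blocks: Mapping[str, Sequence[str]],
                edges: Sequence[tuple[str, str]],
                mode: str = "A", inner_scheme: str = "factorial",
                tol: float = 1e-10, max_iter: int = 300,
                latent_order: Sequence[str] | None = None,
                mode_b_steps: int = 1) -> WeightMatrix:
    """PLS outer weights computed from the covariance matrix.

    mode 'A'  : outer update w proportional to Cov(x_block, inner proxy)
    mode 'B'  : outer update w proportional to S_block^{-1} Cov(x_block, proxy)
    mode 'B_A': Mode-A iteration to convergence followed by ``mode_b_steps``
                Mode-B outer updates (default one).

    Iteration stops when the maximum absolute weight change is below ``tol``.
    """
    mode = mode.upper()
    if mode not in {"A", "B", "B_A", "BA"}:
        raise ValueError(f"unknown PLS mode {mode!r}")
    order = tuple(latent_order) if latent_order is not None else tuple(blocks)
    m = len(order)
    pos = {n: j for j, n in enumerate(order)}
    adj = np.zeros((m, m))
    parents: list[list[int]] = [[] for _ in range(m)]
    for src, dst in edges:
        adj[pos[src], pos[dst]] = adj[pos[dst], pos[src]] = 1.0
        parents[pos[dst]].append(pos[src])
    if m > 1 and np.any(adj.sum(axis=0) == 0):
        lonely = [order[j] for j in range(m) if adj[:, j].sum() == 0]
        raise ValueError(f"latent(s) {lonely} are disconnected in the "
                         "structural graph; PLS inner proxies are undefined")
    idx = _block_indices(S.labels, blocks, order)
    Smat = S.matrix

    def outer_step(W: np.ndarray, outer_mode: str) -> np.ndarray:
        C = W.T @ Smat @ W
        E = _inner_weights(C, adj, inner_scheme, parents) if m > 1 else np.ones((1, 1))
        Wnew = np.zeros_like(W)
        for name in order:
            j = pos[name]
            rows = idx[name]
            proxy = W @ E[:, j] if m > 1 else W[:, 0]
            v = Smat[rows, :] @ proxy
            if outer_mode == "B":
                Sbb = Smat[np.ix_(rows, rows)]
                try:
                    v = np.linalg.solve(Sbb, v)
                except np.linalg.LinAlgError as exc:
                    raise ValueError(f"within-block covariance of {name!r} is "
                                     "singular under Mode B") from exc
            Wnew[rows, j] = v
        return _normalize_and_sign(Smat, idx, Wnew)

    # equal-weight initialization, unit-variance scaled
    W = weights_equal(S, blocks, latent_order=order).weights.copy()
    base_mode = "A" if mode in {"A", "B_A", "BA"} else "B"
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        Wnew = outer_step(W, base_mode)
        delta = float(np.max(np.abs(Wnew - W)))
        W = Wnew
        if delta < tol:
            converged = True
            break
    scheme = {"A": "PLS_A", "B": "PLS_B"}.get(mode, "PLS_BA")
    if mode in {"B_A", "BA"}:
        for _ in range(mode_b_steps):
            W = outer_step(W, "B")
            iterations += 1
    return WeightMatrix(W, S.labels, order, scheme, iterations, converged)


def composite_cov(S: CovarianceInput, W: WeightMatrix) -> CovarianceInput:
    """Covariance matrix of the composites, W'SW (unit diagonal by scaling)."""
    if W.indicator_names != S.labels:
        raise ValueError("weight matrix labels do not match covariance labels")
    C = W.weights.T @ S.matrix @ W.weights
    return CovarianceInput((C + C.T) / 2.0, S.n, W.latent_names)
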