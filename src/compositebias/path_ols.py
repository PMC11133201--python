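"""Per-equation least squares on a composite covariance matrix.

Path coefficients for each endogenous composite are obtained from moments:
gamma_hat = C_xx^{-1} C_xy with residual variance from the Schur
complement, so no raw data are needed.  z-statistics use the usual OLS
normal-theory standard errors, and the signal-to-noise ratio tau = z /
sqrt(N) is attached to every record; tau is the empirical effect-size
measure E(gamma_hat) / [N Var(gamma_hat)]^{1/2}.

Rescaling any composite by a positive constant rescales gamma_hat but
leaves every z and tau unchanged -- which is why adjusting composite
scales can never alter significance patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .model import CovarianceInput

__all__ = ["EstimateRecord", "fit_path_equations", "snr"]


@dataclass(frozen=True)
class EstimateRecord:
    """One path coefficient's estimate under a named method."""

    path: tuple[str, str]
    method: str
    gamma_hat: float
    se: float
    z: float
    tau: float
    n: int

    def as_dict(self) -> dict:
        return {"path": f"{self.path[0]}->{self.path[1]}", "method": self.method,
                "gamma_hat": self.gamma_hat, "se": self.se, "z": self.z,
                "tau": self.tau, "n": self.n}


def _topological_endo(labels: Sequence[str],
                      edges: Sequence[tuple[str, str]]) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structural graph must be recursive (acyclic)")
    targets = {d for _, d in edges}
    return [n for n in nx.topological_sort(g) if n in targets]


def fit_path_equations(C: CovarianceInput, edges: Sequence[tuple[str, str]],
                       method: str = "composite", n: int | None = None,
                       df_correction: bool = True) -> list[EstimateRecord]:
    """OLS path estimates from the composite covariance matrix.

    Parameters
    ----------
    C
        Covariance matrix over composites (labels = latent names).
    edges
        Structural edge list ``(source, target)``.
    n
        Sample size; defaults to ``C.n``.  Population matrices need an
        explicit nominal ``n`` for z and tau.
    df_correction
        Use the residual degrees of freedom n-k-1 in the error variance
        (standard regression output); ``False`` selects the uncorrected
        1/n maximum-likelihood variant.
    """
    n = n if n is not None else C.n
    if n is None:
        raise ValueError("a (nominal) sample size is required for z-statistics")
    pos = {lab: i for i, lab in enumerate(C.labels)}
    records: list[EstimateRecord] = []
    for dep in _topological_endo(C.labels, edges):
        preds = [s for s, d in edges if d == dep]
        preds = [lab for lab in C.labels if lab in set(preds)]
        ix = [pos[s] for s in preds]
        iy = pos[dep]
        Cxx = C.matrix[np.ix_(ix, ix)]
        Cxy = C.matrix[ix, iy]
        if np.linalg.cond(Cxx) > 1e12:
            raise ValueError(
                f"predictor covariance for equation {dep!r} is (near-)singular; "
                f"collinear composites among {preds}")
        Cxx_inv = np.linalg.inv(Cxx)
        gamma = Cxx_inv @ Cxy
        resid = float(C.matrix[iy, iy] - Cxy @ gamma)
        resid = max(resid, 0.0)
        k = len(preds)
        dof = (n - k - 1) if df_correction else n
        if dof <= 0:
            raise ValueError(f"non-positive residual degrees of freedom for {dep!r}")
        var = resid * np.diag(Cxx_inv) / dof
        se = np.sqrt(var)
        for j, src in enumerate(preds):
            z = gamma[j] / se[j] if se[j] > 0 else np.inf * np.sign(gamma[j])
            records.append(EstimateRecord(
                path=(src, dep), method=method, gamma_hat=float(gamma[j]),
                se=float(se[j]), z=float(z), tau=float(z / np.sqrt(n)), n=int(n)))
    return records


def snr(record: EstimateRecord) -> float:
    """Signal-to-noise ratio tau = z / sqrt(n) of one estimate record."""
    return record.z / np.sqrt(record.n)
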