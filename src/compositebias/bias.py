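"""Probability limits of composite-based path coefficients.

For one structural equation eta_dep = gamma' eta_ind + zeta estimated by
OLS on factor-wise composite scores, the estimates converge in probability
to M gamma with bias matrix

    M = (Q Sigma Q + Sigma_delta)^{-1} Q Sigma q_dep,

where Sigma is the covariance matrix of the equation's predictors, Q the
diagonal matrix of predictor attenuation factors q = w'lambda,
Sigma_delta the diagonal matrix of composite measurement-error variances
w'Theta w, and q_dep the dependent composite's attenuation factor.  M
plays the role of a reliability matrix from the errors-in-variables
literature: it is generally *not* diagonal when predictors are correlated,
so the bias cannot be removed by rescaling composites, and nonzero true
coefficients can map to exactly zero probability limits (and vice versa).

For equations whose predictors include endogenous latent variables, the
same formula applies with Sigma taken from the model-implied latent
covariance matrix; the disturbance term of a recursive system is
uncorrelated with the equation's predictors, so Cov(eta_pred, eta_dep) =
Sigma gamma still holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PopulationModel, WeightMatrix, attenuation, implied_latent_cov

__all__ = ["BiasReport", "bias_matrix", "plim_gamma", "scaling_correctable",
           "solve_degenerate"]


@dataclass(frozen=True)
class BiasReport:
    """Bias matrix, probability limit, and rescaling-correctability for one
    endogenous latent variable's equation."""

    equation: str
    predictors: tuple[str, ...]
    M: np.ndarray
    plim: np.ndarray
    correctable: bool
    D: np.ndarray | None


def _predictor_cov(model: PopulationModel, dep: str) -> np.ndarray:
    preds = model.parents(dep)
    K = implied_latent_cov(model)
    pos = {n: i for i, n in enumerate(model.latent_names)}
    idx = [pos[p] for p in preds]
    return K[np.ix_(idx, idx)]


def _bias_core(model: PopulationModel, W: WeightMatrix, dep: str,
               include_q_dep: bool = True) -> tuple[np.ndarray, tuple[str, ...]]:
    att = attenuation(model, W, dep)
    Sigma = _predictor_cov(model, dep)
    A = att.Q @ Sigma @ att.Q + att.sigma_delta
    try:
        M = np.linalg.solve(A, att.Q @ Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("QSQ + Sigma_delta is singular for equation "
                         f"{dep!r}") from exc
    if include_q_dep:
        M = M * att.q_dep
    return M, att.predictors


def bias_matrix(model: PopulationModel, W: WeightMatrix, dep: str) -> np.ndarray:
    """The bias matrix M mapping true coefficients to composite plims."""
    M, _ = _bias_core(model, W, dep)
    return M


def plim_gamma(model: PopulationModel, W: WeightMatrix, dep: str) -> np.ndarray:
    """Probability limit M gamma of the composite OLS coefficients of ``dep``."""
    M, preds = _bias_core(model, W, dep)
    gamma = model.coefficients(dep)
    if len(preds) == 0:
        return np.zeros(0)
    return M @ gamma


def scaling_correctable(M: np.ndarray, tol: float = 1e-8
                        ) -> tuple[bool, np.ndarray | None]:
    """Can the bias M be undone by positively rescaling composites?

    True iff M is diagonal (within ``tol``) with nonzero diagonal; then the
    correction D = diag(1/M_ii) satisfies D M = I.  A single-predictor
    equation is always correctable; correlated predictors generally are not.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    off = M - np.diag(np.diag(M))
    if np.max(np.abs(off), initial=0.0) >= tol:
        return False, None
    if np.any(np.abs(np.diag(M)) <= tol):
        return False, None
    return True, np.diag(1.0 / np.diag(M))


def bias_report(model: PopulationModel, W: WeightMatrix, dep: str,
                tol: float = 1e-8) -> BiasReport:
    """Convenience bundle of bias matrix, plim, and correctability."""
    M, preds = _bias_core(model, W, dep)
    flag, D = scaling_correctable(M, tol)
    gamma = model.coefficients(dep)
    return BiasReport(equation=dep, predictors=preds, M=M,
                      plim=M @ gamma if len(preds) else np.zeros(0),
                      correctable=flag, D=D)


def solve_degenerate(model: PopulationModel, W: WeightMatrix, dep: str,
                     target: str, value: float = 1.0) -> np.ndarray | None:
    """Find true coefficients whose composite plim vanishes at ``target``.

    Solves the single homogeneous condition (M gamma)_target = 0 subject to
    gamma_target = ``value`` != 0, using the minimum-norm completion over
    the remaining coefficients.  Returns None when the row of M forces
    gamma_target = 0 (e.g., uncorrelated predictors make M diagonal).

    The dependent composite's factor q_dep only scales M by a positive
    constant, so it is omitted: zeros of the plim do not depend on it.
    """
    if value == 0:
        raise ValueError("the target coefficient must be nonzero")
    M, preds = _bias_core(model, W, dep, include_q_dep=False)
    if target not in preds:
        raise ValueError(f"{target!r} is not a predictor of {dep!r}")
    if len(preds) < 2:
        return None
    t = preds.index(target)
    row = M[t]
    r_t = row[t]
    r_rest = np.delete(row, t)
    if np.max(np.abs(r_rest), initial=0.0) < 1e-14:
        # row is (effectively) diagonal: (M gamma)_t = r_t gamma_t
        return None
    rest = -r_t * value * r_rest / float(r_rest @ r_rest)
    gamma = np.empty(len(preds))
    gamma[t] = value
    gamma[[i for i in range(len(preds)) if i != t]] = rest
    return gamma
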