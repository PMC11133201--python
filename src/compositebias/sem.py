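"""Covariance-based SEM by normal-theory maximum likelihood (NML).

Minimizes the ML discrepancy

    F_ML(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^{-1}) - log|S| - p

over the free parameters of a reflective latent-variable model, under one
of two latent-variable scaling methods:

``marker``
    Variances of the exogenous latent variables fixed to 1; the first
    loading of each endogenous latent variable fixed to 1; disturbance
    variances free.
``standardized``
    Every latent variable's total variance constrained to 1.  The
    constraint is imposed by substitution: each disturbance variance is
    expressed as 1 minus the variance explained by the equation's
    predictors under the current coefficients, so the constraint holds
    exactly at every iterate and no Lagrangian machinery is needed.

Both scalings parameterize the same implied-covariance manifold, so the
minimized discrepancy (and hence the chi-square and degrees of freedom)
coincide, while individual z-statistics generally do not.

Derivatives of F_ML are computed by complex-step differentiation, which is
exact to machine precision (no subtractive cancellation); the same device
supplies dSigma/dtheta for the expected (Fisher) information matrix
I_ij = tr(Sigma^{-1} dSigma_i Sigma^{-1} dSigma_j)/2 behind the standard
errors, se = sqrt(diag(I^{-1})/(n-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .model import CovarianceInput, PopulationModel
from .path_ols import EstimateRecord

__all__ = ["SemFit", "fit_nml", "standard_errors", "structural_z",
           "SCALING_METHODS"]

SCALING_METHODS = ("marker", "standardized")
_CSTEP = 1e-60
_PENALTY = 1e10


class _Template:
    """Free-parameter layout and Sigma(theta) builder for one model/scaling."""

    def __init__(self, model: PopulationModel, scaling: str):
        if scaling not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {scaling!r}; "
                             f"choose one of {SCALING_METHODS}")
        self.model = model
        self.scaling = scaling
        self.latents = list(model.latent_names)
        self.exo = list(model.exo_names)
        self.endo_topo = list(model.causal_order())
        self.inds = list(model.indicator_names)
        self.p = len(self.inds)
        self.m = len(self.latents)
        lpos = {n: j for j, n in enumerate(self.latents)}
        ipos = {n: i for i, n in enumerate(self.inds)}
        self.lam_rows, self.lam_cols = [], []
        for name in self.latents:
            for ind in model.blocks[name]:
                self.lam_rows.append(ipos[ind])
                self.lam_cols.append(lpos[name])

        names: list[str] = []
        self.free_loading_inds: list[str] = []
        self.fixed_loadings: dict[str, float] = {}
        endo_set = set(self.endo_topo)
        for name in self.latents:
            block = model.blocks[name]
            fixed_first = scaling == "marker" and name in endo_set
            for k, ind in enumerate(block):
                if fixed_first and k == 0:
                    self.fixed_loadings[ind] = 1.0
                else:
                    self.free_loading_inds.append(ind)
                    names.append(f"lambda[{ind}]")
        self.sl_theta = slice(len(names), len(names) + self.p)
        names.extend(f"theta[{ind}]" for ind in self.inds)
        self.exo_pairs = [(a, b) for i, a in enumerate(self.exo)
                          for b in self.exo[i + 1:]]
        self.sl_phi = slice(self.sl_theta.stop, self.sl_theta.stop + len(self.exo_pairs))
        names.extend(f"phi[{a},{b}]" for a, b in self.exo_pairs)
        self.edges = [(s, d) for s, d, _ in model.structural]
        self.sl_beta = slice(self.sl_phi.stop, self.sl_phi.stop + len(self.edges))
        names.extend(f"beta[{s}->{d}]" for s, d in self.edges)
        if scaling == "marker":
            self.sl_psi = slice(self.sl_beta.stop, self.sl_beta.stop + len(self.endo_topo))
            names.extend(f"psi[{name}]" for name in self.endo_topo)
        else:
            self.sl_psi = slice(self.sl_beta.stop, self.sl_beta.stop)
        self.param_names = names
        self.k = len(names)
        self.df = self.p * (self.p + 1) // 2 - self.k

        # per-endo coefficient bookkeeping (parent latent + param indices)
        epos = {(s, d): self.sl_beta.start + i for i, (s, d) in enumerate(self.edges)}
        self.endo_info = []
        for j, name in enumerate(self.endo_topo):
            preds = model.parents(name)
            self.endo_info.append((lpos[name],
                                   [lpos[pn] for pn in preds],
                                   [epos[(pn, name)] for pn in preds],
                                   self.sl_psi.start + j))
        self.exo_idx = [lpos[n] for n in self.exo]
        base = np.zeros(self.p)
        for ind, val in self.fixed_loadings.items():
            base[ipos[ind]] = val
        self.lam_base = base
        self.free_lam_idx = [ipos[ind] for ind in self.free_loading_inds]

    # ------------------------------------------------------------------

    def latent_cov(self, x: np.ndarray) -> np.ndarray:
        dtype = x.dtype
        K = np.zeros((self.m, self.m), dtype=dtype)
        kx = self.exo_idx
        for i in kx:
            K[i, i] = 1.0
        for (a, b), v in zip(self.exo_pairs, x[self.sl_phi]):
            ia, ib = self.latents.index(a), self.latents.index(b)
            K[ia, ib] = K[ib, ia] = v
        for lj, pidx, cidx, psi_i in self.endo_info:
            a = x[cidx]
            row = a @ K[pidx, :]
            var_pred = a @ K[np.ix_(pidx, pidx)] @ a
            psi = x[psi_i] if self.scaling == "marker" else 1.0 - var_pred
            K[lj, :] = row
            K[:, lj] = row
            K[lj, lj] = var_pred + psi
        return K

    def sigma(self, x: np.ndarray) -> np.ndarray:
        dtype = x.dtype
        lam = self.lam_base.astype(dtype).copy()
        lam[self.free_lam_idx] = x[: len(self.free_lam_idx)]
        Lam = np.zeros((self.p, self.m), dtype=dtype)
        Lam[self.lam_rows, self.lam_cols] = lam[self.lam_rows]
        K = self.latent_cov(x)
        Sig = Lam @ K @ Lam.T
        Sig[np.diag_indices(self.p)] += x[self.sl_theta]
        return Sig

    def dsigma(self, x: np.ndarray) -> list[np.ndarray]:
        """dSigma/dtheta_i by complex step, one p x p matrix per parameter."""
        out = []
        for i in range(self.k):
            xc = x.astype(complex)
            xc[i] += 1j * _CSTEP
            out.append(self.sigma(xc).imag / _CSTEP)
        return out

    def psi_values(self, x: np.ndarray) -> dict[str, float]:
        K = self.latent_cov(x)
        vals = {}
        for (lj, pidx, cidx, psi_i), name in zip(self.endo_info, self.endo_topo):
            if self.scaling == "marker":
                vals[name] = float(x[psi_i])
            else:
                a = x[cidx]
                vals[name] = float(1.0 - a @ K[np.ix_(pidx, pidx)] @ a)
        return vals


def _fml_factory(tpl: _Template, S: np.ndarray):
    p = tpl.p
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("input covariance matrix is not positive definite")

    def fml(x: np.ndarray):
        Sig = tpl.sigma(x)
        if not np.iscomplexobj(x):
            sign, logdet = np.linalg.slogdet(Sig)
            if sign <= 0 or not np.isfinite(logdet):
                return _PENALTY * (1.0 + float(x @ x))
            try:
                tr = float(np.trace(np.linalg.solve(Sig, S)))
            except np.linalg.LinAlgError:
                return _PENALTY * (1.0 + float(x @ x))
            return logdet + tr - logdet_s - p
        # complex path: slogdet returns log|det| with the phase on the sign,
        # so the imaginary (derivative-carrying) part must be restored
        sign, logabs = np.linalg.slogdet(Sig)
        logdet = logabs + np.log(sign)
        tr = np.trace(np.linalg.solve(Sig, S))
        return logdet + tr - logdet_s - p

    def grad(x: np.ndarray) -> np.ndarray:
        g = np.empty(tpl.k)
        for i in range(tpl.k):
            xc = x.astype(complex)
            xc[i] += 1j * _CSTEP
            g[i] = np.imag(fml(xc)) / _CSTEP
        return g

    return fml, grad


@dataclass(frozen=True)
class SemFit:
    """Result of one NML fit: estimates, uncertainty, and fit statistic."""

    model: PopulationModel
    scaling: str
    param_names: tuple[str, ...]
    x: np.ndarray
    fml: float
    chi_square: float | None
    df: int
    n: int | None
    converged: bool
    grad_norm: float
    heywood: bool
    data: CovarianceInput | None = None
    se: dict[str, float] | None = None
    information: str | None = None

    @property
    def estimates(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(self.param_names, self.x)}

    def z(self) -> dict[str, float]:
        if self.se is None:
            raise ValueError("standard errors have not been computed")
        return {name: self.estimates[name] / self.se[name]
                for name in self.param_names}

    # parameter views ---------------------------------------------------

    def _template(self) -> _Template:
        return _Template(self.model, self.scaling)

    def loading_estimates(self) -> dict[str, float]:
        tpl = self._template()
        out = dict(tpl.fixed_loadings)
        for ind, val in zip(tpl.free_loading_inds, self.x[: len(tpl.free_loading_inds)]):
            out[ind] = float(val)
        return out

    def error_variance_estimates(self) -> dict[str, float]:
        tpl = self._template()
        return {ind: float(v) for ind, v in zip(tpl.inds, self.x[tpl.sl_theta])}

    def structural_estimates(self) -> dict[tuple[str, str], float]:
        tpl = self._template()
        return {edge: float(v) for edge, v in zip(tpl.edges, self.x[tpl.sl_beta])}

    def disturbance_estimates(self) -> dict[str, float]:
        return self._template().psi_values(self.x)


def _start_values(tpl: _Template, S: np.ndarray) -> np.ndarray:
    """Regression-heuristic starting values from equal-weight composites."""
    from .weights import composite_cov, weights_equal

    model = tpl.model
    cov = CovarianceInput(S, None, tuple(tpl.inds))
    x = np.zeros(tpl.k)
    try:
        W = weights_equal(cov, model.blocks, latent_order=model.latent_names)
        C = composite_cov(cov, W).matrix
    except ValueError:
        return _fallback_start(tpl, S)
    lpos = {n: j for j, n in enumerate(tpl.latents)}
    ipos = {n: i for i, n in enumerate(tpl.inds)}
    # loading proxies: covariance of indicator with its unit-variance composite
    c = S @ W.weights  # p x m
    latent_sd = {}
    for name in tpl.latents:
        j = lpos[name]
        block = model.blocks[name]
        if tpl.scaling == "marker" and name in set(tpl.endo_topo):
            marker = block[0]
            cm = c[ipos[marker], j]
            latent_sd[name] = max(abs(cm), 0.2)
        else:
            latent_sd[name] = 1.0
    for t, ind in enumerate(tpl.free_loading_inds):
        name = next(n for n in tpl.latents if ind in model.blocks[n])
        lam0 = c[ipos[ind], lpos[name]] / latent_sd[name]
        x[t] = lam0 if abs(lam0) > 0.05 else 0.5
    lam_full = tpl.lam_base.copy()
    lam_full[tpl.free_lam_idx] = x[: len(tpl.free_lam_idx)]
    for i, ind in enumerate(tpl.inds):
        name = next(n for n in tpl.latents if ind in model.blocks[n])
        resid = S[i, i] - (lam_full[i] * latent_sd[name]) ** 2
        x[tpl.sl_theta.start + i] = max(resid, 0.1 * S[i, i])
    for t, (a, b) in enumerate(tpl.exo_pairs):
        x[tpl.sl_phi.start + t] = np.clip(C[lpos[a], lpos[b]], -0.9, 0.9)
    for t, (src, dst) in enumerate(tpl.edges):
        preds = model.parents(dst)
        pidx = [lpos[pn] for pn in preds]
        try:
            coef = np.linalg.solve(C[np.ix_(pidx, pidx)], C[pidx, lpos[dst]])
        except np.linalg.LinAlgError:
            coef = np.zeros(len(pidx))
        b0 = coef[preds.index(src)] * latent_sd[dst] / latent_sd[src]
        x[tpl.sl_beta.start + t] = np.clip(b0, -2.0, 2.0)
    for t, name in enumerate(tpl.endo_topo):
        if tpl.scaling == "marker":
            x[tpl.sl_psi.start + t] = 0.5 * latent_sd[name] ** 2
    return x


def _fallback_start(tpl: _Template, S: np.ndarray) -> np.ndarray:
    x = np.zeros(tpl.k)
    x[: len(tpl.free_lam_idx)] = 0.5
    x[tpl.sl_theta] = 0.5 * np.diag(S)
    if tpl.scaling == "marker":
        x[tpl.sl_psi] = 0.5
    return x


def fit_nml(data: CovarianceInput, model: PopulationModel,
            scaling: str = "marker", nominal_n: int | None = None,
            compute_se: bool = True, information: str = "expected",
            max_iter: int = 500, gtol: float = 1e-9) -> SemFit:
    """Fit ``model`` to a covariance matrix by NML under a scaling method.

    ``data.n`` (or ``nominal_n`` for population matrices) supplies the
    sample size used for the chi-square multiplier (n-1) and the standard
    errors.  Heywood cases (negative variance estimates) are flagged on the
    returned fit, not truncated.
    """
    tpl = _Template(model, scaling)
    if tuple(data.labels) != tuple(tpl.inds):
        raise ValueError("covariance labels do not match the model's indicators")
    S = data.matrix
    fml, grad = _fml_factory(tpl, S)
    best = None
    for attempt, x0 in enumerate((_start_values(tpl, S), _fallback_start(tpl, S))):
        if fml(x0) >= _PENALTY:
            continue
        res = minimize(fml, x0, jac=grad, method="BFGS",
                       options={"gtol": gtol, "maxiter": max_iter})
        gn = float(np.linalg.norm(grad(res.x), ord=np.inf))
        if gn > gtol * 10:  # polish from the current point
            res2 = minimize(fml, res.x, jac=grad, method="BFGS",
                            options={"gtol": gtol, "maxiter": max_iter})
            if res2.fun <= res.fun:
                res = res2
                gn = float(np.linalg.norm(grad(res.x), ord=np.inf))
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gn)
        if best[1] < 1e-6:
            break
    if best is None:
        raise RuntimeError("no feasible starting values for the NML fit")
    res, gn = best
    converged = bool(np.isfinite(res.fun) and gn < 1e-6)
    n = data.n if data.n is not None else nominal_n
    theta_hat = res.x[tpl.sl_theta]
    psis = np.array(list(tpl.psi_values(res.x).values())) if tpl.endo_topo else np.zeros(0)
    heywood = bool(np.any(theta_hat < 0) or np.any(psis < 0))
    fit = SemFit(model=model, scaling=scaling,
                 param_names=tuple(tpl.param_names), x=res.x,
                 fml=float(res.fun),
                 chi_square=float((n - 1) * res.fun) if n is not None else None,
                 df=tpl.df, n=n, converged=converged, grad_norm=gn,
                 heywood=heywood, data=data)
    if compute_se and n is not None:
        fit = standard_errors(fit, information=information)
    return fit


def _expected_information(tpl: _Template, x: np.ndarray, S_unused=None) -> np.ndarray:
    Sig = tpl.sigma(x)
    Sinv = np.linalg.inv(Sig)
    dS = tpl.dsigma(x)
    A = [Sinv @ d for d in dS]
    k = tpl.k
    info = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.sum(A[i] * A[j].T)
    return info


def _observed_information(tpl: _Template, x: np.ndarray, S: np.ndarray) -> np.ndarray:
    _, grad = _fml_factory(tpl, S)
    k = tpl.k
    H = np.empty((k, k))
    step = 1e-5
    for i in range(k):
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] -= step
        H[:, i] = (grad(xp) - grad(xm)) / (2 * step)
    H = (H + H.T) / 2.0
    return H / 2.0  # observed information per (n-1) observations, F_ML scale


def standard_errors(fit: SemFit, information: str = "expected") -> SemFit:
    """Attach standard errors from the expected or observed information.

    se = sqrt(diag(I(theta)^{-1}) / (n-1)) on the free-parameter
    (constraint-reduced) vector; under the standardized scaling the
    substituted disturbance variances are not free parameters, so the
    information matrix is automatically the constrained one.
    """
    if fit.n is None:
        raise ValueError("standard errors need a sample size (n or nominal_n)")
    if information not in {"expected", "observed"}:
        raise ValueError("information must be 'expected' or 'observed'")
    tpl = fit._template()
    if information == "observed":
        if fit.data is None:
            raise ValueError("observed information needs the fitted covariance "
                             "matrix on the SemFit")
        info = _observed_information(tpl, fit.x, fit.data.matrix)
    else:
        info = _expected_information(tpl, fit.x)
    eigvals, eigvecs = np.linalg.eigh(info)
    if eigvals.min() <= 0 or eigvals.max() / max(eigvals.min(), 1e-300) > 1e12:
        null = eigvecs[:, int(np.argmin(eigvals))]
        worst = np.argsort(-np.abs(null))[:3]
        bad = [fit.param_names[i] for i in worst]
        raise np.linalg.LinAlgError(
            "information matrix is (near-)singular; the model is not "
            f"identified in the direction of parameters {bad}")
    cov = np.linalg.inv(info) / (fit.n - 1)
    se = {name: float(np.sqrt(max(cov[i, i], 0.0)))
          for i, name in enumerate(fit.param_names)}
    return replace(fit, se=se, information=information)


def structural_z(fit: SemFit, method: str = "CBSEM_NML") -> list[EstimateRecord]:
    """One estimate record (gamma_hat, se, z, tau = z/sqrt(n)) per path."""
    if not fit.converged:
        raise RuntimeError("cannot report z-statistics for a non-converged fit")
    if fit.se is None:
        raise ValueError("standard errors have not been computed")
    tpl = fit._template()
    out = []
    for t, (src, dst) in enumerate(tpl.edges):
        name = f"beta[{src}->{dst}]"
        est = float(fit.x[tpl.sl_beta.start + t])
        se = fit.se[name]
        z = est / se
        out.append(EstimateRecord(path=(src, dst), method=method,
                                  gamma_hat=est, se=se, z=z,
                                  tau=z / np.sqrt(fit.n), n=fit.n))
    return out
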