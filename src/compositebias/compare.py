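"""Five-method comparison engine and Monte-Carlo rejection studies.

``compare_methods`` runs CB-SEM (NML, chosen scaling) and path analysis
with BFS, EWC, PLS Mode A and PLS Mode B_A composites over a registry of
problems and collects the z-statistics into a table with one row per
structural path.  ``rank_summary`` aggregates that table the way
meta-comparisons report it: counts of largest/smallest absolute z, mean
rank of |z| (rank 1 = largest), and mean |z| per method.

Bartlett factor scores are always computed from the marker-scaled CB-SEM
fit regardless of the scaling requested for the CB-SEM column: the
Bartlett weight vector is invariant (up to the unit-variance rescaling) to
the latent scaling of the loading estimates, and pinning it to one
canonical fit makes the composite-method columns bit-identical across
CB-SEM scaling choices.

``monte_carlo_rejection`` wraps the whole pipeline in a seeded
replication loop and reports per-method, per-path rejection proportions
of the two-sided z-test, with Monte-Carlo standard errors and explicit
counts of estimation failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CovarianceInput, PopulationModel
from .path_ols import fit_path_equations
from .sem import fit_nml, structural_z
from .synthetic import SimulationDesign, sample_data
from .weights import (composite_cov, weights_bartlett_from_fit, weights_equal,
                      weights_pls)

__all__ = ["Problem", "ZTable", "RankSummary", "RejectionTable",
           "compare_methods", "rank_summary", "monte_carlo_rejection",
           "ALL_METHODS"]

ALL_METHODS = ("CBSEM_NML", "BFS", "EWC", "PLS_A", "PLS_BA")


@dataclass(frozen=True)
class Problem:
    """One registry entry: a labelled covariance input plus model template."""

    label: str
    data: CovarianceInput
    model: PopulationModel
    nominal_n: int | None = None

    @property
    def n(self) -> int:
        n = self.data.n if self.data.n is not None else self.nominal_n
        if n is None:
            raise ValueError(f"problem {self.label!r} has no sample size")
        return n


@dataclass(frozen=True)
class ZTable:
    """z- and tau-statistics, rows = (problem, path), columns = methods."""

    z: pd.DataFrame
    tau: pd.DataFrame
    estimates: pd.DataFrame
    scaling: str
    failures: tuple[tuple[str, str], ...] = ()

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.z.columns)


@dataclass(frozen=True)
class RankSummary:
    """Counts/ranks/averages of |z| per method (meta-comparison layout)."""

    table: pd.DataFrame  # index: methods; columns: the four summary rows

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


def _composite_records(S, model, scheme, n, marker_fit=None,
                       df_correction=True):
    edges = [(s, d) for s, d, _ in model.structural]
    if scheme == "EWC":
        W = weights_equal(S, model.blocks, latent_order=model.latent_names)
    elif scheme == "BFS":
        W = weights_bartlett_from_fit(marker_fit, S)
    elif scheme == "PLS_A":
        W = weights_pls(S, model.blocks, edges, mode="A",
                        latent_order=model.latent_names)
    elif scheme == "PLS_BA":
        W = weights_pls(S, model.blocks, edges, mode="B_A",
                        latent_order=model.latent_names)
    else:
        raise ValueError(f"unknown composite scheme {scheme!r}")
    C = composite_cov(S, W)
    return fit_path_equations(C, edges, method=scheme, n=n,
                              df_correction=df_correction)


def compare_methods(problems: Sequence[Problem], scaling: str = "marker",
                    methods: Sequence[str] = ALL_METHODS,
                    df_correction: bool = True) -> ZTable:
    """Run the selected methods over a registry and tabulate z-statistics.

    Per-problem failures (non-convergence, singular systems) are recorded
    on the returned table instead of aborting the batch.
    """
    methods = tuple(methods)
    rows_z: dict[tuple[str, str], dict[str, float]] = {}
    rows_tau: dict[tuple[str, str], dict[str, float]] = {}
    rows_est: dict[tuple[str, str], dict[str, float]] = {}
    failures: list[tuple[str, str]] = []
    for prob in problems:
        n = prob.n
        need_bfs = "BFS" in methods
        need_cbsem = "CBSEM_NML" in methods
        marker_fit = cbsem_fit = None
        try:
            if need_bfs or (need_cbsem and scaling == "marker"):
                marker_fit = fit_nml(prob.data, prob.model, scaling="marker",
                                     nominal_n=n)
            if need_cbsem:
                cbsem_fit = (marker_fit if scaling == "marker"
                             else fit_nml(prob.data, prob.model,
                                          scaling=scaling, nominal_n=n))
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            failures.append((prob.label, f"CBSEM_NML: {exc}"))
            continue
        for method in methods:
            try:
                if method == "CBSEM_NML":
                    records = structural_z(cbsem_fit)
                else:
                    records = _composite_records(prob.data, prob.model, method,
                                                 n, marker_fit=marker_fit,
                                                 df_correction=df_correction)
            except Exception as exc:  # noqa: BLE001
                failures.append((prob.label, f"{method}: {exc}"))
                continue
            for rec in records:
                key = (prob.label, f"{rec.path[0]}->{rec.path[1]}")
                rows_z.setdefault(key, {})[method] = rec.z
                rows_tau.setdefault(key, {})[method] = rec.tau
                rows_est.setdefault(key, {})[method] = rec.gamma_hat
    index = pd.MultiIndex.from_tuples(list(rows_z) or [],
                                      names=["problem", "path"])
    z = pd.DataFrame([rows_z[k] for k in rows_z], index=index,
                     columns=list(methods))
    tau = pd.DataFrame([rows_tau[k] for k in rows_tau], index=index,
                       columns=list(methods))
    est = pd.DataFrame([rows_est[k] for k in rows_est], index=index,
                       columns=list(methods))
    return ZTable(z=z, tau=tau, estimates=est, scaling=scaling,
                  failures=tuple(failures))


def rank_summary(zt: ZTable) -> RankSummary:
    """Aggregate |z| across paths: extreme counts, mean rank, mean |z|.

    Ties receive averaged ranks; tied extremes get fractional counts so
    the count rows always sum to the number of paths.
    """
    absz = zt.z.abs()
    if absz.isna().any().any():
        raise ValueError("ZTable has missing entries; cannot rank")
    m = absz.shape[1]
    ranks = absz.rank(axis=1, method="average", ascending=False)
    largest = pd.Series(0.0, index=absz.columns)
    smallest = pd.Series(0.0, index=absz.columns)
    for _, row in absz.iterrows():
        top = row == row.max()
        bot = row == row.min()
        largest[top.index[top]] += 1.0 / top.sum()
        smallest[bot.index[bot]] += 1.0 / bot.sum()
    table = pd.DataFrame({
        "count_largest_abs_z": largest,
        "count_smallest_abs_z": smallest,
        "mean_rank": ranks.mean(axis=0) if len(absz) else pd.Series(np.nan, index=absz.columns),
        "mean_abs_z": absz.mean(axis=0) if len(absz) else pd.Series(np.nan, index=absz.columns),
    })
    assert table["mean_rank"].isna().all() or \
        ((table["mean_rank"] >= 1 - 1e-9) & (table["mean_rank"] <= m + 1e-9)).all()
    return RankSummary(table=table)


@dataclass(frozen=True)
class RejectionTable:
    """Rejection proportions of the two-sided z-test per method and path."""

    proportions: pd.DataFrame  # rows: paths, columns: methods
    mcse: pd.DataFrame
    reps: int
    alpha: float
    failure_counts: dict[str, int] = field(default_factory=dict)
    reps_effective: dict[str, int] = field(default_factory=dict)


def monte_carlo_rejection(design: SimulationDesign,
                          methods: Sequence[str] = ALL_METHODS,
                          alpha: float = 0.05, scaling: str = "marker",
                          df_correction: bool = True) -> RejectionTable:
    """Seeded Monte-Carlo rejection rates for every method and path.

    Each replication draws multivariate-normal data from the design's
    population model, computes the sample covariance, runs every method,
    and applies a two-sided z-test at level ``alpha`` against the standard
    normal.  Replications where a method fails to produce an estimate are
    excluded from that method's proportions and reported in
    ``failure_counts``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    crit = stats.norm.ppf(1 - alpha / 2)
    methods = tuple(methods)
    paths = [f"{s}->{d}" for s, d, _ in design.model.structural]
    rejections = {m: {p: 0 for p in paths} for m in methods}
    successes = {m: 0 for m in methods}
    failures = {m: 0 for m in methods}
    for cov in sample_data(design):
        prob = Problem(label="mc", data=cov, model=design.model)
        zt = compare_methods([prob], scaling=scaling, methods=methods,
                             df_correction=df_correction)
        for m in methods:
            ok = (m in zt.z.columns and len(zt.z) == len(paths)
                  and zt.z[m].notna().all())
            if not ok:
                failures[m] += 1
                continue
            successes[m] += 1
            for p in paths:
                if abs(zt.z.loc[("mc", p), m]) > crit:
                    rejections[m][p] += 1
    prop = pd.DataFrame(index=paths, columns=list(methods), dtype=float)
    mcse = pd.DataFrame(index=paths, columns=list(methods), dtype=float)
    for m in methods:
        r = successes[m]
        for p in paths:
            if r:
                pr = rejections[m][p] / r
                prop.loc[p, m] = pr
                mcse.loc[p, m] = np.sqrt(pr * (1 - pr) / r)
    return RejectionTable(proportions=prop, mcse=mcse, reps=design.reps,
                          alpha=alpha, failure_counts=failures,
                          reps_effective=successes)
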