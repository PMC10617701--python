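"""Decomposition of the Erreygers index into covariate contributions.

A weighted logit model for the binary indicator supplies average marginal
effects (AMEs) :math:`\\beta^m_k` on the probability scale.  For each design
column :math:`x_k` the decomposition reports

* elasticity :math:`e_k = 4\\,\\beta^m_k\\,\\bar{x}_k` (Erreygers scale),
* the covariate's own concentration index
  :math:`C_k = 2\\,\\mathrm{cov}_w(x_k, r)/\\bar{x}_k`,
* contribution :math:`a_k = e_k C_k`, and its share
  :math:`100\\,a_k/E` of the total index,

with the unexplained residual :math:`E - \\sum_k a_k` (the generalized
concentration of the model error).  Algebraically
:math:`a_k = 8\\,\\beta^m_k\\,\\mathrm{cov}_w(x_k, r)`, which is used as an
independent check.  AMEs are discrete changes (column set to 1 vs 0, other
columns at observed values) for indicator columns and weighted means of
:math:`p_i(1-p_i)\\beta_k` for continuous columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concentration import weighted_cov, weighted_mean
from .survey_data import CovariateSpec

__all__ = [
    "LogitFit",
    "DecompositionResult",
    "fit_logit",
    "average_marginal_effects",
    "decompose_index",
    "elasticity",
    "percentage_contribution",
]


@dataclass
class LogitFit:
    params: pd.Series  # includes "intercept"
    fitted: np.ndarray
    converged: bool
    iterations: int
    loglik: float
    columns: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy removal of linearly dependent columns (after adding intercept)."""
    cols = list(X.columns)
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(M)
    if rank == M.shape[1]:
        return X, []
    dropped: list[str] = []
    keep = cols.copy()
    for c in cols:
        trial = [k for k in keep if k != c]
        Mt = np.column_stack([np.ones(len(X))] + [X[k].to_numpy(dtype=float) for k in trial])
        if np.linalg.matrix_rank(Mt) == rank:
            keep = trial
            dropped.append(c)
            if rank == len(keep) + 1:
                break
    return X[keep], dropped


def fit_logit(h: np.ndarray, design: pd.DataFrame, weights: np.ndarray) -> LogitFit:
    """Weighted logit (binomial GLM) of the binary indicator on the design.

    The weight-scaled binomial likelihood is maximized by iteratively
    reweighted least squares; collinear columns are dropped with a warning,
    and coefficients beyond +-15 trigger a separation warning.
    """
    hv = np.asarray(h, dtype=float)
    if hv.min() == hv.max():
        raise ValueError("outcome is constant; logit model undefined")
    w = np.asarray(weights, dtype=float)
    X, dropped = _drop_collinear(design)
    if dropped:
        warnings.warn(f"dropping collinear design column(s): {dropped}", stacklevel=2)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.GLM(hv, exog, family=sm.families.Binomial(), var_weights=w)
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(f"logit did not converge in {res.fit_history['iteration']} iterations")
    params = pd.Series(res.params, index=["intercept"] + list(X.columns))
    if (params.abs() > 15).any():
        offenders = list(params[params.abs() > 15].index)
        warnings.warn(f"possible separation: |coefficient| > 15 for {offenders}", stacklevel=2)
    return LogitFit(
        params=params,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        converged=bool(res.converged),
        iterations=int(res.fit_history["iteration"]),
        loglik=float(res.llf),
        columns=list(X.columns),
        dropped=dropped,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def average_marginal_effects(
    fit: LogitFit, design: pd.DataFrame, weights: np.ndarray
) -> pd.Series:
    """Average marginal effects on the probability scale.

    Indicator (0/1) columns use the discrete change: the weighted mean of
    ``p(x | x_k = 1) - p(x | x_k = 0)`` with all other columns at their
    observed values.  Continuous columns use the weighted mean of
    ``p_i (1 - p_i) beta_k``.
    """
    if not fit.converged:
        raise ValueError("cannot compute marginal effects from a non-converged fit")
    w = np.asarray(weights, dtype=float)
    X = design[fit.columns].to_numpy(dtype=float)
    beta = fit.params.to_numpy()
    eta = beta[0] + X @ beta[1:]
    p = _sigmoid(eta)
    ames = {}
    for j, col in enumerate(fit.columns):
        xj = X[:, j]
        is_indicator = np.all((xj == 0) | (xj == 1))
        bj = beta[1 + j]
        if is_indicator:
            eta1 = eta + (1.0 - xj) * bj
            eta0 = eta - xj * bj
            ames[col] = weighted_mean(_sigmoid(eta1) - _sigmoid(eta0), w)
        else:
            ames[col] = weighted_mean(p * (1.0 - p) * bj, w)
    return pd.Series(ames)


def elasticity(beta_m: float, xbar: float) -> float:
    """Erreygers-scale elasticity ``e_k = 4 * beta_m * xbar``."""
    return 4.0 * beta_m * xbar


def percentage_contribution(elasticity_k: float, ci_k: float, E: float) -> float:
    """Percentage share ``100 * e_k * C_k / E`` of the total index."""
    return 100.0 * elasticity_k * ci_k / E


@dataclass
class DecompositionResult:
    """Per-column contributions and their accounting against the total index."""

    table: pd.DataFrame  # beta_m, xbar, elasticity, ci_k, contribution, percent
    E: float
    residual: float
    total_percent_explained: float
    group_percent: pd.Series  # summed percentage per covariate (CovariateSpec)


def decompose_index(
    E: float,
    fit: LogitFit,
    design: pd.DataFrame,
    ranks: np.ndarray,
    weights: np.ndarray,
    specs: Sequence[CovariateSpec] = (),
) -> DecompositionResult:
    """Wagstaff-type decomposition of the Erreygers index.

    Requires ``|E| >= 1e-6`` (percent shares are otherwise undefined).
    ``specs`` is used only to report summed percentages per covariate group.
    """
    if abs(E) < 1e-6:
        raise ValueError("total index is ~0; percentage contributions undefined")
    w = np.asarray(weights, dtype=float)
    r = np.asarray(ranks, dtype=float)
    ames = average_marginal_effects(fit, design, w)
    rows = []
    for col in fit.columns:
        x = design[col].to_numpy(dtype=float)
        xbar = weighted_mean(x, w)
        cov = weighted_cov(x, r, w)
        ci_k = 2.0 * cov / xbar if xbar != 0 else float("nan")
        e_k = elasticity(ames[col], xbar)
        a_k = e_k * ci_k if xbar != 0 else 8.0 * ames[col] * cov
        rows.append(
            {
                "column": col,
                "beta_m": ames[col],
                "xbar": xbar,
                "elasticity": e_k,
                "ci_k": ci_k,
                "contribution": a_k,
                "percent": 100.0 * a_k / E,
            }
        )
    table = pd.DataFrame(rows).set_index("column")
    explained = float(table["contribution"].sum())
    residual = E - explained
    groups = {}
    for spec in specs:
        cols = [c for c in spec.column_names() if c in table.index]
        if cols:
            groups[spec.name] = float(table.loc[cols, "percent"].sum())
    return DecompositionResult(
        table=table,
        E=E,
        residual=residual,
        total_percent_explained=float(table["percent"].sum()),
        group_percent=pd.Series(groups, dtype=float),
    )
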