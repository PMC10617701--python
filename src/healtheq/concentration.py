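"""Concentration curves and the Erreygers concentration index.

A binary health indicator :math:`h_i` with sampling weights :math:`w_i` is
ranked by a living-standards score.  The weighted fractional rank
:math:`r_i \\in (0,1)` is the midpoint of respondent *i*'s interval in the
cumulative weight distribution, so the weighted mean rank is exactly 0.5.

The standard concentration index is

.. math:: C = \\frac{2\\,\\mathrm{cov}_w(h, r)}{\\mu},

twice the weighted covariance between the indicator and the rank scaled by
the weighted mean :math:`\\mu`; it equals twice the area between the
concentration curve and the diagonal.  For a binary indicator the Erreygers
(bounded-outcome) correction reduces to

.. math:: E = 8\\,\\mathrm{cov}_w(h, r) = 4 \\mu C \\in [-1, 1],

positive when the indicator concentrates among the rich.  Weighted
covariances use the population (``W``-denominator) form so the identity
``E = 8 cov`` holds exactly under weight rescaling.

Uncertainty comes from a stratified cluster bootstrap: primary sampling
units are resampled with replacement within strata and the statistic is
recomputed on each pseudo-sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationResult",
    "CurvePoints",
    "BootstrapResult",
    "weighted_mean",
    "weighted_cov",
    "fractional_rank",
    "concentration_curve",
    "erreygers_index",
    "index_from_curve",
    "bootstrap_se",
]


@dataclass
class ConcentrationResult:
    """Weighted mean, standard index C, Erreygers index E and ranks."""

    mu: float
    C: float
    E: float
    n: int
    ranks: np.ndarray
    se_E: float | None = None

    def to_dict(self) -> dict:
        return {"mu": self.mu, "C": self.C, "E": self.E, "n": self.n, "se_E": self.se_E}


@dataclass
class CurvePoints:
    """Concentration curve: cumulative population share vs outcome share."""

    p: np.ndarray
    L: np.ndarray


@dataclass
class BootstrapResult:
    se: float
    ci_low: float
    ci_high: float
    values: np.ndarray
    B: int
    seed: int


def weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    return float((w * x).sum() / w.sum())


def weighted_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Population-form weighted covariance (denominator ``sum(w)``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    return float((w * (x - xm) * (y - ym)).sum() / W)


def _check_scores_weights(scores: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return s, w


def fractional_rank(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted fractional rank in (0, 1) with block-midpoint tie handling.

    After sorting ascending by score, ``r_i = (cumw_before_i + w_i/2) / W``;
    all members of a tie block receive the midpoint rank of the block's
    combined weight interval.  The weighted mean of the ranks is exactly 0.5.
    """
    s, w = _check_scores_weights(scores, weights)
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    w_sorted = w[order]
    W = w_sorted.sum()
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s_sorted[1:] != s_sorted[:-1]
    block_id = np.cumsum(new_block) - 1
    cum = np.cumsum(w_sorted)
    starts = np.flatnonzero(new_block)
    block_before = np.concatenate(([0.0], cum[:-1]))[starts]
    # combined weight of each block
    block_end = np.concatenate((block_before[1:], [W]))
    block_mid = (block_before + block_end) / 2.0 / W
    ranks_sorted = block_mid[block_id]
    ranks = np.empty(len(s))
    ranks[order] = ranks_sorted
    return ranks


def concentration_curve(h: np.ndarray, scores: np.ndarray, weights: np.ndarray) -> CurvePoints:
    """Concentration curve points at each distinct score block.

    ``p`` is the cumulative population weight share and ``L`` the cumulative
    weighted outcome share, ranked poorest to richest; the origin ``(0, 0)``
    is prepended.  Undefined (raises) when the indicator is identically 0.
    """
    s, w = _check_scores_weights(scores, weights)
    hv = np.asarray(h, dtype=float)
    total = (w * hv).sum()
    if total <= 0:
        raise ValueError("concentration curve undefined: outcome is identically zero")
    order = np.argsort(s, kind="mergesort")
    s_sorted, w_sorted, h_sorted = s[order], w[order], hv[order]
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s_sorted[1:] != s_sorted[:-1]
    block_id = np.cumsum(new_block) - 1
    nblocks = block_id[-1] + 1
    bw = np.bincount(block_id, weights=w_sorted, minlength=nblocks)
    bh = np.bincount(block_id, weights=w_sorted * h_sorted, minlength=nblocks)
    p = np.concatenate(([0.0], np.cumsum(bw) / w_sorted.sum()))
    L = np.concatenate(([0.0], np.cumsum(bh) / total))
    p[-1] = 1.0
    L[-1] = 1.0
    return CurvePoints(p=p, L=L)


def erreygers_index(h: np.ndarray, ranks: np.ndarray, weights: np.ndarray) -> ConcentrationResult:
    """Covariance-based concentration indices for a binary indicator.

    ``C = 2 cov_w(h, r) / mu`` and ``E = 8 cov_w(h, r)``.  When the indicator
    is identically zero the standard index is undefined (returned as NaN with
    a warning) while ``E = 0``.
    """
    hv = np.asarray(h, dtype=float)
    r = np.asarray(ranks, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    mu = weighted_mean(hv, w)
    cov = weighted_cov(hv, r, w)
    E = 8.0 * cov
    if mu == 0.0:
        warnings.warn("outcome identically zero: standard concentration index undefined", stacklevel=2)
        C = float("nan")
        E = 0.0
    else:
        C = 2.0 * cov / mu
    return ConcentrationResult(mu=mu, C=C, E=E, n=len(hv), ranks=r)


def index_from_curve(curve: CurvePoints, mu: float) -> tuple[float, float]:
    """Area-based indices: ``C = 1 - 2 * trapezoid(L, p)``, ``E = 4 mu C``.

    Independent of the covariance route; used for cross-checks.
    """
    area = float(np.trapezoid(curve.L, curve.p))
    C = 1.0 - 2.0 * area
    return C, 4.0 * mu * C


def bootstrap_se(
    df: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    B: int = 200,
    seed: int = 0,
    cluster_col: str = "cluster",
    stratum_col: str = "stratum",
    alpha: float = 0.05,
) -> BootstrapResult:
    """Stratified cluster bootstrap of an arbitrary statistic.

    Within each stratum, primary sampling units (clusters) are resampled with
    replacement (same number of clusters as observed); the statistic is then
    recomputed on the stacked pseudo-sample.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if df[cluster_col].nunique() < 2:
        raise ValueError("cluster bootstrap requires at least 2 clusters")
    rng = np.random.default_rng(seed)
    arr_df = df.reset_index(drop=True)
    if stratum_col in arr_df.columns:
        strat_vals = arr_df[stratum_col]
    else:
        strat_vals = pd.Series(0, index=arr_df.index)
    by_stratum: dict[object, list[np.ndarray]] = {}
    for (s, _c), idx in arr_df.groupby([strat_vals, arr_df[cluster_col]], sort=True).indices.items():
        by_stratum.setdefault(s, []).append(np.asarray(idx))
    strata = [by_stratum[s] for s in sorted(by_stratum, key=str)]
    values = np.empty(B)
    for b in range(B):
        picked: list[np.ndarray] = []
        for clusters in strata:
            k = len(clusters)
            choice = rng.integers(0, k, size=k)
            picked.extend(clusters[c] for c in choice)
        idx = np.concatenate(picked)
        values[b] = statistic(arr_df.iloc[idx])
    se = float(values.std(ddof=1)) if B > 1 else 0.0
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(se=se, ci_low=float(lo), ci_high=float(hi), values=values, B=B, seed=seed)
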