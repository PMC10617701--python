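"""Asset-based wealth index: weighted first principal component and quintiles.

Living standards are proxied by the first principal component of a matrix of
binary asset-ownership indicators, each standardized by its weighted mean and
standard deviation, with the eigendecomposition taken on the weighted
correlation matrix.  The component is oriented so that owning assets raises
the score (sum of loadings positive), and respondents are grouped into five
weighted quintiles (poorest ... richest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WealthIndex", "compute_wealth_scores", "assign_quintiles", "QUINTILE_LABELS"]

QUINTILE_LABELS = ("poorest", "poorer", "middle", "richer", "richest")


@dataclass
class WealthIndex:
    scores: np.ndarray
    loadings: pd.Series
    explained_share: float


def _weighted_standardize(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    wn = w / w.sum()
    mean = wn @ X
    var = wn @ (X - mean) ** 2
    return (X - mean) / np.sqrt(var)


def compute_wealth_scores(assets: pd.DataFrame | np.ndarray, weights: np.ndarray) -> WealthIndex:
    """First principal component of weighted-standardized asset indicators.

    Constant columns are dropped with a warning; if no column varies the
    index is undefined and a ``ValueError`` is raised.
    """
    if isinstance(assets, pd.DataFrame):
        names = list(assets.columns)
        X = assets.to_numpy(dtype=float)
    else:
        X = np.asarray(assets, dtype=float)
        names = [f"asset_{i}" for i in range(X.shape[1])]
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wn = w / w.sum()
    var = wn @ (X - wn @ X) ** 2
    keep = var > 0
    if not keep.any():
        raise ValueError("all asset columns are constant; wealth index undefined")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant asset column(s): {dropped}", stacklevel=2)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 varying asset columns")
    Z = _weighted_standardize(X, w)
    corr = (Z * wn[:, None]).T @ Z
    corr = (corr + corr.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if v.sum() < 0:  # orientation: ownership loads positively (richer -> higher)
        v = -v
    scores = Z @ v
    explained = float(eigvals[-1] / eigvals.sum())
    return WealthIndex(scores=scores, loadings=pd.Series(v, index=names), explained_share=explained)


def assign_quintiles(scores: np.ndarray, weights: np.ndarray, labels=QUINTILE_LABELS) -> np.ndarray:
    """Weighted quintile groups with a deterministic lower-group tie rule.

    Respondents are sorted by score; tied scores form one block.  A block
    occupying the cumulative-weight interval ``(a, a + b]`` is assigned the
    quintile containing the start ``a`` of its interval, so a block that
    straddles a 20% boundary goes wholly to the lower group and all members
    of a tie share one quintile.  With all scores tied the single block
    starts at 0 and everyone is "poorest".
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    w_sorted = w[order]
    W = w_sorted.sum()
    # block starts: first index of each run of tied scores
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s_sorted[1:] != s_sorted[:-1]
    block_id = np.cumsum(new_block) - 1
    cum_before = np.concatenate(([0.0], np.cumsum(w_sorted)[:-1]))
    block_start = cum_before[np.flatnonzero(new_block)]  # cum weight before each block
    start_per_unit = block_start[block_id]
    group_sorted = np.minimum((start_per_unit / (W / 5.0)).astype(int), 4)
    # exact-boundary starts belong to the upper side: floor already does that,
    # but guard against float jitter just below a boundary
    frac = start_per_unit / (W / 5.0)
    near = np.isclose(frac, np.round(frac), rtol=0, atol=1e-12)
    group_sorted = np.where(near, np.minimum(np.round(frac).astype(int), 4), group_sorted)
    out = np.empty(len(s), dtype=object)
    out[order] = np.asarray(labels, dtype=object)[group_sorted]
    return out
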