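"""Linear trend of an inequality index across survey rounds.

Ordinary least squares of the index on calendar year, plus the Pearson
correlation of the (year, index) pairs.  With three or four survey rounds
this is descriptive, not inferential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TrendResult", "fit_trend"]


@dataclass
class TrendResult:
    slope: float
    intercept: float
    pearson_r: float
    points: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "points": [list(p) for p in self.points],
        }


def fit_trend(points: Sequence[tuple[float, float]]) -> TrendResult:
    """OLS line of index on calendar year; Pearson r of the pairs."""
    pts = [(float(y), float(v)) for y, v in points]
    years = np.array([p[0] for p in pts])
    values = np.array([p[1] for p in pts])
    if len(np.unique(years)) < 2:
        raise ValueError("trend requires at least 2 distinct years")
    res = stats.linregress(years, values)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        points=pts,
    )
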