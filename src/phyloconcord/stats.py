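"""Simple linear regression with exactly specified edge-case semantics.

Used for the locus length-vs-informative-sites association and for the
congruence-vs-branch-duration fit. Ordinary least squares with the slope's
two-sided t test on n-2 degrees of freedom; a zero-variance response is
defined to have R-squared 0 (not NaN), and p-value underflow is clamped so
p stays in (0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["RegressionFit", "linear_fit", "congruence_duration_fit"]

_P_FLOOR = 5e-324  # smallest positive subnormal double


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS fit of y on x.

    Requires n >= 3 points and non-constant x. Adjusted R-squared follows
    1 - (1 - R^2)(n - 1)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    if sxx == 0.0:
        raise ValueError("x is constant; slope undefined")
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy == 0.0:
        r2 = 0.0
        ss_res = 0.0
    else:
        ss_res = max(syy - slope * sxy, 0.0)
        r2 = 1.0 - ss_res / syy
    dof = n - 2
    se2 = ss_res / dof / sxx
    if se2 > 0.0:
        t = slope / math.sqrt(se2)
        p = 2.0 * sps.t.sf(abs(t), dof)
    else:
        # perfect fit (or flat y): t degenerates; flat slope is maximally
        # non-significant, a perfect nonzero slope maximally significant
        p = 1.0 if slope == 0.0 else 0.0
    p = min(max(p, _P_FLOOR), 1.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(slope, intercept, r2, adj, p, n)


def congruence_duration_fit(
    joined: pd.DataFrame, response: str = "n_support"
) -> RegressionFit:
    """Regress gene-tree support on branch duration (Ma).

    ``joined`` is a congruence table with a ``duration_ma`` column (see
    ``concordance.congruence_report``). ``response`` is ``n_support`` — the
    raw count of supporting loci — or ``fraction``. Rows without a duration
    are dropped with a logged count; at least 3 usable rows are required.
    """
    if response not in ("n_support", "fraction"):
        raise ValueError(f"response must be 'n_support' or 'fraction', got {response!r}")
    if "duration_ma" not in joined.columns:
        raise ValueError("table has no duration_ma column; join durations first")
    usable = joined.dropna(subset=["duration_ma"])
    dropped = len(joined) - len(usable)
    if dropped:
        logger.info("dropping %d rows without branch durations", dropped)
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} rows have durations; need at least 3"
        )
    return linear_fit(usable["duration_ma"].to_numpy(), usable[response].to_numpy())
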