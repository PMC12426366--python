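"""Small closed-form regression helpers shared across evaluation modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SimpleOLS:
    slope: float
    intercept: float
    r_squared: float
    slope_ci_halfwidth: Optional[float]
    n: int


def simple_ols(x: Sequence[float], y: Sequence[float]) -> SimpleOLS:
    """Ordinary least squares y = a + b x with R^2 and a 95% t CI on the slope.

    A constant response yields slope 0 and R^2 defined as 0.  The CI is None
    when there are no residual degrees of freedom (n <= 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    ssx = float(np.sum((x - x.mean()) ** 2))
    if ssx == 0.0:
        raise ValueError("zero variance in predictor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / ssx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    ci = None
    if n > 2:
        se = np.sqrt(ss_res / (n - 2) / ssx)
        ci = float(stats.t.ppf(0.975, n - 2) * se)
    return SimpleOLS(slope, intercept, r2, ci, int(n))
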