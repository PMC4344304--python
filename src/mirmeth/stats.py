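"""Downstream statistics linking IP enrichment and knockdown response.

The scatter of log2 enrichment against log2 knockdown fold change is
summarized by the Pearson product-moment correlation with its least-squares
regression line, and the fold-change distribution is checked for normality
with the Shapiro-Wilk test (Royston's algorithm, as implemented in scipy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    slope: float
    intercept: float


@dataclass(frozen=True)
class NormalityResult:
    W: float
    pvalue: float


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Pearson r plus the ordinary least-squares line y = slope*x + intercept."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in xs or ys")
    res = sps.linregress(x, y)
    return CorrelationResult(
        r=float(res.rvalue), n=int(x.size),
        slope=float(res.slope), intercept=float(res.intercept),
    )


def shapiro_wilk(xs: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk normality test for 3 <= n <= 5000 observations."""
    x = np.asarray(xs, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero variance input")
    w, p = sps.shapiro(x)
    return NormalityResult(W=float(w), pvalue=float(p))
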