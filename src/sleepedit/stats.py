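"""Association statistics: Pearson correlation with Fisher-z confidence
intervals (as used to relate editing efficiency to phenotypes) and per-group
mean/sd/sem summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationResult:
    """Pearson r with two-sided p-value and 95% Fisher-z CI."""

    r: float
    p: float
    ci95: tuple[float, float]
    n: int

    def __str__(self) -> str:
        return (f"r = {self.r:.4f}, p = {self.p:.4g}, "
                f"95% CI [{self.ci95[0]:.4f}, {self.ci95[1]:.4f}], n = {self.n}")


def pearson_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with t-test p-value and Fisher-z CI.

    r follows the product-moment formula; the two-sided p-value uses
    ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom; the 95% CI is
    ``tanh(atanh(r) +- 1.96 / sqrt(n-3))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in x or y")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    if n == 3 or abs(r) == 1.0:
        ci = (-1.0, 1.0) if n == 3 else (r, r)
    else:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=r, p=p, ci95=ci, n=n)


def group_summary(values: Sequence[float],
                  labels: Sequence[str]) -> pd.DataFrame:
    """Mean, sample sd (n-1 denominator), and sem per group.

    Single-observation groups get NaN sd/sem (the sample sd is undefined).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    if len(values) == 0:
        raise ValueError("no observations")
    df = pd.DataFrame({"group": labels, "value": values})
    out = df.groupby("group")["value"].agg(
        n="size", mean="mean", sd=lambda v: v.std(ddof=1))
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
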