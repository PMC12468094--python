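"""Agreement statistics: Lin's concordance correlation and Bland-Altman limits.

Routine hypothesis tests (Wilcoxon, t, ANOVA/Tukey) are delegated to scipy /
statsmodels via the pipeline's cohort report and are not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementStats", "ccc", "bland_altman", "agreement"]


@dataclass(frozen=True)
class AgreementStats:
    pearson_r2: float
    ccc: float
    bias: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return {"pearson_r2": self.pearson_r2, "ccc": self.ccc, "bias": self.bias,
                "loa_low": self.loa_low, "loa_high": self.loa_high}


def _check_pair(x, y, min_len=3):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_len:
        raise ValueError(f"need at least {min_len} paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def ccc(x, y, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient:

        2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    Lin's original population (1/n) moments by default; pass ``ddof=1`` for
    sample moments (the ratio is ddof-invariant apart from the shift term).
    """
    x, y = _check_pair(x, y)
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both inputs are constant")
    n = len(x)
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def bland_altman(x, y, ddof: int = 1, z: float = 1.96):
    """Bias and 95% limits of agreement of d = x - y (sample SD by default).

    Convention: pass the clinical/reference values first and the model second,
    so a negative bias means the model overestimates.
    """
    x, y = _check_pair(x, y)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=ddof))
    return bias, bias - z * sd, bias + z * sd


def agreement(x, y) -> AgreementStats:
    """Full agreement panel between a reference vector and a model vector."""
    x, y = _check_pair(x, y)
    if x.var() == 0.0 or y.var() == 0.0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    bias, lo, hi = bland_altman(x, y)
    return AgreementStats(pearson_r2=r2, ccc=ccc(x, y), bias=bias, loa_low=lo, loa_high=hi)
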