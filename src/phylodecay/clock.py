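"""Constant versus accelerating somatic molecular clocks.

Tests whether SNA (or GD-peak) accumulation with age is linear or
accelerating by comparing two through-the-origin regressions,

    value = s * age            (constant clock)
    value = q * age^2 + s * age  (relaxed clock)

with a likelihood ratio test under Gaussian errors (MLE variance,
chi-square with 1 degree of freedom for the nested comparison).  Models
carry no intercept: a newborn has accumulated essentially no adult-phase
SNAs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = ["ClockFit", "fit_clock"]


@dataclasses.dataclass(frozen=True)
class ClockFit:
    """A fitted accumulation model and (for quadratic form) its LRT."""

    form: str                 # "linear" or "quadratic"
    slope: float              # SNAs / yr
    quad: float | None        # SNAs / yr^2 (None for the linear form)
    rss: float
    resid_var: float          # MLE variance rss / n
    n: int
    lrt_stat: float | None    # vs the nested linear model
    p_value: float | None


def _lstsq_origin(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_clock(ages, values, form: str = "quadratic") -> ClockFit:
    """Fit a no-intercept accumulation model of SNAs/GDs versus age.

    For ``form="quadratic"`` the nested linear model is fitted too and a
    likelihood ratio statistic n*log(RSS_lin / RSS_quad) is compared to
    chi-square(1).
    """
    a = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if a.shape != y.shape or a.ndim != 1:
        raise ValueError("ages and values must be matching 1-D arrays")
    if np.any(a <= 0):
        raise ValueError("ages must be strictly positive")
    n = a.size
    if form == "linear":
        if n < 2:
            raise ValueError("linear clock fit needs at least 2 points")
        coef, rss = _lstsq_origin(a[:, None], y)
        return ClockFit(form="linear", slope=float(coef[0]), quad=None,
                        rss=rss, resid_var=rss / n, n=n,
                        lrt_stat=None, p_value=None)
    if form != "quadratic":
        raise ValueError("form must be 'linear' or 'quadratic'")
    if n < 3:
        raise ValueError("quadratic clock fit needs at least 3 points")
    Xq = np.column_stack([a * a, a])
    coef_q, rss_q = _lstsq_origin(Xq, y)
    _, rss_l = _lstsq_origin(a[:, None], y)
    rss_q = min(rss_q, rss_l)  # nested models: guard rounding
    if rss_q == 0.0:
        lrt = 0.0 if rss_l == 0.0 else float("inf")
    else:
        lrt = n * float(np.log(rss_l / rss_q))
    p = float(stats.chi2.sf(lrt, df=1)) if np.isfinite(lrt) else 0.0
    return ClockFit(form="quadratic", slope=float(coef_q[1]),
                    quad=float(coef_q[0]), rss=rss_q, resid_var=rss_q / n,
                    n=n, lrt_stat=lrt, p_value=p)
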