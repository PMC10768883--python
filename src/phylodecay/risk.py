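"""Exponential incidence-by-age model and the residualAge -> risk map.

Blood-cancer (MPN) incidence grows exponentially with age,

    incidence per 100K  =  c * exp(r * age),

with published rates well described by c = 0.04 and r = 0.08 per year.
Because incidence is exponential, the fold increase in risk implied by
premature HSC aging depends only on the residualAge:

    fold = exp(r * (phyloAge - chronologicalAge)).

The default model ships the constants above; any user-supplied incidence
table (age, rate per 100K) refits them by nonlinear least squares on the
natural scale.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from ._nls import FitError, gauss_newton

__all__ = [
    "IncidenceModel",
    "RiskEstimate",
    "DEFAULT_INCIDENCE",
    "fit_incidence",
    "fold_risk",
]


@dataclasses.dataclass(frozen=True)
class IncidenceModel:
    """incidence(age) = baseline * exp(rate * age), per 100K individuals."""

    baseline: float          # incidence per 100K at age 0 (c > 0)
    rate: float              # per-year exponential coefficient (r > 0)
    r_squared: float | None  # goodness of fit; None for the shipped default

    def predict(self, age: float) -> float:
        return self.baseline * math.exp(self.rate * age)


DEFAULT_INCIDENCE = IncidenceModel(baseline=0.04, rate=0.08, r_squared=None)


def fit_incidence(ages, rates_per_100k) -> IncidenceModel:
    """Fit the exponential incidence model to an (age, rate) table.

    Nonlinear least squares on the natural scale (Gauss-Newton with a
    log-linear initialization); needs at least 3 pairs with strictly
    positive rates.
    """
    a = np.asarray(ages, dtype=float)
    y = np.asarray(rates_per_100k, dtype=float)
    if a.shape != y.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need at least 3 (age, rate) pairs")
    if np.any(y <= 0):
        raise ValueError("incidence rates must be strictly positive")
    slope, intercept = np.polyfit(a, np.log(y), 1)
    if slope <= 1e-12:
        warnings.warn("incidence shows no increase with age", stacklevel=2)
        raise FitError(
            "no age signal in incidence table (rate -> 0)",
            last_params=np.array([math.exp(intercept), slope]),
        )
    theta0 = np.array([intercept, math.log(slope)])  # (ln c, ln r)

    def residual(theta):
        c, r = np.exp(theta)
        return y - c * np.exp(r * a)

    def jacobian(theta):
        c, r = np.exp(theta)
        e = np.exp(r * a)
        return np.column_stack([-c * e, -c * a * e * r])

    res = gauss_newton(residual, jacobian, theta0)
    if not res.converged:
        raise FitError("incidence model fit did not converge",
                       last_params=np.exp(res.params))
    c, r = (float(v) for v in np.exp(res.params))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - res.rss / tss if tss > 0 else 1.0
    return IncidenceModel(baseline=c, rate=r, r_squared=float(r2))


@dataclasses.dataclass(frozen=True)
class RiskEstimate:
    """Fold-increased risk implied by a residualAge."""

    fold: float              # dimensionless, 1 when residualAge == 0
    residual_age: float      # years, signed
    rate: float              # exponential coefficient used
    younger_than_age: bool   # True when the HSC pool looks younger


def fold_risk(phylo_age: float, chronological_age: float,
              model: IncidenceModel | None = None) -> RiskEstimate:
    """Fold increase in risk: exp(rate * (phyloAge - chronologicalAge)).

    Values below 1 (HSC pool younger than chronological age) are allowed
    and flagged via ``younger_than_age``.
    """
    if phylo_age < 0 or chronological_age < 0:
        raise ValueError("ages must be non-negative")
    if model is None:
        model = DEFAULT_INCIDENCE
    residual = float(phylo_age) - float(chronological_age)
    fold = math.exp(model.rate * residual)
    return RiskEstimate(fold=fold, residual_age=residual, rate=model.rate,
                        younger_than_age=residual < 0)
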