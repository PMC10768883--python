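"""phyloAge: predicting HSC age from diversity-decay markers.

Each decay metric m in {alpha, beta} is modelled as an exponential
function of age,

    m(age) = a * exp(b * age),      a > 0, b > 0 per year,

fitted by a damped Gauss-Newton search that minimizes the sum of squared
differences between observed and predicted *age* (i.e. residuals are in
years, the scale on which predictions are made).  Inverting a fitted
model gives a per-marker age prediction,

    age(m) = ln(m / a) / b,

with a standard error from first-order (delta-method) propagation of the
parameter covariance plus the residual variance of the fit.  The two
per-marker predictions are combined by an inverse-variance random-effects
meta-analysis with maximum-likelihood between-marker variance tau^2 into
the phyloAge; phyloAge minus chronological age is the residualAge that
feeds the risk model.

Markers that are not positive carry no decay signal; such a marker is
dropped from the combination, and when both are dropped the individual
is reported as younger than the model's resolution rather than given an
arbitrary age.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._nls import FitError, gauss_newton

__all__ = [
    "MarkerModel",
    "CombinedEstimate",
    "PhyloAgeEstimate",
    "LOOResult",
    "fit_marker_model",
    "predict_age",
    "combine_estimates",
    "estimate_phyloage",
    "loo_validate",
    "FitError",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass(frozen=True)
class MarkerModel:
    """Exponential age model m(age) = a * exp(b * age) for one marker."""

    marker: str
    a: float                 # scale (marker units at age 0)
    b: float                 # rate per year
    cov: np.ndarray          # 2x2 covariance of (a, b)
    resid_var: float         # residual variance of the fit, in years^2
    n: int                   # individuals used in the fit
    min_value: float         # smallest positive marker value in the fit
    min_age: float           # youngest age in the fit (detection floor)

    def predict_marker(self, age: float) -> float:
        return self.a * math.exp(self.b * age)


def fit_marker_model(ages, values, marker: str = "alpha") -> MarkerModel:
    """Fit the exponential marker model by Gauss-Newton in age space.

    Individuals with non-positive marker values carry no decay signal
    and are dropped (with a warning); at least 3 positive values are
    required.  Initial parameters come from a log-linear regression of
    ln(value) on age; convergence requires the relative SSE change to
    fall below 1e-10 within 100 iterations.
    """
    y = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("ages and marker values must be matching 1-D arrays")
    mask = np.isfinite(v) & (v > 0) & np.isfinite(y)
    if mask.sum() < v.size:
        warnings.warn(
            f"{int(v.size - mask.sum())} individual(s) with non-positive "
            f"{marker} dropped from the model fit",
            stacklevel=2,
        )
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 individuals with positive {marker} values"
        )
    y, v = y[mask], v[mask]
    lv = np.log(v)
    slope, intercept = np.polyfit(y, lv, 1)
    if slope <= 0:
        raise FitError(
            f"{marker} does not increase with age; exponential model "
            "cannot be fitted",
            last_params=np.array([math.exp(intercept), slope]),
        )
    # theta = (ln a, ln b) keeps both parameters positive
    theta0 = np.array([intercept, math.log(slope)])

    def residual(theta):
        la, lb = theta
        return y - (lv - la) / math.exp(lb)

    def jacobian(theta):
        la, lb = theta
        b = math.exp(lb)
        d_la = np.full_like(y, 1.0 / b)
        d_lb = (lv - la) / b
        return np.column_stack([d_la, d_lb])

    res = gauss_newton(residual, jacobian, theta0)
    if not res.converged:
        raise FitError(
            f"Gauss-Newton fit of the {marker} model did not converge",
            last_params=np.exp(res.params),
        )
    a, b = float(math.exp(res.params[0])), float(math.exp(res.params[1]))
    D = np.diag([a, b])  # theta -> (a, b) delta method
    cov_ab = D @ res.cov @ D
    return MarkerModel(
        marker=marker, a=a, b=b, cov=cov_ab, resid_var=float(res.resid_var),
        n=int(y.size), min_value=float(v.min()), min_age=float(y.min()),
    )


def predict_age(model: MarkerModel, value: float) -> tuple[float, float]:
    """Invert a marker model: age and its delta-method standard error."""
    if not (value > 0):
        raise ValueError(
            f"{model.marker} value must be positive to predict an age; "
            "a non-positive value is below the model's resolution"
        )
    age = (math.log(value) - math.log(model.a)) / model.b
    g = np.array([-1.0 / (model.a * model.b), -age / model.b])
    var = float(g @ model.cov @ g) + model.resid_var
    return age, math.sqrt(max(var, 0.0))


@dataclasses.dataclass(frozen=True)
class CombinedEstimate:
    """Random-effects meta-analysis combination of point estimates."""

    value: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int


def combine_estimates(estimates, ses) -> CombinedEstimate:
    """Inverse-variance random-effects pooling with ML tau^2.

    The between-estimate variance tau^2 is chosen by maximizing the
    profile normal log-likelihood (the pooled mean is profiled out);
    weights are 1 / (se_i^2 + tau^2).  A single estimate passes through
    unchanged.
    """
    x = np.asarray(estimates, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    ok = np.isfinite(x) & np.isfinite(v)
    x, v = x[ok], v[ok]
    k = x.size
    if k == 0:
        raise ValueError("no estimate with a finite standard error")
    if k == 1:
        se = math.sqrt(v[0])
        return CombinedEstimate(float(x[0]), se, float(x[0] - _Z95 * se),
                                float(x[0] + _Z95 * se), 0.0, 1)

    def nll(tau2):
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * x) / np.sum(w))
        return 0.5 * float(np.sum(np.log(v + tau2) + w * (x - mu) ** 2))

    ub = 10.0 * float(np.var(x)) + float(v.max()) + 1e-6
    res = optimize.minimize_scalar(nll, bounds=(0.0, ub), method="bounded")
    tau2 = float(res.x) if res.fun < nll(0.0) else 0.0
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * x) / np.sum(w))
    se = math.sqrt(1.0 / float(np.sum(w)))
    return CombinedEstimate(mu, se, mu - _Z95 * se, mu + _Z95 * se, tau2, k)


@dataclasses.dataclass(frozen=True)
class PhyloAgeEstimate:
    """Combined phyloAge for one individual."""

    marker_ages: dict         # marker -> (age, se) for usable markers
    phylo_age: float | None   # None when below the model's resolution
    se: float | None
    ci_low: float | None
    ci_high: float | None
    tau2: float | None
    residual_age: float | None    # phyloAge - chronological age (signed)
    below_resolution: bool = False
    upper_bound: float | None = None  # youngest resolvable age if censored

    @property
    def abs_residual_age(self) -> float | None:
        if self.residual_age is None:
            return None
        return abs(self.residual_age)


def estimate_phyloage(
    alpha: float,
    beta: float,
    alpha_model: MarkerModel,
    beta_model: MarkerModel,
    chronological_age: float | None = None,
) -> PhyloAgeEstimate:
    """Predict phyloAge from alpha and beta via fitted marker models.

    Markers with non-positive values are dropped from the combination.
    If both are dropped, the individual shows no measurable decay and is
    reported as at most the youngest age resolvable by the models.
    """
    marker_ages: dict = {}
    for model, value in ((alpha_model, alpha), (beta_model, beta)):
        if value is not None and np.isfinite(value) and value > 0:
            marker_ages[model.marker] = predict_age(model, float(value))
    if not marker_ages:
        bound = min(alpha_model.min_age, beta_model.min_age)
        return PhyloAgeEstimate(
            marker_ages={}, phylo_age=None, se=None, ci_low=None,
            ci_high=None, tau2=None, residual_age=None,
            below_resolution=True, upper_bound=bound,
        )
    combined = combine_estimates(
        [a for a, _ in marker_ages.values()],
        [s for _, s in marker_ages.values()],
    )
    residual = None
    if chronological_age is not None:
        residual = combined.value - float(chronological_age)
    return PhyloAgeEstimate(
        marker_ages=marker_ages, phylo_age=combined.value, se=combined.se,
        ci_low=combined.ci_low, ci_high=combined.ci_high, tau2=combined.tau2,
        residual_age=residual,
    )


@dataclasses.dataclass(frozen=True)
class LOOResult:
    """Leave-one-out validation summary for a healthy cohort."""

    table: pd.DataFrame          # id, age, phylo_age, se, lo, hi, residual
    correlation: float           # Pearson r(predicted, chronological)
    mean_abs_residual: float     # mean |residualAge| in years
    n_completed: int


def loo_validate(cohort: pd.DataFrame, *, min_individuals: int = 4) -> LOOResult:
    """Leave-one-out validation of the phyloAge model.

    ``cohort`` needs columns id, age, alpha, beta with one row per
    individual.  For each individual both marker models and the
    combination are refitted without that individual and then applied to
    it.  Folds whose refits fail are recorded as missing and summarized
    over the completed folds with a warning.
    """
    required = {"id", "age", "alpha", "beta"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    df = cohort.reset_index(drop=True)
    if len(df) < min_individuals:
        raise ValueError(
            f"leave-one-out validation needs at least {min_individuals} "
            "individuals"
        )
    rows = []
    failures = 0
    for i in range(len(df)):
        rest = df.drop(index=i)
        held = df.loc[i]
        models = {}
        for marker in ("alpha", "beta"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    models[marker] = fit_marker_model(
                        rest["age"], rest[marker], marker
                    )
            except (ValueError, FitError):
                pass
        record = {
            "id": held["id"], "age": float(held["age"]),
            "phylo_age": np.nan, "se": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "residual_age": np.nan,
        }
        if models:
            preds = []
            for marker, model in models.items():
                value = float(held[marker])
                if value > 0:
                    preds.append(predict_age(model, value))
            if preds:
                comb = combine_estimates(
                    [a for a, _ in preds], [s for _, s in preds]
                )
                record.update(
                    phylo_age=comb.value, se=comb.se, ci_low=comb.ci_low,
                    ci_high=comb.ci_high,
                    residual_age=comb.value - float(held["age"]),
                )
            else:
                failures += 1
        else:
            failures += 1
        rows.append(record)
    table = pd.DataFrame(rows)
    done = table["phylo_age"].notna()
    if failures:
        warnings.warn(
            f"{failures} leave-one-out fold(s) could not be predicted; "
            "summary covers completed folds only",
            stacklevel=2,
        )
    n_done = int(done.sum())
    if n_done >= 2:
        corr = float(np.corrcoef(table.loc[done, "age"],
                                 table.loc[done, "phylo_age"])[0, 1])
    else:
        corr = float("nan")
    mean_abs = float(table.loc[done, "residual_age"].abs().mean())
    return LOOResult(table=table, correlation=corr,
                     mean_abs_residual=mean_abs, n_completed=n_done)
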