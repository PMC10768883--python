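"""Small Gauss-Newton nonlinear least-squares engine.

Shared by the marker-model and incidence-model fits.  Damped Gauss-Newton
with step halving; convergence when the relative change in the sum of
squared residuals falls below ``tol`` (default 1e-10) or after
``max_iter`` iterations (default 100).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["FitError", "NLSResult", "gauss_newton"]


class FitError(RuntimeError):
    """Nonlinear fit failure; carries the last iterate if available."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclasses.dataclass(frozen=True)
class NLSResult:
    params: np.ndarray
    cov: np.ndarray        # resid_var * (J^T J)^-1 at the solution
    rss: float
    resid_var: float       # rss / (n - p)
    n_iter: int
    converged: bool


def gauss_newton(residual, jacobian, x0, *, tol: float = 1e-10,
                 max_iter: int = 100) -> NLSResult:
    """Minimize ||residual(x)||^2 by damped Gauss-Newton.

    ``jacobian(x)`` must return d residual / d x (n x p).  The step is
    halved (up to 40 times) until the SSE does not increase.
    """
    x = np.asarray(x0, dtype=float).copy()
    r = np.asarray(residual(x), dtype=float)
    sse = float(r @ r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = np.asarray(jacobian(x), dtype=float)
        delta, *_ = np.linalg.lstsq(J, r, rcond=None)
        step = 1.0
        accepted = False
        for _ in range(40):
            x_new = x - step * delta
            r_new = np.asarray(residual(x_new), dtype=float)
            if np.all(np.isfinite(r_new)):
                sse_new = float(r_new @ r_new)
                if sse_new <= sse:
                    accepted = True
                    break
            step *= 0.5
        if not accepted:
            break
        if abs(sse - sse_new) <= tol * max(sse_new, 1e-300):
            x, r, sse = x_new, r_new, sse_new
            converged = True
            break
        x, r, sse = x_new, r_new, sse_new

    J = np.asarray(jacobian(x), dtype=float)
    n, p = J.shape
    dof = n - p
    resid_var = sse / dof if dof > 0 else float("nan")
    jtj = J.T @ J
    cov = resid_var * np.linalg.pinv(jtj)
    return NLSResult(params=x, cov=cov, rss=sse, resid_var=resid_var,
                     n_iter=it, converged=converged)
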