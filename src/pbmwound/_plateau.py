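"""Shared plateau-exponential least-squares machinery.

The model ``y(x) = (y0 - yp) * exp(-k*x) + yp`` describes a monotone approach
from an initial level ``y0`` to a plateau ``yp`` with rate constant ``k``; it is
used both for wound-closure trajectories over time and for the
eccentricity-versus-size regression. The fit is unweighted nonlinear least
squares; the parameter covariance is the Jacobian-based (Gauss-Newton)
estimate scaled by the residual variance at ``n - 3`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitConvergenceError, InsufficientDataError

K_LOWER_BOUND = 1e-8
K_UPPER_BOUND = 10.0


def plateau_model(x, y0: float, yp: float, k: float):
    """Evaluate ``(y0 - yp) * exp(-k*x) + yp`` elementwise."""
    x = np.asarray(x, dtype=float)
    return (y0 - yp) * np.exp(-k * x) + yp


def _plateau_jacobian(x, y0, yp, k):
    x = np.asarray(x, dtype=float)
    e = np.exp(-k * x)
    return np.column_stack([e, 1.0 - e, -(y0 - yp) * x * e])


@dataclass(frozen=True)
class PlateauFit:
    """A fitted plateau-exponential curve with its parameter covariance.

    Parameter order in ``covariance`` is (y0, yp, k). ``degenerate`` marks fits
    where the optimizer pinned ``k`` at its lower bound (flat data), in which
    case the curve was refit as a constant mean and the band reduces to the
    standard error of the mean.
    """

    y0: float
    yp: float
    k: float
    covariance: np.ndarray = field(repr=False)
    n: int = 0
    residual_ss: float = 0.0
    degenerate: bool = False

    # Aliases matching the wound-closure notation W0/Wp.
    @property
    def w0(self) -> float:
        return self.y0

    @property
    def wp(self) -> float:
        return self.yp

    @property
    def dof(self) -> int:
        return max(self.n - (1 if self.degenerate else 3), 1)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def predict(self, x):
        if self.degenerate:
            return np.full_like(np.asarray(x, dtype=float), self.yp)
        return plateau_model(x, self.y0, self.yp, self.k)

    def mean_band(self, x, level: float = 0.95):
        """Delta-method mean prediction band at confidence ``level``.

        Returns ``(fit, lower, upper)`` arrays over ``x``: the pointwise
        standard error is ``sqrt(g' C g)`` with ``g`` the parameter gradient of
        the model, scaled by the Student-t quantile at the fit's residual df.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        yhat = self.predict(x)
        tq = stats.t.ppf(0.5 + level / 2.0, self.dof)
        if self.degenerate:
            se = np.full(x.shape, np.sqrt(max(self.covariance[1, 1], 0.0)))
        else:
            grads = _plateau_jacobian(x, self.y0, self.yp, self.k)
            se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", grads, self.covariance, grads), 0, None))
        return yhat, yhat - tq * se, yhat + tq * se


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    y0 = float(np.mean(ys[xs == xs[0]]))
    yp = float(np.mean(ys[xs == xs[-1]]))
    if y0 >= yp:
        yp_init = float(np.min(ys))
    else:
        yp_init = float(np.max(ys))
    amp = y0 - yp_init
    span = float(xs[-1] - xs[0])
    k0 = 2.0 / span if span > 0 else 0.1
    # log-linear slope of the shifted residual decay, where defined
    if abs(amp) > 1e-12:
        shifted = (ys - (yp_init - 0.05 * amp)) / (1.05 * amp)
        ok = shifted > 1e-3
        if ok.sum() >= 2 and np.ptp(xs[ok]) > 0:
            slope = np.polyfit(xs[ok], np.log(shifted[ok]), 1)[0]
            if slope < 0:
                k0 = float(np.clip(-slope, K_LOWER_BOUND * 10, K_UPPER_BOUND / 2))
    return y0, yp_init, k0


def _constant_fit(x: np.ndarray, y: np.ndarray) -> PlateauFit:
    mean = float(np.mean(y))
    n = len(y)
    rss = float(np.sum((y - mean) ** 2))
    var_mean = rss / max(n - 1, 1) / n
    cov = np.zeros((3, 3))
    cov[0, 0] = cov[1, 1] = cov[0, 1] = cov[1, 0] = var_mean
    return PlateauFit(
        y0=mean, yp=mean, k=K_LOWER_BOUND, covariance=cov, n=n,
        residual_ss=rss, degenerate=True,
    )


def fit_plateau_exponential(
    x, y, *, min_points: int = 4, min_distinct: int = 3
) -> PlateauFit:
    """Least-squares fit of the plateau-exponential model to ``(x, y)``.

    Raises :class:`InsufficientDataError` below ``min_points`` observations or
    ``min_distinct`` distinct abscissae, and :class:`FitConvergenceError` with
    the optimizer's status message when the solver fails. A fit whose rate
    constant collapses onto its lower bound is refit as a constant mean and
    flagged ``degenerate`` (the three-parameter covariance is singular there).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} points, got {len(x)}"
        )
    if len(np.unique(x)) < min_distinct:
        raise InsufficientDataError(
            f"need at least {min_distinct} distinct x values, got {len(np.unique(x))}"
        )
    if np.ptp(y) == 0.0:
        return _constant_fit(x, y)

    p0 = _initial_guess(x, y)
    lower = [-np.inf, -np.inf, K_LOWER_BOUND]
    upper = [np.inf, np.inf, K_UPPER_BOUND]
    p0 = (p0[0], p0[1], float(np.clip(p0[2], K_LOWER_BOUND, K_UPPER_BOUND)))
    try:
        popt, pcov = optimize.curve_fit(
            plateau_model, x, y, p0=p0, bounds=(lower, upper),
            jac=_plateau_jacobian, maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitConvergenceError(str(exc)) from exc
    y0, yp, k = (float(v) for v in popt)
    if k <= K_LOWER_BOUND * 1.01:
        return _constant_fit(x, y)
    resid = y - plateau_model(x, y0, yp, k)
    rss = float(resid @ resid)
    if not np.all(np.isfinite(pcov)):
        pcov = np.zeros((3, 3))
    return PlateauFit(
        y0=y0, yp=yp, k=k, covariance=np.asarray(pcov), n=len(x), residual_ss=rss
    )
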