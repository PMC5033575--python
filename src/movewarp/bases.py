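"""B-spline bases and the two parametric covariance families.

The mean structure of the warping model is expanded in a cubic B-spline
basis on [0, 1].  Serially correlated amplitude deviations are modelled by a
stationary Matern process; the random warp anchors carry a Brownian-bridge
covariance, which pins warping functions at the movement onset and offset.

Conventions
-----------
* A :class:`SplineBasis` with ``n_knots = K`` places K equidistant knots on
  [0, 1] *including* both boundaries.  With cubic order and clamped boundary
  knots this yields ``K + 2`` basis functions.
* The Matern family is parametrized as
  ``tau2 * 2**(1-mu)/Gamma(mu) * (alpha*d)**mu * K_mu(alpha*d)``
  so that ``1/alpha`` is the e-folding range at ``mu = 1/2`` (plain
  ``alpha*d`` convention, no ``sqrt(2*mu)`` factor).
* Brownian-bridge covariance between anchors t <= t' is
  ``gamma2 * t * (1 - t')``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import gamma as gamma_fn
from scipy.special import kv

from .exceptions import DomainError

__all__ = [
    "SplineBasis",
    "MaternCovariance",
    "BrownianBridgeCovariance",
    "bspline_design",
    "matern_cov",
    "matern_matrix",
    "brownian_bridge_cov",
]


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis with ``n_knots`` equidistant knots on [0, 1]."""

    n_knots: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.n_knots < 2:
            raise DomainError("a spline basis needs at least 2 knots (the boundaries)")
        if self.degree != 3:
            raise DomainError("only cubic (degree 3) bases are supported")

    @property
    def n_basis(self) -> int:
        """Number of basis functions: interior knots + order = (K-2) + 4."""
        return self.n_knots + 2

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector with repeated boundary knots."""
        inner = np.linspace(0.0, 1.0, self.n_knots)
        return np.concatenate([np.zeros(3), inner, np.ones(3)])

    def spline(self, coef: np.ndarray) -> BSpline:
        """A :class:`scipy.interpolate.BSpline` with the given weights."""
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.n_basis,):
            raise DomainError(
                f"expected {self.n_basis} spline weights, got {coef.shape}"
            )
        return BSpline(self.knots, coef, self.degree, extrapolate=False)


def bspline_design(basis: SplineBasis, eval_times: np.ndarray) -> np.ndarray:
    """Design matrix of the basis at ``eval_times``.

    Each row holds the values of all basis functions at one time point; at
    most 4 entries per row are nonzero and rows sum to one (partition of
    unity of the clamped cubic B-spline basis).

    Raises
    ------
    DomainError
        If any evaluation time falls outside [0, 1]; the basis is never
        extrapolated.
    """
    t = np.asarray(eval_times, dtype=float)
    if t.ndim != 1:
        raise DomainError("eval_times must be a 1-d array")
    if t.size and (t.min() < 0.0 or t.max() > 1.0):
        raise DomainError("evaluation times must lie within [0, 1]")
    mat = BSpline.design_matrix(t, basis.knots, basis.degree)
    return np.asarray(mat.todense())


@dataclass(frozen=True)
class MaternCovariance:
    """Stationary Matern covariance: smoothness ``mu``, relative scale
    ``tau2`` (variance at lag 0), inverse range ``alpha``."""

    mu: float
    tau2: float
    alpha: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise DomainError("Matern smoothness mu must be positive")
        if self.tau2 < 0:
            raise DomainError("Matern scale tau2 must be nonnegative")
        if self.alpha <= 0:
            raise DomainError("Matern inverse range alpha must be positive")


def matern_cov(d, params: MaternCovariance):
    """Matern covariance at lag(s) ``d >= 0``.

    ``tau2 * 2**(1-mu)/Gamma(mu) * (alpha*d)**mu * K_mu(alpha*d)``, which is
    ``tau2`` at lag zero and reduces to ``tau2 * exp(-alpha*d)`` at
    ``mu = 1/2``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("lags must be nonnegative")
    x = params.alpha * d
    with np.errstate(invalid="ignore", over="ignore"):
        val = (
            params.tau2
            * 2.0 ** (1.0 - params.mu)
            / gamma_fn(params.mu)
            * x**params.mu
            * kv(params.mu, x)
        )
    # kv(mu, 0) is inf and 0**mu is 0; the limit of the product is 1.
    val = np.where(x == 0.0, params.tau2, val)
    # Far in the tail kv underflows to 0 * inf -> nan; the true value is 0.
    val = np.nan_to_num(val, nan=0.0, posinf=0.0)
    return val if val.ndim else float(val)


def matern_matrix(times: np.ndarray, params: MaternCovariance) -> np.ndarray:
    """Covariance matrix of the amplitude process at the given time points."""
    t = np.asarray(times, dtype=float)
    lags = np.abs(t[:, None] - t[None, :])
    return matern_cov(lags, params)


@dataclass(frozen=True)
class BrownianBridgeCovariance:
    """Brownian-bridge covariance for warp anchors: relative scale ``gamma2``
    at ``n_w`` equidistant anchor points in (0, 1)."""

    gamma2: float
    n_w: int

    def __post_init__(self) -> None:
        if self.gamma2 < 0:
            raise DomainError("bridge scale gamma2 must be nonnegative")
        if self.n_w < 0:
            raise DomainError("number of anchors must be nonnegative")

    @property
    def anchors(self) -> np.ndarray:
        return np.arange(1, self.n_w + 1) / (self.n_w + 1.0)

    def matrix(self) -> np.ndarray:
        return brownian_bridge_cov(self.anchors, self.gamma2)


def brownian_bridge_cov(anchors: np.ndarray, gamma2: float) -> np.ndarray:
    """Covariance matrix ``gamma2 * min(t, t') * (1 - max(t, t'))`` of a
    zero-drift Brownian bridge observed at the anchor points.

    Anchors at 0 or 1 are rejected: the bridge is pinned there and the
    resulting matrix would be singular.
    """
    t = np.asarray(anchors, dtype=float)
    if t.size and (t.min() <= 0.0 or t.max() >= 1.0):
        raise DomainError("anchor points must lie strictly inside (0, 1)")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DomainError("anchor points must be strictly increasing")
    if gamma2 < 0:
        raise DomainError("gamma2 must be nonnegative")
    return gamma2 * np.minimum(t[:, None], t[None, :]) * (1.0 - np.maximum(t[:, None], t[None, :]))
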