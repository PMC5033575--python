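"""Likelihood components of the hierarchical warping model.

The generative model for curve j of participant i observed at times t_k is

    y_ij(t) = (theta + phi_i) o (nu_i + v_ij)(t) + x_ij(t) + eps_ij(t)

with theta = Phi c and phi_i = Phi d_i in a common cubic B-spline basis,
piecewise-linear warps (see :mod:`movewarp.warping`), a stationary Matern
amplitude process x_ij with covariance sigma2 * S, warp anchors
w_ij ~ N(0, sigma2 * C) with Brownian-bridge C, and white noise of variance
sigma2.  All random effects are scaled by the noise standard deviation,
which is what makes the profile likelihood below so compact.

Estimation operates on three levels:

* fixed-warp level -- generalized-least-squares updates of c and d_i given
  the warps (:func:`update_theta`, :func:`update_phi`);
* nonlinear level -- the joint negative log posterior of (nu_i, {w_ij})
  used to estimate/predict warps (:func:`warp_posterior`);
* linearized level -- a first-order expansion in w around the current
  prediction w0 (:func:`linearize`), whose exact linear-mixed-model
  likelihood (:func:`linearized_nll`) is the Laplace-approximate marginal
  likelihood used to estimate the variance parameters.

The amplitude covariance S is indexed by *recorded* observation times (the
process is attached to the observation grid, stationarity in observed
time), while the mean is evaluated at warped times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .bases import (
    BrownianBridgeCovariance,
    MaternCovariance,
    SplineBasis,
    bspline_design,
    matern_matrix,
)
from .exceptions import DomainError, NumericError, RankError
from .warping import eval_warp, is_valid_homeomorphism, warp_design_row

__all__ = [
    "ModelParameters",
    "amplitude_cholesky",
    "update_theta",
    "update_phi",
    "center_deviations",
    "warp_posterior",
    "linearize",
    "linearized_nll",
    "eta_from_lambda",
]


@dataclass
class ModelParameters:
    """All parameters of the warping model.

    ``d`` holds one deviation-weight vector per participant (rows); the
    deviations are kept centered (summing to zero across participants).
    ``eta`` is the normalized ridge weight lambda / (1 + tau2).
    """

    c: np.ndarray
    d: np.ndarray  # (n_participants, n_basis)
    participant_ids: list = field(default_factory=list)
    sigma2: float = 1.0
    matern: MaternCovariance = None
    bridge: BrownianBridgeCovariance = None
    lam: float = 0.0

    @property
    def eta(self) -> float:
        return eta_from_lambda(self.lam, self.matern.tau2)

    def to_dict(self) -> dict:
        return {
            "c": np.asarray(self.c).tolist(),
            "d": np.asarray(self.d).tolist(),
            "participant_ids": list(self.participant_ids),
            "sigma2": self.sigma2,
            "matern": {"mu": self.matern.mu, "tau2": self.matern.tau2, "alpha": self.matern.alpha},
            "bridge": {"gamma2": self.bridge.gamma2, "n_w": self.bridge.n_w},
            "lam": self.lam,
        }

    @classmethod
    def from_dict(cls, dd: dict) -> "ModelParameters":
        return cls(
            c=np.asarray(dd["c"], dtype=float),
            d=np.asarray(dd["d"], dtype=float),
            participant_ids=list(dd["participant_ids"]),
            sigma2=float(dd["sigma2"]),
            matern=MaternCovariance(**dd["matern"]),
            bridge=BrownianBridgeCovariance(**dd["bridge"]),
            lam=float(dd["lam"]),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def eta_from_lambda(lam: float, tau2: float) -> float:
    """Ridge weight normalized by the amplitude variance: lambda/(1 + tau2)."""
    if lam < 0 or tau2 < 0:
        raise DomainError("lambda and tau2 must be nonnegative")
    return lam / (1.0 + tau2)


def amplitude_cholesky(times_list: Sequence[np.ndarray], matern: MaternCovariance):
    """Cholesky factors of (I + S_ij) for each curve's recorded times.

    Identical time grids share a single factorization.
    """
    cache: dict[bytes, tuple] = {}
    out = []
    for t in times_list:
        key = np.asarray(t).tobytes()
        if key not in cache:
            A = matern_matrix(t, matern) + np.eye(len(t))
            cache[key] = cho_factor(A, lower=True)
        out.append(cache[key])
    return out


def update_theta(
    values: Sequence[np.ndarray],
    warped_times: Sequence[np.ndarray],
    times: Sequence[np.ndarray],
    basis: SplineBasis,
    matern: MaternCovariance,
    chols=None,
) -> np.ndarray:
    """GLS estimate of the common template weights c given fixed warps.

    Solves (Phi' (I+S)^-1 Phi) c = Phi' (I+S)^-1 y exploiting the
    block-diagonal structure of S across curves.  ``warped_times`` are the
    composite warps evaluated at each curve's observed times.
    """
    if chols is None:
        chols = amplitude_cholesky(times, matern)
    K = basis.n_basis
    A = np.zeros((K, K))
    b = np.zeros(K)
    for y, wt, ch in zip(values, warped_times, chols):
        Phi = bspline_design(basis, np.clip(wt, 0.0, 1.0))
        PhiS = cho_solve(ch, Phi)
        A += Phi.T @ PhiS
        b += PhiS.T @ y
    try:
        chA = cho_factor(A)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise RankError(f"normal matrix singular for K={basis.n_knots} knots") from e
    except Exception as e:
        raise RankError(f"normal matrix singular for K={basis.n_knots} knots") from e
    return cho_solve(chA, b)


def update_phi(
    values_i: Sequence[np.ndarray],
    warped_times_i: Sequence[np.ndarray],
    times_i: Sequence[np.ndarray],
    basis: SplineBasis,
    matern: MaternCovariance,
    c: np.ndarray,
    eta: float,
    chols=None,
) -> np.ndarray:
    """Ridge-penalized GLS estimate of participant i's deviation weights d_i.

    d_i = (Phi_i'(I+S_i)^-1 Phi_i + eta I)^-1 Phi_i'(I+S_i)^-1 (y_i - Phi_i c).
    """
    if chols is None:
        chols = amplitude_cholesky(times_i, matern)
    K = basis.n_basis
    A = eta * np.eye(K)
    b = np.zeros(K)
    for y, wt, ch in zip(values_i, warped_times_i, chols):
        Phi = bspline_design(basis, np.clip(wt, 0.0, 1.0))
        PhiS = cho_solve(ch, Phi)
        A += Phi.T @ PhiS
        b += PhiS.T @ (y - Phi @ c)
    try:
        chA = cho_factor(A)
    except Exception as e:
        raise RankError(f"normal matrix singular for K={basis.n_knots} knots") from e
    return cho_solve(chA, b)


def center_deviations(c: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Re-center participant deviations to sum to zero.

    The per-participant ridge estimators do not themselves enforce
    sum_i d_i = 0; the mean deviation is moved into the template so fitted
    values are unchanged.
    """
    mean_d = d.mean(axis=0)
    return c + mean_d, d - mean_d[None, :]


def warp_posterior(
    values_i: Sequence[np.ndarray],
    times_i: Sequence[np.ndarray],
    nu_anchors: np.ndarray,
    w_list: Sequence[np.ndarray],
    coef_i: np.ndarray,
    basis: SplineBasis,
    matern: MaternCovariance,
    bridge: BrownianBridgeCovariance,
    chols=None,
    bridge_chol=None,
) -> float:
    """Joint negative log posterior of (nu_i, {w_ij}) for one participant.

    sum_j ||y_ij - template(warp_ij(t))||^2_{I+S_ij} + sum_j ||w_ij||^2_C
    where template = Phi (c + d_i) evaluated at the (clamped) warped times
    and ||.||_A denotes the A^-1-weighted squared norm.  Invalid warps
    (non-homeomorphic anchor sequences) return +inf -- a barrier value,
    deliberately distinct from raising a numeric error.
    """
    for w in w_list:
        if not is_valid_homeomorphism(nu_anchors, w):
            return np.inf
    if chols is None:
        chols = amplitude_cholesky(times_i, matern)
    if bridge_chol is None and bridge.n_w > 0 and bridge.gamma2 > 0:
        bridge_chol = cho_factor(bridge.matrix(), lower=True)
    spline = basis.spline(coef_i)
    total = 0.0
    for y, t, w, ch in zip(values_i, times_i, w_list, chols):
        wt = np.clip(eval_warp(nu_anchors, w, t), 0.0, 1.0)
        r = y - spline(wt)
        total += float(r @ cho_solve(ch, r))
        if bridge.n_w > 0:
            w = np.asarray(w, dtype=float)
            if bridge.gamma2 > 0:
                total += float(w @ cho_solve(bridge_chol, w))
            elif np.any(w != 0):
                return np.inf
    return total


def linearize(
    coef_i: np.ndarray,
    basis: SplineBasis,
    nu_anchors: np.ndarray,
    w0: np.ndarray,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order expansion of one curve's prediction in the warp anchors.

    Returns (vartheta, Z): the prediction at w0 and the Jacobian
    Z = diag(template'(warp(t))) @ (hat-function rows), the product of the
    template's analytic spline derivative at the warped times and the
    gradient of the warp w.r.t. w.  Warped times are clamped to [0, 1]
    (valid homeomorphisms cannot leave it; clamping guards rounding), and
    the derivative is taken as zero where clamping is active.
    """
    spline = basis.spline(coef_i)
    dspline = spline.derivative()
    wt_raw = eval_warp(nu_anchors, w0, times)
    wt = np.clip(wt_raw, 0.0, 1.0)
    vartheta = spline(wt)
    slope = dspline(wt)
    slope = np.where((wt_raw < 0.0) | (wt_raw > 1.0), 0.0, slope)
    H = warp_design_row(nu_anchors, w0, times)
    Z = slope[:, None] * H
    return vartheta, Z


def linearized_nll(
    values: Sequence[np.ndarray],
    vartheta: Sequence[np.ndarray],
    Z: Sequence[np.ndarray],
    w0: Sequence[np.ndarray],
    sigma2: float,
    times: Sequence[np.ndarray],
    matern: MaternCovariance,
    bridge: BrownianBridgeCovariance,
) -> float:
    """Twice the negative profile log likelihood of the linearized model.

    m log sigma2 + log det V + sigma2^-1 ||y - vartheta + Z w0||^2_V with
    V = S + Z C Z' + I, evaluated per curve via triangular factorizations
    (the full m x m matrix is never formed).  The additive constant
    m log 2 pi is omitted.
    """
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    C = bridge.matrix()
    m = 0
    logdet = 0.0
    quad = 0.0
    for idx, (y, vt, Zb, w0b, t) in enumerate(zip(values, vartheta, Z, w0, times)):
        m += len(y)
        V = matern_matrix(t, matern) + np.eye(len(t))
        if Zb.shape[1] > 0:
            V = V + Zb @ C @ Zb.T
        try:
            ch = cho_factor(V, lower=True)
        except Exception as e:
            raise NumericError(f"V block {idx} is not positive definite") from e
        r = y - vt + (Zb @ np.asarray(w0b) if Zb.shape[1] > 0 else 0.0)
        logdet += 2.0 * float(np.sum(np.log(np.diag(ch[0]))))
        quad += float(r @ cho_solve(ch, r))
    return m * np.log(sigma2) + logdet + quad / sigma2
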