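"""Piecewise-linear time warps.

A warp is an increasing homeomorphism of [0, 1] onto itself, parametrized by
its values at ``n_w`` equidistant anchor points in (0, 1).  Each participant
carries a fixed warp ``nu`` (anchor values are free parameters, endpoints
pinned at (0,0) and (1,1)); each repetition adds a random deviation whose
anchor values ``w`` interpolate linearly between (0, 0), the anchors, and
(1, 0).  The composite warp evaluated at time t is

    warp(t) = interp(t; (0,0), (a_k, nu_k), (1,1)) + interp(t; (0,0), (a_k, w_k), (1,0))

so warp(0) = 0 and warp(1) = 1 exactly for any parameter values.  Validity
(strict monotonicity) is checked on the anchor sequence only, which for
piecewise-linear interpolation is equivalent to monotonicity everywhere.

``n_w = 0`` means no warping: the warp is the identity and all gradient
rows are empty.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError

__all__ = [
    "anchor_points",
    "eval_warp",
    "warp_design_row",
    "is_valid_homeomorphism",
    "invert_warp",
]


def anchor_points(n_w: int) -> np.ndarray:
    """The ``n_w`` equidistant anchor points ``k/(n_w+1)`` in (0, 1)."""
    if n_w < 0:
        raise DomainError("n_w must be nonnegative")
    return np.arange(1, n_w + 1) / (n_w + 1.0)


def _check_t(t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size and (t.min() < 0.0 or t.max() > 1.0):
        raise DomainError("warp evaluation times must lie in [0, 1]")
    return t


def _as_anchors(nu_anchors, w):
    nu = np.atleast_1d(np.asarray(nu_anchors, dtype=float))
    wv = np.atleast_1d(np.asarray(w, dtype=float))
    if nu.shape != wv.shape:
        raise DomainError("nu_anchors and w must have the same length")
    return nu, wv


def eval_warp(nu_anchors, w, t) -> np.ndarray:
    """Evaluate the composite warp (nu + deviation) at times ``t``.

    Parameters
    ----------
    nu_anchors : (n_w,) array
        Values of the fixed participant warp at the equidistant anchors.
        The identity warp has ``nu_anchors == anchor_points(n_w)``.
    w : (n_w,) array
        Random anchor deviations of this repetition.
    t : array in [0, 1]
    """
    t = _check_t(t)
    nu, wv = _as_anchors(nu_anchors, w)
    n_w = nu.size
    if n_w == 0:
        return t.copy()
    a = anchor_points(n_w)
    xp = np.concatenate([[0.0], a, [1.0]])
    nu_part = np.interp(t, xp, np.concatenate([[0.0], nu, [1.0]]))
    dev_part = np.interp(t, xp, np.concatenate([[0.0], wv, [0.0]]))
    return nu_part + dev_part


def warp_design_row(nu_anchors, w, t) -> np.ndarray:
    """Gradient of the warp with respect to ``w`` at times ``t``.

    Returns the hat-function weights of linear interpolation: an array of
    shape ``(len(t), n_w)`` with nonnegative rows summing to at most 1.
    The gradient does not depend on the current (nu, w) values, only on the
    anchor layout; the arguments are accepted for interface symmetry and
    validated.
    """
    t = _check_t(t)
    nu, wv = _as_anchors(nu_anchors, w)
    n_w = nu.size
    if n_w == 0:
        return np.zeros((t.size, 0))
    a = anchor_points(n_w)
    xp = np.concatenate([[0.0], a, [1.0]])
    rows = np.empty((t.size, n_w))
    for k in range(n_w):
        fp = np.zeros(n_w + 2)
        fp[k + 1] = 1.0
        rows[:, k] = np.interp(t, xp, fp)
    return rows


def is_valid_homeomorphism(nu_anchors, w) -> bool:
    """True iff the sequence 0, (nu + w at the anchors), 1 is strictly
    increasing, i.e. the composite warp maps [0, 1] bijectively onto itself."""
    nu, wv = _as_anchors(nu_anchors, w)
    seq = np.concatenate([[0.0], nu + wv, [1.0]])
    return bool(np.all(np.diff(seq) > 0.0))


def invert_warp(nu_anchors, w, s) -> np.ndarray:
    """Numerical inverse of a valid warp, exact for piecewise-linear maps.

    ``s`` are points in [0, 1] on the warped scale; returns the original
    times t with warp(t) = s.
    """
    if not is_valid_homeomorphism(nu_anchors, w):
        raise DomainError("cannot invert an invalid warp")
    nu, wv = _as_anchors(nu_anchors, w)
    s = _check_t(s)
    a = anchor_points(nu.size)
    xp = np.concatenate([[0.0], a, [1.0]])
    fp = np.concatenate([[0.0], nu + wv, [1.0]])
    return np.interp(s, fp, xp)
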