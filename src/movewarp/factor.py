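"""Mixed-effects factor analysis of aligned 3-D movement paths.

Each aligned trajectory (30 time points x 3 coordinates) is modelled as a
deviation from a reference mean path theta (the lowest obstacle height)
lying in a low-dimensional subspace spanned by q orthonormal loadings W:

    y_ijh = theta + (X_h beta + sum_l Z_{i, g_l(j,h), l}) W' + eps_ij

where X_h encodes obstacle height (ANOVA: S=(0,0), M=(1,0), T=(0,1);
regression: the height increase in cm, 0 / 7.5 / 15), beta are fixed
covariate weights, and the three independent Gaussian latent levels are
(1) participant, shared by all of a participant's curves, (2) the
participant's reaction to height change, shared within participant x
height, and (3) repetition, one per curve.  Each level carries a q x q
covariance; the noise has one variance per spatial coordinate.

Trajectories are vectorized time-major (coordinate fastest) into
90-vectors.  Fitting is maximum likelihood via an ECM algorithm whose
fixed-point iteration is accelerated with SQUAREM extrapolation under a
monotonicity safeguard: an extrapolated step that would decrease the
log likelihood is rejected in favor of the plain ECM step.

The loadings are identified like in PCA: W is orthonormal, and the
rotation is fixed by requiring the total latent covariance of a single
curve, sum_l Sigma_l, to be diagonal with decreasing diagonal; column
signs make each loading's largest-magnitude entry positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .data import TrajectorySample
from .exceptions import ConvergenceError, DomainError, RankError, StateError

__all__ = [
    "FactorModel",
    "height_design_row",
    "fit_factor_model",
    "identify_loadings",
    "variance_explained",
    "lrt_height_design",
    "level_ellipsoids",
    "Ellipsoid",
]

_LEVELS = ("participant", "height_reaction", "repetition")
_LAMBDA_FLOOR = 1e-12
_COV_JITTER = 1e-10


def height_design_row(level: int, design: str) -> np.ndarray:
    """Covariate encoding of an obstacle-height level (1, 2, 3).

    ``"anova"``: two free contrasts against the reference height,
    S=(0,0), M=(1,0), T=(0,1).  ``"regression"``: a single slope in the
    height increase in cm (0, 7.5, 15).
    """
    if design == "anova":
        return {1: np.array([0.0, 0.0]), 2: np.array([1.0, 0.0]), 3: np.array([0.0, 1.0])}[level]
    if design == "regression":
        return {1: np.array([0.0]), 2: np.array([7.5]), 3: np.array([15.0])}[level]
    raise DomainError(f"unknown design {design!r}")


@dataclass
class FactorModel:
    """Fitted mixed-effects factor model.

    ``theta`` is the 30x3 reference mean path; ``W`` the (90 x q)
    orthonormal loadings; ``beta`` the (p x q) covariate weights;
    ``level_covs`` the (participant, height-reaction, repetition)
    covariances; ``noise_variances`` one noise variance per spatial
    coordinate; ``loglik`` the maximized log likelihood.
    """

    theta: np.ndarray
    W: np.ndarray
    beta: np.ndarray
    design: str
    level_covs: tuple
    noise_variances: np.ndarray
    reference: int = 1
    loglik: float = np.nan

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def total_latent_cov(self) -> np.ndarray:
        """sum_l Sigma_l: total latent covariance of a single curve."""
        return sum(self.level_covs)


# ---------------------------------------------------------------------------
# Internal parameter vectorization (for SQUAREM extrapolation)


def _chol_pack(S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S + _COV_JITTER * np.eye(S.shape[0]))
    return L[np.tril_indices(S.shape[0])]


def _chol_unpack(v: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = v
    return L @ L.T


def _pack(W, B, covs, lam) -> np.ndarray:
    return np.concatenate(
        [W.ravel(), B.ravel()]
        + [_chol_pack(S) for S in covs]
        + [np.log(np.maximum(lam, _LAMBDA_FLOOR))]
    )


def _unpack(x, q, p):
    n = 90 * q
    W = x[:n].reshape(90, q)
    B = x[n : n + q * p].reshape(q, p)
    pos = n + q * p
    ntri = q * (q + 1) // 2
    covs = []
    for _ in range(3):
        covs.append(_chol_unpack(x[pos : pos + ntri], q))
        pos += ntri
    lam = np.exp(x[pos : pos + 3])
    # re-orthonormalize W (extrapolation breaks orthonormality) and
    # co-transform so the represented model is unchanged
    W, B, covs = _orthonormalize(W, B, covs)
    return W, B, covs, lam


def _orthonormalize(W, B, covs):
    Q, R = np.linalg.qr(W)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    Q, R = Q * sign[None, :], R * sign[:, None]
    B = R @ B
    covs = [R @ S @ R.T for S in covs]
    return Q, B, covs


def _project_psd(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < -1e-10:
        warnings.warn("projecting an indefinite level covariance to the PSD cone")
    vals = np.maximum(vals, 0.0)
    return (vecs * vals[None, :]) @ vecs.T


# ---------------------------------------------------------------------------
# ECM machinery


class _Problem:
    """Preprocessed data and group structure for the ECM iteration."""

    def __init__(self, trajectories: Sequence[TrajectorySample], q, design, reference):
        ref = [tr.path for tr in trajectories if tr.height_level == reference]
        if not ref:
            raise StateError(f"no trajectories at reference height level {reference}")
        self.theta = np.mean(ref, axis=0)
        self.design = design
        self.reference = reference
        self.q = q
        pids = sorted({tr.participant_id for tr in trajectories})
        per_pid = {}
        n_curves = 0
        for pid in pids:
            curves = sorted(
                (tr for tr in trajectories if tr.participant_id == pid),
                key=lambda tr: (tr.height_level, tr.repetition_id),
            )
            U = np.stack([(tr.path - self.theta).ravel() for tr in curves])  # (n_c, 90)
            heights = tuple(tr.height_level for tr in curves)
            per_pid[pid] = (U, heights)
            n_curves += len(curves)
        self.n_curves = n_curves
        # group participants with the same height pattern: they share the
        # design, hence the posterior precision, and the E step is batched
        self.groups = []
        by_pattern: dict = {}
        for pid in pids:
            U, heights = per_pid[pid]
            by_pattern.setdefault(heights, []).append(U)
        for heights, Us in by_pattern.items():
            X = np.stack([height_design_row(h, design) for h in heights])
            uniq = sorted(set(heights))
            n_c = len(heights)
            n_u = 1 + len(uniq) + n_c
            D = np.zeros((n_c, n_u))
            D[:, 0] = 1.0
            for c, h in enumerate(heights):
                D[c, 1 + uniq.index(h)] = 1.0
                D[c, 1 + len(uniq) + c] = 1.0
            level_of_unit = np.array([0] + [1] * len(uniq) + [2] * n_c)
            self.groups.append(
                {
                    "U": np.stack(Us),  # (P_g, n_c, 90)
                    "X": X,
                    "D": D,
                    "DtD": D.T @ D,
                    "levels": level_of_unit,
                }
            )
        self.p = self.groups[0]["X"].shape[1]
        allU = np.vstack([pp["U"].reshape(-1, 90) for pp in self.groups])
        sv = np.linalg.svd(allU - allU.mean(axis=0), compute_uv=False)
        rank = int(np.sum(sv > max(sv[0], 1e-300) * 1e-10)) if sv.size else 0
        if q > 90 or q > max(rank, 1):
            raise RankError(f"q={q} exceeds the rank of the centered data ({rank})")
        self.allU = allU

    def init_params(self):
        q = self.q
        Uc = self.allU - self.allU.mean(axis=0)
        _, _, Vt = np.linalg.svd(Uc, full_matrices=False)
        W = Vt[:q].T
        B = np.zeros((q, self.p))
        scores = Uc @ W
        Sv = np.cov(scores.T, ddof=0).reshape(q, q)
        covs = [Sv / 3.0 + 1e-6 * np.trace(Sv) / q * np.eye(q) for _ in range(3)]
        resid = Uc - scores @ W.T
        lam = np.maximum(resid.reshape(-1, 30, 3).var(axis=(0, 1)), 1e-6)
        return W, B, covs, lam

    def em_step(self, W, B, covs, lam):
        """One ECM iteration.  Returns (new params, loglik at input params)."""
        q, p = self.q, self.p
        lam_full = np.tile(lam, 30)  # time-major, coordinate fastest
        Wl = W / lam_full[:, None]
        G = W.T @ Wl
        cov_invs, cov_logdets = [], []
        for S in covs:
            chS = cho_factor(S + _COV_JITTER * np.eye(q), lower=True)
            cov_invs.append(cho_solve(chS, np.eye(q)))
            cov_logdets.append(2.0 * float(np.sum(np.log(np.diag(chS[0])))))
        log_lam_full = float(np.sum(np.log(lam_full)))

        ll = 0.0
        sum_xx = np.zeros((p, p))
        sum_ux = np.zeros((q, p))  # accumulates W' Lam^-1 u x'
        sum_tx = np.zeros((q, p))
        S_stats = [np.zeros((q, q)) for _ in range(3)]
        N_units = [0, 0, 0]
        posterior = []  # per group: (U, X, T, Vc)

        # E step, batched over participants sharing a design pattern: the
        # posterior moments of the latent levels, and the observed log
        # likelihood at the input parameters via the determinant lemma (the
        # per-participant marginal covariance is never formed).
        for pp in self.groups:
            U, X, D, DtD, levels = pp["U"], pp["X"], pp["D"], pp["DtD"], pp["levels"]
            P_g, n_c, _ = U.shape
            n_u = D.shape[1]
            mean = (X @ B.T) @ W.T  # (n_c, 90), shared within the group
            R = U - mean[None, :, :]
            proj = np.einsum("pci,iq->pcq", R, Wl)
            b = np.einsum("cu,pcq->puq", D, proj).reshape(P_g, n_u * q)

            P = np.kron(DtD, G)
            for u in range(n_u):
                P[u * q : (u + 1) * q, u * q : (u + 1) * q] += cov_invs[levels[u]]
            chP = cho_factor(P, lower=True)
            Pinv = cho_solve(chP, np.eye(n_u * q))
            logdetP = 2.0 * float(np.sum(np.log(np.diag(chP[0]))))

            Z = cho_solve(chP, b.T).T.reshape(P_g, n_u, q)
            T = np.einsum("cu,puq->pcq", D, Z)  # combined latent means
            Cov4 = Pinv.reshape(n_u, q, n_u, q)

            quad = float(np.einsum("pci,pci->", R / lam_full[None, None, :], R)) - float(
                np.einsum("pk,pk->", b, Z.reshape(P_g, n_u * q))
            )
            logdet = (
                n_c * log_lam_full
                + sum(cov_logdets[levels[u]] for u in range(n_u))
                + logdetP
            )
            ll += -0.5 * (
                P_g * (n_c * 90 * math.log(2.0 * math.pi) + logdet) + quad
            )

            diag_blocks = np.einsum("uiuj->uij", Cov4)
            for lev in range(3):
                idx = np.nonzero(levels == lev)[0]
                if idx.size:
                    Zl = Z[:, idx, :]
                    S_stats[lev] += np.einsum("pui,puj->ij", Zl, Zl) + P_g * diag_blocks[
                        idx
                    ].sum(axis=0)
                    N_units[lev] += P_g * idx.size
            Vc = np.einsum("cu,uivj,cv->cij", D, Cov4, D)  # same for all in group
            posterior.append((U, X, T, Vc))

            sum_xx += P_g * (X.T @ X)
            sum_ux += np.einsum("pcq,cd->qd", np.einsum("pci,iq->pcq", U, Wl), X)
            sum_tx += np.einsum("pcq,cd->qd", T, X)

        # CM steps in Gauss-Seidel order: beta -> level covariances ->
        # noise -> loadings; the noise and loading updates use the fresh
        # beta so each step conditionally maximizes Q.
        Ginv = np.linalg.inv(G)
        Sxx_inv = np.linalg.pinv(sum_xx)
        B_new = (Ginv @ sum_ux - sum_tx) @ Sxx_inv  # (q, p)
        covs_new = [
            _project_psd(S_stats[l] / max(N_units[l], 1)) for l in range(3)
        ]
        sum_us = np.zeros((90, q))
        sum_ss = np.zeros((q, q))
        resid_sq = np.zeros(90)
        for U, X, T, Vc in posterior:
            P_g = U.shape[0]
            s_mean = (X @ B_new.T)[None, :, :] + T  # (P_g, n_c, q)
            sum_us += np.einsum("pci,pcq->iq", U, s_mean)
            sum_ss += np.einsum("pcq,pcr->qr", s_mean, s_mean) + P_g * Vc.sum(axis=0)
            res = U - np.einsum("pcq,iq->pci", s_mean, W)
            resid_sq += (res**2).sum(axis=(0, 1)) + P_g * np.einsum(
                "ri,cij,rj->r", W, Vc, W
            )
        lam_new = np.maximum(
            resid_sq.reshape(30, 3).sum(axis=0) / (30.0 * self.n_curves), _LAMBDA_FLOOR
        )
        W_new = sum_us @ np.linalg.inv(sum_ss)
        W_new, B_new, covs_new = _orthonormalize(W_new, B_new, covs_new)
        return (W_new, B_new, covs_new, lam_new), ll

    def loglik(self, W, B, covs, lam) -> float:
        _, ll = self.em_step(W, B, covs, lam)
        return ll


def fit_factor_model(
    trajectories: Sequence[TrajectorySample],
    q: int,
    design: str = "anova",
    reference: int = 1,
    max_iter: int = 500,
    tol: float = 1e-9,
    use_squarem: bool = True,
    init_params: tuple | None = None,
) -> tuple[FactorModel, list]:
    """Fit the mixed-effects factor model by maximum likelihood.

    The reference mean path theta is the pointwise mean of the
    reference-height trajectories and stays fixed during the ECM iteration.
    Returns the identified model (see :func:`identify_loadings`) and the
    nondecreasing log-likelihood trace of accepted steps.  ``max_iter``
    caps the number of ECM-equivalent iterations; convergence is declared
    when the relative log-likelihood change drops below ``tol``.
    ``init_params`` optionally supplies a starting point ``(W, B, covs,
    lam)`` (e.g. a converted fit of a nested design) in place of the
    default SVD-based initialization.
    """
    prob = _Problem(trajectories, q, design, reference)
    params = init_params if init_params is not None else prob.init_params()
    trace: list[float] = []
    n_eval = 0
    ll_prev = -np.inf
    while n_eval < max_iter:
        params1, ll0 = prob.em_step(*params)
        n_eval += 1
        trace.append(ll0)
        if np.isfinite(ll_prev) and abs(ll0 - ll_prev) <= tol * (abs(ll_prev) + 1.0):
            params = params1
            ll_prev = ll0
            break
        ll_prev = ll0
        if not use_squarem or n_eval + 2 > max_iter:
            params = params1
            continue
        params2, ll1 = prob.em_step(*params1)
        n_eval += 1
        trace.append(ll1)
        x0 = _pack(*params)
        x1 = _pack(*params1)
        x2 = _pack(*params2)
        r = x1 - x0
        v = (x2 - x1) - r
        nv = float(np.linalg.norm(v))
        if nv == 0.0:
            params = params2
            ll_prev = ll1
            continue
        alpha = -max(float(np.linalg.norm(r)) / nv, 1.0)  # S3 step length, safeguarded
        x_sq = x0 - 2.0 * alpha * r + alpha**2 * v
        try:
            params_sq = _unpack(x_sq, q, prob.p)
            params3, ll_sq = prob.em_step(*params_sq)
            n_eval += 1
        except (np.linalg.LinAlgError, ValueError):
            ll_sq = -np.inf
        if ll_sq >= ll1 - 1e-10:
            trace.append(ll_sq)
            params = params3
            ll_prev = ll_sq
        else:
            params = params2
            ll_prev = ll1
    W, B, covs, lam = params
    ll_final = prob.loglik(W, B, covs, lam)
    trace.append(ll_final)
    model = FactorModel(
        theta=prob.theta,
        W=W,
        beta=B.T,
        design=design,
        level_covs=tuple(covs),
        noise_variances=lam,
        reference=reference,
        loglik=ll_final,
    )
    return identify_loadings(model), trace


def identify_loadings(model: FactorModel) -> FactorModel:
    """Identify scale and rotation of the loadings.

    W is orthonormalized; the rotation diagonalizing the total latent
    covariance sum_l Sigma_l is applied (diagonal sorted decreasing), with
    beta and the level covariances co-rotated so the likelihood is
    unchanged.  Column signs are fixed so each loading's largest-magnitude
    entry is positive.  The operation is an involution-stable projection:
    applying it twice gives the same model.
    """
    W, B, covs = _orthonormalize(model.W, model.beta.T, list(model.level_covs))
    total = sum(covs)
    vals, vecs = np.linalg.eigh(0.5 * (total + total.T))
    order = np.argsort(vals)[::-1]
    R = vecs[:, order]
    W = W @ R
    B = R.T @ B
    covs = [R.T @ S @ R for S in covs]
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    W = W * signs[None, :]
    B = signs[:, None] * B
    covs = [signs[:, None] * S * signs[None, :] for S in covs]
    return replace(
        model, W=W, beta=B.T, level_covs=tuple(covs)
    )


def variance_explained(model: FactorModel, trajectories: Sequence[TrajectorySample]) -> np.ndarray:
    """Percentage of total fitted variance explained by each loading.

    Per loading: the covariate-driven variance (variance of the fitted
    height effect over the observed design) plus the summed level variances
    along that loading, relative to the total including the noise term.
    Percentages over the q loadings sum to at most 100; the remainder is
    the share of the white noise eps.
    """
    X = np.stack([height_design_row(tr.height_level, model.design) for tr in trajectories])
    scores = X @ model.beta  # (n, q)
    v_beta = scores.var(axis=0, ddof=0)
    v_level = np.diag(model.total_latent_cov)
    v = v_beta + v_level
    noise = 30.0 * float(np.sum(model.noise_variances))
    return 100.0 * v / (v.sum() + noise)


def lrt_height_design(
    trajectories: Sequence[TrajectorySample],
    q: int,
    reference: int = 1,
    **fit_kwargs,
) -> tuple[float, float]:
    """Likelihood-ratio test of linear height scaling.

    Fits the two-parameter ANOVA design and the one-parameter regression
    design (height increase 0 / 7.5 / 15 cm) on the same data and compares
    twice the log-likelihood difference to a chi-squared distribution with
    q degrees of freedom (the regression model removes q slope parameters'
    worth of freedom per extra covariate column).
    """
    def as_params(m: FactorModel, B: np.ndarray):
        return (m.W.copy(), B, [S.copy() for S in m.level_covs], m.noise_variances.copy())

    model_r, _ = fit_factor_model(
        trajectories, q, design="regression", reference=reference, **fit_kwargs
    )
    # ECM fits can settle in different basins; warm-start each design from
    # the other's solution and keep the better likelihood, which also keeps
    # the nesting numerically intact (the ANOVA design can represent any
    # regression solution exactly)
    x_m = height_design_row(2, "regression")[0]
    x_t = height_design_row(3, "regression")[0]
    b_to_anova = lambda m: np.column_stack([x_m * m.beta[0], x_t * m.beta[0]])  # (q, 2)
    model_a, _ = fit_factor_model(
        trajectories, q, design="anova", reference=reference, **fit_kwargs
    )
    model_a2, _ = fit_factor_model(
        trajectories, q, design="anova", reference=reference,
        init_params=as_params(model_r, b_to_anova(model_r)), **fit_kwargs
    )
    if model_a2.loglik > model_a.loglik:
        model_a = model_a2
    # project the ANOVA height effects onto the linear-scaling subspace for
    # a second regression start
    denom = x_m**2 + x_t**2
    b_lin = (x_m * model_a.beta[0] + x_t * model_a.beta[1]) / denom  # (q,)
    model_r2, _ = fit_factor_model(
        trajectories, q, design="regression", reference=reference,
        init_params=as_params(model_a, b_lin[:, None]), **fit_kwargs
    )
    if model_r2.loglik > model_r.loglik:
        model_r = model_r2
    stat = 2.0 * (model_a.loglik - model_r.loglik)
    if stat < -1e-4 * (1.0 + abs(model_a.loglik)):
        raise ConvergenceError(
            f"regression fit exceeds the nesting ANOVA fit (stat={stat:.3g}); "
            "tighten the convergence tolerance"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df=q))


@dataclass(frozen=True)
class Ellipsoid:
    """A prediction ellipsoid: spatial covariance, principal radii and axes."""

    cov: np.ndarray
    radii: np.ndarray
    axes: np.ndarray


def level_ellipsoids(
    model: FactorModel, level: str, time_index: int, coverage: float = 0.95
) -> Ellipsoid:
    """Prediction ellipsoid of one random-effect level at one time point.

    The marginal 3x3 spatial covariance at the time point is
    W_t Sigma_level W_t' with W_t the three loading rows of that time
    point; the ellipsoid radii scale its principal axes by the square root
    of the chi-squared(3) quantile at the requested coverage.
    """
    if not (0.0 < coverage < 1.0):
        raise DomainError("coverage must lie in (0, 1)")
    if level not in _LEVELS:
        raise DomainError(f"level must be one of {_LEVELS}")
    if not (1 <= time_index <= 30):
        raise DomainError("time_index must be in 1..30")
    Sig = model.level_covs[_LEVELS.index(level)]
    Wt = model.W.reshape(30, 3, model.q)[time_index - 1]  # (3, q)
    cov3 = Wt @ Sig @ Wt.T
    vals, vecs = np.linalg.eigh(0.5 * (cov3 + cov3.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    radii = np.sqrt(np.maximum(vals, 0.0) * chi2.ppf(coverage, df=3))
    return Ellipsoid(cov=cov3, radii=radii, axes=vecs)
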