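"""Maximum-likelihood fitting of the warping model and template classification.

The fitting scheme alternates over three levels:

1. *fixed-warp*: GLS/ridge-GLS updates of the template and participant
   deviations given the current warps;
2. *nonlinear*: joint estimation of each participant's fixed warp ``nu_i``
   and prediction of the repetition warps ``w_ij`` by minimizing the
   negative log posterior, restricted to valid homeomorphisms;
3. *linearized*: estimation of the variance parameters (sigma2, tau2,
   alpha, gamma2) by minimizing the Laplace-approximate marginal likelihood
   of the model linearized at the current warp predictions.

The outer/inner iteration: inner loops alternate warp prediction and
template updates until the warps stop changing (max anchor change below
``warp_tol``); outer loops re-estimate variances.  Five of each are enough
in practice.  sigma2 is profiled analytically inside the variance
criterion, and the ridge weight eta = lambda/(1+tau2) is re-derived from
lambda after every variance update.

Classification ("timing and motion separation", TMS) scores a test curve
against each participant's fitted template (theta+phi_i) o nu_i by
minimizing the same negative log posterior over the test repetition's warp
only -- the participant's fixed warp is a learned trait and stays fixed --
and assigns the participant with the smallest posterior distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .bases import (
    BrownianBridgeCovariance,
    MaternCovariance,
    SplineBasis,
    matern_matrix,
)
from .data import FunctionalSample
from .exceptions import ConfigError, DomainError, FitError, StateError
from .model import (
    ModelParameters,
    amplitude_cholesky,
    center_deviations,
    eta_from_lambda,
    linearize,
    update_phi,
    update_theta,
)
from .warping import anchor_points, eval_warp, is_valid_homeomorphism, warp_design_row

__all__ = [
    "PavpopConfig",
    "FitResult",
    "fit_pavpop",
    "predict_warps",
    "estimate_variances",
    "classify_tms",
    "chronological_cv_folds",
]

_BARRIER = 1e9
_MIN_GAP = 1e-6


@dataclass(frozen=True)
class PavpopConfig:
    """Hyperparameters and initial variance values for :func:`fit_pavpop`.

    ``n_knots`` counts equidistant spline knots on [0, 1] including the
    boundaries (K + 2 basis functions); ``mu`` is the Matern smoothness,
    treated as a grid hyperparameter and never optimized continuously.
    ``n_w = 0`` disables warping and the model degrades to a linear mixed
    model.  ``seed`` is reserved for stochastic restart strategies; the
    default optimization path is deterministic.

    The ridge weight on participant deviations exists to guide alignment
    while the template is still poor, so the first ``n_burnin`` outer
    iterations use ``max(lam, lam_burnin)``; afterwards the configured
    ``lam`` applies, which keeps the final deviation estimates unbiased by
    the stabilizing penalty.
    """

    n_knots: int = 12
    n_w: int = 2
    lam: float = 0.0
    mu: float = 1.0
    i_max: int = 5
    j_max: int = 5
    tau2_init: float = 1.0
    alpha_init: float = 10.0
    gamma2_init: float = 0.1
    lam_burnin: float = 2.0
    n_burnin: int = 2
    warp_tol: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_knots < 2 or self.n_w < 0 or self.lam < 0:
            raise ConfigError("invalid configuration")
        if self.i_max < 1 or self.j_max < 1:
            raise ConfigError("iteration limits must be at least 1")


@dataclass
class FitResult:
    """Fitted model: parameters, per-participant fixed warps, per-repetition
    warp predictions, the linearized-nll trace and a convergence flag."""

    params: ModelParameters
    nu: dict
    w: dict
    trace: list
    converged: bool
    basis: SplineBasis
    config: PavpopConfig

    def template_coefs(self, participant_id) -> np.ndarray:
        i = self.params.participant_ids.index(participant_id)
        return self.params.c + self.params.d[i]


# ---------------------------------------------------------------------------
# Warp prediction (nonlinear level)


def _warp_objective(
    x: np.ndarray,
    values_i,
    times_i,
    hats_i,
    chols_i,
    spline,
    dspline,
    Cinv,
    n_w: int,
    nu_fixed,
    optimize_w: bool,
):
    """Objective and gradient of the joint negative log posterior.

    ``x`` packs [nu (unless fixed), w_1, ..., w_J (if optimized)].
    Non-monotone anchor sequences get a barrier value whose gradient pushes
    the anchors back into the feasible region.
    """
    J = len(values_i)
    pos = 0
    if nu_fixed is None:
        nu = x[:n_w]
        pos = n_w
    else:
        nu = nu_fixed
    W = x[pos:].reshape(J, n_w) if optimize_w else np.zeros((J, n_w))

    seq = np.concatenate(
        [np.zeros((J, 1)), nu[None, :] + W, np.ones((J, 1))], axis=1
    )
    diffs = np.diff(seq, axis=1)  # (J, n_w + 1)
    active = (_MIN_GAP - diffs) > 0
    if active.any():
        viol = np.maximum(_MIN_GAP - diffs, 0.0)
        f = _BARRIER * (1.0 + viol.sum())
        # d viol / d anchor_k = active_{k+1} - active_k  (anchor k sits between
        # gap k and gap k+1 of the padded sequence)
        g_anchor = active[:, 1:].astype(float) - active[:, :-1].astype(float)
        grad = np.zeros_like(x)
        if nu_fixed is None:
            grad[:n_w] = _BARRIER * g_anchor.sum(axis=0)
        if optimize_w:
            grad[pos:] = _BARRIER * g_anchor.ravel()
        return f, grad

    f = 0.0
    g_nu = np.zeros(n_w)
    g_w = np.zeros((J, n_w))
    for j in range(J):
        wt = np.clip(eval_warp(nu, W[j], times_i[j]), 0.0, 1.0)
        r = values_i[j] - spline(wt)
        u = cho_solve(chols_i[j], r)
        f += float(r @ u)
        gj = -2.0 * ((u * dspline(wt)) @ hats_i[j])
        g_nu += gj
        if optimize_w:
            pw = Cinv @ W[j]
            f += float(W[j] @ pw)
            g_w[j] = gj + 2.0 * pw
    grad = np.zeros_like(x)
    if nu_fixed is None:
        grad[:n_w] = g_nu
    if optimize_w:
        grad[pos:] = g_w.ravel()
    return f, grad


def predict_warps(
    values_i: Sequence[np.ndarray],
    times_i: Sequence[np.ndarray],
    coef_i: np.ndarray,
    basis: SplineBasis,
    matern: MaternCovariance,
    bridge: BrownianBridgeCovariance,
    nu0: np.ndarray | None = None,
    w0: Sequence[np.ndarray] | None = None,
    chols_i=None,
    maxiter: int = 200,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Jointly minimize the warp posterior over (nu_i, {w_ij}) for one
    participant by bounded quasi-Newton descent with analytic gradients.

    Starts from the previous iterate (``nu0``/``w0``) and, when that
    differs, also from the identity warp, keeping the better optimum.
    Returns ``(nu, W, descended)``; if no valid descent below the identity
    warp is found the identity warps are returned with ``descended =
    False``.
    """
    J = len(values_i)
    n_w = bridge.n_w
    ident = anchor_points(n_w)
    if n_w == 0:
        return ident, np.zeros((J, 0)), True
    if chols_i is None:
        chols_i = amplitude_cholesky(times_i, matern)
    spline = basis.spline(coef_i)
    dspline = spline.derivative()
    hats_i = [warp_design_row(ident, np.zeros(n_w), t) for t in times_i]
    optimize_w = bridge.gamma2 > 0
    Cinv = np.linalg.inv(bridge.matrix()) if optimize_w else None

    nu0 = ident.copy() if nu0 is None else np.asarray(nu0, dtype=float)
    W0 = (
        np.zeros((J, n_w))
        if w0 is None
        else np.vstack([np.asarray(w, dtype=float).reshape(1, n_w) for w in w0])
    )

    args = (values_i, times_i, hats_i, chols_i, spline, dspline, Cinv, n_w, None, optimize_w)

    def pack(nu, W):
        return np.concatenate([nu, W.ravel()]) if optimize_w else nu.copy()

    def unpack(x):
        nu = x[:n_w].copy()
        W = x[n_w:].reshape(J, n_w).copy() if optimize_w else np.zeros((J, n_w))
        return nu, W

    bounds = [(1e-4, 1.0 - 1e-4)] * n_w
    if optimize_w:
        bounds += [(-1.0, 1.0)] * (J * n_w)

    x_id = pack(ident, np.zeros((J, n_w)))
    starts = [pack(nu0, W0)]
    if not np.allclose(starts[0], x_id):
        starts.append(x_id)

    best = None
    for x_start in starts:
        res = minimize(
            _warp_objective,
            x_start,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    f_id, _ = _warp_objective(x_id, *args)
    nu, W = unpack(best.x)
    valid = all(is_valid_homeomorphism(nu, W[j]) for j in range(J))
    if not valid or best.fun > f_id:
        return ident, np.zeros((J, n_w)), False
    return nu, W, True


# ---------------------------------------------------------------------------
# Variance estimation (linearized level)


def _profiled_linearized_nll(groups, tau2, alpha, gamma2, mu, bridge_base):
    """Profiled (over sigma2) linearized -2 log likelihood (no 2 pi term).

    ``groups`` is a list of (times, R, Zs) where curves sharing a time grid
    are stacked: R is (n_curves, m) residuals y - vartheta + Z w0 and Zs is
    (n_curves, m, n_w).  Uses the matrix-determinant lemma / Woodbury so
    only one m x m factorization per distinct grid is needed.
    """
    matern = MaternCovariance(mu, tau2, alpha)
    m_total = 0
    logdet = 0.0
    quad = 0.0
    for t, R, Zs in groups:
        n, m, n_w = Zs.shape
        m_total += n * m
        M = matern_matrix(t, matern) + np.eye(m)
        ch = cho_factor(M, lower=True)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(ch[0]))))
        MiR = cho_solve(ch, R.T)  # (m, n)
        q0 = np.einsum("im,mi->i", R, MiR)
        if n_w > 0 and gamma2 > 0:
            C = gamma2 * bridge_base
            Cinv = np.linalg.inv(C)
            Zflat = np.moveaxis(Zs, 0, 1).reshape(m, n * n_w)
            MiZ = cho_solve(ch, Zflat).reshape(m, n, n_w)
            A = np.einsum("kmi,mkj->kij", Zs, MiZ)  # (n, n_w, n_w) = Z' M^-1 Z
            b = np.einsum("kmi,mk->ki", Zs, MiR)  # (n, n_w) = Z' M^-1 r
            eye = np.eye(n_w)
            inner = Cinv[None, :, :] + A
            corr = np.einsum("ki,ki->k", b, np.linalg.solve(inner, b[..., None])[..., 0])
            sign, ld = np.linalg.slogdet(eye[None, :, :] + C[None, :, :] @ A)
            if np.any(sign <= 0):
                raise np.linalg.LinAlgError("indefinite low-rank update")
            logdet += n * logdetM + float(ld.sum())
            quad += float((q0 - corr).sum())
        else:
            logdet += n * logdetM
            quad += float(q0.sum())
    sigma2_hat = quad / m_total
    nll = m_total * math.log(max(sigma2_hat, 1e-300)) + logdet + m_total
    return nll, sigma2_hat


def _build_linearization(values, times, coefs, basis, nus, w0s):
    """Group curves by time grid and assemble residuals/Jacobians at the
    current warp predictions."""
    groups: dict = {}
    for y, t, coef, nu, w0 in zip(values, times, coefs, nus, w0s):
        vt, Z = linearize(coef, basis, nu, w0, t)
        r = y - vt + (Z @ np.asarray(w0) if Z.shape[1] else 0.0)
        key = (t.tobytes(), Z.shape[1])
        groups.setdefault(key, (t, [], []))
        groups[key][1].append(r)
        groups[key][2].append(Z)
    return [
        (t, np.vstack([r[None, :] for r in rs]), np.stack(zs, axis=0))
        for t, rs, zs in groups.values()
    ]


def estimate_variances(
    values: Sequence[np.ndarray],
    times: Sequence[np.ndarray],
    coefs: Sequence[np.ndarray],
    nus: Sequence[np.ndarray],
    w0s: Sequence[np.ndarray],
    basis: SplineBasis,
    mu: float,
    n_w: int,
    init: tuple[float, float, float] = (1.0, 10.0, 0.1),
    optimize_gamma: bool | None = None,
    log_bounds: tuple[float, float] = (math.log(1e-10), math.log(1e6)),
    maxiter: int = 60,
) -> tuple[float, float, float, float, float]:
    """Estimate (sigma2, tau2, alpha, gamma2) from the linearized likelihood.

    The linearization point is the current warp prediction (Laplace);
    sigma2 is profiled analytically and (tau2, alpha, gamma2) are optimized
    on the log scale within ``log_bounds``.  ``init`` is ``(tau2, alpha,
    gamma2)``; the returned criterion value never exceeds the value at the
    initial point.  ``coefs``, ``nus`` and ``w0s`` give each curve's
    template weights, fixed-warp anchors and predicted warp anchors.
    Returns ``(sigma2, tau2, alpha, gamma2, nll)``.
    """
    if optimize_gamma is None:
        optimize_gamma = n_w > 0
    groups = _build_linearization(values, times, coefs, basis, nus, w0s)
    bridge_base = (
        BrownianBridgeCovariance(1.0, n_w).matrix() if n_w > 0 else np.zeros((0, 0))
    )
    tau2_0, alpha_0, gamma2_0 = init

    def criterion(x):
        tau2, alpha = math.exp(x[0]), math.exp(x[1])
        gamma2 = math.exp(x[2]) if optimize_gamma else gamma2_0
        try:
            nll, _ = _profiled_linearized_nll(groups, tau2, alpha, gamma2, mu, bridge_base)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        return nll if np.isfinite(nll) else 1e12

    def pack(tau2, alpha, gamma2):
        x = [math.log(max(tau2, 1e-10)), math.log(alpha)]
        if optimize_gamma:
            x.append(math.log(max(gamma2, 1e-10)))
        return np.asarray(x)

    x0 = pack(tau2_0, alpha_0, gamma2_0)
    # the criterion can have several basins (e.g. amplitude variance
    # collapsing to zero); probe a few deterministic starts and keep the best
    starts = [x0, pack(1.0, 10.0, gamma2_0), pack(0.3, 30.0, gamma2_0)]
    x_best, f_best = x0, criterion(x0)
    for x_start in starts:
        res = minimize(
            criterion,
            x_start,
            method="L-BFGS-B",
            bounds=[log_bounds] * len(x_start),
            options={"maxiter": maxiter},
        )
        if res.fun < f_best:
            x_best, f_best = res.x, res.fun
    tau2, alpha = math.exp(x_best[0]), math.exp(x_best[1])
    gamma2 = math.exp(x_best[2]) if optimize_gamma else gamma2_0
    nll, sigma2 = _profiled_linearized_nll(groups, tau2, alpha, gamma2, mu, bridge_base)
    if not np.isfinite(nll):
        raise FitError("variance estimation produced a non-finite objective")
    return sigma2, tau2, alpha, gamma2, nll


# ---------------------------------------------------------------------------
# Full fitting algorithm


def _group_samples(samples: Sequence[FunctionalSample]):
    by_pid: dict = {}
    for s in samples:
        by_pid.setdefault(s.participant_id, []).append(s)
    pids = sorted(by_pid)
    values, times, rep_ids = [], [], []
    for pid in pids:
        reps = sorted(by_pid[pid], key=lambda s: s.repetition_id)
        times.append([s.observed()[0] for s in reps])
        values.append([s.observed()[1] for s in reps])
        rep_ids.append([s.repetition_id for s in reps])
    return pids, values, times, rep_ids


def fit_pavpop(
    samples: Sequence[FunctionalSample], config: PavpopConfig | None = None
) -> FitResult:
    """Fit the hierarchical warping model by three-level maximum likelihood.

    All samples should belong to one experimental condition.  With
    ``config.n_w = 0`` the model is an (unwarped) linear mixed model and
    only (sigma2, tau2, alpha) are estimated.
    """
    config = config or PavpopConfig()
    if not samples:
        raise StateError("no samples to fit")
    pids, values, times, rep_ids = _group_samples(samples)
    n_p = len(pids)
    basis = SplineBasis(config.n_knots)
    n_w = config.n_w
    matern = MaternCovariance(config.mu, config.tau2_init, config.alpha_init)
    bridge = BrownianBridgeCovariance(config.gamma2_init if n_w > 0 else 0.0, n_w)
    lam_eff = max(config.lam, config.lam_burnin) if config.n_burnin > 0 else config.lam
    eta = eta_from_lambda(lam_eff, matern.tau2)

    ident = anchor_points(n_w)
    nus = [ident.copy() for _ in range(n_p)]
    Ws = [np.zeros((len(values[i]), n_w)) for i in range(n_p)]

    def update_templates(chols_by_part):
        wt_all, t_all, y_all = [], [], []
        for i in range(n_p):
            for j, t in enumerate(times[i]):
                wt_all.append(eval_warp(nus[i], Ws[i][j], t))
                t_all.append(t)
                y_all.append(values[i][j])
        chols_flat = [ch for chl in chols_by_part for ch in chl]
        c_new = update_theta(y_all, wt_all, t_all, basis, matern, chols=chols_flat)
        d_new = np.zeros((n_p, basis.n_basis))
        k = 0
        for i in range(n_p):
            wt_i = wt_all[k : k + len(times[i])]
            d_new[i] = update_phi(
                values[i], wt_i, times[i], basis, matern, c_new, eta,
                chols=chols_by_part[i],
            )
            k += len(times[i])
        return center_deviations(c_new, d_new)

    chols_by_part = [amplitude_cholesky(times[i], matern) for i in range(n_p)]
    c, d = update_templates(chols_by_part)

    trace: list[float] = []
    sigma2 = 1.0
    last_delta = np.inf if n_w > 0 else 0.0
    for outer in range(config.i_max):
        lam_eff = max(config.lam, config.lam_burnin) if outer < config.n_burnin else config.lam
        eta = eta_from_lambda(lam_eff, matern.tau2)
        if n_w > 0:
            for inner in range(config.j_max):
                new_nus, new_Ws = [], []
                for i in range(n_p):
                    nu_new, W_new, _ = predict_warps(
                        values[i], times[i], c + d[i], basis, matern, bridge,
                        nu0=nus[i], w0=Ws[i], chols_i=chols_by_part[i],
                    )
                    new_nus.append(nu_new)
                    new_Ws.append(W_new)
                delta = 0.0
                for i in range(n_p):
                    delta = max(
                        delta,
                        float(np.max(np.abs(new_nus[i] - nus[i]), initial=0.0)),
                        float(np.max(np.abs(new_Ws[i] - Ws[i]), initial=0.0)),
                    )
                    nus[i], Ws[i] = new_nus[i], new_Ws[i]
                last_delta = delta
                if delta < config.warp_tol:
                    break
                c, d = update_templates(chols_by_part)
        flat_v = [v for vs in values for v in vs]
        flat_t = [t for ts in times for t in ts]
        flat_c = [c + d[i] for i in range(n_p) for _ in values[i]]
        flat_n = [nus[i] for i in range(n_p) for _ in values[i]]
        flat_w = [Ws[i][j] for i in range(n_p) for j in range(len(values[i]))]
        sigma2, tau2, alpha, gamma2_new, nll = estimate_variances(
            flat_v, flat_t, flat_c, flat_n, flat_w, basis, config.mu, n_w,
            init=(matern.tau2, matern.alpha, bridge.gamma2 if n_w > 0 else 0.0),
            optimize_gamma=n_w > 0,
        )
        if not np.isfinite(nll):
            raise FitError(
                f"non-finite linearized likelihood at outer iteration {outer + 1}"
            )
        matern = MaternCovariance(config.mu, tau2, alpha)
        bridge = BrownianBridgeCovariance(gamma2_new if n_w > 0 else 0.0, n_w)
        eta = eta_from_lambda(lam_eff, tau2)
        trace.append(float(nll))
        chols_by_part = [amplitude_cholesky(times[i], matern) for i in range(n_p)]
        c, d = update_templates(chols_by_part)

    params = ModelParameters(
        c=c, d=d, participant_ids=pids, sigma2=sigma2,
        matern=matern, bridge=bridge, lam=config.lam,
    )
    return FitResult(
        params=params,
        nu={pid: nus[i] for i, pid in enumerate(pids)},
        w={
            (pid, rep_ids[i][j]): Ws[i][j]
            for i, pid in enumerate(pids)
            for j in range(len(rep_ids[i]))
        },
        trace=trace,
        converged=bool(last_delta < config.warp_tol),
        basis=basis,
        config=config,
    )


# ---------------------------------------------------------------------------
# Classification and cross-validation


def classify_tms(test_sample: FunctionalSample, fitted: FitResult) -> int:
    """Assign a test curve to the participant with the least negative log
    posterior, minimized over the test repetition's warp only (each
    candidate's fixed warp stays at its estimate).  Ties break toward the
    lowest participant id."""
    if not fitted.params.participant_ids:
        raise StateError("fitted model contains no participants")
    t, y = test_sample.observed()
    matern = fitted.params.matern
    bridge = fitted.params.bridge
    basis = fitted.basis
    n_w = bridge.n_w
    chols = amplitude_cholesky([t], matern)
    optimize_w = n_w > 0 and bridge.gamma2 > 0
    Cinv = np.linalg.inv(bridge.matrix()) if optimize_w else None
    hats = [warp_design_row(anchor_points(n_w), np.zeros(n_w), t)]
    best_pid, best_val = None, np.inf
    for pid in fitted.params.participant_ids:
        coef = fitted.template_coefs(pid)
        nu = fitted.nu[pid]
        spline = basis.spline(coef)
        if not optimize_w:
            wt = np.clip(eval_warp(nu, np.zeros(n_w), t), 0.0, 1.0)
            r = y - spline(wt)
            val = float(r @ cho_solve(chols[0], r))
        else:
            dspline = spline.derivative()
            args = ([y], [t], hats, chols, spline, dspline, Cinv, n_w, nu, True)
            x0 = np.zeros(n_w)
            res = minimize(
                _warp_objective, x0, args=args, jac=True, method="L-BFGS-B",
                bounds=[(-1.0, 1.0)] * n_w, options={"maxiter": 100},
            )
            f0, _ = _warp_objective(x0, *args)
            val = float(min(res.fun, f0))
        if val < best_val - 1e-12:
            best_val, best_pid = val, pid
    return best_pid


def chronological_cv_folds(n_repetitions: int, n_folds: int) -> list[tuple[list, list]]:
    """Chronological cross-validation folds over repetition numbers 1..n.

    Fold f tests the f-th consecutive block of ``n/k`` repetitions and
    trains on the rest; ``n_folds`` must divide ``n_repetitions``.
    """
    if n_folds < 1 or n_repetitions < 1:
        raise DomainError("counts must be positive")
    if n_repetitions % n_folds != 0:
        raise DomainError(f"n_folds={n_folds} must divide n_repetitions={n_repetitions}")
    size = n_repetitions // n_folds
    all_ids = list(range(1, n_repetitions + 1))
    return [
        (
            all_ids[: f * size] + all_ids[(f + 1) * size :],
            all_ids[f * size : (f + 1) * size],
        )
        for f in range(n_folds)
    ]
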