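"""Synthetic-data generators for both models.

These simulators draw from the exact generative forms of the two models so
that every stage of estimation can be exercised and checked against known
ground truth.  The warping-model simulator emulates repeated movement
signals: a common smooth template (by default a double-bump profile
qualitatively matching acceleration traces of a reach with an obstacle
lift), participant-specific spline deviations, participant fixed warps,
Brownian-bridge random warps per repetition, a stationary Matern amplitude
process and white observation noise.  The factor-model simulator draws
aligned 30 x 3 paths with the three nested Gaussian levels (participant,
participant x height reaction, repetition), a height covariate effect
along orthonormal loadings, and per-coordinate noise.

Default scales mirror the study design the models target: 10 participants
with 10 repetitions per condition, 3 obstacle heights for the factor
model.  Every draw is governed by a single integer seed; a fixed seed
reproduces the data bit for bit, and the returned ground-truth records
contain every latent quantity needed for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bases import (
    BrownianBridgeCovariance,
    MaternCovariance,
    SplineBasis,
    bspline_design,
    matern_matrix,
)
from .data import FunctionalSample, TrajectorySample
from .exceptions import ConfigError
from .factor import height_design_row
from .warping import anchor_points, eval_warp, is_valid_homeomorphism

__all__ = [
    "PavpopSimConfig",
    "FactorSimConfig",
    "double_bump_weights",
    "default_reference_path",
    "default_loadings",
    "simulate_pavpop",
    "simulate_factor",
]


def double_bump_weights(basis: SplineBasis) -> np.ndarray:
    """Spline weights of a smooth double-bump template on [0, 1].

    Two Gaussian bumps (a smaller one early, a larger one past midway)
    qualitatively matching movement acceleration profiles, projected onto
    the basis by least squares on a dense grid so the template is exactly
    representable and the GLS update can recover it without bias.
    """
    grid = np.linspace(0.0, 1.0, 400)
    g = 0.6 * np.exp(-(((grid - 0.3) / 0.08) ** 2)) + 1.0 * np.exp(
        -(((grid - 0.65) / 0.1) ** 2)
    )
    design = bspline_design(basis, grid)
    coef, *_ = np.linalg.lstsq(design, g, rcond=None)
    return coef


@dataclass
class PavpopSimConfig:
    """Generative configuration for the warping model.

    Defaults are the study conditions the model targets: 10 participants x
    10 repetitions, 50 points per curve, noise variance 1e-4 on unit-span
    data, amplitude process with tau2 = 1, alpha = 5, mu = 1, warp variance
    gamma2 = 0.25 on n_w = 2 anchors.  ``phi_scale`` and ``nu_scale``
    control the participant-level amplitude and timing traits; explicit
    ``d``, ``nu`` or ``w`` arrays override the random draws (useful for
    noise-free recovery designs).
    """

    n_participants: int = 10
    n_repetitions: int = 10
    n_timepoints: int = 50
    n_knots: int = 12
    n_w: int = 2
    sigma2: float = 1e-4
    tau2: float = 1.0
    alpha: float = 5.0
    mu: float = 1.0
    gamma2: float = 0.25
    phi_scale: float = 0.1
    nu_scale: float = 0.05
    template: str | np.ndarray = "double-bump"
    d: np.ndarray | None = None
    nu: np.ndarray | None = None
    w: np.ndarray | None = None
    condition_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_repetitions, self.n_timepoints) < 1:
            raise ConfigError("all counts must be at least 1")
        if min(self.sigma2, self.tau2, self.gamma2, self.phi_scale, self.nu_scale) < 0:
            raise ConfigError("variances and scales must be nonnegative")


def _template_weights(config: PavpopSimConfig, basis: SplineBasis) -> np.ndarray:
    if isinstance(config.template, str):
        if config.template != "double-bump":
            raise ConfigError(f"unknown template {config.template!r}")
        return double_bump_weights(basis)
    coef = np.asarray(config.template, dtype=float)
    if coef.shape != (basis.n_basis,):
        raise ConfigError(f"template weights must have length {basis.n_basis}")
    return coef


def simulate_pavpop(config: PavpopSimConfig | None = None) -> tuple[list, dict]:
    """Draw a dataset from the warping model's generative form.

    Returns ``(samples, truth)`` where ``truth`` records the template
    weights ``c``, participant deviations ``d``, fixed warps ``nu``, random
    warps ``w``, amplitude paths ``x`` and the generating configuration.
    Random warp draws that violate the homeomorphism constraint are
    redrawn (rejection), matching the truncated-Gaussian reading of the
    warp distribution; the truncation effect is negligible at realistic
    scales.
    """
    config = config or PavpopSimConfig()
    rng = np.random.default_rng(config.seed)
    basis = SplineBasis(config.n_knots)
    c = _template_weights(config, basis)
    n_p, n_r, n_t, n_w = (
        config.n_participants,
        config.n_repetitions,
        config.n_timepoints,
        config.n_w,
    )
    t = np.linspace(0.0, 1.0, n_t)
    anchors = anchor_points(n_w)

    if config.d is not None:
        d = np.asarray(config.d, dtype=float)
    else:
        d = rng.normal(0.0, config.phi_scale, size=(n_p, basis.n_basis))
        d -= d.mean(axis=0, keepdims=True)

    if config.nu is not None:
        nu = np.asarray(config.nu, dtype=float).reshape(n_p, n_w)
    else:
        nu = np.empty((n_p, n_w))
        for i in range(n_p):
            while True:
                cand = anchors + rng.normal(0.0, config.nu_scale, size=n_w)
                if n_w == 0 or is_valid_homeomorphism(cand, np.zeros(n_w)):
                    nu[i] = cand
                    break

    C = BrownianBridgeCovariance(config.gamma2, n_w).matrix()
    w_chol = (
        np.linalg.cholesky(config.sigma2 * C + 1e-14 * np.eye(n_w))
        if n_w > 0 and config.gamma2 > 0 and config.sigma2 > 0
        else None
    )
    S = matern_matrix(t, MaternCovariance(config.mu, max(config.tau2, 1e-300), config.alpha))
    x_chol = (
        np.linalg.cholesky(config.sigma2 * S + 1e-14 * np.eye(n_t))
        if config.tau2 > 0 and config.sigma2 > 0
        else None
    )

    spline_by_part = [basis.spline(c + d[i]) for i in range(n_p)]
    samples: list[FunctionalSample] = []
    w_true = np.zeros((n_p, n_r, n_w))
    x_true = np.zeros((n_p, n_r, n_t))
    for i in range(n_p):
        for j in range(n_r):
            if config.w is not None:
                w_ij = np.asarray(config.w, dtype=float)[i, j]
            elif w_chol is not None:
                while True:
                    w_ij = w_chol @ rng.standard_normal(n_w)
                    if is_valid_homeomorphism(nu[i], w_ij):
                        break
            else:
                w_ij = np.zeros(n_w)
            w_true[i, j] = w_ij
            wt = np.clip(eval_warp(nu[i], w_ij, t), 0.0, 1.0)
            y = spline_by_part[i](wt)
            if x_chol is not None:
                x_ij = x_chol @ rng.standard_normal(n_t)
            else:
                x_ij = np.zeros(n_t)
            x_true[i, j] = x_ij
            y = y + x_ij
            if config.sigma2 > 0:
                y = y + rng.normal(0.0, np.sqrt(config.sigma2), size=n_t)
            samples.append(
                FunctionalSample(
                    participant_id=i + 1,
                    repetition_id=j + 1,
                    condition_id=config.condition_id,
                    times=t,
                    values=y,
                    missing_mask=np.zeros(n_t, dtype=bool),
                )
            )
    truth = {
        "c": c,
        "d": d,
        "nu": nu,
        "w": w_true,
        "x": x_true,
        "times": t,
        "config": config,
    }
    return samples, truth


# ---------------------------------------------------------------------------
# Factor model


def default_reference_path(n_points: int = 30) -> np.ndarray:
    """A canonical reference path: a 40 cm transport with a 12 cm lift and
    a small lateral excursion, sampled at 30 equidistant points."""
    s = np.linspace(0.0, 1.0, n_points)
    x = 40.0 * s
    y = 2.0 * np.sin(np.pi * s)
    z = 12.0 * np.sin(np.pi * s)
    return np.column_stack([x, y, z])


def default_loadings(q: int = 3, n_points: int = 30) -> np.ndarray:
    """Deterministic smooth orthonormal loadings (90 x q).

    Columns are built from low-frequency sine profiles acting on the
    vertical, lateral and along-path coordinates respectively, then
    orthonormalized; they mimic the dominant modes of path variation
    (higher lift, lateral shift, along-path stretch).
    """
    s = np.linspace(0.0, 1.0, n_points)
    profiles = [
        np.column_stack([np.zeros_like(s), np.zeros_like(s), np.sin(np.pi * s)]),
        np.column_stack([np.zeros_like(s), np.sin(np.pi * s), np.zeros_like(s)]),
        np.column_stack([np.sin(2.0 * np.pi * s), np.zeros_like(s), np.zeros_like(s)]),
        np.column_stack([np.zeros_like(s), np.zeros_like(s), np.sin(2.0 * np.pi * s)]),
        np.column_stack([np.sin(3.0 * np.pi * s), np.zeros_like(s), np.zeros_like(s)]),
    ]
    if q > len(profiles):
        raise ConfigError(f"at most {len(profiles)} default loadings available")
    M = np.column_stack([p.ravel() for p in profiles[:q]])
    Q, R = np.linalg.qr(M)
    return Q * np.sign(np.diag(R))[None, :]


@dataclass
class FactorSimConfig:
    """Generative configuration for the factor model.

    Defaults mirror the study design: 10 participants x 10 repetitions x 3
    obstacle heights, q = 3 loadings, a linear (regression) height effect
    of 0.15 / 0.05 / 0.02 cm per cm of height increase along the three
    loadings, participant variation as the largest random level and the
    height-reaction level as the smallest, and 0.05 cm^2 noise per
    coordinate.
    """

    n_participants: int = 10
    n_repetitions: int = 10
    heights: tuple = (1, 2, 3)
    q: int = 3
    design: str = "regression"
    theta: np.ndarray = field(default_factory=default_reference_path)
    W: np.ndarray | None = None
    beta: np.ndarray | None = None
    participant_sd: tuple = (2.0, 1.2, 0.8)
    reaction_sd: tuple = (0.4, 0.3, 0.2)
    repetition_sd: tuple = (1.0, 0.7, 0.5)
    noise_variances: tuple = (0.05, 0.05, 0.05)
    distance_cm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_repetitions, self.q) < 1:
            raise ConfigError("all counts must be at least 1")
        if self.W is None:
            self.W = default_loadings(self.q)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (90, self.q):
            raise ConfigError(f"W must be 90 x {self.q}")
        if not np.allclose(self.W.T @ self.W, np.eye(self.q), atol=1e-8):
            raise ConfigError("loadings W must be orthonormal")
        p = height_design_row(1, self.design).size
        if self.beta is None:
            base = np.array([0.15, 0.05, 0.02])[: self.q]
            base = np.pad(base, (0, max(0, self.q - 3)))
            if self.design == "regression":
                self.beta = base[None, :]
            else:
                self.beta = np.vstack([7.5 * base, 15.0 * base])
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (p, self.q):
            raise ConfigError(f"beta must be {p} x {self.q}")
        for sd in (self.participant_sd, self.reaction_sd, self.repetition_sd):
            if len(sd) != self.q or min(sd) < 0:
                raise ConfigError("level sds must be nonnegative, one per loading")


def simulate_factor(config: FactorSimConfig | None = None) -> tuple[list, dict]:
    """Draw aligned trajectories from the factor model's generative form.

    Participant effects are shared across all of a participant's curves,
    reaction effects within participant x height, repetition effects are
    independent per curve.  Returns ``(trajectories, truth)`` with all
    latent draws in ``truth``.
    """
    config = config or FactorSimConfig()
    rng = np.random.default_rng(config.seed)
    q = config.q
    W = config.W
    theta = np.asarray(config.theta, dtype=float)
    sd1 = np.asarray(config.participant_sd)
    sd2 = np.asarray(config.reaction_sd)
    sd3 = np.asarray(config.repetition_sd)
    noise_sd = np.sqrt(np.asarray(config.noise_variances))

    trajectories: list[TrajectorySample] = []
    z1_all, z2_all, z3_all = {}, {}, {}
    for i in range(1, config.n_participants + 1):
        z1 = rng.normal(0.0, sd1)
        z1_all[i] = z1
        for h in config.heights:
            z2 = rng.normal(0.0, sd2)
            z2_all[(i, h)] = z2
            x_h = height_design_row(h, config.design)
            for j in range(1, config.n_repetitions + 1):
                z3 = rng.normal(0.0, sd3)
                z3_all[(i, j, h)] = z3
                score = x_h @ config.beta + z1 + z2 + z3
                path = theta + (W @ score).reshape(30, 3)
                path = path + rng.normal(0.0, noise_sd, size=(30, 3))
                trajectories.append(
                    TrajectorySample(
                        participant_id=i,
                        repetition_id=j,
                        height_level=int(h),
                        distance_cm=config.distance_cm,
                        path=path,
                    )
                )
    truth = {
        "W": W,
        "beta": config.beta,
        "theta": theta,
        "level_covs": (np.diag(sd1**2), np.diag(sd2**2), np.diag(sd3**2)),
        "noise_variances": np.asarray(config.noise_variances),
        "z_participant": z1_all,
        "z_reaction": z2_all,
        "z_repetition": z3_all,
        "config": config,
    }
    return trajectories, truth
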