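"""Alternating solver for joint label propagation and sparse feature selection.

The joint objective couples a cluster indicator matrix H (n x c) and a
non-negative feature selection matrix F (m x c):

    min_{H, F}  sum_{ij} w_ij || H_i/sqrt(d_ii) - H_j/sqrt(d_jj) ||^2
                + mu * sum_i || H_i - Y_i ||^2
                + || X F - H ||_F^2
                + beta * || F ||_{2,1}

The first term asks H to be smooth over the sample graph, the second anchors
labeled samples to their initial one-hot labels Y, the third ties H to a
non-negative linear scoring of the expression matrix, and the l2,1 penalty
drives whole columns of F toward sparsity so that few genes support each
category.

The two blocks are optimized alternately:

* F-step: with H fixed, minimize ||XF - H||_F^2 + beta ||F||_{2,1} over
  F >= 0 by multiplicative updates derived from the KKT conditions,

      f_ij <- f_ij * (X^T H)_ij / (X^T X F + beta F U)_ij,

  where U = diag(1 / (2 ||F^j||_2)) is the standard l2,1 reweighting
  matrix.  The update preserves non-negativity and never increases the
  F-subproblem objective.

* H-step: with F fixed, the propagation has the closed form

      H* = ((1+mu) I - Z)^{-1} (mu Y + X F),

  i.e. label propagation over the normalized graph toward the augmented
  anchor Y + XF/mu.  Since the spectral radius of Z is at most 1, the
  system matrix is positive definite for every mu > 0 and the solve is
  exact.  Sample labels are the row-wise argmax of H*, and H is then
  re-binarized to the one-hot indicator fed to the next F-step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .datamodel import ExpressionMatrix, LabelSpec, LPFSConfig, ValidationError, build_initial_label_matrix
from .graph import SampleGraph, build_sample_graph

logger = logging.getLogger(__name__)

#: Floor applied to multiplicative-update denominators and column norms.
EPS = 1e-12


@dataclass
class FeatureSelectionMatrix:
    """Non-negative feature weights F (m x c) and the l2,1 auxiliary diagonal.

    ``u[j] = 1 / (2 ||F^j||_2)`` with the norm floored at :data:`EPS`; it is
    recomputed from the current F before every multiplicative update.
    """

    F: np.ndarray
    u: np.ndarray

    @classmethod
    def from_F(cls, F: np.ndarray) -> "FeatureSelectionMatrix":
        F = np.asarray(F, dtype=float)
        if np.any(F < 0):
            raise ValidationError("feature selection matrix must be non-negative")
        return cls(F=F, u=auxiliary_diagonal(F))


@dataclass
class PropagationResult:
    """Continuous propagation result, its binarization, and sample labels."""

    H_star: np.ndarray   # (n, c) solution of the propagation system
    H_bin: np.ndarray    # (n, c) one-hot row-wise argmax of H_star
    labels: np.ndarray   # (n,) categories in 1..c; argmax ties -> smallest j


@dataclass
class FitTrace:
    """Objective traces of one alternating fit."""

    outer_objective: list[float] = field(default_factory=list)
    f_objective: list[list[float]] = field(default_factory=list)
    converged: bool = False
    rounds_used: int = 0


@dataclass
class FitResult:
    feature_selection: FeatureSelectionMatrix
    propagation: PropagationResult
    trace: FitTrace


def l21_norm(F: np.ndarray) -> float:
    """Sum of column-wise Euclidean norms."""
    return float(np.sum(np.sqrt(np.sum(F * F, axis=0))))


def auxiliary_diagonal(F: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Diagonal of U: ``1 / (2 max(||F^j||_2, eps))`` per column j."""
    norms = np.sqrt(np.sum(F * F, axis=0))
    return 1.0 / (2.0 * np.maximum(norms, eps))


def f_objective(X: np.ndarray, F: np.ndarray, H: np.ndarray, beta: float) -> float:
    """F-subproblem objective ``||XF - H||_F^2 + beta ||F||_{2,1}``."""
    R = X @ F - H
    return float(np.sum(R * R)) + beta * l21_norm(F)


def objective(
    xm: ExpressionMatrix | np.ndarray,
    graph: SampleGraph,
    H: np.ndarray,
    Y: np.ndarray,
    F: np.ndarray,
    mu: float,
    beta: float,
) -> float:
    """Evaluate the joint objective at (H, F).

    The graph-smoothness term is the squared-norm penalty
    ``sum_{ij} w_ij ||H_i/sqrt(d_ii) - H_j/sqrt(d_jj)||^2``, evaluated in
    closed form as ``2 ||H||_F^2 - 2 tr(Hn^T W Hn)`` with the
    degree-normalized rows ``Hn_i = H_i / sqrt(d_ii)``.
    """
    X = xm.values if isinstance(xm, ExpressionMatrix) else np.asarray(xm, dtype=float)
    n, c = H.shape
    if Y.shape != (n, c):
        raise ValidationError(f"Y shape {Y.shape} does not match H shape {H.shape}")
    if X.shape[0] != n or F.shape != (X.shape[1], c):
        raise ValidationError(
            f"inconsistent shapes: X {X.shape}, F {F.shape}, H {H.shape}"
        )
    Hn = H / np.sqrt(graph.degrees)[:, None]
    smooth = 2.0 * float(np.sum(H * H)) - 2.0 * float(np.sum(Hn * (graph.W @ Hn)))
    anchor = float(np.sum((H - Y) ** 2))
    R = X @ F - H
    fit = float(np.sum(R * R))
    return smooth + mu * anchor + fit + beta * l21_norm(F)


def update_F(
    fsm: FeatureSelectionMatrix,
    X: np.ndarray,
    H: np.ndarray,
    beta: float,
    eps: float = EPS,
) -> FeatureSelectionMatrix:
    """One multiplicative update of F with U held at its current value.

    Entries multiply by ``(X^T H)_ij / (X^T X F + beta F U)_ij``; zero
    entries are absorbing, and the denominator is floored at ``eps``.  A
    negative numerator entry (possible only when a continuous H carries
    negative values) is clamped to zero, which sends the corresponding
    coefficient to its KKT-optimal boundary value 0.
    """
    F = fsm.F
    if np.any(F < 0):
        raise ValidationError("update_F requires a non-negative F")
    numer = np.maximum(X.T @ H, 0.0)
    denom = X.T @ (X @ F) + beta * F * fsm.u[None, :] + eps
    F_new = F * (numer / denom)
    return FeatureSelectionMatrix(F=F_new, u=auxiliary_diagonal(F_new, eps))


def solve_F(
    X: np.ndarray,
    H: np.ndarray,
    beta: float,
    *,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    F0: np.ndarray | None = None,
) -> tuple[FeatureSelectionMatrix, list[float]]:
    """Minimize the F-subproblem by multiplicative updates.

    F starts uniformly in (0, 1) (from ``seed``/``rng``) unless a warm-start
    ``F0`` is given.  Iterates until the relative change of the subproblem
    objective drops below ``tol`` or ``max_iter`` is hit (logged as a
    warning; the last iterate is still returned).
    """
    if beta < 0:
        raise ValidationError(f"beta must be >= 0, got {beta}")
    m, c = X.shape[1], H.shape[1]
    if F0 is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        F = rng.uniform(0.0, 1.0, size=(m, c))
    else:
        F = np.asarray(F0, dtype=float).copy()
        if F.shape != (m, c):
            raise ValidationError(f"F0 shape {F.shape} does not match ({m}, {c})")
        if np.any(F < 0):
            raise ValidationError("F0 must be non-negative")
    fsm = FeatureSelectionMatrix(F=F, u=auxiliary_diagonal(F))
    trace = [f_objective(X, fsm.F, H, beta)]
    converged = False
    for _ in range(max_iter):
        fsm = update_F(fsm, X, H, beta)
        obj = f_objective(X, fsm.F, H, beta)
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= tol * max(abs(prev), EPS):
            converged = True
            break
    if not converged:
        logger.warning(
            "F-subproblem did not reach tol=%.1e within %d iterations "
            "(last relative change %.3e)", tol, max_iter,
            abs(trace[-2] - trace[-1]) / max(abs(trace[-2]), EPS),
        )
    return fsm, trace


def binarize(H_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise argmax labels (ties -> smallest index) and one-hot indicator."""
    labels = np.argmax(H_star, axis=1) + 1
    H_bin = np.zeros_like(H_star)
    H_bin[np.arange(H_star.shape[0]), labels - 1] = 1.0
    return labels, H_bin


def solve_H(
    graph: SampleGraph,
    Y: np.ndarray,
    xm: ExpressionMatrix | np.ndarray,
    F: np.ndarray,
    mu: float,
    *,
    lu: tuple | None = None,
) -> PropagationResult:
    """Closed-form propagation step for fixed F.

    Solves ``((1+mu) I - Z) H* = mu Y + X F`` as a linear system (the matrix
    is positive definite for mu > 0).  Pass a precomputed ``lu``
    factorization of the system matrix to reuse it across outer rounds.
    """
    if not mu > 0:
        raise ValidationError(f"mu must be > 0, got {mu}")
    X = xm.values if isinstance(xm, ExpressionMatrix) else np.asarray(xm, dtype=float)
    rhs = mu * Y + X @ F
    if lu is None:
        A = (1.0 + mu) * np.eye(graph.n_samples) - graph.Z
        lu = lu_factor(A)
    H_star = lu_solve(lu, rhs)
    labels, H_bin = binarize(H_star)
    return PropagationResult(H_star=H_star, H_bin=H_bin, labels=labels)


def propagation_system(graph: SampleGraph, mu: float) -> tuple:
    """LU factorization of ``(1+mu) I - Z`` for reuse across rounds."""
    A = (1.0 + mu) * np.eye(graph.n_samples) - graph.Z
    return lu_factor(A)


def lpfs_fit(
    xm: ExpressionMatrix,
    spec: LabelSpec,
    cfg: LPFSConfig,
    *,
    rng: np.random.Generator | None = None,
    graph: SampleGraph | None = None,
) -> FitResult:
    """Run the alternating solver on one expression matrix.

    Starting from H = Y, each outer round (i) minimizes the F-subproblem
    against the current indicator H (random initialization on the first
    round, warm-started afterwards), and (ii) recomputes the propagation
    H* and its binarization from the new F.  The joint objective is
    evaluated at the state passed forward (binarized H by default) and the
    loop stops when its relative change falls below ``cfg.outer_tol``.

    An outer round that empties a category (an all-zero indicator column)
    is logged as a warning: the fit continues, and downstream multi-restart
    consensus absorbs such degenerate runs.
    """
    if spec.n_samples != xm.n_samples:
        raise ValidationError(
            f"label vector length {spec.n_samples} does not match "
            f"{xm.n_samples} samples"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if graph is None:
        graph = build_sample_graph(xm, cfg.delta)
    X = xm.values
    Y = build_initial_label_matrix(spec)
    lu = propagation_system(graph, cfg.mu)

    H = Y.copy()
    trace = FitTrace()
    fsm: FeatureSelectionMatrix | None = None
    prop: PropagationResult | None = None
    for round_ix in range(cfg.outer_max_iter):
        fsm, f_trace = solve_F(
            X, H, cfg.beta,
            tol=cfg.f_tol, max_iter=cfg.f_max_iter,
            rng=rng, F0=None if fsm is None else fsm.F,
        )
        trace.f_objective.append(f_trace)
        prop = solve_H(graph, Y, X, fsm.F, cfg.mu, lu=lu)
        empty = np.flatnonzero(prop.H_bin.sum(axis=0) == 0)
        if empty.size:
            logger.warning(
                "empty categories %s after round %d; key-gene columns for "
                "them will be unstable in this run",
                (empty + 1).tolist(), round_ix + 1,
            )
        H = prop.H_bin if cfg.h_mode == "binary" else prop.H_star
        obj = objective(X, graph, H, Y, fsm.F, cfg.mu, cfg.beta)
        trace.outer_objective.append(obj)
        trace.rounds_used = round_ix + 1
        if round_ix > 0:
            prev = trace.outer_objective[-2]
            if abs(prev - obj) <= cfg.outer_tol * max(abs(prev), EPS):
                trace.converged = True
                break
    if not trace.converged:
        logger.warning(
            "outer loop did not reach tol=%.1e within %d rounds",
            cfg.outer_tol, cfg.outer_max_iter,
        )
    assert fsm is not None and prop is not None
    return FitResult(feature_selection=fsm, propagation=prop, trace=trace)
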