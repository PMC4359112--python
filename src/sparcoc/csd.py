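"""Common-background and sparse-foreground decomposition (CSD) by ADMM.

Two convex programs are solved.  The common-vector model writes a genes x
samples matrix M as

    M = x*iota + Y + Z,     minimize ||Y||_1  subject to  ||Z||_F <= delta,

where ``iota`` is the all-one row vector, so the background ``x*iota`` is a
rank-one matrix whose every column equals the vector x (the "common"
expression profile shared by all samples), Y is the sparse foreground of
sample-specific deviations, and Z absorbs noise up to Frobenius budget delta.

The multi-condition relaxation replaces the common-vector background by a
general low-rank one, shared across K condition matrices M_1..M_K:

    minimize ||X||_* + sum_i rho_i ||Y_i||_1
    subject to X + Y_i + Z_i = M_i,  ||Z_i||_F <= delta.

Both are solved by the alternating direction method of multipliers: each
primal block has a closed-form update (row means / soft-thresholding /
singular-value thresholding / ball projection), followed by a dual ascent
step on the multiplier of the coupling equality constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "CommonVectorDecomposition",
    "MultiConditionDecomposition",
    "soft_threshold",
    "project_frobenius_ball",
    "update_background",
    "singular_value_threshold",
    "decompose_common_vector",
    "decompose_multi_condition",
]


def soft_threshold(A: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise soft-thresholding, the proximal operator of tau*||.||_1.

    Returns sign(a) * max(|a| - tau, 0) for each entry a.
    """
    if tau < 0:
        raise ValueError("threshold tau must be nonnegative")
    A = np.asarray(A, dtype=float)
    return np.sign(A) * np.maximum(np.abs(A) - tau, 0.0)


def project_frobenius_ball(A: np.ndarray, delta: float) -> np.ndarray:
    """Euclidean projection of A onto the Frobenius ball of radius delta."""
    if delta < 0:
        raise ValueError("radius delta must be nonnegative")
    A = np.asarray(A, dtype=float)
    norm = np.linalg.norm(A)
    if norm <= delta:
        return A.copy()
    if delta == 0.0:
        return np.zeros_like(A)
    return A * (delta / norm)


def update_background(R: np.ndarray) -> np.ndarray:
    """Closed-form x-update of the augmented Lagrangian: row means of R.

    Minimizing (gamma/2)*||x*iota - R||_F^2 over x decouples per gene and
    gives x_i = mean_j R_ij.
    """
    R = np.asarray(R, dtype=float)
    return R.mean(axis=1)


def singular_value_threshold(A: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding, the prox of tau*||.||_* (nuclear)."""
    if tau < 0:
        raise ValueError("threshold tau must be nonnegative")
    U, s, Vt = np.linalg.svd(np.asarray(A, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


@dataclass
class CommonVectorDecomposition:
    """Solution of the common-vector model for one matrix.

    ``x`` is the per-gene background, so the rank-one background matrix is
    ``np.outer(x, np.ones(n))``; Y the sparse foreground; Z noise with
    ||Z||_F <= delta; D the Lagrange multiplier at the solution.
    """

    x: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    D: np.ndarray
    delta: float
    gamma: float
    iterations: int
    converged: bool
    primal_residual_trace: list[float] = field(default_factory=list)

    @property
    def background(self) -> np.ndarray:
        """The rank-one background matrix x*iota (every column equals x)."""
        return np.outer(self.x, np.ones(self.Y.shape[1]))

    @property
    def objective(self) -> float:
        """||Y||_1 at the solution."""
        return float(np.abs(self.Y).sum())


@dataclass
class MultiConditionDecomposition:
    """Solution of the multi-condition low-rank model."""

    X: np.ndarray
    Y_list: list[np.ndarray]
    Z_list: list[np.ndarray]
    D_list: list[np.ndarray]
    rho_list: list[float]
    delta: float
    gamma: float
    iterations: int
    converged: bool
    primal_residual_trace: list[float] = field(default_factory=list)

    @property
    def objective(self) -> float:
        """||X||_* + sum_i rho_i*||Y_i||_1 at the solution."""
        nuc = float(np.linalg.svd(self.X, compute_uv=False).sum())
        return nuc + float(
            sum(r * np.abs(Y).sum() for r, Y in zip(self.rho_list, self.Y_list))
        )


def _as_values(M) -> np.ndarray:
    if isinstance(M, ExpressionMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def default_gamma(M: np.ndarray) -> float:
    """Default ADMM penalty: 1/mean(|M_ij|), scaling prox thresholds to the data."""
    mean_abs = float(np.abs(M).mean())
    return 1.0 / mean_abs if mean_abs > 0 else 1.0


def decompose_common_vector(
    M,
    delta: float,
    gamma: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    init: CommonVectorDecomposition | None = None,
) -> CommonVectorDecomposition:
    """Solve the common-vector model by ADMM.

    Parameters
    ----------
    M
        ExpressionMatrix or array, genes as rows.
    delta
        Frobenius budget for the noise matrix Z.  With delta=0 the
        decomposition is exact: M = x*iota + Y.  If delta is as large as the
        residual of the row-mean background, Y = 0 becomes feasible (a valid
        but degenerate regime).
    gamma
        ADMM penalty parameter; default 1/mean(|M_ij|).
    tol
        Stopping tolerance: relative primal residual
        ||x*iota + Y + Z - M||_F / max(1, ||M||_F) < tol and relative change
        of ||Y||_1 < tol.
    max_iter
        Iteration cap; on exhaustion the partial result is returned with
        ``converged=False`` and a warning.
    init
        Optional warm start (a previous decomposition of a similar matrix).

    Notes
    -----
    The augmented Lagrangian is
    ``||Y||_1 - <D, x*iota+Y+Z-M> + (gamma/2)||x*iota+Y+Z-M||_F^2`` and the
    blocks are minimized in the order x, Y, Z followed by the multiplier
    step ``D <- D - gamma*(x*iota+Y+Z-M)``.  All updates are closed-form:
    x by row means, Y by soft-thresholding at 1/gamma, Z by projection onto
    the delta-ball.  Initialization Y=Z=D=0 makes the solver deterministic.
    """
    M = _as_values(M)
    if not np.all(np.isfinite(M)):
        raise ValueError("M contains non-finite entries")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    m, n = M.shape
    if gamma is None:
        gamma = default_gamma(M)
    if gamma <= 0:
        raise ValueError("gamma must be positive")

    if init is not None:
        Y, Z, D = init.Y.copy(), init.Z.copy(), init.D.copy()
    else:
        Y = np.zeros_like(M)
        Z = np.zeros_like(M)
        D = np.zeros_like(M)

    norm_M = max(1.0, float(np.linalg.norm(M)))
    trace: list[float] = []
    prev_l1 = np.inf
    converged = False
    x = M.mean(axis=1)
    it = 0
    for it in range(1, max_iter + 1):
        x = update_background(M - Y - Z + D / gamma)
        bg = x[:, None]  # broadcasts as x*iota
        Y = soft_threshold(M - bg - Z + D / gamma, 1.0 / gamma)
        if delta == 0.0:
            Z.fill(0.0)
        else:
            Z = project_frobenius_ball(M - bg - Y + D / gamma, delta)
        residual_mat = bg + Y + Z - M
        D = D - gamma * residual_mat
        residual = float(np.linalg.norm(residual_mat))
        trace.append(residual)
        l1 = float(np.abs(Y).sum())
        rel_change = abs(l1 - prev_l1) / max(1.0, l1)
        prev_l1 = l1
        if residual / norm_M < tol and rel_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"common-vector ADMM did not converge in {max_iter} iterations "
            f"(relative residual {trace[-1] / norm_M:.2e})"
        )
    return CommonVectorDecomposition(
        x=x, Y=Y, Z=Z, D=D, delta=float(delta), gamma=float(gamma),
        iterations=it, converged=converged, primal_residual_trace=trace,
    )


def decompose_multi_condition(
    M_list,
    rho_list,
    delta: float,
    gamma: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    common_vector: bool = False,
) -> MultiConditionDecomposition:
    """Solve the multi-condition low-rank model by ADMM.

    All condition matrices must share shape and gene/sample ordering.  The
    shared background X is updated by singular-value thresholding (nuclear
    prox), each Y_i by soft-thresholding at rho_i/gamma, each Z_i by ball
    projection, with one multiplier per condition.

    With ``common_vector=True`` the background is constrained to the
    common-vector form X = x*iota (the nuclear term drops out, the X-update
    becomes a row-mean update); at K=1 this reproduces
    :func:`decompose_common_vector` exactly.
    """
    mats = [_as_values(M) for M in M_list]
    K = len(mats)
    if K < 1:
        raise ValueError("need at least one condition matrix")
    shape = mats[0].shape
    for i, A in enumerate(mats):
        if A.shape != shape:
            raise ValueError(
                f"condition {i} has shape {A.shape}, expected {shape}"
            )
        if not np.all(np.isfinite(A)):
            raise ValueError(f"condition {i} contains non-finite entries")
    rho_list = [float(r) for r in np.atleast_1d(rho_list)]
    if len(rho_list) == 1 and K > 1:
        rho_list = rho_list * K
    if len(rho_list) != K or any(r <= 0 for r in rho_list):
        raise ValueError("need one positive rho per condition")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if gamma is None:
        gamma = default_gamma(np.stack(mats))
    if gamma <= 0:
        raise ValueError("gamma must be positive")

    Y_list = [np.zeros(shape) for _ in range(K)]
    Z_list = [np.zeros(shape) for _ in range(K)]
    D_list = [np.zeros(shape) for _ in range(K)]
    X = np.zeros(shape)

    norm_all = max(1.0, float(np.sqrt(sum(np.linalg.norm(A) ** 2 for A in mats))))
    trace: list[float] = []
    prev_obj = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # X-update: prox of ||.||_* / (K*gamma) at the mean of the K targets
        R_mean = np.mean(
            [M - Y - Z + D / gamma
             for M, Y, Z, D in zip(mats, Y_list, Z_list, D_list)],
            axis=0,
        )
        if common_vector:
            X = np.repeat(update_background(R_mean)[:, None], shape[1], axis=1)
        else:
            X = singular_value_threshold(R_mean, 1.0 / (K * gamma))
        sq_res = 0.0
        obj = 0.0 if common_vector else float(
            np.linalg.svd(X, compute_uv=False).sum()
        )
        for i in range(K):
            Y_list[i] = soft_threshold(
                mats[i] - X - Z_list[i] + D_list[i] / gamma, rho_list[i] / gamma
            )
            if delta == 0.0:
                Z_list[i].fill(0.0)
            else:
                Z_list[i] = project_frobenius_ball(
                    mats[i] - X - Y_list[i] + D_list[i] / gamma, delta
                )
            residual_mat = X + Y_list[i] + Z_list[i] - mats[i]
            D_list[i] = D_list[i] - gamma * residual_mat
            sq_res += float(np.linalg.norm(residual_mat)) ** 2
            obj += rho_list[i] * float(np.abs(Y_list[i]).sum())
        residual = float(np.sqrt(sq_res))
        trace.append(residual)
        rel_change = abs(obj - prev_obj) / max(1.0, obj)
        prev_obj = obj
        if residual / norm_all < tol and rel_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"multi-condition ADMM did not converge in {max_iter} iterations "
            f"(relative residual {trace[-1] / norm_all:.2e})"
        )
    return MultiConditionDecomposition(
        X=X, Y_list=Y_list, Z_list=Z_list, D_list=D_list,
        rho_list=rho_list, delta=float(delta), gamma=float(gamma),
        iterations=it, converged=converged, primal_residual_trace=trace,
    )
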