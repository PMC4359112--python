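"""Independent oracles used by the test suite.

Everything here deliberately avoids the library's own code paths: generic
scipy optimizers, closed forms, exhaustive enumeration, and direct textbook
formulas, so agreement with the package is evidence of correctness rather
than self-confirmation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, NonlinearConstraint, minimize


def l1_common_vector_optimum(M: np.ndarray) -> float:
    """Exact optimum of min_x ||M - x*iota||_1: per-row medians (delta=0)."""
    x = np.median(M, axis=1)
    return float(np.abs(M - x[:, None]).sum())


def solve_common_vector_program(M: np.ndarray, delta: float) -> float:
    """Optimal ||Y||_1 of the common-vector program by a generic solver.

    For delta=0 the constraint eliminates Y and the optimum is attained at
    per-row medians.  For delta>0 the program is recast with epigraph
    variables t >= |Y| and solved by scipy's trust-constr:

        min sum(t)  s.t.  -t <= Y <= t,  ||M - x*iota - Y||_F^2 <= delta^2.
    """
    if delta == 0:
        return l1_common_vector_optimum(M)
    m, n = M.shape
    mn = m * n

    def unpack(z):
        return z[:m], z[m:m + mn].reshape(m, n)

    grad = np.concatenate([np.zeros(m + mn), np.ones(mn)])
    I = sparse.identity(mn)
    Z0 = sparse.csr_matrix((mn, m))
    A = sparse.vstack(
        [sparse.hstack([Z0, I, -I]), sparse.hstack([Z0, -I, -I])]
    ).tocsr()
    lin = LinearConstraint(A, -np.inf, 0.0)

    def residual(z):
        x, Y = unpack(z)
        return M - x[:, None] - Y

    def con_f(z):
        return float((residual(z) ** 2).sum())

    def con_j(z):
        R = residual(z)
        return sparse.csr_matrix(
            np.concatenate([-2.0 * R.sum(axis=1), -2.0 * R.ravel(),
                            np.zeros(mn)])[None, :]
        )

    nonlin = NonlinearConstraint(con_f, -np.inf, delta**2, jac=con_j)
    x0 = np.median(M, axis=1)
    Y0 = M - x0[:, None]
    z0 = np.concatenate([x0, Y0.ravel(), np.abs(Y0).ravel() + 1e-3])
    res = minimize(
        lambda z: z[m + mn:].sum(), z0, jac=lambda z: grad,
        constraints=[lin, nonlin], method="trust-constr",
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=3000),
    )
    _, Y = unpack(res.x)
    return float(np.abs(Y).sum())


def multi_condition_duality_gap(result, mats) -> float:
    """Relative duality gap certificate for the low-rank program.

    The Lagrange dual of  min ||X||_* + sum_i rho_i ||Y_i||_1  subject to
    X + Y_i + Z_i = M_i, ||Z_i||_F <= delta  is

        max sum_i <L_i, M_i> - delta * sum_i ||L_i||_F
        s.t. ||sum_i L_i||_2 <= 1,  max|L_i| <= rho_i.

    Scaling the solver's multipliers into the dual-feasible set gives a
    lower bound on the optimum; the primal objective is an upper bound.
    """
    D = result.D_list
    rho = result.rho_list
    s = max(1.0, float(np.linalg.norm(sum(D), 2)))
    s = max(s, *[float(np.abs(Di).max()) / r for Di, r in zip(D, rho)])
    lam = [Di / s for Di in D]
    dual = sum(float((L * M).sum()) for L, M in zip(lam, mats))
    dual -= result.delta * sum(float(np.linalg.norm(L)) for L in lam)
    primal = result.objective
    return (primal - dual) / max(1.0, primal)


def nuclear_prox_certificate(A: np.ndarray, X: np.ndarray, tau: float) -> float:
    """Violation of the optimality condition for X = prox of tau*||.||_*.

    X minimizes tau*||X||_* + 0.5*||X - A||_F^2 iff G = A - X satisfies
    ||G||_2 <= tau and <G, X> = tau*||X||_*.  Returns the larger of the two
    violations (0 at the optimum).
    """
    G = A - X
    spectral = max(0.0, float(np.linalg.norm(G, 2)) - tau)
    nuc = float(np.linalg.svd(X, compute_uv=False).sum())
    alignment = abs(float((G * X).sum()) - tau * nuc)
    return max(spectral, alignment)


def block_mean_brute(A, row_labels, col_labels, k1, k2) -> np.ndarray:
    """Block centroids by explicit enumeration of block members."""
    core = np.zeros((k1, k2))
    for g in range(1, k1 + 1):
        for h in range(1, k2 + 1):
            vals = [
                A[i, j]
                for i in range(A.shape[0]) if row_labels[i] == g
                for j in range(A.shape[1]) if col_labels[j] == h
            ]
            core[g - 1, h - 1] = np.mean(vals) if vals else 0.0
    return core


def cocluster_objective_brute(A, row_labels, col_labels, core) -> float:
    """Objective by a plain double loop."""
    total = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            total += (A[i, j] - core[row_labels[i] - 1, col_labels[j] - 1]) ** 2
    return total


def exhaustive_cocluster_optimum(A: np.ndarray, k1: int, k2: int) -> float:
    """Global optimum over every (row, column) labeling, optimal core each."""
    m, n = A.shape
    best = np.inf
    for rl in itertools.product(range(1, k1 + 1), repeat=m):
        rl = np.array(rl)
        for cl in itertools.product(range(1, k2 + 1), repeat=n):
            cl = np.array(cl)
            core = block_mean_brute(A, rl, cl, k1, k2)
            best = min(best, cocluster_objective_brute(A, rl, cl, core))
    return best


def coassignment_brute(labelings) -> np.ndarray:
    """Pairwise co-assignment fractions by explicit pair counting."""
    n = len(labelings[0])
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = np.mean([lab[i] == lab[j] for lab in labelings])
    return C


def km_product_limit(time, event):
    """Textbook product-limit estimate at each distinct event time.

    Returns (event_times, survival_just_after_each).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    event_times = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return event_times, np.array(surv)
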