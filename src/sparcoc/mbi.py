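"""Checkerboard co-clustering by Maximum Block Improvement (MBI).

The model partitions the m rows of a matrix A into k1 groups and its n
columns into k2 groups, approximating A by a k1 x k2 grid of constant
blocks (the "core" matrix of block centroids) and minimizing the total
squared deviation

    sum_ij ( A_ij - core[row_group(i), col_group(j)] )^2 .

The formulation is exact: if A is exactly blockwise constant under some
labeling, the optimum value is zero.  MBI is a block-coordinate scheme over
three variable blocks -- all row labels, all column labels, the core -- that
at each step evaluates the improvement available from re-optimizing each
block alone (the others fixed) and commits only the block with the maximum
objective decrease, which makes the committed objective sequence
monotonically nonincreasing.  When no whole block improves, the search is
refined with maximum-improvement single-label moves (one row or column at a
time, the core profiled out), which escapes coarse-block local optima at
negligible cost; every committed move still decreases the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoClustering",
    "compute_block_centroids",
    "cocluster_objective",
    "mbi_cocluster",
    "best_of_restarts",
    "local_search_dims",
]

_IMPROVEMENT_EPS = 1e-12


@dataclass
class CoClustering:
    """A checkerboard co-clustering.

    Row labels take values in 1..k1, column labels in 1..k2 (1-based, the
    convention used in all user-facing output).  ``core`` holds the block
    centroids; ``objective`` the total squared deviation from them.
    """

    row_labels: np.ndarray
    col_labels: np.ndarray
    core: np.ndarray
    objective: float
    k1: int
    k2: int
    proximity: str = "squared_error"
    objective_trace: list[float] = field(default_factory=list)

    def row_groups(self) -> list[np.ndarray]:
        """0-based row indices of each of the k1 row groups."""
        return [np.flatnonzero(self.row_labels == g + 1) for g in range(self.k1)]

    def col_groups(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.col_labels == h + 1) for h in range(self.k2)]


def _check_labels(labels: np.ndarray, k: int, size: int, what: str) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size != size:
        raise ValueError(f"{what}: expected {size} labels, got {labels.size}")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"{what}: labels must lie in 1..{k}")
    return labels


def compute_block_centroids(
    A: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray, k1: int, k2: int
) -> np.ndarray:
    """Mean of each (row-group, column-group) block; empty blocks get 0."""
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    row_labels = _check_labels(row_labels, k1, m, "row_labels")
    col_labels = _check_labels(col_labels, k2, n, "col_labels")
    R = np.zeros((k1, m))
    R[row_labels - 1, np.arange(m)] = 1.0
    C = np.zeros((n, k2))
    C[np.arange(n), col_labels - 1] = 1.0
    sums = R @ A @ C
    counts = np.outer(R.sum(axis=1), C.sum(axis=0))
    core = np.zeros((k1, k2))
    nonempty = counts > 0
    core[nonempty] = sums[nonempty] / counts[nonempty]
    return core


def cocluster_objective(A: np.ndarray, clustering: CoClustering) -> float:
    """Total squared deviation of A from its assigned block centroids."""
    A = np.asarray(A, dtype=float)
    r = _check_labels(clustering.row_labels, clustering.k1, A.shape[0], "row_labels")
    c = _check_labels(clustering.col_labels, clustering.k2, A.shape[1], "col_labels")
    fitted = clustering.core[np.ix_(r - 1, c - 1)]
    return float(((A - fitted) ** 2).sum())


def _objective(A, row_labels, col_labels, core) -> float:
    fitted = core[np.ix_(row_labels - 1, col_labels - 1)]
    return float(((A - fitted) ** 2).sum())


def _best_row_assignment(A, col_labels, core, k1, k2):
    """Best group per row given column labels and core (rows decouple)."""
    n = A.shape[1]
    C = np.zeros((n, k2))
    C[np.arange(n), col_labels - 1] = 1.0
    counts = C.sum(axis=0)                      # column-group sizes
    T = A @ C                                   # m x k2 block row-sums
    s2 = (A**2).sum(axis=1)                     # per-row constant term
    quad = (core**2 * counts).sum(axis=1)       # k1
    cost = s2[:, None] - 2.0 * (T @ core.T) + quad[None, :]
    best = np.argmin(cost, axis=1) + 1          # ties -> lowest group index
    return best, cost[np.arange(A.shape[0]), best - 1].sum()


def _polish_single_moves(A, row_labels, col_labels, k1, k2, max_moves=10_000):
    """Maximum-improvement single-label moves with the core profiled out.

    Whole-block updates can stall at points where no block alone improves
    but moving one row or column (with the core re-optimized afterwards)
    would.  With squared error the optimal core given labels is the block
    mean, so the profiled objective is

        sum(A^2) - sum_gh S[g,h]^2 / N[g,h]

    with S the block sums and N the block sizes; a single-label move touches
    only two rows (or columns) of S, so each candidate costs O(k).  Moves
    that would empty their source group are skipped.  Returns the labels,
    the profiled objective, and the list of committed objectives.
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    row_labels = row_labels.copy()
    col_labels = col_labels.copy()
    ss_total = float((A**2).sum())

    Cind = np.zeros((n, k2))
    Cind[np.arange(n), col_labels - 1] = 1.0
    Rind = np.zeros((m, k1))
    Rind[np.arange(m), row_labels - 1] = 1.0
    T = A @ Cind              # m x k2: per-row sums over column groups
    U = A.T @ Rind            # n x k1: per-column sums over row groups
    S = Rind.T @ T            # k1 x k2 block sums
    rcount = Rind.sum(axis=0)
    ccount = Cind.sum(axis=0)

    def total_fit():
        N = np.outer(rcount, ccount)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(N > 0, S**2 / np.where(N > 0, N, 1), 0.0).sum()

    def _move_gains(S, T, src_count, dst_count, inv_other, labels0, fit_rows):
        """Vectorized gains for moving each item (rows of T) between the
        groups indexing S's rows; columns weighted by inv_other."""
        q = (S**2 * inv_other[None, :]).sum(axis=1)          # per-group sum
        p = (T**2 * inv_other[None, :]).sum(axis=1)          # per-item
        C = T @ (S * inv_other[None, :]).T                   # item x group
        src = labels0
        num_remove = q[src] - 2 * C[np.arange(T.shape[0]), src] + p
        num_add = q[None, :] + 2 * C + p[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            new_src = np.where(src_count[src] > 1,
                               num_remove / np.maximum(src_count[src] - 1, 1), np.nan)
            new_dst = num_add / (dst_count[None, :] + 1)
        gains = new_src[:, None] + new_dst - fit_rows[src][:, None] - fit_rows[None, :]
        gains[np.arange(T.shape[0]), src] = -np.inf          # no-op moves
        gains[src_count[src] <= 1, :] = -np.inf              # would empty source
        return gains

    obj = ss_total - total_fit()
    trace: list[float] = []
    for _ in range(max_moves):
        inv_c = 1.0 / np.maximum(ccount, 1)
        inv_r = 1.0 / np.maximum(rcount, 1)
        fit_row_groups = (S**2 * inv_c[None, :]).sum(axis=1) * inv_r
        fit_col_groups = (S**2 * inv_r[:, None]).sum(axis=0) * inv_c
        row_gains = _move_gains(S, T, rcount, rcount, inv_c,
                                row_labels - 1, fit_row_groups)
        col_gains = _move_gains(S.T, U, ccount, ccount, inv_r,
                                col_labels - 1, fit_col_groups)
        best_row = np.unravel_index(np.argmax(row_gains), row_gains.shape)
        best_col = np.unravel_index(np.argmax(col_gains), col_gains.shape)
        if row_gains[best_row] >= col_gains[best_col]:
            best_gain = row_gains[best_row]
            best_move = ("row", int(best_row[0]), int(best_row[1]))
        else:
            best_gain = col_gains[best_col]
            best_move = ("col", int(best_col[0]), int(best_col[1]))
        if not np.isfinite(best_gain) or best_gain <= _IMPROVEMENT_EPS:
            break
        kind, idx, tgt = best_move
        if kind == "row":
            g0 = row_labels[idx] - 1
            S[g0] -= T[idx]
            S[tgt] += T[idx]
            U[:, g0] -= A[idx]
            U[:, tgt] += A[idx]
            rcount[g0] -= 1
            rcount[tgt] += 1
            row_labels[idx] = tgt + 1
        else:
            h0 = col_labels[idx] - 1
            S[:, h0] -= U[idx]
            S[:, tgt] += U[idx]
            T[:, h0] -= A[:, idx]
            T[:, tgt] += A[:, idx]
            ccount[h0] -= 1
            ccount[tgt] += 1
            col_labels[idx] = tgt + 1
        obj = ss_total - total_fit()
        trace.append(obj)
    return row_labels, col_labels, obj, trace


def _repair_empty(labels: np.ndarray, k: int, residuals: np.ndarray) -> np.ndarray:
    """Move the worst-fit item into each empty group, keeping k honest."""
    labels = labels.copy()
    for g in range(1, k + 1):
        if not np.any(labels == g):
            order = np.argsort(-residuals)
            for idx in order:
                # do not empty another group by moving its only member
                if np.count_nonzero(labels == labels[idx]) > 1:
                    labels[idx] = g
                    residuals[idx] = -np.inf
                    break
    return labels


def mbi_cocluster(
    A: np.ndarray,
    k1: int,
    k2: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
) -> CoClustering:
    """Co-cluster A into k1 row groups x k2 column groups by MBI.

    Starting from uniform random labels drawn from ``seed``, each sweep
    evaluates three candidate moves -- re-optimize all row labels, all
    column labels, or the core, with the other blocks fixed -- and commits
    the one with the largest objective decrease.  Terminates when no block
    improves the objective by more than 1e-12, or at ``max_iter`` committed
    updates.  A group left empty by an update is repaired by moving the
    worst-fit row/column into it.
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    if not (1 <= k1 <= m):
        raise ValueError(f"k1 must be in 1..{m}, got {k1}")
    if not (1 <= k2 <= n):
        raise ValueError(f"k2 must be in 1..{n}, got {k2}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # random init covering every group at least once when possible
    row_labels = np.concatenate(
        [np.arange(1, k1 + 1), rng.integers(1, k1 + 1, size=m - k1)]
    )
    rng.shuffle(row_labels)
    col_labels = np.concatenate(
        [np.arange(1, k2 + 1), rng.integers(1, k2 + 1, size=n - k2)]
    )
    rng.shuffle(col_labels)
    core = compute_block_centroids(A, row_labels, col_labels, k1, k2)
    obj = _objective(A, row_labels, col_labels, core)
    trace = [obj]

    for _outer in range(max_iter):
        row_labels, col_labels, core, obj = _block_phase(
            A, row_labels, col_labels, core, obj, k1, k2, max_iter, trace
        )
        # refine: maximum-improvement single-label moves with profiled core;
        # escapes points where no whole block alone improves
        row_labels, col_labels, pol_obj, pol_trace = _polish_single_moves(
            A, row_labels, col_labels, k1, k2
        )
        trace.extend(pol_trace)
        core = compute_block_centroids(A, row_labels, col_labels, k1, k2)
        new_obj = _objective(A, row_labels, col_labels, core)
        if new_obj >= obj - _IMPROVEMENT_EPS:
            obj = min(obj, new_obj)
            break
        obj = new_obj

    return CoClustering(
        row_labels=row_labels, col_labels=col_labels, core=core,
        objective=obj, k1=k1, k2=k2, objective_trace=trace,
    )


def _block_phase(A, row_labels, col_labels, core, obj, k1, k2, max_iter, trace):
    """Whole-block maximum-improvement loop (row labels / col labels / core)."""
    for _ in range(max_iter):
        # candidate 1: re-optimize all row labels (repair empty groups first,
        # so the improvement comparison sees the objective actually committed)
        cand_rows, _ = _best_row_assignment(A, col_labels, core, k1, k2)
        if np.unique(cand_rows).size < k1:
            fitted = core[np.ix_(cand_rows - 1, col_labels - 1)]
            cand_rows = _repair_empty(cand_rows, k1, ((A - fitted) ** 2).sum(axis=1))
        obj_rows = _objective(A, cand_rows, col_labels, core)
        # candidate 2: re-optimize all column labels (transpose symmetry)
        cand_cols, _ = _best_row_assignment(A.T, row_labels, core.T, k2, k1)
        if np.unique(cand_cols).size < k2:
            fitted = core[np.ix_(row_labels - 1, cand_cols - 1)]
            cand_cols = _repair_empty(cand_cols, k2, ((A - fitted) ** 2).sum(axis=0))
        obj_cols = _objective(A, row_labels, cand_cols, core)
        # candidate 3: re-optimize the core
        cand_core = compute_block_centroids(A, row_labels, col_labels, k1, k2)
        obj_core = _objective(A, row_labels, col_labels, cand_core)

        improvements = np.array([obj - obj_rows, obj - obj_cols, obj - obj_core])
        best = int(np.argmax(improvements))
        if improvements[best] <= _IMPROVEMENT_EPS:
            break
        if best == 0:
            row_labels, obj = cand_rows, obj_rows
        elif best == 1:
            col_labels, obj = cand_cols, obj_cols
        else:
            core, obj = cand_core, obj_core
        trace.append(obj)
    return row_labels, col_labels, core, obj


def best_of_restarts(
    A: np.ndarray,
    k1: int,
    k2: int,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[CoClustering, list[CoClustering]]:
    """Run MBI from ``restarts`` random initializations; keep the best.

    Returns ``(best, all_runs)`` so callers can feed every run into the
    consensus step.
    """
    if restarts < 1:
        raise ValueError("need at least one restart")
    ss = np.random.SeedSequence(seed)
    runs = [
        mbi_cocluster(A, k1, k2, seed=np.random.default_rng(child), max_iter=max_iter)
        for child in ss.spawn(restarts)
    ]
    best = min(runs, key=lambda r: r.objective)
    return best, runs


def _penalized(A, k1, k2, restarts, seed, max_iter) -> tuple[float, CoClustering]:
    best, _ = best_of_restarts(A, k1, k2, restarts=restarts, seed=seed,
                               max_iter=max_iter)
    m, n = A.shape
    penalty = np.log(m * n) * k1 * k2
    return best.objective + penalty, best


def local_search_dims(
    A: np.ndarray,
    k1_range,
    k2_range,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[int, int, CoClustering]:
    """Hill-climb over the (k1, k2) grid to pick the block-grid dimensions.

    Each candidate pair is scored by the best-of-restarts objective plus a
    complexity penalty log(m*n) * k1 * k2 (a BIC-style charge per block, a
    heuristic: the model itself offers no dimension-selection rule).  Moves
    are +/-1 in either or both coordinates; the search starts from the
    smallest pair and stops at a local minimum of the penalized score.
    """
    A = np.asarray(A, dtype=float)
    k1s = sorted(set(int(k) for k in k1_range))
    k2s = sorted(set(int(k) for k in k2_range))
    if not k1s or not k2s:
        raise ValueError("empty dimension range")

    cache: dict[tuple[int, int], tuple[float, CoClustering]] = {}

    def score(k1: int, k2: int):
        if (k1, k2) not in cache:
            cache[(k1, k2)] = _penalized(A, k1, k2, restarts, seed, max_iter)
        return cache[(k1, k2)]

    current = (k1s[0], k2s[0])
    current_score, _ = score(*current)
    while True:
        neighbors = [
            (current[0] + d1, current[1] + d2)
            for d1 in (-1, 0, 1)
            for d2 in (-1, 0, 1)
            if (d1, d2) != (0, 0)
            and (current[0] + d1) in k1s
            and (current[1] + d2) in k2s
        ]
        best_nb, best_nb_score = None, current_score
        for nb in neighbors:
            s, _ = score(*nb)
            if s < best_nb_score - _IMPROVEMENT_EPS:
                best_nb, best_nb_score = nb, s
        if best_nb is None:
            break
        current, current_score = best_nb, best_nb_score
    _, clustering = score(*current)
    return current[0], current[1], clustering
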