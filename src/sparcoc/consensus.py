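"""Consensus over stochastic co-clustering runs.

MBI starts from random labels, so repeated runs on the same matrix may
assign samples differently.  The consensus (co-assignment) matrix records,
for every pair of samples, the fraction of runs that placed them in the same
column group; samples of a genuine subtype should co-assign in nearly every
run.  Final clusters are cut from the co-assignment matrix by average-linkage
hierarchical clustering on the dissimilarity 1 - C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mbi import CoClustering, best_of_restarts

__all__ = [
    "ConsensusResult",
    "consensus_matrix",
    "consensus_labels",
    "cluster_stability",
    "consensus_cocluster",
]


@dataclass
class ConsensusResult:
    """Co-assignment frequencies and the consensus sample clusters."""

    coassignment: np.ndarray
    final_labels: np.ndarray
    n_runs: int
    stability: float


def consensus_matrix(labelings: list[np.ndarray]) -> np.ndarray:
    """Fraction of labelings assigning each pair of samples the same label.

    Symmetric n x n with unit diagonal; a single labeling yields its exact
    co-membership indicator matrix.
    """
    if len(labelings) == 0:
        raise ValueError("need at least one labeling")
    arrs = [np.asarray(lab) for lab in labelings]
    n = arrs[0].size
    for a in arrs:
        if a.size != n:
            raise ValueError("labelings have unequal lengths")
    C = np.zeros((n, n))
    for a in arrs:
        C += (a[:, None] == a[None, :]).astype(float)
    return C / len(arrs)


def cluster_stability(C: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-cluster co-assignment frequency (1.0 = perfectly stable).

    Averages C_ij over all unordered pairs i<j sharing a label; clusters
    that are singletons contribute nothing.  Returns 1.0 if no cluster has
    two members.
    """
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    mask = same[iu]
    if not mask.any():
        return 1.0
    return float(np.asarray(C)[iu][mask].mean())


def consensus_labels(C: np.ndarray, k: int) -> np.ndarray:
    """Cut average-linkage hierarchical clustering of 1 - C into k groups."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if n == 1:
        return np.array([1])
    dist = 1.0 - C
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # symmetrize away float asymmetry
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cocluster(
    A: np.ndarray,
    k1: int,
    k2: int,
    n_runs: int = 10,
    seed: int = 0,
    stability_threshold: float = 0.8,
    max_iter: int = 500,
) -> tuple[ConsensusResult, CoClustering, list[CoClustering]]:
    """Run MBI ``n_runs`` times and build the sample consensus.

    Returns the consensus over column (sample) labelings, the single best
    run by objective, and every run; callers choosing the best run by an
    external criterion (e.g. a survival comparison) have all runs available.
    A consensus with ``stability`` at or above ``stability_threshold``
    (default 0.8) is conventionally called consistent.
    """
    best, runs = best_of_restarts(A, k1, k2, restarts=n_runs, seed=seed,
                                  max_iter=max_iter)
    C = consensus_matrix([r.col_labels for r in runs])
    labels = consensus_labels(C, k2)
    result = ConsensusResult(
        coassignment=C,
        final_labels=labels,
        n_runs=n_runs,
        stability=cluster_stability(C, labels),
    )
    return result, best, runs
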