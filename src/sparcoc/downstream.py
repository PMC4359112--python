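"""Signature discovery and validation steps downstream of co-clustering.

Given sample clusters, genes separating the clusters are selected by
per-gene Welch t-tests at a raw p-value cutoff (no multiple-testing
correction: the selection is a screening step whose output is validated on
independent cohorts, not an inference).  Signatures from independent cohorts
are intersected; samples of a new cohort are assigned to the training class
whose per-gene mean centroid is nearest in squared error; and survival of
the resulting groups is compared by Kaplan-Meier curves and the log-rank
test (see :mod:`sparcoc.survival`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .survival import (  # noqa: F401  (re-exported: the survival steps live here too)
    KaplanMeierCurve,
    SurvivalTable,
    km_estimate,
    logrank_test,
    truncate_survival,
)

__all__ = [
    "GeneSignature",
    "differential_genes",
    "intersect_signatures",
    "filter_signature",
    "least_squares_classify",
    "SurvivalTable",
    "km_estimate",
    "logrank_test",
    "truncate_survival",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    """Genes differentially expressed between two sample groups."""

    gene_ids: list[str]
    t_stats: np.ndarray
    p_values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.t_stats = np.asarray(self.t_stats, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not (len(self.gene_ids) == self.t_stats.size == self.p_values.size):
            raise ValueError("gene_ids, t_stats, p_values must be aligned")

    def __len__(self) -> int:
        return len(self.gene_ids)


def differential_genes(
    M: ExpressionMatrix, labels: np.ndarray, alpha: float = 0.01,
    source: str = "",
) -> GeneSignature:
    """Per-gene Welch two-sample t-test between the two label groups.

    Returns the genes with p < ``alpha`` (default 0.01, raw, uncorrected).
    Genes with zero variance in both groups have no defined t statistic;
    they are excluded and counted in a log message.  Both groups must have
    at least two samples.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two sample groups, got {groups.size}")
    mask = labels == groups[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least two samples for a t-test")
    A = M.values[:, mask]
    B = M.values[:, ~mask]
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    if degenerate.any():
        logger.info(
            "differential_genes: excluded %d gene(s) with zero variance in "
            "both groups", int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    keep = ~degenerate & np.isfinite(p) & (p < alpha)
    idx = np.flatnonzero(keep)
    return GeneSignature(
        gene_ids=[M.gene_ids[i] for i in idx],
        t_stats=t[idx],
        p_values=p[idx],
        source=source,
    )


def intersect_signatures(sigs: list[GeneSignature]) -> list[str]:
    """Genes present in every signature, in the first signature's order."""
    if len(sigs) < 2:
        raise ValueError("need at least two signatures to intersect")
    common = set(sigs[0].gene_ids)
    for sig in sigs[1:]:
        common &= set(sig.gene_ids)
    return [g for g in sigs[0].gene_ids if g in common]


def filter_signature(gene_ids: list[str], allowed: list[str]) -> list[str]:
    """Restrict a gene list to a user-supplied allow-list (order preserved).

    Generic id filtering, e.g. against a curated cancer-gene catalogue the
    user provides; no catalogue is bundled.
    """
    allowed_set = set(allowed)
    return [g for g in gene_ids if g in allowed_set]


def least_squares_classify(
    train: ExpressionMatrix,
    train_labels: np.ndarray,
    test: ExpressionMatrix,
) -> np.ndarray:
    """Assign each test sample to the nearest training-class centroid.

    The score of class c for sample s is the sum over genes of squared
    differences between the sample and the class's per-gene mean; the class
    minimizing it is assigned.  Ties break to the lowest class label.  Train
    and test must carry identical, identically ordered gene sets.
    """
    if train.gene_ids != test.gene_ids:
        raise ValueError("train and test gene sets must be identical and aligned")
    labels = np.asarray(train_labels)
    classes = np.unique(labels)
    if classes.size < 1:
        raise ValueError("no training classes")
    centroids = np.stack(
        [train.values[:, labels == c].mean(axis=1) for c in classes], axis=1
    )  # genes x classes
    # squared distance of every test sample to every centroid
    diffs = test.values[:, :, None] - centroids[:, None, :]
    scores = (diffs**2).sum(axis=0)  # samples x classes
    best = np.argmin(scores, axis=1)  # argmin takes the first (lowest) on ties
    return classes[best]
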