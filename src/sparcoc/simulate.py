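"""Synthetic planted-structure expression matrices.

Two generators:

* :func:`generate_fig1_toy` builds the 20x20 worked example that motivates
  the whole pipeline: a positive rank-one background (entries spanning
  roughly 1..100) plus a single 5x5 foreground block of constant value 10 at
  rows 10-14 x columns 10-14 (1-based).  The sum is exactly rank two, and
  the common-vector decomposition with delta=0 recovers both parts exactly.

* :func:`generate_planted` generalizes this: a low-rank background, a full
  k1 x k2 checkerboard of block effects on balanced random row/column
  partitions, and optional i.i.d. Gaussian noise, with ground-truth labels
  returned for recovery benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["PlantedInstance", "generate_fig1_toy", "generate_planted"]

# 0-based half-open slices of the toy foreground block (rows/cols 10-14, 1-based)
TOY_BLOCK_ROWS = slice(9, 14)
TOY_BLOCK_COLS = slice(9, 14)
TOY_BLOCK_VALUE = 10.0


@dataclass
class PlantedInstance:
    """A generated matrix together with its planted ground truth."""

    M: ExpressionMatrix
    background: np.ndarray
    foreground: np.ndarray
    noise_sd: float
    row_truth: np.ndarray
    col_truth: np.ndarray
    seed: int


def generate_fig1_toy(seed: int = 0) -> PlantedInstance:
    """The 20x20 rank-one-background + 5x5-block worked example.

    The background is of the common-vector form x*iota: every sample
    (column) carries the same random per-gene level x, drawn uniformly and
    affinely rescaled so the entries span exactly [1, 100].  Such a matrix
    is rank one, and it is the background structure the common-vector
    decomposition models, so exact recovery at delta=0 is attainable.  The
    foreground is 10 on rows 10-14 x columns 10-14 (1-based) and 0
    elsewhere; there is no noise, so M = background + foreground has rank
    exactly two.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=20)
    x = 1.0 + 99.0 * (x - x.min()) / (x.max() - x.min())
    background = np.outer(x, np.ones(20))
    foreground = np.zeros((20, 20))
    foreground[TOY_BLOCK_ROWS, TOY_BLOCK_COLS] = TOY_BLOCK_VALUE
    row_truth = np.ones(20, dtype=int)
    row_truth[TOY_BLOCK_ROWS] = 2
    col_truth = np.ones(20, dtype=int)
    col_truth[TOY_BLOCK_COLS] = 2
    M = ExpressionMatrix(background + foreground)
    return PlantedInstance(
        M=M, background=background, foreground=foreground, noise_sd=0.0,
        row_truth=row_truth, col_truth=col_truth, seed=seed,
    )


def _balanced_partition(size: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into k groups of near-equal size; labels 1..k."""
    labels = 1 + (np.arange(size) % k)
    rng.shuffle(labels)
    return labels


def generate_planted(
    m: int,
    n: int,
    k1: int,
    k2: int,
    background_rank: int = 1,
    block_effects=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    common_background: bool = True,
) -> PlantedInstance:
    """A planted checkerboard on a low-rank background.

    Rows/columns get balanced random partitions into k1/k2 groups; the
    foreground entry of cell (i, j) is ``block_effects[g(i)-1, h(j)-1]``
    (default: 10 on the (1,1) block, 0 elsewhere, the toy example's
    contrast), and i.i.d. Gaussian noise of sd ``noise_sd`` is added on top.

    With ``common_background=True`` (default, requires background_rank <= 1)
    the background is a common-vector matrix x*iota: each gene has one
    baseline level shared by every sample, the structure the common-vector
    decomposition removes.  With ``common_background=False`` it is a sum of
    ``background_rank`` outer products of uniform (0.5, 1.5) vectors — a
    generic low-rank background for the multi-condition model.
    """
    if not (1 <= k1 <= m and 1 <= k2 <= n):
        raise ValueError("need 1 <= k1 <= m and 1 <= k2 <= n")
    if background_rank < 0 or min(m, n) < background_rank:
        raise ValueError("background_rank must be in 0..min(m, n)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if block_effects is None:
        block_effects = np.zeros((k1, k2))
        block_effects[0, 0] = 10.0
    block_effects = np.asarray(block_effects, dtype=float)
    if block_effects.shape != (k1, k2):
        raise ValueError(f"block_effects must be {k1}x{k2}")

    background = np.zeros((m, n))
    if common_background:
        if background_rank > 1:
            raise ValueError("common-vector background has rank at most 1")
        if background_rank == 1:
            background = np.outer(rng.uniform(1.0, 100.0, size=m), np.ones(n))
    else:
        for _ in range(background_rank):
            background += np.outer(
                rng.uniform(0.5, 1.5, size=m), rng.uniform(0.5, 1.5, size=n)
            )
    row_truth = _balanced_partition(m, k1, rng)
    col_truth = _balanced_partition(n, k2, rng)
    foreground = block_effects[np.ix_(row_truth - 1, col_truth - 1)]
    noise = rng.normal(0.0, noise_sd, size=(m, n)) if noise_sd > 0 else np.zeros((m, n))
    M = ExpressionMatrix(background + foreground + noise)
    return PlantedInstance(
        M=M, background=background, foreground=foreground, noise_sd=noise_sd,
        row_truth=row_truth, col_truth=col_truth, seed=seed,
    )
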