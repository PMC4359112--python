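"""Dense genes x samples expression matrix container.

Orientation is fixed throughout the package: rows are genes, columns are
samples.  The container is a thin, validated wrapper around a numpy array
plus the two identifier lists; heavy lifting (decomposition, clustering)
operates on the ``values`` array directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_ids(ids: list[str], n: int, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValueError(f"{what}: expected {n} identifiers, got {len(ids)}")
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what[:-1]}: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """An m x n expression matrix with gene (row) and sample (column) ids.

    Parameters
    ----------
    values
        Real m x n array; all entries must be finite.
    gene_ids
        m unique row identifiers.
    sample_ids
        n unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one row and column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j + 1}" for j in range(n)]
        self.gene_ids = _check_ids(self.gene_ids, m, "gene_ids")
        self.sample_ids = _check_ids(self.sample_ids, n, "sample_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def like(self, values: np.ndarray) -> "ExpressionMatrix":
        """A new matrix with the same identifiers but different values."""
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids))

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows], list(gene_ids), list(self.sample_ids))
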