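"""CSV readers and writers.

Matrix CSV dialect: comma-separated, UTF-8, header row of sample ids, first
column of gene ids, no quoting of numerics, '.' decimal point.  Survival CSV:
columns ``sample_id,time,event`` with event coded 0 (censored) / 1 (death).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .survival import SurvivalTable


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix CSV (genes as rows, samples as columns)."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    return ExpressionMatrix(values, gene_ids, sample_ids)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix CSV; inverse of :func:`read_matrix`."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(path, index_label="gene_id")


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a clinical survival table CSV (sample_id, time, event)."""
    df = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
    events = df["event"].to_numpy()
    bad = [e for e in events if e not in (0, 1)]
    if bad:
        raise ValueError(f"event values must be 0 or 1; found {bad[:5]}")
    return SurvivalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        time=df["time"].to_numpy(dtype=float),
        event=events.astype(int),
    )


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": table.sample_ids, "time": table.time, "event": table.event}
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a two-column ``sample_id,label`` CSV (used by the CLI)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label CSV needs columns: sample_id, label")
    return [str(s) for s in df.iloc[:, 0]], df.iloc[:, 1].to_numpy(dtype=int)


def write_labels(ids: list[str], labels: np.ndarray, path: str | Path,
                 id_col: str = "sample_id") -> None:
    pd.DataFrame({id_col: ids, "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )
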