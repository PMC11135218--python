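"""Reading and writing expression matrices, trees, assignments and grid reports.

The on-disk matrix convention is delimited text with a header row of
sample identifiers and a first column of gene identifiers, e.g.::

    Genes   Time 1  Time 2  Time 3
    Gene 1  0.25    0.22    0.65
    Gene 2  -0.75   1.25    -0.63

Values may be negative depending on the upstream normalization.  Missing
cells are a load error: the pipeline never imputes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .agglomerate import Dendrogram
    from .fitness_eval import CombinationGrid, FitnessRecord
    from .partition import ClusterAssignment


class ExpressionIOError(ValueError):
    """Raised for malformed expression matrix files."""


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of real-valued expression intensities.

    ``values`` has one row per gene and one column per sample; gene IDs
    are unique; no cell is missing.  ``name`` optionally identifies the
    dataset (used by the pleiotropy stage to label disease rows).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    name: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionIOError("values must be a 2-D grid")
        n, p = self.values.shape
        if n != len(self.gene_ids) or p != len(self.sample_ids):
            raise ExpressionIOError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene IDs x {len(self.sample_ids)} sample IDs"
            )
        if n == 0 or p == 0:
            raise ExpressionIOError("empty matrix")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ExpressionIOError(f"duplicate gene ID: {g!r}")
            seen.add(g)
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionIOError(
                f"missing or non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Load a delimited expression matrix (header row + gene-ID first column).

    Raises :class:`ExpressionIOError` on a missing file, a non-numeric or
    missing cell (reported with its row and column), a duplicate gene ID,
    or an empty matrix.
    """
    path = Path(path)
    if not path.exists():
        raise ExpressionIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionIOError(f"empty matrix in {path}")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ExpressionIOError(f"duplicate gene ID: {dup[0]!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raw = df.loc[bad[0], col]
            raise ExpressionIOError(
                f"non-numeric cell {raw!r} at gene {bad[0]!r}, sample {col!r}"
            )
        values[:, j] = parsed.to_numpy()
    return ExpressionMatrix(gene_ids, sample_ids, values, name=path.stem)


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the same layout :func:`read_expression_matrix` reads."""
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_ids)
    df.index.name = "Genes"
    df.to_csv(path, sep=delimiter)


def _fmt(x: float) -> str:
    # shortest exact round-trip representation; integers without ".0"
    x = float(x)
    if x.is_integer() and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def write_newick(tree: "Dendrogram", labels) -> str:
    """Serialize a dendrogram as an ultrametric Newick string.

    Node height = merge height, leaf height = 0; each branch length is
    the parent height minus the child height, so every leaf-to-root path
    sums to the root height.
    """
    labels = list(labels)
    n = tree.n_leaves
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} leaves")
    if n == 1:
        return f"{labels[0]};"
    # node id -> subtree string; leaves are 0..n-1, merges n..2n-2.
    # children are written smallest-leaf-first so the output is canonical.
    text: list[str] = list(labels) + [""] * (n - 1)
    height = [0.0] * (2 * n - 1)
    min_leaf = list(range(n)) + [0] * (n - 1)
    for i in range(n - 1):
        left, right = int(tree.left[i]), int(tree.right[i])
        if min_leaf[right] < min_leaf[left]:
            left, right = right, left
        h = float(tree.height[i])
        node = n + i
        bl = _fmt(h - height[left])
        br = _fmt(h - height[right])
        text[node] = f"({text[left]}:{bl},{text[right]}:{br})"
        height[node] = h
        min_leaf[node] = min(min_leaf[left], min_leaf[right])
    return text[2 * n - 2] + ";"


def write_assignments(assignment: "ClusterAssignment", path, delimiter: str = "\t") -> None:
    """Write gene_id / cluster_label pairs as TSV."""
    with open(path, "w") as fh:
        fh.write(f"gene_id{delimiter}cluster\n")
        for item, lab in zip(assignment.item_ids, assignment.labels):
            fh.write(f"{item}{delimiter}{int(lab)}\n")


def read_assignments(path, delimiter: str = "\t") -> "ClusterAssignment":
    from .partition import ClusterAssignment

    df = pd.read_csv(path, sep=delimiter)
    return ClusterAssignment.from_labels(
        [str(g) for g in df["gene_id"]], df["cluster"].to_numpy()
    )


def _record_dict(r: "FitnessRecord") -> dict:
    return {
        "metric": r.metric,
        "linkage": r.linkage,
        "cut_height": r.cut_height,
        "k": r.k,
        "S": r.S,
        "W": r.W,
        "F": r.F,
    }


def write_grid_report(grid: "CombinationGrid", path) -> None:
    """Write the metric x linkage optimum table as a JSON report.

    One record per cell (metric, linkage, optimal cut height, cluster
    count, S, W, F) plus the argmax cell.
    """
    payload = {
        "cells": [_record_dict(r) for r in grid.records],
        "best": _record_dict(grid.best),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_grid_report(path) -> "CombinationGrid":
    """Re-parse a report written by :func:`write_grid_report`."""
    from .fitness_eval import CombinationGrid, FitnessRecord

    with open(path) as fh:
        payload = json.load(fh)
    records = [FitnessRecord(**c) for c in payload["cells"]]
    best = FitnessRecord(**payload["best"])
    return CombinationGrid(records=records, best=best)
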