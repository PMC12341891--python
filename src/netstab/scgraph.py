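"""Cell graphs from reduced-dimensional embeddings.

Exact K-nearest-neighbor search in embedding space (Euclidean, deterministic
tie-break by cell order), followed by shared-nearest-neighbor refinement:
edge weight between two cells is the Jaccard overlap of their neighbor sets
(each set includes the cell itself, size k+1), with edges at or below the
prune threshold dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .errors import DomainError, ValidationError
from .graph import Graph
from .partition import Partition

__all__ = [
    "Embedding",
    "NeighborTable",
    "read_embedding",
    "write_embedding",
    "knn_neighbors",
    "snn_jaccard_graph",
    "export_annotations",
    "read_annotations",
]

DEFAULT_PRUNE = 1.0 / 15.0


@dataclass
class Embedding:
    """Cells x dimensions coordinate matrix (typically principal components)."""

    cell_ids: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self):
        self.cell_ids = tuple(str(c) for c in self.cell_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValidationError("coords must be a 2-D matrix")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("one coordinate row per cell id required")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.coords.shape[1] < 2:
            raise ValidationError("embedding needs at least 2 dimensions")
        if self.coords.shape[0] < 10:
            raise ValidationError("embedding needs at least 10 cells")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains missing/non-finite values")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def read_embedding(path, sep: str | None = None) -> Embedding:
    """Read a CSV/TSV with header whose first column is the cell id."""
    import pandas as pd

    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: expected cell_id column plus >= 2 coordinate columns"
        )
    return Embedding(tuple(df.iloc[:, 0].astype(str)), df.iloc[:, 1:].to_numpy(float))


def write_embedding(embedding: Embedding, path, sep: str | None = None) -> None:
    import pandas as pd

    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    cols = {"cell_id": list(embedding.cell_ids)}
    for d in range(embedding.coords.shape[1]):
        cols[f"dim{d + 1}"] = embedding.coords[:, d]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


@dataclass
class NeighborTable:
    """Each cell's k nearest neighbors (indices into cell order), nearest first."""

    cell_ids: tuple[str, ...]
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2 or self.indices.shape[0] != len(self.cell_ids):
            raise ValidationError("indices must be (n_cells, k)")

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def knn_neighbors(embedding: Embedding, k: int, chunk: int = 1024) -> NeighborTable:
    """Exact k nearest neighbors by Euclidean distance, excluding self.

    Ties are broken deterministically by cell order (stable sort on exact
    squared distances), so duplicated coordinates give reproducible tables.
    """
    n = embedding.n_cells
    if not 1 <= k < n:
        raise DomainError(f"k must satisfy 1 <= k < n_cells ({n}), got {k}")
    coords = embedding.coords
    sq = np.einsum("ij,ij->i", coords, coords)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = coords[start:stop]
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * block @ coords.T
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[rows - start, rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return NeighborTable(embedding.cell_ids, out)


def snn_jaccard_graph(neighbors: NeighborTable, prune: float = DEFAULT_PRUNE) -> Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Candidate edges are pairs (i, j) where j is in knn(i) or i is in knn(j);
    the weight is |N(i) ∩ N(j)| / |N(i) ∪ N(j)| with N(x) = knn(x) ∪ {x}.
    Edges with weight <= prune are dropped.
    """
    if not 0.0 <= prune < 1.0:
        raise DomainError(f"prune must be in [0, 1), got {prune}")
    n, k = neighbors.indices.shape
    size = k + 1

    rows = np.repeat(np.arange(n), size)
    cols = np.concatenate(
        [neighbors.indices, np.arange(n)[:, None]], axis=1
    ).ravel()
    member = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    knn_only = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), neighbors.indices.ravel())),
        shape=(n, n),
    )
    candidate = ((knn_only + knn_only.T) > 0).tocoo()
    mask = candidate.row < candidate.col
    ci, cj = candidate.row[mask], candidate.col[mask]

    inter = member @ member.T
    inter_vals = np.asarray(inter[ci, cj]).ravel()
    union = 2.0 * size - inter_vals
    weights = inter_vals / union

    keep = weights > prune
    edges = np.column_stack([ci[keep], cj[keep]])
    return Graph(neighbors.cell_ids, edges, weights[keep])


def export_annotations(partition: Partition, cell_ids: Sequence[str], path) -> None:
    """Write cluster annotations as a (cell_id, cluster) CSV in the given order."""
    cell_ids = [str(c) for c in cell_ids]
    if len(cell_ids) != partition.n or set(cell_ids) != set(partition.ids):
        raise ValidationError(
            "cell_ids do not match the partition's element set "
            f"({len(cell_ids)} vs {partition.n} elements)"
        )
    membership = partition.membership
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "cluster"])
        for cid in cell_ids:
            writer.writerow([cid, membership[cid]])


def read_annotations(path) -> Partition:
    """Inverse of :func:`export_annotations`."""
    ids, labels = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            if row:
                ids.append(row[0])
                labels.append(row[1])
    return Partition(tuple(ids), tuple(labels))
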