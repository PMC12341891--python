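"""Partitions of a node set and the similarity/distance measures between them.

All measures are computed from the contingency table of two labelings over
the same element set.  Entropies use natural logarithms, so the variation of
information is reported in nats and bounded by ``ln n``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import DomainError, ValidationError

__all__ = [
    "Partition",
    "variation_of_information",
    "normalized_mutual_information",
    "adjusted_rand",
    "split_join",
    "as_distance",
    "partition_distance",
    "MEASURES",
]

#: Registered measure kinds -> True if the raw value is already a distance.
MEASURES: dict[str, bool] = {
    "vi": True,
    "split_join": True,
    "nmi": False,
    "ari": False,
}


@dataclass(frozen=True)
class Partition:
    """A labeling of elements into communities.

    ``ids`` gives the element order; ``labels`` the community label of each
    element (opaque, compared by equality).
    """

    ids: tuple[str, ...]
    labels: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.labels):
            raise ValidationError("ids and labels must have equal length")
        if len(self.ids) == 0:
            raise ValidationError("a partition must cover at least one element")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate element ids")

    @classmethod
    def from_membership(cls, membership: Mapping[str, object]) -> "Partition":
        ids = tuple(str(k) for k in membership)
        return cls(ids, tuple(membership[k] for k in membership))

    @classmethod
    def from_labels(cls, ids: Sequence[str], labels: Sequence) -> "Partition":
        return cls(tuple(str(i) for i in ids), tuple(labels))

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def membership(self) -> dict[str, object]:
        return dict(zip(self.ids, self.labels))

    def codes(self) -> np.ndarray:
        """Integer community codes in id order (0..k-1, first-appearance)."""
        _, inv = np.unique(
            np.asarray(self.labels, dtype=object).astype(str), return_inverse=True
        )
        return inv

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))

    def sizes(self) -> dict[object, int]:
        out: dict[object, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    # -- serialization: two-column CSV (node_id, community) ---------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node_id", "community"])
            for i, lab in zip(self.ids, self.labels):
                writer.writerow([i, lab])

    @classmethod
    def from_csv(cls, path) -> "Partition":
        path = Path(path)
        ids, labels = [], []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or len(header) < 2:
                raise ValidationError(f"{path}: expected a two-column CSV header")
            for row in reader:
                if not row:
                    continue
                ids.append(row[0])
                labels.append(row[1])
        return cls(tuple(ids), tuple(labels))


def _aligned_codes(p: Partition, q: Partition) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of p and q over the same elements, in p's id order."""
    if p.n != q.n or set(p.ids) != set(q.ids):
        raise DomainError("partitions are over different element sets")
    pc = p.codes()
    if p.ids == q.ids:
        qc = q.codes()
    else:
        pos = {i: k for k, i in enumerate(q.ids)}
        perm = np.array([pos[i] for i in p.ids])
        qc = q.codes()[perm]
    return pc, qc


def _contingency(p: Partition, q: Partition):
    """Sparse contingency table plus marginals; n_ij counts shared elements."""
    pc, qc = _aligned_codes(p, q)
    n = p.n
    table = sp.coo_matrix(
        (np.ones(n), (pc, qc)), shape=(pc.max() + 1, qc.max() + 1)
    ).tocsr()
    table.sum_duplicates()
    return table, np.asarray(table.sum(axis=1)).ravel(), np.asarray(
        table.sum(axis=0)
    ).ravel(), n


def _entropy(counts: np.ndarray, n: int) -> float:
    probs = counts[counts > 0] / n
    return float(-np.sum(probs * np.log(probs)))


def variation_of_information(p: Partition, q: Partition) -> float:
    """VI(p, q) = 2 H(p, q) - H(p) - H(q), in nats; 0 iff p == q, <= ln n."""
    table, a, b, n = _contingency(p, q)
    h_joint = _entropy(table.data, n)
    vi = 2.0 * h_joint - _entropy(a, n) - _entropy(b, n)
    return max(vi, 0.0)


def _mutual_information(table, a, b, n) -> float:
    nij = table.tocoo()
    vals = nij.data
    outer = a[nij.row] * b[nij.col]
    return float(np.sum((vals / n) * np.log(vals * n / outer)))


def normalized_mutual_information(p: Partition, q: Partition) -> float:
    """NMI with geometric-mean normalization, I / sqrt(H(p) H(q)).

    Both partitions single-block (both entropies zero) => 1 by convention;
    exactly one entropy zero => 0 (no information shared).
    """
    table, a, b, n = _contingency(p, q)
    hp, hq = _entropy(a, n), _entropy(b, n)
    if hp == 0.0 and hq == 0.0:
        return 1.0
    if hp == 0.0 or hq == 0.0:
        return 0.0
    mi = _mutual_information(table, a, b, n)
    return float(np.clip(mi / np.sqrt(hp * hq), 0.0, 1.0))


def adjusted_rand(p: Partition, q: Partition) -> float:
    """Permutation-model adjusted Rand index; 1 iff identical, can be < 0."""
    table, a, b, n = _contingency(p, q)
    nij = table.data
    sum_ij = float(np.sum(nij * (nij - 1) / 2))
    sum_a = float(np.sum(a * (a - 1) / 2))
    sum_b = float(np.sum(b * (b - 1) / 2))
    pairs = n * (n - 1) / 2
    expected = sum_a * sum_b / pairs
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:  # both partitions trivial in the same way
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def split_join(p: Partition, q: Partition) -> int:
    """van Dongen split-join distance: 2n - sum of best overlaps both ways."""
    table, _, _, n = _contingency(p, q)
    dense = table.toarray()
    return int(round(2 * n - dense.max(axis=1).sum() - dense.max(axis=0).sum()))


def as_distance(value: float, measure: str, n: int | None = None) -> float:
    """Map a raw measure value onto a non-negative distance scale.

    Distances (vi, split_join) pass through; similarities map to 1 - value.
    """
    if measure not in MEASURES:
        raise DomainError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    if MEASURES[measure]:
        return float(value)
    return float(1.0 - value)


_MEASURE_FUNCS = {
    "vi": variation_of_information,
    "nmi": normalized_mutual_information,
    "ari": adjusted_rand,
    "split_join": split_join,
}


def partition_distance(p: Partition, q: Partition, measure: str = "vi") -> float:
    """Distance between two partitions under the named measure."""
    if measure not in _MEASURE_FUNCS:
        raise DomainError(f"unknown measure {measure!r}; expected one of {sorted(MEASURES)}")
    return as_distance(_MEASURE_FUNCS[measure](p, q), measure, p.n)
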