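"""Undirected simple graphs: representation, I/O, perturbation, null model.

The :class:`Graph` here is deliberately minimal — node identifiers are opaque
strings, edges are stored as a canonically sorted integer index array, and an
optional positive weight is attached per edge.  Conversion to ``igraph`` is
provided for the community-detection layer.

Two randomized operators live here:

* :func:`rewire_fraction` — the perturbation used to build stability curves.
  It removes a fixed number of edges and replaces them with uniformly random
  pairs that did not occur in the original graph, so node count, edge count
  and (for weighted graphs) the weight multiset are conserved exactly.
* :func:`configuration_null` — a degree-preserving randomization by repeated
  double-edge swaps, used as the "no real structure" reference graph.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DomainError, GraphFormatError, GraphTooDenseError, ValidationError
from .rng import RandomState

__all__ = [
    "Graph",
    "read_graph",
    "write_graph",
    "rewire_fraction",
    "configuration_null",
]

_FORMATS = ("edgelist", "graphml", "mtx")


def _canonicalize(edges: np.ndarray, weights: Optional[np.ndarray]):
    """Sort endpoints within rows and rows lexicographically; keep weights aligned."""
    edges = np.sort(edges, axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges = edges[order]
    if weights is not None:
        weights = weights[order]
    return edges, weights


class Graph:
    """Simple undirected graph with opaque string node ids.

    Parameters
    ----------
    nodes:
        Ordered node identifiers (coerced to ``str``); order defines the
        internal 0-based indexing, which never leaks into files.
    edges:
        Iterable of index pairs referring to ``nodes``.
    weights:
        Optional positive weight per edge, aligned with ``edges``.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[Sequence[int]] = (),
        weights: Optional[Sequence[float]] = None,
    ):
        self.nodes: tuple[str, ...] = tuple(str(n) for n in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        n = len(self.nodes)
        edges = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                           dtype=np.int64)
        if edges.size == 0:
            edges = edges.reshape(0, 2)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValidationError("edges must be an (m, 2) array of node indices")
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValidationError("edge endpoint index out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValidationError("self-loops are not allowed")
        w = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if w.shape != (edges.shape[0],):
                raise ValidationError("weights must align one-to-one with edges")
            if not np.all(w > 0):
                raise ValidationError("edge weights must be strictly positive")
        edges, w = _canonicalize(edges, w)
        keys = edges[:, 0] * n + edges[:, 1]
        if len(np.unique(keys)) != len(keys):
            raise ValidationError("duplicate edges are not allowed")
        self.edges: np.ndarray = edges
        self.weights: Optional[np.ndarray] = w

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    def degrees(self) -> np.ndarray:
        """Degree of every node, in node order."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def edge_keys(self) -> np.ndarray:
        """Canonical integer key i*n + j (i < j) per edge."""
        return self.edges[:, 0] * self.n_nodes + self.edges[:, 1]

    def edge_id_pairs(self) -> list[tuple[str, str]]:
        return [(self.nodes[i], self.nodes[j]) for i, j in self.edges]

    def copy(self) -> "Graph":
        g = Graph.__new__(Graph)
        g.nodes = self.nodes
        g.edges = self.edges.copy()
        g.weights = None if self.weights is None else self.weights.copy()
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        if self.nodes != other.nodes or not np.array_equal(self.edges, other.edges):
            return False
        if (self.weights is None) != (other.weights is None):
            return False
        return self.weights is None or np.array_equal(self.weights, other.weights)

    def __repr__(self) -> str:
        tag = "weighted" if self.is_weighted else "unweighted"
        return f"Graph(|V|={self.n_nodes}, |E|={self.n_edges}, {tag})"

    def require_engine_ready(self) -> None:
        """Invariant gate for graphs entering the robustness engine."""
        if self.n_nodes < 2 or self.n_edges < 1:
            raise ValidationError(
                f"graph must have >= 2 nodes and >= 1 edge (got |V|={self.n_nodes}, "
                f"|E|={self.n_edges})"
            )

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_id_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        weights: Optional[Sequence[float]] = None,
        nodes: Optional[Sequence[str]] = None,
    ) -> "Graph":
        """Build from (u, v) id pairs; node order is first appearance unless given."""
        pairs = list(pairs)
        if nodes is None:
            seen: dict[str, int] = {}
            for u, v in pairs:
                for x in (str(u), str(v)):
                    if x not in seen:
                        seen[x] = len(seen)
            nodes = list(seen)
        index = {str(x): i for i, x in enumerate(nodes)}
        edges = [(index[str(u)], index[str(v)]) for u, v in pairs]
        return cls(nodes, edges, weights)

    def to_igraph(self):
        """Convert to ``igraph.Graph``; weights become the 'weight' attribute."""
        import igraph as ig

        g = ig.Graph(n=self.n_nodes, edges=self.edges.tolist(), directed=False)
        g.vs["name"] = list(self.nodes)
        if self.weights is not None:
            g.es["weight"] = self.weights.tolist()
        return g


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".mtx":
        return "mtx"
    return "edgelist"


def read_graph(path, format: Optional[str] = None) -> Graph:
    """Read a graph from ``path`` in one of {edgelist, graphml, mtx}.

    * edgelist: whitespace-delimited ``u v [weight]`` lines, ``#`` comments;
      a single-token line declares an isolated node.  Duplicate and reversed
      duplicate edges collapse to one (first weight wins); self-loops dropped.
    * graphml: standard GraphML; edge attribute ``weight`` used when present
      on every edge.
    * mtx: square symmetric MatrixMarket coordinate matrix read as a weighted
      adjacency; diagonal dropped, zero entries absent; node ids are the
      1-based row indices as strings.  If all values equal 1 the graph is
      returned unweighted.
    """
    path = Path(path)
    if not path.exists():
        raise GraphFormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise DomainError(f"unknown graph format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        return _read_edgelist(path)
    if fmt == "graphml":
        return _read_graphml(path)
    return _read_mtx(path)


def _read_edgelist(path: Path) -> Graph:
    node_order: dict[str, int] = {}
    pair_weight: dict[tuple[int, int], Optional[float]] = {}
    n_cols: Optional[int] = None

    def node_idx(tok: str) -> int:
        if tok not in node_order:
            node_order[tok] = len(node_order)
        return node_order[tok]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) == 1:
                node_idx(toks[0])
                continue
            if len(toks) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 1-3 whitespace-separated fields, "
                    f"got {len(toks)}"
                )
            if n_cols is None:
                n_cols = len(toks)
            elif len(toks) != n_cols:
                raise GraphFormatError(
                    f"{path}:{lineno}: inconsistent column count (file mixes "
                    "weighted and unweighted edges)"
                )
            u, v = node_idx(toks[0]), node_idx(toks[1])
            if u == v:
                continue
            w = None
            if len(toks) == 3:
                try:
                    w = float(toks[2])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: cannot parse weight {toks[2]!r}"
                    ) from exc
            key = (min(u, v), max(u, v))
            if key not in pair_weight:
                pair_weight[key] = w
    nodes = list(node_order)
    edges = list(pair_weight)
    weights = None
    if n_cols == 3:
        weights = [pair_weight[e] for e in edges]
    return Graph(nodes, edges, weights)


def _read_graphml(path: Path) -> Graph:
    import networkx as nx

    try:
        nxg = nx.read_graphml(path)
    except Exception as exc:
        raise GraphFormatError(f"{path}: invalid GraphML: {exc}") from exc
    nxg = nx.Graph(nxg)  # collapse any multi-edges, force undirected
    nxg.remove_edges_from(nx.selfloop_edges(nxg))
    nodes = [str(n) for n in nxg.nodes()]
    pairs, weights = [], []
    weighted = nxg.number_of_edges() > 0 and all(
        "weight" in d for _, _, d in nxg.edges(data=True)
    )
    for u, v, d in nxg.edges(data=True):
        pairs.append((str(u), str(v)))
        if weighted:
            weights.append(float(d["weight"]))
    return Graph.from_id_pairs(pairs, weights if weighted else None, nodes=nodes)


def _read_mtx(path: Path) -> Graph:
    import scipy.io
    import scipy.sparse as sp

    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise GraphFormatError(f"{path}: invalid MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape[0] != mat.shape[1]:
        raise GraphFormatError(
            f"{path}: adjacency matrix must be square, got {mat.shape}"
        )
    if (abs(mat - mat.T)).nnz != 0:
        raise GraphFormatError(f"{path}: adjacency matrix is not symmetric")
    mask = mat.row < mat.col  # strict upper triangle: drops diagonal
    rows, cols, vals = mat.row[mask], mat.col[mask], mat.data[mask]
    nz = vals != 0
    rows, cols, vals = rows[nz], cols[nz], vals[nz]
    if np.any(vals < 0):
        raise GraphFormatError(f"{path}: negative adjacency values are not weights")
    nodes = [str(i + 1) for i in range(mat.shape[0])]
    edges = np.column_stack([rows, cols])
    weights = None if vals.size and np.all(vals == 1.0) else vals
    if vals.size == 0:
        weights = None
    return Graph(nodes, edges, weights)


def write_graph(graph: Graph, path, format: Optional[str] = None) -> None:
    """Write ``graph`` so that :func:`read_graph` round-trips it.

    Edgelist and GraphML preserve node identifiers exactly; MTX stores nodes
    as 1-based indices in node order, so only graphs whose ids are already
    "1".."n" round-trip their ids through MTX (weights and topology always do).
    """
    if not isinstance(graph, Graph):
        raise ValidationError("write_graph expects a Graph")
    graph.require_engine_ready()  # refuse to serialize degenerate graphs
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise DomainError(f"unknown graph format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        _write_edgelist(graph, path)
    elif fmt == "graphml":
        _write_graphml(graph, path)
    else:
        _write_mtx(graph, path)


def _fmt_float(x: float) -> str:
    return f"{x:.17g}"


def _write_edgelist(graph: Graph, path: Path) -> None:
    used = np.zeros(graph.n_nodes, dtype=bool)
    used[graph.edges.ravel()] = True
    with open(path, "w") as fh:
        for idx, (i, j) in enumerate(graph.edges):
            u, v = graph.nodes[i], graph.nodes[j]
            if graph.weights is not None:
                fh.write(f"{u}\t{v}\t{_fmt_float(graph.weights[idx])}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        for i in np.flatnonzero(~used):
            fh.write(f"{graph.nodes[i]}\n")


def _write_graphml(graph: Graph, path: Path) -> None:
    import networkx as nx

    nxg = nx.Graph()
    nxg.add_nodes_from(graph.nodes)
    for idx, (i, j) in enumerate(graph.edges):
        if graph.weights is not None:
            nxg.add_edge(graph.nodes[i], graph.nodes[j],
                         weight=float(graph.weights[idx]))
        else:
            nxg.add_edge(graph.nodes[i], graph.nodes[j])
    nx.write_graphml(nxg, path)


def _write_mtx(graph: Graph, path: Path) -> None:
    import scipy.io
    import scipy.sparse as sp

    n = graph.n_nodes
    vals = graph.weights if graph.weights is not None else np.ones(graph.n_edges)
    rows = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
    cols = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
    data = np.concatenate([vals, vals])
    mat = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    scipy.io.mmwrite(str(path), mat, symmetry="symmetric", precision=17)


# ---------------------------------------------------------------------------
# Randomized operators
# ---------------------------------------------------------------------------


def rewire_fraction(graph: Graph, fraction: float, rng: RandomState) -> Graph:
    """Replace ``round(fraction * |E|)`` edges with uniformly random new pairs.

    Node set and edge count are conserved exactly.  The k removed edges are
    chosen uniformly; replacement pairs are drawn uniformly from pairs absent
    from the *original* graph (so exactly k original edges are missing from
    the result).  Weights, if present, are conserved as a multiset: kept
    edges keep theirs, removed-edge weights are reassigned to the new edges
    in random order.

    ``fraction = 0`` returns an identical copy.  Rounding is half-to-even.
    """
    if not isinstance(rng, RandomState):
        raise TypeError("rng must be a RandomState")
    if not (0.0 <= fraction <= 1.0):
        raise DomainError(f"fraction must be in [0, 1], got {fraction}")
    graph.require_engine_ready()
    n, m = graph.n_nodes, graph.n_edges
    k = int(np.rint(fraction * m))
    if k == 0:
        return graph.copy()
    total_pairs = n * (n - 1) // 2
    if k > total_pairs - m:
        raise GraphTooDenseError(
            f"cannot place {k} new edges: only {total_pairs - m} non-edges exist"
        )
    gen = rng.generator
    remove = gen.choice(m, size=k, replace=False)
    keep_mask = np.ones(m, dtype=bool)
    keep_mask[remove] = False

    forbidden = set(graph.edge_keys().tolist())
    new_keys: list[int] = []
    chosen: set[int] = set()
    max_attempts = max(100 * k, 1000)
    attempts = 0
    while len(new_keys) < k and attempts < max_attempts:
        batch = min(max(2 * (k - len(new_keys)), 64), max_attempts - attempts)
        cand = gen.integers(0, n, size=(batch, 2))
        attempts += batch
        ok = cand[:, 0] != cand[:, 1]
        cand = np.sort(cand[ok], axis=1)
        for key in (cand[:, 0] * n + cand[:, 1]).tolist():
            if key in forbidden or key in chosen:
                continue
            chosen.add(key)
            new_keys.append(key)
            if len(new_keys) == k:
                break
    if len(new_keys) < k:
        raise GraphTooDenseError(
            f"failed to draw {k} replacement edges after {attempts} attempts; "
            "graph too dense for this perturbation level"
        )
    new_arr = np.array(new_keys, dtype=np.int64)
    new_edges = np.column_stack([new_arr // n, new_arr % n])
    edges = np.vstack([graph.edges[keep_mask], new_edges])
    weights = None
    if graph.weights is not None:
        removed_w = gen.permutation(graph.weights[~keep_mask])
        weights = np.concatenate([graph.weights[keep_mask], removed_w])
    return Graph(graph.nodes, edges, weights)


def configuration_null(
    graph: Graph, rng: RandomState, swaps_per_edge: int = 10
) -> Graph:
    """Degree-preserving randomization by rejected-sampling double-edge swaps.

    Attempts ``swaps_per_edge * |E|`` swaps; each picks two distinct edges and
    one of the two re-pairings of their endpoints, rejecting any swap that
    would create a self-loop or duplicate edge.  The degree sequence is
    conserved exactly.  Weights, if present, are permuted uniformly over the
    final edge set.  If no swap ever succeeds (e.g. a star graph) the input
    topology is returned with a warning.
    """
    if not isinstance(rng, RandomState):
        raise TypeError("rng must be a RandomState")
    if swaps_per_edge < 1:
        raise DomainError("swaps_per_edge must be a positive integer")
    graph.require_engine_ready()
    n, m = graph.n_nodes, graph.n_edges
    gen = rng.generator
    edges = graph.edges.copy()
    present = set((edges[:, 0] * n + edges[:, 1]).tolist())

    successes = 0
    if m >= 2:
        n_attempts = swaps_per_edge * m
        pick = gen.integers(0, m, size=(n_attempts, 2))
        flip = gen.random(n_attempts) < 0.5
        for t in range(n_attempts):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip[t]:
                c, d = d, c
            # proposed replacement: (a, c) and (b, d)
            if a == c or b == d:
                continue
            k1 = (min(a, c)) * n + max(a, c)
            k2 = (min(b, d)) * n + max(b, d)
            if k1 == k2 or k1 in present or k2 in present:
                continue
            old1 = edges[e1, 0] * n + edges[e1, 1]
            old2 = edges[e2, 0] * n + edges[e2, 1]
            present.discard(int(old1))
            present.discard(int(old2))
            present.add(int(k1))
            present.add(int(k2))
            edges[e1] = (min(a, c), max(a, c))
            edges[e2] = (min(b, d), max(b, d))
            successes += 1
    if successes == 0:
        warnings.warn(
            "configuration_null: no degree-preserving swap was possible; "
            "returning a graph identical to the input topology",
            stacklevel=2,
        )
    weights = None
    if graph.weights is not None:
        weights = gen.permutation(graph.weights)
    out = Graph(graph.nodes, edges, weights)
    return out
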