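"""Synthetic graphs and embeddings with known ground truth.

Everything downstream is testable against these generators without any
external data: planted-partition (stochastic block model) graphs, Erdős–Rényi
null graphs, and Gaussian-mixture embeddings emulating a PC space.
All generators are pure functions of (parameters, RandomState).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .errors import DomainError
from .graph import Graph
from .partition import Partition
from .rng import RandomState
from .scgraph import Embedding

__all__ = ["sbm_graph", "er_graph", "gaussian_mixture_embedding"]


def _pair_edges(n: int, probs: np.ndarray, gen: np.random.Generator) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    mask = gen.random(iu.size) < probs
    return np.column_stack([iu[mask], ju[mask]])


def sbm_graph(
    block_sizes: Sequence[int],
    p_in: float,
    p_out: float,
    rng: RandomState,
) -> tuple[Graph, Partition]:
    """Stochastic block model: within-block edges w.p. ``p_in``, between w.p. ``p_out``.

    Returns the sampled graph and the planted block partition.  Warns when
    ``p_in <= p_out`` (no assortative structure to recover).
    """
    block_sizes = [int(b) for b in block_sizes]
    if not block_sizes or any(b < 1 for b in block_sizes):
        raise DomainError("block_sizes must be positive integers")
    for p, name in ((p_in, "p_in"), (p_out, "p_out")):
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"{name} must be a probability, got {p}")
    if p_in <= p_out:
        warnings.warn("p_in <= p_out: planted blocks are not assortative", stacklevel=2)
    n = sum(block_sizes)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    iu, ju = np.triu_indices(n, k=1)
    probs = np.where(labels[iu] == labels[ju], p_in, p_out)
    gen = rng.generator
    mask = gen.random(iu.size) < probs
    edges = np.column_stack([iu[mask], ju[mask]])
    nodes = [f"v{i}" for i in range(n)]
    graph = Graph(nodes, edges)
    planted = Partition(tuple(nodes), tuple(f"B{c}" for c in labels))
    return graph, planted


def er_graph(n: int, p: float, rng: RandomState) -> Graph:
    """Erdős–Rényi G(n, p) simple graph.

    ``p = 0`` yields an edgeless graph (accepted here with a warning; the
    robustness engine rejects it at its own gate).
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must be a probability, got {p}")
    gen = rng.generator
    iu, ju = np.triu_indices(n, k=1)
    mask = gen.random(iu.size) < p
    if not mask.any():
        warnings.warn("generated graph has no edges", stacklevel=2)
    edges = np.column_stack([iu[mask], ju[mask]])
    return Graph([f"v{i}" for i in range(n)], edges)


def gaussian_mixture_embedding(
    n_cells: int,
    k: int,
    dims: int,
    separation: float,
    sigma: float,
    rng: RandomState,
) -> tuple[Embedding, Partition]:
    """Isotropic Gaussian mixture in ``dims`` dimensions.

    Centers are drawn in random directions and rescaled so every pair of
    centers is at least ``separation`` apart; cells are split as evenly as
    possible across the k clusters (counts differ by at most 1) and jittered
    with N(0, sigma^2) noise.
    """
    if n_cells < 10:
        raise DomainError("n_cells must be >= 10")
    if k < 1 or k > n_cells:
        raise DomainError("k must be in [1, n_cells]")
    if dims < 2:
        raise DomainError("dims must be >= 2")
    if separation <= 0 or sigma <= 0:
        raise DomainError("separation and sigma must be positive")
    gen = rng.generator
    if k == 1:
        centers = np.zeros((1, dims))
    else:
        while True:
            centers = gen.normal(size=(k, dims))
            diffs = centers[:, None, :] - centers[None, :, :]
            dist = np.sqrt((diffs**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            min_dist = dist.min()
            if min_dist > 0:
                break
        centers *= separation / min_dist

    counts = np.full(k, n_cells // k)
    counts[: n_cells % k] += 1
    labels = np.repeat(np.arange(k), counts)
    coords = centers[labels] + gen.normal(scale=sigma, size=(n_cells, dims))
    ids = tuple(f"cell{i:05d}" for i in range(n_cells))
    return (
        Embedding(ids, coords),
        Partition(ids, tuple(f"M{c}" for c in labels)),
    )
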