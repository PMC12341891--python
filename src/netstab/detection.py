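"""Uniform contract over community-detection algorithms.

Algorithms themselves are delegated to igraph (and leidenalg for Leiden);
this module owns the catalogue, parameter validation, weight handling and
the determinism contract: ``detect_communities(graph, method, rng)`` is a
pure function of its arguments.  Stochastic igraph routines are seeded per
call from the supplied :class:`~netstab.rng.RandomState`, so scheduling and
call order never affect results.
"""

from __future__ import annotations

import hashlib
import random as _pyrandom
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import CatalogueError, ValidationError
from .graph import Graph
from .partition import Partition
from .rng import RandomState

__all__ = ["DetectionMethod", "detect_communities", "method_grid", "parse_method"]


def _positive_float(name):
    def check(v):
        v = float(v)
        if not v > 0:
            raise ValidationError(f"{name} must be > 0, got {v}")
        return v

    return check


def _positive_int(name):
    def check(v):
        iv = int(v)
        if iv != float(v) or iv < 1:
            raise ValidationError(f"{name} must be a positive integer, got {v}")
        return iv

    return check


#: name -> {param: (validator, default)}; defaults follow the delegated library.
_CATALOGUE: dict[str, dict[str, tuple]] = {
    "louvain": {"resolution": (_positive_float("resolution"), 1.0)},
    "leiden": {
        "resolution": (_positive_float("resolution"), 1.0),
        "n_iterations": (_positive_int("n_iterations"), 2),
    },
    "walktrap": {"steps": (_positive_int("steps"), 4)},
    "fastgreedy": {},
    "infomap": {"trials": (_positive_int("trials"), 1)},
    "labelprop": {},
}


@dataclass(frozen=True)
class DetectionMethod:
    """An algorithm name plus a validated parameter set."""

    name: str
    params: tuple = field(default=())

    def __post_init__(self):
        if self.name not in _CATALOGUE:
            raise CatalogueError(
                f"unknown method {self.name!r}; catalogue: {sorted(_CATALOGUE)}"
            )
        spec = _CATALOGUE[self.name]
        raw = dict(self.params) if not isinstance(self.params, Mapping) else dict(self.params)
        cleaned = {}
        for key, value in raw.items():
            if key not in spec:
                raise ValidationError(
                    f"method {self.name!r} takes no parameter {key!r}; "
                    f"allowed: {sorted(spec) or 'none'}"
                )
            cleaned[key] = spec[key][0](value)
        object.__setattr__(self, "params", tuple(sorted(cleaned.items())))

    @classmethod
    def make(cls, name: str, **params) -> "DetectionMethod":
        return cls(name, tuple(params.items()))

    def param(self, key: str):
        got = dict(self.params)
        if key in got:
            return got[key]
        return _CATALOGUE[self.name][key][1]

    @property
    def spec(self) -> str:
        """Canonical string form, e.g. ``leiden:resolution=0.5``."""
        if not self.params:
            return self.name
        args = ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                        for k, v in self.params)
        return f"{self.name}:{args}"

    def digest(self) -> int:
        """Stable 32-bit integer identifying this method spec (for substreams)."""
        return int(hashlib.md5(self.spec.encode()).hexdigest()[:8], 16)

    def __str__(self) -> str:
        return self.spec


def parse_method(text: str) -> DetectionMethod:
    """Parse ``name`` or ``name:param=value,param=value``."""
    name, _, rest = text.strip().partition(":")
    params = {}
    if rest:
        for item in rest.split(","):
            key, sep, value = item.partition("=")
            if not sep:
                raise ValidationError(f"malformed method parameter {item!r}")
            params[key.strip()] = value.strip()
    return DetectionMethod.make(name, **params)


def method_grid(name: str, param_name: str, values: Sequence) -> list[DetectionMethod]:
    """One :class:`DetectionMethod` per value of ``param_name``."""
    if name not in _CATALOGUE:
        raise CatalogueError(f"unknown method {name!r}; catalogue: {sorted(_CATALOGUE)}")
    if values and param_name not in _CATALOGUE[name]:
        raise ValidationError(
            f"method {name!r} takes no parameter {param_name!r}; "
            f"allowed: {sorted(_CATALOGUE[name]) or 'none'}"
        )
    return [DetectionMethod.make(name, **{param_name: v}) for v in values]


def detect_communities(graph: Graph, method: DetectionMethod, rng: RandomState) -> Partition:
    """Run ``method`` on ``graph``; deterministic given (graph, method, rng)."""
    import igraph as ig

    if not isinstance(method, DetectionMethod):
        raise ValidationError("method must be a DetectionMethod")
    graph.require_engine_ready()
    g = graph.to_igraph()
    weights = "weight" if graph.is_weighted else None
    seed = rng.integer(2**31 - 1)
    # igraph's stochastic routines draw from a process-global RNG; pin it
    # right before the call so results depend only on (graph, method, rng).
    ig.set_random_number_generator(_pyrandom.Random(seed))

    name = method.name
    if name == "louvain":
        clustering = g.community_multilevel(
            weights=weights, resolution=method.param("resolution")
        )
    elif name == "leiden":
        import leidenalg as la

        part = la.find_partition(
            g,
            la.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=method.param("resolution"),
            n_iterations=method.param("n_iterations"),
            seed=seed,
        )
        clustering = part
    elif name == "walktrap":
        dendro = g.community_walktrap(weights=weights, steps=method.param("steps"))
        clustering = dendro.as_clustering()
    elif name == "fastgreedy":
        dendro = g.community_fastgreedy(weights=weights)
        clustering = dendro.as_clustering()
    elif name == "infomap":
        clustering = g.community_infomap(
            edge_weights=weights, trials=method.param("trials")
        )
    elif name == "labelprop":
        clustering = g.community_label_propagation(weights=weights)
    else:  # pragma: no cover - catalogue enforced in __post_init__
        raise CatalogueError(name)
    labels = tuple(int(c) for c in clustering.membership)
    return Partition(graph.nodes, labels)
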