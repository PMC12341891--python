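"""Stability-curve engine: perturb, re-detect, measure, repeat.

Two top-level procedures:

* :func:`validate_vs_null` — one method, run on the graph of interest and on
  a degree-matched configuration-model null, producing an observed and a
  null curve set for statistical comparison.
* :func:`compare_methods` — several methods run on the *same* perturbed
  graphs (paired design), producing one observed curve set per method for
  AUC ranking.

Random substreams are addressed by (purpose, level-index, replicate-index,
method-digest), so results are bit-identical for any worker count or
scheduling order; parallelism is over perturbation levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .detection import DetectionMethod, detect_communities
from .errors import DomainError, ValidationError
from .graph import Graph, configuration_null, rewire_fraction
from .partition import MEASURES, Partition, partition_distance
from .rng import RandomState

__all__ = [
    "PerturbationGrid",
    "CurveSet",
    "RobustnessResult",
    "stability_curves",
    "validate_vs_null",
    "compare_methods",
]

# substream purpose tags (first index of every substream key)
_S_REF = 0
_S_PERTURB = 1
_S_DETECT = 2
_S_NULLGRAPH = 3
_S_NULLBASE = 4

_DEFAULT_LEVELS = tuple(np.round(np.arange(1, 13) * 0.05, 10))  # 0.05 .. 0.60


@dataclass(frozen=True)
class PerturbationGrid:
    """Perturbation levels and replicate count for curve construction.

    Defaults: 12 levels 5%..60% in 5% steps, 10 replicates per level.
    A leading level of 0 is allowed only as an explicit diagnostic (it yields
    distance 0 for deterministic methods).
    """

    levels: tuple[float, ...] = _DEFAULT_LEVELS
    replicates: int = 10

    def __post_init__(self):
        levels = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 1:
            raise ValidationError("grid needs at least one level")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValidationError("levels must be strictly increasing")
        if levels[0] < 0 or levels[-1] > 1:
            raise ValidationError("levels must lie in [0, 1]")
        if levels[-1] <= 0:
            raise ValidationError("the last level must be positive")
        if int(self.replicates) < 2:
            raise ValidationError("replicates must be >= 2")
        object.__setattr__(self, "replicates", int(self.replicates))

    @classmethod
    def default(cls, replicates: int = 10) -> "PerturbationGrid":
        return cls(_DEFAULT_LEVELS, replicates)

    def with_zero(self) -> "PerturbationGrid":
        """Diagnostic grid with an extra level 0 prepended."""
        if self.levels[0] == 0.0:
            return self
        return PerturbationGrid((0.0,) + self.levels, self.replicates)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class CurveSet:
    """Matrix of stability distances, levels x replicates, with provenance."""

    values: np.ndarray
    levels: tuple[float, ...]
    method: str
    condition: str  # "observed" | "null"
    measure: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.levels = tuple(float(x) for x in self.levels)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.levels):
            raise ValidationError(
                f"values must be (n_levels, replicates), got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValidationError("stability distances must be non-negative")
        if self.condition not in ("observed", "null"):
            raise ValidationError("condition must be 'observed' or 'null'")
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")

    @property
    def replicates(self) -> int:
        return self.values.shape[1]

    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def __eq__(self, other):
        if not isinstance(other, CurveSet):
            return NotImplemented
        return (
            self.levels == other.levels
            and self.method == other.method
            and self.condition == other.condition
            and self.measure == other.measure
            and np.array_equal(self.values, other.values)
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "condition": self.condition,
            "measure": self.measure,
            "levels": list(self.levels),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurveSet":
        return cls(
            np.asarray(d["values"], dtype=float),
            tuple(d["levels"]),
            d["method"],
            d["condition"],
            d["measure"],
        )


@dataclass
class RobustnessResult:
    """Container for one engine run: curves, references, grid, seed."""

    n_nodes: int
    n_edges: int
    grid: PerturbationGrid
    measure: str
    seed: Optional[int]
    curves: list[CurveSet]
    references: dict[str, Partition]  # key "method|condition"

    def __post_init__(self):
        for cs in self.curves:
            if cs.levels != self.grid.levels:
                raise ValidationError("every CurveSet must share the result grid")

    def curve(self, method: str, condition: str = "observed") -> CurveSet:
        for cs in self.curves:
            if cs.method == method and cs.condition == condition:
                return cs
        raise KeyError(f"no curve for ({method!r}, {condition!r})")

    def methods(self) -> list[str]:
        seen: list[str] = []
        for cs in self.curves:
            if cs.method not in seen:
                seen.append(cs.method)
        return seen

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "grid": {"levels": list(self.grid.levels),
                     "replicates": self.grid.replicates},
            "measure": self.measure,
            "seed": self.seed,
            "curves": [cs.to_dict() for cs in self.curves],
            "references": {
                key: {"ids": list(part.ids), "labels": list(part.labels)}
                for key, part in self.references.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RobustnessResult":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        grid = PerturbationGrid(tuple(d["grid"]["levels"]), d["grid"]["replicates"])
        refs = {
            key: Partition(tuple(v["ids"]), tuple(v["labels"]))
            for key, v in d["references"].items()
        }
        return cls(
            d["n_nodes"],
            d["n_edges"],
            grid,
            d["measure"],
            d["seed"],
            [CurveSet.from_dict(c) for c in d["curves"]],
            refs,
        )

    def curves_to_csv(self, path) -> None:
        """Long format: level, replicate, method, condition, value."""
        import pandas as pd

        rows = []
        for cs in self.curves:
            for li, level in enumerate(cs.levels):
                for r in range(cs.replicates):
                    rows.append(
                        (level, r, cs.method, cs.condition, cs.values[li, r])
                    )
        pd.DataFrame(
            rows, columns=["level", "replicate", "method", "condition", "value"]
        ).to_csv(path, index=False)


def _ref_partition(graph: Graph, method: DetectionMethod, rng: RandomState) -> Partition:
    return detect_communities(graph, method, rng.substream(_S_REF, method.digest()))


def _level_column(
    graph: Graph,
    methods: Sequence[DetectionMethod],
    references: Sequence[Partition],
    level: float,
    li: int,
    replicates: int,
    measure: str,
    rng: RandomState,
) -> np.ndarray:
    """Distances for one level: shape (n_methods, replicates)."""
    out = np.empty((len(methods), replicates))
    for r in range(replicates):
        if level == 0.0:
            perturbed = graph
        else:
            perturbed = rewire_fraction(graph, level, rng.substream(_S_PERTURB, li, r))
        for mi, method in enumerate(methods):
            part = detect_communities(
                perturbed, method, rng.substream(_S_DETECT, li, r, method.digest())
            )
            out[mi, r] = partition_distance(references[mi], part, measure)
    return out


def _run_curves(
    graph: Graph,
    methods: Sequence[DetectionMethod],
    grid: PerturbationGrid,
    measure: str,
    rng: RandomState,
    condition: str,
    n_jobs: int,
) -> tuple[list[CurveSet], dict[str, Partition]]:
    graph.require_engine_ready()
    if measure not in MEASURES:
        raise DomainError(f"unknown measure {measure!r}")
    references = [_ref_partition(graph, m, rng) for m in methods]
    columns = Parallel(n_jobs=n_jobs)(
        delayed(_level_column)(
            graph, methods, references, level, li, grid.replicates, measure, rng
        )
        for li, level in enumerate(grid.levels)
    )
    stacked = np.stack(columns)  # (levels, methods, replicates)
    curvesets = [
        CurveSet(stacked[:, mi, :], grid.levels, m.spec, condition, measure)
        for mi, m in enumerate(methods)
    ]
    refs = {f"{m.spec}|{condition}": references[mi] for mi, m in enumerate(methods)}
    return curvesets, refs


def stability_curves(
    graph: Graph,
    method: DetectionMethod,
    grid: Optional[PerturbationGrid] = None,
    measure: str = "vi",
    rng: RandomState = RandomState(0),
    n_jobs: int = 1,
) -> CurveSet:
    """Stability curve of one method on one graph.

    For each (level, replicate): rewire the original graph by the level
    fraction, re-detect, and measure the distance to the reference partition
    detected on the unperturbed graph.  Perturbations are independent across
    cells (never cumulative), so levels are directly comparable.
    """
    grid = grid or PerturbationGrid()
    curvesets, _ = _run_curves(graph, [method], grid, measure, rng, "observed", n_jobs)
    return curvesets[0]


def validate_vs_null(
    graph: Graph,
    method: DetectionMethod,
    grid: Optional[PerturbationGrid] = None,
    measure: str = "vi",
    rng: RandomState = RandomState(0),
    swaps_per_edge: int = 10,
    n_jobs: int = 1,
) -> RobustnessResult:
    """Observed vs configuration-model-null stability curves for one method.

    The null graph preserves the degree sequence of the input; its curve uses
    its *own* reference partition, so the null curve reflects whatever
    community structure survives degree-preserving randomization.
    """
    grid = grid or PerturbationGrid()
    graph.require_engine_ready()
    null_graph = configuration_null(graph, rng.substream(_S_NULLGRAPH), swaps_per_edge)
    obs_curves, obs_refs = _run_curves(
        graph, [method], grid, measure, rng, "observed", n_jobs
    )
    null_curves, null_refs = _run_curves(
        null_graph, [method], grid, measure, rng.substream(_S_NULLBASE), "null", n_jobs
    )
    return RobustnessResult(
        graph.n_nodes,
        graph.n_edges,
        grid,
        measure,
        rng.seed if not rng.key else None,
        obs_curves + null_curves,
        {**obs_refs, **null_refs},
    )


def compare_methods(
    graph: Graph,
    methods: Sequence[DetectionMethod],
    grid: Optional[PerturbationGrid] = None,
    measure: str = "vi",
    rng: RandomState = RandomState(0),
    n_jobs: int = 1,
    allow_duplicates: bool = False,
) -> RobustnessResult:
    """Paired multi-method comparison on shared perturbed graphs.

    For every (level, replicate) cell ONE perturbed graph is generated and
    every method is run on it, which removes perturbation noise from
    between-method contrasts.  Each method keeps its own reference partition
    on the unperturbed graph.
    """
    grid = grid or PerturbationGrid()
    methods = list(methods)
    if len(methods) < 2:
        raise ValidationError("compare_methods needs at least two methods")
    specs = [m.spec for m in methods]
    if len(set(specs)) != len(specs) and not allow_duplicates:
        raise ValidationError(f"duplicate method specifications: {specs}")
    curves, refs = _run_curves(graph, methods, grid, measure, rng, "observed", n_jobs)
    return RobustnessResult(
        graph.n_nodes,
        graph.n_edges,
        grid,
        measure,
        rng.seed if not rng.key else None,
        curves,
        refs,
    )
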