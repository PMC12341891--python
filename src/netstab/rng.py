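"""Deterministic, hierarchically splittable random streams.

Every stochastic operation in the package takes a :class:`RandomState` and
derives the numbers it needs from it.  A ``RandomState`` is an immutable
(seed, key) pair; ``substream(*indices)`` extends the key, and the underlying
generator is created fresh from ``numpy.random.SeedSequence(seed, spawn_key=key)``
each time it is requested.  Consequences:

* identical seed => bit-identical results, regardless of the order in which
  substreams are consumed or how work is scheduled across workers;
* a ``RandomState`` carries no mutable state, so passing the same object to
  two calls yields the same draws (substreams exist precisely to avoid that
  when independence is wanted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RandomState"]


@dataclass(frozen=True)
class RandomState:
    """Immutable handle on a seeded random stream.

    Parameters
    ----------
    seed:
        Any Python integer; reduced modulo 2**64 before use.
    key:
        Substream path, extended by :meth:`substream`.  Leave empty at the
        top level.
    """

    seed: int
    key: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError(f"seed must be an integer, got {type(self.seed).__name__}")
        if any(i < 0 for i in self.key):
            raise ValueError("substream indices must be non-negative")

    def substream(self, *indices: int) -> "RandomState":
        """Return an independent child stream addressed by ``indices``."""
        return RandomState(self.seed, self.key + tuple(int(i) for i in indices))

    @property
    def generator(self) -> np.random.Generator:
        """A fresh Generator for this (seed, key) pair.

        Repeated access returns an equivalent generator positioned at the
        start of the stream.
        """
        ss = np.random.SeedSequence(self.seed % 2**64, spawn_key=self.key)
        return np.random.default_rng(ss)

    def integer(self, high: int = 2**31) -> int:
        """A deterministic integer in [0, high), e.g. to seed a foreign RNG."""
        return int(self.generator.integers(high))
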