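"""Core vector types: an ordered gene universe and signed ternary vectors.

Every analysis in this package operates on dense ternary vectors over a
fixed, ordered gene universe.  A value of +1 encodes up-regulation of a
transcript (transcriptomic vectors) or activation of a protein by a
compound (target vectors); -1 encodes down-regulation / inhibition; 0
encodes no change / no known binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["GeneUniverse", "SignedVector", "UniverseMismatchError"]


class UniverseMismatchError(ValueError):
    """Raised when two vectors defined over different universes are combined."""


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered list of unique gene identifiers.

    The ordering defines the index of every gene in all vectors built over
    this universe.  Identifiers are opaque strings; matching is exact.
    """

    genes: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            dups = sorted({g for g in genes if g in seen or seen.add(g)})
            raise ValueError(f"duplicate gene identifiers in universe: {dups[:5]}")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(genes)})

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        """Indices of ``genes``, raising ``KeyError`` listing unknown ones."""
        idx, unknown = [], []
        for g in genes:
            i = self._index.get(g)
            if i is None:
                unknown.append(g)
            else:
                idx.append(i)
        if unknown:
            raise KeyError(f"genes not in universe: {sorted(unknown)}")
        return np.asarray(idx, dtype=np.intp)


@dataclass
class SignedVector:
    """A dense ternary (-1/0/+1) vector over an ordered gene universe."""

    universe: GeneUniverse
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 1 or len(values) != len(self.universe):
            raise ValueError(
                f"vector length {values.shape} does not match universe size "
                f"{len(self.universe)}"
            )
        if not np.isin(values, (-1, 0, 1)).all():
            bad = np.unique(values[~np.isin(values, (-1, 0, 1))])
            raise ValueError(f"vector values must be in {{-1, 0, +1}}; got {bad}")
        self.values = values

    @classmethod
    def zeros(cls, universe: GeneUniverse) -> "SignedVector":
        return cls(universe, np.zeros(len(universe), dtype=np.int8))

    @classmethod
    def from_dict(
        cls, universe: GeneUniverse, signs: Mapping[str, int]
    ) -> "SignedVector":
        """Build a vector from a ``gene -> sign`` mapping; other genes are 0."""
        values = np.zeros(len(universe), dtype=np.int8)
        if signs:
            idx = universe.indices(signs.keys())
            values[idx] = np.fromiter(signs.values(), dtype=np.int8, count=len(signs))
        return cls(universe, values)

    def to_dict(self) -> dict[str, int]:
        """Nonzero entries as a ``gene -> sign`` mapping."""
        nz = np.flatnonzero(self.values)
        return {self.universe.genes[i]: int(self.values[i]) for i in nz}

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.universe.genes[i] for i in np.flatnonzero(self.values))

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.values))

    def copy(self) -> "SignedVector":
        return SignedVector(self.universe, self.values.copy())

    def __getitem__(self, gene: str) -> int:
        return int(self.values[self.universe.index_of(gene)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedVector):
            return NotImplemented
        return self.universe == other.universe and np.array_equal(
            self.values, other.values
        )


def stack_vectors(vectors: Sequence[SignedVector]) -> np.ndarray:
    """Stack aligned vectors into an ``(n, n_genes)`` int8 matrix.

    All vectors must share the same universe.
    """
    if not vectors:
        raise ValueError("cannot stack an empty vector collection")
    universe = vectors[0].universe
    for v in vectors[1:]:
        if v.universe != universe:
            raise UniverseMismatchError("vectors defined over different universes")
    return np.stack([v.values for v in vectors])
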