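"""Densification of sparse target vectors with prior knowledge.

Target vectors typically carry only a handful of nonzero entries, far
fewer than transcriptomic vectors, so direct correlation between the two
is dominated by zeros.  Two enrichment routes copy a target's sign onto
genes expected to change downstream of it:

* **pathway vectors** — every gene co-occurring with a target in a
  retained pathway gene set inherits the target's sign;
* **PPI vectors** — signs are propagated level by level through a signed
  directed protein-protein interaction network, the sign of a newly
  reached gene being the product of its source's sign and the edge
  polarity (activation +1 / inhibition -1).

In both routes the original target entries are preserved verbatim and a
gene receiving conflicting signs is set to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .vectors import SignedVector

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "SignedNetwork",
    "filter_gene_sets",
    "build_pathway_vector",
    "propagate_ppi",
    "subset_gene_sets",
]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets with a provenance label."""

    sets: dict[str, frozenset[str]]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty[:5]}")
        self.sets = {name: frozenset(s) for name, s in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sets.items()}

    def membership_index(self) -> dict[str, list[str]]:
        """Mapping ``gene -> list of set names containing it``."""
        index: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            for g in members:
                index.setdefault(g, []).append(name)
        return index


class SignedNetwork:
    """A directed graph whose edges carry an activation/inhibition polarity.

    Duplicate edges are deduplicated; a pair of contradictory duplicates
    (same endpoints, both polarities) is collapsed into a single edge of
    polarity 0, which acts as a sign conflict during propagation.
    Self-loops are stored but never participate in propagation.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, int]],
        nodes: Iterable[str] = (),
    ) -> None:
        self._edges: dict[tuple[str, str], int] = {}
        self._nodes: set[str] = set(nodes)
        for u, v, pol in edges:
            if pol not in (-1, 1):
                raise ValueError(f"edge ({u}, {v}): polarity must be -1 or +1")
            self._nodes.add(u)
            self._nodes.add(v)
            prev = self._edges.get((u, v))
            if prev is None:
                self._edges[(u, v)] = pol
            elif prev != pol and prev != 0:
                logger.warning(
                    "contradictory duplicate edge %s->%s; treating as conflict", u, v
                )
                self._edges[(u, v)] = 0
        self._succ: dict[str, list[tuple[str, int]]] = {}
        for (u, v), pol in self._edges.items():
            self._succ.setdefault(u, []).append((v, pol))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_list(self) -> list[tuple[str, str, int]]:
        return [(u, v, pol) for (u, v), pol in sorted(self._edges.items())]

    def successors(self, node: str) -> list[tuple[str, int]]:
        return self._succ.get(node, [])

    def degrees(self) -> dict[str, tuple[int, int]]:
        """Per-node ``(in_degree, out_degree)``."""
        deg = {n: [0, 0] for n in self._nodes}
        for u, v in self._edges:
            deg[u][1] += 1
            deg[v][0] += 1
        return {n: (i, o) for n, (i, o) in deg.items()}

    def polarity_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for pol in self._edges.values():
            counts[pol] = counts.get(pol, 0) + 1
        return counts

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for (u, v), pol in self._edges.items():
            g.add_edge(u, v, polarity=pol)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self._edges == other._edges and self._nodes == other._nodes


def filter_gene_sets(
    collection: GeneSetCollection, min_size: int = 15, max_size: int = 300
) -> GeneSetCollection:
    """Keep gene sets with ``min_size <= |set| <= max_size`` (inclusive).

    The defaults follow common pathway-enrichment practice: very small
    sets are statistically unstable and very large ones (e.g. global
    metabolism) are uninformative.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError(f"invalid size bounds ({min_size}, {max_size})")
    kept = {
        name: s
        for name, s in collection.sets.items()
        if min_size <= len(s) <= max_size
    }
    return GeneSetCollection(kept, provenance=collection.provenance)


def build_pathway_vector(
    target: SignedVector,
    collection: GeneSetCollection,
    membership: Mapping[str, list[str]] | None = None,
) -> SignedVector:
    """Copy each target's sign onto its pathway co-members.

    Every non-target universe gene sharing at least one retained pathway
    with a target receives that target's sign; conflicting signs from
    different targets cancel to 0.  Original target entries always win
    over propagated values.  ``membership`` may carry a precomputed
    ``collection.membership_index()`` when enriching many compounds
    against the same collection.
    """
    universe = target.universe
    if membership is None:
        membership = collection.membership_index()
    plus: set[str] = set()
    minus: set[str] = set()
    for i in np.flatnonzero(target.values):
        gene = universe.genes[i]
        sign = int(target.values[i])
        sink = plus if sign > 0 else minus
        for name in membership.get(gene, ()):
            sink.update(collection.sets[name])
    out = target.values.copy()
    target_mask = target.values != 0
    for genes, sign in ((plus - minus, 1), (minus - plus, -1)):
        idx = [universe.index_of(g) for g in genes if g in universe]
        for i in idx:
            if not target_mask[i]:
                out[i] = sign
    # conflicting contributions (gene in both plus and minus) stay 0
    return SignedVector(universe, out)


def propagate_ppi(
    target: SignedVector,
    network: SignedNetwork,
    levels: int,
    *,
    allow_any_levels: bool = False,
) -> SignedVector:
    """Propagate target signs through a signed directed network.

    Breadth-first by level from all nonzero seed genes.  A gene first
    reached at level k inherits ``source sign x edge polarity``; if it is
    reached at that level through routes whose sign products disagree it
    is set to 0 and marked visited.  A conflicted gene contributes no
    sign of its own, but its conflict travels onward: genes first
    reached through it inherit the disagreement and are likewise 0.
    Genes already assigned (seeds included) are never overwritten, so
    the result for every gene is determined by its *shortest* signed
    routes from the seed set: the common sign product when they all
    agree, 0 otherwise.  Output support is non-decreasing in ``levels``.

    ``levels`` outside 1..5 is rejected unless ``allow_any_levels`` is
    set: deeper propagation saturates the vector and is rarely
    informative.
    """
    if not allow_any_levels and not 1 <= levels <= 5:
        raise ValueError(
            f"levels must be in 1..5 (got {levels}); pass allow_any_levels=True "
            "to override"
        )
    if levels < 0:
        raise ValueError("levels must be non-negative")
    universe = target.universe
    assigned: dict[str, int] = {
        universe.genes[i]: int(target.values[i])
        for i in np.flatnonzero(target.values)
    }
    frontier = list(assigned)
    for _ in range(levels):
        contributions: dict[str, set[int]] = {}
        for g in frontier:
            s = assigned[g]
            for h, pol in network.successors(g):
                if h == g or h in assigned:
                    continue
                if s == 0 or pol == 0:
                    # conflicted source or contradictory duplicate edge:
                    # the disagreement itself propagates
                    contributions.setdefault(h, set()).update((1, -1))
                else:
                    contributions.setdefault(h, set()).add(s * pol)
        frontier = []
        for h, signs in contributions.items():
            assigned[h] = signs.pop() if len(signs) == 1 else 0
            frontier.append(h)
        if not frontier:
            break
    out = target.values.copy()
    for g, s in assigned.items():
        if g in universe:
            i = universe.index_of(g)
            if target.values[i] == 0:
                out[i] = s
    return SignedVector(universe, out)


def subset_gene_sets(
    collection: GeneSetCollection,
    drop_top_k: int | None = None,
    size_band: tuple[int, int] | None = None,
) -> GeneSetCollection:
    """Subset a collection either by dropping its k largest sets or by size band.

    Exactly one selector must be given.  ``drop_top_k`` removes the k
    largest sets (ties broken by name order); ``size_band=(lo, hi)``
    keeps sets with ``lo <= size <= hi``.
    """
    if (drop_top_k is None) == (size_band is None):
        raise ValueError("give exactly one of drop_top_k or size_band")
    if drop_top_k is not None:
        if drop_top_k < 0:
            raise ValueError("drop_top_k must be >= 0")
        ranked = sorted(
            collection.sets.items(), key=lambda kv: (-len(kv[1]), kv[0])
        )
        kept = dict(ranked[drop_top_k:])
        return GeneSetCollection(
            {name: collection.sets[name] for name in collection.sets if name in kept},
            provenance=collection.provenance,
        )
    lo, hi = size_band
    kept = {
        name: s for name, s in collection.sets.items() if lo <= len(s) <= hi
    }
    return GeneSetCollection(kept, provenance=collection.provenance)


def log_uniform_sizes(
    rng: np.random.Generator, n: int, lo: int, hi: int
) -> np.ndarray:
    """Draw integer set sizes log-uniformly in [lo, hi] (long-tail shape)."""
    raw = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    return np.clip(np.round(raw).astype(int), lo, hi)
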