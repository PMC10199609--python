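"""Permutation null models and empirical p-value machinery.

Three nulls probe different layers of the analysis:

* **pair shuffling** — breaks the compound-level pairing of target and
  transcriptomic vectors while keeping both vector populations intact;
* **occurrence-preserving random gene sets** — rebuilds each pathway at
  its original size from the pooled multiset of gene occurrences, so an
  enrichment gain cannot be explained by set sizes alone;
* **XSWAP network randomisation** — degree-preserving edge rewiring that
  destroys higher-order network structure while conserving every node's
  in/out-degree and the polarity multiset.

All empirical p-values are one-sided upper-tail with a +1 pseudocount:
p = (1 + #{null >= observed}) / (n_iter + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .enrichment import GeneSetCollection, SignedNetwork, propagate_ppi
from .metrics import jaccard_matrix, pearson_matrix
from .vectors import SignedVector, stack_vectors

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "pair_shuffle_test",
    "random_gene_sets",
    "xswap",
    "network_permutation_test",
    "gene_set_permutation_test",
]

_METRICS = ("pearson", "jaccard", "abs_pearson")


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and raw/adjusted p-values."""

    observed: float
    null_means: np.ndarray
    n_iter: int
    p_raw: float
    n_tests: int = 1
    seed: int | None = None
    defined: bool = True
    p_adjusted: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_means = np.asarray(self.null_means, dtype=np.float64)
        if len(self.null_means) != self.n_iter:
            raise ValueError("null_means length must equal n_iter")
        self.p_adjusted = min(1.0, self.p_raw * self.n_tests)

    def summary(self) -> dict:
        q = np.quantile(self.null_means, [0.025, 0.5, 0.975]) if self.n_iter else []
        return {
            "observed": self.observed,
            "defined": self.defined,
            "null_mean": float(np.mean(self.null_means)) if self.n_iter else None,
            "null_sd": float(np.std(self.null_means)) if self.n_iter else None,
            "null_quantiles": [float(v) for v in q],
            "n_iter": self.n_iter,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "n_tests": self.n_tests,
            "seed": self.seed,
        }


def _empirical_p(observed: float, null: np.ndarray) -> float:
    return (1 + int(np.count_nonzero(null >= observed))) / (len(null) + 1)


def _metric_matrix(
    X: np.ndarray, Y: np.ndarray, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    if metric == "pearson":
        return pearson_matrix(X, Y)
    if metric == "abs_pearson":
        vals, defined = pearson_matrix(X, Y)
        return np.abs(vals), defined
    if metric == "jaccard":
        return jaccard_matrix(X, Y)
    raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def _masked_mean(vals: np.ndarray, defined: np.ndarray) -> float:
    n = int(np.count_nonzero(defined))
    if n == 0:
        return float("nan")
    return float(vals[defined].sum() / n)


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return vectors
    return stack_vectors(list(vectors))


def pair_shuffle_test(
    targets: Sequence[SignedVector] | np.ndarray,
    transcriptomics: Sequence[SignedVector] | np.ndarray,
    metric: str = "pearson",
    n_iter: int = 100_000,
    seed: int = 0,
    n_tests: int = 1,
) -> PermutationResult:
    """Test whether aligned target/transcriptomic pairs agree beyond chance.

    The observed statistic is the mean metric over aligned pairs
    (undefined pairs excluded).  Each iteration shuffles the
    transcriptomic collection against the fixed target collection and
    records the resulting mean.

    Shuffling a pairing only permutes which precomputed cross-metric
    entries are read, so the full ``n x n`` metric matrix is computed
    once and each iteration is an indexing pass.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = _as_matrix(targets)
    Y = _as_matrix(transcriptomics)
    if len(X) != len(Y) or len(X) < 2:
        raise ValueError(
            f"collections must be aligned with length >= 2; got {len(X)}, {len(Y)}"
        )
    vals, defined = _metric_matrix(X, Y, metric)
    n = len(X)
    idx = np.arange(n)
    observed = _masked_mean(vals[idx, idx], defined[idx, idx])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(n)
        null[i] = _masked_mean(vals[idx, perm], defined[idx, perm])
    ok = np.isfinite(observed)
    p_raw = _empirical_p(observed, null[np.isfinite(null)]) if ok else 1.0
    if not ok:
        observed = 0.0
    return PermutationResult(
        observed=observed,
        null_means=null,
        n_iter=n_iter,
        p_raw=p_raw,
        n_tests=n_tests,
        seed=seed,
        defined=bool(ok),
    )


def random_gene_sets(
    collection: GeneSetCollection, n_collections: int, seed: int = 0
) -> Iterator[GeneSetCollection]:
    """Occurrence-preserving random gene-set collections.

    Each emitted collection keeps every set's name and size; members are
    drawn without replacement (per set) from the multiset of gene
    occurrences pooled over the whole original collection, so a gene
    appearing in many original pathways is proportionally likely to
    appear in many random ones.

    Draws use systematic probability-proportional-to-size sampling (in a
    freshly shuffled gene order per draw): a set of size m selects each
    pool gene with inclusion probability exactly m * occurrence / pool
    size (capped at 1 with proportional redistribution), so per-gene
    occurrence is preserved in expectation, not merely approximately —
    naive sequential weighted draws without replacement under-sample
    frequent genes.
    """
    if not collection.sets:
        raise ValueError("collection must be non-empty")
    counts: dict[str, int] = {}
    for members in collection.sets.values():
        for g in members:
            counts[g] = counts.get(g, 0) + 1
    pool = np.array(sorted(counts), dtype=object)
    weights = np.array([counts[g] for g in pool], dtype=np.float64)
    rng = np.random.default_rng(seed)

    def inclusion_probs(m: int) -> np.ndarray:
        pi = m * weights / weights.sum()
        # cap at 1 and redistribute until feasible
        for _ in range(len(pi)):
            over = pi > 1.0
            if not over.any():
                break
            free = ~over
            deficit = m - int(over.sum())
            pi = np.where(over, 1.0, 0.0)
            if deficit > 0 and free.any():
                pi[free] = deficit * weights[free] / weights[free].sum()
        return pi

    probs_by_size = {m: inclusion_probs(m) for m in {len(s) for s in collection.sets.values()}}
    for _ in range(n_collections):
        sets = {}
        for name, members in collection.sets.items():
            m = len(members)
            order = rng.permutation(len(pool))
            cum = np.cumsum(probs_by_size[m][order])
            thresholds = rng.random() + np.arange(m)
            picked = np.searchsorted(cum, thresholds, side="right")
            picked = np.clip(picked, 0, len(pool) - 1)  # float-precision guard
            sets[name] = frozenset(pool[order[i]] for i in picked)
        yield GeneSetCollection(sets, provenance=f"{collection.provenance}|random")


def xswap(
    network: SignedNetwork, n_swap_attempts: int, seed: int = 0
) -> SignedNetwork:
    """Degree-preserving randomisation of a signed directed network.

    Repeatedly picks two directed edges (a->b, c->d) and rewires them to
    (a->d, c->b) unless that would create a self-loop or a duplicate
    edge.  Polarity travels with the original source's edge, so every
    node's in/out-degree, the edge count and the polarity multiset are
    conserved exactly.
    """
    if n_swap_attempts < 1:
        raise ValueError("n_swap_attempts must be >= 1")
    edges = network.edge_list()
    if len(edges) < 2:
        raise ValueError("network must have at least 2 edges")
    present = {(u, v) for u, v, _ in edges}
    rng = np.random.default_rng(seed)
    m = len(edges)
    for _ in range(n_swap_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b, p1 = edges[i]
        c, d, p2 = edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        new1, new2 = (a, d), (c, b)
        if new1 == new2:
            continue
        remaining = present - {(a, b), (c, d)}
        if new1 in remaining or new2 in remaining:
            continue  # would create a duplicate edge
        edges[i] = (a, d, p1)
        edges[j] = (c, b, p2)
        present = remaining | {new1, new2}
    return SignedNetwork(edges, nodes=network.nodes)


def network_permutation_test(
    targets: Sequence[SignedVector],
    transcriptomics: Sequence[SignedVector],
    network: SignedNetwork,
    levels: int = 3,
    n_networks: int = 100,
    metric: str = "abs_pearson",
    seed: int = 0,
    n_swap_attempts: int | None = None,
    n_tests: int = 1,
) -> PermutationResult:
    """Does the real network topology explain target/transcriptome agreement?

    The observed statistic is the mean metric between PPI-propagated
    target vectors (through the original network, ``levels`` deep) and
    the transcriptomic vectors.  Each null draw propagates the same
    targets through a freshly XSWAP-randomised network of identical
    degree structure.  Compounds whose propagated vector is all-zero
    under the original network are excluded from every mean (with a
    warning); ``n_swap_attempts`` defaults to 10 x |E|.
    """
    if len(targets) != len(transcriptomics) or len(targets) < 2:
        raise ValueError("collections must be aligned with length >= 2")
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if n_swap_attempts is None:
        n_swap_attempts = 10 * network.n_edges

    targets = list(targets)
    Y = stack_vectors(list(transcriptomics))

    def mean_metric(net: SignedNetwork, keep: np.ndarray | None) -> tuple[float, np.ndarray]:
        prop = np.stack(
            [propagate_ppi(t, net, levels).values for t in targets]
        )
        nonzero = prop.any(axis=1)
        mask = nonzero if keep is None else keep
        vals, defined = _metric_matrix(prop, Y, metric)
        idx = np.arange(len(targets))
        d = defined[idx, idx] & mask
        return _masked_mean(vals[idx, idx], d), nonzero

    observed, nonzero = mean_metric(network, None)
    n_dropped = int(np.count_nonzero(~nonzero))
    if n_dropped:
        logger.warning(
            "%d/%d compounds have an all-zero propagated vector; excluded "
            "from means",
            n_dropped,
            len(targets),
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_networks)
    for k in range(n_networks):
        if n_swap_attempts == 0:
            permuted = network
        else:
            permuted = xswap(
                network, n_swap_attempts, seed=int(rng.integers(2**31 - 1))
            )
        null[k], _ = mean_metric(permuted, nonzero)
    ok = np.isfinite(observed)
    p_raw = _empirical_p(observed, null[np.isfinite(null)]) if ok else 1.0
    return PermutationResult(
        observed=float(observed) if ok else 0.0,
        null_means=null,
        n_iter=n_networks,
        p_raw=p_raw,
        n_tests=n_tests,
        seed=seed,
        defined=bool(ok),
    )


def gene_set_permutation_test(
    targets: Sequence[SignedVector],
    transcriptomics: Sequence[SignedVector],
    collection: GeneSetCollection,
    n_collections: int = 1000,
    metric: str = "jaccard",
    seed: int = 0,
    n_tests: int = 1,
) -> PermutationResult:
    """Pathway-level null: re-enrich targets with random gene-set collections.

    The observed statistic is the mean metric between pathway-enriched
    target vectors (using the original, size-filtered collection) and
    the transcriptomic vectors; each null draw repeats the full
    enrichment with an occurrence-preserving random collection from
    :func:`random_gene_sets`.
    """
    from .enrichment import build_pathway_vector  # local to avoid cycle noise

    if len(targets) != len(transcriptomics) or len(targets) < 2:
        raise ValueError("collections must be aligned with length >= 2")
    Y = stack_vectors(list(transcriptomics))
    idx = np.arange(len(targets))

    def mean_metric(coll: GeneSetCollection) -> float:
        membership = coll.membership_index()
        X = np.stack(
            [build_pathway_vector(t, coll, membership).values for t in targets]
        )
        vals, defined = _metric_matrix(X, Y, metric)
        return _masked_mean(vals[idx, idx], defined[idx, idx])

    observed = mean_metric(collection)
    null = np.array(
        [
            mean_metric(c)
            for c in random_gene_sets(collection, n_collections, seed=seed)
        ]
    )
    ok = np.isfinite(observed)
    p_raw = _empirical_p(observed, null[np.isfinite(null)]) if ok else 1.0
    return PermutationResult(
        observed=float(observed) if ok else 0.0,
        null_means=null,
        n_iter=n_collections,
        p_raw=p_raw,
        n_tests=n_tests,
        seed=seed,
        defined=bool(ok),
    )
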