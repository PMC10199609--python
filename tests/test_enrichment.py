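"""Pathway and signed-network enrichment of target vectors."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from chemtx import (
    GeneSetCollection,
    GeneUniverse,
    SignedNetwork,
    build_pathway_vector,
    filter_gene_sets,
    propagate_ppi,
    subset_gene_sets,
)
from chemtx.vectors import SignedVector

from conftest import make_vector


def sets_of_sizes(*sizes):
    return GeneSetCollection(
        {f"S{k}": frozenset(f"g{k}_{i}" for i in range(n)) for k, n in enumerate(sizes)}
    )


class TestFilterGeneSets:
    def test_boundaries_inclusive(self):
        coll = sets_of_sizes(10, 15, 150, 300, 301)
        kept = filter_gene_sets(coll)
        assert sorted(kept.sizes().values()) == [15, 150, 300]

    def test_wide_bounds_identity(self):
        coll = sets_of_sizes(3, 40, 500)
        assert filter_gene_sets(coll, 1, 10**9).sets == coll.sets

    def test_empty_collection(self):
        assert len(filter_gene_sets(GeneSetCollection({}))) == 0

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_gene_sets(sets_of_sizes(5), 10, 5)


class TestBuildPathwayVector:
    def test_co_members_inherit_target_sign(self):
        uni = GeneUniverse(("B", "C", "D", "E"))
        coll = GeneSetCollection({"P": frozenset({"B", "C", "D"})})
        t = SignedVector.from_dict(uni, {"B": 1})
        assert build_pathway_vector(t, coll).values.tolist() == [1, 1, 1, 0]

    def test_conflicting_contributions_cancel(self):
        uni = GeneUniverse(("B", "F", "C"))
        coll = GeneSetCollection(
            {"P1": frozenset({"B", "C"}), "P2": frozenset({"F", "C"})}
        )
        t = SignedVector.from_dict(uni, {"B": 1, "F": -1})
        v = build_pathway_vector(t, coll)
        assert v["B"] == 1 and v["F"] == -1 and v["C"] == 0

    def test_all_zero_target_stays_zero(self):
        uni = GeneUniverse(("A", "B"))
        coll = GeneSetCollection({"P": frozenset({"A", "B"})})
        v = build_pathway_vector(SignedVector.zeros(uni), coll)
        assert v.n_nonzero == 0

    def test_original_targets_win_over_propagation(self):
        # F is itself a target (-1) and co-occurs with B (+1): keeps -1
        uni = GeneUniverse(("B", "F"))
        coll = GeneSetCollection({"P": frozenset({"B", "F"})})
        t = SignedVector.from_dict(uni, {"B": 1, "F": -1})
        v = build_pathway_vector(t, coll)
        assert v["F"] == -1

    def test_genes_outside_universe_ignored(self):
        uni = GeneUniverse(("B", "C"))
        coll = GeneSetCollection({"P": frozenset({"B", "C", "NOT_MEASURED"})})
        v = build_pathway_vector(SignedVector.from_dict(uni, {"B": 1}), coll)
        assert v.values.tolist() == [1, 1]

    def test_support_superset_of_target(self, rng):
        genes = tuple(f"G{i}" for i in range(40))
        uni = GeneUniverse(genes)
        coll = GeneSetCollection(
            {
                f"P{k}": frozenset(
                    np.random.default_rng(k).choice(genes, size=8, replace=False)
                )
                for k in range(6)
            }
        )
        for _ in range(10):
            idx = rng.choice(40, size=3, replace=False)
            t = SignedVector.from_dict(
                uni, {genes[i]: int(s) for i, s in zip(idx, rng.choice([-1, 1], 3))}
            )
            assert build_pathway_vector(t, coll).support >= t.support


def enumerate_minimal_path_signs(edges, seeds, k):
    """Independent oracle: exhaustive minimal-length signed path enumeration.

    ``edges``: dict (u, v) -> polarity.  ``seeds``: dict node -> sign.
    For each non-seed node reachable within k hops, collect the sign
    products of *all* walks from a seed whose length equals the node's
    minimal distance from the seed set; assign the common product if
    they agree, else 0.
    """
    succ = {}
    for (u, v), pol in edges.items():
        if u != v:
            succ.setdefault(u, []).append((v, pol))
    # multi-source BFS distances
    dist = {s: 0 for s in seeds}
    q = deque(seeds)
    while q:
        u = q.popleft()
        if dist[u] >= k:
            continue
        for v, _ in succ.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)

    def walk_products(node, length):
        """Sign products of all length-``length`` walks seed -> node."""
        if length == 0:
            return [seeds[node]] if node in seeds else []
        products = []
        for (u, v), pol in edges.items():
            if v == node and u != v and u in dist and dist[u] <= length - 1:
                for p in walk_products(u, length - 1):
                    products.append(p * pol)
        return products

    out = {}
    for node, d in dist.items():
        if node in seeds:
            out[node] = seeds[node]
            continue
        prods = set(walk_products(node, d))
        out[node] = prods.pop() if len(prods) == 1 else 0
    return out


class TestPropagatePPI:
    def test_activation_carries_sign(self):
        uni = GeneUniverse(("T", "A"))
        net = SignedNetwork([("T", "A", 1)])
        v = propagate_ppi(SignedVector.from_dict(uni, {"T": 1}), net, 1)
        assert v["A"] == 1

    def test_inhibition_of_inhibited_target_activates(self):
        uni = GeneUniverse(("T", "B"))
        net = SignedNetwork([("T", "B", -1)])
        v = propagate_ppi(SignedVector.from_dict(uni, {"T": -1}), net, 1)
        assert v["B"] == 1

    def test_sign_is_product_of_polarities_along_path(self):
        uni = GeneUniverse(("T", "A", "C"))
        net = SignedNetwork([("T", "A", 1), ("A", "C", -1)])
        t = SignedVector.from_dict(uni, {"T": 1})
        assert propagate_ppi(t, net, 2)["C"] == -1
        assert propagate_ppi(t, net, 1)["C"] == 0

    def test_conflicting_minimal_routes_cancel(self):
        uni = GeneUniverse(("T", "A", "B", "C"))
        net = SignedNetwork([("T", "A", 1), ("T", "B", -1), ("A", "C", 1), ("B", "C", 1)])
        v = propagate_ppi(SignedVector.from_dict(uni, {"T": 1}), net, 2)
        assert v["C"] == 0

    def test_conflict_poisons_downstream_genes(self):
        # D is only reachable through the conflicted gene C: also 0
        uni = GeneUniverse(("T", "A", "B", "C", "D"))
        net = SignedNetwork(
            [("T", "A", 1), ("T", "B", -1), ("A", "C", 1), ("B", "C", 1), ("C", "D", 1)]
        )
        v = propagate_ppi(SignedVector.from_dict(uni, {"T": 1}), net, 3)
        assert v["C"] == 0 and v["D"] == 0

    def test_seeds_never_overwritten(self):
        uni = GeneUniverse(("T", "U"))
        net = SignedNetwork([("T", "U", -1), ("U", "T", -1)])
        v = propagate_ppi(SignedVector.from_dict(uni, {"T": 1, "U": 1}), net, 2)
        assert v["T"] == 1 and v["U"] == 1

    def test_levels_range_enforced_with_override(self):
        uni = GeneUniverse(("T", "A"))
        net = SignedNetwork([("T", "A", 1)])
        t = SignedVector.from_dict(uni, {"T": 1})
        with pytest.raises(ValueError, match="levels"):
            propagate_ppi(t, net, 6)
        assert propagate_ppi(t, net, 6, allow_any_levels=True)["A"] == 1

    def test_support_nondecreasing_in_levels(self, rng):
        genes = tuple(f"N{i}" for i in range(15))
        uni = GeneUniverse(genes)
        edges = []
        for _ in range(30):
            u, v = rng.choice(15, size=2, replace=False)
            edges.append((genes[u], genes[v], int(rng.choice([-1, 1]))))
        net = SignedNetwork(edges)
        t = SignedVector.from_dict(uni, {genes[0]: 1, genes[1]: -1})
        supports = [propagate_ppi(t, net, k).support for k in range(1, 6)]
        for a, b in zip(supports, supports[1:]):
            assert a <= b

    def test_all_positive_network_support_is_bfs_ball(self, rng):
        genes = tuple(f"N{i}" for i in range(12))
        uni = GeneUniverse(genes)
        edges = []
        seen = set()
        for _ in range(25):
            u, v = rng.choice(12, size=2, replace=False)
            if (u, v) not in seen:
                seen.add((u, v))
                edges.append((genes[u], genes[v], 1))
        net = SignedNetwork(edges)
        t = SignedVector.from_dict(uni, {genes[0]: 1})
        for k in (1, 2, 3):
            v = propagate_ppi(t, net, k)
            # k-hop BFS ball from the seed
            ball = {genes[0]}
            frontier = {genes[0]}
            for _ in range(k):
                frontier = {
                    h for g in frontier for h, _ in net.successors(g)
                } - ball
                ball |= frontier
            assert v.support == ball

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        genes = tuple(f"N{i}" for i in range(n))
        uni = GeneUniverse(genes)
        edges = {}
        for _ in range(int(rng.integers(n, 3 * n))):
            u, v = rng.choice(n, size=2, replace=False)
            edges[(genes[u], genes[v])] = int(rng.choice([-1, 1]))
        net = SignedNetwork([(u, v, p) for (u, v), p in edges.items()])
        n_seeds = int(rng.integers(1, 3))
        seed_idx = rng.choice(n, size=n_seeds, replace=False)
        seeds = {genes[i]: int(s) for i, s in zip(seed_idx, rng.choice([-1, 1], n_seeds))}
        t = SignedVector.from_dict(uni, seeds)
        for k in range(1, 6):
            got = propagate_ppi(t, net, k).to_dict()
            expected = {
                g: s for g, s in enumerate_minimal_path_signs(edges, seeds, k).items() if s != 0
            }
            assert got == expected, f"seed={seed} k={k}"


class TestSubsetGeneSets:
    def test_drop_top_k(self):
        coll = sets_of_sizes(300, 200, 100, 50)
        kept = subset_gene_sets(coll, drop_top_k=2)
        assert sorted(kept.sizes().values()) == [50, 100]

    def test_size_band(self):
        coll = sets_of_sizes(50, 100, 200, 300, 350)
        kept = subset_gene_sets(coll, size_band=(100, 300))
        assert sorted(kept.sizes().values()) == [100, 200, 300]

    def test_drop_zero_is_identity(self):
        coll = sets_of_sizes(30, 20)
        assert subset_gene_sets(coll, drop_top_k=0).sets == coll.sets

    def test_exactly_one_selector_required(self):
        coll = sets_of_sizes(10)
        with pytest.raises(ValueError):
            subset_gene_sets(coll)
        with pytest.raises(ValueError):
            subset_gene_sets(coll, drop_top_k=1, size_band=(1, 5))

    def test_drop_ties_broken_by_name_order(self):
        coll = GeneSetCollection(
            {
                "B": frozenset({"x", "y"}),
                "A": frozenset({"p", "q"}),
                "C": frozenset({"z"}),
            }
        )
        kept = subset_gene_sets(coll, drop_top_k=1)
        assert set(kept.sets) == {"B", "C"}  # "A" sorts first among size-2 ties


def test_contradictory_duplicate_edges_flagged_and_conflict(caplog):
    with caplog.at_level("WARNING"):
        net = SignedNetwork([("A", "B", 1), ("A", "B", -1)])
    assert any("contradictory" in r.message for r in caplog.records)
    uni = GeneUniverse(("A", "B"))
    v = propagate_ppi(SignedVector.from_dict(uni, {"A": 1}), net, 1)
    assert v["B"] == 0


def test_self_loops_do_not_propagate():
    uni = GeneUniverse(("A", "B"))
    net = SignedNetwork([("A", "A", -1), ("A", "B", 1)])
    v = propagate_ppi(SignedVector.from_dict(uni, {"A": 1}), net, 3)
    assert v["A"] == 1 and v["B"] == 1
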