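"""Compound-pair similarity analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chemtx import (
    CompoundCollection,
    CompoundRecord,
    GeneUniverse,
    TranscriptomicExperiment,
    build_pair_table,
    eligible_pairs,
    same_target_pairs,
    shared_target_fraction,
    similarity_correlation,
)


def exp(cid, cell, up=(), down=(), conc="c1"):
    return TranscriptomicExperiment(cid, cell, conc, frozenset(up), frozenset(down))


@pytest.fixture
def universe():
    return GeneUniverse(tuple(f"G{i}" for i in range(8)))


def collection(universe, specs):
    """specs: list of (cid, targets, [(cell, up, down), ...])."""
    records = [
        CompoundRecord(
            cid, dict(targets), [exp(cid, cell, up, down, conc=f"c{i}") for i, (cell, up, down) in enumerate(exps)]
        )
        for cid, targets, exps in specs
    ]
    return CompoundCollection(universe, records)


class TestEligiblePairs:
    def test_shared_cell_line_required(self, universe):
        coll = collection(
            universe,
            [
                ("A", {"G0": 1}, [("HepG2", ["G1"], [])]),
                ("B", {"G2": 1}, [("HepG2", ["G3"], [])]),
                ("C", {"G4": 1}, [("MCF7", ["G5"], [])]),
            ],
        )
        assert eligible_pairs(coll) == [("A", "B")]

    def test_all_shared_gives_all_pairs(self, universe):
        coll = collection(
            universe,
            [(c, {"G0": 1}, [("CL", ["G1"], [])]) for c in "ABCD"],
        )
        assert len(eligible_pairs(coll)) == 6

    def test_disjoint_cell_lines_give_empty(self, universe):
        coll = collection(
            universe,
            [
                ("A", {"G0": 1}, [("X", ["G1"], [])]),
                ("B", {"G0": 1}, [("Y", ["G1"], [])]),
            ],
        )
        assert eligible_pairs(coll) == []


class TestBuildPairTable:
    def test_identical_compounds_score_one(self, universe):
        specs = [
            (cid, {"G0": 1, "G1": -1}, [("CL", ["G2"], ["G3"])]) for cid in ("A", "B")
        ]
        table = build_pair_table(collection(universe, specs))
        row = table.iloc[0]
        assert row["target_jaccard"] == pytest.approx(1.0)
        assert row["transcriptomic_jaccard"] == pytest.approx(1.0)
        assert row["shares_target"]

    def test_shares_target_is_sign_blind(self, universe):
        specs = [
            ("A", {"G0": 1}, [("CL", ["G2"], [])]),
            ("B", {"G0": -1}, [("CL", ["G3"], [])]),
        ]
        row = build_pair_table(collection(universe, specs)).iloc[0]
        assert row["shares_target"]
        assert row["target_jaccard"] == pytest.approx(0.0)

    def test_disjoint_targets_do_not_share(self, universe):
        specs = [
            ("A", {"G0": 1}, [("CL", ["G2"], [])]),
            ("B", {"G1": 1}, [("CL", ["G3"], [])]),
        ]
        assert not build_pair_table(collection(universe, specs)).iloc[0]["shares_target"]

    def test_row_count_matches_eligible_pairs(self, universe):
        specs = [
            ("A", {"G0": 1}, [("X", ["G1"], [])]),
            ("B", {"G0": 1}, [("X", ["G1"], [])]),
            ("C", {"G0": 1}, [("Y", ["G1"], [])]),
            ("D", {"G0": 1}, [("X", ["G1"], []), ("Y", ["G2"], [])]),
        ]
        coll = collection(universe, specs)
        assert len(build_pair_table(coll)) == len(eligible_pairs(coll))

    def test_cell_line_restriction_changes_vectors(self, universe):
        # B has a second experiment in another cell line adding G4; the
        # pair vector restricted to the shared line ignores it
        specs = [
            ("A", {"G0": 1}, [("X", ["G2"], [])]),
            ("B", {"G1": 1}, [("X", ["G2"], []), ("Y", ["G4"], [])]),
        ]
        coll = collection(universe, specs)
        restricted = build_pair_table(coll).iloc[0]
        global_union = build_pair_table(
            coll, restrict_to_shared_cell_lines=False
        ).iloc[0]
        assert restricted["transcriptomic_jaccard"] == pytest.approx(1.0)
        assert global_union["transcriptomic_jaccard"] == pytest.approx(0.5)

    def test_missing_compound_named(self, universe):
        coll = collection(universe, [("A", {"G0": 1}, [("X", ["G1"], [])])])
        with pytest.raises(KeyError, match="ZZ"):
            build_pair_table(coll, pairs=[("A", "ZZ")])


class TestSimilarityCorrelation:
    def test_y_equal_x_gives_one(self):
        table = pd.DataFrame(
            {
                "compound_a": list("abcd"),
                "compound_b": list("wxyz"),
                "target_jaccard": [0.1, 0.4, 0.2, 0.9],
                "transcriptomic_jaccard": [0.1, 0.4, 0.2, 0.9],
                "shares_target": [True] * 4,
            }
        )
        res = similarity_correlation(table, n_iter=50, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_two_rows_rejected(self):
        table = pd.DataFrame(
            {
                "compound_a": ["a", "b"],
                "compound_b": ["x", "y"],
                "target_jaccard": [0.1, 0.2],
                "transcriptomic_jaccard": [0.3, 0.4],
                "shares_target": [False, False],
            }
        )
        with pytest.raises(ValueError):
            similarity_correlation(table, n_iter=10)

    def test_zero_variance_flagged_undefined(self):
        table = pd.DataFrame(
            {
                "compound_a": list("abc"),
                "compound_b": list("xyz"),
                "target_jaccard": [0.5, 0.5, 0.5],
                "transcriptomic_jaccard": [0.1, 0.2, 0.3],
                "shares_target": [False] * 3,
            }
        )
        res = similarity_correlation(table, n_iter=10, seed=0)
        assert not res.defined and res.p_raw == 1.0

    def test_null_calibrated_when_independent(self, rng):
        # X and Y independent: observed near 0 and p rarely small
        n_sig = 0
        for rep in range(40):
            table = pd.DataFrame(
                {
                    "compound_a": [f"a{i}" for i in range(60)],
                    "compound_b": [f"b{i}" for i in range(60)],
                    "target_jaccard": rng.random(60),
                    "transcriptomic_jaccard": rng.random(60),
                    "shares_target": [False] * 60,
                }
            )
            res = similarity_correlation(table, n_iter=200, seed=rep)
            n_sig += res.p_raw < 0.05
        assert n_sig <= 8  # ~5% nominal one-sided rate over 40 replicates


class TestSharedTargetFraction:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "compound_a": list("abcd"),
                "compound_b": list("wxyz"),
                "target_jaccard": [0.2, 0.0, 1.0, 0.5],
                "transcriptomic_jaccard": [0.7, 0.65, 0.5, 0.9],
                "shares_target": [True, False, True, True],
            }
        )

    def test_hand_filtered_fraction(self, table):
        out = shared_target_fraction(table, 0.6)
        assert out.n_pairs == 3
        assert out.fraction == pytest.approx(2 / 3)
        assert out.mean_target_jaccard == pytest.approx((0.2 + 0.0 + 0.5) / 3)

    def test_zero_threshold_keeps_all(self, table):
        out = shared_target_fraction(table, 0.0)
        assert out.n_pairs == 4 and out.fraction == pytest.approx(3 / 4)

    def test_strict_flag_excludes_boundary(self, table):
        assert shared_target_fraction(table, 0.7).n_pairs == 2
        assert shared_target_fraction(table, 0.7, strict=True).n_pairs == 1

    def test_empty_selection_undefined(self, table):
        out = shared_target_fraction(table, 1.0, strict=True)
        assert not out.defined and out.n_pairs == 0 and np.isnan(out.fraction)


class TestSameTargetPairs:
    def test_identical_signed_targets_included(self, universe):
        specs = [
            ("A", {"G0": 1, "G1": -1}, [("CL", ["G2"], [])]),
            ("B", {"G0": 1, "G1": -1}, [("CL", ["G2"], [])]),
            ("C", {"G0": -1, "G1": -1}, [("CL", ["G3"], [])]),  # one sign flipped
        ]
        table = build_pair_table(collection(universe, specs))
        pairs, mean_tx, defined = same_target_pairs(table)
        assert pairs == [("A", "B")]
        assert defined and mean_tx == pytest.approx(1.0)

    def test_no_qualifying_rows(self):
        table = pd.DataFrame(
            {
                "compound_a": ["a"],
                "compound_b": ["b"],
                "target_jaccard": [0.5],
                "transcriptomic_jaccard": [0.4],
                "shares_target": [True],
            }
        )
        pairs, mean_tx, defined = same_target_pairs(table)
        assert pairs == [] and not defined and np.isnan(mean_tx)
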