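"""Compound-pair similarity analyses.

For every pair of compounds tested in at least one common cell line we
compute the signed Jaccard similarity of their target vectors and of
their transcriptomic vectors.  These (target, transcriptomic) similarity
pairs feed three questions: are the two similarity scales correlated at
all; do compounds with highly similar transcriptomic profiles tend to
share a target; and do compounds with identical signed target profiles
induce similar transcriptomic responses?
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import jaccard
from .permutation import PermutationResult, _empirical_p
from .vector_builder import (
    CompoundCollection,
    CompoundRecord,
    build_target_vector,
    merge_experiments_union,
)
from .vectors import SignedVector

__all__ = [
    "eligible_pairs",
    "build_pair_table",
    "similarity_correlation",
    "shared_target_fraction",
    "same_target_pairs",
    "SharedTargetSummary",
]

PAIR_COLUMNS = [
    "compound_a",
    "compound_b",
    "shared_cell_lines",
    "target_jaccard",
    "transcriptomic_jaccard",
    "shares_target",
]


def eligible_pairs(collection: CompoundCollection) -> list[tuple[str, str]]:
    """Unordered compound pairs sharing at least one cell line.

    Pairs tested in disjoint cell lines are excluded to discard the
    inherent transcriptomic variability across cell lines.  Pairs are
    returned with ``a < b`` lexicographically, each pair once.
    """
    cell_lines = {}
    for record in collection:
        if not record.cell_lines:
            raise ValueError(f"compound {record.compound_id} has no cell line")
        cell_lines[record.compound_id] = record.cell_lines
    pairs = []
    for a, b in combinations(sorted(cell_lines), 2):
        if cell_lines[a] & cell_lines[b]:
            pairs.append((a, b))
    return pairs


def _restricted_union_vector(
    record: CompoundRecord, cell_lines: frozenset[str], collection: CompoundCollection
) -> SignedVector:
    """Union transcriptomic vector using only experiments from given cell lines."""
    sub = CompoundRecord(
        compound_id=record.compound_id,
        target_effects=dict(record.target_effects),
        experiments=[e for e in record.experiments if e.cell_line in cell_lines],
    )
    return merge_experiments_union(sub, collection.universe)


def build_pair_table(
    collection: CompoundCollection,
    pairs: Sequence[tuple[str, str]] | None = None,
    *,
    restrict_to_shared_cell_lines: bool = True,
) -> pd.DataFrame:
    """Per-pair similarity table.

    One row per unordered pair with the signed Jaccard of the two target
    vectors, the signed Jaccard of the two transcriptomic vectors, and a
    sign-blind ``shares_target`` flag (any gene targeted by both, in
    either direction).

    By default each pair's transcriptomic vectors are rebuilt as the
    union over experiments from the pair's *shared* cell lines only;
    ``restrict_to_shared_cell_lines=False`` uses the global all-experiment
    union instead.
    """
    if pairs is None:
        pairs = eligible_pairs(collection)
    universe = collection.universe
    target_vectors: dict[str, SignedVector] = {}
    global_tx: dict[str, SignedVector] = {}
    for a, b in pairs:
        for cid in (a, b):
            if cid not in collection:
                raise KeyError(f"no record for compound {cid}")
            if cid not in target_vectors:
                target_vectors[cid] = build_target_vector(collection[cid], universe)
                if not restrict_to_shared_cell_lines:
                    global_tx[cid] = merge_experiments_union(
                        collection[cid], universe
                    )
    rows = []
    for a, b in pairs:
        a, b = sorted((a, b))
        shared = collection[a].cell_lines & collection[b].cell_lines
        ta, tb = target_vectors[a], target_vectors[b]
        if restrict_to_shared_cell_lines:
            xa = _restricted_union_vector(collection[a], shared, collection)
            xb = _restricted_union_vector(collection[b], shared, collection)
        else:
            xa, xb = global_tx[a], global_tx[b]
        shares = bool(np.any((ta.values != 0) & (tb.values != 0)))
        rows.append(
            {
                "compound_a": a,
                "compound_b": b,
                "shared_cell_lines": ",".join(sorted(shared)),
                "target_jaccard": jaccard(ta, tb).value,
                "transcriptomic_jaccard": jaccard(xa, xb).value,
                "shares_target": shares,
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def similarity_correlation(
    table: pd.DataFrame, n_iter: int = 100_000, seed: int = 0, n_tests: int = 1
) -> PermutationResult:
    """Pearson correlation between target and transcriptomic similarity.

    The target-similarity column is X, the transcriptomic-similarity
    column Y; the null permutes Y independently ``n_iter`` times.  A
    zero-variance column yields a ``defined=False`` result.
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 pairs; got {len(table)}")
    x = table["target_jaccard"].to_numpy(dtype=np.float64)
    y = table["transcriptomic_jaccard"].to_numpy(dtype=np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return PermutationResult(
            observed=0.0,
            null_means=np.zeros(n_iter),
            n_iter=n_iter,
            p_raw=1.0,
            n_tests=n_tests,
            seed=seed,
            defined=False,
        )
    observed = float(xc @ yc / (sx * sy))
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = xc @ rng.permutation(yc) / (sx * sy)
    return PermutationResult(
        observed=observed,
        null_means=null,
        n_iter=n_iter,
        p_raw=_empirical_p(observed, null),
        n_tests=n_tests,
        seed=seed,
    )


@dataclass(frozen=True)
class SharedTargetSummary:
    fraction: float
    n_pairs: int
    mean_target_jaccard: float
    defined: bool


def shared_target_fraction(
    table: pd.DataFrame, tx_threshold: float, *, strict: bool = False
) -> SharedTargetSummary:
    """Fraction of transcriptomically similar pairs sharing a target.

    Restricts the table to pairs whose transcriptomic Jaccard is at
    least ``tx_threshold`` (``strict=True`` uses a strict ``>`` instead)
    and reports the fraction of retained pairs with ``shares_target``,
    the retained count, and their mean target Jaccard.  An empty
    selection is flagged ``defined=False``.
    """
    if not 0.0 <= tx_threshold <= 1.0:
        raise ValueError("tx_threshold must be in [0, 1]")
    scores = table["transcriptomic_jaccard"]
    kept = table[scores > tx_threshold] if strict else table[scores >= tx_threshold]
    if len(kept) == 0:
        return SharedTargetSummary(float("nan"), 0, float("nan"), defined=False)
    return SharedTargetSummary(
        fraction=float(kept["shares_target"].mean()),
        n_pairs=int(len(kept)),
        mean_target_jaccard=float(kept["target_jaccard"].mean()),
        defined=True,
    )


def same_target_pairs(
    table: pd.DataFrame,
) -> tuple[list[tuple[str, str]], float, bool]:
    """Pairs whose signed target vectors are identical (target Jaccard = 1).

    The strict cutoff keeps only pairs sharing all their targets *and*
    affecting them in the same direction.  Returns the pair list, the
    mean transcriptomic Jaccard over them, and a defined flag (False
    when no pair qualifies).
    """
    kept = table[table["target_jaccard"] >= 1.0 - 1e-12]
    pairs = list(zip(kept["compound_a"], kept["compound_b"]))
    if len(kept) == 0:
        return [], float("nan"), False
    return pairs, float(kept["transcriptomic_jaccard"].mean()), True


def pair_heatmap_matrix(table: pd.DataFrame, value: str = "target_jaccard") -> pd.DataFrame:
    """Symmetric compound x compound matrix of a pair-table column."""
    ids = sorted(set(table["compound_a"]) | set(table["compound_b"]))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for _, row in table.iterrows():
        mat.loc[row["compound_a"], row["compound_b"]] = row[value]
        mat.loc[row["compound_b"], row["compound_a"]] = row[value]
    return mat


def save_pair_heatmap(
    table: pd.DataFrame, path, value: str = "target_jaccard"
) -> None:
    """Minimal clustered-heatmap export of a pair-table column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = pair_heatmap_matrix(table, value=value)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.to_numpy(), cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(value)
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
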