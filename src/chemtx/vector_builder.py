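"""Construction of per-compound signed target and transcriptomic vectors.

A compound's target vector is read directly off its annotated target
effects (+1 activation, -1 inhibition).  Its transcriptomic vector is
built from one or more differential-expression experiments (per cell
line / concentration); when several experiments exist they are combined
by taking the union of all differentially expressed genes, with a 2x
majority rule resolving genes called up in some experiments and down in
others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .vectors import GeneUniverse, SignedVector

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptomicExperiment",
    "CompoundRecord",
    "CompoundCollection",
    "build_target_vector",
    "resolve_discrepancy",
    "merge_experiments_union",
    "select_max_deg",
]


@dataclass
class TranscriptomicExperiment:
    """One differential-expression readout for a compound.

    ``up_genes`` and ``down_genes`` are the ternary DEG calls; a gene may
    not appear in both.
    """

    compound_id: str
    cell_line: str
    concentration: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"experiment {self.compound_id}/{self.cell_line}/"
                f"{self.concentration}: genes in both up and down lists: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def n_deg(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class CompoundRecord:
    """A compound's target effects plus its transcriptomic experiments."""

    compound_id: str
    target_effects: dict[str, int]
    experiments: list[TranscriptomicExperiment] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.target_effects.items() if s not in (-1, 1)}
        if bad:
            raise ValueError(
                f"compound {self.compound_id}: target effects must be -1 or +1; "
                f"got {bad}"
            )

    @property
    def cell_lines(self) -> frozenset[str]:
        return frozenset(e.cell_line for e in self.experiments)


@dataclass
class CompoundCollection:
    """All compounds of a study over a shared gene universe."""

    universe: GeneUniverse
    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        self._by_id = {r.compound_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate compound identifiers")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]


def build_target_vector(record: CompoundRecord, universe: GeneUniverse) -> SignedVector:
    """Encode a compound's target effects as a signed vector.

    +1 where the compound activates the protein, -1 where it inhibits it,
    0 for all other genes.  Raises ``KeyError`` naming any target gene
    missing from the universe.
    """
    return SignedVector.from_dict(universe, record.target_effects)


def resolve_discrepancy(n_up: int, n_down: int) -> int:
    """Resolve a gene called up in some experiments and down in others.

    The call goes to a direction only when it was seen more than twice as
    often as the opposite one ("more than two times" read strictly):
    +1 iff n_up > 2*n_down (and n_up > 0), -1 iff n_down > 2*n_up, else 0.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError(f"counts must be non-negative; got ({n_up}, {n_down})")
    if n_up > 0 and n_up > 2 * n_down:
        return 1
    if n_down > 0 and n_down > 2 * n_up:
        return -1
    return 0


def merge_experiments_union(
    record: CompoundRecord, universe: GeneUniverse
) -> SignedVector:
    """Transcriptomic vector as the union of DEGs across all experiments.

    Each gene's sign is the 2x-majority resolution of the number of
    experiments calling it up versus down; genes never called are 0.
    """
    if not record.experiments:
        raise ValueError(f"compound {record.compound_id} has no experiments")
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for exp in record.experiments:
        for g in exp.up_genes:
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in exp.down_genes:
            down_counts[g] = down_counts.get(g, 0) + 1
    signs: dict[str, int] = {}
    for g in up_counts.keys() | down_counts.keys():
        s = resolve_discrepancy(up_counts.get(g, 0), down_counts.get(g, 0))
        if s != 0:
            signs[g] = s
    return SignedVector.from_dict(universe, signs)


def select_max_deg(record: CompoundRecord, universe: GeneUniverse) -> SignedVector:
    """Transcriptomic vector from the single experiment with the most DEGs.

    Ties are broken by input order (the earliest experiment wins), with a
    warning logged since the choice is arbitrary.
    """
    if not record.experiments:
        raise ValueError(f"compound {record.compound_id} has no experiments")
    best = max(record.experiments, key=lambda e: e.n_deg)
    tied = [e for e in record.experiments if e.n_deg == best.n_deg]
    if len(tied) > 1:
        logger.warning(
            "compound %s: %d experiments tied at %d DEGs; using the first "
            "in input order (%s/%s)",
            record.compound_id,
            len(tied),
            best.n_deg,
            tied[0].cell_line,
            tied[0].concentration,
        )
    chosen = tied[0]
    signs = {g: 1 for g in chosen.up_genes}
    signs.update({g: -1 for g in chosen.down_genes})
    return SignedVector.from_dict(universe, signs)


def build_matrix(
    collection: CompoundCollection, mode: str = "union"
) -> tuple[np.ndarray, list[str]]:
    """Stack per-compound transcriptomic vectors into a matrix.

    ``mode`` is ``"union"`` (union across experiments) or ``"maxdeg"``
    (single experiment with the most DEGs).  Returns ``(matrix, ids)``
    with compounds as rows.
    """
    builder = {"union": merge_experiments_union, "maxdeg": select_max_deg}[mode]
    vectors = [builder(r, collection.universe) for r in collection.records]
    return np.stack([v.values for v in vectors]), collection.compound_ids
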