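"""Generator of ChemPert-shaped synthetic datasets with a planted signal.

Real compound-perturbation resources pair sparse ternary target vectors
(most compounds touch 1-5 proteins) with much denser ternary
differential-expression calls, recorded per cell line and sometimes at
several concentrations.  This module emulates that statistical shape —
gene universe, pathway collection with a long-tailed size distribution,
signed directed interaction network, compound target tables and
experiment tables — and plants a tunable causal link from a compound's
targets to its transcriptomic readout: genes in a target's enriched
neighbourhood (pathway co-members plus genes within three signed
network hops) are differentially expressed with the propagated sign
with probability ``effect_strength``; all other genes fire at a
background rate with a random sign.  Setting ``effect_strength`` to 0
yields pure noise, which is what the permutation nulls should see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .enrichment import (
    GeneSetCollection,
    SignedNetwork,
    build_pathway_vector,
    log_uniform_sizes,
    propagate_ppi,
)
from .vector_builder import (
    CompoundCollection,
    CompoundRecord,
    TranscriptomicExperiment,
    build_target_vector,
)
from .vectors import GeneUniverse

__all__ = ["SyntheticConfig", "ConfigurationError", "generate_dataset"]

#: Probability that a compound has k targets, k = 1..5 (sparse, mode at 1).
DEFAULT_TARGET_COUNT_DIST = {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.12, 5: 0.08}

#: Depth of the network neighbourhood used when planting the signal.
PLANT_PPI_LEVELS = 3


class ConfigurationError(ValueError):
    """An invalid generator configuration, naming the offending field."""

    def __init__(self, field_name: str, message: str) -> None:
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the shape of a full-scale compound-perturbation
    resource: ~4938 measured genes, ~2152 compounds with both target and
    transcriptomic data, pathways of 15-300 genes, and a minority of
    compounds profiled at several concentrations.  Scale down ``n_genes``
    / ``n_compounds`` (and the pathway size range with them) for desk
    experiments.
    """

    n_genes: int = 4938
    n_compounds: int = 2152
    targets_per_compound: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_COUNT_DIST)
    )
    n_cell_lines: int = 10
    multi_concentration_fraction: float = 0.2
    concentrations_per_multi: tuple[int, int] = (2, 4)
    n_pathways: int = 150
    pathway_size_range: tuple[int, int] = (15, 300)
    mean_degree: float = 3.0
    activation_fraction: float = 0.6
    effect_strength: float = 0.3
    background_de_rate: float = 0.05
    shared_target_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "multi_concentration_fraction",
            "activation_fraction",
            "effect_strength",
            "background_de_rate",
            "shared_target_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, f"must be a probability; got {v}")
        for name in ("n_genes", "n_compounds", "n_cell_lines", "n_pathways"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(name, f"must be a positive integer; got {v}")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(
                "pathway_size_range", f"need 2 <= min <= max; got ({lo}, {hi})"
            )
        if self.n_genes < hi:
            raise ConfigurationError(
                "n_genes",
                f"must be >= pathway_size_range.max ({hi}); got {self.n_genes}",
            )
        if self.mean_degree < 0:
            raise ConfigurationError("mean_degree", "must be non-negative")
        clo, chi = self.concentrations_per_multi
        if clo < 2 or chi < clo:
            raise ConfigurationError(
                "concentrations_per_multi", f"need 2 <= min <= max; got ({clo}, {chi})"
            )
        dist = self.targets_per_compound
        if not dist:
            raise ConfigurationError("targets_per_compound", "must be non-empty")
        for k, p in dist.items():
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ConfigurationError(
                    "targets_per_compound", f"support must be positive ints; got {k}"
                )
            if p < 0:
                raise ConfigurationError(
                    "targets_per_compound", f"probabilities must be >= 0; got {p}"
                )
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                "targets_per_compound",
                f"probabilities must sum to 1; got {sum(dist.values())}",
            )
        if max(dist) > self.n_genes:
            raise ConfigurationError(
                "targets_per_compound", "support exceeds the gene universe"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed", "must be an integer")

    def scaled(self, **overrides) -> "SyntheticConfig":
        """A copy with fields replaced (convenience for desk-scale configs)."""
        return replace(self, **overrides)


def _make_universe(n_genes: int) -> GeneUniverse:
    width = max(4, len(str(n_genes)))
    return GeneUniverse(tuple(f"G{i:0{width}d}" for i in range(n_genes)))


def _make_gene_sets(
    rng: np.random.Generator, universe: GeneUniverse, config: SyntheticConfig
) -> GeneSetCollection:
    lo, hi = config.pathway_size_range
    sizes = log_uniform_sizes(rng, config.n_pathways, lo, hi)
    genes = np.array(universe.genes, dtype=object)
    sets = {}
    for p, size in enumerate(sizes):
        members = rng.choice(len(genes), size=int(size), replace=False)
        sets[f"P{p:04d}"] = frozenset(genes[i] for i in members)
    return GeneSetCollection(sets, provenance="synthetic")


def _make_network(
    rng: np.random.Generator, universe: GeneUniverse, config: SyntheticConfig
) -> SignedNetwork:
    n = len(universe)
    n_edges = int(round(config.mean_degree * n))
    genes = universe.genes
    edges: list[tuple[str, str, int]] = []
    seen: set[tuple[int, int]] = set()
    # rejection sampling of distinct non-self directed pairs
    while len(edges) < n_edges:
        need = n_edges - len(edges)
        u = rng.integers(0, n, size=2 * need + 8)
        v = rng.integers(0, n, size=2 * need + 8)
        pol = np.where(rng.random(len(u)) < config.activation_fraction, 1, -1)
        for ui, vi, pi in zip(u, v, pol):
            if ui == vi or (ui, vi) in seen:
                continue
            seen.add((int(ui), int(vi)))
            edges.append((genes[ui], genes[vi], int(pi)))
            if len(edges) == n_edges:
                break
    return SignedNetwork(edges, nodes=genes)


def _planted_signal(
    record: CompoundRecord,
    universe: GeneUniverse,
    gene_sets: GeneSetCollection,
    membership: dict[str, list[str]],
    network: SignedNetwork,
) -> np.ndarray:
    """Per-gene planted DE sign for a compound's enriched neighbourhood.

    The neighbourhood is the union of the pathway-enriched vector and
    the 3-level PPI-propagated vector; where the two routes disagree the
    gene is left unplanted.  The targets themselves are excluded: in
    real perturbation data a compound's targets are rarely
    differentially expressed, the response appearing downstream.
    """
    target = build_target_vector(record, universe)
    pv = build_pathway_vector(target, gene_sets, membership).values
    nv = propagate_ppi(target, network, PLANT_PPI_LEVELS).values
    agree = (pv == nv) | (pv == 0) | (nv == 0)
    planted = np.where(agree, np.where(pv != 0, pv, nv), 0).astype(np.int8)
    planted[target.values != 0] = 0
    return planted


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[CompoundCollection, GeneSetCollection, SignedNetwork]:
    """Generate a full synthetic dataset under the given study conditions.

    Returns the compound collection (targets + experiments), the raw
    (unfiltered) pathway collection and the signed interaction network.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = _make_universe(config.n_genes)
    gene_sets = _make_gene_sets(rng, universe, config)
    network = _make_network(rng, universe, config)
    membership = gene_sets.membership_index()

    counts = np.array(sorted(config.targets_per_compound), dtype=int)
    probs = np.array(
        [config.targets_per_compound[int(k)] for k in counts], dtype=np.float64
    )
    probs /= probs.sum()
    genes_arr = np.array(universe.genes, dtype=object)
    cell_lines = [f"CL{i:02d}" for i in range(config.n_cell_lines)]

    records: list[CompoundRecord] = []
    width = max(4, len(str(config.n_compounds)))
    for c in range(config.n_compounds):
        cid = f"C{c:0{width}d}"
        if records and rng.random() < config.shared_target_fraction:
            donor = records[int(rng.integers(len(records)))]
            effects = dict(donor.target_effects)
        else:
            k = int(rng.choice(counts, p=probs))
            t_idx = rng.choice(config.n_genes, size=k, replace=False)
            signs = np.where(rng.random(k) < 0.5, 1, -1)
            effects = {genes_arr[i]: int(s) for i, s in zip(t_idx, signs)}
        record = CompoundRecord(compound_id=cid, target_effects=effects)
        planted = _planted_signal(record, universe, gene_sets, membership, network)
        cell_line = cell_lines[int(rng.integers(config.n_cell_lines))]
        if rng.random() < config.multi_concentration_fraction:
            clo, chi = config.concentrations_per_multi
            n_exp = int(rng.integers(clo, chi + 1))
        else:
            n_exp = 1
        for e in range(n_exp):
            fires = (planted != 0) & (rng.random(config.n_genes) < config.effect_strength)
            de = np.where(fires, planted, 0).astype(np.int8)
            background = (~fires) & (rng.random(config.n_genes) < config.background_de_rate)
            bg_signs = np.where(rng.random(config.n_genes) < 0.5, 1, -1)
            de = np.where(background, bg_signs, de).astype(np.int8)
            record.experiments.append(
                TranscriptomicExperiment(
                    compound_id=cid,
                    cell_line=cell_line,
                    concentration=f"c{e + 1}",
                    up_genes=frozenset(genes_arr[i] for i in np.flatnonzero(de > 0)),
                    down_genes=frozenset(genes_arr[i] for i in np.flatnonzero(de < 0)),
                )
            )
        records.append(record)
    return CompoundCollection(universe, records), gene_sets, network
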