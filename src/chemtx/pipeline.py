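"""End-to-end orchestration of the correspondence analysis.

``run_pipeline`` ties the stages together: load (or synthesise) the
dataset, build per-compound vectors, enrich targets via pathways and
via the signed network, correlate the two modalities per compound, run
the three permutation nulls, perform the pairwise similarity analyses
and, when structures are supplied, the structural case study.  Every
random stage derives its own seed from the pipeline seed and is
recorded in the summary so a run is reproducible from its report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .chem_case import CompoundStructure, morgan_tanimoto, shares_murcko_scaffold
from .enrichment import (
    GeneSetCollection,
    SignedNetwork,
    build_pathway_vector,
    filter_gene_sets,
    propagate_ppi,
)
from .metrics import jaccard, pearson
from .pairwise_analysis import (
    build_pair_table,
    eligible_pairs,
    same_target_pairs,
    shared_target_fraction,
    similarity_correlation,
)
from .permutation import (
    gene_set_permutation_test,
    network_permutation_test,
    pair_shuffle_test,
)
from .synthetic_data import SyntheticConfig, generate_dataset
from .vector_builder import (
    CompoundCollection,
    build_target_vector,
    merge_experiments_union,
    select_max_deg,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

REDUCED_REPLICATION_FLOOR = 100  # below this, results are flagged as desk-scale


@dataclass
class PipelineConfig:
    """Paths, stage parameters and seeds for one pipeline run.

    Either ``synthetic`` is given (a :class:`SyntheticConfig`, the data
    are generated) or the four input paths point at existing files.
    Iteration counts default to the full-scale analysis (100,000 vector
    shuffles, 1000 random gene-set collections, 100 random networks) and
    should be scaled down for desk runs.
    """

    out_dir: str | Path = "chemtx_out"
    synthetic: SyntheticConfig | None = None
    targets_path: str | Path | None = None
    experiments_path: str | Path | None = None
    gene_sets_path: str | Path | None = None
    network_path: str | Path | None = None
    universe_path: str | Path | None = None
    structures_path: str | Path | None = None
    case_pair: tuple[str, str] | None = None
    vector_mode: str = "union"  # or "maxdeg"
    min_pathway_size: int = 15
    max_pathway_size: int = 300
    ppi_levels: int = 3
    n_iter_vectors: int = 100_000
    n_gene_set_collections: int = 1000
    n_networks: int = 100
    tx_threshold: float = 0.6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_yaml_config(path)
        synthetic = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synthetic is not None:
            if "concentrations_per_multi" in synthetic:
                synthetic["concentrations_per_multi"] = tuple(
                    synthetic["concentrations_per_multi"]
                )
            if "pathway_size_range" in synthetic:
                synthetic["pathway_size_range"] = tuple(
                    synthetic["pathway_size_range"]
                )
            if "targets_per_compound" in synthetic:
                synthetic["targets_per_compound"] = {
                    int(k): float(v)
                    for k, v in synthetic["targets_per_compound"].items()
                }
            cfg.synthetic = SyntheticConfig(**synthetic)
        if cfg.case_pair is not None:
            cfg.case_pair = tuple(cfg.case_pair)
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("targets_path", "experiments_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: missing input file {p}")
        if self.vector_mode not in ("union", "maxdeg"):
            raise ValueError(f"vector_mode must be union or maxdeg; got {self.vector_mode}")


def _load_inputs(
    config: PipelineConfig,
) -> tuple[CompoundCollection, GeneSetCollection | None, SignedNetwork | None]:
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    universe = (
        io.read_universe(config.universe_path) if config.universe_path else None
    )
    compounds = io.read_compound_collection(
        config.targets_path, config.experiments_path, universe
    )
    gene_sets = (
        io.read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    )
    network = (
        io.read_signed_edges(config.network_path) if config.network_path else None
    )
    return compounds, gene_sets, network


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write per-stage TSVs plus a summary JSON.

    Returns the summary dictionary.  Any stage failure aborts with an
    exception naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("vector_shuffle", "gene_sets", "networks", "pairwise")
    }
    summary: dict = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "reduced_replication": config.n_iter_vectors < REDUCED_REPLICATION_FLOOR
        or config.n_gene_set_collections < REDUCED_REPLICATION_FLOOR
        or config.n_networks < REDUCED_REPLICATION_FLOOR,
        "stages": {},
    }

    stage = "load"
    try:
        compounds, gene_sets, network = _load_inputs(config)
        universe = compounds.universe
        if config.synthetic is not None:
            io.write_universe(universe, out / "genes.txt")
            io.write_compound_collection(
                compounds, out / "targets.tsv", out / "experiments.tsv"
            )
            if gene_sets is not None:
                io.write_gmt(gene_sets, out / "gene_sets.gmt")
            if network is not None:
                io.write_signed_edges(network, out / "network.tsv")
        summary["stages"][stage] = {
            "n_compounds": len(compounds),
            "n_genes": len(universe),
            "n_gene_sets": len(gene_sets) if gene_sets else 0,
            "n_edges": network.n_edges if network else 0,
        }

        stage = "build_vectors"
        builder = merge_experiments_union if config.vector_mode == "union" else select_max_deg
        target_vectors = [build_target_vector(r, universe) for r in compounds]
        tx_vectors = [builder(r, universe) for r in compounds]
        ids = compounds.compound_ids
        io.write_vector_matrix(target_vectors, ids, out / "target_vectors.tsv")
        io.write_vector_matrix(tx_vectors, ids, out / "transcriptomic_vectors.tsv")

        stage = "correlate_raw"
        per_compound = pd.DataFrame(
            {
                "compound_id": ids,
                "pearson": [pearson(t, x).value for t, x in zip(target_vectors, tx_vectors)],
                "pearson_defined": [
                    pearson(t, x).defined for t, x in zip(target_vectors, tx_vectors)
                ],
                "jaccard": [jaccard(t, x).value for t, x in zip(target_vectors, tx_vectors)],
                "jaccard_defined": [
                    jaccard(t, x).defined for t, x in zip(target_vectors, tx_vectors)
                ],
            }
        )
        per_compound.to_csv(out / "per_compound_correlations.tsv", sep="\t", index=False)
        shuffle_raw = pair_shuffle_test(
            target_vectors,
            tx_vectors,
            metric="pearson",
            n_iter=config.n_iter_vectors,
            seed=stage_seeds["vector_shuffle"],
        )
        summary["stages"]["raw_correlation"] = shuffle_raw.summary()

        if gene_sets is not None:
            stage = "enrich_pathway"
            filtered = filter_gene_sets(
                gene_sets, config.min_pathway_size, config.max_pathway_size
            )
            membership = filtered.membership_index()
            pathway_vectors = [
                build_pathway_vector(t, filtered, membership) for t in target_vectors
            ]
            io.write_vector_matrix(pathway_vectors, ids, out / "pathway_vectors.tsv")
            shuffle_pw = pair_shuffle_test(
                pathway_vectors,
                tx_vectors,
                metric="pearson",
                n_iter=config.n_iter_vectors,
                seed=stage_seeds["vector_shuffle"],
            )
            summary["stages"]["pathway_correlation"] = shuffle_pw.summary()

            stage = "gene_set_null"
            gs_null = gene_set_permutation_test(
                target_vectors,
                tx_vectors,
                filtered,
                n_collections=config.n_gene_set_collections,
                metric="jaccard",
                seed=stage_seeds["gene_sets"],
            )
            summary["stages"]["gene_set_null"] = gs_null.summary()
        else:
            logger.info("no gene sets supplied; pathway stages skipped")
            summary["stages"]["pathway_correlation"] = "skipped (no gene sets)"

        if network is not None:
            stage = "enrich_ppi"
            ppi_vectors = [
                propagate_ppi(t, network, config.ppi_levels) for t in target_vectors
            ]
            io.write_vector_matrix(
                ppi_vectors, ids, out / f"ppi_vectors_level{config.ppi_levels}.tsv"
            )
            stage = "network_null"
            net_null = network_permutation_test(
                target_vectors,
                tx_vectors,
                network,
                levels=config.ppi_levels,
                n_networks=config.n_networks,
                metric="abs_pearson",
                seed=stage_seeds["networks"],
            )
            summary["stages"]["network_null"] = net_null.summary()
        else:
            logger.info("no network supplied; PPI stages skipped")
            summary["stages"]["network_null"] = "skipped (no network)"

        stage = "pairwise"
        pairs = eligible_pairs(compounds)
        if len(pairs) >= 3:
            table = build_pair_table(compounds, pairs)
            table.to_csv(out / "pair_table.tsv", sep="\t", index=False)
            sim = similarity_correlation(
                table,
                n_iter=min(config.n_iter_vectors, 10_000),
                seed=stage_seeds["pairwise"],
            )
            shared = shared_target_fraction(table, config.tx_threshold)
            same_pairs, same_mean, same_defined = same_target_pairs(table)
            summary["stages"]["pairwise"] = {
                "n_pairs": len(table),
                "similarity_correlation": sim.summary(),
                "shared_target": {
                    "tx_threshold": config.tx_threshold,
                    "fraction": shared.fraction,
                    "n_pairs": shared.n_pairs,
                    "mean_target_jaccard": shared.mean_target_jaccard,
                    "defined": shared.defined,
                },
                "same_target": {
                    "n_pairs": len(same_pairs),
                    "mean_transcriptomic_jaccard": same_mean,
                    "defined": same_defined,
                },
            }
        else:
            summary["stages"]["pairwise"] = f"skipped ({len(pairs)} eligible pairs)"

        if config.structures_path is not None and config.case_pair is not None:
            stage = "case_study"
            smiles = io.read_structures(config.structures_path)
            a, b = config.case_pair
            sa = CompoundStructure(a, smiles[a])
            sb = CompoundStructure(b, smiles[b])
            summary["stages"]["case_study"] = {
                "pair": [a, b],
                "morgan_tanimoto": morgan_tanimoto(sa, sb),
                "shares_murcko_scaffold": shares_murcko_scaffold(sa, sb),
            }

        stage = "report"
        io.write_json(summary, out / "summary.json")
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary
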