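"""Readers and writers for the plain-text exchange formats.

All tables are TSV with a header row; gene sets travel as GMT; the
signed interaction network as a three-column edge list whose polarity
accepts ``+1``/``-1``/``1`` or the words ``activation``/``inhibition``.
Gene identifiers are opaque strings matched exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSetCollection, SignedNetwork
from .vector_builder import (
    CompoundCollection,
    CompoundRecord,
    TranscriptomicExperiment,
)
from .vectors import GeneUniverse, SignedVector

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_gmt",
    "write_gmt",
    "read_signed_edges",
    "write_signed_edges",
    "read_universe",
    "write_universe",
    "read_compound_collection",
    "write_compound_collection",
    "write_vector_matrix",
    "read_vector_matrix",
    "read_structures",
]

_POLARITY_TOKENS = {
    "+1": 1,
    "1": 1,
    "-1": -1,
    "activation": 1,
    "inhibition": -1,
}


class ParseError(ValueError):
    """A malformed input file; the message carries the line number."""


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...).

    Duplicate genes within a line are deduplicated with a warning in the
    returned set sizes; blank lines are skipped.
    """
    sets: dict[str, frozenset[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene; got {len(fields)} fields"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: duplicate genes within set %s deduplicated",
                    path,
                    lineno,
                    name,
                )
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.provenance, *sorted(members)]) + "\n")


def read_signed_edges(path: str | Path) -> SignedNetwork:
    """Read a signed directed edge list TSV (source, target, polarity)."""
    path = Path(path)
    edges: list[tuple[str, str, int]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise ParseError(f"{path}:1: expected header starting with 'source'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            u, v, tok = fields
            pol = _POLARITY_TOKENS.get(tok.strip().lower())
            if pol is None:
                raise ParseError(
                    f"{path}:{lineno}: unknown polarity token {tok!r} "
                    f"(expected one of {sorted(_POLARITY_TOKENS)})"
                )
            edges.append((u, v, pol))
    return SignedNetwork(edges)


def write_signed_edges(network: SignedNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tpolarity\n")
        for u, v, pol in network.edge_list():
            fh.write(f"{u}\t{v}\t{pol:+d}\n")


def read_universe(path: str | Path) -> GeneUniverse:
    genes = [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]
    return GeneUniverse(tuple(genes))


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    Path(path).write_text("\n".join(universe.genes) + "\n")


def write_compound_collection(
    collection: CompoundCollection, targets_path: str | Path, experiments_path: str | Path
) -> None:
    """Write the target table and the experiment table.

    Targets: ``compound_id, gene, effect`` (+1/-1).  Experiments:
    ``compound_id, cell_line, concentration, gene, direction``.
    """
    with Path(targets_path).open("w") as fh:
        fh.write("compound_id\tgene\teffect\n")
        for record in collection:
            for gene in sorted(record.target_effects):
                fh.write(f"{record.compound_id}\t{gene}\t{record.target_effects[gene]:+d}\n")
    with Path(experiments_path).open("w") as fh:
        fh.write("compound_id\tcell_line\tconcentration\tgene\tdirection\n")
        for record in collection:
            for exp in record.experiments:
                for gene in sorted(exp.up_genes):
                    fh.write(
                        f"{exp.compound_id}\t{exp.cell_line}\t{exp.concentration}"
                        f"\t{gene}\t+1\n"
                    )
                for gene in sorted(exp.down_genes):
                    fh.write(
                        f"{exp.compound_id}\t{exp.cell_line}\t{exp.concentration}"
                        f"\t{gene}\t-1\n"
                    )


_DIRECTION_TOKENS = {"+1": 1, "1": 1, "up": 1, "-1": -1, "down": -1}


def read_compound_collection(
    targets_path: str | Path,
    experiments_path: str | Path,
    universe: GeneUniverse | None = None,
) -> CompoundCollection:
    """Read targets + experiments tables back into a compound collection.

    When ``universe`` is omitted it is derived as the sorted union of
    all genes seen in either table.
    """
    targets = pd.read_csv(targets_path, sep="\t", dtype=str)
    experiments = pd.read_csv(experiments_path, sep="\t", dtype=str)
    for df, cols, path in (
        (targets, ["compound_id", "gene", "effect"], targets_path),
        (
            experiments,
            ["compound_id", "cell_line", "concentration", "gene", "direction"],
            experiments_path,
        ),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
    if universe is None:
        genes = sorted(set(targets["gene"]) | set(experiments["gene"]))
        universe = GeneUniverse(tuple(genes))

    effects: dict[str, dict[str, int]] = {}
    for row in targets.itertuples(index=False):
        tok = str(row.effect).strip()
        sign = _DIRECTION_TOKENS.get(tok.lower())
        if sign is None:
            raise ParseError(f"{targets_path}: unknown effect token {tok!r}")
        effects.setdefault(row.compound_id, {})[row.gene] = sign

    exp_map: dict[tuple[str, str, str], dict[str, set[str]]] = {}
    order: list[tuple[str, str, str]] = []
    for row in experiments.itertuples(index=False):
        tok = str(row.direction).strip()
        sign = _DIRECTION_TOKENS.get(tok.lower())
        if sign is None:
            raise ParseError(
                f"{experiments_path}: unknown direction token {tok!r}"
            )
        key = (row.compound_id, row.cell_line, row.concentration)
        if key not in exp_map:
            exp_map[key] = {"up": set(), "down": set()}
            order.append(key)
        exp_map[key]["up" if sign > 0 else "down"].add(row.gene)

    records: dict[str, CompoundRecord] = {}
    for cid, eff in effects.items():
        records[cid] = CompoundRecord(compound_id=cid, target_effects=eff)
    for cid, cell_line, conc in order:
        if cid not in records:
            records[cid] = CompoundRecord(compound_id=cid, target_effects={})
        d = exp_map[(cid, cell_line, conc)]
        records[cid].experiments.append(
            TranscriptomicExperiment(
                compound_id=cid,
                cell_line=cell_line,
                concentration=conc,
                up_genes=frozenset(d["up"]),
                down_genes=frozenset(d["down"]),
            )
        )
    return CompoundCollection(universe, list(records.values()))


def write_vector_matrix(
    vectors: Sequence[SignedVector], ids: Sequence[str], path: str | Path
) -> None:
    """Write a genes x compounds ternary matrix TSV (gene column first)."""
    if not vectors:
        raise ValueError("no vectors to write")
    universe = vectors[0].universe
    mat = np.stack([v.values for v in vectors]).T
    df = pd.DataFrame(mat, columns=list(ids))
    df.insert(0, "gene", universe.genes)
    df.to_csv(path, sep="\t", index=False)


def read_vector_matrix(
    path: str | Path, universe: GeneUniverse | None = None
) -> tuple[list[SignedVector], list[str]]:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing 'gene' column")
    genes = tuple(df["gene"].astype(str))
    if universe is None:
        universe = GeneUniverse(genes)
    elif genes != universe.genes:
        raise ParseError(f"{path}: gene column does not match the given universe")
    ids = [c for c in df.columns if c != "gene"]
    vectors = [
        SignedVector(universe, df[c].to_numpy(dtype=np.int8)) for c in ids
    ]
    return vectors, ids


def read_structures(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (compound_id, smiles)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("compound_id", "smiles") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return dict(zip(df["compound_id"], df["smiles"]))


def load_yaml_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: configuration must be a YAML mapping")
    return data


def write_json(data: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True, default=_default) + "\n")
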