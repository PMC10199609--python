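"""Structural case-study helpers for compound pairs.

When two compounds share all their targets and induce highly similar
transcriptomic responses, structural comparison (Morgan-fingerprint
Tanimoto, Bemis-Murcko scaffold identity) and an overlay of their DEGs
on the signed interaction network help argue a shared mechanism of
action.  The canonical example shipped here is the cardenolide pair
digitoxigenin / sarmentogenin, two plant natural products that inhibit
the Na+/K+-ATPase subunit ATP1A1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .enrichment import SignedNetwork
from .vectors import SignedVector

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundStructure",
    "CASE_STUDY_SMILES",
    "morgan_tanimoto",
    "shares_murcko_scaffold",
    "concordance_overlay",
]

#: Registry structures (flat SMILES; stereocentres omitted — the default
#: Morgan fingerprint ignores chirality) for the shipped case-study pair.
CASE_STUDY_SMILES = {
    "digitoxigenin": "CC12CCC(CC1CCC3C2CCC4(C3(CCC4C5=CC(=O)OC5)O)C)O",
    "sarmentogenin": "CC12CCC(CC1CCC3C2CC(C4(C3(CCC4C5=CC(=O)OC5)O)C)O)O",
}


@dataclass(frozen=True)
class CompoundStructure:
    """A compound identifier with its SMILES string."""

    compound_id: str
    smiles: str

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(
                f"compound {self.compound_id}: SMILES does not parse: {self.smiles!r}"
            )
        return mol


def morgan_tanimoto(
    a: CompoundStructure,
    b: CompoundStructure,
    radius: int = 2,
    n_bits: int = 2048,
) -> float:
    """Tanimoto similarity of hashed Morgan (circular) fingerprints.

    Defaults (radius 2, 2048 bits) are the community-standard ECFP4
    equivalent.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fa = gen.GetFingerprint(a.to_mol())
    fb = gen.GetFingerprint(b.to_mol())
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def shares_murcko_scaffold(a: CompoundStructure, b: CompoundStructure) -> bool:
    """True iff the canonical Bemis-Murcko frameworks are identical.

    Acyclic molecules have an empty framework; two such molecules
    compare equal, with a warning since the comparison is vacuous.
    """
    sa = MurckoScaffold.MurckoScaffoldSmiles(mol=a.to_mol())
    sb = MurckoScaffold.MurckoScaffoldSmiles(mol=b.to_mol())
    if sa == "" and sb == "":
        logger.warning(
            "both %s and %s are acyclic: empty Murcko frameworks compare equal",
            a.compound_id,
            b.compound_id,
        )
        return True
    return sa == sb


def concordance_overlay(
    pair: tuple[str, str],
    transcriptomic_vectors: dict[str, SignedVector],
    network: SignedNetwork,
    targets: dict[str, int],
) -> pd.DataFrame:
    """Label every network node by the pair's DEG agreement.

    Labels: ``target`` (a shared-target gene), ``concordant`` (same
    nonzero sign in both compounds' vectors), ``discordant`` (opposite
    nonzero signs), ``single-compound`` (nonzero in exactly one),
    ``no-change`` (measured, zero in both), ``unmeasured`` (absent from
    the vectors' gene universe).
    """
    a, b = pair
    va = transcriptomic_vectors[a]
    vb = transcriptomic_vectors[b]
    if va.universe != vb.universe:
        raise ValueError("pair vectors defined over different universes")
    universe = va.universe
    rows = []
    for node in sorted(network.nodes):
        if node in targets:
            label = "target"
        elif node not in universe:
            label = "unmeasured"
        else:
            sa, sb = va[node], vb[node]
            if sa != 0 and sb != 0:
                label = "concordant" if sa == sb else "discordant"
            elif sa != 0 or sb != 0:
                label = "single-compound"
            else:
                label = "no-change"
        rows.append(
            {
                "gene": node,
                "label": label,
                f"sign_{a}": va[node] if node in universe else 0,
                f"sign_{b}": vb[node] if node in universe else 0,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "label", f"sign_{a}", f"sign_{b}"])
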