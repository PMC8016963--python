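"""2D fingerprints, Tanimoto similarity and structure groups.

Structurally similar drugs are expected to be substrates of similar
transporters, so drugs are grouped by 2D-fingerprint Tanimoto similarity
(threshold 0.35) before rank integration.

Fingerprint scheme ``ap-v1``: the set of RDKit atom-pair codes of the
molecule, augmented with one key per distinct atomic number.  Both are
graph invariants, so any SMILES of the same molecule yields the same bit
set, and every parseable structure (even a single heavy atom, which has no
atom pairs) gets a non-empty fingerprint.  Synthetic cohorts may bypass
SMILES entirely and supply bit sets directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .exceptions import ParseError

FINGERPRINT_VERSION = "ap-v1"


@dataclass(frozen=True)
class Fingerprint:
    """A drug's 2D descriptor key set."""

    drug_id: str
    bits: frozenset[str]


def fingerprint_from_smiles(smiles: str, drug_id: str = "") -> Fingerprint:
    """Deterministic 2D fingerprint (scheme ``ap-v1``) from a SMILES string."""
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ParseError(f"unparseable SMILES for {drug_id or 'drug'}: {smiles!r}")
    bits = {
        f"ap:{code}"
        for code in rdMolDescriptors.GetAtomPairFingerprint(mol)
        .GetNonzeroElements()
        .keys()
    }
    bits |= {f"at:{atom.GetAtomicNum()}" for atom in mol.GetAtoms()}
    return Fingerprint(drug_id=drug_id, bits=frozenset(bits))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |a∩b| / |a∪b| of two bit sets."""
    if not a.bits or not b.bits:
        raise ParseError(
            f"empty fingerprint for {a.drug_id if not a.bits else b.drug_id!r}"
        )
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def pairwise_similarity(fingerprints: dict[str, Fingerprint]) -> dict[tuple[str, str], float]:
    """All pairwise Tanimoto coefficients, keyed by sorted (drug_a, drug_b)."""
    ids = sorted(fingerprints)
    return {
        (a, b): tanimoto(fingerprints[a], fingerprints[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    }


def structure_groups(
    fingerprints: dict[str, Fingerprint], threshold: float = 0.35
) -> list[list[str]]:
    """Partition drugs into structure groups.

    Groups are the connected components of the similarity graph with an
    edge wherever Tanimoto strictly exceeds ``threshold``; singletons are
    legitimate groups.  Note that components can chain pairwise-similar
    drugs whose endpoints are themselves dissimilar.  The result is
    order-invariant: groups and members are sorted by drug id.
    """
    g = nx.Graph()
    g.add_nodes_from(fingerprints)
    for (a, b), sim in pairwise_similarity(fingerprints).items():
        if sim > threshold:
            g.add_edge(a, b)
    groups = [sorted(comp) for comp in nx.connected_components(g)]
    return sorted(groups, key=lambda grp: grp[0])
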