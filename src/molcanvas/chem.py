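"""Chemistry adapter: the single place the package talks to RDKit.

Canonicalization, validity, Morgan fingerprints, BRICS fragments,
Bemis-Murcko scaffolds, molecular properties (logP, tPSA, QED) and the
default descriptor featurizer used by the Frechet-distance metric.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, BRICS, Descriptors, QED
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")


def mol_from_smiles(smiles: str):
    """Parse a SMILES string; returns None for invalid input."""
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def is_valid(smiles: str) -> bool:
    return mol_from_smiles(smiles) is not None


def canonical_smiles(smiles: str) -> str | None:
    mol = mol_from_smiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def morgan_fingerprint(smiles_or_mol, radius: int = 2,
                       n_bits: int = 1024) -> np.ndarray | None:
    """Morgan (ECFP-like) fingerprint as a 0/1 numpy vector."""
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    if mol is None:
        return None
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A&B|/|A|B| over bit vectors; T(m, m) = 1."""
    inter = int(np.sum(np.logical_and(a, b)))
    union = int(np.sum(np.logical_or(a, b)))
    return 1.0 if union == 0 else inter / union


def brics_fragments(smiles_or_mol) -> list[str]:
    """BRICS decomposition fragments (canonical SMILES)."""
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    if mol is None:
        return []
    return sorted(BRICS.BRICSDecompose(mol))


def murcko_scaffold(smiles_or_mol) -> str | None:
    """Bemis-Murcko scaffold SMILES ('' for acyclic molecules)."""
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    if mol is None:
        return None
    try:
        return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    except Exception:
        return None


PROPERTIES = ("logP", "tPSA", "QED")


def compute_property(smiles_or_mol, name: str) -> float | None:
    """logP / tPSA / QED via RDKit; None when RDKit cannot compute it."""
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    if mol is None:
        return None
    try:
        if name == "logP":
            return float(Descriptors.MolLogP(mol))
        if name == "tPSA":
            return float(Descriptors.TPSA(mol))
        if name == "QED":
            return float(QED.qed(mol))
    except Exception:
        return None
    raise ValueError(f"unknown property {name!r}; expected one of {PROPERTIES}")


def heavy_atom_count(smiles: str) -> float | None:
    """Adapter-light property proxy used by desk-scale conditional runs."""
    mol = mol_from_smiles(smiles)
    return None if mol is None else float(mol.GetNumHeavyAtoms())


_DESCRIPTOR_FNS = (
    Descriptors.MolWt, Descriptors.MolLogP, Descriptors.TPSA,
    Descriptors.NumHDonors, Descriptors.NumHAcceptors,
    Descriptors.NumRotatableBonds, Descriptors.RingCount,
    Descriptors.FractionCSP3, Descriptors.HeavyAtomCount,
    Descriptors.NumAromaticRings,
)


def descriptor_features(smiles: str) -> np.ndarray | None:
    """Fixed vector of cheap RDKit descriptors.

    The default featurizer for the Frechet distance metric; values are not
    comparable to ChemNet-based FCD numbers.
    """
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    try:
        return np.array([f(mol) for f in _DESCRIPTOR_FNS], dtype=float)
    except Exception:
        return None
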