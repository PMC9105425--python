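"""SMILES parsing and atom featurization for drug molecular graphs.

A drug is represented as its heavy-atom molecular graph: atoms are nodes,
covalent bonds are undirected edges, hydrogens are implicit.  Each atom
carries a 78-dimensional initial feature vector laid out as fixed blocks:

====================================  =====  ========================
block                                 width  encoding
====================================  =====  ========================
element symbol (43 named + "other")   44     one-hot
heavy-atom degree 0-10                11     one-hot
implicit valence 0-6                  7      one-hot
formal charge                         1      signed integer scalar
radical electron count                1      integer scalar
hybridization SP/SP2/SP3/SP3D/SP3D2   5      one-hot
total hydrogen count 0-7              8      one-hot
aromaticity                           1      0/1 flag
====================================  =====  ========================

Out-of-range degree/valence/H counts clamp to the top bin and unlisted
hybridization states map to the nearest listed one, each with a logged
warning, so every row satisfies the block one-hot invariants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger("gnnddi")
RDLogger.DisableLog("rdApp.*")  # rdkit's own stderr chatter; we raise instead

ATOM_FEATURE_DIM = 78

# 43 named elements; anything else falls into the 44th "other" slot.
ELEMENT_SYMBOLS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
)
SYMBOL_BLOCK = len(ELEMENT_SYMBOLS) + 1  # 44
MAX_DEGREE = 10
MAX_VALENCE = 6
MAX_NUM_HS = 7
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of one drug.

    ``edges`` stores each bond once as an unordered (i < j) 0-based index
    pair; the encoder expands them to both directions.  ``atom_features``
    is ``None`` on the skeleton returned by :func:`parse_smiles` and a
    ``(num_atoms, 78)`` float array after :func:`build_graph`.
    """

    drug_id: str
    smiles: str
    num_atoms: int
    edges: frozenset
    elements: tuple
    atom_features: np.ndarray | None = None

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (no self loops)."""
        adj = np.zeros((self.num_atoms, self.num_atoms))
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = 1.0
        return adj

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)


def _mol_from_smiles(smiles: str, drug_id: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"drug {drug_id!r}: empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"drug {drug_id!r}: unparseable SMILES {smiles!r}")
    if mol.GetNumAtoms() < 1:
        raise SmilesParseError(f"drug {drug_id!r}: SMILES {smiles!r} has no heavy atoms")
    return mol


def parse_smiles(smiles: str, drug_id: str = "?") -> MolecularGraph:
    """Parse a SMILES string into a graph skeleton (atoms + bonds, no features)."""
    mol = _mol_from_smiles(smiles, drug_id)
    edges = frozenset(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return MolecularGraph(
        drug_id=drug_id,
        smiles=smiles,
        num_atoms=mol.GetNumAtoms(),
        edges=edges,
        elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
    )


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def _clamped(value: int, top: int, what: str, drug_id: str) -> int:
    if value > top:
        logger.warning("drug %s: %s %d exceeds bin range, clamped to %d",
                       drug_id, what, value, top)
        return top
    return value


def featurize_atom(atom: Chem.Atom, drug_id: str = "?") -> np.ndarray:
    """Compute the 78-dim feature vector of one atom in a parsed molecule."""
    symbol = atom.GetSymbol()
    try:
        sym_idx = ELEMENT_SYMBOLS.index(symbol)
    except ValueError:
        sym_idx = SYMBOL_BLOCK - 1  # catch-all "other" slot

    hyb = atom.GetHybridization()
    if hyb in HYBRIDIZATIONS:
        hyb_idx = HYBRIDIZATIONS.index(hyb)
    else:
        # nearest listed state: pure-s centers to SP, everything else to SP3
        hyb_idx = 0 if hyb == Chem.HybridizationType.S else 2
        logger.warning("drug %s: hybridization %s not in the listed states, "
                       "mapped to %s", drug_id, hyb, HYBRIDIZATIONS[hyb_idx])

    degree = _clamped(atom.GetDegree(), MAX_DEGREE, "degree", drug_id)
    valence = _clamped(atom.GetImplicitValence(), MAX_VALENCE, "implicit valence",
                       drug_id)
    num_hs = _clamped(atom.GetTotalNumHs(), MAX_NUM_HS, "hydrogen count", drug_id)

    return np.concatenate([
        _one_hot(sym_idx, SYMBOL_BLOCK),
        _one_hot(degree, MAX_DEGREE + 1),
        _one_hot(valence, MAX_VALENCE + 1),
        [float(atom.GetFormalCharge())],
        [float(atom.GetNumRadicalElectrons())],
        _one_hot(hyb_idx, len(HYBRIDIZATIONS)),
        _one_hot(num_hs, MAX_NUM_HS + 1),
        [1.0 if atom.GetIsAromatic() else 0.0],
    ])


def build_graph(drug_id: str, smiles: str) -> MolecularGraph:
    """Parse and featurize one drug into a complete :class:`MolecularGraph`."""
    skeleton = parse_smiles(smiles, drug_id)
    mol = _mol_from_smiles(smiles, drug_id)
    features = np.stack([featurize_atom(a, drug_id) for a in mol.GetAtoms()])
    return MolecularGraph(
        drug_id=skeleton.drug_id,
        smiles=skeleton.smiles,
        num_atoms=skeleton.num_atoms,
        edges=skeleton.edges,
        elements=skeleton.elements,
        atom_features=features,
    )


# -- drug table I/O ----------------------------------------------------------


def read_drug_table(path) -> pd.DataFrame:
    """Read a TSV/CSV drug table with header columns ``drug_id`` and ``smiles``.

    The delimiter is sniffed; lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = {"drug_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"drug table {path}: missing columns {sorted(missing)}")
    df["drug_id"] = df["drug_id"].astype(str)
    if df["drug_id"].duplicated().any():
        dupes = df.loc[df["drug_id"].duplicated(), "drug_id"].tolist()
        raise ValueError(f"drug table {path}: duplicate drug ids {dupes}")
    return df[["drug_id", "smiles"]]


def read_smiles_file(path) -> pd.DataFrame:
    """Read a raw one-SMILES-per-line file, assigning ids ``d0001``, ``d0002``, ..."""
    smiles = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                smiles.append(line)
    ids = [f"d{i + 1:04d}" for i in range(len(smiles))]
    return pd.DataFrame({"drug_id": ids, "smiles": smiles})


def build_graph_table(drugs: pd.DataFrame) -> dict:
    """Featurize every drug in a table; returns ``{drug_id: MolecularGraph}``."""
    return {
        row.drug_id: build_graph(row.drug_id, row.smiles)
        for row in drugs.itertuples(index=False)
    }
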