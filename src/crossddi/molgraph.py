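"""Molecular graphs, BRICS pharmacophore decomposition, and featurization.

A drug enters the pipeline as a SMILES string and leaves this module as a
:class:`DecomposedMolecule`: an ordered set of pharmacophore subgraphs, each
carrying one-hot node (atom type) and edge (bond type) feature matrices.
Pharmacophores are operationalized as BRICS fragments — the BRICS rule set
cleaves bonds in retrosynthetically meaningful environments, so the resulting
fragments correspond to chemically coherent substructures.

Conventions:

* heavy atoms only; implicit hydrogens are never nodes (explicitly bracketed
  H atoms are kept);
* BRICS attachment points survive as atoms of the reserved type ``ATTACH`` —
  they mark where a fragment connected to the rest of the molecule but are
  excluded from atom-coverage accounting;
* molecules with no BRICS-cleavable bond yield exactly one pharmacophore (the
  whole molecule), so every molecule has N >= 1 fragments;
* disconnected SMILES (salts, mixtures "A.B") are reduced to their largest
  connected component with a warning, following the usual preprocessing of
  drug-interaction datasets;
* all atom and bond indices are 0-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit's own stderr chatter; errors are raised instead

ATTACH = "ATTACH"
OTHER = "OTHER"

DEFAULT_ATOM_SYMBOLS = ("H", "C", "O", "N", "S", "P", "F", "Cl", "Br", "I", OTHER, ATTACH)
DEFAULT_BOND_TYPES = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


class FeaturizationError(ValueError):
    """Raised when an atom or bond cannot be resolved against the vocabulary."""


@dataclass(frozen=True)
class FeatureVocab:
    """Fixed atom/bond vocabularies defining the one-hot feature spaces.

    The atom vocabulary leads with (H, C, O, N) and is extended with the halogens
    and heteroatoms common in approved drugs, plus the reserved ``OTHER``
    (out-of-vocabulary fallback) and ``ATTACH`` (BRICS attachment point) slots.
    ``extra_atom_columns`` reserves additional all-zero descriptor columns so
    the node width can be widened without retraining the featurizer.
    """

    atom_symbols: tuple[str, ...] = DEFAULT_ATOM_SYMBOLS
    bond_types: tuple[str, ...] = DEFAULT_BOND_TYPES
    extra_atom_columns: int = 0

    def __post_init__(self):
        if OTHER not in self.atom_symbols or ATTACH not in self.atom_symbols:
            raise ValueError("atom vocabulary must reserve OTHER and ATTACH slots")

    @property
    def d_v(self) -> int:
        return len(self.atom_symbols) + self.extra_atom_columns

    @property
    def d_e(self) -> int:
        return len(self.bond_types)

    def atom_index(self, symbol: str) -> int:
        try:
            return self.atom_symbols.index(symbol)
        except ValueError:
            return self.atom_symbols.index(OTHER)

    def bond_index(self, bond_type: str) -> int:
        try:
            return self.bond_types.index(bond_type)
        except ValueError:
            raise FeaturizationError(f"unsupported bond type {bond_type!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "atom_symbols": list(self.atom_symbols),
                "bond_types": list(self.bond_types),
                "extra_atom_columns": self.extra_atom_columns,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureVocab":
        obj = json.loads(text)
        return cls(
            tuple(obj["atom_symbols"]), tuple(obj["bond_types"]), obj["extra_atom_columns"]
        )


@dataclass
class MoleculeRecord:
    """A parsed molecule: heavy atoms as nodes, bonds as undirected edges."""

    drug_id: str
    smiles: str
    atoms: list[str]
    bonds: list[tuple[int, int, str]]
    rdmol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)


@dataclass
class PharmacophoreSubgraph:
    """One BRICS fragment of a molecule.

    ``parent_atom_indices`` maps each local atom back to the parent molecule's
    atom index; attachment-point atoms map to ``None`` (they do not exist in
    the parent).  Bonds are local-index pairs with a bond-type name.
    """

    atom_symbols: list[str]
    parent_atom_indices: list[int | None]
    bonds: list[tuple[int, int, str]]

    @property
    def num_atoms(self) -> int:
        return len(self.atom_symbols)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    @property
    def heavy_parent_indices(self) -> list[int]:
        return [i for i in self.parent_atom_indices if i is not None]


@dataclass
class DecomposedMolecule:
    molecule: MoleculeRecord
    pharmacophores: list[PharmacophoreSubgraph]
    n_cleaved_bonds: int = 0

    @property
    def n(self) -> int:
        return len(self.pharmacophores)


def parse_smiles(smiles: str, drug_id: str = "") -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Hydrogens are implicit (not nodes) unless explicitly bracketed in the
    input.  Disconnected structures keep only the largest component.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    params = Chem.SmilesParserParams()
    params.removeHs = False  # keep explicitly written [H] atoms as nodes
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        logger.warning(
            "SMILES %r for drug %r is disconnected; keeping largest component",
            smiles, drug_id,
        )
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    atoms = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        name = _RDKIT_BOND_NAMES.get(b.GetBondType())
        if name is None:
            raise SmilesParseError(
                f"unsupported bond type {b.GetBondType()} in SMILES {smiles!r}"
            )
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), name))
    return MoleculeRecord(drug_id=drug_id, smiles=smiles, atoms=atoms, bonds=bonds, rdmol=mol)


def _subgraph_from_atom_set(mol: Chem.Mol, atom_ids: tuple[int, ...],
                            n_parent: int) -> PharmacophoreSubgraph:
    atom_ids = sorted(atom_ids)
    local = {a: i for i, a in enumerate(atom_ids)}
    symbols, parents = [], []
    for a in atom_ids:
        atom = mol.GetAtomWithIdx(a)
        if atom.GetAtomicNum() == 0 or a >= n_parent:  # dummy from fragmentation
            symbols.append(ATTACH)
            parents.append(None)
        else:
            symbols.append(atom.GetSymbol())
            parents.append(a)
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in local and j in local:
            bonds.append((local[i], local[j], _RDKIT_BOND_NAMES[b.GetBondType()]))
    return PharmacophoreSubgraph(symbols, parents, bonds)


def brics_decompose(mol: MoleculeRecord) -> DecomposedMolecule:
    """Decompose a molecule into pharmacophore subgraphs via BRICS.

    Bonds matching a BRICS cleavage environment are broken; each resulting
    fragment becomes one pharmacophore, with the cleaved-bond stubs kept as
    ``ATTACH`` atoms.  The heavy atoms of the fragments partition the heavy
    atoms of the molecule.  If no bond is cleavable the whole molecule is the
    single pharmacophore.
    """
    rdmol = mol.rdmol if mol.rdmol is not None else parse_smiles(mol.smiles, mol.drug_id).rdmol
    n_parent = rdmol.GetNumAtoms()
    brics_bonds = sorted(
        {tuple(sorted(pair)) for pair, _labels in BRICS.FindBRICSBonds(rdmol)}
    )
    if not brics_bonds:
        whole = _subgraph_from_atom_set(rdmol, tuple(range(n_parent)), n_parent)
        return DecomposedMolecule(mol, [whole], n_cleaved_bonds=0)
    bond_ids = [rdmol.GetBondBetweenAtoms(i, j).GetIdx() for i, j in brics_bonds]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fragged = Chem.FragmentOnBonds(rdmol, bond_ids, addDummies=True)
    pharmacophores = [
        _subgraph_from_atom_set(fragged, atom_ids, n_parent)
        for atom_ids in Chem.GetMolFrags(fragged)
    ]
    return DecomposedMolecule(mol, pharmacophores, n_cleaved_bonds=len(bond_ids))


def featurize_subgraph(sub: PharmacophoreSubgraph,
                       vocab: FeatureVocab) -> tuple[np.ndarray, np.ndarray]:
    """One-hot feature matrices ``(X_V, X_E)`` for one pharmacophore.

    ``X_V`` is ``|V| x D_V`` with one row per atom, one-hot over the atom
    vocabulary (out-of-vocabulary elements fall back to ``OTHER``, attachment
    points to ``ATTACH``); ``X_E`` is ``|E| x D_E``, one-hot over bond types.
    Row order follows the subgraph's atom/bond order.
    """
    if sub.num_atoms == 0:
        raise FeaturizationError("empty pharmacophore subgraph (|V| = 0)")
    x_v = np.zeros((sub.num_atoms, vocab.d_v))
    for row, symbol in enumerate(sub.atom_symbols):
        x_v[row, vocab.atom_index(symbol)] = 1.0
    x_e = np.zeros((sub.num_bonds, vocab.d_e))
    for row, (_i, _j, btype) in enumerate(sub.bonds):
        x_e[row, vocab.bond_index(btype)] = 1.0
    return x_v, x_e


def atom_bond_indices(sub: PharmacophoreSubgraph,
                      vocab: FeatureVocab) -> tuple[np.ndarray, np.ndarray]:
    """Vocabulary index form of :func:`featurize_subgraph`.

    Because the features are pure one-hots, multiplying ``X_V`` by a projection
    matrix equals selecting rows of that matrix; the encoders exploit this and
    consume indices directly.
    """
    if sub.num_atoms == 0:
        raise FeaturizationError("empty pharmacophore subgraph (|V| = 0)")
    atoms = np.array([vocab.atom_index(s) for s in sub.atom_symbols], dtype=np.intp)
    bonds = np.array([vocab.bond_index(b[2]) for b in sub.bonds], dtype=np.intp)
    return atoms, bonds


def read_drug_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a drug table with required columns ``drug_id`` and ``smiles``.

    The delimiter is sniffed (comma or tab) unless given explicitly.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = {"drug_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"drug table {path} missing columns: {sorted(missing)}")
    df["drug_id"] = df["drug_id"].astype(str)
    return df
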