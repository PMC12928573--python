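"""Synthetic drugs and interaction labels with a plantable substructure rule.

The generator emulates the structure of real drug-interaction datasets — a
pool of valid small-molecule SMILES and a symmetric pairwise binary label
table — at desk scale and without downloads.  Molecules are assembled by
joining 2-4 library fragments with single bonds at designated attachment
atoms.  The library's ring fragments connect through bond environments that
the BRICS rules cleave, so the planted fragments re-emerge as pharmacophore
subgraphs under decomposition and the graph view sees the signal directly.

Interactions follow a pharmacophore-pair rule: the clean label of pair (A, B)
is 1 iff one drug contains the signal fragment f1 (a furan ring by default)
and the other contains f2 (a thiophene ring) — symmetric by construction —
and each label is then flipped independently with probability epsilon.  The
ground-truth rule parameters are recorded so that signal recovery can be
verified downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .molgraph import parse_smiles


@dataclass(frozen=True)
class Fragment:
    name: str
    smiles: str
    attach: tuple[int, ...]  # atom indices usable as junction points
    is_ring: bool


# Ring fragments form the molecule backbone (every ring-ring single bond is
# BRICS-cleavable); chain fragments decorate terminal attachment points.
DEFAULT_FRAGMENTS: tuple[Fragment, ...] = (
    Fragment("benzene", "c1ccccc1", (0, 3), True),
    Fragment("furan", "c1ccoc1", (1, 4), True),        # signal f1
    Fragment("thiophene", "c1ccsc1", (1, 4), True),    # signal f2
    Fragment("pyridine", "c1ccncc1", (0, 2), True),
    Fragment("cyclohexane", "C1CCCCC1", (0, 3), True),
    Fragment("pyrrolidine", "C1CCNC1", (0, 2), True),
    Fragment("acetyl", "CC(=O)", (1,), False),
    Fragment("ethylamine", "NCC", (0,), False),
    Fragment("methoxy", "OC", (0,), False),
    Fragment("isopropyl", "CC(C)", (1,), False),
)


@dataclass(frozen=True)
class FragmentLibrary:
    """Named, chemically valid fragments with two designated signal members."""

    fragments: tuple[Fragment, ...] = DEFAULT_FRAGMENTS
    f1: str = "furan"
    f2: str = "thiophene"

    def __post_init__(self):
        if len(self.fragments) < 8:
            raise ValueError("fragment library must contain at least 8 fragments")
        if self.f1 == self.f2:
            raise ValueError("the two signal fragments must differ")
        names = {f.name for f in self.fragments}
        if self.f1 not in names or self.f2 not in names:
            raise ValueError("signal fragments must be members of the library")
        for frag in self.fragments:
            if Chem.MolFromSmiles(frag.smiles) is None:
                raise ValueError(f"library fragment {frag.name!r} does not parse")

    def get(self, name: str) -> Fragment:
        return next(f for f in self.fragments if f.name == name)

    @property
    def rings(self) -> list[Fragment]:
        return [f for f in self.fragments if f.is_ring]

    @property
    def chains(self) -> list[Fragment]:
        return [f for f in self.fragments if not f.is_ring]

    def query_mol(self, name: str) -> Chem.Mol:
        return Chem.MolFromSmiles(self.get(name).smiles)


@dataclass
class SyntheticDataset:
    drugs: pd.DataFrame      # columns: drug_id, smiles
    triplets: pd.DataFrame   # columns: drug_a, drug_b, label
    truth: dict = field(default_factory=dict)


def _assemble(backbone: list[Fragment], decorations: list[Fragment | None]) -> str:
    """Join backbone rings in a chain with single bonds; decorate free ends."""
    mols = [Chem.MolFromSmiles(f.smiles) for f in backbone]
    combined = mols[0]
    offsets = [0]
    for m in mols[1:]:
        offsets.append(combined.GetNumAtoms())
        combined = Chem.CombineMols(combined, m)
    rw = Chem.RWMol(combined)
    for i in range(len(backbone) - 1):
        left = offsets[i] + backbone[i].attach[-1 if i > 0 else 0]
        right = offsets[i + 1] + backbone[i + 1].attach[0]
        rw.AddBond(left, right, Chem.BondType.SINGLE)
    # decorations attach to the two terminal rings' free attachment sites
    free_sites = []
    if len(backbone) == 1:
        free_sites = [offsets[0] + a for a in backbone[0].attach[1:]]
    else:
        free_sites = [offsets[0] + backbone[0].attach[-1],
                      offsets[-1] + backbone[-1].attach[0 if len(backbone[-1].attach) == 1 else -1]]
    for site, deco in zip(free_sites, decorations):
        if deco is None:
            continue
        offset = rw.GetNumAtoms()
        rw.InsertMol(Chem.MolFromSmiles(deco.smiles))
        rw.AddBond(site, offset + deco.attach[0], Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)  # raises on valence errors: must never escape
    return Chem.MolToSmiles(mol)


def contains_fragment(smiles: str, library: FragmentLibrary, name: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol.HasSubstructMatch(library.query_mol(name))


def gen_molecules(n: int, seed: int,
                  library: FragmentLibrary = FragmentLibrary(),
                  p_f1: float = 0.55, p_f2: float = 0.55,
                  p_decoration: float = 0.5) -> pd.DataFrame:
    """Generate ``n`` distinct valid molecules as a drug table.

    Each molecule has a backbone of 2-4 rings; with probability ``p_f1`` one
    backbone slot is forced to the f1 signal fragment, independently with
    ``p_f2`` another slot to f2 (so the two signal-carrier fractions are the
    configured ones up to chance extra occurrences).  Remaining slots draw
    uniformly from the non-signal rings, and terminal sites are decorated
    with chain fragments at rate ``p_decoration``.
    """
    if n < 2:
        raise ValueError("need at least 2 molecules")
    rng = np.random.default_rng(seed)
    plain_rings = [f for f in library.rings if f.name not in (library.f1, library.f2)]
    chains = library.chains
    rows, seen = [], set()
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cannot generate enough distinct molecules")
        length = int(rng.integers(2, 5))
        backbone = [plain_rings[i] for i in rng.integers(0, len(plain_rings), length)]
        slots = list(rng.permutation(length))
        if rng.random() < p_f1:
            backbone[slots[0]] = library.get(library.f1)
        if rng.random() < p_f2:
            backbone[slots[1]] = library.get(library.f2)
        decorations = [
            chains[int(rng.integers(0, len(chains)))] if rng.random() < p_decoration else None
            for _ in range(2)
        ]
        smiles = _assemble(backbone, decorations)
        parse_smiles(smiles)  # assembly validity is an internal guarantee
        if smiles in seen:
            continue
        seen.add(smiles)
        rows.append({"drug_id": f"SYN{len(rows):04d}", "smiles": smiles})
    return pd.DataFrame(rows)


def gen_ddi_labels(drugs: pd.DataFrame, library: FragmentLibrary,
                   noise: float, n_pairs: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample unordered drug pairs and label them by the planted rule.

    Returns ``(triplets, clean)``: the noisy table (label flipped with
    probability ``noise``) and the noise-free rule output for the same pairs.
    Pairs are stored canonically with drug_a < drug_b.
    """
    if not (0 <= noise < 0.5):
        raise ValueError("noise rate must lie in [0, 0.5)")
    ids = list(drugs["drug_id"])
    n_drugs = len(ids)
    max_pairs = n_drugs * (n_drugs - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"requested {n_pairs} pairs but only {max_pairs} exist")
    rng = np.random.default_rng(seed)

    has_f1 = {r.drug_id: contains_fragment(r.smiles, library, library.f1)
              for r in drugs.itertuples()}
    has_f2 = {r.drug_id: contains_fragment(r.smiles, library, library.f2)
              for r in drugs.itertuples()}
    if not any(has_f1.values()) or not any(has_f2.values()):
        import warnings

        warnings.warn("a signal fragment is absent from the pool: all clean labels are 0")

    all_i, all_j = np.triu_indices(n_drugs, k=1)
    flat = rng.choice(max_pairs, size=n_pairs, replace=False)
    i_idx, j_idx = all_i[flat], all_j[flat]
    rows, clean_rows = [], []
    flips = rng.random(n_pairs) < noise
    for i, j, flip in zip(i_idx, j_idx, flips):
        a, b = sorted((ids[i], ids[j]))
        clean = int((has_f1[a] and has_f2[b]) or (has_f2[a] and has_f1[b]))
        rows.append({"drug_a": a, "drug_b": b, "label": clean ^ int(flip)})
        clean_rows.append({"drug_a": a, "drug_b": b, "label": clean})
    return pd.DataFrame(rows), pd.DataFrame(clean_rows)


def make_dataset(n_drugs: int = 300, n_pairs: int = 3000, noise: float = 0.1,
                 seed: int = 7,
                 library: FragmentLibrary = FragmentLibrary()) -> SyntheticDataset:
    """One-call benchmark: drug table, noisy triplets, recorded ground truth."""
    drugs = gen_molecules(n_drugs, seed, library)
    triplets, clean = gen_ddi_labels(drugs, library, noise, n_pairs, seed + 1)
    truth = {
        "f1": library.f1,
        "f2": library.f2,
        "noise": noise,
        "seed": seed,
        "clean_labels": clean["label"].tolist(),
        "positive_rate_clean": float(clean["label"].mean()),
    }
    return SyntheticDataset(drugs=drugs, triplets=triplets, truth=truth)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.drugs.to_csv(out / "drugs.tsv", sep="\t", index=False)
    ds.triplets.to_csv(out / "ddis.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(ds.truth, indent=2))
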