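"""Graph-view encoder: pharmacophore token matrices to a molecule embedding.

Per pharmacophore k, node and edge one-hot features are projected into a
common width d and stacked row-wise,

    X'_k = [X'_{V_k} || X'_{E_k}]   in R^{(|V_k|+|E_k|) x d},

encoded by a stack of multi-head self-attention layers (no positional
encoding — the rows form a set, so the molecule embedding is invariant to
atom, bond and pharmacophore ordering), and pooled in two stages: rows within
each pharmacophore, then across the N pharmacophores, giving the graph-view
embedding z_mol of length d.  Mean pooling is the default at both stages; sum
and max are available by configuration.

One encoder is shared across all pharmacophores and all drugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .molgraph import (
    DecomposedMolecule,
    FeatureVocab,
    atom_bond_indices,
    featurize_subgraph,
)
from .transformer import (
    encoder_stack,
    init_layer,
    length_buckets,
    masked_mean,
    xavier,
)

_NEG_INF = -1e30


@dataclass(frozen=True)
class GraphEncoderConfig:
    d: int = 64          # drug embedding dimension
    heads: int = 4
    layers: int = 2
    readout: str = "mean"  # pooling at both stages: mean | sum | max
    d_ff: int | None = None  # feed-forward width; defaults to 2*d

    def __post_init__(self):
        if self.d % self.heads != 0:
            raise ValueError(f"heads ({self.heads}) must divide d ({self.d})")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")

    @property
    def ff_width(self) -> int:
        return self.d_ff if self.d_ff is not None else 2 * self.d


def graph_readout(embeddings: list[Tensor], mode: str = "mean") -> Tensor:
    """Pool a non-empty list of per-pharmacophore embeddings into z_mol.

    Each element is an (T_k, d) matrix of encoded tokens; stage one pools the
    rows of each pharmacophore, stage two pools across pharmacophores.
    """
    if len(embeddings) == 0:
        raise ValueError("readout requires at least one pharmacophore (N >= 1)")

    def pool(x: Tensor, axis: int) -> Tensor:
        if mode == "mean":
            return x.mean(axis=axis)
        if mode == "sum":
            return x.sum(axis=axis)
        return x.max(axis=axis)

    stacked = concat([pool(e, 0).reshape(1, -1) for e in embeddings], axis=0)
    return pool(stacked, 0)


class GraphEncoder:
    """Shared-parameter encoder from decomposed molecules to z_mol vectors."""

    def __init__(self, vocab: FeatureVocab, cfg: GraphEncoderConfig,
                 rng: np.random.Generator):
        self.vocab = vocab
        self.cfg = cfg
        d = cfg.d
        self.params: dict[str, Tensor] = {
            "graph.node_proj": Tensor(xavier(rng, vocab.d_v, d), requires_grad=True),
            "graph.edge_proj": Tensor(xavier(rng, vocab.d_e, d), requires_grad=True),
        }
        for layer in range(cfg.layers):
            self.params.update(init_layer(rng, d, cfg.ff_width, f"graph.layer{layer}"))

    # -- single-pharmacophore surface (reference path, used by the tests) -----

    def project_and_concat(self, x_v: np.ndarray, x_e: np.ndarray) -> Tensor:
        """Build the token matrix X' = [X_V P_V || X_E P_E] for one subgraph."""
        if x_v.shape[1] != self.vocab.d_v:
            raise ValueError(
                f"X_V has {x_v.shape[1]} columns, expected D_V={self.vocab.d_v}"
            )
        if x_e.size and x_e.shape[1] != self.vocab.d_e:
            raise ValueError(
                f"X_E has {x_e.shape[1]} columns, expected D_E={self.vocab.d_e}"
            )
        nodes = Tensor(x_v) @ self.params["graph.node_proj"]
        if x_e.shape[0] == 0:
            return nodes
        edges = Tensor(x_e) @ self.params["graph.edge_proj"]
        return concat([nodes, edges], axis=0)

    def encode_pharmacophore(self, tokens: Tensor) -> Tensor:
        """Encode one (T, d) token matrix through the attention stack."""
        if not np.all(np.isfinite(tokens.data)):
            raise ValueError("non-finite token matrix")
        out = encoder_stack(
            tokens.reshape(1, *tokens.shape), self.params, "graph",
            self.cfg.layers, self.cfg.heads,
        )
        return out.reshape(*tokens.shape)

    def encode_molecule(self, decomposed: DecomposedMolecule) -> Tensor:
        """Full graph view for one molecule: z_mol of length d."""
        embeddings = []
        for sub in decomposed.pharmacophores:
            x_v, x_e = featurize_subgraph(sub, self.vocab)
            tokens = self.project_and_concat(x_v, x_e)
            embeddings.append(self.encode_pharmacophore(tokens))
        return graph_readout(embeddings, self.cfg.readout)

    # -- batched surface (training path) --------------------------------------

    def prepare(self, decomposed: DecomposedMolecule) -> list[tuple[np.ndarray, np.ndarray]]:
        """Precompute vocabulary-index arrays per pharmacophore."""
        return [atom_bond_indices(sub, self.vocab) for sub in decomposed.pharmacophores]

    def encode_batch(self, prepared: list[list[tuple[np.ndarray, np.ndarray]]]) -> Tensor:
        """Encode a batch of prepared molecules into a (B, d) embedding matrix.

        All pharmacophores of all molecules are padded into one (F, T_max, d)
        token tensor and encoded in a single pass.  One-hot projection is a
        row-gather from the stacked projection table, which is exactly the
        matrix product of the one-hot features with the projections.
        """
        frag_atoms: list[np.ndarray] = []
        frag_bonds: list[np.ndarray] = []
        owner: list[int] = []
        for mol_idx, fragments in enumerate(prepared):
            for atoms, bonds in fragments:
                frag_atoms.append(atoms)
                frag_bonds.append(bonds)
                owner.append(mol_idx)
        n_frag = len(frag_atoms)
        lengths = np.array([a.size + e.size for a, e in zip(frag_atoms, frag_bonds)])
        d_v = self.vocab.d_v
        table = concat(
            [self.params["graph.node_proj"], self.params["graph.edge_proj"]], axis=0
        )

        # encode in near-uniform length buckets to avoid quadratic pad waste
        bucket_outputs: list[Tensor] = []
        bucket_rows: list[np.ndarray] = []
        for rows, t_pad in length_buckets(lengths):
            idx = np.zeros((rows.size, t_pad), dtype=np.intp)
            mask = np.zeros((rows.size, t_pad), dtype=bool)
            for r, f in enumerate(rows):
                row = np.concatenate([frag_atoms[f], frag_bonds[f] + d_v])
                idx[r, : row.size] = row
                mask[r, : row.size] = True
            tokens = table[idx]  # (F_b, T, d) gather == one-hot matmul
            encoded = encoder_stack(tokens, self.params, "graph",
                                    self.cfg.layers, self.cfg.heads, mask)
            bucket_outputs.append(self._pool_tokens(encoded, mask))
            bucket_rows.append(rows)
        inverse = np.argsort(np.concatenate(bucket_rows))
        pooled = concat(bucket_outputs, axis=0)[inverse]     # (F, d), input order
        return self._pool_fragments(pooled, np.array(owner), len(prepared))

    def _pool_tokens(self, encoded: Tensor, mask: np.ndarray) -> Tensor:
        if self.cfg.readout == "mean":
            return masked_mean(encoded, mask)
        if self.cfg.readout == "sum":
            return (encoded * Tensor(mask[:, :, None].astype(float))).sum(axis=1)
        neg = Tensor(np.where(mask, 0.0, _NEG_INF)[:, :, None])
        return (encoded + neg).max(axis=1)

    def _pool_fragments(self, pooled: Tensor, owner: np.ndarray, n_mol: int) -> Tensor:
        if self.cfg.readout in ("mean", "sum"):
            seg = np.zeros((n_mol, owner.size))
            seg[owner, np.arange(owner.size)] = 1.0
            if self.cfg.readout == "mean":
                seg /= seg.sum(axis=1, keepdims=True)
            return Tensor(seg) @ pooled
        # max: pad fragment embeddings per molecule, then reduce
        counts = np.bincount(owner, minlength=n_mol)
        f_max = int(counts.max())
        gather = np.zeros((n_mol, f_max), dtype=np.intp)
        mmask = np.zeros((n_mol, f_max), dtype=bool)
        slot = np.zeros(n_mol, dtype=int)
        for f, m in enumerate(owner):
            gather[m, slot[m]] = f
            mmask[m, slot[m]] = True
            slot[m] += 1
        padded = pooled[gather] + Tensor(np.where(mmask, 0.0, _NEG_INF)[:, :, None])
        return padded.max(axis=1)
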