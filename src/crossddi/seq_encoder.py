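"""Sequence-view encoder: SMILES tokens to a molecule embedding.

SMILES strings are tokenized at the atom level — bracket atoms ``[...]`` and
the two-character elements Cl/Br are single tokens; ring-closure digits
(including the ``%nn`` form), bond symbols, branch parentheses and aromatic
lowercase atoms are their own tokens — so that concatenating the tokens
reproduces the input exactly.  Tokens are embedded, combined with a learned
positional embedding, and passed through a stack of self-attention layers
(the same per-layer computation as the graph view), yielding contextual token
embeddings H = (h_1, ..., h_n).  Mean pooling over the n tokens gives the
sequence-view embedding h_mol; no classification token is added.

The encoder is trained from scratch jointly with the rest of the model; its
interface (SMILES -> H -> h_mol) matches a pretrained BERT-style molecular
language model, but no external weights are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .transformer import encoder_stack, init_layer, length_buckets, masked_mean

PAD = "<pad>"
UNK = "<unk>"

# characters legal as single-character SMILES tokens (organic subset atoms,
# aromatic atoms, ring digits, bonds, branches, charges, stereo markers)
_SINGLE_CHARS = set("BCNOPSFIbcnops0123456789()=#-+/\\.@*~$:")


class TokenizationError(ValueError):
    """Raised when a SMILES character matches no tokenization rule."""


def tokenize(smiles: str) -> list[str]:
    """Atom-level tokenization of a SMILES string.

    The token list joins back to the input byte-for-byte.  Examples:
    ``"CCO" -> [C, C, O]``, ``"ClCCl" -> [Cl, C, Cl]``,
    ``"c1ccccc1" -> [c, 1, c, c, c, c, c, 1]``.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            end = smiles.find("]", i)
            if end == -1:
                raise TokenizationError(f"unclosed bracket atom at position {i}")
            tokens.append(smiles[i : end + 1])
            i = end + 1
        elif smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise TokenizationError(f"malformed ring closure at position {i}")
            tokens.append(smiles[i : i + 3])
            i += 3
        elif ch in _SINGLE_CHARS:
            tokens.append(ch)
            i += 1
        else:
            raise TokenizationError(
                f"character {ch!r} at position {i} matches no token rule"
            )
    return tokens


class SmilesVocab:
    """Token-to-id mapping with reserved PAD and UNK entries.

    Built once from a training corpus and serialized with checkpoints so that
    tokenization is stable across save/load.
    """

    def __init__(self, tokens: list[str]):
        self.itos = [PAD, UNK] + sorted(set(tokens) - {PAD, UNK})
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    @classmethod
    def from_corpus(cls, smiles_iter) -> "SmilesVocab":
        seen: list[str] = []
        for smi in smiles_iter:
            seen.extend(tokenize(smi))
        return cls(seen)

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, tokens: list[str]) -> np.ndarray:
        unk = self.stoi[UNK]
        return np.array([self.stoi.get(t, unk) for t in tokens], dtype=np.intp)

    def to_list(self) -> list[str]:
        return list(self.itos)

    @classmethod
    def from_list(cls, itos: list[str]) -> "SmilesVocab":
        vocab = cls.__new__(cls)
        vocab.itos = list(itos)
        vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
        return vocab


@dataclass(frozen=True)
class SeqEncoderConfig:
    d: int = 64
    heads: int = 4
    layers: int = 2
    max_len: int = 256
    d_ff: int | None = None

    def __post_init__(self):
        if self.d % self.heads != 0:
            raise ValueError(f"heads ({self.heads}) must divide d ({self.d})")

    @property
    def ff_width(self) -> int:
        return self.d_ff if self.d_ff is not None else 2 * self.d


class SeqEncoder:
    """BERT-style encoder over SMILES token sequences."""

    def __init__(self, vocab: SmilesVocab, cfg: SeqEncoderConfig,
                 rng: np.random.Generator):
        self.vocab = vocab
        self.cfg = cfg
        d = cfg.d
        self.params: dict[str, Tensor] = {
            "seq.tok_emb": Tensor(rng.normal(0.0, 0.02, size=(len(vocab), d)),
                                  requires_grad=True),
            "seq.pos_emb": Tensor(rng.normal(0.0, 0.02, size=(cfg.max_len, d)),
                                  requires_grad=True),
        }
        for layer in range(cfg.layers):
            self.params.update(init_layer(rng, d, cfg.ff_width, f"seq.layer{layer}"))

    def prepare(self, smiles: str) -> np.ndarray:
        """Tokenize and map to vocabulary ids; errors if too long."""
        ids = self.vocab.encode(tokenize(smiles))
        if ids.size > self.cfg.max_len:
            raise ValueError(
                f"sequence of {ids.size} tokens exceeds max_len={self.cfg.max_len}"
            )
        return ids

    def encode_batch(self, id_seqs: list[np.ndarray],
                     return_tokens: bool = False):
        """Contextual embeddings for a batch of id sequences.

        Returns the pooled (B, d) embeddings h_mol; with ``return_tokens`` also
        the padded (B, T_max, d) token matrix H and its mask.
        """
        lengths = np.array([s.size for s in id_seqs])
        if (lengths == 0).any():
            raise ValueError("cannot encode an empty token sequence")

        def encode_rows(rows: np.ndarray, t_pad: int):
            ids = np.zeros((rows.size, t_pad), dtype=np.intp)
            mask = np.zeros((rows.size, t_pad), dtype=bool)
            for r, b in enumerate(rows):
                ids[r, : id_seqs[b].size] = id_seqs[b]
                mask[r, : id_seqs[b].size] = True
            tok = self.params["seq.tok_emb"][ids]                   # (B, T, d)
            pos = self.params["seq.pos_emb"][np.arange(t_pad)]      # (T, d)
            x = tok + pos.reshape(1, t_pad, self.cfg.d)
            h = encoder_stack(x, self.params, "seq",
                              self.cfg.layers, self.cfg.heads, mask)
            return h, mask

        if return_tokens:
            rows = np.arange(len(id_seqs))
            h, mask = encode_rows(rows, int(lengths.max()))
            return masked_mean(h, mask), h, mask

        # near-uniform length buckets avoid quadratic padding waste
        outputs: list[Tensor] = []
        all_rows: list[np.ndarray] = []
        for rows, t_pad in length_buckets(lengths):
            h, mask = encode_rows(rows, t_pad)
            outputs.append(masked_mean(h, mask))
            all_rows.append(rows)
        inverse = np.argsort(np.concatenate(all_rows))
        return concat(outputs, axis=0)[inverse]

    def encode(self, smiles: str) -> tuple[Tensor, Tensor]:
        """Single-molecule convenience: returns (H of shape (n, d), h_mol)."""
        ids = self.prepare(smiles)
        pooled, h, _mask = self.encode_batch([ids], return_tokens=True)
        return h.reshape(ids.size, self.cfg.d), pooled.reshape(self.cfg.d)


def sequence_readout(h: Tensor) -> Tensor:
    """Mean pooling over token rows: h_mol = (1/n) sum_i h_i."""
    if h.shape[0] == 0:
        raise ValueError("cannot pool an empty token matrix")
    return h.mean(axis=0)
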