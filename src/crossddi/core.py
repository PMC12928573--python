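"""Method core: cross-view contrastive loss, cross-attention fusion, head.

For each drug the two encoders produce a graph-view embedding z_mol and a
sequence-view embedding h_mol of equal width d.  Training aligns the two
views of the same drug while pushing apart views of different drugs with the
pairwise contrastive loss (cosine similarity, temperature tau):

    L(A, B) = -log [ e^{s(z_A,h_A)/t} + e^{s(z_B,h_B)/t} ] /
              [ e^{s(z_A,z_B)/t} + e^{s(z_A,h_B)/t} + e^{s(h_A,z_B)/t} + e^{s(h_A,h_B)/t} ]

with exactly the two positive (same-drug) pairs in the numerator and the four
cross-drug pairs in the denominator — note the positive terms are *not*
repeated in the denominator, which distinguishes this loss from standard
InfoNCE and means it can be negative.  The batch form averages the pairwise
loss over all unordered drug pairs in the batch (``pairwise`` mode, default);
an NT-Xent-style ``batch`` mode is available as a documented alternative and
is never silently substituted.

For prediction the two views of each drug are fused by bidirectional
cross-attention — each view acts as a one-token query attending over the
two-token set {z, h}; the two attended outputs are averaged and projected —
and the fused vectors of the two drugs are concatenated and scored by an MLP
with a sigmoid output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .transformer import xavier


@dataclass
class ViewPair:
    """Both view embeddings of one drug."""

    drug_id: str
    z_mol: np.ndarray
    h_mol: np.ndarray


@dataclass(frozen=True)
class ContrastiveConfig:
    tau: float = 0.5
    mode: str = "pairwise"  # pairwise (as-printed loss averaged over pairs) | batch (NT-Xent)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")
        if self.mode not in ("pairwise", "batch"):
            raise ValueError(f"unknown contrastive mode {self.mode!r}")


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-zero vectors; errors on zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def contrastive_loss_pair(a: ViewPair, b: ViewPair,
                          cfg: ContrastiveConfig = ContrastiveConfig()) -> float:
    """Scalar, formula-literal evaluation of the pairwise loss for two drugs."""
    t = cfg.tau
    num = math.exp(cosine_sim(a.z_mol, a.h_mol) / t) + math.exp(
        cosine_sim(b.z_mol, b.h_mol) / t
    )
    den = (
        math.exp(cosine_sim(a.z_mol, b.z_mol) / t)
        + math.exp(cosine_sim(a.z_mol, b.h_mol) / t)
        + math.exp(cosine_sim(a.h_mol, b.z_mol) / t)
        + math.exp(cosine_sim(a.h_mol, b.h_mol) / t)
    )
    return -math.log(num / den)


def _normalize_rows(x: Tensor) -> Tensor:
    norms = (x * x).sum(axis=-1, keepdims=True).sqrt()
    if np.any(norms.data == 0.0):
        raise ValueError("zero-norm embedding in contrastive batch")
    return x / norms


def contrastive_loss_batch(z: Tensor, h: Tensor,
                           cfg: ContrastiveConfig = ContrastiveConfig()) -> Tensor:
    """Vectorized contrastive loss over a batch of B >= 2 drugs.

    ``z`` and ``h`` are (B, d) graph- and sequence-view embeddings with
    matching row order.  In ``pairwise`` mode this is the mean of the
    two-drug loss over all B(B-1)/2 unordered drug pairs and reduces exactly
    to :func:`contrastive_loss_pair` when B = 2.  In ``batch`` mode each
    drug's (z_i, h_i) is the positive pair and every cross-drug view
    combination is a negative (NT-Xent with temperature tau).
    """
    n = z.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 drugs (no negatives)")
    t = cfg.tau
    zn = _normalize_rows(z)
    hn = _normalize_rows(h)
    s_zh = zn @ hn.swapaxes(-1, -2)   # (B, B): s_zh[i, j] = sim(z_i, h_j)
    s_zz = zn @ zn.swapaxes(-1, -2)
    s_hh = hn @ hn.swapaxes(-1, -2)
    diag = np.arange(n)
    pos = s_zh[diag, diag]            # (B,): same-drug view similarity

    if cfg.mode == "pairwise":
        e_pos = (pos / t).exp()
        num = e_pos.reshape(n, 1) + e_pos.reshape(1, n)
        den = (s_zz / t).exp() + (s_zh / t).exp() + \
            (s_zh.swapaxes(-1, -2) / t).exp() + (s_hh / t).exp()
        losses = den.log() - num.log()
        upper = np.triu(np.ones((n, n)), k=1)
        weights = Tensor(upper / upper.sum())
        return (losses * weights).sum()

    # NT-Xent: anchor z_i against {h_j for all j} and {z_j, j != i}; symmetric in h
    off = Tensor(np.where(np.eye(n, dtype=bool), -np.inf, 0.0))
    e_zh = (s_zh / t).exp()
    e_hz = (s_zh.swapaxes(-1, -2) / t).exp()
    e_zz = ((s_zz + off) / t).exp()   # -inf on the diagonal -> exp = 0
    e_hh = ((s_hh + off) / t).exp()
    den_z = e_zh.sum(axis=1) + e_zz.sum(axis=1)
    den_h = e_hz.sum(axis=1) + e_hh.sum(axis=1)
    log_pos = pos / t
    loss_z = den_z.log() - log_pos
    loss_h = den_h.log() - log_pos
    return (loss_z + loss_h).mean() * 0.5


@dataclass(frozen=True)
class FusionConfig:
    d: int = 64
    d_f: int | None = None   # fused width; defaults to d
    heads: int = 1

    @property
    def fused_width(self) -> int:
        return self.d_f if self.d_f is not None else self.d


class CrossAttentionFusion:
    """Bidirectional one-layer cross-attention between the two views.

    z queries the two-token sequence [z; h]; h does the same; the two attended
    outputs are averaged and linearly projected to the fused width d_f.
    """

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        if cfg.d % cfg.heads != 0:
            raise ValueError(f"fusion heads ({cfg.heads}) must divide d ({cfg.d})")
        self.cfg = cfg
        d = cfg.d
        self.params: dict[str, Tensor] = {
            "fuse.Wq": Tensor(xavier(rng, d, d), requires_grad=True),
            "fuse.Wk": Tensor(xavier(rng, d, d), requires_grad=True),
            "fuse.Wv": Tensor(xavier(rng, d, d), requires_grad=True),
            "fuse.Wp": Tensor(xavier(rng, d, cfg.fused_width), requires_grad=True),
        }

    def fuse(self, z: Tensor, h: Tensor) -> Tensor:
        """Fuse (B, d) view embeddings into (B, d_f) drug representations."""
        if z.shape != h.shape:
            raise ValueError(f"view shapes differ: {z.shape} vs {h.shape}")
        b, d = z.shape
        hds, d_k = self.cfg.heads, d // self.cfg.heads
        kv = concat(
            [z.reshape(b, 1, d), h.reshape(b, 1, d)], axis=1
        )  # (B, 2, d) token sequence per drug

        def heads_of(x: Tensor, t: int) -> Tensor:
            return x.reshape(b, t, hds, d_k).transpose(0, 2, 1, 3)

        k = heads_of(kv @ self.params["fuse.Wk"], 2)       # (B, h, 2, d_k)
        v = heads_of(kv @ self.params["fuse.Wv"], 2)

        def attend(query: Tensor) -> Tensor:               # query: (B, d)
            q = heads_of(query.reshape(b, 1, d) @ self.params["fuse.Wq"], 1)
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
            out = scores.softmax() @ v                     # (B, h, 1, d_k)
            return out.transpose(0, 2, 1, 3).reshape(b, d)

        fused = (attend(z) + attend(h)) * 0.5
        return fused @ self.params["fuse.Wp"]


class PredictionHead:
    """MLP scoring head: sigma(MLP([d_A ; d_B])) with ReLU hidden layers.

    Default widths are [2*d_f, d_f, 1].  The concatenation order is (first
    argument, second argument); an optional symmetrized score averaging
    y(A,B) and y(B,A) is applied by the caller, not here.
    """

    def __init__(self, d_f: int, rng: np.random.Generator,
                 hidden: tuple[int, ...] | None = None):
        widths = [2 * d_f] + list(hidden if hidden is not None else (d_f,)) + [1]
        self.params: dict[str, Tensor] = {}
        for i, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
            self.params[f"head.W{i}"] = Tensor(xavier(rng, w_in, w_out),
                                               requires_grad=True)
            self.params[f"head.b{i}"] = Tensor(np.zeros(w_out), requires_grad=True)
        self.n_layers = len(widths) - 1

    def predict(self, d_a: Tensor, d_b: Tensor) -> Tensor:
        """Interaction probabilities in (0, 1) for (B, d_f) fused vectors."""
        x = concat([d_a, d_b], axis=-1)
        for i in range(self.n_layers):
            x = x @ self.params[f"head.W{i}"] + self.params[f"head.b{i}"]
            if i < self.n_layers - 1:
                x = x.relu()
        return x.reshape(x.shape[0]).sigmoid()


def supervised_loss(y_hat, y) -> float:
    """Binary cross-entropy on probabilities; batch inputs are averaged.

    Probabilities must lie strictly inside (0, 1) — clamping is an explicit
    caller decision, never applied silently here.
    """
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y_hat <= 0.0) or np.any(y_hat >= 1.0):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    return float(np.mean(-(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat))))


def bce_loss(y_hat: Tensor, y: np.ndarray) -> Tensor:
    """Differentiable batch-mean binary cross-entropy."""
    y = np.asarray(y, dtype=float)
    return -(Tensor(y) * y_hat.log() + Tensor(1.0 - y) * (1.0 - y_hat).log()).mean()


def total_objective(bce, cl, phase: str = "supervised",
                    lambda_cl: float = 1.0):
    """Combine the supervised and contrastive terms.

    Two-stage schedule (default training mode): the ``contrastive`` phase
    optimizes the contrastive term alone and the ``supervised`` phase the
    cross-entropy alone.  The ``joint`` phase returns bce + lambda_cl * cl.
    """
    if lambda_cl < 0:
        raise ValueError("lambda_cl must be non-negative")
    if phase == "contrastive":
        return cl
    if phase == "supervised":
        return bce
    if phase == "joint":
        return bce + lambda_cl * cl
    raise ValueError(f"unknown phase {phase!r}")
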