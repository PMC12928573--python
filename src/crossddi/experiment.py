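"""Dataset splits, negative sampling, model training and ablation.

Two evaluation regimes are supported.  In the warm-start regime, labeled drug
pairs are stratified into k folds; within each cross-validation round one
fold is the test set, one the validation set and the remaining k-2 folds the
training set, so every test drug also occurs in training pairs.  In the
cold-start regime a fraction of *drugs* (20% by default) is sampled as "new";
training pairs touch only old drugs and, in the default strict mode, test
pairs touch only new drugs, so the train and test drug sets are disjoint.
Negative pairs are sampled uniformly from the non-interacting pairs of each
split's own drug pool, never crossing splits.

Training follows the published recipe: mini-batch gradient descent with an
Adam-style optimizer with decoupled weight decay (lr 1e-3, weight decay
4e-4, batch size 256, embedding width 64 by default), under either the
two-stage schedule (contrastive alignment first, then supervised
cross-entropy) or a joint objective bce + lambda * cl.  Validation AUROC
selects the checkpoint used for the final test report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .autodiff import AdamW, Tensor
from .core import (
    ContrastiveConfig,
    CrossAttentionFusion,
    FusionConfig,
    PredictionHead,
    bce_loss,
    contrastive_loss_batch,
    total_objective,
)
from .graph_encoder import GraphEncoder, GraphEncoderConfig
from .metrics import MetricsReport, auroc, compute_metrics
from .molgraph import FeatureVocab, brics_decompose, parse_smiles
from .seq_encoder import SeqEncoder, SeqEncoderConfig, SmilesVocab

VARIANTS = ("full", "no_graph_view", "no_sequence_view")


class SplitError(ValueError):
    pass


# --------------------------------------------------------------------------
# splits and negative sampling
# --------------------------------------------------------------------------

def canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Store each unordered pair once, with drug_a < drug_b lexicographically."""
    a = df["drug_a"].astype(str)
    b = df["drug_b"].astype(str)
    if (a == b).any():
        raise ValueError("self-pairs (drug_a == drug_b) are not allowed")
    out = df.copy()
    swap = a > b
    out.loc[swap, ["drug_a", "drug_b"]] = df.loc[swap, ["drug_b", "drug_a"]].values
    return out


@dataclass
class SplitPlan:
    mode: str                      # warm | cold
    seed: int
    fold_of: np.ndarray | None = None      # warm: triplet -> fold id
    k: int | None = None
    new_drugs: frozenset[str] = frozenset()  # cold
    old_drugs: frozenset[str] = frozenset()
    train_idx: np.ndarray | None = None      # cold: triplet row indices
    test_idx: np.ndarray | None = None
    n_dropped: int = 0
    cold_test_rule: str = "strict"

    def warm_round(self, fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train, val, test) triplet indices for one cross-validation round."""
        if self.mode != "warm":
            raise SplitError("warm_round is only defined for warm splits")
        test = np.flatnonzero(self.fold_of == fold)
        val = np.flatnonzero(self.fold_of == (fold + 1) % self.k)
        train = np.flatnonzero((self.fold_of != fold) & (self.fold_of != (fold + 1) % self.k))
        return train, val, test

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fold_of"] = None if self.fold_of is None else self.fold_of.tolist()
        d["train_idx"] = None if self.train_idx is None else self.train_idx.tolist()
        d["test_idx"] = None if self.test_idx is None else self.test_idx.tolist()
        d["new_drugs"] = sorted(self.new_drugs)
        d["old_drugs"] = sorted(self.old_drugs)
        return d


def make_warm_split(triplets: pd.DataFrame, k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified k-fold partition of the triplets.

    Stratification uses the interaction-type column when present (so each
    fold preserves the type distribution) and the binary label otherwise;
    each fold's positive fraction is within one item of the global fraction.
    """
    if k < 2:
        raise SplitError("k must be >= 2")
    strat = triplets["type"] if "type" in triplets.columns else triplets["label"]
    counts = strat.value_counts()
    if (counts < k).any():
        bad = counts[counts < k]
        raise SplitError(f"classes with fewer than k={k} members: {dict(bad)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(triplets), dtype=int)
    for fold, (_tr, te) in enumerate(skf.split(np.zeros(len(triplets)), strat)):
        fold_of[te] = fold
    return SplitPlan(mode="warm", seed=seed, fold_of=fold_of, k=k)


def make_cold_split(triplets: pd.DataFrame, drugs: pd.DataFrame,
                    frac_new: float = 0.2, seed: int = 0,
                    test_rule: str = "strict") -> SplitPlan:
    """Drug-disjoint split: sample new drugs, derive train/test triplets.

    Training triplets touch only old drugs.  Test triplets have both drugs
    new (``strict``, default) or at least one new (``one_new``); all other
    triplets are dropped and counted.
    """
    if not 0 < frac_new < 1:
        raise SplitError("frac_new must lie in (0, 1)")
    if test_rule not in ("strict", "one_new"):
        raise SplitError(f"unknown test rule {test_rule!r}")
    ids = sorted(drugs["drug_id"].astype(str))
    n_new = int(round(frac_new * len(ids)))
    if n_new == 0 or n_new == len(ids):
        raise SplitError("frac_new leaves an empty drug set")
    rng = np.random.default_rng(seed)
    new = frozenset(rng.choice(ids, size=n_new, replace=False).tolist())
    old = frozenset(ids) - new

    a_new = triplets["drug_a"].astype(str).isin(new).values
    b_new = triplets["drug_b"].astype(str).isin(new).values
    train_mask = ~a_new & ~b_new
    test_mask = (a_new & b_new) if test_rule == "strict" else (a_new | b_new)
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(test_mask)
    if train_idx.size == 0 or test_idx.size == 0:
        raise SplitError(
            f"empty split: {train_idx.size} train / {test_idx.size} test triplets "
            f"({len(new)} new drugs, rule={test_rule})"
        )
    return SplitPlan(
        mode="cold", seed=seed, new_drugs=new, old_drugs=old,
        train_idx=train_idx, test_idx=test_idx,
        n_dropped=len(triplets) - train_idx.size - test_idx.size,
        cold_test_rule=test_rule,
    )


def sample_negatives(positives: pd.DataFrame, drug_pool, ratio: float = 1.0,
                     seed: int = 0) -> pd.DataFrame:
    """Uniform negative pairs from a drug pool, avoiding known positives.

    Draws ``round(ratio * |positives|)`` unordered pairs without replacement
    from the pool, excluding every positive pair and self-pair, labeled 0.
    For cold-start evaluation call this once per split with that split's own
    drug pool so negatives never bridge the train/test drug sets.
    """
    pool = sorted(str(d) for d in drug_pool)
    if len(pool) < 2:
        raise ValueError("drug pool must contain at least 2 drugs")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    want = int(round(ratio * len(positives)))
    forbidden = {
        tuple(sorted((str(a), str(b))))
        for a, b in zip(positives["drug_a"], positives["drug_b"])
    }
    max_pairs = len(pool) * (len(pool) - 1) // 2
    available = max_pairs - sum(
        1 for p in forbidden if p[0] in set(pool) and p[1] in set(pool)
    )
    if want > available:
        raise ValueError(f"requested {want} negatives but only {available} candidate pairs")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < want:
        i, j = rng.integers(0, len(pool), size=2)
        if i == j:
            continue
        pair = (pool[min(i, j)], pool[max(i, j)])
        if pair in forbidden or pair in chosen:
            continue
        chosen.add(pair)
    rows = [{"drug_a": a, "drug_b": b, "label": 0} for a, b in sorted(chosen)]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# configuration and model assembly
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """All knobs of one training run (published defaults)."""

    epochs: int = 300            # supervised (or joint) epochs
    lr: float = 1e-3
    batch_size: int = 256
    weight_decay: float = 4e-4
    d: int = 64                  # drug embedding dimension
    seed: int = 0

    graph_heads: int = 4
    graph_layers: int = 2
    graph_readout: str = "mean"
    seq_heads: int = 4
    seq_layers: int = 2
    seq_max_len: int = 256
    fusion_heads: int = 1
    d_f: int | None = None

    tau: float = 0.5
    contrastive_mode: str = "pairwise"
    schedule: str = "two_stage"   # two_stage | joint
    lambda_cl: float = 1.0
    cl_epochs: int = 20           # phase-1 length under the two-stage schedule
    freeze_encoders: bool = False

    threshold: float = 0.5
    symmetrize: bool = False
    variant: str = "full"

    def __post_init__(self):
        if self.schedule not in ("two_stage", "joint"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.lambda_cl < 0:
            raise ValueError("lambda_cl must be non-negative")
        for name in ("epochs", "lr", "batch_size", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class DDIModel:
    """Both encoders, the fusion module and the head, wired per variant."""

    def __init__(self, drugs: pd.DataFrame, cfg: TrainConfig,
                 vocab: FeatureVocab | None = None):
        self.cfg = cfg
        self.feature_vocab = vocab or FeatureVocab()
        rng = np.random.default_rng(cfg.seed)
        self.drug_ids = [str(d) for d in drugs["drug_id"]]
        self.index_of = {d: i for i, d in enumerate(self.drug_ids)}

        self.use_graph = cfg.variant != "no_graph_view"
        self.use_seq = cfg.variant != "no_sequence_view"

        self.graph_encoder = None
        self.graph_data: list | None = None
        if self.use_graph:
            gcfg = GraphEncoderConfig(d=cfg.d, heads=cfg.graph_heads,
                                      layers=cfg.graph_layers, readout=cfg.graph_readout)
            self.graph_encoder = GraphEncoder(self.feature_vocab, gcfg, rng)
            self.graph_data = [
                self.graph_encoder.prepare(brics_decompose(parse_smiles(s, i)))
                for i, s in zip(self.drug_ids, drugs["smiles"])
            ]

        self.seq_encoder = None
        self.seq_data: list | None = None
        if self.use_seq:
            smiles_vocab = SmilesVocab.from_corpus(drugs["smiles"])
            scfg = SeqEncoderConfig(d=cfg.d, heads=cfg.seq_heads,
                                    layers=cfg.seq_layers, max_len=cfg.seq_max_len)
            self.seq_encoder = SeqEncoder(smiles_vocab, scfg, rng)
            self.seq_data = [self.seq_encoder.prepare(s) for s in drugs["smiles"]]

        self.fusion = CrossAttentionFusion(
            FusionConfig(d=cfg.d, d_f=cfg.d_f, heads=cfg.fusion_heads), rng
        )
        self.head = PredictionHead(self.fusion.cfg.fused_width, rng)
        self.contrastive_cfg = ContrastiveConfig(tau=cfg.tau, mode=cfg.contrastive_mode)

    # -- parameter groups -----------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        if self.graph_encoder is not None:
            params.update(self.graph_encoder.params)
        if self.seq_encoder is not None:
            params.update(self.seq_encoder.params)
        params.update(self.fusion.params)
        params.update(self.head.params)
        return params

    def encoder_parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        if self.graph_encoder is not None:
            params.update(self.graph_encoder.params)
        if self.seq_encoder is not None:
            params.update(self.seq_encoder.params)
        return params

    def no_decay_names(self) -> set[str]:
        return {
            name for name in self.parameters()
            if name.endswith((".b", ".g", ".b1", ".b2")) or "emb" in name
            or name.startswith("head.b")
        }

    # -- forward passes -------------------------------------------------------

    def encode(self, drug_idx: np.ndarray) -> tuple[Tensor | None, Tensor | None]:
        """View embeddings (z, h) for the given drug indices; None if disabled."""
        z = h = None
        if self.use_graph:
            z = self.graph_encoder.encode_batch([self.graph_data[i] for i in drug_idx])
        if self.use_seq:
            h = self.seq_encoder.encode_batch([self.seq_data[i] for i in drug_idx])
        return z, h

    def fuse(self, z: Tensor | None, h: Tensor | None) -> Tensor:
        """Cross-attention fusion; single-view variants project that view."""
        if z is not None and h is not None:
            return self.fusion.fuse(z, h)
        only = z if z is not None else h
        return only @ self.fusion.params["fuse.Wp"]

    def score_pairs(self, idx_a: np.ndarray, idx_b: np.ndarray,
                    return_views: bool = False):
        """Interaction probabilities for index-aligned drug pairs.

        Each distinct drug in the batch is encoded once; pair rows are gathered
        from the shared embedding matrix, so gradients accumulate correctly
        across pairs that share a drug.
        """
        unique, inverse = np.unique(np.concatenate([idx_a, idx_b]), return_inverse=True)
        pos_a, pos_b = inverse[: idx_a.size], inverse[idx_a.size:]
        z, h = self.encode(unique)
        fused = self.fuse(z, h)
        y_hat = self.head.predict(fused[pos_a], fused[pos_b])
        if self.cfg.symmetrize:
            y_hat = (y_hat + self.head.predict(fused[pos_b], fused[pos_a])) * 0.5
        if return_views:
            return y_hat, z, h
        return y_hat


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: DDIModel
    history: list[dict]
    report: MetricsReport
    best_val_auroc: float
    config: TrainConfig


def _triplet_arrays(model: DDIModel, triplets: pd.DataFrame,
                    idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = triplets.iloc[idx]
    a = np.array([model.index_of[str(d)] for d in sub["drug_a"]])
    b = np.array([model.index_of[str(d)] for d in sub["drug_b"]])
    y = sub["label"].to_numpy().astype(float)
    return a, b, y


def _evaluate_scores(model: DDIModel, a: np.ndarray, b: np.ndarray,
                     batch: int = 512) -> np.ndarray:
    scores = []
    for lo in range(0, a.size, batch):
        scores.append(model.score_pairs(a[lo:lo + batch], b[lo:lo + batch]).data)
    return np.concatenate(scores)


def _resolve_round(split: SplitPlan, fold: int,
                   seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if split.mode == "warm":
        return split.warm_round(fold)
    # cold: carve a validation subset out of the training triplets
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(split.train_idx)
    n_val = max(1, int(0.1 * perm.size))
    return perm[n_val:], perm[:n_val], split.test_idx


def train_model(drugs: pd.DataFrame, triplets: pd.DataFrame, split: SplitPlan,
                cfg: TrainConfig, fold: int = 0,
                verbose: bool = False) -> TrainResult:
    """Train one model on one split round and evaluate it on the test set.

    Deterministic given (config seed, split, single-threaded math).  Divergence
    (a non-finite loss) aborts with epoch/batch context.  The checkpoint with
    the best validation AUROC is restored before the test evaluation.
    """
    triplets = canonical_pairs(triplets)
    model = DDIModel(drugs, cfg)
    train_idx, val_idx, test_idx = _resolve_round(split, fold, cfg.seed)
    if train_idx.size == 0 or test_idx.size == 0:
        raise SplitError("empty train or test set")
    tr_a, tr_b, tr_y = _triplet_arrays(model, triplets, train_idx)
    va_a, va_b, va_y = _triplet_arrays(model, triplets, val_idx)
    te_a, te_b, te_y = _triplet_arrays(model, triplets, test_idx)

    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    history: list[dict] = []

    # ---- phase 1: contrastive alignment (two-stage schedule, full model only)
    both_views = model.use_graph and model.use_seq
    if cfg.schedule == "two_stage" and both_views and cfg.cl_epochs > 0:
        optimizer = AdamW(model.encoder_parameters(), lr=cfg.lr,
                          weight_decay=cfg.weight_decay,
                          no_decay=model.no_decay_names())
        train_drugs = np.unique(np.concatenate([tr_a, tr_b]))
        for epoch in range(cfg.cl_epochs):
            perm = rng.permutation(train_drugs)
            losses = []
            for lo in range(0, perm.size, cfg.batch_size):
                batch = perm[lo:lo + cfg.batch_size]
                if batch.size < 2:
                    continue
                z, h = model.encode(batch)
                loss = total_objective(
                    None, contrastive_loss_batch(z, h, model.contrastive_cfg),
                    phase="contrastive",
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite contrastive loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            history.append({"phase": "contrastive", "epoch": epoch,
                            "loss": float(np.mean(losses))})
            if verbose:
                print(f"[cl] epoch {epoch}: loss={np.mean(losses):.4f}")

    # ---- phase 2: supervised (or joint) training on pairs
    if cfg.schedule == "two_stage" and cfg.freeze_encoders:
        trainable = {**model.fusion.params, **model.head.params}
    else:
        trainable = params
    optimizer = AdamW(trainable, lr=cfg.lr, weight_decay=cfg.weight_decay,
                      no_decay=model.no_decay_names())
    joint = cfg.schedule == "joint" and both_views and cfg.lambda_cl > 0

    best_val = -np.inf
    best_state: dict[str, np.ndarray] | None = None
    order = np.arange(tr_y.size)
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        losses = []
        for lo in range(0, order.size, cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            y_hat, z, h = model.score_pairs(tr_a[sel], tr_b[sel], return_views=True)
            bce = bce_loss(y_hat, tr_y[sel])
            if joint and z.shape[0] >= 2:
                cl = contrastive_loss_batch(z, h, model.contrastive_cfg)
                loss = total_objective(bce, cl, phase="joint", lambda_cl=cfg.lambda_cl)
            else:
                loss = total_objective(bce, None, phase="supervised")
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        record = {"phase": "supervised", "epoch": epoch, "loss": float(np.mean(losses))}
        if va_y.size >= 2 and len(np.unique(va_y)) == 2:
            val_scores = _evaluate_scores(model, va_a, va_b)
            record["val_auroc"] = auroc(va_y.astype(int), val_scores)
            if record["val_auroc"] > best_val:
                best_val = record["val_auroc"]
                best_state = {k: p.data.copy() for k, p in params.items()}
        history.append(record)
        if verbose:
            print(f"[sup] epoch {epoch}: loss={record['loss']:.4f} "
                  f"val_auroc={record.get('val_auroc', float('nan')):.4f}")

    if best_state is not None:
        for name, value in best_state.items():
            params[name].data = value

    test_scores = _evaluate_scores(model, te_a, te_b)
    report = compute_metrics(te_y.astype(int), test_scores, threshold=cfg.threshold)
    return TrainResult(model=model, history=history, report=report,
                       best_val_auroc=float(best_val), config=cfg)


def save_checkpoint(model: DDIModel, drugs: pd.DataFrame, path) -> None:
    """Archive all parameter groups, vocabularies, drug table and config.

    Everything needed to rebuild the model and score new pairs is stored, so
    tokenization and featurization are stable across save/load.
    """
    import json

    meta = {
        "config": asdict(model.cfg),
        "drug_ids": model.drug_ids,
        "smiles": [str(s) for s in drugs["smiles"]],
        "feature_vocab": model.feature_vocab.to_json(),
        "seq_vocab": model.seq_encoder.vocab.to_list() if model.seq_encoder else None,
    }
    arrays = {f"param:{k}": p.data for k, p in model.parameters().items()}
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path) -> tuple[DDIModel, pd.DataFrame]:
    """Rebuild a model (and its drug table) from a checkpoint archive."""
    import json

    from .molgraph import FeatureVocab as _FeatureVocab

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"].tobytes()).decode())
        weights = {k.removeprefix("param:"): archive[k]
                   for k in archive.files if k.startswith("param:")}
    drugs = pd.DataFrame({"drug_id": meta["drug_ids"], "smiles": meta["smiles"]})
    cfg = TrainConfig(**meta["config"])
    model = DDIModel(drugs, cfg, vocab=_FeatureVocab.from_json(meta["feature_vocab"]))
    if model.seq_encoder is not None:
        from .seq_encoder import SmilesVocab

        model.seq_encoder.vocab = SmilesVocab.from_list(meta["seq_vocab"])
        model.seq_data = [model.seq_encoder.prepare(s) for s in drugs["smiles"]]
    params = model.parameters()
    for name, value in weights.items():
        params[name].data = value
    return model, drugs


def run_ablation(variant: str, drugs: pd.DataFrame, triplets: pd.DataFrame,
                 split: SplitPlan, cfg: TrainConfig, fold: int = 0) -> TrainResult:
    """Train one model variant on a shared split.

    ``no_graph_view`` drops the pharmacophore encoder (the sequence view is
    projected to the fused width; the contrastive term vanishes since only one
    view exists); ``no_sequence_view`` is symmetric; ``full`` is the complete
    model.  Everything else — split, negatives, hyperparameters — is identical.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return train_model(drugs, triplets, split, replace(cfg, variant=variant), fold=fold)
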