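"""Evaluation metrics and statistical model comparison.

Binary classification metrics follow the usual confusion-matrix definitions
(recall = TP/(TP+FN), accuracy = (TP+TN)/total, precision = TP/(TP+FP),
F1 = 2PR/(P+R)) with predictions thresholded at score >= threshold.  AUROC is
the rank (Mann-Whitney) formulation — the probability that a random positive
outscores a random negative with ties credited half — and AUPRC is the
step-wise integral of the precision-recall curve without interpolation; both
delegate to scikit-learn, whose implementations compute exactly these
quantities.

Model comparison across repeated runs uses a Kruskal-Wallis omnibus test
(tie-corrected); if significant, all pairwise Mann-Whitney U tests are
performed (exact for small tie-free samples, normal approximation with tie
and continuity correction otherwise) and adjusted by the Holm-Bonferroni
step-down procedure with monotonicity enforcement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests


class MetricError(ValueError):
    """Raised for undefined metrics (e.g. single-class AUROC) or bad inputs."""


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics for one evaluation."""

    tp: int
    fn: int
    fp: int
    tn: int
    recall: float
    accuracy: float
    precision: float
    f1: float
    auroc: float
    auprc: float
    threshold: float
    zero_denominator_flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return asdict(self)


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1 or labels.size == 0:
        raise MetricError(
            f"labels and scores must be equal-length 1-D, got {labels.shape} vs {scores.shape}"
        )
    return labels.astype(int), scores


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report at a decision threshold (score >= threshold -> 1).

    Metrics with a zero denominator are reported as 0 and flagged rather than
    returned as NaN.
    """
    labels, scores = _validate(labels, scores)
    predicted = scores >= threshold
    actual = labels == 1
    tp = int(np.sum(predicted & actual))
    fn = int(np.sum(~predicted & actual))
    fp = int(np.sum(predicted & ~actual))
    tn = int(np.sum(~predicted & ~actual))

    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    accuracy = (tp + tn) / labels.size
    if precision + recall == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)

    if len(np.unique(labels)) < 2:
        raise MetricError("AUROC/AUPRC undefined: only one class present")
    return MetricsReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        recall=recall, accuracy=accuracy, precision=precision, f1=f1,
        auroc=auroc(labels, scores), auprc=auprc(labels, scores),
        threshold=threshold, zero_denominator_flags=flags,
    )


def auroc(labels, scores) -> float:
    """Probability that a random positive outscores a random negative (ties 0.5)."""
    labels, scores = _validate(labels, scores)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve by step-wise integration."""
    labels, scores = _validate(labels, scores)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUPRC undefined: only one class present")
    return float(average_precision_score(labels, scores))


@dataclass
class StatCompareResult:
    h_statistic: float
    omnibus_p: float
    alpha: float
    significant: bool
    pairs: list[tuple[str, str]]
    raw_p: list[float]
    adjusted_p: list[float]

    def to_dict(self) -> dict:
        return asdict(self)


def stat_compare(samples: dict[str, list[float]], alpha: float = 0.05) -> StatCompareResult:
    """Kruskal-Wallis omnibus + Holm-adjusted pairwise Mann-Whitney U tests.

    ``samples`` maps a model name to its metric values across runs (>= 2 each).
    Pairwise tests are only performed when the omnibus test is significant at
    ``alpha``.
    """
    if len(samples) < 2 or any(len(v) < 2 for v in samples.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate ranks: all observations identical across groups")
    h_stat, omnibus_p = stats.kruskal(*groups.values())

    significant = bool(omnibus_p < alpha)
    pairs: list[tuple[str, str]] = []
    raw_p: list[float] = []
    adjusted: list[float] = []
    if significant:
        for name_a, name_b in combinations(groups, 2):
            _u, p = stats.mannwhitneyu(
                groups[name_a], groups[name_b], alternative="two-sided", method="auto"
            )
            pairs.append((name_a, name_b))
            raw_p.append(float(p))
        adjusted = list(multipletests(raw_p, method="holm")[1]) if raw_p else []
    return StatCompareResult(
        h_statistic=float(h_stat), omnibus_p=float(omnibus_p), alpha=alpha,
        significant=significant, pairs=pairs, raw_p=raw_p,
        adjusted_p=[float(p) for p in adjusted],
    )
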