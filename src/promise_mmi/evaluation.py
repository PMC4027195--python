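"""Benchmarking of interaction rankings and sample classifiers.

Interaction scores (signature probabilities, seed counts, correlations, ...)
are turned into a total deterministic ordering and assessed against labeled
target sets with ROC / precision-recall curves, validated-target counts in
the top K, and a Pearson-correlation baseline. The mean cross-entropy used
to score tumor/normal classifiers is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .preprocess import ExpressionMatrix
from .seedmatch import SeedMatchMatrix

__all__ = [
    "RankedInteractions",
    "LabelSet",
    "rank_matrix",
    "roc_curve",
    "auroc",
    "pr_curve",
    "aupr",
    "count_validated_topk",
    "pearson_baseline",
    "mean_cross_entropy",
]

DEFAULT_TOPK_GRID = (500, 1000, 1500, 2000)


@dataclass
class RankedInteractions:
    """A total ordering of (gene, miRNA, score) triples.

    Sorted by descending score; ties are broken by (gene, miRNA)
    lexicographically, so the ordering is deterministic.
    """

    items: list[tuple[str, str, float]] = field(repr=False)

    def __post_init__(self) -> None:
        for g, m, s in self.items:
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for ({g}, {m})")
        self.items = sorted(self.items, key=lambda t: (-t[2], t[0], t[1]))

    def __len__(self) -> int:
        return len(self.items)

    def pairs(self) -> list[tuple[str, str]]:
        return [(g, m) for g, m, _ in self.items]

    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.items])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.items, columns=["gene", "mirna", "score"])


@dataclass
class LabelSet:
    """Disjoint positive and negative (gene, miRNA) pair sets."""

    positives: set
    negatives: set

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"labels overlap: {sorted(overlap)[:3]} ...")


def rank_matrix(scores: np.ndarray, genes: list[str], mirnas: list[str],
                mask: np.ndarray | None = None) -> RankedInteractions:
    """Rank every (optionally masked) entry of a score matrix."""
    scores = np.asarray(scores, dtype=float)
    if mask is None:
        mask = np.ones_like(scores, dtype=bool)
    rows, cols = np.nonzero(mask)
    return RankedInteractions(
        [(genes[i], mirnas[k], float(scores[i, k])) for i, k in zip(rows, cols)]
    )


def _labeled_scores(ranked: RankedInteractions, labels: LabelSet):
    y, s = [], []
    for g, m, score in ranked.items:
        if (g, m) in labels.positives:
            y.append(1)
            s.append(score)
        elif (g, m) in labels.negatives:
            y.append(0)
            s.append(score)
    return np.array(y), np.array(s)


def roc_curve(ranked: RankedInteractions, labels: LabelSet):
    """(fpr, tpr, thresholds) over labeled items, by descending-score sweep."""
    y, s = _labeled_scores(ranked, labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative labeled item")
    fpr, tpr, thr = _skm.roc_curve(y, s)
    return fpr, tpr, thr


def auroc(ranked: RankedInteractions, labels: LabelSet) -> float:
    """Area under the ROC curve; equals the Mann-Whitney statistic
    (probability a random positive outscores a random negative, ties 1/2)."""
    y, s = _labeled_scores(ranked, labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative labeled item")
    return float(_skm.roc_auc_score(y, s))


def pr_curve(ranked: RankedInteractions, labels: LabelSet):
    """Precision-recall points from a descending-score sweep, ties grouped.

    Returns (recall, precision, thresholds): one point per distinct score,
    recorded after all items at that score enter the prediction set.
    """
    y, s = _labeled_scores(ranked, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive labeled item")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    tp = np.cumsum(y)
    n_pred = np.arange(1, len(y) + 1)
    # keep only the last index of each tied-score group
    last = np.r_[s[1:] != s[:-1], True]
    recall = tp[last] / n_pos
    precision = tp[last] / n_pred[last]
    return recall, precision, s[last]


def aupr(ranked: RankedInteractions, labels: LabelSet) -> float:
    """Area under the precision-recall curve, trapezoid over recall.

    Anchored at (recall 0, first swept precision) so a ranking whose top
    block is all positive scores 1 over the covered recall range.
    """
    recall, precision, _ = pr_curve(ranked, labels)
    r = np.r_[0.0, recall]
    p = np.r_[precision[0], precision]
    return float(np.trapezoid(p, r))


def count_validated_topk(ranked: RankedInteractions, validated: set,
                         K: int) -> int:
    """Number of externally validated pairs within the top-K ranking."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return sum(1 for pair in ranked.pairs()[:K] if pair in validated)


def pearson_baseline(mrna: ExpressionMatrix, mirna: ExpressionMatrix,
                     C: SeedMatchMatrix) -> RankedInteractions:
    """Across-sample Pearson correlation baseline over seed-matched pairs.

    The most negative correlations rank first (targets are expected to be
    anti-correlated with their miRNA), so the returned score is ``-r``.
    Pairs whose correlation is undefined (zero variance) are ranked after
    every defined pair, carrying score -2 as a flag (|score| of defined
    pairs is <= 1).
    """
    samples = [s for s in mrna.sample_ids if s in set(mirna.sample_ids)]
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples for correlations")
    genes = [g for g in C.genes if g in set(mrna.feature_ids)]
    mirnas = [m for m in C.mirnas if m in set(mirna.feature_ids)]
    C_sub = C.subset(genes, mirnas)
    X = mrna.to_frame().loc[genes, samples].to_numpy(float)
    Z = mirna.to_frame().loc[mirnas, samples].to_numpy(float)

    Xc = X - X.mean(axis=1, keepdims=True)
    Zc = Z - Z.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc ** 2).sum(axis=1))
    zn = np.sqrt((Zc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Zc.T) / np.outer(xn, zn)

    items = []
    rows, cols = np.nonzero(C_sub.counts > 0)
    for i, k in zip(rows, cols):
        rv = r[i, k]
        score = -float(rv) if np.isfinite(rv) else -2.0
        items.append((genes[i], mirnas[k], score))
    return RankedInteractions(items)


def mean_cross_entropy(t: np.ndarray, p: np.ndarray,
                       clamp: float | None = None,
                       full: bool = False) -> float:
    """Mean cross-entropy of predicted tumor probabilities.

    MCE = (1/N) sum_n -t_n * ln(p_n) with t_n in {0, 1}: only tumor samples
    (t_n = 1) contribute loss, penalizing low predicted tumor probability.
    With ``full=True`` the symmetric term -(1 - t_n) * ln(1 - p_n) is added,
    giving the usual binary cross-entropy that also penalizes confident
    false alarms on normal samples. ``clamp`` bounds probabilities away
    from {0, 1} before taking logs; without it a zero probability on a
    tumor sample is an error (infinite loss).
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.shape != p.shape:
        raise ValueError("t and p must have the same length")
    if np.any((t != 0) & (t != 1)):
        raise ValueError("labels must be binary")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if clamp is not None:
        p = np.clip(p, clamp, 1 - clamp)
    loss = np.zeros_like(p)
    pos = t == 1
    if np.any(p[pos] == 0):
        raise ValueError("p=0 with t=1 gives infinite loss; pass clamp=")
    loss[pos] = -np.log(p[pos])
    if full:
        neg = t == 0
        if np.any(p[neg] == 1):
            raise ValueError("p=1 with t=0 gives infinite loss; pass clamp=")
        loss[neg] = -np.log(1 - p[neg])
    return float(loss.mean())
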