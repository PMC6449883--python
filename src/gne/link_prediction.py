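"""Interaction prediction from embeddings.

An unordered gene pair (i, j) is represented by the Hadamard (elementwise)
product y_i * y_j of the two gene embeddings — symmetric by construction —
and an L2-regularized logistic classifier is trained to separate observed
interactions from sampled non-edges. Ranking quality is summarized by AUROC
and AUPR (average precision); a probability-binned audit reports, per bin,
how many scored pairs are confirmed in a reference network and how many
interaction partners the two genes share there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph_io import (
    EdgeSplit,
    GeneNetwork,
    ExpressionMatrix,
    Pair,
    sample_negative_pairs,
)
from .model import GeneEmbeddings

logger = logging.getLogger(__name__)

DEFAULT_AUDIT_BINS = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]


@dataclass
class EdgeFeatureSet:
    pairs: list[Pair]
    X: np.ndarray
    labels: np.ndarray | None = None


@dataclass
class EvalReport:
    """Link-prediction evaluation summary."""

    auroc: float
    aupr: float
    pairs: list[Pair]
    labels: np.ndarray
    probabilities: np.ndarray
    bin_table: pd.DataFrame


def edge_features(
    emb: GeneEmbeddings | np.ndarray, pairs: Sequence[Pair],
    labels: np.ndarray | None = None,
) -> EdgeFeatureSet:
    """Hadamard edge features: row for (i, j) is y_i * y_j."""
    Y = emb.Y if isinstance(emb, GeneEmbeddings) else np.asarray(emb, dtype=float)
    pairs = [tuple(p) for p in pairs]
    if pairs:
        idx = np.asarray(pairs, dtype=np.int64)
        if idx.min() < 0 or idx.max() >= Y.shape[0]:
            raise IndexError("pair index out of range for embedding matrix")
        X = Y[idx[:, 0]] * Y[idx[:, 1]]
    else:
        X = np.zeros((0, Y.shape[1]))
    return EdgeFeatureSet(pairs=pairs, X=X, labels=labels)


def fit_logistic(features: EdgeFeatureSet) -> LogisticRegression:
    """L2-regularized logistic regression on labelled edge features."""
    if features.labels is None:
        raise ValueError("features must carry labels")
    labels = np.asarray(features.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both positive and negative examples")
    clf = LogisticRegression(C=1.0, tol=1e-6, max_iter=5000, solver="lbfgs")
    clf.fit(features.X, labels)
    return clf


def predict_proba(clf: LogisticRegression, features: EdgeFeatureSet) -> np.ndarray:
    """Interaction probability sigma(w.x + b) per pair, in (0, 1)."""
    if features.X.shape[1] != clf.coef_.shape[1]:
        raise ValueError("feature width does not match classifier")
    return clf.predict_proba(features.X)[:, 1]


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney with midrank tie handling)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve as average precision."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR undefined with a single class")
    return float(average_precision_score(labels, scores))


def shared_neighbor_counts(
    net: GeneNetwork, pairs: Sequence[Pair]
) -> np.ndarray:
    """|N_i intersect N_j| in ``net`` for each pair."""
    adj = net.adjacency()
    return np.array([(adj[i] & adj[j]).sum() for i, j in pairs], dtype=np.int64)


def bin_audit(
    pairs: Sequence[Pair],
    probabilities: np.ndarray,
    reference: GeneNetwork,
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Audit predictions by probability bin against a reference network.

    ``bins`` are interval edges; pairs land in the right-closed interval
    (bins[k], bins[k+1]]. Per bin the table reports the pair count, the
    fraction of pairs confirmed as edges of ``reference``, and the mean
    number of interaction partners the two genes share in ``reference``.
    Pair indices must refer to ``reference``'s gene ordering.
    """
    if bins is None:
        bins = DEFAULT_AUDIT_BINS
    bins = list(bins)
    probabilities = np.asarray(probabilities, dtype=float)
    confirmed = np.array([tuple(sorted(p)) in reference.edges for p in pairs])
    shared = shared_neighbor_counts(reference, pairs) if len(pairs) else np.zeros(0)
    which = np.digitize(probabilities, bins[1:-1], right=True) if len(pairs) else np.zeros(0)
    in_range = (probabilities > bins[0]) & (probabilities <= bins[-1]) if len(pairs) else np.zeros(0, bool)
    rows = []
    for k in range(len(bins) - 1):
        mask = in_range & (which == k)
        count = int(mask.sum())
        rows.append(
            {
                "bin_low": bins[k],
                "bin_high": bins[k + 1],
                "count": count,
                "frac_confirmed": float(confirmed[mask].mean()) if count else np.nan,
                "mean_shared_neighbors": float(shared[mask].mean()) if count else np.nan,
            }
        )
    return pd.DataFrame(rows)


def evaluate(
    emb: GeneEmbeddings,
    net: GeneNetwork,
    split: EdgeSplit,
    seed: int = 0,
    bins: Sequence[float] | None = None,
    extra_exclude: Sequence[Pair] = (),
    return_classifier: bool = False,
):
    """Full link-prediction evaluation on a held-out edge split.

    A logistic classifier is fitted on the split's training edges plus an
    equal number of freshly sampled non-edges (excluded from every positive
    edge, from the split's negatives, and from ``extra_exclude``), then
    scored on test positives and negatives. The audit bins default to the
    ten deciles of (0, 1] so counts sum to the number of scored pairs.
    """
    if not split.test_pos or not split.test_neg:
        raise ValueError("empty test set")
    exclude = set(split.val_neg) | set(split.test_neg) | {tuple(sorted(p)) for p in extra_exclude}
    train_neg = sample_negative_pairs(net, len(split.train_pos), exclude=exclude, seed=seed)
    train_pairs = list(split.train_pos) + train_neg
    train_labels = np.r_[np.ones(len(split.train_pos)), np.zeros(len(train_neg))]
    clf = fit_logistic(edge_features(emb, train_pairs, train_labels))
    test_pairs = list(split.test_pos) + list(split.test_neg)
    labels = np.r_[np.ones(len(split.test_pos)), np.zeros(len(split.test_neg))]
    probs = predict_proba(clf, edge_features(emb, test_pairs))
    if bins is None:
        bins = list(np.linspace(0.0, 1.0, 11))
    report = EvalReport(
        auroc=auroc(probs, labels),
        aupr=aupr(probs, labels),
        pairs=test_pairs,
        labels=labels,
        probabilities=probs,
        bin_table=bin_audit(test_pairs, probs, net, bins=bins),
    )
    if return_classifier:
        return report, clf
    return report


def pearson_baseline(expr: ExpressionMatrix, pairs: Sequence[Pair]) -> np.ndarray:
    """Signed Pearson correlation r(x_i, x_j) per pair; constant rows score 0."""
    v = expr.values
    mean = v.mean(axis=1, keepdims=True)
    centered = v - mean
    norm = np.linalg.norm(centered, axis=1)
    degenerate = norm == 0
    if degenerate.any():
        logger.info("pearson_baseline: %d constant expression rows score 0", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, norm)
    unit = centered / safe[:, None]
    unit[degenerate] = 0.0
    out = np.array([float(unit[i] @ unit[j]) for i, j in pairs])
    return np.clip(out, -1.0, 1.0)


def ranked_predictions(
    genes: Sequence[str], pairs: Sequence[Pair], probabilities: np.ndarray,
    threshold: float | None = None,
) -> pd.DataFrame:
    """(gene_i, gene_j, probability) table sorted by descending probability.

    With ``threshold`` set, keeps only pairs at or above it (the candidate
    novel-interaction export uses 0.5).
    """
    df = pd.DataFrame(
        {
            "gene_i": [genes[i] for i, _ in pairs],
            "gene_j": [genes[j] for _, j in pairs],
            "probability": np.asarray(probabilities, dtype=float),
        }
    )
    if threshold is not None:
        df = df[df["probability"] >= threshold]
    return df.sort_values("probability", ascending=False, kind="mergesort").reset_index(drop=True)
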