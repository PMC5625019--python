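"""Gold standards, network averaging/completion, and ROC/AUC scoring.

The averaged gold standard scores a TF pair by its mean weight over all
cell-type networks where the pair is observed; binarizing at a threshold
yields evaluation labels. Averaged integrative networks (AI-Nets) apply the
same rule within one lineage and also serve to fill missing entries of
individual cell-type networks. AUC is computed as the Mann-Whitney
concordance probability of the score ranking (ties count 1/2), which the
trapezoidal integral of the ROC curve must reproduce exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .containers import GoldStandard, WeightedNetwork

__all__ = [
    "build_gold_standard_avg",
    "ai_net",
    "complete_ct_net",
    "binarize_gold",
    "roc_auc",
    "auc_network_vs_labels",
]


def _masked_mean(networks: list[WeightedNetwork]) -> tuple[np.ndarray, np.ndarray]:
    nodes = networks[0].nodes
    for net in networks[1:]:
        if net.nodes != nodes:
            raise ValueError("networks must share one node ordering")
    w = np.stack([net.weights for net in networks])
    m = np.stack([net.mask for net in networks])
    counts = m.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, (w * m).sum(axis=0) / np.maximum(counts, 1), 0.0)
    return mean, counts > 0


def build_gold_standard_avg(
    networks: list[WeightedNetwork], threshold: float = 0.8
) -> GoldStandard:
    """Per-pair mean over all networks where the pair is observed.

    Pairs observed nowhere stay masked and are excluded from evaluation.
    """
    if not networks:
        raise ValueError("need at least one network")
    mean, mask = _masked_mean(networks)
    return GoldStandard(
        weights=mean, mask=mask, nodes=list(networks[0].nodes), threshold=threshold
    )


def ai_net(lineage_networks: list[WeightedNetwork]) -> WeightedNetwork:
    """Averaged integrative network: per-pair mean of existing edges across
    one lineage's cell-type networks."""
    if not lineage_networks:
        raise ValueError("need at least one cell-type network")
    mean, mask = _masked_mean(lineage_networks)
    return WeightedNetwork(lineage_networks[0].nodes, mean, mask)


def complete_ct_net(
    ct_net: WeightedNetwork, ai: WeightedNetwork
) -> WeightedNetwork:
    """Fill a cell-type network's missing entries from its lineage AI-Net.

    Entries masked in the cell-type network take the AI-Net's value where
    that is observed; entries masked in both remain masked.
    """
    if ct_net.nodes != ai.nodes:
        raise ValueError("networks must share one node ordering")
    fill = ~ct_net.mask & ai.mask
    weights = np.where(fill, ai.weights, ct_net.weights)
    mask = ct_net.mask | ai.mask
    return WeightedNetwork(ct_net.nodes, weights, mask)


def binarize_gold(
    gold: GoldStandard, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary labels over observed upper-triangle pairs.

    A pair is positive when its gold weight is >= the threshold (boundary
    inclusive). Returns (i indices, j indices, labels).
    """
    t = gold.threshold if threshold is None else threshold
    iu, ju = np.triu_indices(len(gold.nodes), k=1)
    keep = gold.mask[iu, ju]
    iu, ju = iu[keep], ju[keep]
    labels = (gold.weights[iu, ju] >= t).astype(int)
    return iu, ju, labels


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points and AUC from per-pair scores and binary labels.

    AUC is the Mann-Whitney concordance probability — the chance a random
    positive outscores a random negative, ties counting 1/2 — computed from
    mid-ranks. ROC points are (FPR, TPR) at every distinct score, scores
    descending, with (0, 0) and (1, 1) endpoints.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an ROC")

    ranks = rankdata(scores)  # mid-ranks for ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # keep only the last index of each tied score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fp[distinct] / n_neg, 1.0]
    points = np.column_stack([fpr, tpr])
    return points, float(auc)


def auc_network_vs_labels(
    net: WeightedNetwork, gold: GoldStandard, threshold: float | None = None
) -> float:
    """AUC of a predicted network against a binarized gold standard.

    Evaluation is restricted to pairs observed in *both* the gold standard
    and the prediction; predicted-but-unassessable pairs are simply
    excluded, never counted as errors.
    """
    if net.nodes != gold.nodes:
        raise ValueError("prediction and gold standard must share node order")
    iu, ju, labels = binarize_gold(gold, threshold)
    keep = net.mask[iu, ju]
    _, auc = roc_auc(net.weights[iu[keep], ju[keep]], labels[keep])
    return auc
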