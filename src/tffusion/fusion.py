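"""Fusing CP factors into one TF network and calling interactions.

The third tensor mode indexes evidence networks (slices). Each rank-one
component contributes a TF x TF interaction pattern (the outer product of
its two TF-mode columns) weighted by the mean of its network-mode column;
the fused network is the weighted sum of these patterns, symmetrized and
min-max scaled to [0, 1]. Before scaling, this fusion is algebraically
identical to the slice-mean of the reconstructed tensor — it is the unique
linear fusion that reduces to plain network averaging when the
factorization is exact.

Downstream calling: per-TF outlier edges (above Q3 + alpha * IQR of the
TF's incident weights) are "strong"; the top fraction of TFs by strong-edge
degree are hubs; strong edges are classified across lineages as
lineage-specific, shared, or housekeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bcpf import CPModelState, reconstruct
from .containers import WeightedNetwork

__all__ = [
    "StrongEdgeConfig",
    "EdgeClassification",
    "fuse_network_mode",
    "strong_interactions",
    "hub_tfs",
    "classify_edges",
    "degree_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class StrongEdgeConfig:
    """Thresholds for strong-interaction and hub calling.

    ``alpha`` multiplies the IQR above the 75th percentile; ``hub_fraction``
    is the top fraction of TFs (by strong degree) called hubs.
    """

    alpha: float = 1.5
    hub_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValueError("hub_fraction must lie in (0, 1)")


@dataclass
class EdgeClassification:
    """Cross-lineage classification of strong edges."""

    labels: dict[tuple[str, str], str]  # "specific:<lineage>" | "shared" | "housekeeping"
    provenance: dict[tuple[str, str], frozenset[str]]
    lineages: list[str]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def per_lineage_summary(self) -> dict[str, dict[str, float]]:
        """Per lineage: total strong edges there, how many are specific to it,
        and the specific fraction."""
        summary: dict[str, dict[str, float]] = {}
        for lin in self.lineages:
            total = sum(1 for prov in self.provenance.values() if lin in prov)
            specific = sum(
                1 for lab in self.labels.values() if lab == f"specific:{lin}"
            )
            summary[lin] = {
                "strong_edges": total,
                "specific": specific,
                "specific_fraction": specific / total if total else 0.0,
            }
        return summary


def fuse_network_mode(
    state: CPModelState, network_mode: int = 2, normalize: bool = True
) -> WeightedNetwork:
    """Fuse the factorization into one weighted TF interaction network.

    Component weight ``w_r`` is the mean of the network-mode factor column
    ``r``; the fused matrix ``sum_r w_r a_r b_r^T`` equals the mean over
    network slices of the reconstructed tensor, then is symmetrized and
    (optionally) min-max normalized to [0, 1] with the diagonal excluded.
    """
    if network_mode not in (0, 1, 2):
        raise ValueError(f"network_mode must be 0, 1 or 2, got {network_mode}")
    tf_modes = [n for n in range(3) if n != network_mode]
    a, b = (state.factor_means[n] for n in tf_modes)
    w = state.factor_means[network_mode].mean(axis=0)
    fused = np.einsum("r,ir,jr->ij", w, a, b)
    fused = (fused + fused.T) / 2.0
    if normalize:
        off = ~np.eye(fused.shape[0], dtype=bool)
        lo, hi = fused[off].min(), fused[off].max()
        fused = (fused - lo) / (hi - lo) if hi > lo else np.zeros_like(fused)
    nodes = [f"TF{i:03d}" for i in range(fused.shape[0])]
    return WeightedNetwork(nodes, fused)


def slice_mean_network(state: CPModelState, network_mode: int = 2) -> np.ndarray:
    """Mean over network slices of the reconstructed tensor (un-normalized,
    un-symmetrized); fuse_network_mode must match this before normalization."""
    return reconstruct(state).mean(axis=network_mode)


def strong_interactions(
    net: WeightedNetwork, config: StrongEdgeConfig | None = None
) -> list[tuple[str, str, float]]:
    """Per-TF outlier edges: weight strictly above Q3 + alpha * IQR.

    For each TF, Q3 and IQR are taken over its observed incident edge
    weights (linear-interpolation quartiles). An edge is returned when it is
    strong for *either* endpoint. TFs with fewer than 4 observed incident
    edges contribute none (logged). Edges are returned as (tf_a, tf_b,
    weight) with tf_a before tf_b in node order.
    """
    if config is None:
        config = StrongEdgeConfig()
    n = net.n_nodes
    strong: set[tuple[int, int]] = set()
    for i in range(n):
        incident = np.nonzero(net.mask[i])[0]
        if incident.size < 4:
            logger.info(
                "TF %s has %d observed edges (<4); contributes no strong edges",
                net.nodes[i],
                incident.size,
            )
            continue
        w = net.weights[i, incident]
        q1, q3 = np.percentile(w, [25, 75])
        threshold = q3 + config.alpha * (q3 - q1)
        for j in incident[w > threshold]:
            strong.add((min(i, j), max(i, j)))
    return sorted(
        (net.nodes[i], net.nodes[j], float(net.weights[i, j]))
        for i, j in strong
    )


def hub_tfs(
    strong_net: list[tuple[str, str, float]],
    config: StrongEdgeConfig | None = None,
) -> list[str]:
    """Top-fraction TFs by strong-edge degree (ceiling count, ties kept).

    Degree counts strong edges incident to the TF; the hub count is
    ``ceil(hub_fraction * n_active)`` over TFs with degree > 0, and TFs tied
    with the last included degree are all kept.
    """
    if config is None:
        config = StrongEdgeConfig()
    degree: dict[str, int] = {}
    for a, b, _ in strong_net:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    if not degree:
        return []
    n_hubs = int(np.ceil(config.hub_fraction * len(degree)))
    ordered = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ordered[n_hubs - 1][1]
    return [tf for tf, d in ordered if d >= cutoff]


def classify_edges(
    per_lineage_strong: dict[str, set[tuple[str, str]]],
) -> EdgeClassification:
    """Label each strong edge by the lineages it appears in.

    ``specific:<lineage>`` — found in exactly one lineage; ``housekeeping``
    — found in every lineage; ``shared`` — anything in between. Requires at
    least two lineages (the distinction is undefined for one).
    """
    lineages = sorted(per_lineage_strong)
    if len(lineages) < 2:
        raise ValueError("edge classification needs at least 2 lineages")
    norm = {
        lin: {(min(a, b), max(a, b)) for a, b in edges}
        for lin, edges in per_lineage_strong.items()
    }
    union = set().union(*norm.values())
    labels: dict[tuple[str, str], str] = {}
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    for edge in union:
        prov = frozenset(lin for lin in lineages if edge in norm[lin])
        provenance[edge] = prov
        if len(prov) == 1:
            labels[edge] = f"specific:{next(iter(prov))}"
        elif len(prov) == len(lineages):
            labels[edge] = "housekeeping"
        else:
            labels[edge] = "shared"
    return EdgeClassification(labels=labels, provenance=provenance, lineages=lineages)


def degree_profile(
    per_lineage_strong: dict[str, set[tuple[str, str]]], tfs: list[str]
) -> np.ndarray:
    """TF x lineage matrix of strong-edge degrees (lineages in sorted order)."""
    lineages = sorted(per_lineage_strong)
    out = np.zeros((len(tfs), len(lineages)), dtype=int)
    index = {tf: i for i, tf in enumerate(tfs)}
    for k, lin in enumerate(lineages):
        for a, b in per_lineage_strong[lin]:
            if a in index:
                out[index[a], k] += 1
            if b in index:
                out[index[b], k] += 1
    return out
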