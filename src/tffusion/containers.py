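"""Core data containers shared across the pipeline.

Conventions used throughout:

* Genomic intervals are 0-based, half-open (BED dialect).
* TF x TF networks are symmetric; the diagonal carries no information and is
  always masked out of statistics.
* Missing evidence is encoded with an explicit boolean mask, never with a
  sentinel weight: "no evidence" and "evidence of no interaction" are
  different observations and the tensor machinery treats them differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Interval",
    "IntervalSet",
    "WeightedNetwork",
    "RegulatoryNetwork",
    "ObservedTensor",
    "GoldStandard",
]


@dataclass(frozen=True)
class Interval:
    """One scored genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """A TF's set of scored binding intervals."""

    entries: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.entries:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def on(self, chrom: str) -> list[Interval]:
        return [iv for iv in self.entries if iv.chrom == chrom]

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.entries, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )


class WeightedNetwork:
    """Symmetric weighted TF x TF network with an observation mask.

    Parameters
    ----------
    nodes
        Ordered TF labels.
    weights
        Square matrix of edge weights. Values at unobserved positions are
        ignored (stored as 0).
    mask
        Boolean matrix marking observed entries. The diagonal is always
        forced unobserved. If omitted, every off-diagonal entry is observed.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        weights: np.ndarray,
        mask: np.ndarray | None = None,
    ) -> None:
        weights = np.asarray(weights, dtype=float)
        n = len(nodes)
        if weights.shape != (n, n):
            raise ValueError(
                f"weights shape {weights.shape} does not match {n} nodes"
            )
        if mask is None:
            mask = np.isfinite(weights)
        mask = np.asarray(mask, dtype=bool).copy()
        if mask.shape != (n, n):
            raise ValueError(f"mask shape {mask.shape} does not match {n} nodes")
        np.fill_diagonal(mask, False)
        both = mask & mask.T
        w = np.where(np.isfinite(weights), weights, 0.0)
        if not np.allclose(w[both], w.T[both], atol=1e-9):
            raise ValueError("weights are asymmetric on jointly observed entries")
        self.nodes = list(nodes)
        self.weights = np.where(mask, w, 0.0)
        self.mask = mask

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def observed_upper(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices (i, j) with i < j of observed pairs plus their weights."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.mask[iu, ju]
        return iu[keep], ju[keep], self.weights[iu[keep], ju[keep]]

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.nodes, self.weights.copy(), self.mask.copy())


@dataclass
class RegulatoryNetwork:
    """Directed TF -> TF-gene occupancy edges for one cell type."""

    edges: set[tuple[str, str]]
    tf_universe: list[str]

    def __post_init__(self) -> None:
        universe = set(self.tf_universe)
        for reg, tgt in self.edges:
            if reg not in universe or tgt not in universe:
                raise ValueError(
                    f"edge ({reg}, {tgt}) has an endpoint outside the TF universe"
                )

    def targets_of(self, tf: str) -> set[str]:
        return {tgt for reg, tgt in self.edges if reg == tf}


class ObservedTensor:
    """A 3-way array of stacked evidence networks with an observation mask."""

    def __init__(
        self,
        values: np.ndarray,
        mask: np.ndarray | None = None,
        labels: Sequence[Sequence[str]] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-way array, got ndim={values.ndim}")
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape does not match values")
        self.values = np.where(mask, values, 0.0)
        self.mask = mask
        if labels is None:
            labels = [
                [f"m{n}_{i}" for i in range(values.shape[n])] for n in range(3)
            ]
        labels = [list(l) for l in labels]
        for n, lab in enumerate(labels):
            if len(lab) != values.shape[n]:
                raise ValueError(f"mode-{n} labels do not match shape")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


@dataclass
class GoldStandard:
    """Averaged-network gold standard: weighted scores plus a binarization rule."""

    weights: np.ndarray
    mask: np.ndarray
    nodes: list[str]
    threshold: float = 0.8

    def as_network(self) -> WeightedNetwork:
        return WeightedNetwork(self.nodes, self.weights, self.mask)
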