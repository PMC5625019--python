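"""Readers and writers for every interchange format the pipeline uses.

TSV is the primary, diffable interchange: labeled weight matrices with
``NA`` for masked entries, 3-column strong-edge lists, 2-column regulatory
edge lists, and BED (0-based, half-open, score in column 5) for peaks.
Tensors round-trip either as one ``.npz`` container or as per-slice TSV
pairs (values + mask).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Interval, IntervalSet, ObservedTensor, RegulatoryNetwork, WeightedNetwork

__all__ = [
    "read_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_edge_list",
    "write_edge_list",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "read_tensor",
    "write_tensor",
    "read_tensor_tsv",
    "write_tensor_tsv",
    "write_strong_edges",
]


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file into an IntervalSet (0-based, half-open).

    Columns: chrom, start, end, optional name, optional score. Malformed
    lines raise with their line number.
    """
    entries: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) >= 5 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            entries.append(Interval(fields[0], start, end, score))
    return IntervalSet(entries)


def write_bed(intervals: IntervalSet, path: str | Path, name_prefix: str = "peak") -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t{iv.score:g}\n"
            )


def write_matrix_tsv(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a labeled TSV matrix; masked entries become NA."""
    mat = np.where(net.mask, net.weights, np.nan)
    pd.DataFrame(mat, index=net.nodes, columns=net.nodes).to_csv(
        path, sep="\t", na_rep="NA"
    )


def read_matrix_tsv(path: str | Path) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    mask = np.isfinite(values)
    return WeightedNetwork([str(n) for n in df.index], values, mask)


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg, tgt in sorted(network.edges):
            fh.write(f"{reg}\t{tgt}\n")


def read_edge_list(
    path: str | Path, tf_universe: list[str] | None = None
) -> RegulatoryNetwork:
    """Read a 2-column regulator TAB target edge list.

    Without an explicit TF universe, the universe is the sorted set of all
    endpoint labels.
    """
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            edges.add((fields[0], fields[1]))
    if tf_universe is None:
        tf_universe = sorted({tf for e in edges for tf in e})
    return RegulatoryNetwork(edges, tf_universe)


def write_profiles_tsv(
    profiles: np.ndarray, path: str | Path, tf_labels: list[str] | None = None
) -> None:
    n_tfs, n_samples = profiles.shape
    if tf_labels is None:
        tf_labels = [f"TF{i:03d}" for i in range(n_tfs)]
    cols = [f"sample{j}" for j in range(n_samples)]
    pd.DataFrame(profiles, index=tf_labels, columns=cols).to_csv(path, sep="\t")


def read_profiles_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(n) for n in df.index]


def write_tensor(tensor: ObservedTensor, path: str | Path) -> None:
    """Single-file binary container (.npz) for tensor round-trips."""
    np.savez_compressed(
        path,
        values=tensor.values,
        mask=tensor.mask,
        labels0=np.array(tensor.labels[0]),
        labels1=np.array(tensor.labels[1]),
        labels2=np.array(tensor.labels[2]),
    )


def read_tensor(path: str | Path) -> ObservedTensor:
    with np.load(path, allow_pickle=False) as data:
        labels = [
            [str(x) for x in data[f"labels{n}"]] for n in range(3)
        ]
        return ObservedTensor(data["values"], data["mask"], labels)


def write_tensor_tsv(tensor: ObservedTensor, directory: str | Path) -> None:
    """Diffable tensor container: one labeled TSV per slice (NA = masked)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, cols = tensor.labels[0], tensor.labels[1]
    for k, name in enumerate(tensor.labels[2]):
        mat = np.where(tensor.mask[:, :, k], tensor.values[:, :, k], np.nan)
        pd.DataFrame(mat, index=rows, columns=cols).to_csv(
            directory / f"{name}.tsv", sep="\t", na_rep="NA"
        )


def read_tensor_tsv(directory: str | Path) -> ObservedTensor:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise ValueError(f"no slice TSVs found in {directory}")
    values, masks, names = [], [], []
    rows = None
    for path in paths:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        if rows is None:
            rows, cols = [str(x) for x in df.index], [str(x) for x in df.columns]
        mat = df.to_numpy(dtype=float)
        values.append(np.nan_to_num(mat))
        masks.append(np.isfinite(mat))
        names.append(path.stem)
    return ObservedTensor(
        np.stack(values, axis=2), np.stack(masks, axis=2), [rows, cols, names]
    )


def write_strong_edges(
    edges: list[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("tf_a\ttf_b\tweight\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
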