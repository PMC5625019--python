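"""Shared synthetic worlds for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tffusion as tfn

# the overcomplete-rank start is the intended protocol; silence its warning
warnings.filterwarnings("ignore", message="initial rank")
warnings.filterwarnings("ignore", message="fit did not converge")


def planted_module_truth(
    n: int, n_modules: int, module_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric 0/1 adjacency with disjoint planted interaction modules."""
    truth = np.zeros((n, n))
    order = rng.permutation(n)
    for m in range(n_modules):
        members = order[m * module_size : (m + 1) * module_size]
        for i in members:
            for j in members:
                if i != j:
                    truth[i, j] = 1.0
    return truth


def noisy_slices(
    truth: np.ndarray,
    n_slices: int,
    noise_std: float,
    missing_fraction: float,
    rng: np.random.Generator,
) -> list[tfn.WeightedNetwork]:
    """Independent noisy, partially observed views of one planted network."""
    n = truth.shape[0]
    nodes = [f"TF{i:03d}" for i in range(n)]
    out = []
    for _ in range(n_slices):
        noise = rng.normal(0.0, noise_std, size=(n, n))
        noise = (noise + noise.T) / np.sqrt(2.0)
        mask = np.ones((n, n), dtype=bool)
        iu, ju = np.triu_indices(n, k=1)
        n_drop = int(round(missing_fraction * iu.size))
        if n_drop:
            drop = rng.choice(iu.size, size=n_drop, replace=False)
            mask[iu[drop], ju[drop]] = False
            mask[ju[drop], iu[drop]] = False
        out.append(tfn.WeightedNetwork(nodes, truth + noise, mask))
    return out


LINEAGE_WORLD = dict(
    n_tfs=40,
    lineages={"A": 4, "B": 4, "C": 4},
    shared_modules=[set(range(0, 8))],
    specific_modules={
        "A": [set(range(8, 16))],
        "B": [set(range(16, 24))],
        "C": [set(range(24, 32))],
    },
)


def module_pairs(members: set[int], n_tfs: int = 40) -> set[tuple[str, str]]:
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]
    return {
        (tfs[min(i, j)], tfs[max(i, j)])
        for i in members
        for j in members
        if i < j
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
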