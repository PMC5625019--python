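"""Synthetic data generators for every pipeline input.

These emulate the statistical structure the analysis assumes — CP-structured
tensors with i.i.d. Gaussian noise and uniform missingness, peak sets with
planted co-binding pairs, profile matrices with correlated blocks, and
lineage-structured regulatory networks with planted co-occupancy modules —
so every stage is testable without genome-scale data.

All generators are deterministic under their integer seed; multi-stage
randomness is split off a single ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Interval, IntervalSet, ObservedTensor, RegulatoryNetwork

__all__ = [
    "SyntheticTensorTruth",
    "gen_cp_tensor",
    "gen_toy_peaks",
    "gen_profiles",
    "gen_regulatory_networks",
    "DEFAULT_PEAK_LENGTH",
]

#: Fixed synthetic peak length (coordinate units). A constant keeps the
#: interval-overlap null analytically tractable.
DEFAULT_PEAK_LENGTH = 200


@dataclass
class SyntheticTensorTruth:
    """Ground truth behind a simulated observed tensor."""

    latent_tensor: np.ndarray
    factor_matrices: list[np.ndarray]
    true_rank: int
    noise_precision: float
    missing_fraction: float
    seed: int


def _compose_cp(factors: list[np.ndarray]) -> np.ndarray:
    a, b, c = factors
    return np.einsum("ir,jr,kr->ijk", a, b, c)


def gen_cp_tensor(
    shape: tuple[int, int, int],
    rank: int,
    noise_precision: float,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[ObservedTensor, SyntheticTensorTruth]:
    """Simulate a low-rank 3-way tensor observed through noise and missingness.

    The latent tensor is a sum of ``rank`` rank-one terms whose factor columns
    are i.i.d. standard normal (the model's own prior family at unit
    precision). Observed values are the latent values plus i.i.d. Gaussian
    noise of precision ``noise_precision`` (``numpy.inf`` or ``None`` means
    noise-free); exactly ``round(missing_fraction * size)`` entries are then
    masked uniformly at random.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be three positive integers, got {shape}")
    if rank < 1:
        raise ValueError("rank must be positive")
    # one mode may be smaller than the rank (a 3-slice network stack can
    # carry rank > 3 structure); two or more deficient modes cannot
    deficient = [mode for mode, s in enumerate(shape) if rank > s]
    if len(deficient) > 1:
        raise ValueError(
            f"rank {rank} exceeds the dimension of modes {deficient} "
            f"(shape {shape}); at most one mode may be smaller than the rank"
        )
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError(f"missing_fraction must lie in [0, 1), got {missing_fraction}")
    size = int(np.prod(shape))
    n_missing = int(round(missing_fraction * size))
    n_observed = size - n_missing
    if n_observed < rank * sum(shape):
        raise ValueError(
            f"only {n_observed} observed entries for rank {rank}: need at least "
            f"rank * sum(shape) = {rank * sum(shape)}"
        )

    rng = np.random.default_rng(seed)
    factors = [rng.standard_normal((s, rank)) for s in shape]
    latent = _compose_cp(factors)

    noise_free = noise_precision is None or np.isinf(noise_precision)
    if not noise_free and noise_precision <= 0:
        raise ValueError("noise_precision must be positive")
    if noise_free:
        values = latent.copy()
        tau = np.inf
    else:
        tau = float(noise_precision)
        values = latent + rng.normal(0.0, tau ** -0.5, size=shape)

    mask = np.ones(size, dtype=bool)
    if n_missing:
        mask[rng.choice(size, size=n_missing, replace=False)] = False
    mask = mask.reshape(shape)

    tensor = ObservedTensor(values, mask)
    truth = SyntheticTensorTruth(
        latent_tensor=latent,
        factor_matrices=factors,
        true_rank=rank,
        noise_precision=tau,
        missing_fraction=missing_fraction,
        seed=seed,
    )
    return tensor, truth


def gen_toy_peaks(
    domain_length: int,
    n_tfs: int,
    planted_pairs: list[tuple[int, int]] | None = None,
    peaks_per_tf: int = 20,
    jitter: int = 0,
    seed: int = 0,
    peak_length: int = DEFAULT_PEAK_LENGTH,
) -> dict[int, IntervalSet]:
    """Simulate per-TF peak sets on one linear domain ("chr1").

    TFs in a planted pair share peak centers up to ``+/- jitter``; all other
    TFs get independently uniform placements. Peak scores are drawn uniform
    on [1, 10] and carry no planted signal.
    """
    planted_pairs = list(planted_pairs or [])
    if peak_length + 2 * jitter > domain_length:
        raise ValueError(
            f"peak length {peak_length} with jitter {jitter} cannot fit in "
            f"domain of length {domain_length}"
        )
    for a, b in planted_pairs:
        if not (0 <= a < n_tfs and 0 <= b < n_tfs):
            raise ValueError(f"planted pair ({a}, {b}) outside TF range")

    rng = np.random.default_rng(seed)
    lo = jitter
    hi = domain_length - peak_length - jitter
    starts: dict[int, np.ndarray] = {}
    for a, b in planted_pairs:
        if a not in starts:
            starts[a] = rng.integers(lo, hi + 1, size=peaks_per_tf)
        base = starts[a]
        if jitter > 0:
            offset = rng.integers(-jitter, jitter + 1, size=peaks_per_tf)
        else:
            offset = np.zeros(peaks_per_tf, dtype=int)
        starts.setdefault(b, base + offset)
    for tf in range(n_tfs):
        if tf not in starts:
            starts[tf] = rng.integers(0, domain_length - peak_length + 1,
                                      size=peaks_per_tf)

    out: dict[int, IntervalSet] = {}
    for tf in range(n_tfs):
        scores = rng.uniform(1.0, 10.0, size=peaks_per_tf)
        out[tf] = IntervalSet(
            [
                Interval("chr1", int(s), int(s) + peak_length, float(sc))
                for s, sc in zip(starts[tf], scores)
            ]
        ).sorted()
    return out


def gen_profiles(
    n_tfs: int,
    n_samples: int,
    blocks: list[set[int]] | None = None,
    within_block_correlation: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a TF x sample profile matrix with correlated planted blocks.

    Each block shares a latent sample-wise factor; a member row is
    ``sqrt(rho) * latent + sqrt(1 - rho) * noise`` so the expected pairwise
    Pearson correlation inside the block is ``rho`` and zero across blocks.
    """
    blocks = [set(b) for b in (blocks or [])]
    seen: set[int] = set()
    for b in blocks:
        if b & seen:
            raise ValueError("blocks must be disjoint")
        if any(not 0 <= tf < n_tfs for tf in b):
            raise ValueError("block member outside TF range")
        seen |= b
    rho = float(within_block_correlation)
    if blocks and not 0.0 < rho < 1.0:
        raise ValueError("within_block_correlation must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    profiles = rng.standard_normal((n_tfs, n_samples))
    for b in blocks:
        latent = rng.standard_normal(n_samples)
        for tf in sorted(b):
            profiles[tf] = np.sqrt(rho) * latent + np.sqrt(1 - rho) * profiles[tf]
    return profiles


def gen_regulatory_networks(
    n_tfs: int,
    lineages: dict[str, int],
    shared_modules: list[set[int]] | None = None,
    specific_modules: dict[str, list[set[int]]] | None = None,
    edge_noise: float = 0.0,
    seed: int = 0,
    module_target_fraction: float = 0.15,
    background_density: float = 0.05,
) -> dict[tuple[str, str], RegulatoryNetwork]:
    """Simulate lineage-structured directed TF -> TF-gene regulatory networks.

    The target universe is the TF gene set itself. TFs in a shared module
    co-occupy one common random promoter set in every cell type; TFs in a
    lineage-specific module co-occupy their module's promoter set only within
    that lineage. Every TF additionally regulates an independent random
    background set (density ``background_density``, matching the ~0.05 edge
    density of real cell-type regulatory networks); each potential edge is
    finally flipped with probability ``edge_noise``. The module target
    fraction is kept small so that independently drawn module target sets
    overlap only at chance level.

    Returns a map ``(lineage, cell_type_label) -> RegulatoryNetwork``.
    """
    shared_modules = [set(m) for m in (shared_modules or [])]
    specific_modules = {
        lin: [set(m) for m in mods]
        for lin, mods in (specific_modules or {}).items()
    }
    for lin in specific_modules:
        if lin not in lineages:
            raise ValueError(f"specific_modules names unknown lineage {lin!r}")
    if not 0.0 <= edge_noise <= 1.0:
        raise ValueError("edge_noise must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]
    n_module_targets = max(1, int(round(module_target_fraction * n_tfs)))

    # Module promoter sets are drawn disjointly: distinct functional modules
    # occupy distinct promoters. At a realistic target-universe size (~500
    # TF genes) chance overlap between independently drawn module sets is
    # within background; at desk-scale universes it would be a large
    # finite-size artifact, so it is not modeled.
    n_modules = len(shared_modules) + sum(map(len, specific_modules.values()))
    if n_modules * n_module_targets > n_tfs:
        raise ValueError(
            f"{n_modules} modules x {n_module_targets} targets exceed the "
            f"{n_tfs}-gene target universe"
        )
    pool = list(rng.permutation(n_tfs))

    def next_target_set() -> frozenset[int]:
        out = frozenset(int(t) for t in pool[:n_module_targets])
        del pool[:n_module_targets]
        return out

    shared_targets = [next_target_set() for _ in shared_modules]
    specific_targets = {
        lin: [next_target_set() for _ in mods]
        for lin, mods in sorted(specific_modules.items())
    }

    out: dict[tuple[str, str], RegulatoryNetwork] = {}
    for lin in sorted(lineages):
        for ct in range(lineages[lin]):
            adj = rng.random((n_tfs, n_tfs)) < background_density
            for module, targets in zip(shared_modules, shared_targets):
                for tf in module:
                    adj[tf, list(targets)] = True
            for module, targets in zip(
                specific_modules.get(lin, []), specific_targets.get(lin, [])
            ):
                for tf in module:
                    adj[tf, list(targets)] = True
            if edge_noise > 0:
                flips = rng.random((n_tfs, n_tfs)) < edge_noise
                adj ^= flips
            edges = {
                (tfs[i], tfs[j]) for i, j in zip(*np.nonzero(adj))
            }
            out[(lin, f"{lin}_ct{ct}")] = RegulatoryNetwork(edges, list(tfs))
    return out
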