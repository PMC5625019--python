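"""End-to-end pipeline orchestration as a plain Python function.

:func:`run_pipeline` runs selected stages over a synthetic world (or saved
inputs), writing every artifact plus the resolved configuration next to the
outputs so a run is reproducible from ``(resolved config, seed)`` alone.
Stages, in order: ``simulate``, ``build-networks``, ``normalize``,
``factorize``, ``fuse``, ``call-strong``, ``evaluate``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, fusion, io, networks, synthetic
from .bcpf import PriorConfig, fit
from .containers import ObservedTensor, WeightedNetwork

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "integrate_networks",
    "infer_lineage_networks",
]

logger = logging.getLogger(__name__)

_STAGES = (
    "simulate",
    "build-networks",
    "normalize",
    "factorize",
    "fuse",
    "call-strong",
    "evaluate",
)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run. Unknown keys are rejected
    when loading from a mapping or YAML file."""

    out_dir: str = "pipeline_out"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    seed: int = 0
    # synthetic world
    n_tfs: int = 30
    n_slices: int = 3
    n_modules: int = 3
    module_size: int = 6
    slice_noise_std: float = 0.3
    slice_missing_fraction: float = 0.1
    # model
    prior: PriorConfig = field(default_factory=PriorConfig)
    strong: fusion.StrongEdgeConfig = field(default_factory=fusion.StrongEdgeConfig)
    lower_pct: float = 5.0
    upper_pct: float = 95.0
    gold_threshold: float = 0.5
    tensor_path: str | None = None  # skip simulate/build and load this tensor

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "prior" in mapping and isinstance(mapping["prior"], dict):
            mapping["prior"] = PriorConfig(**mapping["prior"])
        if "strong" in mapping and isinstance(mapping["strong"], dict):
            mapping["strong"] = fusion.StrongEdgeConfig(**mapping["strong"])
        cfg = cls(**mapping)
        for stage in cfg.stages:
            if stage not in _STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def integrate_networks(
    nets: list[WeightedNetwork],
    prior: PriorConfig | None = None,
    normalize: bool = True,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
):
    """Normalize evidence networks, stack, factorize, and fuse.

    Returns ``(fused WeightedNetwork, CPModelState)``. This is the
    integration backbone shared by both applications: heterogeneous
    evidence slices in, one precise weighted TF interaction network out.
    """
    if normalize:
        nets = [networks.normalize_network(n, lower_pct, upper_pct) for n in nets]
    tensor = networks.stack_tensor(nets)
    state = fit(tensor, prior)
    fused = fusion.fuse_network_mode(state)
    fused.nodes = list(nets[0].nodes)
    return fused, state


def infer_lineage_networks(
    reg_networks: dict[tuple[str, str], "object"],
    prior: PriorConfig | None = None,
    strong: fusion.StrongEdgeConfig | None = None,
) -> dict[str, dict]:
    """Per-lineage integration of cell-type regulatory networks.

    For each lineage: build co-occupancy (Jaccard) networks per cell type,
    normalize, stack into a tensor, factorize, fuse into the cell-lineage
    network (CL-Net), and call its strong edges. The lineage AI-Net (plain
    per-pair average of the normalized cell-type networks) is returned
    alongside for comparison.
    """
    if strong is None:
        strong = fusion.StrongEdgeConfig()
    by_lineage: dict[str, list] = {}
    for (lin, _ct), reg in sorted(reg_networks.items()):
        by_lineage.setdefault(lin, []).append(reg)

    out: dict[str, dict] = {}
    for lin, regs in by_lineage.items():
        # co-occupancy slices are all Jaccard scores on one common [0, 1]
        # scale, so they stack directly; percentile min-max normalization is
        # for heterogeneous evidence and would stretch the background tail
        # over the full range, drowning the module signal in per-TF spread
        ct_nets = [networks.cooccupancy_jaccard(r) for r in regs]
        fused, state = integrate_networks(ct_nets, prior, normalize=False)
        strong_edges = fusion.strong_interactions(fused, strong)
        out[lin] = {
            "cl_net": fused,
            "state": state,
            "ct_nets": ct_nets,
            "ai_net": evaluation.ai_net(ct_nets),
            "strong_edges": strong_edges,
            "strong_set": {(a, b) for a, b, _ in strong_edges},
        }
    return out


def _simulate_world(cfg: PipelineConfig, rng: np.random.Generator):
    """Planted-module truth network plus noisy, partially observed slices."""
    n = cfg.n_tfs
    truth = np.zeros((n, n))
    order = rng.permutation(n)
    for m in range(cfg.n_modules):
        members = order[m * cfg.module_size : (m + 1) * cfg.module_size]
        for i in members:
            for j in members:
                if i != j:
                    truth[i, j] = 1.0
    nodes = [f"TF{i:03d}" for i in range(n)]
    slices: list[WeightedNetwork] = []
    for _ in range(cfg.n_slices):
        noise = rng.normal(0.0, cfg.slice_noise_std, size=(n, n))
        noise = (noise + noise.T) / np.sqrt(2.0)
        w = truth + noise
        mask = np.ones((n, n), dtype=bool)
        iu, ju = np.triu_indices(n, k=1)
        n_drop = int(round(cfg.slice_missing_fraction * iu.size))
        if n_drop:
            drop = rng.choice(iu.size, size=n_drop, replace=False)
            mask[iu[drop], ju[drop]] = False
            mask[ju[drop], iu[drop]] = False
        slices.append(WeightedNetwork(nodes, w, mask))
    return truth, nodes, slices


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the selected stages; returns a summary dict of artifact paths
    and headline numbers. Fails before any computation when a selected stage
    is missing its inputs."""
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_mapping(config)
    else:
        cfg = config

    stages = [s for s in _STAGES if s in cfg.stages]
    needs_tensor = {"factorize", "fuse", "call-strong", "evaluate"} & set(stages)
    if needs_tensor and "simulate" not in stages and cfg.tensor_path is None:
        raise ValueError(
            "stage 'factorize' selected without inputs: run 'simulate' or set tensor_path"
        )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = asdict(cfg)
    resolved_text = yaml.safe_dump(resolved)
    (out / "resolved_config.yaml").write_text(resolved_text)
    logger.info(
        "resolved config hash %s",
        hashlib.sha256(resolved_text.encode()).hexdigest()[:16],
    )

    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"out_dir": str(out)}
    timings: dict[str, float] = {}
    truth = None
    tensor: ObservedTensor | None = None
    slices: list[WeightedNetwork] = []
    nodes: list[str] = []

    t0 = time.perf_counter()
    if "simulate" in stages:
        truth, nodes, slices = _simulate_world(cfg, rng)
        for k, net in enumerate(slices):
            io.write_matrix_tsv(net, out / f"slice{k}.tsv")
        timings["simulate"] = time.perf_counter() - t0

    if "normalize" in stages and slices:
        slices = [
            networks.normalize_network(s, cfg.lower_pct, cfg.upper_pct)
            for s in slices
        ]
    if slices:
        tensor = networks.stack_tensor(slices)
    elif cfg.tensor_path is not None:
        tensor = io.read_tensor(cfg.tensor_path)
        nodes = tensor.labels[0]

    state = None
    if "factorize" in stages:
        t0 = time.perf_counter()
        assert tensor is not None
        io.write_tensor(tensor, out / "tensor.npz")
        prior = PriorConfig(**{**asdict(cfg.prior), "seed": cfg.seed})
        state = fit(tensor, prior)
        timings["factorize"] = time.perf_counter() - t0
        summary["rank"] = state.rank
        summary["converged"] = state.converged

    fused = None
    if "fuse" in stages and state is not None:
        fused = fusion.fuse_network_mode(state)
        fused.nodes = nodes if nodes else fused.nodes
        io.write_matrix_tsv(fused, out / "fused_network.tsv")

    strong = None
    if "call-strong" in stages and fused is not None:
        strong = fusion.strong_interactions(fused, cfg.strong)
        io.write_strong_edges(strong, out / "strong_edges.tsv")
        summary["n_strong"] = len(strong)
        summary["hubs"] = fusion.hub_tfs(strong, cfg.strong)

    if "evaluate" in stages and fused is not None and truth is not None:
        from .containers import GoldStandard

        mask = ~np.eye(len(nodes), dtype=bool)
        gold = GoldStandard(truth, mask, nodes, threshold=cfg.gold_threshold)
        auc_fused = evaluation.auc_network_vs_labels(fused, gold)
        slice_aucs = [
            evaluation.auc_network_vs_labels(s, gold) for s in slices
        ]
        summary["auc_fused"] = auc_fused
        summary["auc_slices"] = slice_aucs
        with open(out / "evaluation.json", "w") as fh:
            json.dump({"auc_fused": auc_fused, "auc_slices": slice_aucs}, fh)

    summary["timings"] = timings
    for stage, dt in timings.items():
        logger.info("stage %s: %.2fs", stage, dt)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {k: v for k, v in summary.items() if k != "timings"},
            fh,
            default=str,
        )
    return summary
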