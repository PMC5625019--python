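"""Cell-lineage analysis: specific vs housekeeping TF interactions.

Simulates 3 lineages x 4 cell types of directed regulatory networks with
one shared co-occupancy module (present everywhere) and one module specific
to each lineage. Per lineage, cell-type Jaccard networks are stacked and
factorized into a cell-lineage network (CL-Net); strong edges are called
and classified across lineages, and the CL-Net is compared with the plain
averaged network (AI-Net).
"""

import warnings

import numpy as np

import tffusion as tfn
from tffusion import evaluation
from tffusion.pipeline import infer_lineage_networks

warnings.filterwarnings("ignore", message="initial rank")

SHARED = [set(range(0, 8))]
SPECIFIC = {
    "blood": [set(range(8, 16))],
    "cancer": [set(range(16, 24))],
    "stromal": [set(range(24, 32))],
}

regs = tfn.gen_regulatory_networks(
    n_tfs=40,
    lineages={"blood": 4, "cancer": 4, "stromal": 4},
    shared_modules=SHARED,
    specific_modules=SPECIFIC,
    edge_noise=0.05,
    seed=0,
)
res = infer_lineage_networks(regs, tfn.PriorConfig(r_init=10, seed=0))

cls = tfn.classify_edges({lin: r["strong_set"] for lin, r in res.items()})
print("strong-edge classification:", cls.counts())
for lin, summary in cls.per_lineage_summary().items():
    print(f"  {lin}: {summary['strong_edges']:.0f} strong edges, "
          f"{summary['specific']:.0f} specific "
          f"({100 * summary['specific_fraction']:.0f}%)")

tfs = [f"TF{i:03d}" for i in range(40)]
degrees = tfn.degree_profile(
    {lin: r["strong_set"] for lin, r in res.items()}, tfs
)
top = np.argsort(-degrees.sum(axis=1))[:5]
print("highest strong-degree TFs (rows: TF, cols: lineage):")
for i in top:
    print(f"  {tfs[i]}: {degrees[i].tolist()}")

for lin, r in res.items():
    truth = np.zeros((40, 40))
    for members in [SHARED[0], SPECIFIC[lin][0]]:
        for i in members:
            for j in members:
                if i != j:
                    truth[i, j] = 1.0
    gold = tfn.GoldStandard(truth, ~np.eye(40, dtype=bool), tfs, 0.5)
    auc_cl = evaluation.auc_network_vs_labels(r["cl_net"], gold)
    auc_ai = evaluation.auc_network_vs_labels(r["ai_net"], gold)
    print(f"{lin}: CL-Net AUC {auc_cl:.3f} vs AI-Net AUC {auc_ai:.3f}")

# Housekeeping labels should cover the shared module's 28 pairs; each
# lineage's specific module surfaces only in its own strong set; and the
# factorized CL-Net matches or beats plain averaging because it denoises
# through the shared low-rank structure.
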