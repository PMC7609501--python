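#!/usr/bin/env python
"""Stage 4 - discovery: RF classification of FMV vs bed-time urine per
legume food, with combined RF + AUC + t feature selection.

For each legume food the baseline class is the first morning void of the
exposure day and the exposed class the same day's bed-time urine.  Reads
results/processed/ and results/simulation/truth.tsv; writes per-food feature
tables, OOB metrics and proximity-MDS embeddings to results/discovery/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from bfikit import discovery, io
from bfikit.discovery import ContrastSpec, RFParams
from bfikit.simulate import LEGUME_FOODS

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/discovery")
OUT.mkdir(parents=True, exist_ok=True)

matrix = io.read_fingerprint(
    "results/processed/fingerprint_normalized.tsv",
    "results/processed/metadata.tsv",
    normalized=True,
)
truth = io.read_truth("results/simulation/truth.tsv")

metrics_all = {}
for food in LEGUME_FOODS:
    result = discovery.discover(
        matrix, truth, ContrastSpec(target=food),
        k=25, fdr_alpha=0.05, params=RFParams(n_trees=1000), seed=SEED,
    )
    safe = food.replace(" ", "_")
    io.write_feature_stats(result.selected, OUT / f"features_{safe}.tsv")
    np.savetxt(OUT / f"embedding_{safe}.tsv", result.embedding,
               delimiter="\t", header="dim1\tdim2", comments="")
    metrics_all[food] = {
        "accuracy": result.metrics.accuracy,
        "mean_margin": result.metrics.mean_margin,
        "auc": result.metrics.auc,
        "n_selected": len(result.selected),
    }
    print(f"{food:16s} OOB accuracy {result.metrics.accuracy:.3f}  "
          f"margin {result.metrics.mean_margin:.3f}  "
          f"AUC {result.metrics.auc:.3f}  selected {len(result.selected)}")

(OUT / "metrics.json").write_text(json.dumps(metrics_all, indent=2, sort_keys=True) + "\n")
print(f"feature tables and embeddings -> {OUT}")
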