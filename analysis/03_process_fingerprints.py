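#!/usr/bin/env python
"""Stage 3 - conditioning: per-sample dilution normalization and log
transform of the simulated fingerprints (mirrors the per-sample
refractive-index normalization used on real urines).

Reads results/simulation/, writes results/processed/.
"""

from pathlib import Path

from bfikit import io, processing

IN = Path("results/simulation")
OUT = Path("results/processed")
OUT.mkdir(parents=True, exist_ok=True)

matrix = io.read_fingerprint(IN / "fingerprint.tsv", IN / "metadata.tsv")
matrix = processing.normalize_dilution(matrix)
matrix = processing.transform_log(matrix)
io.write_fingerprint(matrix, OUT / "fingerprint_normalized.tsv")
io.write_metadata(matrix, OUT / "metadata.tsv")
print(f"normalized + log-transformed {matrix.n_samples} samples -> {OUT}")
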