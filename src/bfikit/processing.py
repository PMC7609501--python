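"""Pre-classification conditioning of fingerprint matrices.

Spot urines vary widely in concentration; real acquisitions are normalized
per sample (by refractive index in the source protocol) before analysis so
all measurements share a dynamic range.  Here the per-sample normalization
scalar lives in the sample metadata (the simulator records the exact dilution
factor it applied), and intensities are optionally log-transformed for
variance stabilization before classification.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np

from .simulate import FingerprintMatrix, SampleMeta, bin_center


def normalize_dilution(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Divide each sample's intensities by its recorded dilution factor."""
    if matrix.normalized:
        raise ValueError("matrix is already dilution-normalized")
    factors = np.array([m.dilution_factor for m in matrix.sample_meta])
    # SampleMeta validates positivity, but user-supplied metadata may bypass it
    bad = [m.sample_id for m, f in zip(matrix.sample_meta, factors) if f <= 0]
    if bad:
        raise ValueError(f"non-positive dilution factor for samples: {bad}")
    return FingerprintMatrix(
        mz_bins=matrix.mz_bins.copy(),
        intensities=matrix.intensities / factors[:, None],
        sample_meta=list(matrix.sample_meta),
        normalized=True,
    )


def bin_peaks(
    peaks_per_sample: Sequence[Sequence[tuple[float, float]]],
    sample_meta: Sequence[SampleMeta],
    bin_width: float = 0.01,
) -> FingerprintMatrix:
    """Sum peak lists into fixed-width m/z bins.

    Bins are half-open intervals [k*w, (k+1)*w): a peak exactly on a boundary
    belongs to the upper bin.  Only occupied bins appear in the output.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if len(peaks_per_sample) != len(sample_meta):
        raise ValueError("one peak list per sample is required")
    occupied: set[int] = set()
    for i, peaks in enumerate(peaks_per_sample):
        for mz, intensity in peaks:
            if intensity < 0:
                raise ValueError(
                    f"sample {i}: negative intensity {intensity} at m/z {mz}"
                )
            occupied.add(math.floor(mz / bin_width))
    ks = sorted(occupied)
    index = {k: j for j, k in enumerate(ks)}
    out = np.zeros((len(peaks_per_sample), len(ks)))
    for i, peaks in enumerate(peaks_per_sample):
        for mz, intensity in peaks:
            out[i, index[math.floor(mz / bin_width)]] += intensity
    centers = np.array([(k + 0.5) * bin_width for k in ks])
    return FingerprintMatrix(
        mz_bins=centers, intensities=out, sample_meta=list(sample_meta)
    )


def transform_log(matrix: FingerprintMatrix, offset: float = 1.0) -> FingerprintMatrix:
    """Apply x -> log(x + offset) elementwise (order-preserving)."""
    if offset <= 0:
        raise ValueError(f"log offset must be positive, got {offset}")
    return FingerprintMatrix(
        mz_bins=matrix.mz_bins.copy(),
        intensities=np.log(matrix.intensities + offset),
        sample_meta=list(matrix.sample_meta),
        normalized=matrix.normalized,
    )
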