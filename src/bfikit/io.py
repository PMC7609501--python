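"""Bit-exact TSV/CSV readers and writers for the pipeline's tables.

All tables are UTF-8 TSV with a header row and "." decimal point; fingerprint
tables carry ``sample_id`` first and one column per m/z bin (bin centers
printed to 5 decimal places, matching the reporting precision of the
annotation engine).  Round-tripping any table through write/read is an
identity on its values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import FingerprintMatrix, SampleMeta

META_COLUMNS = [
    "sample_id", "participant_id", "week", "day",
    "urine_type", "time_h", "dilution_factor",
]


def write_fingerprint(matrix: FingerprintMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_metadata(matrix: FingerprintMatrix, path) -> None:
    matrix.meta_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fingerprint(matrix_path, meta_path, normalized: bool = False) -> FingerprintMatrix:
    df = _read_table(matrix_path)
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{matrix_path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    meta_df = read_metadata(meta_path)
    meta_by_id = {row["sample_id"]: row for _, row in meta_df.iterrows()}
    meta: list[SampleMeta] = []
    for lineno, sid in enumerate(df["sample_id"], start=2):
        if sid not in meta_by_id:
            raise ValueError(
                f"{matrix_path} line {lineno}: sample {sid!r} missing from metadata"
            )
        row = meta_by_id[sid]
        meta.append(
            SampleMeta(
                participant_id=str(row["participant_id"]),
                week=int(row["week"]),
                day=int(row["day"]),
                urine_type=str(row["urine_type"]),
                time_h=float(row["time_h"]),
                dilution_factor=float(row["dilution_factor"]),
                sample_id=str(sid),
            )
        )
    mz_bins = np.array([float(c) for c in df.columns[1:]])
    return FingerprintMatrix(
        mz_bins=mz_bins,
        intensities=df.iloc[:, 1:].to_numpy(dtype=float),
        sample_meta=meta,
        normalized=normalized,
    )


def read_metadata(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata header missing columns {missing}")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: truth table must have a sample_id column")
    return df


def write_feature_stats(stats, path) -> None:
    pd.DataFrame(
        {
            "mz": [f"{s.mz:.5f}" for s in stats],
            "rf_importance": [s.rf_importance for s in stats],
            "auc": [s.auc for s in stats],
            "t_statistic": [s.t_statistic for s in stats],
            "p_value": [s.p_value for s in stats],
            "fdr_q": [s.fdr_q for s in stats],
            "aggregate_rank": [s.aggregate_rank for s in stats],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_annotations(annotations, path) -> None:
    pd.DataFrame(
        {
            "observed_mz": [f"{a.observed_mz:.5f}" for a in annotations],
            "compound": [a.compound_name for a in annotations],
            "rule_label": [a.rule.label for a in annotations],
            "theoretical_mz": [f"{a.theoretical_mz:.5f}" for a in annotations],
            "ppm_error": [f"{a.ppm_error:.3f}" for a in annotations],
            "msi_level": [a.msi_level for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def write_candidates(candidates, path) -> None:
    rows = []
    for c in candidates:
        top = c.annotations[0] if c.annotations else None
        rows.append(
            {
                "mz": f"{c.mz:.5f}",
                "source_contrast": c.source_contrast,
                "aggregate_rank": c.aggregate_rank,
                "annotation": top.compound_name if top else "",
                "rule_label": top.rule.label if top else "",
                "ppm_error": f"{top.ppm_error:.3f}" if top else "",
                "msi_level": top.msi_level if top else "",
                "specificity_score": (
                    f"{c.specificity_score:.4f}"
                    if c.specificity_score is not None else ""
                ),
                "shared_across": ";".join(c.shared_across),
                "elevation_window_h": (
                    f"{c.elevation_window_h:.3f}"
                    if c.elevation_window_h is not None else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        # pandas reports the offending line number in its message
        raise ValueError(f"{path}: malformed table: {exc}") from None
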