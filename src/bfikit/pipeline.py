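"""End-to-end orchestration: simulate -> process -> discover -> annotate ->
specificity, with a machine-readable run manifest.

The manifest records the configuration, the seed, and a SHA-256 hash of every
artifact written, so two runs with identical configuration and seed can be
verified byte-identical without diffing the artifacts themselves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import chem, design, discovery, io, simulate, specificity
from .discovery import ContrastSpec, RFParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one end-to-end run."""

    seed: int = 0
    study: int = 2
    n_participants: int = 12
    weeks: Optional[tuple[int, ...]] = None
    panel_path: Optional[str] = None
    menu_path: Optional[str] = None
    n_background: int = 2000
    bin_width: float = 0.01
    noise_cv: float = 0.2
    dilution_cv: float = 0.3
    contrast_targets: tuple[str, ...] = (
        "garden peas", "baked beans", "peanuts", "tofu stir fry",
    )
    group_map: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("legumes", ("garden peas", "baked beans", "peanuts", "tofu stir fry")),
    )
    k: int = 25
    fdr_alpha: float = 0.05
    ppm_tolerance: float = 5.0
    n_trees: int = 500
    log_transform: bool = True
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.study not in (1, 2):
            raise ValueError(f"study must be 1 or 2, got {self.study}")
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")
        if self.panel_path == "":
            raise ValueError("config field panel_path must not be empty")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full discovery pipeline and write all artifacts.

    Returns the manifest (also written to ``manifest.json``): configuration,
    seed, stage summaries and SHA-256 hashes of every output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        panel = simulate.load_panel(config.panel_path)
        menus = design.load_menu_plans(config.menu_path)

        stage = "design"
        t0 = time.perf_counter()
        profile_key = f"study{config.study}"
        base = simulate.STUDY_PROFILES[profile_key]
        profile = simulate.CohortProfile(
            n=config.n_participants,
            female_fraction=base.female_fraction,
            age=base.age, weight_kg=base.weight_kg,
            height_cm=base.height_cm, waist_cm=base.waist_cm,
        )
        cohort = simulate.generate_cohort(profile, seed=config.seed)
        if config.study == 2:
            assignments = design.randomize_study2(cohort.ids, seed=config.seed)
        else:
            assignments = design.randomize_study1(cohort.ids, seed=config.seed)
        cohort.to_frame().to_csv(out / "cohort.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        _write_assignments(assignments, out / "assignments.tsv")
        logger.info("design stage done in %.1f s", time.perf_counter() - t0)

        stage = "simulate"
        t0 = time.perf_counter()
        exposures = simulate.simulate_exposures(
            cohort, assignments, menus, seed=config.seed, weeks=config.weeks
        )
        matrix, truth = simulate.simulate_fingerprints(
            exposures, panel, assignments,
            background=simulate.BackgroundSpec(n_features=config.n_background),
            noise_cv=config.noise_cv, dilution_cv=config.dilution_cv,
            bin_width=config.bin_width, seed=config.seed, weeks=config.weeks,
        )
        simulate.exposures_to_frame(exposures).to_csv(
            out / "exposures.tsv", sep="\t", index=False, float_format="%.10g"
        )
        io.write_fingerprint(matrix, out / "fingerprint.tsv")
        io.write_metadata(matrix, out / "metadata.tsv")
        io.write_truth(truth, out / "truth.tsv")
        logger.info("simulate stage done in %.1f s", time.perf_counter() - t0)

        stage = "process"
        from . import processing

        matrix_n = processing.normalize_dilution(matrix)
        if config.log_transform:
            matrix_n = processing.transform_log(matrix_n)

        stage = "discover"
        t0 = time.perf_counter()
        params = RFParams(n_trees=config.n_trees)
        candidates_by_food: dict[str, list] = {}
        metrics_all: dict[str, dict] = {}
        for target in config.contrast_targets:
            contrast = ContrastSpec(target=target)
            result = discovery.discover(
                matrix_n, truth, contrast, k=config.k,
                fdr_alpha=config.fdr_alpha, params=params, seed=config.seed,
            )
            safe = target.replace(" ", "_").replace(":", "-")
            io.write_feature_stats(
                result.selected, out / f"features_{safe}.tsv"
            )
            np.savetxt(
                out / f"embedding_{safe}.tsv", result.embedding,
                delimiter="\t", header="dim1\tdim2", comments="",
            )
            candidates_by_food[target] = list(result.selected)
            metrics_all[target] = {
                "accuracy": result.metrics.accuracy,
                "mean_margin": result.metrics.mean_margin,
                "auc": result.metrics.auc,
                "n_selected": len(result.selected),
            }
        (out / "metrics.json").write_text(
            json.dumps(metrics_all, indent=2, sort_keys=True) + "\n"
        )
        logger.info("discover stage done in %.1f s", time.perf_counter() - t0)

        stage = "annotate+specificity"
        t0 = time.perf_counter()
        db = [(s.compound_name, s.formula) for s in panel]
        msi = simulate.panel_msi_levels(panel)
        shared = specificity.cross_food_consistency(
            candidates_by_food, dict(config.group_map)
        )
        candidates = _score_candidates(
            candidates_by_food, shared, matrix_n, truth, db, msi, config
        )
        io.write_candidates(candidates, out / "candidates.tsv")
        summary = {
            "n_candidates": len(candidates),
            "shared_bins_per_group": {
                g: {f"{mz:.5f}": ranks for mz, ranks in bins.items()}
                for g, bins in shared.items()
            },
            "metrics": metrics_all,
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        logger.info("annotate+specificity done in %.1f s", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    # JSON-stable form: tuples become lists so the manifest round-trips
    d = asdict(config)
    d["group_map"] = {g: list(foods) for g, foods in config.group_map}
    d["contrast_targets"] = list(config.contrast_targets)
    if config.weeks is not None:
        d["weeks"] = list(config.weeks)
    return d


def _write_assignments(assignments, path) -> None:
    rows = []
    for a in assignments:
        rows.append(
            {
                "participant_id": a.participant_id,
                "study": a.study,
                "square_index": a.square_index if a.square_index is not None else "",
                "dinner_order": (
                    "".join(map(str, a.dinner_order)) if a.dinner_order else ""
                ),
                "arm": a.crossover_arm or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _score_candidates(
    candidates_by_food, shared, matrix, truth, db, msi, config: PipelineConfig
):
    group_of_food = {}
    for group, foods in dict(config.group_map).items():
        for f in foods:
            group_of_food[f] = group
    out = []
    for food, feats in candidates_by_food.items():
        group = group_of_food.get(food)
        shared_bins = shared.get(group, {}) if group else {}
        for f in feats:
            # a bin center can sit up to half a bin width from the true ion
            # m/z, so widen the ppm tolerance to cover the bin if needed
            tol = max(
                config.ppm_tolerance, 1e6 * (config.bin_width / 2.0) / f.mz
            )
            annotations = []
            for polarity in ("neg", "pos"):
                annotations.extend(
                    chem.annotate_mz(
                        f.mz, polarity, db, tol_ppm=tol, msi_levels=msi,
                    )
                )
            annotations.sort(
                key=lambda a: (abs(a.ppm_error), a.compound_name, a.rule.label)
            )
            mz_key = round(f.mz, 9)
            shared_across = tuple(
                sorted(set(shared_bins.get(mz_key, {})) - {food})
            )
            try:
                score = specificity.specificity_score(f.mz, matrix, truth, food)
            except ValueError:
                score = None
            out.append(
                specificity.BiomarkerCandidate(
                    mz=f.mz,
                    source_contrast=food,
                    aggregate_rank=f.aggregate_rank,
                    annotations=tuple(annotations),
                    specificity_score=score,
                    shared_across=shared_across,
                    elevation_window_h=None,
                )
            )
    out.sort(key=lambda c: (c.source_contrast, c.aggregate_rank))
    return out
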