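"""Random-forest urine classification and combined feature selection.

The discovery strategy contrasts two urine classes per food exposure —
typically the first morning void (baseline) against bed-time urine of the
same day — with a supervised random forest evaluated out-of-bag by accuracy,
mean classification margin and ROC AUC, and visualized by classical
multidimensional scaling of the RF proximity matrix.  Explanatory m/z
features are then ranked by a combination of RF importance, per-feature
Mann-Whitney AUC and a two-sample t statistic; the three ranks are summed
and candidates must additionally pass Benjamini-Hochberg FDR control on the
t-test p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RFParams:
    """Random-forest settings: 1000 trees, sqrt(p) features per split,
    out-of-bag evaluation."""

    n_trees: int = 1000
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class ModelMetrics:
    accuracy: float
    mean_margin: float
    auc: float
    out_of_bag: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(f"accuracy out of range: {self.accuracy}")
        if not -1.0 <= self.mean_margin <= 1.0:
            raise ValueError(f"mean margin out of range: {self.mean_margin}")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of range: {self.auc}")


def _validate_two_class(labels: np.ndarray, min_per_class: int = 5) -> np.ndarray:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"exactly two classes are required, got {classes.size}: {classes!r}"
        )
    for c in classes:
        n = int(np.sum(labels == c))
        if n < min_per_class:
            raise ValueError(
                f"class {c!r} has {n} samples; >= {min_per_class} required"
            )
    return classes


def classify_urine_classes(
    X: np.ndarray,
    labels: Sequence,
    positive_class=None,
    params: RFParams | None = None,
    seed: int = 0,
    feature_importances: bool = False,
):
    """Two-class RF with out-of-bag evaluation and proximity matrix.

    Returns ``(ModelMetrics, proximity)`` — or
    ``(ModelMetrics, proximity, importances)`` when requested.  Margin is
    Breiman's: mean over samples of OOB vote share for the true class minus
    the vote share for the other class.  Proximity of two samples is the
    fraction of trees in whose terminal nodes they co-occur.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("feature matrix must be 2-D with >= 2 features")
    classes = _validate_two_class(labels)
    if positive_class is None:
        positive_class = classes[1]
    params = params or RFParams()
    rf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(X, labels)
    oob = rf.oob_decision_function_  # (n, 2), class order = rf.classes_
    # samples never out of bag yield NaN rows; with >= ~50 trees this is rare
    valid = ~np.isnan(oob).any(axis=1)
    oob_v = oob[valid]
    y_v = labels[valid]
    pos_col = int(np.where(rf.classes_ == positive_class)[0][0])
    true_col = (y_v == rf.classes_[1]).astype(int)
    p_true = oob_v[np.arange(len(y_v)), true_col]
    margin = float(np.mean(p_true - (1.0 - p_true)))
    accuracy = float(np.mean((oob_v[:, pos_col] > 0.5) == (y_v == positive_class)))
    auc = float(roc_auc_score(y_v == positive_class, oob_v[:, pos_col]))
    leaves = rf.apply(X)  # (n, n_trees)
    proximity = _leaf_proximity(leaves)
    metrics = ModelMetrics(
        accuracy=accuracy, mean_margin=margin, auc=auc, out_of_bag=True
    )
    if feature_importances:
        return metrics, proximity, rf.feature_importances_
    return metrics, proximity


def _leaf_proximity(leaves: np.ndarray) -> np.ndarray:
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), dtype=float)
    for t in range(n_trees):
        col = leaves[:, t]
        prox += (col[:, None] == col[None, :])
    prox /= n_trees
    return prox


def mds_embed(proximity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of distance = 1 - proximity.

    Deterministic: eigenvectors are sign-fixed so the largest-magnitude
    loading of each axis is positive.
    """
    proximity = np.asarray(proximity, dtype=float)
    if proximity.ndim != 2 or proximity.shape[0] != proximity.shape[1]:
        raise ValueError("proximity must be a square matrix")
    if not np.allclose(proximity, proximity.T, atol=1e-10):
        raise ValueError("proximity matrix must be symmetric")
    d = 1.0 - proximity
    d2 = d * d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    for k in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def feature_auc(values: Sequence[float], labels: Sequence, positive_class) -> float:
    """P(random positive-class value > random other value), ties counted 1/2.

    Mann-Whitney construction: AUC = U / (n_pos * n_neg).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive_class]
    neg = values[labels != positive_class]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def welch_t(
    values: Sequence[float],
    labels: Sequence,
    positive_class,
    pooled: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test of positive class vs rest; two-sided p.

    Welch's unequal-variance form with Welch-Satterthwaite degrees of freedom
    by default; ``pooled=True`` switches to the classical equal-variance
    Student form.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == positive_class]
    b = values[labels != positive_class]
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs >= 2 samples")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both classes")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


@dataclass(frozen=True)
class FeatureStats:
    mz: float
    rf_importance: float
    auc: float
    t_statistic: float
    p_value: float
    fdr_q: float = 1.0
    aggregate_rank: int = 0

    def __post_init__(self) -> None:
        if self.rf_importance < 0:
            raise ValueError("rf_importance must be non-negative")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc out of range: {self.auc}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value out of range: {self.p_value}")


def compute_feature_stats(
    X: np.ndarray,
    labels: Sequence,
    mz_bins: Sequence[float],
    positive_class,
    importances: np.ndarray,
) -> list[FeatureStats]:
    """Per-feature AUC and Welch t alongside the RF importances."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    importances = np.asarray(importances, dtype=float)
    if X.shape[1] != len(mz_bins) or X.shape[1] != importances.size:
        raise ValueError("mz_bins, importances and matrix width must agree")
    out: list[FeatureStats] = []
    for j, mz in enumerate(mz_bins):
        col = X[:, j]
        auc = feature_auc(col, labels, positive_class)
        a = col[labels == positive_class]
        b = col[labels != positive_class]
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0  # constant feature: uninformative
            else:
                # degenerate perfect separation: zero within-class variance
                t = math.copysign(math.inf, a.mean() - b.mean())
                p = float(np.finfo(float).tiny)
        else:
            t, p = welch_t(col, labels, positive_class)
            if not np.isfinite(t):
                t, p = 0.0, 1.0
            p = min(max(p, np.finfo(float).tiny), 1.0)
        out.append(
            FeatureStats(
                mz=float(mz),
                rf_importance=float(importances[j]),
                auc=auc,
                t_statistic=t,
                p_value=p,
            )
        )
    return out


def select_features(
    feature_stats: Sequence[FeatureStats],
    k: int = 25,
    fdr_alpha: float = 0.05,
) -> list[FeatureStats]:
    """Rank-sum aggregation of the three criteria with a BH-FDR gate.

    Features are ranked separately by RF importance (descending),
    |AUC - 0.5| (descending) and |t| (descending) using average ranks for
    ties; the aggregate score is the sum of the three ranks, with ties broken
    by ascending m/z.  The top ``k`` features whose t-test q-value passes
    Benjamini-Hochberg FDR <= ``fdr_alpha`` are returned, best first, with
    ``aggregate_rank`` (1-based position) and ``fdr_q`` filled in.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 < fdr_alpha < 1.0:
        raise ValueError(f"fdr_alpha must be in (0, 1), got {fdr_alpha}")
    fs = list(feature_stats)
    if not fs:
        return []
    imp = np.array([f.rf_importance for f in fs])
    auc_dev = np.array([abs(f.auc - 0.5) for f in fs])
    t_abs = np.array([abs(f.t_statistic) for f in fs])
    pvals = np.array([f.p_value for f in fs])
    r1 = stats.rankdata(-imp, method="average")
    r2 = stats.rankdata(-auc_dev, method="average")
    r3 = stats.rankdata(-t_abs, method="average")
    score = r1 + r2 + r3
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    order = sorted(range(len(fs)), key=lambda i: (score[i], fs[i].mz))
    selected: list[FeatureStats] = []
    for pos, i in enumerate(order, start=1):
        if len(selected) >= k:
            break
        if not reject[i]:
            continue
        f = fs[i]
        selected.append(
            FeatureStats(
                mz=f.mz,
                rf_importance=f.rf_importance,
                auc=f.auc,
                t_statistic=f.t_statistic,
                p_value=f.p_value,
                fdr_q=float(min(qvals[i], 1.0)),
                aggregate_rank=pos,
            )
        )
    return selected


def aggregate_rank_of(
    feature_stats: Sequence[FeatureStats], mz: float
) -> int:
    """1-based aggregate-rank position of the feature at ``mz`` among all
    features (no FDR gate), using the same rank-sum ordering as
    :func:`select_features`."""
    fs = list(feature_stats)
    imp = np.array([f.rf_importance for f in fs])
    auc_dev = np.array([abs(f.auc - 0.5) for f in fs])
    t_abs = np.array([abs(f.t_statistic) for f in fs])
    score = (
        stats.rankdata(-imp, method="average")
        + stats.rankdata(-auc_dev, method="average")
        + stats.rankdata(-t_abs, method="average")
    )
    order = sorted(range(len(fs)), key=lambda i: (score[i], fs[i].mz))
    for pos, i in enumerate(order, start=1):
        if np.isclose(fs[i].mz, mz):
            return pos
    raise ValueError(f"no feature at m/z {mz}")


# ---------------------------------------------------------------------------
# contrast construction


@dataclass(frozen=True)
class ContrastSpec:
    """Which samples form the baseline and exposed classes for one contrast.

    Default mirrors the discovery schematic: baseline = first morning void of
    the exposure day, exposed = bed-time urine of the same day.
    """

    target: str  # food name or "group:<name>" key into the truth table
    baseline_types: tuple[str, ...] = ("FMV",)
    exposed_types: tuple[str, ...] = ("bed_time",)

    @property
    def truth_column(self) -> str:
        return self.target if ":" in self.target else f"food:{self.target}"


def build_contrast(
    matrix, truth: pd.DataFrame, contrast: ContrastSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Select samples and labels for one baseline-vs-exposed contrast.

    Exposure days are the days on which the target food (or group) was
    actually consumed by that participant: exposed samples are those of the
    configured exposed urine types on such days with a positive truth flag,
    baseline samples the configured baseline types of the same
    participant-days.  Returns ``(row_indices, labels)`` with labels
    "baseline" / "exposed".
    """
    col = contrast.truth_column
    if col not in truth.columns:
        raise ValueError(f"truth table has no column {col!r}")
    flags = dict(zip(truth["sample_id"], truth[col]))
    exposed_days: set[tuple[str, int, int]] = set()
    for i, m in enumerate(matrix.sample_meta):
        if m.urine_type in contrast.exposed_types and flags.get(m.sample_id, 0):
            exposed_days.add((m.participant_id, m.week, m.day))
    idx: list[int] = []
    labels: list[str] = []
    for i, m in enumerate(matrix.sample_meta):
        key = (m.participant_id, m.week, m.day)
        if key not in exposed_days:
            continue
        if m.urine_type in contrast.exposed_types and flags.get(m.sample_id, 0):
            idx.append(i)
            labels.append("exposed")
        elif m.urine_type in contrast.baseline_types:
            idx.append(i)
            labels.append("baseline")
    return np.array(idx, dtype=int), np.array(labels)


@dataclass(frozen=True)
class DiscoveryResult:
    contrast: ContrastSpec
    metrics: ModelMetrics
    proximity: np.ndarray = field(repr=False)
    embedding: np.ndarray = field(repr=False)
    feature_stats: tuple[FeatureStats, ...] = field(repr=False)
    selected: tuple[FeatureStats, ...] = ()


def discover(
    matrix,
    truth: pd.DataFrame,
    contrast: ContrastSpec,
    k: int = 25,
    fdr_alpha: float = 0.05,
    params: RFParams | None = None,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full discovery stage for one contrast."""
    idx, labels = build_contrast(matrix, truth, contrast)
    X = matrix.intensities[idx]
    metrics, proximity, importances = classify_urine_classes(
        X, labels, positive_class="exposed", params=params, seed=seed,
        feature_importances=True,
    )
    embedding = mds_embed(proximity)
    fstats = compute_feature_stats(
        X, labels, matrix.mz_bins, "exposed", importances
    )
    selected = select_features(fstats, k=k, fdr_alpha=fdr_alpha)
    return DiscoveryResult(
        contrast=contrast,
        metrics=metrics,
        proximity=proximity,
        embedding=embedding,
        feature_stats=tuple(fstats),
        selected=tuple(selected),
    )
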