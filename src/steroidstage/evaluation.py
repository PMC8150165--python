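"""ROC/AUC machinery, repeated stratified-split validation, and the
nonparametric group comparisons used for the enzyme-activity ratios.

The validation design: for a binary stage contrast (e.g. early F0-F2 vs
advanced F3-F4 fibrosis), repeatedly draw stratified train/test partitions,
fit the whole preprocessing chain (detection floor, z-scoring) and the GMLVQ
classifier on the training subjects only, score the held-out subjects with
the signed relative distance, and summarise the per-split AUCs by their mean
and 2.5/97.5 percentile interval.  Per-feature relevances are averaged over
splits for the panel ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import clinical_scores as cs
from .gmlvq import TrainConfig, decision_scores, init_model, relevances, train
from .preprocessing import (
    FeatureMatrix,
    build_feature_matrix,
    corrected_matrix,
    half_min_positive_floor,
    log10_transform,
    augment_covariates,
    zscore_fit_apply,
)
from .synthetic import parse_contrast

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "roc_auc",
    "repeated_split_validation",
    "evaluate_comparator_scores",
    "group_compare",
    "GroupComparison",
    "PairwiseTest",
]

log = logging.getLogger(__name__)

NEGATIVE_ARM = "negative"
POSITIVE_ARM = "positive"

_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class PipelineConfig:
    """Everything the per-split pipeline needs besides the data."""

    covariates: tuple[str, ...] = ()
    panel: tuple[str, ...] | None = None  # None → every metabolite present
    train: TrainConfig = field(default_factory=TrainConfig)
    corrected: bool = True  # creatinine-corrected vs per-litre mode


@dataclass
class ValidationReport:
    contrast: tuple[tuple[str, ...], tuple[str, ...]]
    n_splits: int
    test_fraction: float
    per_split_auc: list[float]
    auc_mean: float
    ci95: tuple[float, float]
    pooled_roc: list[tuple[float, float, float]]
    relevance_mean: dict[str, float]
    per_split_test_ids: list[list[str]] = field(default_factory=list)
    training_logs: list[list[float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.per_split_auc) != self.n_splits:
            raise ValueError("per_split_auc length must equal n_splits")
        for a in self.per_split_auc:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"AUC {a} outside [0, 1]")
        lo, hi = self.ci95
        if not (lo <= self.auc_mean <= hi):
            raise ValueError("auc_mean must lie inside ci95")

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def roc_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.pooled_roc, columns=["fpr", "tpr", "threshold"])


def roc_auc(scores, labels):
    """ROC curve (threshold sweep over the observed scores) and trapezoidal
    AUC, which equals the Mann-Whitney concordance with half-credit ties.

    ``labels`` are binary (0/1 or boolean); both classes must be present.
    Returns ``(curve, auc)`` with curve rows ``(fpr, tpr, threshold)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist())), float(_sk_auc(fpr, tpr))


def _stratified_split(rng: np.random.Generator, y: np.ndarray, test_fraction: float):
    """Index arrays (train, test) with each class represented in both."""
    test_idx = []
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 2)  # ≥2 train per class
        if n_test < 1:
            raise ValueError(f"class {c!r} too small for a stratified split")
        test_idx.append(rng.permutation(idx)[:n_test])
    test = np.sort(np.concatenate(test_idx))
    mask = np.ones(len(y), dtype=bool)
    mask[test] = False
    return np.where(mask)[0], test


def _contrast_records(records: Sequence, contrast: str):
    neg, pos = parse_contrast(contrast)
    subset, y = [], []
    for r in records:
        if r.stage in neg:
            subset.append(r)
            y.append(NEGATIVE_ARM)
        elif r.stage in pos:
            subset.append(r)
            y.append(POSITIVE_ARM)
    if NEGATIVE_ARM not in y or POSITIVE_ARM not in y:
        raise ValueError(f"contrast {contrast!r}: one arm is empty in these records")
    return (neg, pos), subset, np.asarray(y)


def _panel_of(records: Sequence, config: PipelineConfig) -> tuple[str, ...]:
    return tuple(config.panel) if config.panel is not None else tuple(records[0].steroids_raw)


def repeated_split_validation(
    records: Sequence,
    contrast: str,
    config: PipelineConfig | None = None,
    n_splits: int = 100,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> ValidationReport:
    """Repeated stratified random splits; fully deterministic given ``seed``.

    All data-dependent fitting (detection floor, z-scoring statistics, GMLVQ
    training) happens on the training subjects of each split only.
    """
    config = config or PipelineConfig()
    arms, subset, y = _contrast_records(records, contrast)
    panel = _panel_of(subset, config)
    raw = corrected_matrix(subset, panel, corrected=config.corrected)
    ids = [r.subject_id for r in subset]

    rng = np.random.default_rng(seed)
    aucs, rel_sum = [], np.zeros(len(panel) + len(config.covariates))
    tprs = []
    test_ids_all, tlogs = [], []
    feature_names = None
    for split in range(n_splits):
        for attempt in range(10):
            tr_idx, te_idx = _stratified_split(rng, y, test_fraction)
            if len(set(y[te_idx])) == 2:
                break
            log.warning("split %d attempt %d had a single-class test set; resampled", split, attempt)
        else:
            raise RuntimeError("could not draw a two-class test set in 10 attempts")
        floor = half_min_positive_floor(raw[tr_idx])
        tr_fm = FeatureMatrix(
            values=log10_transform(raw[tr_idx], floor),
            feature_names=panel,
            labels=tuple(y[tr_idx]),
        )
        te_fm = FeatureMatrix(
            values=log10_transform(raw[te_idx], floor),
            feature_names=panel,
            labels=tuple(y[te_idx]),
        )
        if config.covariates:
            tr_recs = [subset[i] for i in tr_idx]
            te_recs = [subset[i] for i in te_idx]
            tr_fm = augment_covariates(tr_fm, tr_recs, config.covariates)
            te_fm = augment_covariates(te_fm, te_recs, config.covariates)
        tr_fm, te_fm = zscore_fit_apply(tr_fm, te_fm)

        train_seed = int(rng.integers(2**31))
        split_cfg = TrainConfig(**{**asdict(config.train), "seed": train_seed})
        model = train(init_model(tr_fm, seed=train_seed), tr_fm, split_cfg)
        feature_names = model.feature_names

        scores = decision_scores(model, te_fm.values, POSITIVE_ARM)
        curve, a = roc_auc(scores, [lab == POSITIVE_ARM for lab in te_fm.labels])
        aucs.append(a)
        rel = relevances(model)
        rel_sum += np.array([rel[f] for f in model.feature_names])
        fpr = np.array([p[0] for p in curve])
        tpr = np.array([p[1] for p in curve])
        tprs.append(np.interp(_FPR_GRID, fpr, tpr))
        test_ids_all.append([ids[i] for i in te_idx])
        tlogs.append(list(model.training_log))

    aucs_arr = np.asarray(aucs)
    mean_tpr = np.mean(tprs, axis=0)
    lo, hi = np.percentile(aucs_arr, [2.5, 97.5])
    mean_auc = float(aucs_arr.mean())
    return ValidationReport(
        contrast=arms,
        n_splits=n_splits,
        test_fraction=test_fraction,
        per_split_auc=[float(a) for a in aucs],
        auc_mean=mean_auc,
        ci95=(min(float(lo), mean_auc), max(float(hi), mean_auc)),
        pooled_roc=[(float(f), float(t), float("nan")) for f, t in zip(_FPR_GRID, mean_tpr)],
        relevance_mean={
            f: float(v) for f, v in zip(feature_names, rel_sum / n_splits)
        },
        per_split_test_ids=test_ids_all,
        training_logs=tlogs,
    )


def evaluate_comparator_scores(records: Sequence, contrast: str, score_name: str):
    """ROC of a serum comparator score (no training, no splits) against a
    binary stage contrast.  Returns ``(curve, auc)``."""
    if score_name not in cs.SCORE_FUNCTIONS:
        raise ValueError(
            f"unknown score {score_name!r}; choose from {sorted(cs.SCORE_FUNCTIONS)}"
        )
    _arms, subset, y = _contrast_records(records, contrast)
    fn = cs.SCORE_FUNCTIONS[score_name]
    values, bad = [], []
    for r in subset:
        try:
            v = fn(r)
            if not np.isfinite(v):
                raise ValueError("non-finite score")
            values.append(v)
        except (ValueError, TypeError):
            bad.append(r.subject_id)
    if bad:
        raise ValueError(f"cannot compute {score_name} for subjects: {bad}")
    return roc_auc(values, y == POSITIVE_ARM)


# ---------------------------------------------------------------------------
# Nonparametric group comparisons (steroid ratios across control / F0-2 / F3-4)

@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    h_statistic: float
    p_value: float
    pairwise: tuple[PairwiseTest, ...]


def group_compare(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal-Wallis omnibus test (tie-corrected) with Dunn's post hoc
    pairwise z-tests, Bonferroni-adjusted over the pairs.

    ``groups`` is a mapping name → values or a sequence of value sequences.
    Pairwise flags mark adjusted p < ``alpha`` (the analysis threshold 0.05).
    """
    if not isinstance(groups, Mapping):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    data = [np.asarray(groups[name], dtype=float) for name in names]
    if len(data) < 2:
        raise ValueError("at least two groups are required")
    for name, g in zip(names, data):
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")

    h, p = stats.kruskal(*data)

    # Dunn's test: mean ranks of the pooled sample, tie-corrected variance.
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in data:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p_raw * n_pairs)
            pairs.append(
                PairwiseTest(
                    group_a=names[i],
                    group_b=names[j],
                    z=float(z),
                    p_raw=float(p_raw),
                    p_adjusted=float(p_adj),
                    significant=bool(p_adj < alpha),
                )
            )
    return GroupComparison(h_statistic=float(h), p_value=float(p), pairwise=tuple(pairs))
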