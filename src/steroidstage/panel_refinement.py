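"""Relevance-driven panel reduction (backward elimination).

The relevance-matrix diagonal ranks the steroids by their contribution to
the learned metric.  Starting from the full panel, the least relevant
steroid (mean relevance over validation splits) is removed, the pipeline is
re-validated on the reduced panel, and so on down to a target size — the
route from the 32-steroid assay to a reduced 10-steroid panel.  Clinical
covariates (age, BMI), when included, are exempt from removal; they define
the reduced-panel-plus-covariates model variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import PipelineConfig, ValidationReport, repeated_split_validation

__all__ = ["FeatureRanking", "PanelTrajectory", "rank_features", "backward_eliminate"]


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by descending mean relevance; ties alphabetical."""

    order: tuple[str, ...]
    has_ties: bool

    def __iter__(self):
        return iter(self.order)

    def __getitem__(self, i):
        return self.order[i]

    def __len__(self):
        return len(self.order)


@dataclass
class TrajectoryStep:
    panel_size: int
    removed_feature: str | None  # feature removed after evaluating this panel
    auc_mean: float
    ci95: tuple[float, float]


@dataclass
class PanelTrajectory:
    steps: list[TrajectoryStep]
    final_panel: tuple[str, ...]
    ranking: tuple[str, ...]  # full-panel relevance ranking

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "panel_size": s.panel_size,
                    "removed_feature": s.removed_feature,
                    "auc_mean": s.auc_mean,
                    "ci_lo": s.ci95[0],
                    "ci_hi": s.ci95[1],
                }
                for s in self.steps
            ]
        )


def rank_features(report: ValidationReport) -> FeatureRanking:
    """Order features by descending mean diagonal relevance (deterministic:
    exact ties broken alphabetically and flagged)."""
    items = sorted(report.relevance_mean.items(), key=lambda kv: (-kv[1], kv[0]))
    values = [v for _, v in items]
    has_ties = len(set(values)) < len(values)
    return FeatureRanking(order=tuple(k for k, _ in items), has_ties=has_ties)


def backward_eliminate(
    records: Sequence,
    contrast: str,
    config: PipelineConfig | None = None,
    stop_at: int = 10,
    n_splits: int = 20,
    test_fraction: float = 0.1,
    seed: int = 0,
    mode: str = "sequential",
) -> PanelTrajectory:
    """Shrink the steroid panel one metabolite at a time.

    ``mode="sequential"`` (default) re-ranks after every removal;
    ``mode="fixed"`` ranks once on the full panel and removes in that fixed
    order, still re-validating at every size so the AUC trajectory is
    recorded either way.  Covariate features are never candidates for
    removal.  Deterministic given ``seed``.
    """
    if mode not in ("sequential", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or PipelineConfig()
    panel = list(config.panel) if config.panel is not None else list(records[0].steroids_raw)
    if stop_at >= len(panel):
        raise ValueError(f"stop_at={stop_at} must be smaller than the panel ({len(panel)})")
    if stop_at < 1:
        raise ValueError("stop_at must be >= 1")
    covariates = set(config.covariates)

    rng = np.random.default_rng(seed)
    steps: list[TrajectoryStep] = []
    ranking: tuple[str, ...] | None = None
    fixed_order: list[str] | None = None
    current = list(panel)
    while True:
        report = repeated_split_validation(
            records,
            contrast,
            replace(config, panel=tuple(current)),
            n_splits=n_splits,
            test_fraction=test_fraction,
            seed=int(rng.integers(2**31)),
        )
        if ranking is None:
            full_ranking = rank_features(report)
            ranking = full_ranking.order
            if mode == "fixed":
                # removal order: ascending relevance, steroids only
                fixed_order = [f for f in reversed(full_ranking.order) if f not in covariates]
        if len(current) == stop_at:
            steps.append(
                TrajectoryStep(len(current), None, report.auc_mean, report.ci95)
            )
            break
        if mode == "sequential":
            candidates = {
                f: report.relevance_mean[f] for f in current if f not in covariates
            }
            victim = min(candidates.items(), key=lambda kv: (kv[1], kv[0]))[0]
        else:
            victim = fixed_order.pop(0)
        steps.append(TrajectoryStep(len(current), victim, report.auc_mean, report.ci95))
        current.remove(victim)

    return PanelTrajectory(steps=steps, final_panel=tuple(current), ranking=ranking)
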