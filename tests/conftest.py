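import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from steroidstage import (
    CohortSpec,
    PipelineConfig,
    generate_cohort,
    repeated_split_validation,
)
from steroidstage.gmlvq import TrainConfig
from steroidstage.panel_refinement import rank_features
from steroidstage.synthetic import DEFAULT_PANEL, default_spec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SEPARABLE_INFORMATIVE = tuple((m, 4.0) for m in DEFAULT_PANEL[:5])


def separable_spec(seed: int, n_per_class: int = 100) -> CohortSpec:
    """Two-class cohort with a 4-SD shift on 5 of the 32 metabolites."""
    return CohortSpec(
        n_per_class={"control": n_per_class, "F4": n_per_class},
        informative_features={"control:F4": SEPARABLE_INFORMATIVE},
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down version of the default study cohort (same structure)."""
    spec = dataclasses.replace(
        default_spec(seed=42),
        n_per_class={
            "control": 30,
            "F0": 6,
            "F1": 6,
            "F2": 6,
            "F3": 12,
            "F4": 12,
            "alcohol_cirrhosis": 12,
        },
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_battery():
    """Twenty independent separable cohorts, each validated with repeated
    stratified splits, plus shuffled-label controls on five of them.

    Shared by the separability and relevance-recovery checks.
    """
    rng = np.random.default_rng(0)
    mean_aucs, top6_sets = [], []
    for seed in range(20):
        records = generate_cohort(separable_spec(seed))
        report = repeated_split_validation(
            records, "control:F4", PipelineConfig(), n_splits=10, seed=1000 + seed
        )
        mean_aucs.append(report.auc_mean)
        top6_sets.append(set(rank_features(report)[:6]))

    null_aucs = []
    for seed in range(5):
        records = generate_cohort(separable_spec(seed))
        stages = [r.stage for r in records]
        rng.shuffle(stages)
        shuffled = [
            dataclasses.replace(r, stage=s) for r, s in zip(records, stages)
        ]
        report = repeated_split_validation(
            shuffled, "control:F4", PipelineConfig(), n_splits=10, seed=2000 + seed
        )
        null_aucs.append(report.auc_mean)

    return {
        "informative": set(m for m, _ in SEPARABLE_INFORMATIVE),
        "mean_aucs": mean_aucs,
        "top6_sets": top6_sets,
        "null_aucs": null_aucs,
    }


@pytest.fixture()
def tiny_train_config():
    return TrainConfig(epochs=30, seed=0)
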