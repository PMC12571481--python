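import numpy as np
import pandas as pd
import pytest

from attnping import (
    EffectParams,
    SimConfig,
    make_ground_truth,
    simulate_subject,
)
from attnping.patterns import PatternSet


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small two-ROI design used across unit tests."""
    return SimConfig(
        n_subjects_per_session=2,
        n_shared_subjects=1,
        n_voxels=20,
        rois=("V1", "PFC"),
        n_attention_runs=3,
        n_perception_runs=2,
        trials_per_attention_run=16,
        trials_per_perception_run=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_effects() -> EffectParams:
    return EffectParams()


@pytest.fixture(scope="session")
def tiny_ground_truth(tiny_config, tiny_effects):
    return make_ground_truth(tiny_config, tiny_effects, seed=7)


@pytest.fixture(scope="session")
def tiny_subject(tiny_ground_truth, tiny_config):
    return simulate_subject(tiny_ground_truth, tiny_config, "Ping", "S00", seed=21)


def make_pattern_set(
    matrix: np.ndarray,
    labels=None,
    runs=None,
    roi: str = "V1",
    task: str = "attention",
    period: str = "preparation",
    **extra_cols,
) -> PatternSet:
    """Hand-build a PatternSet with minimal metadata for unit tests."""
    n = matrix.shape[0]
    meta = pd.DataFrame(
        {
            "task": task,
            "period": period,
            "orientation": labels if labels is not None else ["leftward"] * n,
            "run": runs if runs is not None else np.zeros(n, dtype=int),
            "trial_index_in_run": np.arange(n),
            "delay": "long",
            "correct": True,
        }
    )
    for k, v in extra_cols.items():
        meta[k] = v
    return PatternSet(roi=roi, matrix=np.asarray(matrix, float), meta=meta)
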