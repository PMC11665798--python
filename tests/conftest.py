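import numpy as np
import pytest

from surgrsd import (
    CohortSplit,
    StepInterval,
    WorkflowTimeline,
    sample_cohort,
    scaled_config,
)


def fast_sim_config(seed=0, **overrides):
    """Short surgeries (a few minutes) with the default 14-step structure."""
    overrides.setdefault("duration_scale", 1 / 8)
    return scaled_config(seed=seed, **overrides)


def tiny_step_config(seed=0, **overrides):
    """Minimal 5-step workflow (5 core, no optional) for temporal-model tests."""
    defaults = dict(
        duration_scale=1 / 8,
        n_core=5,
        n_optional=0,
        repeat_step_code=3,
        repeat_prob_per_step=0.1,
        order_swap_prob=0.1,
        seed=seed,
    )
    defaults.update(overrides)
    return scaled_config(**defaults)


@pytest.fixture
def toy_timeline():
    return WorkflowTimeline(
        video_id="toy",
        intervals=(
            StepInterval(1, 0, 100),
            StepInterval(8, 100, 130),
            StepInterval(1, 130, 250),
        ),
    )


@pytest.fixture
def small_cohort():
    cfg = fast_sim_config(seed=3)
    return sample_cohort(cfg, 8, 2, 3)


@pytest.fixture
def two_interval_timeline():
    return WorkflowTimeline(
        video_id="two",
        intervals=(StepInterval(1, 0, 100), StepInterval(2, 100, 250)),
    )
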