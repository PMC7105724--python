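import numpy as np
import pandas as pd
import pytest

import probebias as pb


@pytest.fixture(scope="session")
def schedule():
    """Default 280-trial dot-probe schedule."""
    return pb.build_dotprobe_schedule(seed=7)


@pytest.fixture(scope="session")
def subjects():
    return pb.sample_cohort(8, seed=3)


@pytest.fixture(scope="session")
def null_trials(subjects, schedule):
    """Both-phase trials for a small cohort with no injected effects."""
    return pb.simulate_experiment(
        subjects, schedule, pb.BiasEffectMap.null(), pb.RTNoiseParams(), seed=9
    )


def simulate_cohort_indices(n_per_sex, effects, noise=None, seed=0, schedule=None,
                            screen_outliers=True):
    """Full generate -> filter -> aggregate -> screen -> score pass."""
    noise = noise or pb.RTNoiseParams()
    schedule = schedule if schedule is not None else pb.build_dotprobe_schedule(seed=seed)
    subs = pb.sample_cohort(n_per_sex, seed=seed)
    trials = pb.simulate_experiment(subs, schedule, effects, noise, seed=seed + 1)
    retained, _ = pb.filter_trials(trials)
    cells = pb.aggregate_cell_means(retained)
    if screen_outliers:
        cells, _ = pb.apply_outlier_policy(cells)
    indices = pb.score_indices(cells)
    return subs, indices
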