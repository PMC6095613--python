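"""Shared fixtures: synthetic cohorts run once through the PID pipeline."""

import numpy as np
import pytest

from avpid import PipelineConfig, SynthConfig, gen_cohort, run_pid_pipeline, surrogate_normalise

# the PID term a node of each planted kind should maximize
KIND_TO_TERM = {"redundant": "red", "unique_a": "uni_a", "unique_v": "uni_v", "synergistic": "syn"}


@pytest.fixture(scope="session")
def recovery_cohort():
    """20 subjects at the generator's high-SNR working point."""
    return gen_cohort(SynthConfig(n_subjects=20, duration=120.0, rng_seed=101))


@pytest.fixture(scope="session")
def recovery_maps(recovery_cohort):
    return run_pid_pipeline(recovery_cohort, PipelineConfig(n_mc=20_000, rng_seed=7))


@pytest.fixture(scope="session")
def recovery_norm(recovery_maps):
    return surrogate_normalise(recovery_maps)


@pytest.fixture(scope="session")
def behavior_cohort():
    """Full-size cohort (44 subjects) with the planted behavior link."""
    return gen_cohort(SynthConfig(n_subjects=44, duration=90.0, rng_seed=202))


@pytest.fixture(scope="session")
def behavior_maps(behavior_cohort):
    return run_pid_pipeline(behavior_cohort, PipelineConfig(n_mc=15_000, rng_seed=13))


def recovery_accuracy(norm) -> float:
    """Fraction of planted (non-null) nodes whose dominant PID term matches the kind."""
    from avpid.pipeline import dominant_term

    planted = norm[norm["node"].isin(KIND_TO_TERM)]
    pred = dominant_term(planted)
    truth = planted["node"].map(KIND_TO_TERM)
    return float(np.mean(pred.to_numpy() == truth.to_numpy()))
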