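"""Shared fixtures.

The heavy objects (cohorts, trained models) are session-scoped so the
full-pipeline and fatigue-statistics tests reuse one generation/training
pass instead of repeating it per test.
"""

import numpy as np
import pytest

from mmgtorque import pipeline, synthetic

MASTER_SEED = 1


@pytest.fixture(scope="session")
def extension_cohort():
    """30 extension sessions, default parameter ranges, master seed 1."""
    return synthetic.generate_cohort(30, mode="extension", seed=MASTER_SEED)


@pytest.fixture(scope="session")
def trained_models(extension_cohort):
    """Both model variants trained on the first 18 extension sessions."""
    train = extension_cohort[:18]
    return {
        v: pipeline.train_variant(train, v, seed=MASTER_SEED)[0]
        for v in ("rms", "rms_zc")
    }


@pytest.fixture(scope="session")
def standing_cohort():
    """20 standing sessions (knee-angle endpoint, no torque channel)."""
    return synthetic.generate_cohort(20, mode="standing", seed=MASTER_SEED)


@pytest.fixture(scope="session")
def quick_session():
    """One short extension session for fast feature-level checks."""
    params = synthetic.FatigueModelParams(
        duration_s=120.0, t_onset_s=20.0, decay_rate=0.08, seed=7
    )
    return synthetic.simulate_session(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
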