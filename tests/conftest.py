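"""Shared fixtures: small synthetic cohorts and derived trials.

Everything is generated at test time with fixed seeds; the expensive
session-scoped fixtures are sized to keep the whole suite fast while
still exercising the full pipeline end to end.
"""

import numpy as np
import pytest

import aadkit as ak
from aadkit.synthetic import SimulationConfig, SyntheticRecording, simulate_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """3 subjects x 4 min dual-speaker cohort (default gains, 0 dB SNR)."""
    cfg = SimulationConfig(n_subjects=3, minutes_per_condition=4.0, seed=101)
    return simulate_cohort(cfg, blocks={"Lab1": ("dual",)})


@pytest.fixture(scope="session")
def mini_prepared(mini_cohort):
    """The mini cohort pushed through the full preprocessing chain."""
    prepared = []
    for key, rec in sorted(mini_cohort.recordings.items()):
        eeg, envs, report = ak.run_pipeline(rec.eeg, [rec.env_att, rec.env_ign])
        prepared.append(
            SyntheticRecording(
                rec.subject, rec.block, rec.condition, eeg, envs[0], envs[1], rec.truth
            )
        )
    return prepared


@pytest.fixture(scope="session")
def mini_trials(mini_prepared):
    return ak.partition_segments(mini_prepared)


@pytest.fixture(scope="session")
def design():
    return ak.make_lag_design()


@pytest.fixture(scope="session")
def mini_cv(mini_trials, design):
    return ak.cross_validate(mini_trials, design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
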