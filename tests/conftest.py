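"""Shared builders for synthetic session logs and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from contingencylab import ExperimentConfig, ParticipantProfile, SessionLog


@pytest.fixture
def default_config() -> ExperimentConfig:
    return ExperimentConfig()


def make_profile(
    density_arm: str = "low",
    instruction_arm: str = "discrete",
    bdi_group: str = "low",
    **kwargs,
) -> ParticipantProfile:
    return ParticipantProfile(
        participant_id=kwargs.pop("participant_id", "P001"),
        bdi_group=bdi_group,
        density_arm=density_arm,
        instruction_arm=instruction_arm,
        **kwargs,
    )


def make_log(
    a: int = 0,
    b: int = 0,
    c: int = 0,
    d: int = 0,
    n_missed: int = 0,
    judgments: np.ndarray | None = None,
    **profile_kwargs,
) -> SessionLog:
    """Build a session log with exact 2×2 event counts (one block)."""
    n = a + b + c + d + n_missed
    if n < 1:
        raise ValueError("log needs at least one trial")
    config = ExperimentConfig(n_trials=n, block_size=n)
    engaged = [1] * (a + b + c + d) + [0] * n_missed
    action = [1] * (a + b) + [0] * (c + d) + [0] * n_missed
    outcome = [1] * a + [0] * b + [1] * c + [0] * d + [0] * n_missed
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "block_index": np.ones(n, dtype=int),
            "onset_s": np.arange(1, n + 1) * 10.0,
            "engaged": engaged,
            "action": action,
            "outcome": outcome,
        }
    )
    if judgments is None:
        judgments = np.zeros(1)
    profile = make_profile(**profile_kwargs)
    return SessionLog(
        participant_id=profile.participant_id,
        profile=profile,
        config=config,
        trials=trials,
        judgments=np.asarray(judgments, dtype=float),
    )


def random_log(rng: np.random.Generator) -> SessionLog:
    """A structurally valid log with random engagement/action/outcome pattern."""
    block_size = int(rng.integers(1, 9))
    n_blocks = int(rng.integers(1, 6))
    n = block_size * n_blocks
    config = ExperimentConfig(n_trials=n, block_size=block_size)
    engaged = rng.random(n) < rng.uniform(0.3, 1.0)
    action = (rng.random(n) < rng.uniform(0.0, 1.0)) & engaged
    outcome = (rng.random(n) < rng.uniform(0.0, 1.0)) & engaged
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "block_index": np.arange(n) // block_size + 1,
            "onset_s": np.arange(1, n + 1) * 5.0,
            "engaged": engaged.astype(int),
            "action": action.astype(int),
            "outcome": outcome.astype(int),
        }
    )
    profile = make_profile(participant_id="R%03d" % rng.integers(1000))
    return SessionLog(
        participant_id=profile.participant_id,
        profile=profile,
        config=config,
        trials=trials,
        judgments=np.zeros(n_blocks),
    )
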