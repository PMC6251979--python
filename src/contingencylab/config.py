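"""Experiment configuration for the ecological contingency-judgment task.

One :class:`ExperimentConfig` describes a single study arm of the task: a
day-long session of brief discrete trials separated by long, irregular
intertrial intervals, with a control-judgment probe after every block of
trials.  The two outcome probabilities are conditional on whether the
participant acts; their difference is the programmed contingency (ΔP), which
is zero in both canonical arms — participants have no control and only the
overall outcome density differs (.25 vs .75).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

InstructionArm = Literal["discrete", "dynamic"]
DensityArm = Literal["low", "high"]

#: Programmed outcome probability per density arm (same for action / no action,
#: so the programmed contingency is zero in both arms).
DENSITY_ARM_PROBABILITY: dict[str, float] = {"low": 0.25, "high": 0.75}


class TrialPhaseDurations(BaseModel):
    """Anatomy of one trial, in seconds.

    alert_to_button: delay from accessing the alert to the button appearing.
    response_window: time the response button is available.
    outcome: duration of the (possible) auditory outcome.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    alert_to_button: float = 2.0
    response_window: float = 3.0
    outcome: float = 1.0

    @model_validator(mode="after")
    def _positive(self) -> "TrialPhaseDurations":
        for name in ("alert_to_button", "response_window", "outcome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"trial phase duration {name!r} must be > 0")
        return self

    @property
    def total(self) -> float:
        return self.alert_to_button + self.response_window + self.outcome


class ExperimentConfig(BaseModel):
    """Timing, probability and factor settings defining one study arm.

    Defaults reproduce the canonical session: 40 six-second trials in 5
    blocks of 8, intertrial intervals averaging 12 minutes, a 2-minute miss
    timeout, and a bipolar −100..+100 control-rating scale.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_trials: int = Field(default=40, ge=1)
    block_size: int = Field(default=8, ge=1)
    trial_phase_durations: TrialPhaseDurations = TrialPhaseDurations()
    miss_timeout_s: float = Field(default=120.0, gt=0)
    mean_iti_s: float = Field(default=720.0, gt=0)
    p_outcome_given_action: float = Field(default=0.25, ge=0.0, le=1.0)
    p_outcome_given_no_action: float = Field(default=0.25, ge=0.0, le=1.0)
    instruction_arm: InstructionArm = "discrete"
    rating_scale_min: int = -100
    rating_scale_max: int = 100

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        if self.n_trials % self.block_size != 0:
            raise ValueError(
                f"n_trials ({self.n_trials}) must be divisible by "
                f"block_size ({self.block_size})"
            )
        if self.rating_scale_min >= self.rating_scale_max:
            raise ValueError("rating_scale_min must be below rating_scale_max")
        return self

    @property
    def n_blocks(self) -> int:
        """Number of judgment probes: one after every ``block_size`` trials."""
        return self.n_trials // self.block_size

    @property
    def trial_duration_s(self) -> float:
        return self.trial_phase_durations.total

    @property
    def density_arm(self) -> DensityArm | None:
        """Canonical density-arm label if the probabilities match one, else None."""
        for arm, p in DENSITY_ARM_PROBABILITY.items():
            if (
                self.p_outcome_given_action == p
                and self.p_outcome_given_no_action == p
            ):
                return arm  # type: ignore[return-value]
        return None

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        """Load a config from a JSON file; unknown keys are rejected."""
        return cls.model_validate(json.loads(Path(path).read_text()))

    @classmethod
    def for_density_arm(
        cls, arm: DensityArm, instruction_arm: InstructionArm = "discrete", **kwargs
    ) -> "ExperimentConfig":
        p = DENSITY_ARM_PROBABILITY[arm]
        return cls(
            p_outcome_given_action=p,
            p_outcome_given_no_action=p,
            instruction_arm=instruction_arm,
            **kwargs,
        )

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form (provenance tag)."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()
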