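"""Synthetic participants: population generation, per-trial behavior and
blocked control judgments.

The experiment this package targets has no public dataset, so every
downstream stage (validation metrics, imputation, ANCOVA) is exercised
against simulated cohorts whose statistical structure matches the study
conditions: 106 participants split 56/50 by a depression screen (low/high
BDI), randomized 2×2 to outcome density (.25/.75) and instruction arm
(discrete/dynamic alternative-cause framing), pressing on ~58% of engaged
trials, missing ~28.5% of trials, and skipping ~10.6% of judgment probes.

Two judgment models are available:

* ``descriptive`` (default) — each design cell has a configured mean rating;
  a participant's rating is cell mean + participant random intercept +
  per-block Gaussian noise, clipped to the instrument scale.  The default
  cell means encode the qualitative findings of interest: illusory control
  in the low-BDI group only, and an outcome-density effect only under
  discrete-cause instructions.
* ``mechanistic`` — an explicit modeling choice (off by default): the rating
  is a weighted blend of the contingency experienced so far and the
  experienced outcome density, implementing the density-bias account in
  which alternative causes absorb more credit under dynamic framing.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .config import DensityArm, ExperimentConfig, InstructionArm
from .errors import ConfigurationError
from .schedule import TrialSchedule

BdiGroup = Literal["low", "high"]

# Behavioral defaults: press proportion .58, ~11.4 of 40 trials missed,
# 10.6% of judgment probes skipped.
DEFAULT_PRESS_PROB = 0.58
DEFAULT_MISS_PROB = 11.4 / 40
DEFAULT_JUDGMENT_MISSING_PROB = 0.106

# Rating-noise defaults.  A participant-level intercept SD of 35 plus a
# per-block SD of 15 puts the SD of participant mean ratings near 36 and the
# group-mean standard errors near 5 at the default group sizes, matching the
# variability the task produces in practice.
DEFAULT_NOISE_SD = 15.0
DEFAULT_SUBJECT_SD = 35.0

#: Default cell means for the descriptive judgment model, keyed by
#: (bdi_group, density_arm, instruction_arm) and constant across blocks.
#: They encode: low-BDI group mean 14.9 vs high-BDI 1.16 (illusory control
#: vs near-accuracy), and a +20 rating-unit density effect under discrete
#: instructions only.
DEFAULT_CELL_MEANS: dict[tuple[str, str, str], float] = {
    ("low", "low", "dynamic"): 5.0,
    ("low", "high", "dynamic"): 5.0,
    ("low", "low", "discrete"): 14.8,
    ("low", "high", "discrete"): 34.8,
    ("high", "low", "dynamic"): -5.0,
    ("high", "high", "dynamic"): -5.0,
    ("high", "low", "discrete"): -2.68,
    ("high", "high", "discrete"): 17.32,
}

#: Default density weights for the mechanistic model: higher for low BDI and
#: for discrete instructions (the density-bias account).
DEFAULT_W_DENSITY: dict[tuple[str, str], float] = {
    ("low", "discrete"): 0.4,
    ("low", "dynamic"): 0.2,
    ("high", "discrete"): 0.2,
    ("high", "dynamic"): 0.05,
}
DEFAULT_W_ACTION = 0.5


class ParticipantProfile(BaseModel):
    """Behavioral and judgment-model parameters for one synthetic participant."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    participant_id: str
    bdi_group: BdiGroup
    instruction_arm: InstructionArm
    density_arm: DensityArm
    press_prob: float = Field(default=DEFAULT_PRESS_PROB, ge=0.0, le=1.0)
    miss_prob: float = Field(default=DEFAULT_MISS_PROB, ge=0.0, le=1.0)
    judgment_model: Literal["descriptive", "mechanistic"] = "descriptive"
    judgment_params: dict[str, Any] = Field(default_factory=dict)
    judgment_missing_prob: float = Field(
        default=DEFAULT_JUDGMENT_MISSING_PROB, ge=0.0, le=1.0
    )
    noise_sd: float = Field(default=DEFAULT_NOISE_SD, ge=0.0)

    @property
    def subject_sd(self) -> float:
        """SD of the participant-level rating intercept (descriptive model)."""
        return float(self.judgment_params.get("subject_sd", DEFAULT_SUBJECT_SD))

    def cell_mean(self, block: int) -> float:
        """Configured mean rating for this profile's design cell at ``block``.

        ``judgment_params['cell_means']`` overrides the packaged table;
        ``judgment_params['block_effects']`` (sequence indexed by block-1)
        adds a per-block shift.
        """
        table = self.judgment_params.get("cell_means", DEFAULT_CELL_MEANS)
        key = (self.bdi_group, self.density_arm, self.instruction_arm)
        try:
            base = table[key]
        except KeyError:
            raise ConfigurationError(
                f"no cell mean configured for design cell {key}"
            ) from None
        effects = self.judgment_params.get("block_effects")
        if effects is not None:
            base = base + effects[block - 1]
        return float(base)


@dataclasses.dataclass
class SessionLog:
    """Realized record of one simulated (or logged) session.

    ``trials`` columns: trial_index, block_index, onset_s, engaged, action,
    outcome (all int/float; missed trials have action=0 and outcome=0).
    ``judgments`` holds one rating per block, NaN where the probe was skipped.
    """

    participant_id: str
    profile: ParticipantProfile
    config: ExperimentConfig
    trials: pd.DataFrame
    judgments: np.ndarray

    def __post_init__(self) -> None:
        cfg = self.config
        if len(self.trials) != cfg.n_trials:
            raise ValueError("trials table length must equal n_trials")
        if len(self.judgments) != cfg.n_blocks:
            raise ValueError(f"expected {cfg.n_blocks} judgment slots")
        missed = self.trials["engaged"] == 0
        if ((self.trials.loc[missed, "action"] != 0).any()
                or (self.trials.loc[missed, "outcome"] != 0).any()):
            raise ValueError("missed trials cannot carry actions or outcomes")
        present = self.judgments[~np.isnan(self.judgments)]
        if len(present) and (
            present.min() < cfg.rating_scale_min or present.max() > cfg.rating_scale_max
        ):
            raise ValueError("ratings outside the instrument scale")

    def judgments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "block": np.arange(1, len(self.judgments) + 1),
                "rating": self.judgments,
            }
        )


def generate_population(
    n_low_bdi: int,
    n_high_bdi: int,
    seed: int | np.random.Generator,
    **profile_overrides: Any,
) -> list[ParticipantProfile]:
    """Generate a cohort with balanced 2×2 randomization within BDI group.

    Within each group, density×instruction cells receive ``n // 4``
    participants each; any remainder cells are chosen at random without
    replacement.  Extra keyword arguments override profile defaults (e.g.
    ``press_prob=1.0``) for every participant.
    """
    if n_low_bdi < 0 or n_high_bdi < 0:
        raise ValueError("group sizes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = [
        (d, i) for d in ("low", "high") for i in ("discrete", "dynamic")
    ]
    profiles: list[ParticipantProfile] = []
    counter = 1
    for group, n in (("low", n_low_bdi), ("high", n_high_bdi)):
        assignment = cells * (n // 4)
        extra = rng.choice(len(cells), size=n % 4, replace=False)
        assignment += [cells[e] for e in extra]
        order = rng.permutation(n)
        for idx in order:
            density, instruction = assignment[idx]
            profiles.append(
                ParticipantProfile(
                    participant_id=f"P{counter:03d}",
                    bdi_group=group,  # type: ignore[arg-type]
                    density_arm=density,  # type: ignore[arg-type]
                    instruction_arm=instruction,  # type: ignore[arg-type]
                    **profile_overrides,
                )
            )
            counter += 1
    return profiles


def population_to_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "bdi_group": p.bdi_group,
                "density_arm": p.density_arm,
                "instruction_arm": p.instruction_arm,
                "press_prob": p.press_prob,
                "miss_prob": p.miss_prob,
                "judgment_model": p.judgment_model,
                "judgment_missing_prob": p.judgment_missing_prob,
                "noise_sd": p.noise_sd,
            }
            for p in profiles
        ]
    )


def _clip_rating(value: float, config: ExperimentConfig) -> float:
    return float(np.clip(value, config.rating_scale_min, config.rating_scale_max))


def descriptive_judgment(
    profile: ParticipantProfile,
    block: int,
    config: ExperimentConfig,
    rng: np.random.Generator,
    subject_offset: float = 0.0,
) -> float:
    """One rating from the descriptive (cell-mean) model, clipped to scale."""
    mean = profile.cell_mean(block)
    noise = rng.normal(0.0, profile.noise_sd) if profile.noise_sd > 0 else 0.0
    return _clip_rating(mean + subject_offset + noise, config)


def mechanistic_judgment(
    profile: ParticipantProfile,
    experienced: "Any",
    config: ExperimentConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """One rating from the mechanistic (contingency + density blend) model.

    ``experienced`` is a contingency summary of all trials up to the probe
    (anything exposing ``delta_p`` and ``outcome_density``; undefined values
    contribute zero).  The rating is

        100 · (w_action · ΔP_experienced + w_density · P(O)_experienced)

    plus Gaussian noise, clipped to the instrument scale.  ``w_density``
    defaults higher for low-BDI participants and for discrete instructions.
    """
    params = profile.judgment_params
    w_action = float(params.get("w_action", DEFAULT_W_ACTION))
    w_density = params.get("w_density")
    if w_density is None:
        w_density = DEFAULT_W_DENSITY[(profile.bdi_group, profile.instruction_arm)]
    dp = experienced.delta_p if experienced.delta_p is not None else 0.0
    density = (
        experienced.outcome_density if experienced.outcome_density is not None else 0.0
    )
    rating = 100.0 * (w_action * dp + float(w_density) * density)
    if rng is not None and profile.noise_sd > 0:
        rating += rng.normal(0.0, profile.noise_sd)
    return _clip_rating(rating, config)


def simulate_session(
    profile: ParticipantProfile, schedule: TrialSchedule, seed: int
) -> SessionLog:
    """Simulate one participant working through a schedule.

    Per trial: miss with ``miss_prob`` (no action, no outcome); otherwise act
    with ``press_prob`` and read the outcome from the pre-drawn branch
    matching the action.  Per block: emit a rating from the judgment model,
    then blank it with ``judgment_missing_prob``.  Deterministic in
    (profile, schedule, seed).
    """
    cfg = schedule.config
    if profile.instruction_arm != cfg.instruction_arm:
        raise ConfigurationError(
            f"profile instruction arm {profile.instruction_arm!r} does not match "
            f"schedule config {cfg.instruction_arm!r}"
        )
    if cfg.density_arm is not None and profile.density_arm != cfg.density_arm:
        raise ConfigurationError(
            f"profile density arm {profile.density_arm!r} does not match "
            f"schedule config {cfg.density_arm!r}"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = cfg.n_trials
    missed = rng.random(n) < profile.miss_prob
    pressed = rng.random(n) < profile.press_prob
    engaged = ~missed
    action = engaged & pressed
    outcome = np.where(
        engaged,
        np.where(action, schedule.outcome_if_action, schedule.outcome_if_no_action),
        False,
    ).astype(bool)

    trials = pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "block_index": schedule.block_index,
            "onset_s": schedule.trial_onsets_s,
            "engaged": engaged.astype(int),
            "action": action.astype(int),
            "outcome": outcome.astype(int),
        }
    )

    subject_offset = (
        rng.normal(0.0, profile.subject_sd) if profile.subject_sd > 0 else 0.0
    )
    judgments = np.empty(cfg.n_blocks)
    for block in range(1, cfg.n_blocks + 1):
        if profile.judgment_model == "descriptive":
            rating = descriptive_judgment(profile, block, cfg, rng, subject_offset)
        else:
            from .metrics import tabulate_events  # deferred: avoids import cycle

            log = SessionLog(
                participant_id=profile.participant_id,
                profile=profile,
                config=cfg,
                trials=trials,
                judgments=np.full(cfg.n_blocks, np.nan),
            )
            experienced = tabulate_events(log, through_block=block)
            rating = mechanistic_judgment(profile, experienced, cfg, rng)
        judgments[block - 1] = rating
    missing = rng.random(cfg.n_blocks) < profile.judgment_missing_prob
    judgments[missing] = np.nan

    return SessionLog(
        participant_id=profile.participant_id,
        profile=profile,
        config=cfg,
        trials=trials,
        judgments=judgments,
    )
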