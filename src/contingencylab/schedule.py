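"""Trial-timeline generation: intertrial intervals, trial onsets, judgment
probes and pre-drawn outcome schedules.

Intertrial intervals follow the Fleshler–Hoffman progression, the closed-form
series used by operant variable-interval schedules to approximate
constant-probability (exponential) spacing with a fixed number of intervals
and an exact arithmetic mean.  For ``n`` intervals with mean ``m`` the k-th
term (k = 1..n) is

    t_k = m * [1 + ln n + (n − k) ln(n − k) − (n − k + 1) ln(n − k + 1)]

with ``0·ln 0 = 0``.  The sum telescopes, so the analytic mean is exactly
``m``; the implementation renormalizes to remove floating-point drift and
shuffles the series so spacing is irregular rather than ramped.

Both outcome branches (outcome-if-action, outcome-if-no-action) are pre-drawn
per trial as independent Bernoulli variables, so a realized session is fully
reproducible from (schedule, behavior).  Because the branches are
independent, this is statistically identical to drawing at response time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig


def fleshler_hoffman_intervals(
    n: int, mean: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Return ``n`` Fleshler–Hoffman intervals with arithmetic mean ``mean``.

    Parameters
    ----------
    n : number of intervals (>= 1).
    mean : target arithmetic mean in seconds (> 0).
    seed : RNG seed or Generator used only to shuffle the ordered series.

    Returns
    -------
    ndarray of shape (n,), seconds; ``mean(out) == mean`` exactly (to float
    renormalization) and the multiset of values is deterministic in ``n`` and
    ``mean`` — only the order depends on ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    k = np.arange(1, n + 1)
    j = n - k  # runs n-1 .. 0
    with np.errstate(divide="ignore", invalid="ignore"):
        jlogj = np.where(j > 0, j * np.log(np.maximum(j, 1)), 0.0)
        j1 = j + 1
        j1logj1 = j1 * np.log(j1)
    terms = 1.0 + np.log(n) + jlogj - j1logj1
    intervals = mean * terms
    intervals *= mean / intervals.mean()  # exact-mean renormalization
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rng.shuffle(intervals)
    return intervals


@dataclasses.dataclass(frozen=True)
class TrialSchedule:
    """Planned timeline for one session.

    Times are seconds from session start.  ``outcome_if_action`` /
    ``outcome_if_no_action`` are the pre-drawn Bernoulli branches; the branch
    matching the participant's realized behavior determines the outcome.
    """

    config: ExperimentConfig
    seed: int
    iti_s: np.ndarray
    trial_onsets_s: np.ndarray
    block_index: np.ndarray  # 1-based
    outcome_if_action: np.ndarray  # bool
    outcome_if_no_action: np.ndarray  # bool
    judgment_times_s: np.ndarray

    def __post_init__(self) -> None:
        n = self.config.n_trials
        for name in ("iti_s", "trial_onsets_s", "block_index",
                     "outcome_if_action", "outcome_if_no_action"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length n_trials={n}")
        if np.any(np.diff(self.trial_onsets_s) <= 0):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.config.n_trials

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(1, self.n_trials + 1),
                "block_index": self.block_index,
                "onset_s": self.trial_onsets_s,
                "iti_s": self.iti_s,
                "outcome_if_action": self.outcome_if_action.astype(int),
                "outcome_if_no_action": self.outcome_if_no_action.astype(int),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        """Write the per-trial table plus a JSON sidecar (config hash, seed)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "config_hash": self.config.config_hash(),
            "config": self.config.model_dump(),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def generate_schedule(config: ExperimentConfig, seed: int) -> TrialSchedule:
    """Build the full planned timeline for one session.

    Trial k starts after the k-th intertrial interval (and the preceding
    trial's 6-second anatomy); a judgment probe is scheduled immediately at
    the end of every ``block_size``-th trial.  Deterministic in
    (config, seed).
    """
    ss = np.random.SeedSequence(seed)
    iti_rng, outcome_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n = config.n_trials
    iti = fleshler_hoffman_intervals(n, config.mean_iti_s, iti_rng)
    dur = config.trial_duration_s
    # onset_k = sum of ITIs 1..k + (k-1) trial durations
    onsets = np.cumsum(iti) + dur * np.arange(n)
    block_index = np.arange(n) // config.block_size + 1
    out_a = outcome_rng.random(n) < config.p_outcome_given_action
    out_na = outcome_rng.random(n) < config.p_outcome_given_no_action
    probe_trials = np.arange(1, config.n_blocks + 1) * config.block_size - 1
    judgment_times = onsets[probe_trials] + dur
    return TrialSchedule(
        config=config,
        seed=seed,
        iti_s=iti,
        trial_onsets_s=onsets,
        block_index=block_index,
        outcome_if_action=out_a,
        outcome_if_no_action=out_na,
        judgment_times_s=judgment_times,
    )


def scheduled_session_duration(schedule: TrialSchedule) -> float:
    """Total planned session length in seconds.

    Sum of all intertrial intervals plus ``n_trials`` trial durations;
    judgment-probe dwell time is zero in the planned timeline (real response
    latencies belong to the event log, not the schedule).
    """
    cfg = schedule.config
    return float(schedule.iti_s.sum() + cfg.n_trials * cfg.trial_duration_s)
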