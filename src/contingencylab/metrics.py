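"""Experienced contingency and engagement statistics from session logs.

The normative contingency metric ΔP = P(O|A) − P(O|~A) is computed from the
2×2 event frequencies over *engaged* trials only (a missed trial carries
neither action nor outcome; misses are tallied separately):

    a : action & outcome        b : action & no outcome
    c : no action & outcome     d : no action & no outcome

Conditional probabilities are reported as explicitly undefined (``None``)
when their denominator is empty — never coerced to 0 or silently NaN — so
downstream covariate handling must impute or drop by its own rules.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .config import ExperimentConfig
    from .participants import SessionLog


@dataclasses.dataclass(frozen=True)
class ContingencySummary:
    """2×2 event frequencies and derived experience statistics."""

    a: int
    b: int
    c: int
    d: int
    n_missed: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.n_missed) < 0:
            raise ValueError("event counts must be non-negative")

    @property
    def n_engaged(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p_o_given_a(self) -> float | None:
        """P(outcome | action); None when the participant never acted."""
        n_act = self.a + self.b
        return self.a / n_act if n_act else None

    @property
    def p_o_given_not_a(self) -> float | None:
        n_no = self.c + self.d
        return self.c / n_no if n_no else None

    @property
    def delta_p(self) -> float | None:
        """P(O|A) − P(O|~A); None when either conditional is undefined."""
        p1, p0 = self.p_o_given_a, self.p_o_given_not_a
        if p1 is None or p0 is None:
            return None
        return p1 - p0

    @property
    def outcome_density(self) -> float | None:
        """P(O) over engaged trials; None when every trial was missed."""
        return (self.a + self.c) / self.n_engaged if self.n_engaged else None

    @property
    def press_proportion(self) -> float | None:
        return (self.a + self.b) / self.n_engaged if self.n_engaged else None


def tabulate_events(
    session: "SessionLog", through_block: int | None = None
) -> ContingencySummary:
    """Tally the 2×2 frequencies from a session log.

    ``through_block`` restricts the tally to blocks 1..through_block
    (cumulative, session-so-far), matching a judge who integrates all
    experience to date; ``None`` uses the whole session.
    """
    trials = session.trials
    n_blocks = session.config.n_blocks
    if through_block is not None:
        if not 1 <= through_block <= n_blocks:
            raise ValueError(
                f"through_block must be in 1..{n_blocks}, got {through_block}"
            )
        trials = trials[trials["block_index"] <= through_block]
    engaged = trials["engaged"].to_numpy(bool)
    action = trials["action"].to_numpy(bool)
    outcome = trials["outcome"].to_numpy(bool)
    return ContingencySummary(
        a=int(np.sum(engaged & action & outcome)),
        b=int(np.sum(engaged & action & ~outcome)),
        c=int(np.sum(engaged & ~action & outcome)),
        d=int(np.sum(engaged & ~action & ~outcome)),
        n_missed=int(np.sum(~engaged)),
    )


def programmed_delta_p(config: "ExperimentConfig") -> float:
    """The contingency programmed into a config: P(O|A) − P(O|~A), exactly."""
    return config.p_outcome_given_action - config.p_outcome_given_no_action


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return np.nan, np.nan
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
    return mean, se


def cohort_validation_report(logs: Sequence["SessionLog"]) -> pd.DataFrame:
    """Per-arm and overall experience statistics (mean and SE = sd/√n).

    One row overall, one per density arm and one per instruction arm, with
    mean/SE of experienced ΔP, outcome density, press proportion and missed
    trials.  SEs are NaN (undefined) for single-log groups; so are ΔP means
    when no log in the group has a defined ΔP.
    """
    if not logs:
        raise ValueError("cohort_validation_report requires at least one log")
    records = []
    for log in logs:
        s = tabulate_events(log)
        records.append(
            {
                "participant_id": log.participant_id,
                "density_arm": log.profile.density_arm,
                "instruction_arm": log.profile.instruction_arm,
                "delta_p": s.delta_p,
                "outcome_density": s.outcome_density,
                "press_proportion": s.press_proportion,
                "n_missed": s.n_missed,
            }
        )
    per = pd.DataFrame(records)

    def row(label: str, sub: pd.DataFrame) -> dict:
        out: dict = {"group": label, "n": len(sub)}
        for col in ("delta_p", "outcome_density", "press_proportion", "n_missed"):
            mean, se = _mean_se(sub[col].tolist())
            out[f"{col}_mean"] = mean
            out[f"{col}_se"] = se
        return out

    rows = [row("overall", per)]
    for arm in ("low", "high"):
        sub = per[per["density_arm"] == arm]
        if len(sub):
            rows.append(row(f"density={arm}", sub))
    for arm in ("discrete", "dynamic"):
        sub = per[per["instruction_arm"] == arm]
        if len(sub):
            rows.append(row(f"instruction={arm}", sub))
    return pd.DataFrame(rows)
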