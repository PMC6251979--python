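"""Regression-based multiple imputation of missing block ratings.

Missing judgments (participants skip ~10.6% of probes in the field) are
replaced by chained-equation regression imputation: each block's rating is
regressed on the other blocks plus the design factors and the experienced-ΔP
covariate, and missing cells are drawn from the fitted predictive
distribution (linear prediction + Gaussian residual noise), sweeping the
columns several times so imputed predictors stabilize.  Several completed
datasets are generated in order; by convention the analysis uses the fifth.
Imputed values are clipped to the bounded rating instrument; observed cells
are never altered.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .metrics import tabulate_events

#: Columns sweep order and count of judgment blocks.
N_BLOCKS_DEFAULT = 5


@dataclasses.dataclass
class JudgmentMatrix:
    """Participants × blocks rating matrix with aligned design metadata.

    ``ratings``: DataFrame indexed by participant_id with one column per
    block (1..n_blocks), NaN for missing.  ``metadata``: DataFrame on the
    same index with bdi_group, density_arm, instruction_arm and the
    experienced-ΔP covariate ``delta_p`` (NaN when undefined for a
    participant).
    """

    ratings: pd.DataFrame
    metadata: pd.DataFrame
    rating_min: float = -100.0
    rating_max: float = 100.0

    def __post_init__(self) -> None:
        if not self.ratings.index.equals(self.metadata.index):
            raise ValueError("ratings and metadata must share an index")
        observed = self.ratings.to_numpy(float)
        present = observed[~np.isnan(observed)]
        if len(present) and (
            present.min() < self.rating_min or present.max() > self.rating_max
        ):
            raise ValueError("observed ratings outside the instrument scale")

    @property
    def n_blocks(self) -> int:
        return self.ratings.shape[1]

    def copy(self) -> "JudgmentMatrix":
        return JudgmentMatrix(
            self.ratings.copy(), self.metadata.copy(), self.rating_min, self.rating_max
        )

    def to_long(self) -> pd.DataFrame:
        """Long format for the inference layer: one row per participant×block."""
        long = (
            self.ratings.rename_axis("participant_id")
            .reset_index()
            .melt(id_vars="participant_id", var_name="block", value_name="rating")
        )
        long["block"] = long["block"].astype(int)
        merged = long.merge(
            self.metadata.rename_axis("participant_id").reset_index(),
            on="participant_id",
        )
        return merged.sort_values(["participant_id", "block"]).reset_index(drop=True)


def judgment_matrix_from_logs(logs: Sequence) -> JudgmentMatrix:
    """Assemble a JudgmentMatrix from simulated/recorded session logs.

    The experienced-ΔP covariate is tabulated over each full session;
    participants with an undefined ΔP (never acted, or always acted) get NaN.
    """
    if not logs:
        raise ValueError("no session logs supplied")
    n_blocks = logs[0].config.n_blocks
    ratings = {}
    meta = []
    for log in logs:
        ratings[log.participant_id] = np.asarray(log.judgments, dtype=float)
        summary = tabulate_events(log)
        meta.append(
            {
                "participant_id": log.participant_id,
                "bdi_group": log.profile.bdi_group,
                "density_arm": log.profile.density_arm,
                "instruction_arm": log.profile.instruction_arm,
                "delta_p": np.nan if summary.delta_p is None else summary.delta_p,
            }
        )
    ratings_df = pd.DataFrame.from_dict(
        ratings, orient="index", columns=range(1, n_blocks + 1)
    )
    meta_df = pd.DataFrame(meta).set_index("participant_id")
    meta_df = meta_df.loc[ratings_df.index]
    cfg = logs[0].config
    return JudgmentMatrix(
        ratings_df,
        meta_df,
        rating_min=cfg.rating_scale_min,
        rating_max=cfg.rating_scale_max,
    )


def _design_predictors(metadata: pd.DataFrame) -> np.ndarray:
    """0/1 dummies for the design factors plus the centered ΔP covariate."""
    cols = []
    if "bdi_group" in metadata:
        cols.append((metadata["bdi_group"] == "high").to_numpy(float))
    if "density_arm" in metadata:
        cols.append((metadata["density_arm"] == "high").to_numpy(float))
    if "instruction_arm" in metadata:
        cols.append((metadata["instruction_arm"] == "dynamic").to_numpy(float))
    if "delta_p" in metadata:
        dp = metadata["delta_p"].to_numpy(float)
        dp = np.where(np.isnan(dp), np.nanmean(dp) if not np.all(np.isnan(dp)) else 0.0, dp)
        cols.append(dp - dp.mean())
    if not cols:
        return np.empty((len(metadata), 0))
    return np.column_stack(cols)


def impute(
    matrix: JudgmentMatrix,
    n_imputations: int = 5,
    seed: int | None = None,
    n_sweeps: int = 10,
) -> list[JudgmentMatrix]:
    """Generate ``n_imputations`` completed matrices by chained regression.

    Preconditions: every participant has at least one observed rating and
    every block column at least two; violations raise :class:`DataError`
    naming the offender.  Deterministic under ``seed``; completed datasets
    are returned in generation order.
    """
    ratings = matrix.ratings.to_numpy(float)
    n, k = ratings.shape
    missing = np.isnan(ratings)

    empty_rows = np.where(missing.all(axis=1))[0]
    if len(empty_rows):
        who = ", ".join(str(matrix.ratings.index[i]) for i in empty_rows)
        raise DataError(f"participant(s) with no observed rating: {who}")
    thin_cols = np.where((~missing).sum(axis=0) < 2)[0]
    if len(thin_cols):
        which = ", ".join(str(matrix.ratings.columns[j]) for j in thin_cols)
        raise DataError(f"block column(s) with fewer than 2 observed values: {which}")

    if not missing.any():
        return [matrix.copy() for _ in range(n_imputations)]

    design = _design_predictors(matrix.metadata)
    col_means = np.nanmean(ratings, axis=0)
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_imputations)]

    completed: list[JudgmentMatrix] = []
    for rng in rngs:
        filled = ratings.copy()
        filled[missing] = np.take(col_means, np.where(missing)[1])
        for _ in range(n_sweeps):
            for j in range(k):
                miss_j = missing[:, j]
                if not miss_j.any():
                    continue
                others = np.delete(filled, j, axis=1)
                X = np.column_stack([np.ones(n), others, design])
                obs = ~miss_j
                beta, *_ = np.linalg.lstsq(X[obs], filled[obs, j], rcond=None)
                resid = filled[obs, j] - X[obs] @ beta
                dof = obs.sum() - np.linalg.matrix_rank(X[obs])
                sigma = np.sqrt(max(resid @ resid, 0.0) / dof) if dof > 0 else 0.0
                draw = X[miss_j] @ beta + rng.normal(0.0, 1.0, miss_j.sum()) * sigma
                filled[miss_j, j] = np.clip(draw, matrix.rating_min, matrix.rating_max)
        out = matrix.copy()
        out.ratings.iloc[:, :] = filled
        completed.append(out)
    return completed


def select_analysis_set(imputations: Sequence[JudgmentMatrix]) -> JudgmentMatrix:
    """Return the fifth completed dataset (the convention analyzed downstream).

    A single generated imputation — not a pooled estimate — is carried into
    the ANCOVA; use :func:`pool_imputations` for the pooled alternative.
    """
    if len(imputations) < 5:
        raise ValueError(
            f"need at least 5 imputations to select the fifth, got {len(imputations)}"
        )
    return imputations[4]


def pool_imputations(imputations: Sequence[JudgmentMatrix]) -> JudgmentMatrix:
    """Cell-wise average of the completed datasets.

    Averaging predictive draws shrinks imputation noise (the spirit of
    pooling estimates across imputations, applied at the data level); for
    fully standard pooled inference, fit the model per imputation and
    combine estimates instead.
    """
    if not imputations:
        raise ValueError("no imputations to pool")
    out = imputations[0].copy()
    stacked = np.stack([m.ratings.to_numpy(float) for m in imputations])
    out.ratings.iloc[:, :] = stacked.mean(axis=0)
    return out
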