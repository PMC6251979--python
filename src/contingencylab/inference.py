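"""Mixed between/within ANCOVA on control judgments, with partial-η² effect
sizes, noncentral-F confidence limits, single-sample t tests and
pooled-error simple effects.

The design is a split-plot: participants are crossed on up to three
between-subject factors (BDI group, outcome density, instruction arm) and
rate their control repeatedly over judgment blocks (the within factor); the
contingency each participant actually experienced (ΔP) enters as a
between-level covariate.  The model is fitted in two strata:

* between stratum — participant mean ratings regressed on the sum-coded
  factorial design plus the grand-mean-centered covariate; Type-III
  (drop-term) sums of squares, scaled by the number of blocks so they sit on
  the per-observation scale; error = participants-within-cells.
* within stratum — participant-centered ratings regressed on all terms
  involving the within factor; error = block × participant residual.

Sum-to-zero coding makes the Type-III tests invariant to the (unbalanced)
group sizes.  Partial η² = SS_effect / (SS_effect + SS_error); its
confidence interval comes from inverting the noncentral-F distribution and
mapping the noncentrality λ to η² via λ/(λ + df1 + df2 + 1).
"""

from __future__ import annotations

import dataclasses
import json
import re
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from .errors import DataError, DesignError, NumericError

ALPHA = 0.05  # decision threshold used throughout the reporting layer

_SUM_TERM = re.compile(r"C\(([^,()]+), Sum\)")


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def f_p_value(f: float, df1: int, df2: int) -> float:
    """Upper-tail central-F probability for an observed F statistic."""
    if f < 0:
        raise ValueError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.sf(f, df1, df2))


def partial_eta_sq_from_f(f: float, df1: int, df2: int) -> float:
    """Partial η² recovered from an F statistic: F·df1 / (F·df1 + df2)."""
    if f < 0:
        raise ValueError("F must be >= 0")
    return float(f * df1 / (f * df1 + df2))


def _lambda_to_eta(lam: float, df1: int, df2: int) -> float:
    return lam / (lam + df1 + df2 + 1)


def eta_ci(
    f: float, df1: int, df2: int, level: float = 0.90
) -> tuple[float, float]:
    """Noncentral-F confidence limits for partial η².

    Finds the noncentrality parameters λ_lo, λ_hi at which the observed F
    sits at the (1−α/2) and α/2 quantiles of the noncentral F distribution,
    then maps each λ to partial η² via λ/(λ+df1+df2+1).  A bound collapses
    to 0 when the quantile equation has no positive root (e.g. small F).
    """
    if f < 0:
        raise ValueError("F must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level

    def solve(target: float) -> float:
        # ncf.cdf is decreasing in λ; at λ=0 it equals the central cdf.
        if stats.ncf.cdf(f, df1, df2, 1e-12) <= target:
            return 0.0
        lo, hi = 0.0, max(8.0, 4.0 * (f * df1 + df1))
        for _ in range(200):
            if stats.ncf.cdf(f, df1, df2, hi) < target:
                break
            lo, hi = hi, hi * 2.0
        else:  # pragma: no cover - pathological inputs
            raise NumericError(
                f"noncentrality bracketing failed (F={f}, df=({df1},{df2}), "
                f"target={target})"
            )
        from scipy.optimize import brentq

        return float(
            brentq(
                lambda lam: stats.ncf.cdf(f, df1, df2, lam) - target,
                lo,
                hi,
                xtol=1e-8,
            )
        )

    lam_lo = solve(1.0 - alpha / 2.0)
    lam_hi = solve(alpha / 2.0)
    lower = _lambda_to_eta(lam_lo, df1, df2)
    upper = _lambda_to_eta(lam_hi, df1, df2)
    if lower > upper:  # pragma: no cover - construction error guard
        raise NumericError("confidence-limit inversion produced lower > upper")
    return lower, upper


def one_sample_t(ratings: Sequence[float], mu: float = 0.0) -> dict:
    """Single-sample t test of mean rating against a criterion value.

    The criterion defaults to 0, the accurate rating for a null contingency;
    a significant positive t evidences illusory control.
    """
    arr = np.asarray(ratings, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("one_sample_t requires at least 2 observations")
    if np.allclose(arr.std(ddof=1), 0.0):
        raise NumericError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(arr, popmean=mu)
    return {
        "t": float(res.statistic),
        "df": int(arr.size - 1),
        "p": float(res.pvalue),
        "mean": float(arr.mean()),
        "se": float(arr.std(ddof=1) / np.sqrt(arr.size)),
    }


# ---------------------------------------------------------------------------
# the mixed ANCOVA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnovaTable:
    """Effect rows plus the two error terms of the split-plot fit."""

    rows: pd.DataFrame
    between_error_ss: float
    between_error_df: int
    within_error_ss: float | None
    within_error_df: int | None
    n_blocks: int

    @property
    def between_error_ms(self) -> float:
        return self.between_error_ss / self.between_error_df

    @property
    def within_error_ms(self) -> float | None:
        if self.within_error_ss is None or not self.within_error_df:
            return None
        return self.within_error_ss / self.within_error_df

    def effect(self, name: str) -> pd.Series:
        match = self.rows[self.rows["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect named {name!r} in the table")
        return match.iloc[0]

    def to_json(self, path=None) -> str:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "between_error": {
                "ss": self.between_error_ss,
                "df": self.between_error_df,
                "ms": self.between_error_ms,
            },
            "within_error": None
            if self.within_error_ss is None
            else {
                "ss": self.within_error_ss,
                "df": self.within_error_df,
                "ms": self.within_error_ms,
            },
            "n_blocks": self.n_blocks,
        }
        def _coerce(obj):
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            raise TypeError(f"not JSON serializable: {type(obj)}")

        text = json.dumps(payload, indent=2, default=_coerce)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = ["effect                                SS      df        MS         F       p    pη²   90% CI"]
        for _, r in self.rows.iterrows():
            ci = f"[{r.eta_ci_low:.4f}, {r.eta_ci_high:.4f}]"
            lines.append(
                f"{r.effect:<32}{r.ss:>10.2f}{r.df:>6d}{r.ms:>10.2f}"
                f"{r.f:>10.3f}{r.p:>8.3f}{r.partial_eta_sq:>7.3f}   {ci}"
            )
        lines.append(
            f"{'error (between)':<32}{self.between_error_ss:>10.2f}"
            f"{self.between_error_df:>6d}{self.between_error_ms:>10.2f}"
        )
        if self.within_error_ss is not None:
            lines.append(
                f"{'error (within)':<32}{self.within_error_ss:>10.2f}"
                f"{self.within_error_df:>6d}{self.within_error_ms:>10.2f}"
            )
        return "\n".join(lines)


def _clean_term(term: str) -> str:
    return _SUM_TERM.sub(r"\1", term)


def _drop_term_ss(
    X: np.ndarray, y: np.ndarray, slices: dict[str, slice]
) -> tuple[dict[str, tuple[float, int]], float, int]:
    """Type-III sums of squares by refitting without each term's columns."""
    n = len(y)
    beta, _, rank_full, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse_full = float(resid @ resid)
    out: dict[str, tuple[float, int]] = {}
    for term, slc in slices.items():
        keep = np.ones(X.shape[1], bool)
        keep[slc] = False
        Xr = X[:, keep]
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        ss = max(float(rr @ rr) - sse_full, 0.0)
        out[term] = (ss, slc.stop - slc.start)
    return out, sse_full, n - rank_full


def _effect_row(
    effect: str, stratum: str, ss: float, df: int, err_ss: float, err_df: int
) -> dict:
    ms = ss / df
    mse = err_ss / err_df if err_df > 0 else 0.0
    if ss <= 1e-12:
        f = 0.0
    elif mse == 0.0:
        f = np.inf
    else:
        f = ms / mse
    p = f_p_value(f, df, err_df) if np.isfinite(f) else 0.0
    eta = ss / (ss + err_ss) if (ss + err_ss) > 0 else 0.0
    if np.isfinite(f):
        lo, hi = eta_ci(f, df, err_df)
    else:  # zero residual error: effect size is exactly 1
        lo, hi = 1.0, 1.0
    return {
        "effect": effect,
        "stratum": stratum,
        "ss": ss,
        "df": df,
        "ms": ms,
        "f": f,
        "p": p,
        "partial_eta_sq": eta,
        "eta_ci_low": lo,
        "eta_ci_high": hi,
    }


def mixed_ancova(
    data: pd.DataFrame,
    between: Sequence[str] = ("bdi_group", "density_arm", "instruction_arm"),
    within: str | None = "block",
    covariate: str | None = "delta_p",
    subject: str = "participant_id",
    response: str = "rating",
) -> AnovaTable:
    """Fit the mixed factorial ANCOVA and return the full effect table.

    ``data`` is long format (one row per subject × within level) with factor
    columns, the response, and an optionally NaN-free numeric covariate that
    is constant within subject (a per-subject mean is taken otherwise).  The
    within data must be complete — impute first.
    """
    data = data.copy()
    for col in (*between, subject, response):
        if col not in data:
            raise ValueError(f"column {col!r} missing from data")

    # empty-cell guard over the full factor cross
    levels = [sorted(data[f].unique()) for f in between]
    counts = data.groupby(list(between), observed=False)[subject].nunique()
    empty = []
    for combo in product(*levels):
        key = combo if len(combo) > 1 else combo[0]
        if key not in counts.index or counts.loc[key] == 0:
            empty.append(dict(zip(between, combo)))
    if empty:
        raise DesignError(f"empty between-subject cell(s): {empty}")

    if within is not None and within in data and data[within].nunique() > 1:
        blocks = sorted(data[within].unique())
        n_blocks = len(blocks)
        pivot = data.pivot_table(
            index=subject, columns=within, values=response, aggfunc="size", fill_value=0
        )
        if not (pivot == 1).all().all():
            raise DataError(
                "each subject needs exactly one response per within level; "
                "impute missing judgments before the ANCOVA"
            )
    else:
        within = None
        n_blocks = 1

    # participant-level table (between stratum)
    sub = data.groupby(subject, observed=False).agg(
        **{response: (response, "mean")},
        **{f: (f, "first") for f in between},
    )
    if covariate is not None:
        if covariate not in data:
            raise ValueError(f"covariate column {covariate!r} missing from data")
        cov = data.groupby(subject, observed=False)[covariate].mean()
        if cov.isna().any():
            raise DataError(
                f"covariate {covariate!r} missing for subjects: "
                f"{list(cov[cov.isna()].index)}"
            )
        sub["_cov_c"] = cov - cov.mean()

    between_formula = " * ".join(f"C({f}, Sum)" for f in between)
    formula = between_formula + (" + _cov_c" if covariate is not None else "")
    Xb = dmatrix(formula, sub, return_type="dataframe")
    slices = {
        t: s
        for t, s in Xb.design_info.term_name_slices.items()
        if t != "Intercept"
    }
    yb = sub[response].to_numpy(float)
    ss_map, sse_b, df_err_b = _drop_term_ss(Xb.to_numpy(), yb, slices)
    if df_err_b <= 0:
        raise DesignError("no residual degrees of freedom in the between stratum")

    scale = float(n_blocks)
    rows = []
    for term, (ss, df) in ss_map.items():
        label = covariate if term == "_cov_c" else _clean_term(term)
        stratum = "covariate" if term == "_cov_c" else "between"
        rows.append(
            _effect_row(label, stratum, ss * scale, df, sse_b * scale, df_err_b)
        )

    within_err_ss = within_err_df = None
    if within is not None:
        centered = data.copy()
        centered["_w"] = centered[response] - centered.groupby(subject, observed=False)[
            response
        ].transform("mean")
        wf = f"C({within}, Sum) * ({between_formula})"
        Xw_full = dmatrix(wf, centered, return_type="dataframe")
        w_slices = {
            t: s
            for t, s in Xw_full.design_info.term_name_slices.items()
            if f"C({within}, Sum)" in t
        }
        # keep only columns of within-involving terms, re-indexed
        cols: list[int] = []
        new_slices: dict[str, slice] = {}
        for t, s in w_slices.items():
            start = len(cols)
            cols.extend(range(s.start, s.stop))
            new_slices[t] = slice(start, len(cols))
        Xw = Xw_full.to_numpy()[:, cols]
        yw = centered["_w"].to_numpy(float)
        n_sub = data[subject].nunique()
        ss_w, sse_w, _ = _drop_term_ss(Xw, yw, new_slices)
        rank_w = np.linalg.matrix_rank(Xw)
        within_err_df = n_sub * (n_blocks - 1) - rank_w
        within_err_ss = sse_w
        if within_err_df <= 0:
            raise DesignError("no residual degrees of freedom in the within stratum")
        for term, (ss, df) in ss_w.items():
            rows.append(
                _effect_row(_clean_term(term), "within", ss, df, sse_w, within_err_df)
            )

    return AnovaTable(
        rows=pd.DataFrame(rows),
        between_error_ss=sse_b * scale,
        between_error_df=df_err_b,
        within_error_ss=within_err_ss,
        within_error_df=within_err_df,
        n_blocks=n_blocks,
    )


# ---------------------------------------------------------------------------
# simple effects
# ---------------------------------------------------------------------------

def pooled_block_mse(between_error_ms: float, n_blocks: int) -> float:
    """Simple-effects error term: the omnibus between-cell MSE averaged over
    the judgment blocks (MSE_omnibus / n_blocks)."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return between_error_ms / n_blocks


def simple_effects(
    table: AnovaTable,
    data: pd.DataFrame,
    factor: str,
    within_level_of: str,
    subject: str = "participant_id",
    response: str = "rating",
) -> pd.DataFrame:
    """Test ``factor`` separately at each level of a moderating factor.

    Each test uses participant mean ratings and the pooled error mean square
    MSE_omnibus / n_blocks with the omnibus between-error df — the follow-up
    appropriate after a significant ``factor × moderator`` interaction.
    """
    for col in (factor, within_level_of):
        if col not in data:
            raise ValueError(f"unknown factor {col!r}")
    interaction = {factor, within_level_of}
    has_interaction = any(
        set(e.split(":")) == interaction for e in table.rows["effect"]
    )
    if not has_interaction:
        raise ValueError(
            f"table has no {factor} × {within_level_of} interaction to follow up"
        )
    sub = data.groupby(subject, observed=False).agg(
        **{response: (response, "mean")},
        **{factor: (factor, "first"), within_level_of: (within_level_of, "first")},
    )
    mse = pooled_block_mse(table.between_error_ms, table.n_blocks)
    df2 = table.between_error_df
    out = []
    for level, grp in sub.groupby(within_level_of, observed=False):
        means = grp.groupby(factor, observed=False)[response].agg(["mean", "size"])
        if len(means) < 2:
            continue
        grand = np.average(means["mean"], weights=means["size"])
        ss = float((means["size"] * (means["mean"] - grand) ** 2).sum())
        df1 = len(means) - 1
        ms = ss / df1
        f = 0.0 if ss <= 1e-12 else (ms / mse if mse > 0 else np.inf)
        p = f_p_value(f, df1, df2) if np.isfinite(f) else 0.0
        eta = partial_eta_sq_from_f(f, df1, df2) if np.isfinite(f) else 1.0
        lo, hi = eta_ci(f, df1, df2) if np.isfinite(f) else (1.0, 1.0)
        out.append(
            {
                "moderator": within_level_of,
                "moderator_level": level,
                "effect": factor,
                "ss": ss,
                "df1": df1,
                "df2": df2,
                "ms_error": mse,
                "f": f,
                "p": p,
                "partial_eta_sq": eta,
                "eta_ci_low": lo,
                "eta_ci_high": hi,
                **{
                    f"mean_{lvl}": float(m)
                    for lvl, m in means["mean"].items()
                },
            }
        )
    return pd.DataFrame(out)
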