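"""Mixed ANCOVA, effect sizes, noncentral-F limits, t tests, simple effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm
from statsmodels.formula.api import ols

from contingencylab import (
    DataError,
    DesignError,
    NumericError,
    eta_ci,
    f_p_value,
    mixed_ancova,
    one_sample_t,
    partial_eta_sq_from_f,
    pooled_block_mse,
    simple_effects,
)


class TestScalarStatistics:
    @pytest.mark.parametrize(
        "f,df1,df2,expected",
        [(4.05, 1, 91, 0.047), (7.05, 1, 91, 0.009), (0.0, 1, 10, 1.0)],
    )
    def test_f_p_value(self, f, df1, df2, expected):
        assert round(f_p_value(f, df1, df2), 3) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "f,df1,df2,expected",
        [(4.05, 1, 91, 0.04), (7.05, 1, 91, 0.07), (0.0, 1, 91, 0.0)],
    )
    def test_partial_eta_sq_from_f(self, f, df1, df2, expected):
        assert round(partial_eta_sq_from_f(f, df1, df2), 2) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            f_p_value(-1.0, 1, 10)
        with pytest.raises(ValueError):
            f_p_value(1.0, 0, 10)
        with pytest.raises(ValueError):
            eta_ci(1.0, 1, 10, level=1.5)


class TestEtaConfidenceLimits:
    @pytest.mark.parametrize(
        "f,expected",
        [(7.05, (0.01, 0.1674)), (6.06, (0.0064, 0.1548))],
    )
    def test_noncentral_inversion_matches_known_intervals(self, f, expected):
        lo, hi = eta_ci(f, 1, 91, level=0.90)
        assert lo == pytest.approx(expected[0], abs=0.005)
        assert hi == pytest.approx(expected[1], abs=0.005)

    def test_zero_f_collapses_lower_bound(self):
        lo, hi = eta_ci(0.0, 1, 91)
        assert lo == 0.0
        assert hi == 0.0

    def test_interval_ordered_and_bounded(self):
        for f in (0.1, 1.0, 3.0, 10.0, 40.0):
            lo, hi = eta_ci(f, 1, 50)
            assert 0.0 <= lo <= hi <= 1.0

    def test_width_shrinks_with_error_df(self):
        widths = []
        for df2 in (20, 80, 320, 1280):
            lo, hi = eta_ci(4.0, 1, df2)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_consistency_with_ss_ratio_definition(self):
        # partial eta from F agrees with SS_eff/(SS_eff+SS_err) identically
        rng = np.random.default_rng(2)
        for _ in range(20):
            ss_eff, ss_err = rng.uniform(0.1, 100, 2)
            df1, df2 = int(rng.integers(1, 5)), int(rng.integers(5, 200))
            f = (ss_eff / df1) / (ss_err / df2)
            assert partial_eta_sq_from_f(f, df1, df2) == pytest.approx(
                ss_eff / (ss_eff + ss_err), rel=1e-12
            )


class TestOneSampleT:
    def test_symmetric_vector(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(3.464, abs=1e-3)
        assert res["df"] == 2

    def test_zero_variance(self):
        with pytest.raises(NumericError):
            one_sample_t([5.0, 5.0, 5.0])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])


def two_group_fixture(rng, n1=14, n2=16):
    return pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n1 + n2)],
            "group": ["a"] * n1 + ["b"] * n2,
            "rating": rng.normal(0, 1, n1 + n2),
        }
    )


def cohort_long(rng, n_per_cell=6, effects=None, n_blocks=5):
    """Balanced 2×2×2×(blocks) long data with configurable cell effects."""
    effects = effects or {}
    rows = []
    pid = 0
    for bdi in ("low", "high"):
        for density in ("low", "high"):
            for instr in ("discrete", "dynamic"):
                for _ in range(n_per_cell):
                    pid += 1
                    intercept = rng.normal(0, 5)
                    dp = rng.normal(0, 0.1)
                    for block in range(1, n_blocks + 1):
                        mu = effects.get((bdi, density, instr), 0.0)
                        rows.append(
                            {
                                "participant_id": f"s{pid:03d}",
                                "bdi_group": bdi,
                                "density_arm": density,
                                "instruction_arm": instr,
                                "block": block,
                                "delta_p": dp,
                                "rating": mu + intercept + rng.normal(0, 3),
                            }
                        )
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            df = two_group_fixture(rng)
            table = mixed_ancova(df, between=("group",), within=None, covariate=None)
            t = stats.ttest_ind(
                df[df.group == "a"].rating, df[df.group == "b"].rating
            )
            row = table.effect("group")
            assert row["f"] == pytest.approx(t.statistic**2, rel=1e-10)
            assert row["p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_between_stratum_matches_statsmodels_type3(self):
        """Independent oracle: Type-III ANOVA on participant means."""
        rng = np.random.default_rng(8)
        long = cohort_long(rng, n_per_cell=5)
        # unbalance the design: drop two participants
        drop = long["participant_id"].isin(["s001", "s017"])
        long = long[~drop]
        table = mixed_ancova(long, covariate=None)

        sub = long.groupby("participant_id", observed=False).agg(
            rating=("rating", "mean"),
            bdi_group=("bdi_group", "first"),
            density_arm=("density_arm", "first"),
            instruction_arm=("instruction_arm", "first"),
        )
        fit = ols(
            "rating ~ C(bdi_group, Sum) * C(density_arm, Sum) "
            "* C(instruction_arm, Sum)",
            data=sub,
        ).fit()
        oracle = sm.stats.anova_lm(fit, typ=3)
        n_blocks = 5
        mapping = {
            "bdi_group": "C(bdi_group, Sum)",
            "density_arm": "C(density_arm, Sum)",
            "density_arm:instruction_arm":
                "C(density_arm, Sum):C(instruction_arm, Sum)",
            "bdi_group:density_arm:instruction_arm":
                "C(bdi_group, Sum):C(density_arm, Sum):C(instruction_arm, Sum)",
        }
        for effect, term in mapping.items():
            row = table.effect(effect)
            assert row["ss"] == pytest.approx(
                oracle.loc[term, "sum_sq"] * n_blocks, rel=1e-8
            )
            assert row["f"] == pytest.approx(oracle.loc[term, "F"], rel=1e-8)
        assert table.between_error_ss == pytest.approx(
            oracle.loc["Residual", "sum_sq"] * n_blocks, rel=1e-8
        )

    def test_no_effect_means_zero_ss(self):
        # identical cell means and zero residuals: factor SS and F collapse to 0
        rows = []
        for i, grp in enumerate(["a"] * 4 + ["b"] * 4):
            rows.append({"participant_id": f"s{i}", "group": grp,
                         "other": "x" if i % 2 else "y", "rating": 1.0})
        df = pd.DataFrame(rows)
        table = mixed_ancova(df, between=("group", "other"), within=None,
                             covariate=None)
        row = table.effect("group")
        assert row["ss"] == pytest.approx(0.0, abs=1e-9)
        assert row["f"] == 0.0

    def test_empty_cell_raises(self):
        rng = np.random.default_rng(9)
        long = cohort_long(rng, n_per_cell=3)
        broken = long[
            ~((long.bdi_group == "high") & (long.density_arm == "high")
              & (long.instruction_arm == "dynamic"))
        ]
        with pytest.raises(DesignError, match="dynamic"):
            mixed_ancova(broken)

    def test_incomplete_within_data_rejected(self):
        rng = np.random.default_rng(10)
        long = cohort_long(rng, n_per_cell=3)
        gap = (long.participant_id == "s001") & (long.block == 3)
        with pytest.raises(DataError, match="impute"):
            mixed_ancova(long[~gap])

    def test_missing_covariate_rejected(self):
        rng = np.random.default_rng(11)
        long = cohort_long(rng, n_per_cell=3)
        long.loc[long.participant_id == "s002", "delta_p"] = np.nan
        with pytest.raises(DataError, match="s002"):
            mixed_ancova(long)

    def test_within_stratum_detects_block_effect(self):
        rng = np.random.default_rng(12)
        long = cohort_long(rng, n_per_cell=6)
        long["rating"] += long["block"] * 4.0  # strong within effect
        table = mixed_ancova(long)
        assert table.effect("block")["p"] < 1e-6
        assert table.within_error_df == 48 * 4 - 32

    def test_table_serialization(self, tmp_path):
        rng = np.random.default_rng(13)
        table = mixed_ancova(cohort_long(rng, n_per_cell=3))
        text = table.to_json(tmp_path / "anova.json")
        assert "between_error" in text
        assert (tmp_path / "anova.json").exists()
        assert "effect" in table.to_text()


class TestSimpleEffects:
    def test_pooled_error_is_block_averaged_omnibus_mse(self):
        assert pooled_block_mse(6671.40, 5) == pytest.approx(1334.28)

    def test_decomposition_identity_balanced(self):
        """Simple-effect SSs sum to main + interaction SS in a balanced 2×2."""
        rng = np.random.default_rng(14)
        long = cohort_long(rng, n_per_cell=6)
        table = mixed_ancova(long, covariate=None)
        simple = simple_effects(table, long, "density_arm", "instruction_arm")
        total_simple = simple["ss"].sum() * table.n_blocks
        expected = (
            table.effect("density_arm")["ss"]
            + table.effect("density_arm:instruction_arm")["ss"]
        )
        assert total_simple == pytest.approx(expected, rel=1e-8)

    def test_zero_residual_zero_effect(self):
        rows = []
        for i in range(8):
            rows.append(
                {
                    "participant_id": f"s{i}",
                    "density_arm": "low" if i % 2 else "high",
                    "instruction_arm": "discrete" if i < 4 else "dynamic",
                    "bdi_group": "low",
                    "block": 1,
                    "rating": 2.0,
                }
            )
        df = pd.DataFrame(rows)
        table = mixed_ancova(
            df, between=("density_arm", "instruction_arm"), within=None,
            covariate=None,
        )
        simple = simple_effects(table, df, "density_arm", "instruction_arm")
        assert (simple["f"] == 0.0).all()

    def test_unknown_factor_rejected(self):
        rng = np.random.default_rng(15)
        long = cohort_long(rng, n_per_cell=3)
        table = mixed_ancova(long)
        with pytest.raises(ValueError):
            simple_effects(table, long, "nonexistent", "instruction_arm")

    def test_detects_density_effect_only_under_discrete(self):
        rng = np.random.default_rng(16)
        effects = {
            ("low", "high", "discrete"): 25.0,
            ("high", "high", "discrete"): 25.0,
        }
        long = cohort_long(rng, n_per_cell=8, effects=effects)
        table = mixed_ancova(long, covariate=None)
        simple = simple_effects(table, long, "density_arm", "instruction_arm")
        by_level = simple.set_index("moderator_level")
        assert by_level.loc["discrete", "p"] < 0.01
        assert by_level.loc["dynamic", "p"] > 0.05
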