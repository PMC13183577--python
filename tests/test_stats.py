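import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tspforage.stats import (
    DesignError,
    aggregate_by_strategy,
    between_anova_2x2,
    mixed_model_anova,
    rm_anova_2x2x3,
)

warnings.filterwarnings("ignore", module="statsmodels")


def null_rm_table(rng, n_per_cell=9):
    rows = []
    i = 0
    for strain in ("SHR", "WKY"):
        for sex in ("F", "M"):
            for _ in range(n_per_cell):
                i += 1
                for strat in ("L_P", "L_NN", "GLOBAL"):
                    rows.append((f"r{i:02d}", strain, sex, strat, rng.normal()))
    return pd.DataFrame(
        rows, columns=["rat_id", "strain", "sex", "strategy", "value"]
    )


class TestAggregateByStrategy:
    @pytest.fixture
    def measures(self, configs_by_id):
        rows = [
            # rat r1 has prop_opt 0.4 on config 3 and 0.6 on config 6 (both L_P)
            ("r1", "SHR", "F", 3, 0.4),
            ("r1", "SHR", "F", 6, 0.6),
            ("r1", "SHR", "F", 1, 0.9),   # baseline, must be excluded
            ("r2", "WKY", "M", 3, 0.5),   # missing config 6
        ]
        return pd.DataFrame(
            rows, columns=["rat_id", "strain", "sex", "config_id", "prop_opt"]
        )

    def test_category_mean_of_two_configs(self, measures, configs_by_id):
        out = aggregate_by_strategy(measures, configs_by_id)
        r1 = out[(out.rat_id == "r1") & (out.strategy == "L_P")]
        assert r1["prop_opt"].item() == pytest.approx(0.5)

    def test_baseline_configs_excluded(self, measures, configs_by_id):
        out = aggregate_by_strategy(measures, configs_by_id)
        assert "BASELINE" not in set(out["strategy"])

    def test_single_config_mean_is_that_value(self, measures, configs_by_id):
        out = aggregate_by_strategy(measures, configs_by_id)
        r2 = out[(out.rat_id == "r2") & (out.strategy == "L_P")]
        assert r2["prop_opt"].item() == pytest.approx(0.5)


class TestRmAnova:
    def test_matches_r_aov_oracle(self, anova_fixture):
        """F statistics frozen from R: aov(value ~ strain*sex*strategy +
        Error(rat_id/strategy)) on the same seeded dataset."""
        res = rm_anova_2x2x3(anova_fixture, "value")
        expected = {
            "strain": (6.245, 0.0280),
            "sex": (8.667, 0.0123),
            "strain*sex": (2.144, 0.1688),
            "strategy": (15.661, 4.44e-05),
            "strain*strategy": (0.186, 0.831),
            "sex*strategy": (1.135, 0.338),
            "strain*sex*strategy": (0.208, 0.813),
        }
        for term, (F, p) in expected.items():
            assert res[term].F == pytest.approx(F, rel=1e-3, abs=1e-3)
            assert res[term].p == pytest.approx(p, rel=2e-2)
        assert res["strain"].df_den == 12
        assert res["strategy"].df_den == 24

    def test_two_group_collapse_equals_t_squared(self):
        """With one sex and one strategy level the strain F equals the
        squared pooled two-sample t statistic."""
        rng = np.random.default_rng(8)
        rows = []
        for i in range(10):
            rows.append((f"a{i}", "SHR", "F", "L_P", rng.normal(0.5)))
            rows.append((f"b{i}", "WKY", "F", "L_P", rng.normal(0.0)))
        df = pd.DataFrame(
            rows, columns=["rat_id", "strain", "sex", "strategy", "value"]
        )
        res = rm_anova_2x2x3(df, "value")
        t, _ = sps.ttest_ind(
            df[df.strain == "SHR"]["value"], df[df.strain == "WKY"]["value"]
        )
        assert res["strain"].F == pytest.approx(t**2, rel=1e-9)

    def test_location_invariance(self, anova_fixture):
        shifted = anova_fixture.assign(value=anova_fixture["value"] + 37.5)
        a = rm_anova_2x2x3(anova_fixture, "value")
        b = rm_anova_2x2x3(shifted, "value")
        for ta, tb in zip(a.terms, b.terms):
            assert ta.F == pytest.approx(tb.F, rel=1e-9)

    def test_incomplete_table_directs_to_mixed_model(self, anova_fixture):
        with pytest.raises(DesignError, match="mixed_model_anova"):
            rm_anova_2x2x3(anova_fixture.drop(index=[0]), "value")

    def test_zero_variance_raises(self):
        rows = []
        for i in range(8):
            strain = "SHR" if i < 4 else "WKY"
            sex = "F" if i % 2 else "M"
            for strat in ("L_P", "L_NN", "GLOBAL"):
                rows.append((f"r{i}", strain, sex, strat, 1.0))
        df = pd.DataFrame(
            rows, columns=["rat_id", "strain", "sex", "strategy", "value"]
        )
        with pytest.raises(DesignError):
            rm_anova_2x2x3(df, "value")

    def test_null_calibration_quick(self):
        """~5% rejections per term under the null (sharper sweep in
        acceptance)."""
        rng = np.random.default_rng(77)
        hits = {}
        R = 400
        for _ in range(R):
            res = rm_anova_2x2x3(null_rm_table(rng, n_per_cell=5), "value")
            for t in res.terms:
                hits[t.term] = hits.get(t.term, 0) + (t.p < 0.05)
        lo, hi = sps.binom.ppf([0.0005, 0.9995], R, 0.05) / R
        for term, h in hits.items():
            assert lo <= h / R <= hi, (term, h / R)


class TestMixedModel:
    def test_agrees_with_rm_anova_on_balanced_data(self, anova_fixture):
        rm = rm_anova_2x2x3(anova_fixture, "value")
        mm = mixed_model_anova(anova_fixture, "value")
        for t in rm.terms:
            assert mm[t.term].p == pytest.approx(t.p, abs=1e-3)
            assert mm[t.term].df_den == t.df_den

    def test_missing_cells_still_returns_all_terms(self, anova_fixture):
        df = anova_fixture.drop(index=[0, 7, 20]).reset_index(drop=True)
        mm = mixed_model_anova(df, "value")
        assert {t.term for t in mm.terms} == {
            "strain", "sex", "strategy", "strain*sex", "strain*strategy",
            "sex*strategy", "strain*sex*strategy",
        }

    def test_power_against_strong_strain_shift(self):
        """Delta = 3 within-cell SD at n = 5/cell is detected essentially
        always."""
        rng = np.random.default_rng(13)
        hits = 0
        R = 60
        for _ in range(R):
            df = null_rm_table(rng, n_per_cell=5)
            df.loc[df.strain == "SHR", "value"] += 3.0
            # knock one observation out to exercise the unbalanced path
            mm = mixed_model_anova(df.drop(index=[2]), "value")
            hits += mm["strain"].p < 0.05
        assert hits / R >= 0.95

    def test_empty_cell_rejected(self, anova_fixture):
        df = anova_fixture[
            ~((anova_fixture.strain == "SHR") & (anova_fixture.sex == "F"))
        ]
        with pytest.raises(DesignError, match="empty design cell"):
            mixed_model_anova(df, "value")


class TestBetweenAnova:
    def test_matches_r_type3_oracle(self):
        """F statistics frozen from R car::Anova(lm(...), type=3) with sum
        contrasts, on the study-shaped unbalanced cells (5,4,6,4)."""
        rng = np.random.default_rng(99)
        rows = []
        for (strain, sex, n) in [("SHR", "F", 5), ("SHR", "M", 4),
                                 ("WKY", "F", 6), ("WKY", "M", 4)]:
            for i in range(n):
                rows.append(
                    (f"{strain}{sex}{i}", strain, sex,
                     30 + (8 if strain == "SHR" else 0) + rng.normal(0, 6))
                )
        df = pd.DataFrame(
            rows, columns=["rat_id", "strain", "sex", "pct_hypertrophic"]
        )
        res = between_anova_2x2(df)
        assert res["strain"].F == pytest.approx(3.5826, rel=1e-3)
        assert res["sex"].F == pytest.approx(0.3369, rel=1e-3)
        assert res["strain*sex"].F == pytest.approx(1.0753, rel=1e-3)
        assert res["strain"].df_den == 15

    def test_balanced_sum_of_squares_partition(self):
        """SS_total = SS_strain + SS_sex + SS_interaction + SS_error in the
        balanced case."""
        rng = np.random.default_rng(4)
        rows = []
        for strain in ("SHR", "WKY"):
            for sex in ("F", "M"):
                for i in range(6):
                    rows.append((f"{strain}{sex}{i}", strain, sex, rng.normal()))
        df = pd.DataFrame(
            rows, columns=["rat_id", "strain", "sex", "pct_hypertrophic"]
        )
        res = between_anova_2x2(df)
        y = df["pct_hypertrophic"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        ms_err = None
        # reconstruct term SS from F and the residual mean square
        df_err = res["strain"].df_den
        # residual SS via one-way decomposition of cell means
        cells = df.groupby(["strain", "sex"])["pct_hypertrophic"]
        ss_err = float(
            sum(((g - g.mean()) ** 2).sum() for _, g in cells)
        )
        ss_terms = sum(
            res[t].F * res[t].df_num * (ss_err / df_err)
            for t in ("strain", "sex", "strain*sex")
        )
        assert ss_terms + ss_err == pytest.approx(ss_total, rel=1e-9)

    def test_empty_cell_rejected(self):
        df = pd.DataFrame(
            [("a", "SHR", "F", 1.0), ("b", "WKY", "F", 2.0),
             ("c", "WKY", "M", 3.0), ("d", "WKY", "M", 2.5)],
            columns=["rat_id", "strain", "sex", "pct_hypertrophic"],
        )
        with pytest.raises(DesignError, match="empty design cell"):
            between_anova_2x2(df)

    def test_strain_shift_dominates_interaction(self):
        """Under a pure strain shift the strain F exceeds the interaction F
        in the vast majority of draws."""
        rng = np.random.default_rng(21)
        wins = 0
        R = 200
        for _ in range(R):
            rows = []
            for strain in ("SHR", "WKY"):
                for sex in ("F", "M"):
                    for i in range(5):
                        y = rng.normal() + (2.0 if strain == "SHR" else 0.0)
                        rows.append((f"{strain}{sex}{i}", strain, sex, y))
            df = pd.DataFrame(
                rows, columns=["rat_id", "strain", "sex", "pct_hypertrophic"]
            )
            res = between_anova_2x2(df)
            wins += res["strain"].F > res["strain*sex"].F
        assert wins / R > 0.9
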