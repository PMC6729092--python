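import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itug.errors import DegenerateInputError, DesignError
from itug.stats import (
    EffectSize,
    PowerSpec,
    achieved_power_ttest,
    anova_two_way_type2,
    cohen_d,
    correlation_map,
    pearson,
    power_ttest,
    required_n_correlation,
    required_n_ttest,
    sidak_adjust,
)


def _statsmodels_anova(y, g, tr, typ):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": y, "g": g, "tr": tr})
    if typ == 3:
        # Type III is only meaningful under sum-to-zero coding
        model = ols("y ~ C(g, Sum) * C(tr, Sum)", data=df).fit()
    else:
        model = ols("y ~ C(g) * C(tr)", data=df).fit()
    return sm.stats.anova_lm(model, typ=typ)


def _random_design(rng, balanced=True):
    if balanced:
        g = np.repeat(["a", "b"], 12)
        tr = np.tile(np.repeat([1, 2, 3], 4), 2)
    else:
        g = np.array(["a"] * 18 + ["b"] * 6)
        tr = np.concatenate([np.repeat([1, 2, 3], 6), np.repeat([1, 2, 3], 2)])
    y = rng.normal(size=g.size) + (g == "a") * rng.normal() + tr * rng.normal(0, 0.3)
    return y, g, tr


class TestAnovaTypeII:
    def test_balanced_design_type2_equals_type3(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y, g, tr = _random_design(rng, balanced=True)
            res = anova_two_way_type2(y, g, tr, posthoc=False)
            sm3 = _statsmodels_anova(y, g, tr, typ=3)
            assert res.table.loc["group", "sum_sq"] == pytest.approx(
                sm3.loc["C(g, Sum)", "sum_sq"], abs=1e-8
            )
            assert res.table.loc["trial", "sum_sq"] == pytest.approx(
                sm3.loc["C(tr, Sum)", "sum_sq"], abs=1e-8
            )

    def test_unbalanced_design_matches_statsmodels_type2(self):
        """Independent oracle: statsmodels anova_lm(typ=2) on unbalanced data."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            y, g, tr = _random_design(rng, balanced=False)
            res = anova_two_way_type2(y, g, tr, posthoc=False)
            sm2 = _statsmodels_anova(y, g, tr, typ=2)
            for ours, theirs in (
                ("group", "C(g)"),
                ("trial", "C(tr)"),
                ("group:trial", "C(g):C(tr)"),
            ):
                assert res.table.loc[ours, "sum_sq"] == pytest.approx(
                    sm2.loc[theirs, "sum_sq"], abs=1e-8
                )
                assert res.table.loc[ours, "p"] == pytest.approx(
                    sm2.loc[theirs, "PR(>F)"], abs=1e-10
                )

    def test_six_observation_worked_dataset(self):
        """Hand-computable 2x2 design with one unbalanced cell (n=6)."""
        y = np.array([1.0, 2.0, 4.0, 5.0, 3.0, 7.0])
        g = np.array(["a", "a", "b", "b", "a", "b"])
        tr = np.array([1, 2, 1, 2, 1, 1])
        res = anova_two_way_type2(y, g, tr, posthoc=False)
        sm2 = _statsmodels_anova(y, g, tr, typ=2)
        assert res.table.loc["group", "sum_sq"] == pytest.approx(
            sm2.loc["C(g)", "sum_sq"], abs=1e-8
        )
        # residual RSS must equal the full-model residual
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(
            sm2.loc["Residual", "sum_sq"], abs=1e-8
        )

    def test_empty_cell_is_design_error(self):
        y = np.arange(6.0)
        g = np.array(["a"] * 3 + ["b"] * 3)
        tr = np.array([1, 1, 2, 1, 1, 1])  # cell (b, 2) empty
        with pytest.raises(DesignError, match="b.*2|2.*b"):
            anova_two_way_type2(y, g, tr)

    def test_posthoc_sidak_adjusts_all_cell_pairs(self):
        rng = np.random.default_rng(2)
        y, g, tr = _random_design(rng, balanced=True)
        res = anova_two_way_type2(y, g, tr)
        assert res.n_contrasts == 15  # C(6,2) cell pairs
        assert (res.posthoc["p_sidak"] >= res.posthoc["p"] - 1e-12).all()


class TestSidak:
    def test_closed_form(self):
        assert sidak_adjust([0.05, 0.05, 0.05]) == pytest.approx(
            [1 - 0.95**3] * 3
        )
        assert sidak_adjust([0.05, 0.05, 0.05])[0] == pytest.approx(0.142625)

    def test_single_comparison_unchanged(self):
        assert sidak_adjust([0.03]) == [pytest.approx(0.03)]

    def test_zero_stays_zero(self):
        assert sidak_adjust([0.0], m=10) == [0.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust([1.5])

    @settings(max_examples=30, deadline=None)
    @given(
        p=st.floats(0, 1),
        q=st.floats(0, 1),
        m=st.integers(1, 50),
    )
    def test_monotone_in_p_and_m(self, p, q, m):
        lo, hi = sorted([p, q])
        assert sidak_adjust([lo], m=m)[0] <= sidak_adjust([hi], m=m)[0] + 1e-12
        assert sidak_adjust([p], m=m)[0] <= sidak_adjust([p], m=m + 1)[0] + 1e-12
        assert sidak_adjust([p], m=m)[0] >= p - 1e-12


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, r2, p = pearson(x, x)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_r_squared_consistency_at_published_precision(self):
        # r = -0.6492 implies r² = 0.4215 at 4 decimals
        assert (-0.6492) ** 2 == pytest.approx(0.4215, abs=5e-5)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = rng.normal(size=(2, 30))
            r, r2, _ = pearson(x, y)
            rx = x - x.mean()
            ry = y - y.mean()
            oracle = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
            assert r == pytest.approx(oracle, abs=1e-12)
            assert r2 == pytest.approx(oracle**2, abs=1e-12)

    def test_linear_transform_gives_sign_of_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        assert pearson(x, 2 + 3 * x)[0] == pytest.approx(1.0)
        assert pearson(x, 2 - 3 * x)[0] == pytest.approx(-1.0)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(10), np.arange(10.0))


class TestCorrelationMap:
    @staticmethod
    def _tidy_and_scores(link_sign=-1.0, n=25, seed=0):
        rng = np.random.default_rng(seed)
        severity = rng.uniform(0, 1, n)
        rows = []
        for i, s in enumerate(severity):
            for phase in ("turn", "full"):
                for ch in ("AccL_total", "AccA_total"):
                    rows.append(
                        {
                            "subject_id": f"S{i}",
                            "channel": ch,
                            "phase": phase,
                            "sparc": -3 + link_sign * 3 * s + rng.normal(0, 0.2),
                        }
                    )
        scores = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "fogq": 5 + 15 * severity + rng.normal(0, 1, n),
                "flat": np.ones(n),
            }
        )
        return pd.DataFrame(rows), scores

    def test_recovers_built_in_negative_link(self):
        tidy, scores = self._tidy_and_scores(link_sign=-1.0)
        out = correlation_map(tidy, scores, score_cols=["fogq"])
        assert (out["r"] < 0).all()
        assert (out["p"] < 0.05).all()

    def test_constant_score_yields_nan_not_crash(self):
        tidy, scores = self._tidy_and_scores()
        out = correlation_map(tidy, scores, score_cols=["flat"])
        assert out["r"].isna().all()

    def test_schema_mirrors_published_table(self):
        tidy, scores = self._tidy_and_scores()
        out = correlation_map(tidy, scores, score_cols=["fogq"], sidak=True)
        for col in ("questionnaire", "phase", "channel", "r", "r2", "p", "p_sidak"):
            assert col in out.columns
        np.testing.assert_allclose(out["r2"], out["r"] ** 2, atol=1e-12)


class TestCohenD:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        with np.errstate(all="ignore"):
            es = cohen_d(a, a)
        assert es.d == 0
        assert es.label == "negligible"
        assert not es.clinically_relevant

    def test_classification_thresholds(self):
        assert EffectSize(0.3).label == "small"
        assert EffectSize(0.6).label == "moderate"
        assert EffectSize(1.52).label == "large"
        assert EffectSize(1.52).clinically_relevant
        assert not EffectSize(0.39).clinically_relevant

    def test_matches_pooled_sd_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(0, 1, 20)
            b = rng.normal(1, 2, 8)
            sp = np.sqrt((19 * a.var(ddof=1) + 7 * b.var(ddof=1)) / 26)
            assert cohen_d(a, b).d == pytest.approx(abs(a.mean() - b.mean()) / sp, abs=1e-12)

    def test_zero_pooled_sd(self):
        with pytest.raises(DegenerateInputError):
            cohen_d(np.ones(5), np.ones(5))


class TestPower:
    def test_study_sample_size_one_tailed(self):
        """d = 1.57/0.79, alpha .05, power .90, one-tailed -> 6 per group."""
        spec = PowerSpec(effect_size=1.57 / 0.79, alpha=0.05, power=0.90, tails=1)
        assert required_n_ttest(spec) == 6

    def test_two_tailed_needs_seven(self):
        spec = PowerSpec(effect_size=1.57 / 0.79, alpha=0.05, power=0.90, tails=2)
        assert required_n_ttest(spec) == 7

    def test_huge_effect_floors_at_two(self):
        assert required_n_ttest(PowerSpec(effect_size=10.0, tails=1)) == 2

    def test_power_at_six_consistent_with_search(self):
        spec = PowerSpec(effect_size=1.57 / 0.79, alpha=0.05, power=0.90, tails=1)
        assert achieved_power_ttest(spec, 6, 6) == pytest.approx(0.94, abs=0.01)
        assert achieved_power_ttest(spec, 5, 5) < 0.90

    def test_null_effect_power_equals_alpha(self):
        assert power_ttest(0.0, 20, 20, alpha=0.05, tails=2) == pytest.approx(0.05, abs=1e-9)

    def test_large_n_power_tends_to_one(self):
        assert power_ttest(0.5, 2000, 2000, tails=2) > 0.999

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        sm_power = TTestIndPower().power(effect_size=0.8, nobs1=15, ratio=1.0, alpha=0.05)
        assert power_ttest(0.8, 15, 15, alpha=0.05, tails=2) == pytest.approx(
            sm_power, abs=1e-6
        )

    def test_monotone_in_d_and_n(self):
        for d1, d2 in [(0.3, 0.6), (0.6, 1.2)]:
            assert required_n_ttest(PowerSpec(effect_size=d1)) >= required_n_ttest(
                PowerSpec(effect_size=d2)
            )
        assert power_ttest(0.5, 30, 30) > power_ttest(0.5, 10, 10)

    def test_correlation_sample_size_conventions(self):
        """Fisher-z: r=0.65, 95% power gives 22 one-tailed / 25 two-tailed."""
        one = required_n_correlation(PowerSpec(effect_size=0.65, power=0.95, tails=1))
        two = required_n_correlation(PowerSpec(effect_size=0.65, power=0.95, tails=2))
        assert one == 22
        assert two == 25

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_size=-1.0)
        with pytest.raises(ValueError):
            power_ttest(0.5, 1, 10)
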