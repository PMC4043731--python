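import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f as f_dist
from scipy.stats import tukey_hsd

import phylogerm as pg
from phylogerm.anova import ModelSpec, design_matrix, fit_ols

from conftest import balanced_frame


def statsmodels_type3(frame, response, factors, interactions=()):
    """Independent Type III oracle: statsmodels with Sum contrasts."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    terms = [f"C({f}, Sum)" for f in factors]
    terms += [f"C({a}, Sum):C({b}, Sum)" for a, b in interactions]
    model = smf.ols(f"{response} ~ {' + '.join(terms)}", data=frame).fit()
    return anova_lm(model, typ=3)


def unbalanced_frame(levels_a, levels_b, seed, interaction=0.0):
    """Unequal cell sizes; `interaction` scales a non-additive cell effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(levels_a):
        for j in range(levels_b):
            for _ in range(int(rng.integers(3, 9))):
                y = (0.7 * i - 0.4 * j
                     + interaction * ((i % 2) * 2 - 1) * ((j % 2) * 2 - 1)
                     + rng.normal())
                rows.append({"A": f"a{i}", "B": f"b{j}", "y": y})
    return pd.DataFrame(rows)


class TestDesignMatrix:
    def test_sum_to_zero_columns_balanced(self):
        frame = balanced_frame(n_per_cell=4, levels_a=3, levels_b=2)
        X, cols = design_matrix(frame, ModelSpec(response="y", factors=("A",)))
        XA = X[:, cols["A"]]
        assert XA.shape[1] == 2
        assert np.allclose(XA.sum(axis=0), 0.0)

    def test_single_level_factor_rejected(self):
        frame = pd.DataFrame({"A": ["a"] * 5, "y": np.arange(5.0)})
        with pytest.raises(ValueError, match="A"):
            design_matrix(frame, ModelSpec(response="y", factors=("A",)))

    def test_empty_cell_reduces_interaction_df_to_rank(self):
        frame = pd.DataFrame({
            "A": ["a"] * 6 + ["b"] * 6,
            "B": ["x", "y"] * 3 + ["x"] * 6,
            "y": np.arange(12.0),
        })
        tab = pg.type3_anova(frame, ModelSpec(
            response="y", factors=("A", "B"), interactions=(("A", "B"),)))
        by = tab.set_index("source")
        assert by.loc["A:B", "df"] == 0
        assert by.loc["A", "df"] == 1
        assert by.loc["B", "df"] == 1


class TestFitOLS:
    def test_intercept_only_residual_is_centered_ss(self):
        y = np.array([1.0, 3.0, 7.0, 9.0])
        fit = fit_ols(np.ones((4, 1)), y)
        assert fit.rss == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_saturated_fit_flags_zero_residual_df(self):
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        fit = fit_ols(X, np.array([2.0, 5.0]))
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.df_resid == 0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 5))])
        y = rng.normal(size=50)
        fit = fit_ols(X, y)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coef, beta, atol=1e-8)


class TestType3Anova:
    def test_textbook_two_group_f(self):
        frame = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3,
                              "y": [1.0, 2, 3, 4, 5, 6]})
        tab = pg.type3_anova(frame, ModelSpec(response="y", factors=("g",)))
        row = tab.set_index("source").loc["g"]
        assert row["SS"] == pytest.approx(13.5)
        assert row["F"] == pytest.approx(13.5)
        assert row["df"] == 1

    def test_balanced_type3_equals_type1(self):
        """Orthogonal design: marginal and sequential SS coincide per term."""
        frame = balanced_frame(n_per_cell=5, levels_a=3, levels_b=4, seed=3)
        spec = ModelSpec(response="y", factors=("A", "B"),
                         interactions=(("A", "B"),))
        tab = pg.type3_anova(frame, spec).set_index("source")
        # sequential (Type I) oracle: add terms in order, difference the RSS
        y = frame["y"].to_numpy()
        X, cols = design_matrix(frame, spec)
        rss = [fit_ols(np.ones((len(y), 1)), y).rss]
        stops = [cols["A"].stop, cols["B"].stop, cols["A:B"].stop]
        for stop in stops:
            rss.append(fit_ols(X[:, :stop], y).rss)
        for term, ss_type1 in zip(["A", "B", "A:B"], -np.diff(rss)):
            assert tab.loc[term, "SS"] == pytest.approx(ss_type1, abs=1e-8)

    @pytest.mark.parametrize("levels", [(2, 2), (3, 4)])
    def test_unbalanced_matches_statsmodels_oracle(self, levels):
        frame = unbalanced_frame(*levels, seed=5, interaction=0.3)
        spec = ModelSpec(response="y", factors=("A", "B"),
                         interactions=(("A", "B"),))
        mine = pg.type3_anova(frame, spec).set_index("source")
        oracle = statsmodels_type3(frame, "y", ["A", "B"], [("A", "B")])
        pairs = [("A", "C(A, Sum)"), ("B", "C(B, Sum)"),
                 ("A:B", "C(A, Sum):C(B, Sum)")]
        for term, sm_term in pairs:
            assert mine.loc[term, "SS"] == pytest.approx(
                oracle.loc[sm_term, "sum_sq"], abs=1e-8)
            assert mine.loc[term, "F"] == pytest.approx(
                oracle.loc[sm_term, "F"], rel=1e-8)

    def test_p_values_match_f_distribution_oracle(self, metrics_with_attributes):
        tab = pg.type3_anova(metrics_with_attributes, ModelSpec(
            response="GP_t", factors=("order", "temperature")))
        resid_df = int(tab.set_index("source").loc["Residual", "df"])
        for _, row in tab.iterrows():
            if np.isfinite(row["F"]):
                assert row["P"] == pytest.approx(
                    float(f_dist.sf(row["F"], row["df"], resid_df)), abs=1e-10)

    @given(a=st.floats(0.5, 20), b=st.floats(-10, 10))
    @settings(deadline=None, max_examples=20)
    def test_r2_invariant_to_affine_response_rescaling(self, a, b):
        frame = unbalanced_frame(3, 2, seed=9)
        spec = ModelSpec(response="y", factors=("A", "B"))
        r2_0 = pg.type3_anova(frame, spec)["R2"]
        frame2 = frame.assign(y=a * frame["y"] + b)
        r2_1 = pg.type3_anova(frame2, spec)["R2"]
        assert np.allclose(r2_0.fillna(-1), r2_1.fillna(-1), atol=1e-9)

    def test_permutation_type_i_error_calibrated(self):
        """Null F-test rejects at ~alpha when the factor is shuffled."""
        rng = np.random.default_rng(17)
        y = rng.normal(size=120)
        labels = np.repeat([f"g{i}" for i in range(4)], 30)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            frame = pd.DataFrame({"g": rng.permutation(labels), "y": y})
            tab = pg.type3_anova(frame, ModelSpec(response="y", factors=("g",)))
            rejections += tab.set_index("source").loc["g", "P"] < 0.05
        assert 0.03 <= rejections / n_perm <= 0.07


class TestTableBatteries:
    def test_one_way_battery_dfs_match_level_counts(self, metrics_with_attributes):
        t1 = pg.run_table1(metrics_with_attributes)
        dfs = t1[t1["response"] == "GP_t"].set_index("source")["df"]
        assert dfs.to_dict() == {
            "order": 13, "life_form": 1, "seed_size_class": 4,
            "dispersal_mode": 3, "flowering_onset": 2,
            "flowering_duration": 2, "temperature": 4, "habitat": 2,
        }

    def test_two_way_interaction_power_and_type_i(self):
        flagged_power = flagged_null = 0
        n_reps = 60
        for rep in range(n_reps):
            with_int = unbalanced_frame(3, 3, seed=1000 + rep, interaction=0.8)
            t = pg.run_table2(with_int, (("A", "B"),), "y")
            flagged_power += bool(t["significant_interaction"].any())
            null = unbalanced_frame(3, 3, seed=5000 + rep, interaction=0.0)
            t0 = pg.run_table2(null, (("A", "B"),), "y")
            flagged_null += bool(t0["significant_interaction"].any())
        assert flagged_power / n_reps > 0.9
        assert flagged_null / n_reps < 0.15


class TestTukey:
    def test_identical_groups_share_letter(self):
        y = list(np.random.default_rng(2).normal(size=6))
        frame = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6, "y": y + y})
        res = pg.tukey_letters(frame, "g", "y")
        assert res.letters == {"a": "a", "b": "a"}

    def test_separated_groups_all_distinct(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame({
            "g": np.repeat(["lo", "mid", "hi"], 6),
            "y": np.concatenate([rng.normal(m, 0.1, 6) for m in (0, 10, 20)]),
        })
        res = pg.tukey_letters(frame, "g", "y")
        assert sorted(res.letters.values()) == ["a", "b", "c"]
        assert res.letters["hi"] == "a"  # descending-mean letter order

    def test_two_groups_reduce_to_t_test(self):
        """Tukey with k=2 equals the ordinary pooled two-sample t-test."""
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(6)
        frame = pd.DataFrame({
            "g": ["a"] * 8 + ["b"] * 11,
            "y": np.concatenate([rng.normal(0, 1, 8), rng.normal(0.9, 1, 11)]),
        })
        res = pg.tukey_letters(frame, "g", "y")
        t_p = ttest_ind(frame.loc[frame.g == "a", "y"],
                        frame.loc[frame.g == "b", "y"]).pvalue
        assert res.p_adjusted.loc["a", "b"] == pytest.approx(t_p, rel=1e-6)

    def test_matches_scipy_tukey_hsd_unequal_n(self):
        rng = np.random.default_rng(7)
        samples = [rng.normal(m, 1, n) for m, n in
                   [(0, 12), (0.8, 7), (2.0, 15), (2.1, 9)]]
        frame = pd.DataFrame({
            "g": np.repeat(list("abcd"), [12, 7, 15, 9]),
            "y": np.concatenate(samples),
        })
        res = pg.tukey_letters(frame, "g", "y")
        oracle = tukey_hsd(*samples)
        for i, gi in enumerate("abcd"):
            for j, gj in enumerate("abcd"):
                if i < j:
                    assert res.p_adjusted.loc[gi, gj] == pytest.approx(
                        oracle.pvalue[i, j], abs=1e-6)

    def test_singleton_group_excluded_with_warning(self):
        frame = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5 + ["c"],
                              "y": np.arange(11.0)})
        res = pg.tukey_letters(frame, "g", "y")
        assert res.excluded == ["c"]
        assert set(res.groups) == {"a", "b"}

    def test_letters_agree_with_pairwise_significance(self, metrics_with_attributes):
        """Groups share a letter iff adjusted P >= alpha (CLD contract)."""
        res = pg.tukey_letters(metrics_with_attributes, "temperature", "GT_t")
        for i, gi in enumerate(res.groups):
            for gj in res.groups[i + 1:]:
                share = bool(set(res.letters[gi]) & set(res.letters[gj]))
                assert share == (res.p_adjusted.loc[gi, gj] >= 0.05)
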