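import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import scipy.stats

import ses_microstates as ms
from ses_microstates.stats import (correlate, extreme_group_split, mixed_ancova,
                                   posthoc_bonferroni, ses_score,
                                   transition_ttests)


def survey(edu1, edu2, occ1, occ2):
    n = len(edu1)
    return pd.DataFrame({
        "subject_id": [f"P{i:02d}" for i in range(n)],
        "parent_edu_1": edu1, "parent_edu_2": edu2,
        "parent_occ_1": occ1, "parent_occ_2": occ2,
        "age": 20.0, "gender": "F",
    })


class TestSesScore:
    def test_two_subject_hand_example(self):
        # family means (2, 4) and (3, 5): each z-scores to -+1/sqrt(2)
        df = ses_score(survey([2, 4], [2, 4], [3, 5], [3, 5]))
        np.testing.assert_allclose(df["ses_z"], [-np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_matches_definitional_formula(self, rng):
        n = 20
        df = survey(*(rng.integers(1, 6, n) for _ in range(2)),
                    *(rng.integers(1, 11, n) for _ in range(2)))
        out = ses_score(df)
        fam_edu = (df.parent_edu_1 + df.parent_edu_2) / 2
        fam_occ = (df.parent_occ_1 + df.parent_occ_2) / 2
        expected = scipy.stats.zscore(fam_edu, ddof=1) + scipy.stats.zscore(fam_occ, ddof=1)
        np.testing.assert_allclose(out["ses_z"], expected, atol=1e-12)

    def test_shift_invariance_of_components(self, rng):
        n = 12
        e1, e2 = rng.integers(1, 4, n), rng.integers(1, 4, n)
        o1, o2 = rng.integers(1, 7, n), rng.integers(1, 7, n)
        a = ses_score(survey(e1, e2, o1, o2))
        b = ses_score(survey(e1 + 1, e2 + 1, o1 + 2, o2 + 2))
        np.testing.assert_allclose(a["ses_z"], b["ses_z"], atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ses_score(survey([3, 3], [3, 3], [5, 5], [5, 5]))

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            ses_score(survey([0, 3], [3, 3], [5, 6], [5, 5]))


class TestExtremeGroupSplit:
    @pytest.mark.parametrize("n, expected", [(107, 29), (10, 3), (100, 27)])
    def test_group_sizes(self, n, expected, rng):
        df = pd.DataFrame({"subject_id": [f"P{i:03d}" for i in range(n)],
                           "ses_z": rng.normal(size=n)})
        out = extreme_group_split(df, fraction=0.27)
        assert (out["group"] == "high").sum() == expected
        assert (out["group"] == "low").sum() == expected

    def test_half_split_leaves_no_middle(self, rng):
        df = pd.DataFrame({"subject_id": [f"P{i}" for i in range(10)],
                           "ses_z": rng.normal(size=10)})
        out = extreme_group_split(df, fraction=0.5)
        assert (out["group"] == "middle").sum() == 0

    def test_extremes_actually_extreme(self, rng):
        df = pd.DataFrame({"subject_id": [f"P{i:03d}" for i in range(50)],
                           "ses_z": rng.normal(size=50)})
        out = extreme_group_split(df)
        assert out.loc[out.group == "high", "ses_z"].min() >= \
            out.loc[out.group == "middle", "ses_z"].max()
        assert out.loc[out.group == "low", "ses_z"].max() <= \
            out.loc[out.group == "middle", "ses_z"].min()

    def test_overfull_split_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b", "c"], "ses_z": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            extreme_group_split(df, fraction=0.5)


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_definitional_formula(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([3.0, 1.0, 5.0, 6.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        res = correlate(x, y)
        assert res.statistic == pytest.approx(r_expected, abs=1e-12)
        t = r_expected * np.sqrt(2 / (1 - r_expected**2))
        assert res.p == pytest.approx(2 * scipy.stats.t.sf(abs(t), 2), abs=1e-12)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(300):
            ps.append(correlate(rng.normal(size=30), rng.normal(size=30)).p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def make_param_table(rng, n=20, effect_a=0.0, sd_between=10.0, sd_within=5.0):
    rows = []
    for i in range(n):
        g = "low" if i < n // 2 else "high"
        base = rng.normal(80, sd_between)
        age = float(rng.normal(20, 2))
        gender = "F" if rng.random() < 0.5 else "M"
        for c in "ABCD":
            y = base + rng.normal(0, sd_within)
            if g == "low" and c == "A":
                y += effect_a
            rows.append({"subject": f"S{i:02d}", "group": g, "class": c,
                         "age": age, "gender": gender, "y": y})
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_no_covariates_matches_pingouin(self, rng):
        df = make_param_table(rng, effect_a=5.0)
        ours = {r.name: r for r in mixed_ancova(df, "y", covariates=None)}
        ref = pg.mixed_anova(data=df, dv="y", within="class", between="group",
                             subject="subject").set_index("Source")
        assert ours["group"].statistic == pytest.approx(ref.loc["group", "F"], abs=1e-8)
        assert ours["class"].statistic == pytest.approx(ref.loc["class", "F"], abs=1e-8)
        assert ours["class*group"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)
        assert ours["class*group"].effect_size == pytest.approx(
            ref.loc["Interaction", "np2"], abs=1e-8)

    def test_df_pattern_for_58_subjects_with_covariates(self, rng):
        df = make_param_table(rng, n=58)
        res = {r.name: r for r in mixed_ancova(df, "y")}
        assert res["group"].df == (1.0, 54.0)
        assert res["class"].df == (3.0, 162.0)
        assert res["class*group"].df == (3.0, 162.0)

    def test_reduces_to_anova_when_covariates_uninformative(self, rng):
        # pure-noise covariates change only error df, not the SS decomposition
        df = make_param_table(rng, effect_a=8.0)
        with_cov = {r.name: r for r in mixed_ancova(df, "y")}
        without = {r.name: r for r in mixed_ancova(df, "y", covariates=None)}
        # F ratios agree approximately because the covariates absorb ~no SS
        for key in ("class*group",):
            assert with_cov[key].statistic == pytest.approx(without[key].statistic,
                                                            rel=0.25)

    def test_projection_oracle_for_between_effect(self, rng):
        """Between-subject F equals an explicit OLS model comparison on the
        subject means (statsmodels as independent route)."""
        import statsmodels.api as sm

        df = make_param_table(rng, n=16, effect_a=6.0)
        res = {r.name: r for r in mixed_ancova(df, "y")}
        wide = df.pivot_table(index="subject", columns="class", values="y")
        info = df.drop_duplicates("subject").set_index("subject").loc[wide.index]
        ybar = wide.mean(axis=1).to_numpy()
        g = (info["group"] == "low").to_numpy(float)
        age = info["age"].to_numpy(float)
        gender = (info["gender"] == "M").to_numpy(float)
        X_full = sm.add_constant(np.column_stack([g, age, gender]))
        X_red = sm.add_constant(np.column_stack([age, gender]))
        fit_full = sm.OLS(ybar, X_full).fit()
        fit_red = sm.OLS(ybar, X_red).fit()
        f = ((fit_red.ssr - fit_full.ssr) / 1) / (fit_full.ssr / fit_full.df_resid)
        assert res["group"].statistic == pytest.approx(f, abs=1e-8)

    def test_missing_class_rejected(self, rng):
        df = make_param_table(rng).iloc[1:]
        with pytest.raises(ValueError, match="missing a class"):
            mixed_ancova(df, "y")


class TestPosthoc:
    def test_bonferroni_multiplies_by_k(self, rng):
        df = make_param_table(rng, effect_a=30.0, sd_between=2.0, sd_within=2.0)
        res = posthoc_bonferroni(df, "y")
        assert len(res) == 4
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 4), abs=1e-12)

    def test_only_programmed_class_flags(self, rng):
        df = make_param_table(rng, n=40, effect_a=15.0, sd_between=2.0, sd_within=3.0)
        res = {r.name.split("[")[1][0]: r for r in posthoc_bonferroni(df, "y")}
        assert res["A"].p_adjusted < 0.05
        for c in "BCD":
            assert res[c].p_adjusted > 0.05


def make_transition_table(rng, n=10, delta=0.0):
    rows = []
    for i in range(n):
        g = "low" if i < n // 2 else "high"
        for src in "AB":
            for dst in "AB":
                if src == dst:
                    continue
                p = 0.5 + rng.normal(0, 0.05)
                if g == "low" and (src, dst) == ("A", "B"):
                    p += delta
                rows.append({"subject": f"S{i}", "group": g,
                             "from": src, "to": dst, "probability": p})
    return pd.DataFrame(rows)


class TestTransitionTtests:
    def test_hand_computed_t_on_toy_table(self):
        a, b = np.array([0.2, 0.3, 0.4]), np.array([0.5, 0.6, 0.7])
        rows = [{"subject": f"S{i}", "group": g, "from": "A", "to": "B",
                 "probability": p}
                for i, (g, p) in enumerate([("low", x) for x in a]
                                           + [("high", x) for x in b])]
        res = transition_ttests(pd.DataFrame(rows))
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t_expected = (b.mean() - a.mean()) / np.sqrt(sp2 * (2 / 3))
        assert res[0].statistic == pytest.approx(t_expected, abs=1e-10)
        assert res[0].df == (4.0,)

    def test_ordered_pair_count_for_k4(self, rng):
        rows = []
        for i in range(6):
            g = "low" if i < 3 else "high"
            for src in "ABCD":
                for dst in "ABCD":
                    if src != dst:
                        rows.append({"subject": f"S{i}", "group": g, "from": src,
                                     "to": dst, "probability": rng.random()})
        res = transition_ttests(pd.DataFrame(rows))
        assert len(res) == 12

    def test_programmed_difference_detected(self, rng):
        res = transition_ttests(make_transition_table(rng, n=30, delta=0.2))
        by_name = {r.name: r for r in res}
        assert by_name["P(A->B) high vs low"].p < 0.05

    def test_zero_variance_flagged(self):
        rows = [{"subject": f"S{i}", "group": g, "from": "A", "to": "B",
                 "probability": 0.5}
                for i, g in enumerate(["low", "low", "high", "high"])]
        res = transition_ttests(pd.DataFrame(rows))
        assert np.isnan(res[0].statistic)
        assert "zero variance" in res[0].note
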