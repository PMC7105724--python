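import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import probebias as pb
from probebias.inference import (
    MixedAnova,
    SummaryStats,
    bonferroni,
    format_effect,
    paired_t,
    posthoc_pairwise,
    response_slowing_test,
    rm_ancova,
    t_from_summary,
)


def mixed_2x2_dataset(seed=0, n_per_group=4, sigma=1.0):
    """Small balanced 2-group x (2x2 within) dataset."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(2 * n_per_group):
        group = "f" if s < n_per_group else "m"
        subj_off = rng.normal(0, 1)
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                y = (
                    subj_off
                    + (0.8 if a == "a2" else 0)
                    + (0.3 if b == "b2" else 0)
                    + (0.5 if (group == "m" and a == "a2") else 0)
                    + rng.normal(0, sigma)
                )
                rows.append(dict(subject_id=f"s{s}", group=group, A=a, B=b, y=y))
    return pd.DataFrame(rows)


def oracle_mixed_anova_2x2(df):
    """Brute-force textbook cell-means decomposition of a balanced 2-group,
    2x2-within design, with classical error strata (subjects within groups;
    subject x within-factor interactions). Returns F per effect."""
    wide = df.pivot_table(index=["subject_id", "group"], columns=["A", "B"], values="y")
    Y = wide.to_numpy(float)  # columns ordered (a1b1, a1b2, a2b1, a2b2)
    groups = wide.index.get_level_values("group").to_numpy()
    n = len(Y)
    gm = Y.mean()
    subj_mean = Y.mean(axis=1)
    grp_mean = {g: Y[groups == g].mean() for g in np.unique(groups)}
    grp_of = np.array([grp_mean[g] for g in groups])

    ss_group = 4 * sum(
        (groups == g).sum() * (grp_mean[g] - gm) ** 2 for g in np.unique(groups)
    )
    ss_subj = 4 * np.sum((subj_mean - grp_of) ** 2)

    def marginal(axis_levels):  # per-subject means over one within factor
        if axis_levels == "A":
            return np.stack([Y[:, :2].mean(axis=1), Y[:, 2:].mean(axis=1)], axis=1)
        return np.stack([Y[:, [0, 2]].mean(axis=1), Y[:, [1, 3]].mean(axis=1)], axis=1)

    out = {}
    for fac, other in (("A", "B"), ("B", "A")):
        M = marginal(fac)  # n x 2 subject means per level of fac
        lev_mean = M.mean(axis=0)
        ss_f = 2 * n * np.sum((lev_mean - gm) ** 2)
        ss_fg = 0.0
        ss_err = 0.0
        for g in np.unique(groups):
            sel = groups == g
            g_lev = M[sel].mean(axis=0)
            ss_fg += 2 * sel.sum() * np.sum((g_lev - grp_mean[g] - lev_mean + gm) ** 2)
            dev = M[sel] - subj_mean[sel][:, None] - g_lev[None, :] + grp_mean[g]
            ss_err += 2 * np.sum(dev**2)
        out[f"ss_{fac}"] = (ss_f, ss_fg, ss_err)

    # A x B stratum via the double-difference score per subject
    ab = Y[:, 0] - Y[:, 1] - Y[:, 2] + Y[:, 3]
    ab_mean = ab.mean()
    ss_ab = n * ab_mean**2 / 4
    ss_abg = 0.0
    ss_err_ab = 0.0
    for g in np.unique(groups):
        sel = groups == g
        ss_abg += sel.sum() * (ab[sel].mean() - ab_mean) ** 2 / 4
        ss_err_ab += np.sum((ab[sel] - ab[sel].mean()) ** 2) / 4

    df_err = n - 2
    F = {
        "group": (ss_group / 1) / (ss_subj / df_err),
        "A": (out["ss_A"][0] / 1) / (out["ss_A"][2] / df_err),
        "A x group": (out["ss_A"][1] / 1) / (out["ss_A"][2] / df_err),
        "B": (out["ss_B"][0] / 1) / (out["ss_B"][2] / df_err),
        "B x group": (out["ss_B"][1] / 1) / (out["ss_B"][2] / df_err),
        "A x B": (ss_ab / 1) / (ss_err_ab / df_err),
        "A x B x group": (ss_abg / 1) / (ss_err_ab / df_err),
    }
    return F


class TestSummaryT:
    @pytest.mark.parametrize(
        "g1,g2,expected_t,expected_p",
        [
            ((28.53, 1.71, 32), (27.91, 1.06, 32), 0.31, 0.757),
            ((36.75, 1.35, 32), (34.59, 1.16, 32), 1.21, 0.230),
            ((21.92, 0.41, 32), (23.66, 0.47, 32), -2.80, 0.007),
        ],
    )
    def test_sample_table_statistics(self, g1, g2, expected_t, expected_p):
        t, df, p = t_from_summary(SummaryStats(*g1), SummaryStats(*g2))
        assert df == 62
        assert t == pytest.approx(expected_t, abs=0.02)
        assert p == pytest.approx(expected_p, abs=0.005)

    def test_identical_groups(self):
        t, _, p = t_from_summary((5.0, 1.0, 10), (5.0, 1.0, 10))
        assert t == 0.0 and p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary((5.0, 1.0, 1), (5.0, 1.0, 10))

    def test_equal_n_shortcut_identity(self):
        t, _, _ = t_from_summary((10.0, 1.5, 20), (8.0, 1.2, 20))
        assert t == pytest.approx((10.0 - 8.0) / np.sqrt(1.5**2 + 1.2**2))


class TestPairedT:
    def test_constant_nonzero_differences_infinite_t(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and t < 0 and p == 0.0 and df == 2

    def test_equal_samples(self):
        t, _, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_oracle_one_sample_on_differences(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(size=30)
        t, df, p = paired_t(a, b)
        ref = stats.ttest_1samp(a - b, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adjustment_properties(self, ps):
        adj = bonferroni(ps)
        assert np.all(adj >= np.asarray(ps)) and np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestMixedAnova:
    def test_two_level_epsilon_exactly_one(self):
        df = (
            mixed_2x2_dataset(seed=2)
            .groupby(["subject_id", "group", "A"], as_index=False)["y"]
            .mean()
        )
        tab = rm_ancova(df, dv="y", within=["A"], between="group")
        eps = tab.loc[tab["effect"] == "A", "gg_epsilon"].iloc[0]
        assert eps == 1.0

    def test_matches_bruteforce_oracle_to_machine_precision(self):
        df = mixed_2x2_dataset(seed=3, n_per_group=2)  # 4 subjects total
        tab = rm_ancova(df, dv="y", within=["A", "B"], between="group").set_index("effect")
        oracle = oracle_mixed_anova_2x2(df)
        assert tab.loc["group", "F"] == pytest.approx(oracle["group"], rel=1e-10)
        assert tab.loc["A", "F"] == pytest.approx(oracle["A"], rel=1e-10)
        assert tab.loc["A x group", "F"] == pytest.approx(oracle["A x group"], rel=1e-10)
        assert tab.loc["B", "F"] == pytest.approx(oracle["B"], rel=1e-10)
        assert tab.loc["B x group", "F"] == pytest.approx(oracle["B x group"], rel=1e-10)
        assert tab.loc["A x B", "F"] == pytest.approx(oracle["A x B"], rel=1e-10)
        assert tab.loc["A x B x group", "F"] == pytest.approx(
            oracle["A x B x group"], rel=1e-10
        )

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        rows = []
        for s in range(18):
            grp = "a" if s < 9 else "b"
            for w in ("w1", "w2", "w3"):
                rows.append(
                    dict(subject_id=f"s{s}", group=grp, cond=w, y=rng.normal())
                )
        df = pd.DataFrame(rows)
        mine = rm_ancova(df, dv="y", within=["cond"], between="group").set_index("effect")
        ref = pg.mixed_anova(
            df, dv="y", within="cond", between="group", subject="subject_id"
        ).set_index("Source")
        assert mine.loc["cond", "F"] == pytest.approx(ref.loc["cond", "F"], rel=1e-9)
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine.loc["cond x group", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine.loc["cond", "partial_eta_sq"] == pytest.approx(
            ref.loc["cond", "np2"], rel=1e-9
        )

    def test_gg_corrected_p_not_smaller(self):
        rng = np.random.default_rng(5)
        rows = [
            dict(subject_id=f"s{s}", cond=w, y=rng.normal() + off)
            for s in range(12)
            for w, off in (("w1", 0.0), ("w2", 0.4), ("w3", 0.1), ("w4", 0.2))
        ]
        tab = rm_ancova(pd.DataFrame(rows), dv="y", within=["cond"])
        row = tab[tab["effect"] == "cond"].iloc[0]
        assert row["gg_epsilon"] <= 1.0
        assert row["p"] >= row["p_uncorrected"] - 1e-15

    def test_constant_covariate_equals_plain_anova(self):
        df = mixed_2x2_dataset(seed=6)
        df["cov"] = 3.0
        with pytest.warns(UserWarning, match="constant covariate"):
            with_cov = rm_ancova(
                df, dv="y", within=["A", "B"], between="group", covariate="cov"
            )
        without = rm_ancova(df, dv="y", within=["A", "B"], between="group")
        pd.testing.assert_frame_equal(
            with_cov.reset_index(drop=True), without.reset_index(drop=True)
        )

    def test_between_f_equals_summary_t_squared(self):
        rng = np.random.default_rng(7)
        vals = {"f": rng.normal(0.0, 1.0, 12), "m": rng.normal(0.6, 1.0, 12)}
        rows = [
            dict(subject_id=f"{g}{i}", group=g, rep=r, y=v)
            for g, arr in vals.items()
            for i, v in enumerate(arr)
            for r in ("r1", "r2")
        ]
        tab = rm_ancova(pd.DataFrame(rows), dv="y", within=["rep"], between="group")
        F = tab.loc[tab["effect"] == "group", "F"].iloc[0]
        summaries = [
            SummaryStats(arr.mean(), arr.std(ddof=1) / np.sqrt(len(arr)), len(arr))
            for arr in vals.values()
        ]
        t, _, _ = t_from_summary(*summaries)
        assert F == pytest.approx(t**2, rel=1e-9)

    def test_incomplete_subjects_dropped_with_warning(self):
        df = mixed_2x2_dataset(seed=8)
        df = df.drop(index=df.index[0])
        with pytest.warns(UserWarning, match="incomplete"):
            model = MixedAnova("y", within=["A", "B"], between="group").fit(df)
        assert model.dropped_subjects_ == ["s0"]

    def test_covariate_adjusts_between_effect(self):
        # a confounded covariate should absorb part of the group effect
        rng = np.random.default_rng(9)
        rows = []
        for s in range(20):
            group = "f" if s < 10 else "m"
            cov = rng.normal(0 if group == "f" else 2.0, 1.0)
            base = 0.8 * cov + rng.normal()
            for w in ("w1", "w2"):
                rows.append(
                    dict(subject_id=f"s{s}", group=group, cov=cov, rep=w,
                         y=base + rng.normal(0, 0.3))
                )
        df = pd.DataFrame(rows)
        adj = rm_ancova(df, dv="y", within=["rep"], between="group", covariate="cov")
        raw = rm_ancova(df, dv="y", within=["rep"], between="group")
        f_adj = adj.loc[adj["effect"] == "group", "F"].iloc[0]
        f_raw = raw.loc[raw["effect"] == "group", "F"].iloc[0]
        assert f_adj < f_raw


class TestPosthocAndResponseSlowing:
    def test_posthoc_bonferroni_and_family(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(40)],
                "sex": ["f"] * 20 + ["m"] * 20,
                "phase": ["baseline", "test"] * 20,
                "y": rng.normal(size=40),
            }
        )
        out = posthoc_pairwise(df, dv="y", factor="sex", by="phase", kind="between")
        assert len(out) == 2
        assert np.all(out["p_bonferroni"] >= out["p_raw"])
        assert np.all(out["p_bonferroni"] <= 1.0)

    def _cells(self, n_subjects, slowing=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            base = 400 + rng.normal(0, 20)
            for label in ("CS+/CSn", "CSn/CSn"):
                inc_shift = slowing if label == "CS+/CSn" else 0.0
                rows.append(
                    dict(
                        subject_id=f"s{s}", phase="test", target_label=label,
                        duration_ms=100,
                        rt_congruent=base + rng.normal(0, 5),
                        rt_incongruent=base + inc_shift + rng.normal(0, 5),
                        rt_neutral=base,
                    )
                )
        return pd.DataFrame(rows)

    def test_injected_slowing_detected_and_monotone(self):
        subjects = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(24)],
             "sex": ["female", "male"] * 12,
             "bmi": np.linspace(19, 29, 24)}
        )
        f_vals = []
        for slowing in (0.0, 10.0, 25.0):
            tab = response_slowing_test(self._cells(24, slowing, seed=3), subjects, 100)
            row = tab[tab["effect"] == "cue x congruency"].iloc[0]
            f_vals.append(row["F"])
        assert f_vals[0] < f_vals[1] < f_vals[2]
        assert f_vals[2] > 10  # a 25 ms CS+-specific slowing is clearly detected

    def test_single_subject_rejected(self):
        subjects = pd.DataFrame(
            {"subject_id": ["s0"], "sex": ["female"], "bmi": [22.0]}
        )
        with pytest.raises(ValueError):
            response_slowing_test(self._cells(1), subjects, 100)


def test_format_effect_report_style():
    row = pd.Series({"F": 7.8, "p": 0.007, "partial_eta_sq": 0.14})
    assert format_effect(row) == "F = 7.80, p = .007, eta2 = .14"
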