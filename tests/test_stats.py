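"""Statistical engine: split-plot ANOVA, bootstrap F-null, Duncan test,
one-sample tests, bootstrap CIs, assumption checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazecue.stats import (SplitPlotData, assumption_checks, bootstrap_f_null,
                           bootstrap_mean_ci, cohens_d, duncan_critical_range,
                           duncan_posthoc, one_sample_t,
                           pearson_with_bootstrap_ci, split_plot_anova)


# ---------------------------------------------------------------------------
# independent projection-matrix oracle
# ---------------------------------------------------------------------------

def _dummies(labels):
    labs = sorted(set(labels))
    return np.array([[1.0 if l == lab else 0.0 for lab in labs]
                     for l in labels])


def projection_oracle(y, n1):
    """Sequential OLS residual-SS differences for the split-plot strata."""
    N, k = y.shape
    subj = np.repeat(np.arange(N), k)
    cond = np.tile(np.arange(k), N)
    grp = np.repeat([0] * n1 + [1] * (N - n1), k)
    yy = y.ravel()

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        return ((yy - X @ beta) ** 2).sum()

    one = np.ones((N * k, 1))
    Xg = np.hstack([one, _dummies(grp)])
    Xgs = np.hstack([Xg, _dummies(subj)])
    Xgsc = np.hstack([Xgs, _dummies(cond)])
    inter = np.array([[1.0 if (g == a and c == b) else 0.0
                       for a in (0, 1) for b in range(k)]
                      for g, c in zip(grp, cond)])
    Xfull = np.hstack([Xgsc, inter])
    return {
        "group": rss(one) - rss(Xg),
        "subj": rss(Xg) - rss(Xgs),
        "condition": rss(Xgs) - rss(Xgsc),
        "interaction": rss(Xgsc) - rss(Xfull),
        "resid": rss(Xfull),
    }


def make_data(y, n1):
    return SplitPlotData(np.asarray(y, float),
                         np.array(["a"] * n1 + ["b"] * (len(y) - n1)))


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

class TestSplitPlotAnova:
    # 2 groups x 3 subjects x 4 conditions; strata verified by hand via the
    # cell-means formulas and by the projection oracle above
    TOY = np.array([
        [3.0, 5.0, 9.0, 7.0],
        [1.0, 8.0, 4.0, 7.0],
        [5.0, 6.0, 8.0, 9.0],
        [4.0, 4.0, 6.0, 2.0],
        [2.0, 5.0, 7.0, 2.0],
        [3.0, 6.0, 8.0, 4.0],
    ])

    def test_toy_table_matches_hand_computation(self):
        res = split_plot_anova(make_data(self.TOY, 3))
        assert res.effects.loc["group", "SS"] == pytest.approx(15.0416667)
        assert res.error_strata.loc["subjects_within_group", "SS"] == \
            pytest.approx(12.1666667)
        assert res.effects.loc["condition", "SS"] == pytest.approx(49.7916667)
        assert res.effects.loc["interaction", "SS"] == pytest.approx(25.125)
        assert res.error_strata.loc["residual", "SS"] == pytest.approx(25.8333333)
        assert res.effects.loc["group", "F"] == pytest.approx(4.9452055)
        assert res.effects.loc["condition", "F"] == pytest.approx(7.7096774)
        assert res.effects.loc["interaction", "F"] == pytest.approx(3.8903226)
        assert res.effects.loc["group", "df_error"] == 4
        assert res.effects.loc["interaction", "df"] == 3
        assert res.effects.loc["interaction", "df_error"] == 12
        assert res.effects.loc["interaction", "partial_eta_sq"] == \
            pytest.approx(0.4930499)

    @pytest.mark.parametrize("n1,n2,seed", [(2, 2, 0), (3, 2, 1), (4, 4, 2),
                                            (4, 3, 3), (2, 4, 4)])
    def test_agrees_with_projection_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(n1 + n2, 4))
        res = split_plot_anova(make_data(y, n1))
        oracle = projection_oracle(y, n1)
        assert res.effects.loc["group", "SS"] == pytest.approx(
            oracle["group"], rel=1e-8)
        assert res.effects.loc["condition", "SS"] == pytest.approx(
            oracle["condition"], rel=1e-8)
        assert res.effects.loc["interaction", "SS"] == pytest.approx(
            oracle["interaction"], rel=1e-8)
        assert res.error_strata.loc["residual", "SS"] == pytest.approx(
            oracle["resid"], rel=1e-8)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(11, 4))
        groups = np.array(["a"] * 6 + ["b"] * 5)
        res = split_plot_anova(SplitPlotData(y, groups))
        long = pd.DataFrame({
            "y": y.ravel(), "subj": np.repeat(np.arange(11), 4),
            "cond": np.tile(np.arange(4), 11), "grp": np.repeat(groups, 4)})
        ref = pg.mixed_anova(long, dv="y", within="cond", subject="subj",
                             between="grp").set_index("Source")
        assert res.effects.loc["group", "F"] == pytest.approx(
            ref.loc["grp", "F"], rel=1e-9)
        assert res.effects.loc["condition", "F"] == pytest.approx(
            ref.loc["cond", "F"], rel=1e-9)
        assert res.effects.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_location_invariance(self, rng):
        y = rng.normal(size=(9, 4))
        f0 = split_plot_anova(make_data(y, 5)).effects["F"]
        f1 = split_plot_anova(make_data(y + 17.3, 5)).effects["F"]
        assert np.allclose(f0, f1)

    def test_flat_within_profile_gives_zero_condition_effect(self):
        y = np.array([[1.0] * 4, [2.0] * 4, [5.0] * 4, [6.0] * 4])
        res = split_plot_anova(make_data(y, 2))
        assert res.effects.loc["condition", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert res.effects.loc["interaction", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert res.effects.loc["group", "F"] > 0

    def test_ss_decomposition_is_exact(self, rng):
        for _ in range(5):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            y = rng.normal(size=(n1 + n2, 4)) * rng.uniform(0.5, 20)
            res = split_plot_anova(make_data(y, n1))
            total = ((y - y.mean()) ** 2).sum()
            assert res.ss_total == pytest.approx(total, rel=1e-10)

    def test_partial_eta_sq_bounds(self, rng):
        y = rng.normal(size=(8, 4))
        res = split_plot_anova(make_data(y, 4))
        assert ((res.effects["partial_eta_sq"] >= 0)
                & (res.effects["partial_eta_sq"] <= 1)).all()

    def test_single_participant_group_rejected(self):
        with pytest.raises(ValueError):
            make_data(np.zeros((3, 4)), 1)


# ---------------------------------------------------------------------------
# bootstrap F-null
# ---------------------------------------------------------------------------

class TestBootstrapFNull:
    def test_seeded_determinism(self, rng):
        data = make_data(rng.normal(size=(10, 4)), 5)
        a = bootstrap_f_null(data, b=200, seed=42)
        b = bootstrap_f_null(data, b=200, seed=42)
        assert a.p_boot == b.p_boot
        assert np.array_equal(a.null_f["interaction"], b.null_f["interaction"])

    def test_huge_effect_gets_zero_p(self, rng):
        # group means 0 vs 1000 with tiny noise: no structure-breaking
        # resample reaches the observed F
        y = np.vstack([rng.normal(0, 0.1, (4, 4)),
                       rng.normal(1000, 0.1, (4, 4))])
        res = bootstrap_f_null(make_data(y, 4), b=300, seed=1)
        assert res.p_boot["group"] == 0.0

    def test_plus_one_convention(self, rng):
        y = np.vstack([rng.normal(0, 0.1, (4, 4)),
                       rng.normal(1000, 0.1, (4, 4))])
        res = bootstrap_f_null(make_data(y, 4), b=299, seed=1, plus_one=True)
        assert res.p_boot["group"] == pytest.approx(1 / 300)

    def test_null_p_values_not_degenerate(self, rng):
        # under the null the bootstrap p should be spread over (0, 1)
        ps = []
        for i in range(40):
            data = make_data(np.random.default_rng(500 + i).normal(size=(12, 4)), 6)
            ps.append(bootstrap_f_null(data, b=150, seed=i).p_boot["interaction"])
        ps = np.array(ps)
        assert ps.min() < 0.2 and ps.max() > 0.8
        assert 0.2 < ps.mean() < 0.8

    def test_participant_resampling_mode(self, rng):
        data = make_data(rng.normal(size=(10, 4)), 5)
        res = bootstrap_f_null(data, b=100, seed=3, unit="participant")
        assert len(res.null_f["group"]) == 100
        assert all(0 <= p <= 1 for p in res.p_boot.values())


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

class TestDuncan:
    # published 5% significant studentized ranges for Duncan's test
    PUBLISHED = {(2, 20): 2.95, (3, 20): 3.10, (4, 20): 3.18, (5, 20): 3.25,
                 (2, 10): 3.15, (3, 10): 3.30, (4, 10): 3.37,
                 (2, 30): 2.89, (3, 30): 3.04, (4, 30): 3.12, (5, 30): 3.20}

    @pytest.mark.parametrize("p,df", sorted(PUBLISHED))
    def test_critical_values_match_published_tables(self, p, df):
        crit = duncan_critical_range(0.05, p, df, error_ms=1.0, n=1.0)
        assert crit == pytest.approx(self.PUBLISHED[(p, df)], abs=0.015)

    def test_identical_means_nothing_significant(self):
        out = duncan_posthoc({"a": 2.0, "b": 2.0, "c": 2.0},
                             error_ms=1.0, error_df=20, n_per_mean=10)
        assert not out["significant"].any()

    def test_two_means_reduce_to_studentized_range_decision(self):
        ms, df, n = 2.0, 20, 8
        crit = sps.studentized_range.ppf(0.95, 2, df) * np.sqrt(ms / n)
        for diff in (crit * 0.95, crit * 1.05):
            out = duncan_posthoc({"a": 0.0, "b": diff}, ms, df, n)
            assert bool(out["significant"].iloc[0]) == (diff > crit)

    def test_wide_separation_all_significant(self):
        out = duncan_posthoc({"a": 0.0, "b": 10.0, "c": 20.0, "d": 30.0},
                             error_ms=1.0, error_df=20, n_per_mean=10)
        assert out["significant"].all()

    def test_nonsignificant_outer_range_blocks_inner_pairs(self):
        # outer spread below its critical range: every inner pair must be
        # declared non-significant too, whatever its own range says
        ms, df, n = 100.0, 20, 2
        out = duncan_posthoc({"a": 0.0, "b": 0.1, "c": 0.2, "d": 0.3},
                             ms, df, n)
        assert not out["significant"].any()

    def test_degenerate_zero_variance_warns_and_flags(self):
        with pytest.warns(UserWarning):
            out = duncan_posthoc({"a": 1.0, "b": 2.0}, 0.0, 20, 10)
        assert out["significant"].all()


# ---------------------------------------------------------------------------
# one-sample tests and bootstrap CIs
# ---------------------------------------------------------------------------

class TestOneSampleT:
    def test_hand_computed_statistic(self):
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res["df"] == 2

    def test_symmetric_sample_gives_zero_t(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([3.0, 3.0, 3.0])


class TestBootstrapMeanCI:
    def test_constant_sample_degenerate_interval(self):
        res = bootstrap_mean_ci([4.2] * 10, b=100, seed=1)
        assert res["ci_low"] == res["ci_high"] == pytest.approx(4.2)

    def test_seeded_determinism(self, rng):
        v = rng.normal(size=15)
        a = bootstrap_mean_ci(v, b=500, seed=9)
        b = bootstrap_mean_ci(v, b=500, seed=9)
        assert a == b

    def test_width_tracks_normal_approximation(self):
        # n=13 from N(8, 10^2): expected width ~ 2 * 1.96 * s / sqrt(13)
        rng = np.random.default_rng(5)
        widths, expected = [], []
        for _ in range(20):
            v = rng.normal(8.0, 10.0, 13)
            res = bootstrap_mean_ci(v, b=2000, seed=int(rng.integers(2**31)))
            widths.append(res["ci_high"] - res["ci_low"])
            expected.append(2 * 1.96 * v.std(ddof=1) / np.sqrt(13))
        assert np.mean(widths) == pytest.approx(np.mean(expected), rel=0.12)


class TestPearsonBootstrap:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_with_bootstrap_ci(x, 2 * x + 1, b=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)
        assert res.excludes_zero

    def test_matches_closed_form_r(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = pearson_with_bootstrap_ci(x, y, b=100, seed=1)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.r == pytest.approx(num / den, rel=1e-12)

    def test_joint_permutation_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        perm = rng.permutation(25)
        r0 = pearson_with_bootstrap_ci(x, y, b=50, seed=2).r
        r1 = pearson_with_bootstrap_ci(x[perm], y[perm], b=50, seed=2).r
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_independent_data_ci_straddles_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=200), rng.normal(size=200)
        res = pearson_with_bootstrap_ci(x, y, b=1000, seed=3)
        assert abs(res.r) < 0.2
        assert res.ci_low < 0 < res.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_bootstrap_ci([1.0] * 5, [1, 2, 3, 4, 5])


class TestCohensD:
    def test_identical_samples_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_pooled(self):
        # means 1 vs 3, pooled SD sqrt(2)
        assert cohens_d([0.0, 2.0], [2.0, 4.0]) == pytest.approx(-np.sqrt(2))

    def test_unit_effect(self, rng):
        a = rng.normal(size=2000)
        d = cohens_d(a + 1.0, a)
        assert d == pytest.approx(1.0, abs=0.05)

    def test_paired_mode_uses_difference_sd(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a - np.array([1.0, 3.0, 1.0, 3.0])
        d = (a - b)
        assert cohens_d(a, b, paired=True) == pytest.approx(
            d.mean() / d.std(ddof=1))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

class TestAssumptionChecks:
    def test_normal_cells_usually_pass(self):
        rng = np.random.default_rng(8)
        cells = {(g, c): rng.normal(size=50)
                 for g in ("a", "b") for c in ("c1", "c2")}
        out = assumption_checks(cells)
        assert (out["shapiro"]["p"] > 0.01).all()
        assert (out["levene"]["p"] > 0.01).all()

    def test_skewed_cell_triggers_bootstrap_routing(self):
        rng = np.random.default_rng(9)
        cells = {("a", "c1"): rng.lognormal(0, 1.5, 60),
                 ("b", "c1"): rng.normal(size=60)}
        out = assumption_checks(cells)
        assert out["bootstrap_recommended"]

    def test_unequal_variances_trigger_levene(self):
        rng = np.random.default_rng(10)
        cells = {("a", "c1"): rng.normal(0, 1, 60),
                 ("b", "c1"): rng.normal(0, 5, 60)}
        out = assumption_checks(cells)
        assert (out["levene"]["p"] < 0.05).any()

    def test_tiny_or_constant_cells_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = assumption_checks({("a", "c1"): np.array([1.0, 2.0]),
                                     ("b", "c1"): np.array([3.0, 3.0, 3.0])})
        assert out["shapiro"]["skipped"].any()
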