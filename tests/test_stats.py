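import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hdpoly.stats import (
    ks_normality,
    mann_whitney_hl,
    oneway_anova,
    partial_spearman,
    rm_anova,
    spearman,
    steiger_z,
    tukey_hsd,
)


def _mixed_table(rng, n_sub, W, group_sizes, covariate=False, group_effect=0.0,
                 within_effect=0.0):
    rows = []
    s = 0
    for g, ng in zip("abc", group_sizes):
        for _ in range(ng):
            base = rng.normal()
            age = rng.uniform(30, 60)
            for w in range(W):
                val = base + within_effect * w + (group_effect * w if g == "b" else 0)
                if covariate:
                    val += 0.02 * age
                rows.append(dict(subject=f"s{s}", group=g, w=f"w{w:03d}", age=age,
                                 value=val + rng.normal(0, 0.5)))
            s += 1
    return pd.DataFrame(rows)


class TestRmAnovaDfs:
    @pytest.mark.parametrize(
        "W,groups,cov,effect,dfn,dfd",
        [
            (171, (20, 20), False, "w", 170, 6460),
            (171, (20, 20), False, "w*group", 170, 6460),
            (6, (20, 20), True, "w", 5, 185),
            (171, (21, 10, 9), False, "w*group", 340, 6290),
            (74, (20, 20), True, "w", 73, 2701),
        ],
    )
    def test_design_df_grid(self, W, groups, cov, effect, dfn, dfd):
        rng = np.random.default_rng(0)
        df = _mixed_table(rng, sum(groups), W, groups, covariate=cov)
        res = rm_anova(df, "value", "subject", "w", "group",
                       covariate="age" if cov else None)
        row = res.effect(effect if not cov else effect)
        assert (row["df_num"], row["df_den"]) == (dfn, dfd)

    def test_df_formula_property(self):
        """df_num = W-1 / (W-1)(G-1); df_den = (W-1)(n-G-c) across a grid."""
        rng = np.random.default_rng(1)
        for W, groups, cov in [(4, (5, 6), False), (3, (4, 4, 5), True),
                               (7, (6, 5), True)]:
            n, G = sum(groups), len(groups)
            c = int(cov)
            df = _mixed_table(rng, n, W, groups, covariate=cov)
            res = rm_anova(df, "value", "subject", "w", "group",
                           covariate="age" if cov else None)
            assert tuple(res.effect("w")[["df_num", "df_den"]]) == \
                (W - 1, (W - 1) * (n - G - c))
            assert tuple(res.effect("w*group")[["df_num", "df_den"]]) == \
                ((W - 1) * (G - 1), (W - 1) * (n - G - c))
            assert tuple(res.effect("group")[["df_num", "df_den"]]) == \
                (G - 1, n - G - c)


class TestRmAnovaValues:
    def test_hand_sums_of_squares_oracle(self):
        """4 subjects x 3 levels, 2 groups: classical marginal-mean SS."""
        data = np.array([  # subjects s0,s1 group a; s2,s3 group b
            [1.0, 2.0, 4.0],
            [2.0, 3.0, 3.0],
            [3.0, 5.0, 7.0],
            [2.0, 6.0, 8.0],
        ])
        rows = [dict(subject=f"s{s}", group="a" if s < 2 else "b", w=f"w{w}",
                     value=data[s, w]) for s in range(4) for w in range(3)]
        res = rm_anova(pd.DataFrame(rows), "value", "subject", "w", "group")
        grand = data.mean()
        subj_m = data.mean(axis=1)
        grp_m = np.array([data[:2].mean(), data[2:].mean()])
        w_m = data.mean(axis=0)
        wg_m = np.array([data[:2].mean(axis=0), data[2:].mean(axis=0)])
        ss_group = 3 * 2 * ((grp_m - grand) ** 2).sum()
        ss_serr = 3 * ((subj_m - np.repeat(grp_m, 2)) ** 2).sum()
        ss_w = 4 * ((w_m - grand) ** 2).sum()
        ss_wg = 2 * ((wg_m - w_m[None, :] - grp_m[:, None] + grand) ** 2).sum()
        resid = (data - subj_m[:, None] - np.repeat(wg_m, 2, axis=0)
                 + np.repeat(grp_m, 2)[:, None])
        ss_werr = (resid ** 2).sum()
        f_group = (ss_group / 1) / (ss_serr / 2)
        f_w = (ss_w / 2) / (ss_werr / 4)
        f_wg = (ss_wg / 2) / (ss_werr / 4)
        assert res.effect("group")["F"] == pytest.approx(f_group, rel=1e-10)
        assert res.effect("w")["F"] == pytest.approx(f_w, rel=1e-10)
        assert res.effect("w*group")["F"] == pytest.approx(f_wg, rel=1e-10)
        # generalized eta squared: effect over effect + all error SS
        denom_err = ss_serr + ss_werr
        assert res.effect("w")["ges"] == pytest.approx(ss_w / (ss_w + denom_err))
        assert res.effect("group")["ges"] == pytest.approx(
            ss_group / (ss_group + denom_err))

    def test_matches_pingouin_balanced_mixed(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = _mixed_table(rng, 12, 4, (6, 6), group_effect=0.4, within_effect=0.3)
        res = rm_anova(df, "value", "subject", "w", "group")
        ref = pg.mixed_anova(data=df, dv="value", within="w", subject="subject",
                             between="group", effsize="ng2")
        for mine, theirs in [("group", "group"), ("w", "w"),
                             ("w*group", "Interaction")]:
            row = ref[ref["Source"] == theirs].iloc[0]
            assert res.effect(mine)["F"] == pytest.approx(row["F"], rel=1e-8)
            assert res.effect(mine)["ges"] == pytest.approx(row["ng2"], rel=1e-8)

    def test_covariate_strata_against_car_oracle(self):
        """Frozen Type III oracle (R car::Anova on the two strata)."""
        rng = np.random.default_rng(7)
        rows = []
        for s in range(11):
            g = "a" if s < 6 else "b"
            base = rng.normal(0, 1)
            age = rng.uniform(30, 60)
            for w in range(3):
                rows.append(dict(
                    subject=f"s{s}", group=g, w=f"w{w}", age=age,
                    value=base + 0.03 * age + w * 0.3 + (0.4 * w if g == "b" else 0)
                    + 0.01 * age * w + rng.normal(0, .5)))
        res = rm_anova(pd.DataFrame(rows), "value", "subject", "w", "group",
                       covariate="age")
        assert res.effect("group")["F"] == pytest.approx(3.5113, abs=2e-4)
        assert res.effect("group")["p"] == pytest.approx(0.0978265, abs=1e-5)
        assert res.effect("age")["F"] == pytest.approx(2.9426, abs=2e-4)
        # within stratum: Type III SS from car (w 17.1656, w:group 0.8626,
        # w:age 0.7404, stratum residual 2.4911 on (W-1)(n-G-c)=16 df)
        assert res.effect("w")["F"] == pytest.approx((17.1656 / 2) / (2.4911 / 16),
                                                     rel=2e-4)
        assert res.effect("w*group")["F"] == pytest.approx(
            (0.8626 / 2) / (2.4911 / 16), rel=2e-4)
        assert res.effect("w*age")["F"] == pytest.approx(
            (0.7404 / 2) / (2.4911 / 16), rel=2e-4)

    def test_identical_groups_zero_group_f(self):
        data = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        rows = [dict(subject=f"s{s}", group=g, w=f"w{w}", value=data[s % 2, w])
                for s in range(8) for w in range(3) for g in [("a" if s < 4 else "b")]]
        res = rm_anova(pd.DataFrame(rows), "value", "subject", "w", "group")
        assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-20)
        assert res.effect("group")["p"] == pytest.approx(1.0)

    def test_ges_affine_invariant(self):
        rng = np.random.default_rng(9)
        df = _mixed_table(rng, 10, 3, (5, 5), group_effect=0.3)
        r1 = rm_anova(df, "value", "subject", "w", "group")
        df2 = df.assign(value=3.0 * df["value"] + 7.0)
        r2 = rm_anova(df2, "value", "subject", "w", "group")
        assert np.allclose(r1.table["ges"], r2.table["ges"])
        assert np.allclose(r1.table["F"], r2.table["F"])

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(10)
        df = _mixed_table(rng, 6, 3, (3, 3))
        df = df.drop(df.index[1])
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, "value", "subject", "w", "group")

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(11)
        df = _mixed_table(rng, 6, 3, (3, 3))
        df["age"] = 50.0
        with pytest.raises(ValueError, match="constant"):
            rm_anova(df, "value", "subject", "w", "group", covariate="age")


class TestOnewayAnova:
    def test_three_group_design_df(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal(40)
        groups = np.array(["ctl"] * 21 + ["near"] * 10 + ["far"] * 9)
        res = oneway_anova(values, groups)
        assert tuple(res.effect("group")[["df_num", "df_den"]]) == (2, 37)

    def test_equal_groups_f_zero(self):
        values = np.tile([1.0, 2.0, 3.0], 2)
        res = oneway_anova(values, ["a"] * 3 + ["b"] * 3)
        assert res.effect("group")["F"] == pytest.approx(0.0)

    def test_hand_ss_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0, 2.0, 4.0, 6.0])
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = oneway_anova(values, groups)
        f_ref, p_ref = sps.f_oneway(values[:3], values[3:6], values[6:])
        assert res.effect("group")["F"] == pytest.approx(f_ref)
        assert res.effect("group")["p"] == pytest.approx(p_ref)
        grand = values.mean()
        ssb = 3 * sum((values[i:i + 3].mean() - grand) ** 2 for i in (0, 3, 6))
        sst = ((values - grand) ** 2).sum()
        assert res.effect("group")["ges"] == pytest.approx(ssb / sst)


class TestTukey:
    def test_identical_groups(self):
        res = tukey_hsd(np.tile([1.0, 2.0, 3.0], 2), ["a"] * 3 + ["b"] * 3)
        row = res.comparison("a", "b")
        assert row["p_adj"] == pytest.approx(1.0)
        assert row["ci_low"] < 0 < row["ci_high"]

    def test_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(10)
        ps = []
        for shift in (0.2, 0.8, 1.6, 3.0):
            res = tukey_hsd(np.concatenate([base, base + shift]),
                            ["a"] * 10 + ["b"] * 10)
            ps.append(res.table.iloc[0]["p_adj"])
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_studentized_range_oracle(self):
        """Tukey-Kramer p from the studentized-range distribution directly."""
        rng = np.random.default_rng(2)
        samples = [rng.standard_normal(6), rng.standard_normal(5) + 1.0,
                   rng.standard_normal(7) - 0.5]
        values = np.concatenate(samples)
        groups = np.array(["a"] * 6 + ["b"] * 5 + ["c"] * 7)
        res = tukey_hsd(values, groups)
        df_err = len(values) - 3
        mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_err
        for (i, a), (j, b) in itertools.combinations(enumerate("abc"), 2):
            se = np.sqrt(mse / 2 * (1 / len(samples[i]) + 1 / len(samples[j])))
            q = abs(samples[i].mean() - samples[j].mean()) / se
            p_ref = sps.studentized_range.sf(q, 3, df_err)
            assert res.comparison(a, b)["p_adj"] == pytest.approx(p_ref, abs=1e-6)

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(18)
        groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        res = tukey_hsd(values, groups)
        for a, b in itertools.combinations("abc", 2):
            t_p = sps.ttest_ind(values[groups == a], values[groups == b]).pvalue
            assert res.comparison(a, b)["p_adj"] >= t_p - 1e-12


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_independent_large_n(self):
        rng = np.random.default_rng(4)
        res = spearman(rng.standard_normal(500), rng.standard_normal(500))
        assert abs(res.rho) < 0.1
        assert res.ci_low < 0 < res.ci_high

    def test_n19_brute_force_rank_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 19))
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_ref = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(rho_ref, abs=1e-12)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))


class TestPartialSpearman:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        z = rng.standard_normal(30)
        x = z + rng.standard_normal(30)
        y = 0.5 * z + rng.standard_normal(30)
        res = partial_spearman(x, y, z)
        ref = pg.partial_corr(data=pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z", method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_removes_shared_driver(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(200)
        x = z + 0.3 * rng.standard_normal(200)
        y = z + 0.3 * rng.standard_normal(200)
        assert spearman(x, y).rho > 0.7
        assert abs(partial_spearman(x, y, z).rho) < 0.25


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.5, 0.5, 0.3, 40)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_formula_evaluation(self):
        # frozen hand evaluation of the pooled-r Steiger Z1* formula
        r_xy, r_xz, r_yz, n = 0.6, 0.3, 0.4, 50
        rbar = 0.45
        psi = r_yz * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r_yz ** 2)
        sbar = psi / (1 - rbar ** 2) ** 2
        z_ref = (np.arctanh(r_xy) - np.arctanh(r_xz)) * np.sqrt(
            (n - 3) / (2 * (1 - sbar)))
        z, p = steiger_z(r_xy, r_xz, r_yz, n)
        assert z == pytest.approx(z_ref, rel=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(z_ref)), rel=1e-12)

    def test_magnitude_comparison_sign_invariance(self):
        z1, _ = steiger_z(0.6, 0.3, 0.4, 50)
        z2, _ = steiger_z(-0.6, 0.3, -0.4, 50)
        assert z1 == pytest.approx(z2)

    def test_invalid_correlation_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            steiger_z(0.9, 0.9, -0.9, 30)

    def test_type_i_error_calibrated(self):
        """Under truly equal dependent correlations, rejects ~5% at alpha=.05."""
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.5], [0.4, 0.5, 1.0]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        n, reps = 60, 2000
        for _ in range(reps):
            d = rng.standard_normal((n, 3)) @ L.T
            r = np.corrcoef(d, rowvar=False)
            _, p = steiger_z(r[0, 1], r[0, 2], r[1, 2], n)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.03 < rate < 0.07  # binomial 95% band around 0.05 is ~(0.040, 0.060)


class TestMannWhitneyHL:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney_hl(x, x.copy())
        assert res.hl_shift == pytest.approx(0.0)
        assert res.u_min == res.u_max == pytest.approx(8.0)

    def test_small_enumerated_example(self):
        res = mann_whitney_hl([1.0, 2.0], [3.0, 5.0])
        assert res.hl_shift == pytest.approx(2.5)  # median of {1,2,3,4}
        assert res.u_max == pytest.approx(4.0)
        assert res.u_min + res.u_max == res.n1 * res.n2

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.standard_normal(4)
            y = rng.standard_normal(4) + 0.8
            res = mann_whitney_hl(x, y)
            pooled = np.concatenate([x, y])
            us = []
            for comb in itertools.combinations(range(8), 4):
                rest = [i for i in range(8) if i not in comb]
                us.append(np.sum(pooled[list(comb)][:, None] > pooled[rest][None, :]))
            us = np.array(us)
            p_ref = min(1.0, (np.sum(us <= res.u_min) + np.sum(us >= res.u_max)) / 70)
            assert res.exact
            assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_hl_within_pairwise_difference_range(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal(8), rng.standard_normal(6) + 1
        res = mann_whitney_hl(x, y)
        diffs = (y[None, :] - x[:, None]).ravel()
        assert diffs.min() <= res.ci_low <= res.hl_shift <= res.ci_high <= diffs.max()
        assert res.hl_shift == pytest.approx(np.median(diffs))

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.1, 2, 12)
        y = rng.uniform(0.1, 2, 9) * 1.4
        p1 = mann_whitney_hl(x, y).p
        p2 = mann_whitney_hl(np.log(x), np.log(y)).p
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_moses_ci_covers_shift(self):
        """Order-statistic CI has ~95% coverage for a pure location shift."""
        rng = np.random.default_rng(12)
        cover = 0
        for _ in range(300):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12) + 1.0
            res = mann_whitney_hl(x, y)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert cover / 300 > 0.90

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_hl([], [1.0])


class TestKsNormality:
    def test_statistic_bounds_and_types(self):
        rng = np.random.default_rng(13)
        stat, p, reject = ks_normality(rng.standard_normal(50))
        assert 0 <= stat <= 1 and 0 <= p <= 1 and isinstance(reject, bool)

    def test_calibration_on_normal_samples(self):
        rng = np.random.default_rng(14)
        accepted = sum(not ks_normality(rng.standard_normal(500))[2]
                       for _ in range(100))
        assert accepted >= 92  # nominal 95% acceptance

    def test_pileup_distribution_rejected_with_large_statistic(self):
        x = np.concatenate([np.zeros(95), np.linspace(10, 12, 5)])
        stat, p, reject = ks_normality(x)
        assert reject and stat > 0.4

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(20))
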