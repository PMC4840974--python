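"""The DV algorithms: elementary tests, empirical-Bayes machinery, runners."""

import numpy as np
import pytest
from scipy import special, stats

from dvmeth import (
    ModeratedVariancePrior,
    SimConfig,
    bartlett_test,
    fit_variance_prior,
    run_bt,
    run_diffvar,
    run_gamlss_ls,
    run_ievora,
    run_jdmdv,
    run_ttest_dmc,
    simulate_dataset,
    two_sample_t,
)
from dvmeth.core import to_mvalues
from dvmeth.simulator import null_config

from .conftest import make_dataset


class TestBartlett:
    def test_identical_groups_null(self):
        stat, p = bartlett_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        x0, x1 = np.arange(1.0, 6.0), np.arange(2.0, 11.0, 2.0)
        n0 = n1 = 5
        v0, v1 = x0.var(ddof=1), x1.var(ddof=1)
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / 8
        num = 8 * np.log(sp2) - 4 * np.log(v0) - 4 * np.log(v1)
        den = 1 + (1 / 4 + 1 / 4 - 1 / 8) / 3
        stat, p = bartlett_test(x0, x1)
        assert stat == pytest.approx(num / den, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(num / den, 1), abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            x0 = rng.normal(size=rng.integers(3, 20))
            x1 = rng.normal(size=rng.integers(3, 20))
            stat, p = bartlett_test(x0, x1)
            ref_stat, ref_p = stats.bartlett(x0, x1)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_scale_invariance(self):
        x0, x1 = [1, 2, 3, 4, 5], [2, 4, 6, 8, 10]
        assert bartlett_test(x0, x1) == pytest.approx(
            bartlett_test([10 * v for v in x0], [10 * v for v in x1])
        )

    def test_degenerate_zero_variance_missing(self):
        stat, p = bartlett_test([1, 1, 1], [1, 2, 3])
        assert np.isnan(stat) and np.isnan(p)
        stat, p = bartlett_test([2, 2, 2], [5, 5, 5])
        assert np.isnan(stat) and np.isnan(p)

    def test_too_few_values_missing(self):
        stat, p = bartlett_test([1, 2], [1, 2, 3])
        assert np.isnan(p)


class TestTwoSampleT:
    def test_identical_groups(self):
        stat, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x0, x1 = rng.normal(size=6), rng.normal(1.0, 1.0, size=8)
        s01, p01 = two_sample_t(x0, x1)
        s10, p10 = two_sample_t(x1, x0)
        assert s01 == pytest.approx(-s10)
        assert p01 == pytest.approx(p10)

    @pytest.mark.parametrize("variant,equal_var", [("welch", False), ("pooled", True)])
    def test_agrees_with_scipy(self, rng, variant, equal_var):
        x0 = np.array([0.1, 0.1, 0.1, 0.1, 0.2])
        x1 = np.array([0.1, 0.6, 0.1, 0.1, 0.1])
        stat, p = two_sample_t(x0, x1, variant)
        ref = stats.ttest_ind(x1, x0, equal_var=equal_var)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_sign_convention(self):
        stat, _ = two_sample_t([0.1, 0.2, 0.1], [0.6, 0.7, 0.8])
        assert stat > 0

    def test_constant_equal_groups(self):
        stat, p = two_sample_t([1, 1, 1], [1, 1, 1])
        assert (stat, p) == (0.0, 1.0)

    def test_constant_unequal_groups_missing(self):
        stat, p = two_sample_t([1, 1, 1], [2, 2, 2])
        assert np.isnan(p)


class TestVariancePrior:
    def test_recovery_from_scaled_chi2(self, rng):
        d0, s0_sq, df = 4.0, 1.0, 20
        s2 = s0_sq * d0 / stats.chi2.rvs(d0, size=20_000, random_state=7)
        s2 *= stats.chi2.rvs(df, size=20_000, random_state=8) / df
        prior = fit_variance_prior(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert prior.s0_squared == pytest.approx(s0_sq, rel=0.05)

    def test_identical_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(100, 2.5), df=10)
        assert np.isinf(prior.d0)
        # with no spread, the point estimate of the prior variance is the
        # bias-corrected common value on the log scale
        e = np.log(2.5) - special.digamma(5) + np.log(5)
        assert prior.s0_squared == pytest.approx(np.exp(e))

    def test_low_dispersion_takes_infinite_branch(self, rng):
        # var(e) below trigamma(df/2) cannot arise from a finite d0
        s2 = np.exp(rng.normal(0, 0.01, size=1000))
        prior = fit_variance_prior(s2, df=4)
        assert np.isinf(prior.d0)

    def test_nonpositive_excluded_then_error(self):
        with pytest.raises(ValueError):
            fit_variance_prior(np.zeros(50), df=10)

    def test_agrees_with_limma_fitFDist(self, tmp_path):
        """The method-of-moments fit matches limma's fitFDist (the canonical
        implementation of this estimator) on the same variance vector."""
        import subprocess

        d0, s0_sq, df = 6.0, 2.0, 18
        s2 = (s0_sq * d0 / stats.chi2.rvs(d0, size=5000, random_state=1)
              * stats.chi2.rvs(df, size=5000, random_state=2) / df)
        np.savetxt(tmp_path / "s2.txt", s2)
        prior = fit_variance_prior(s2, df)
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(limma));'
             f'x<-scan("{tmp_path / "s2.txt"}");'
             f'f<-fitFDist(x, df1={df}); cat(f$df2, f$scale)'],
            capture_output=True, text=True, check=True,
        )
        ref_d0, ref_s0 = map(float, r.stdout.split())
        assert prior.d0 == pytest.approx(ref_d0, rel=1e-4)
        assert prior.s0_squared == pytest.approx(ref_s0, rel=1e-4)

    def test_posterior_between_sample_and_prior(self, rng):
        prior = ModeratedVariancePrior(d0=4.0, s0_squared=1.0)
        s2 = rng.uniform(0.1, 10, size=100)
        post = prior.posterior_variance(s2, np.full(100, 10.0))
        assert np.all(post >= np.minimum(s2, 1.0) - 1e-12)
        assert np.all(post <= np.maximum(s2, 1.0) + 1e-12)


class TestRunBT:
    def test_variance_blowout_ranked_first(self, rng):
        values = rng.beta(10, 90, size=(20, 40))
        values[7, 20:] = np.clip(
            0.1 + rng.normal(0, 0.3, 20), 0.001, 0.999
        )  # group-1 variance ~100x
        ds = make_dataset(values)
        res = run_bt(ds)
        assert res.table.loc[7, "rank"] == 1

    def test_feature_permutation_equivariance(self, rng, small_sim):
        res = run_bt(small_sim.dataset)
        perm = rng.permutation(small_sim.dataset.n_features)
        ds_perm = make_dataset(small_sim.dataset.values[perm],
                               group=small_sim.dataset.group)
        ds_perm.feature_ids = small_sim.dataset.feature_ids[perm]
        res_perm = run_bt(ds_perm)
        a = res.table.set_index("feature_id")
        b = res_perm.table.set_index("feature_id")
        for col in ("statistic", "p_value", "q_value"):
            assert np.allclose(a[col].reindex(b.index), b[col], equal_nan=True)

    def test_mostly_quiet_on_null_data(self):
        zero_call_seeds, total_calls = 0, 0
        for seed in range(10):
            sim = simulate_dataset(null_config(seed=seed))
            res = run_bt(sim.dataset)
            n = int(res.table["significant"].sum())
            zero_call_seeds += n == 0
            total_calls += n
        # Bartlett is slightly anti-conservative on skewed beta data, so a
        # rare seed yields a handful of calls; most seeds are clean
        assert zero_call_seeds >= 8
        assert total_calls <= 20


class TestRunIevora:
    def test_selected_set_identical_to_bt(self, small_sim):
        bt = run_bt(small_sim.dataset, fdr=0.05)
        iev = run_ievora(small_sim.dataset, bt_fdr=0.05)
        assert np.array_equal(bt.table["significant"], iev.table["significant"])

    def test_null_dataset_empty_ranked_set(self):
        sim = simulate_dataset(null_config(seed=0))
        res = run_ievora(sim.dataset)
        assert res.table["rank"].isna().all()
        assert len(res.ranked_features()) == 0

    def test_mean_shift_outranks_outliers(self, rng):
        """A fully shifted (type-1a-like) feature ranks above an
        outlier-driven (type-2-like) feature even when the latter has the
        stronger Bartlett statistic."""
        n = 100
        values = rng.beta(10, 90, size=(50, n))
        values[3, 50:] = rng.beta(6, 4, size=50)       # all disease shifted
        values[9, 50:53] = rng.beta(6, 4, size=3)      # 3 outliers
        ds = make_dataset(values)
        res = run_ievora(ds, bt_fdr=0.05)
        tbl = res.table
        assert tbl.loc[3, "significant"] and tbl.loc[9, "significant"]
        assert tbl.loc[3, "rank"] < tbl.loc[9, "rank"]

    def test_t_columns_present(self, small_sim):
        res = run_ievora(small_sim.dataset)
        assert {"t_stat", "t_p"} <= set(res.table.columns)


class TestRunDiffVar:
    def test_identical_feature_is_null(self, rng):
        values = rng.beta(10, 90, size=(30, 20))
        values[4] = np.tile(np.linspace(0.05, 0.15, 10), 2)  # same in both groups
        ds = make_dataset(values)
        res = run_diffvar(ds)
        assert res.table.loc[4, "statistic"] == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc[4, "p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_d0_zero_reduces_to_ordinary_t(self, rng):
        values = rng.beta(5, 5, size=(40, 30))
        ds = make_dataset(values)
        res = run_diffvar(ds, prior=ModeratedVariancePrior(d0=0.0, s0_squared=1.0))
        mv = to_mvalues(ds)
        z = np.empty_like(mv.values)
        z[:, :15] = np.abs(mv.values[:, :15] - mv.values[:, :15].mean(1, keepdims=True))
        z[:, 15:] = np.abs(mv.values[:, 15:] - mv.values[:, 15:].mean(1, keepdims=True))
        for j in (0, 17, 39):
            ref = stats.ttest_ind(z[j, 15:], z[j, :15], equal_var=True)
            assert res.table.loc[j, "statistic"] == pytest.approx(
                ref.statistic, abs=1e-8
            )
            assert res.table.loc[j, "p_value"] == pytest.approx(ref.pvalue, abs=1e-8)

    def test_squared_deviation_variant_runs(self, small_sim):
        res = run_diffvar(small_sim.dataset, deviation="squared")
        assert np.isfinite(res.table["p_value"].to_numpy()).sum() > 500

    def test_blind_to_outlier_only_dv(self, small_sim):
        """Type-2 sensitivity far below Bartlett's on the same data."""
        bt = run_bt(small_sim.dataset)
        dvar = run_diffvar(small_sim.dataset)
        t2 = small_sim.truth == "type2"
        bt_sens = bt.table.loc[t2, "significant"].mean()
        dv_sens = dvar.table.loc[t2, "significant"].mean()
        assert bt_sens - dv_sens > 0.3


class TestRunJDMDV:
    def test_location_invariance(self, rng):
        values = rng.beta(5, 5, size=(30, 24))
        ds = make_dataset(values)
        base = run_jdmdv(ds)
        # shift all M-values by a constant via a monotone beta remapping is
        # not exact; instead verify directly on the statistic computation:
        # adding a constant to y leaves (y - ybar) unchanged, so recompute
        # with shifted M-values through the internal pathway
        from dvmeth.dv_tests import _group_summaries  # noqa: F401

        mv = to_mvalues(ds)
        mv_shifted = mv.values + 3.7

        def score_stat(Y, group):
            n1 = (group == 1).sum()
            n0 = (group == 0).sum()
            N = n0 + n1
            stats_ = []
            for y in Y:
                ybar = y.mean()
                sig2 = ((y - ybar) ** 2).mean()
                y1 = y[group == 1]
                u_g = 0.5 * (((y1 - ybar) ** 2).sum() / sig2 - n1)
                s = (n0 * n1 * (y1.mean() - y[group == 0].mean()) ** 2
                     / (N * sig2) + 2 * N * u_g**2 / (n0 * n1))
                stats_.append(s)
            return np.array(stats_)

        s_plain = score_stat(mv.values, ds.group)
        s_shift = score_stat(mv_shifted, ds.group)
        assert np.allclose(s_plain, s_shift, atol=1e-8)
        assert np.allclose(base.table["statistic"], s_plain, atol=1e-8)

    def test_joint_statistic_dominates_variance_component(self, rng):
        """The 2-df quadratic form is the sum of a mean part and a variance
        part, so it is at least the variance-only component."""
        values = rng.beta(10, 90, size=(50, 40))
        values[0, 20:] = rng.beta(6, 4, size=20)  # pure mean shift feature
        ds = make_dataset(values)
        res = run_jdmdv(ds)
        mv = to_mvalues(ds)
        y = mv.values[0]
        group = ds.group
        n1, n0 = 20, 20
        ybar = y.mean()
        sig2 = ((y - ybar) ** 2).mean()
        u_g = 0.5 * (((y[group == 1] - ybar) ** 2).sum() / sig2 - n1)
        var_component = 2 * 40 * u_g**2 / (n0 * n1)
        assert res.table.loc[0, "statistic"] >= var_component - 1e-12

    def test_null_uniformity(self, rng):
        values = np.clip(rng.normal(0.5, 0.05, size=(2000, 100)), 0.001, 0.999)
        ds = make_dataset(values)
        p = run_jdmdv(ds).table["p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestRunGAMLSS:
    def test_identical_group_distributions_zero_lrt(self):
        pattern = np.linspace(0.2, 0.4, 10)
        values = np.tile(pattern, (5, 2))
        ds = make_dataset(values)
        res = run_gamlss_ls(ds)
        assert np.allclose(res.table["statistic"], 0.0, atol=1e-9)
        assert np.allclose(res.table["p_mean"], 1.0, atol=1e-6)

    def test_lrts_nonnegative_by_nesting(self, small_sim):
        res = run_gamlss_ls(small_sim.dataset)
        tbl = res.table.dropna(subset=["p_value"])
        assert (tbl["statistic"] >= 0).all()
        assert (tbl["p_mean"] <= 1).all() and (tbl["p_dv"] <= 1).all()

    def test_mean_shift_detected_by_mean_lrt(self, rng):
        """For pure mean-shift features the mean LRT P-value is typically
        far smaller than the variance LRT P-value."""
        n_rep = 100
        values = rng.beta(10, 90, size=(n_rep, 60))
        shift = rng.beta(14, 76, size=(n_rep, 30))  # mean up, same-ish sd
        values[:, 30:] = shift
        ds = make_dataset(values)
        res = run_gamlss_ls(ds)
        ratio = np.median(np.log10(res.table["p_mean"] + 1e-300)
                          - np.log10(res.table["p_dv"] + 1e-300))
        assert ratio < 0

    def test_either_q_rule_selects(self, small_sim):
        res = run_gamlss_ls(small_sim.dataset, fdr=0.05)
        tbl = res.table
        expected = ((tbl["q_mean"] < 0.05) | (tbl["q_dv"] < 0.05)).fillna(False)
        assert (tbl["significant"] == expected).all()

    def test_ranked_set_is_significant_set(self, small_sim):
        res = run_gamlss_ls(small_sim.dataset)
        tbl = res.table
        assert set(tbl.dropna(subset=["rank"]).index) == set(
            tbl[tbl["significant"]].index
        )


class TestRunTTestDMC:
    def test_sign_matches_direction(self, small_sim):
        res = run_ttest_dmc(small_sim.dataset)
        tbl = res.table.dropna(subset=["p_value"])
        nonzero = tbl[tbl["statistic"].abs() > 1e-12]
        assert (
            (nonzero["statistic"] > 0) == (nonzero["direction"] == "hyper")
        ).all()

    def test_outlier_feature_missed_by_t_but_caught_by_bt(self, rng):
        values = rng.beta(10, 90, size=(300, 100))
        values[0, 50:53] = rng.beta(6, 4, size=3)  # type-2 style outliers
        ds = make_dataset(values)
        tt = run_ttest_dmc(ds)
        bt = run_bt(ds)
        assert bool(bt.table.loc[0, "significant"])
        assert not bool(tt.table.loc[0, "significant"])

    def test_quiet_on_null_simulation(self):
        zero = 0
        for seed in range(10):
            sim = simulate_dataset(null_config(seed=100 + seed))
            res = run_ttest_dmc(sim.dataset)
            zero += int(res.table["significant"].sum()) == 0
        assert zero >= 9


class TestMissingDataHandling:
    def test_sparse_feature_yields_missing_row(self, rng):
        values = rng.beta(10, 90, size=(10, 12))
        values[2, :5] = np.nan  # one non-missing value left in group 0
        ds = make_dataset(values)
        for runner in (run_bt, run_jdmdv, run_gamlss_ls, run_diffvar):
            res = runner(ds)
            assert np.isnan(res.table.loc[2, "p_value"])
            assert not res.table.loc[2, "significant"]

    def test_missing_entries_dropped_not_fatal(self, rng):
        values = rng.beta(10, 90, size=(50, 30))
        mask = rng.random(values.shape) < 0.05
        values[mask] = np.nan
        ds = make_dataset(values)
        res = run_bt(ds)
        assert np.isfinite(res.table["p_value"].to_numpy()).sum() > 40


class TestNullCalibrationHeavyTails:
    def test_bartlett_inflated_on_t3_data(self, rng):
        """On heavy-tailed (t with 3 df) inputs Bartlett's null P-values are
        inflated toward 0 (median well below 0.5) while the Levene-type
        DiffVar stays close to uniform."""
        n_feat = 1000
        raw = stats.t.rvs(3, size=(n_feat, 60), random_state=17) * 0.02 + 0.5
        values = np.clip(raw, 0.001, 0.999)
        group = np.r_[np.zeros(30, int), np.ones(30, int)]
        ds = make_dataset(values, group=group)
        bt_p = run_bt(ds).table["p_value"].dropna()
        assert bt_p.median() < 0.5
        # the Levene-type deviations test is far better calibrated here
        dv_p = run_diffvar(ds).table["p_value"].dropna()
        assert abs(dv_p.median() - 0.5) < abs(bt_p.median() - 0.5)
        assert dv_p.median() > 0.4
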