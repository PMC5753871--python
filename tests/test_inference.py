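"""Dataset likelihood, model fitting, LRT and bootstrap behavior."""

import numpy as np
import pytest

import continuitest as ct
from continuitest import inference
from conftest import make_options, simulate_benchmark


def one_site_dataset(x=0.3, a=0, d=1):
    return ct.Dataset([x], [[a]], [[d]])


class TestDataset:
    def test_validation(self):
        with pytest.raises(ValueError):
            ct.Dataset([0.0], [[1]], [[0]])  # non-segregating x
        with pytest.raises(ValueError):
            ct.Dataset([0.5], [[0]], [[0]])  # site without reads
        with pytest.raises(ValueError):
            ct.Dataset([0.5], [[-1]], [[1]])  # negative counts
        with pytest.raises(ValueError):
            ct.Dataset([0.5, 0.6], [[1]], [[0]])  # shape mismatch

    def test_grouping_partitions_sites(self, small_dataset):
        groups = small_dataset.groups()
        idx = np.sort(np.concatenate([g.site_idx for g in groups]))
        np.testing.assert_array_equal(idx, np.arange(small_dataset.n_sites))

    def test_subset_with_repeats(self, small_dataset):
        sub = small_dataset.subset([0, 0, 1])
        assert sub.n_sites == 3
        assert sub.x[0] == sub.x[1] == small_dataset.x[0]


class TestDataLogLikelihood:
    def test_single_derived_read_closed_form(self):
        x, t1, t2, eps = 0.3, 0.07, 0.4, 0.02
        lnl = ct.data_log_likelihood(
            one_site_dataset(x), ct.DriftParams(t1, t2), eps
        )
        assert lnl == pytest.approx(
            np.log(eps + (1 - 2 * eps) * x * np.exp(-t1)), abs=1e-10
        )

    def test_duplicated_dataset_doubles_lnl(self, small_dataset):
        params, eps = ct.DriftParams(0.02, 0.05), 0.01
        base = ct.data_log_likelihood(small_dataset, params, eps)
        doubled = ct.data_log_likelihood(
            small_dataset.subset(
                np.r_[np.arange(small_dataset.n_sites), np.arange(small_dataset.n_sites)]
            ),
            params,
            eps,
        )
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_no_drift_no_error_is_binomial_genotype_sampling(self):
        # t1=t2=0, eps=0, a diploid with two concordant derived reads:
        # P = x^2 + x(1-x)/2; with two ancestral reads: (1-x)^2 + x(1-x)/2
        x = 0.4
        lnl_dd = ct.data_log_likelihood(
            one_site_dataset(x, 0, 2), ct.DriftParams(0.0, 0.0), 0.0
        )
        assert lnl_dd == pytest.approx(np.log(x**2 + x * (1 - x) / 2), abs=1e-10)

    def test_invariant_to_site_and_individual_order(self):
        rng = np.random.default_rng(9)
        L, M = 50, 3
        x = rng.uniform(0.05, 0.95, L)
        a = rng.poisson(1.0, (L, M))
        d = rng.poisson(1.0, (L, M))
        a[(a + d).sum(axis=1) == 0, 0] = 1
        params, eps = ct.DriftParams(0.03, 0.08), 0.02
        base = ct.data_log_likelihood(ct.Dataset(x, a, d), params, eps)
        perm = rng.permutation(L)
        shuffled_sites = ct.data_log_likelihood(
            ct.Dataset(x[perm], a[perm], d[perm]), params, eps
        )
        cols = rng.permutation(M)
        shuffled_inds = ct.data_log_likelihood(
            ct.Dataset(x, a[:, cols], d[:, cols]), params, eps
        )
        assert shuffled_sites == pytest.approx(base, abs=1e-9)
        assert shuffled_inds == pytest.approx(base, abs=1e-9)

    def test_single_read_sites_carry_no_t2_information(self):
        # sites covered by exactly one read in total observe a single
        # chromosome, and the marginal P(derived) = eps + (1-2eps) E[Y]
        # is t2-free (drift preserves the mean).  Note two single-read
        # individuals at the same site are NOT t2-free: their two
        # chromosomes jointly probe E[Y^2].
        rng = np.random.default_rng(3)
        L = 200
        x = rng.uniform(0.05, 0.95, L)
        a = np.zeros((L, 2), dtype=int)
        d = np.zeros((L, 2), dtype=int)
        who = rng.integers(0, 2, L)
        derived = rng.integers(0, 2, L)
        a[np.arange(L), who] = 1 - derived
        d[np.arange(L), who] = derived
        data = ct.Dataset(x, a, d)
        lnls = [
            ct.data_log_likelihood(data, ct.DriftParams(0.05, t2), 0.01)
            for t2 in np.linspace(0.0, 2.0, 9)
        ]
        assert max(lnls) - min(lnls) < 1e-6

    def test_per_individual_eps_vector(self):
        data = ct.Dataset([0.3, 0.6], [[1, 0], [0, 2]], [[1, 1], [2, 0]])
        shared = ct.data_log_likelihood(data, ct.DriftParams(0.01, 0.02), 0.05)
        vec = ct.data_log_likelihood(
            data, ct.DriftParams(0.01, 0.02), np.array([0.05, 0.05])
        )
        assert vec == pytest.approx(shared, abs=1e-12)


class TestFitting:
    def test_refit_is_bit_identical(self, small_dataset):
        options = make_options(2)
        f1 = ct.fit_full(small_dataset, options)
        f2 = ct.fit_full(small_dataset, options)
        assert (f1.t1, f1.t2, f1.eps, f1.lnl) == (f2.t1, f2.t2, f2.eps, f2.lnl)

    def test_null_nested_in_full(self, small_dataset):
        options = make_options(2)
        full = ct.fit_full(small_dataset, options)
        null = ct.fit_null(small_dataset, options)
        assert null.lnl <= full.lnl + 1e-6
        assert null.t2 == 0.0 and null.null_model

    def test_fix_eps_respected(self, small_dataset):
        fit = ct.fit_full(small_dataset, ct.FitOptions(
            t1_starts=(0.02,), t2_starts=(0.02,), fix_eps=0.01
        ))
        assert fit.eps == 0.01

    def test_boundary_null_recovered(self, null_fits):
        # under continuity the asymptotic distribution of the MLE puts
        # probability 1/2 exactly on the t2=0 boundary (the same point
        # mass the mixture LRT null uses); finite samples from one
        # low-coverage diploid sit slightly below that because of the
        # documented upward bias of t2 for sparse single individuals
        t2_hats = np.array([full.t2 for full, _ in null_fits])
        boundary_frac = np.mean(t2_hats < 1e-3)
        assert 0.35 <= boundary_frac <= 0.65
        # and the typical estimate is at or near zero
        assert np.median(t2_hats) < 0.01

    def test_null_lnl_close_to_full_under_null(self, null_fits):
        # nested-model property: median LRT under H0 is ~0
        lrts = np.array([2 * (f.lnl - n.lnl) for f, n in null_fits])
        assert np.median(lrts) < 0.5

    def test_estimates_anticorrelated(self, fig2_fits):
        t1s = np.array([f.t1 for f in fig2_fits])
        t2s = np.array([f.t2 for f in fig2_fits])
        assert np.corrcoef(t1s, t2s)[0, 1] < 0


class TestLRT:
    def test_trivial_equality_gives_p_one(self, small_dataset):
        res = ct.lrt_continuity(small_dataset, make_options(2))
        assert res.lrt >= 0
        if res.lrt == 0:
            assert res.p_mixture == 1.0
        assert res.p_mixture <= res.p_chi2_1df + 1e-12

    def test_statistic_and_p_values_consistent(self, small_dataset):
        from scipy import stats

        res = ct.lrt_continuity(small_dataset, make_options(2))
        assert res.lrt == pytest.approx(
            max(0.0, 2 * (res.lnl_full - res.lnl_null)), abs=1e-9
        )
        if res.lrt > 0:
            assert res.p_chi2_1df == pytest.approx(stats.chi2.sf(res.lrt, 1))
            assert res.p_mixture == pytest.approx(res.p_chi2_1df / 2)


class TestBootstrap:
    def test_seeded_reproducibility(self, small_dataset):
        options = make_options(1)
        b1 = ct.bootstrap_ci(small_dataset, B=8, seed=5, options=options)
        b2 = ct.bootstrap_ci(small_dataset, B=8, seed=5, options=options)
        assert b1.intervals == b2.intervals
        np.testing.assert_array_equal(b1.samples, b2.samples)

    def test_interval_brackets_point_estimate(self, small_dataset):
        options = make_options(1)
        mle = ct.fit_full(small_dataset, options)
        boot = ct.bootstrap_ci(small_dataset, B=20, seed=5, options=options)
        lo, hi = boot.intervals["t1"]
        assert lo - 1e-9 <= mle.t1 <= hi + 1e-9 or abs(hi - lo) < 1e-4

    def test_failure_fraction_guard(self, small_dataset, monkeypatch):
        calls = {"n": 0}
        real = inference.fit_full

        def flaky(data, options=None):
            calls["n"] += 1
            if calls["n"] > 1:  # fail every bootstrap refit
                raise inference.OptimizationError("boom")
            return real(data, options)

        monkeypatch.setattr(inference, "fit_full", flaky)
        with pytest.raises(inference.OptimizationError):
            inference.bootstrap_ci(small_dataset, B=10, seed=1, options=make_options(1))

    def test_doubling_data_shrinks_spread(self):
        # standard-error scaling: doubling the number of sites should
        # shrink the bootstrap spread of t1 by about 1/sqrt(2)
        data = simulate_benchmark(1, m=2, coverage=1.0, L=1_500, seed_tag=13)
        doubled = data.subset(np.r_[np.arange(data.n_sites), np.arange(data.n_sites)])
        options = make_options(1)
        sd1 = ct.bootstrap_ci(data, B=60, seed=2, options=options).samples[:, 0].std()
        sd2 = ct.bootstrap_ci(doubled, B=60, seed=2, options=options).samples[:, 0].std()
        assert sd2 / sd1 == pytest.approx(1 / np.sqrt(2), rel=0.35)

    def test_block_resampling_runs(self, small_dataset):
        boot = ct.bootstrap_ci(
            small_dataset, B=5, seed=3, options=make_options(1), block_size=50
        )
        assert boot.samples.shape == (5, 3)
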