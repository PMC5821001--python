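"""Effective information, MIP search, sample units, surrogates, phi_bar."""

import logging

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from phibar import synth
from phibar.io import ConfigurationError, TimeSeriesMatrix
from phibar.partitions import Bipartition, enumerate_bipartitions
from phibar.phi import (PhiBarModel, ar_fit, draw_sample_units, lagged_moments,
                        min_information_partition, phi_ar, phi_bar, phi_e,
                        surrogate_shuffle)
from phibar.preprocess import segment_epochs

FS = 500.0


def lyapunov_phi(A, noise_cov, bipartition):
    """Independent oracle: effective information from exact stationary moments.

    Solves the discrete Lyapunov equation for the stationary covariance and
    evaluates the log-det residual-covariance difference symbolically, with
    no recourse to the sample path or the package's batched kernel.
    """
    sig0 = solve_discrete_lyapunov(A, noise_cov)
    sigc = A @ sig0  # Cov(x_t, x_{t-1})

    def ld(ix):
        ix = np.asarray(ix)
        p = sig0[np.ix_(ix, ix)]
        c = sigc[np.ix_(ix, ix)]
        resid = p - c @ np.linalg.solve(p, c.T)
        return np.linalg.slogdet(resid)[1]

    whole = tuple(sorted(bipartition.part1 + bipartition.part2))
    return 0.5 * (ld(list(bipartition.part1)) + ld(list(bipartition.part2))
                  - ld(list(whole)))


class TestLaggedMoments:
    def test_iid_noise_moments(self):
        rng = np.random.default_rng(0)
        ts = TimeSeriesMatrix(rng.standard_normal((8, 60000)), FS,
                              [f"E{i}" for i in range(8)])
        m = lagged_moments(ts, tau=1)
        np.testing.assert_allclose(m.cov0, np.eye(8), atol=0.05)
        assert np.abs(m.cov_tau).max() < 0.05

    def test_var_cross_covariance_structure(self):
        A = np.array([[0.5, 0.3], [0.3, 0.5]])
        model = synth.VARModel(A=A, alpha=np.zeros(2), noise_cov=np.eye(2))
        ts = synth.simulate(model, 120, seed=1)
        m = lagged_moments(ts, tau=1)
        sig0 = solve_discrete_lyapunov(A, np.eye(2))
        np.testing.assert_allclose(m.cov0, sig0, atol=0.1)
        np.testing.assert_allclose(m.cov_tau, A @ sig0, atol=0.1)

    def test_epoch_pooling_excludes_seam_pairs(self):
        # a huge jump at the epoch boundary must not leak into cov_tau
        block = np.zeros((1, 100))
        e1 = TimeSeriesMatrix(block + 1000.0, FS, ["a"])
        e2 = TimeSeriesMatrix(block - 1000.0, FS, ["a"])
        rng = np.random.default_rng(2)
        e1.data += rng.standard_normal(e1.data.shape)
        e2.data += rng.standard_normal(e2.data.shape)
        from phibar.io import EpochSet
        m = lagged_moments(EpochSet([e1, e2], 100 / FS), tau=1)
        assert abs(m.cov_tau[0, 0]) < 0.5  # per-epoch demeaning kills the offset

    def test_too_few_samples_rejected(self):
        ts = TimeSeriesMatrix(np.random.default_rng(3).standard_normal((8, 8)),
                              FS, [f"E{i}" for i in range(8)])
        with pytest.raises(ConfigurationError):
            lagged_moments(ts, tau=1)


class TestARFit:
    def test_white_noise_gives_zero_coefficients(self):
        rng = np.random.default_rng(4)
        ts = TimeSeriesMatrix(rng.standard_normal((4, 60000)), FS,
                              ["a", "b", "c", "d"])
        fit = ar_fit(lagged_moments(ts), (0, 1, 2, 3))
        assert np.abs(fit.A).max() < 0.05
        np.testing.assert_allclose(fit.resid_cov, np.eye(4), atol=0.05)

    def test_univariate_ar1_recovery(self):
        model = synth.VARModel(A=[[0.9]], alpha=np.zeros(1), noise_cov=[[1.0]])
        ts = synth.simulate(model, 120, seed=5)
        fit = ar_fit(lagged_moments(ts), (0,))
        assert abs(fit.A[0, 0] - 0.9) < 0.02
        assert abs(fit.resid_cov[0, 0] - 1.0) < 0.05

    def test_duplicated_channel_takes_ridge_path(self, caplog):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(5000)
        ts = TimeSeriesMatrix(np.vstack([x, x]), FS, ["a", "b"])
        with caplog.at_level(logging.WARNING, logger="phibar.phi"):
            fit = ar_fit(lagged_moments(ts), (0, 1))
        assert np.isfinite(fit.resid_cov).all()
        assert fit.ridge_used > 0
        assert any("ridge" in r.message for r in caplog.records)

    def test_empty_subset_rejected(self):
        rng = np.random.default_rng(7)
        ts = TimeSeriesMatrix(rng.standard_normal((2, 1000)), FS, ["a", "b"])
        with pytest.raises(ConfigurationError):
            ar_fit(lagged_moments(ts), ())


class TestEffectiveInformation:
    def test_independent_channels_have_zero_phi(self):
        model = synth.VARModel(A=np.diag([0.9, 0.9]), alpha=np.zeros(2),
                               noise_cov=np.eye(2))
        ts = synth.simulate(model, 120, seed=8)
        m = lagged_moments(ts)
        (bp,) = enumerate_bipartitions(2)
        assert abs(phi_ar(m, bp)) < 1e-2
        assert abs(phi_e(m, bp)) < 1e-2

    def test_sample_phi_matches_lyapunov_oracle(self):
        A = np.array([[0.5, 0.3], [0.3, 0.5]])
        model = synth.VARModel(A=A, alpha=np.zeros(2), noise_cov=np.eye(2))
        (bp,) = enumerate_bipartitions(2)
        exact = lyapunov_phi(A, np.eye(2), bp)
        T = 60000
        for seed in range(5):
            ts = synth.simulate(model, T / FS, seed=seed)
            v = phi_ar(lagged_moments(ts), bp)
            assert abs(v - exact) < 5 / np.sqrt(T)

    def test_phi_invariant_to_within_part_ordering(self):
        model = synth.homogeneous_var(4, 0.8)
        ts = synth.simulate(model, 30, seed=9)
        m = lagged_moments(ts)
        a = phi_ar(m, Bipartition((0, 1), (2, 3)))
        b = phi_ar(m, Bipartition((1, 0), (3, 2)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_phi_scale_invariant(self):
        model = synth.homogeneous_var(4, 0.8)
        ts = synth.simulate(model, 30, seed=10)
        m1 = lagged_moments(ts)
        m2 = lagged_moments(ts.copy_with(7.3 * ts.data))
        bp = Bipartition((0, 1), (2, 3))
        assert phi_ar(m1, bp) == pytest.approx(phi_ar(m2, bp), abs=1e-9)
        assert phi_e(m1, bp) == pytest.approx(phi_e(m2, bp), abs=1e-9)

    def test_phi_e_matches_phi_ar_for_gaussian_system(self):
        A = np.array([[0.5, 0.3], [0.3, 0.5]])
        model = synth.VARModel(A=A, alpha=np.zeros(2), noise_cov=np.eye(2))
        ts = synth.simulate(model, 120, seed=11)
        m = lagged_moments(ts)
        (bp,) = enumerate_bipartitions(2)
        assert phi_e(m, bp) == pytest.approx(phi_ar(m, bp), abs=5e-3)

    def test_heavy_tails_widen_the_estimator_gap(self):
        # the two estimators differ only by finite-sample marginal-covariance
        # asymmetry; t(3) innovations inflate that asymmetry
        A = np.array([[0.5, 0.3], [0.3, 0.5]])
        model = synth.VARModel(A=A, alpha=np.zeros(2), noise_cov=np.eye(2))
        (bp,) = enumerate_bipartitions(2)
        gaps = {}
        for kind in ("gaussian", "t"):
            diffs = []
            for seed in range(8):
                ts = synth.simulate(model, 20, seed=seed, innovations=kind)
                m = lagged_moments(ts)
                diffs.append(abs(phi_ar(m, bp) - phi_e(m, bp)))
            gaps[kind] = np.mean(diffs)
        assert gaps["t"] > gaps["gaussian"]


class TestMIPSearch:
    def test_mip_cuts_along_independence(self, two_pair_var):
        ts = synth.simulate(two_pair_var, 120, seed=12)
        m = lagged_moments(ts)
        res = min_information_partition(m, (0, 1, 2, 3))
        assert set(map(frozenset, (res.mip.part1, res.mip.part2))) == \
            {frozenset({0, 1}), frozenset({2, 3})}
        assert abs(res.phi) < 1e-2

    def test_reported_phi_is_global_minimum(self):
        model = synth.homogeneous_var(4, 0.85)
        ts = synth.simulate(model, 60, seed=13)
        res = min_information_partition(lagged_moments(ts), (0, 1, 2, 3))
        assert res.phi > 0
        assert all(res.phi <= v + 1e-12 for v in res.phi_by_partition.values())

    def test_eight_channel_search_visits_127_partitions(self):
        model = synth.homogeneous_var(8, 0.85)
        ts = synth.simulate(model, 30, seed=14)
        res = min_information_partition(lagged_moments(ts), tuple(range(8)))
        assert len(res.phi_by_partition) == 127

    def test_normalized_search_reports_unnormalized_phi(self):
        model = synth.homogeneous_var(5, 0.85)
        ts = synth.simulate(model, 30, seed=15)
        m = lagged_moments(ts)
        res = min_information_partition(m, tuple(range(5)), normalize=True)
        assert res.phi == pytest.approx(res.phi_by_partition[res.mip], abs=1e-12)


class TestSampleUnits:
    def test_reproducible_from_seed(self):
        a = draw_sample_units(96, 8, 50, seed=42)
        b = draw_sample_units(96, 8, 50, seed=42)
        np.testing.assert_array_equal(a.units, b.units)

    def test_membership_counts_within_binomial_bounds(self):
        s = draw_sample_units(96, 8, 600, seed=1)
        counts = np.bincount(s.units.ravel(), minlength=96)
        p = 8 / 96
        sigma = np.sqrt(600 * p * (1 - p))
        assert np.all(np.abs(counts - 50) <= 3.5 * sigma)

    def test_unit_equals_pool_at_boundary(self):
        s = draw_sample_units(8, 8, 5, seed=2)
        for u in s.units:
            np.testing.assert_array_equal(u, np.arange(8))

    def test_pool_smaller_than_unit_rejected(self):
        with pytest.raises(ConfigurationError):
            draw_sample_units(4, 8, 5, seed=3)


class TestSurrogates:
    @pytest.fixture(scope="class")
    def osc_epochs(self):
        spec = synth.SceneSpec(n_channels=4, n_modules=1, seed=16)
        ts, _ = synth.oscillatory_scene(spec, 24)
        return segment_epochs(ts, 6, 4)

    def test_amplitude_multiset_exactly_preserved(self, osc_epochs):
        (surr,) = surrogate_shuffle(osc_epochs, 1, seed=0)
        for ep, sp in zip(osc_epochs.epochs, surr.epochs):
            np.testing.assert_array_equal(np.sort(ep.data, axis=1),
                                          np.sort(sp.data, axis=1))

    def test_periodogram_preserved(self, osc_epochs):
        (surr,) = surrogate_shuffle(osc_epochs, 1, seed=1)
        for ep, sp in zip(osc_epochs.epochs, surr.epochs):
            pa = np.abs(np.fft.rfft(ep.data, axis=1)) ** 2
            pb = np.abs(np.fft.rfft(sp.data, axis=1)) ** 2
            for a, b in zip(pa, pb):
                assert np.corrcoef(a, b)[0, 1] >= 0.9

    def test_lagged_pair_decorrelated(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(8005)
        ts = TimeSeriesMatrix(np.vstack([x[:-5], x[5:]]), FS, ["a", "b"])
        eps = segment_epochs(ts, 4, 4)
        surrs = surrogate_shuffle(eps, 20, seed=2)
        cc = []
        for s in surrs:
            d = s.data3d()
            for e in d:
                a, b = e[0], e[1]
                a = (a - a.mean()) / a.std()
                b = (b - b.mean()) / b.std()
                cc.append(np.mean(a[:-5] * b[5:]))
        assert abs(np.mean(cc)) < 0.1


class TestPhiBar:
    def test_white_noise_null(self, white_epochs_16):
        est = phi_bar(white_epochs_16, n=8, k=50, seed=0)
        assert abs(est.phi_bar) <= 0.02

    def test_coupled_exceeds_white(self, white_epochs_16, coupled_epochs_16):
        null = phi_bar(white_epochs_16, n=8, k=50, seed=0)
        coupled = phi_bar(coupled_epochs_16, n=8, k=50, seed=0)
        assert coupled.phi_bar > 0
        assert coupled.phi_bar > null.phi_bar

    def test_suppression_like_trace_near_zero(self):
        rng = np.random.default_rng(18)
        ts = TimeSeriesMatrix(0.5 * rng.standard_normal((16, 30000)), FS,
                              [f"E{i}" for i in range(16)])
        est = phi_bar(segment_epochs(ts, 6, 10), n=8, k=50, seed=1)
        assert abs(est.phi_bar) <= 0.05

    def test_estimate_identity(self, coupled_epochs_16):
        est = phi_bar(coupled_epochs_16, n=8, k=30, seed=2)
        assert est.phi_bar == pytest.approx(est.mean_phi - est.surrogate_median_mean,
                                            abs=1e-12)

    def test_cross_block_phi_vanishes_for_block_var(self, two_pair_var):
        ts = synth.simulate(two_pair_var, 60, seed=19)
        m = lagged_moments(ts)
        for bp in enumerate_bipartitions(4):
            cuts_blocks = {0, 1} in (set(bp.part1), set(bp.part2))
            if cuts_blocks:
                assert abs(phi_ar(m, bp)) < 1e-2


class TestReliabilityAndRegional:
    def test_cov_decreases_with_k(self, coupled_epochs_16):
        model = PhiBarModel(coupled_epochs_16, n=8, n_surrogates=10, seed=3)
        curve = model.reliability_curve(k_grid=[10, 100], n_repeats=30, seed=4)
        assert curve.cov[-1] < curve.cov[0]

    def test_homogeneous_regional_map_flat(self, coupled_epochs_16):
        model = PhiBarModel(coupled_epochs_16, n=8, n_surrogates=10, seed=5)
        rm = model.regional(units_per_channel=20, seed=6)
        spread = rm.values.max() - rm.values.min()
        sigma = rm.values.std()
        assert spread <= 5 * sigma  # no channel stands out in a symmetric system

    def test_regional_reproducible(self, coupled_epochs_16):
        model = PhiBarModel(coupled_epochs_16, n=8, n_surrogates=5, seed=7)
        a = model.regional(units_per_channel=5, seed=8)
        b = model.regional(units_per_channel=5, seed=8)
        np.testing.assert_array_equal(a.values, b.values)

    def test_monotone_in_coupling_strength(self):
        from scipy.stats import spearmanr
        levels = np.linspace(0.02, 0.35, 10)
        rhos = []
        for seed in range(3):
            phis = []
            for c in levels:
                spec = synth.SceneSpec(n_channels=16, n_modules=1, intra_coupling=c,
                                       inter_coupling=c, seed=seed)
                ts = synth.simulate(synth.modular_var(spec), 40, seed=seed + 100)
                eps = segment_epochs(ts, 4, 10)
                est = phi_bar(eps, n=8, k=40, n_surrogates=10, seed=7)
                phis.append(est.phi_bar)
            rhos.append(spearmanr(levels, phis).statistic)
        assert min(rhos) >= 0.9
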