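"""Partitioning, meta-analysis, binned curves and smoothing."""

import numpy as np
import pandas as pd
import pytest

from cm3.mixture import MixtureParams
from cm3.resampling import (
    PartitionScheme,
    binned_replication_curves,
    binned_replication_rate,
    meta_z,
    partition_substudies,
    run_resampling,
    smooth_curve,
)
from cm3.simulate import simulate_substudies, simulate_truth
from cm3.sumstats import SubStudyPanel, p_from_z


def _null_panel(m=20_000, J=6, seed=0):
    truth = simulate_truth(m, MixtureParams(0.0, 1.0, 0.0, 0.0), 0.5, seed=seed)
    return simulate_substudies(truth, np.full(J, 2000.0), seed=seed + 1)


class TestPartition:
    def test_split_half_properties(self):
        disc, repl = partition_substudies(52, 26, seed=0)
        assert len(disc) == 26 and len(repl) == 26
        assert len(np.intersect1d(disc, repl)) == 0
        assert sorted(np.concatenate([disc, repl]).tolist()) == list(range(52))

    def test_two_study_frequency(self):
        picks = [partition_substudies(2, 1, seed=s)[0][0] for s in range(2000)]
        frac = np.mean(picks)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_determinism(self):
        a = partition_substudies(10, 4, seed=42)
        b = partition_substudies(10, 4, seed=42)
        np.testing.assert_array_equal(a[0], b[0])

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            PartitionScheme(J=5, n_discovery=5)


class TestMetaZ:
    def _panel(self, z, n):
        m = z.shape[0]
        snps = pd.DataFrame(
            {"snp_id": [f"r{i}" for i in range(m)], "chrom": "1",
             "pos": np.arange(1, m + 1), "a1": "A", "a2": "G"}
        )
        return SubStudyPanel(snps=snps, z=z, n_eff=n)

    def test_single_study_identity(self):
        panel = self._panel(np.array([[1.5, -0.2], [0.3, 2.0]]), [100.0, 300.0])
        zm, n = meta_z(panel, [0])
        np.testing.assert_allclose(zm, [1.5, 0.3])
        assert n == 100.0

    def test_perfect_replication_scaling(self):
        z = np.array([[2.0, 2.0]])
        panel = self._panel(z, [500.0, 500.0])
        zm, _ = meta_z(panel, [0, 1])
        assert zm[0] == pytest.approx(np.sqrt(2) * 2.0)

    def test_hand_arithmetic(self):
        panel = self._panel(np.array([[1.0, 2.0]]), [100.0, 300.0])
        zm, n = meta_z(panel, [0, 1])
        assert zm[0] == pytest.approx((10 * 1 + np.sqrt(300) * 2) / 20, abs=1e-4)
        assert n == 400.0

    def test_missing_handling(self):
        z = np.array([[1.0, np.nan], [np.nan, np.nan]])
        panel = self._panel(z, [100.0, 300.0])
        zm, _ = meta_z(panel, [0, 1])
        assert zm[0] == pytest.approx(1.0)  # only study 0 contributes
        assert np.isnan(zm[1])


class TestBinnedCurves:
    def test_constant_replication(self):
        zd = np.linspace(-3, 3, 1000)
        zr = np.full(1000, 1.7)
        c = binned_replication_curves(zd, zr, n_bins=101, z_range=(-5, 5))
        ok = c.nonempty
        np.testing.assert_allclose(c.value[ok], 1.7)
        np.testing.assert_allclose(c.second[ok], 1.7**2)

    def test_identity_mean_near_midpoint(self):
        rng = np.random.default_rng(1)
        zd = rng.uniform(-4, 4, size=50_000)
        c = binned_replication_curves(zd, zd, n_bins=101, z_range=(-5, 5))
        ok = c.nonempty
        half_width = (c.edges[1] - c.edges[0]) / 2
        assert np.max(np.abs(c.value[ok] - c.midpoints[ok])) <= half_width + 1e-12

    def test_null_mean_within_band(self):
        rng = np.random.default_rng(2)
        zd = rng.normal(size=100_000)
        zr = rng.normal(size=100_000)
        c = binned_replication_curves(zd, zr, n_bins=101, z_range=(-6, 6))
        ok = c.count >= 20
        band = 3.0 / np.sqrt(c.count[ok])
        assert np.mean(np.abs(c.value[ok]) < band) > 0.97

    def test_degenerate_range_fatal(self):
        with pytest.raises(ValueError):
            binned_replication_curves([0.0], [0.0], z_range=(1.0, 1.0))


class TestBinnedRate:
    def test_all_significant(self):
        p = np.full(1000, 0.01)
        c = binned_replication_rate(np.random.default_rng(3).uniform(size=1000), p)
        np.testing.assert_allclose(c.value[c.nonempty], 1.0)

    def test_null_calibration_sign_free_and_consistent(self):
        rng = np.random.default_rng(4)
        n = 200_000
        zd = rng.normal(size=n)
        zr = rng.normal(size=n)
        pd_, pr = p_from_z(zd), p_from_z(zr)
        free = binned_replication_rate(pd_, pr, n_bins=21, neglog10p_range=(0, 2))
        cons = binned_replication_rate(
            pd_, pr, n_bins=21, neglog10p_range=(0, 2),
            sign_consistent=True, z_disc=zd, z_repl=zr,
        )
        for c, target in ((free, 0.05), (cons, 0.025)):
            ok = c.count >= 500
            se = np.sqrt(target * (1 - target) / c.count[ok])
            assert np.all(np.abs(c.value[ok] - target) < 4 * se)


class TestSmoothing:
    def test_linear_reproduced(self):
        # values exactly linear in the midpoints: cubic splines contain
        # linear functions, so the weighted LSQ fit must reproduce them
        from cm3.resampling import BinnedCurve

        edges = np.linspace(-4, 4, 202)
        mids = 0.5 * (edges[:-1] + edges[1:])
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 500, size=mids.size)
        c = BinnedCurve(edges=edges, count=counts, value=0.5 * mids + 1.0)
        sm = smooth_curve(c)
        np.testing.assert_allclose(sm.smoothed, c.value, atol=1e-8)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(6)
        zd = rng.uniform(-3, 3, 20_000)
        zr = rng.normal(size=20_000)
        c = binned_replication_curves(zd, zr, n_bins=201, z_range=(-4, 4))
        sm = smooth_curve(c)
        ok = c.nonempty
        assert np.nanvar(sm.smoothed[ok]) < np.nanvar(c.value[ok])

    def test_cubic_ground_truth_recovered(self):
        rng = np.random.default_rng(7)
        m = 200_000
        zd = rng.uniform(-3, 3, m)
        poly = 0.05 * zd**3 - 0.2 * zd
        noise_sd = 0.5
        c = binned_replication_curves(zd, poly + rng.normal(0, noise_sd, m),
                                      n_bins=201, z_range=(-4, 4))
        sm = smooth_curve(c)
        ok = c.count >= 100
        truth = 0.05 * c.midpoints**3 - 0.2 * c.midpoints
        assert np.max(np.abs(sm.smoothed[ok] - truth[ok])) < noise_sd

    def test_too_few_bins_returns_raw(self):
        c = binned_replication_curves([0.0, 1.0], [0.0, 1.0], n_bins=5,
                                      z_range=(-2, 2))
        with pytest.warns(UserWarning):
            sm = smooth_curve(c)
        assert sm.smoothed is None


class TestRunResampling:
    def test_single_iteration_reduces_to_direct(self):
        panel = _null_panel(m=5_000, J=2)
        scheme = PartitionScheme(J=2, n_discovery=1, iterations=1, seed=3)
        res = run_resampling(panel, scheme, n_bins=101, z_range=(-6, 6))
        disc, repl = partition_substudies(
            2, 1, seed=np.random.SeedSequence(3).spawn(1)[0].spawn(2)[0]
        )
        zd, _ = meta_z(panel, disc)
        zr, _ = meta_z(panel, repl)
        direct = binned_replication_curves(zd, zr, n_bins=101, z_range=(-6, 6))
        np.testing.assert_allclose(
            res.moment_curves[0].value, direct.value, equal_nan=True
        )

    def test_pooled_equals_count_weighted_average(self):
        panel = _null_panel(m=2_000, J=4, seed=8)
        scheme = PartitionScheme(J=4, n_discovery=2, iterations=5, seed=9)
        res = run_resampling(panel, scheme, n_bins=51, z_range=(-6, 6),
                             keep_pairs=True)
        # oracle: pool all SNP-iteration pairs and bin once
        all_zd = np.concatenate([p[0] for p in res.pairs])
        all_zr = np.concatenate([p[1] for p in res.pairs])
        pooled = binned_replication_curves(all_zd, all_zr, n_bins=51,
                                           z_range=(-6, 6))
        np.testing.assert_allclose(
            res.moment_curves[0].value, pooled.value, equal_nan=True, atol=1e-10
        )
        np.testing.assert_array_equal(res.moment_curves[0].count, pooled.count)

    def test_determinism_under_master_seed(self):
        panel = _null_panel(m=1_000, J=4, seed=10)
        scheme = PartitionScheme(J=4, n_discovery=2, iterations=3, seed=11)
        a = run_resampling(panel, scheme, n_bins=51)
        b = run_resampling(panel, scheme, n_bins=51)
        np.testing.assert_array_equal(a.moment_curves[0].count,
                                      b.moment_curves[0].count)
        np.testing.assert_allclose(a.moment_curves[0].value,
                                   b.moment_curves[0].value, equal_nan=True)

    def test_stratified_accumulation_counts(self):
        panel = _null_panel(m=3_000, J=4, seed=12)
        strata = np.tile([1, 2, 3], 1000)
        scheme = PartitionScheme(J=4, n_discovery=2, iterations=2, seed=13)
        res = run_resampling(panel, scheme, stratum_index=strata, n_bins=51,
                             z_range=(-10, 10))
        total = sum(res.moment_curves[s].count.sum() for s in (1, 2, 3))
        assert total == 3_000 * 2  # every SNP-iteration pair lands once
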