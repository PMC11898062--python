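"""WHAM free-energy reconstruction, overlap checks and bootstrap bands."""

import numpy as np
import pytest

from protonwire import (
    FreeEnergyProfile,
    TrajectorySegment,
    UmbrellaWindowSpec,
    UmbrellaWHAM,
    WindowHistogram,
    check_overlap,
    discard_equilibration,
    wham_solve,
)
from protonwire.fes import _wham_core, integrated_autocorr_time
from protonwire.units import KB

BETA = 1.0 / (KB * 310.0)


def double_well_potential(z):
    """Analytic double well on [0, 1], kJ/mol (minima near 0.2 and 0.8)."""
    return 12.0 * np.sin(np.pi * (2 * z + 0.5)) + 20.0 * (z - 0.5) ** 4 + 12.0


def draw_biased_samples(rng, n, zeta0, k, grid=None):
    """iid samples from exp(-beta (U + k/2 (z - z0)^2)) by inverse CDF."""
    grid = np.linspace(0, 1, 20001) if grid is None else grid
    w = np.exp(-BETA * (double_well_potential(grid) + 0.5 * k * (grid - zeta0) ** 2))
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    return np.interp(rng.uniform(0, 1, n), cdf, grid)


def make_segment(zeta, zeta0, k=1000.0, wid=0, dt=0.001, stride=10):
    spec = UmbrellaWindowSpec(zeta0=zeta0, k=k, steps=len(zeta) * stride,
                              seed=wid, window_id=wid, save_stride=stride)
    n = len(zeta)
    return TrajectorySegment(
        window_id=wid, spec=spec, times=dt * stride * np.arange(1, n + 1),
        zeta=np.asarray(zeta, float), t_kin=np.full(n, 310.0),
    )


@pytest.fixture(scope="module")
def double_well_series():
    rng = np.random.default_rng(1234)
    centers = np.arange(0.0, 1.01, 0.1)
    return [draw_biased_samples(rng, 3000, c, 1000.0) for c in centers], centers


class TestWham:
    def test_single_unbiased_window_recovers_log_histogram(self):
        rng = np.random.default_rng(7)
        z = draw_biased_samples(rng, 50000, 0.5, 0.0)
        model = UmbrellaWHAM([z], [0.5], [0.0], temperature=310.0)
        res = model.fit()
        counts, _ = np.histogram(z, bins=model.bin_edges)
        mask = counts > 0
        g_ref = -np.log(counts[mask] / counts.sum()) / BETA
        g_ref -= g_ref.min()
        np.testing.assert_allclose(res.profile.G[mask], g_ref, atol=1e-9)

    def test_biased_double_well_matches_quadrature(self, double_well_series):
        series, centers = double_well_series
        model = UmbrellaWHAM(series, centers, np.full(len(centers), 1000.0))
        res = model.fit()
        z = model.bin_mid
        g_exact = double_well_potential(z)
        # exact free energy of the binned density includes the bin integral;
        # at 0.01 bins the potential itself is accurate to << 0.1 kJ/mol
        g_exact = g_exact - g_exact[np.isfinite(res.profile.G)].min()
        mask = np.isfinite(res.profile.G)
        diff = np.abs(res.profile.G[mask] - g_exact[mask])
        assert diff.max() < 1.5

    def test_duplicating_every_window_is_a_no_op(self, double_well_series):
        series, centers = double_well_series
        ks = np.full(len(centers), 1000.0)
        g1 = UmbrellaWHAM(series, centers, ks).fit().profile.G
        g2 = UmbrellaWHAM(series + series, np.r_[centers, centers],
                          np.r_[ks, ks]).fit().profile.G
        mask = np.isfinite(g1)
        np.testing.assert_allclose(g1[mask], g2[mask], atol=1e-6)

    def test_window_order_invariance(self, double_well_series):
        series, centers = double_well_series
        ks = np.full(len(centers), 1000.0)
        perm = np.random.default_rng(0).permutation(len(series))
        g1 = UmbrellaWHAM(series, centers, ks).fit(tol=1e-12).profile.G
        g2 = UmbrellaWHAM(
            [series[i] for i in perm], centers[perm], ks[perm]
        ).fit(tol=1e-12).profile.G
        mask = np.isfinite(g1)
        np.testing.assert_allclose(g1[mask], g2[mask], atol=1e-9)

    def test_gauge_invariance_of_bias_offsets(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(4, 40)).astype(float)
        bias = rng.uniform(0, 20, size=(4, 40))
        n_i = counts.sum(axis=1)
        p1, *_ = _wham_core(counts, bias, n_i, BETA, 1e-10, 100000)
        p2, *_ = _wham_core(counts, bias + 7.3, n_i, BETA, 1e-10, 100000)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_disconnected_windows_error_names_gap(self):
        rng = np.random.default_rng(3)
        left = rng.uniform(0.0, 0.3, 500)
        right = rng.uniform(0.7, 1.0, 500)
        model = UmbrellaWHAM([left, right], [0.1, 0.9], [1000.0, 1000.0])
        with pytest.raises(RuntimeError, match="disconnected"):
            model.fit()

    def test_agrees_with_independent_mbar_estimator(self, double_well_series):
        """Cross-check against a from-scratch sample-based MBAR solver."""
        series, centers = double_well_series
        ks = np.full(len(centers), 1000.0)
        res = UmbrellaWHAM(series, centers, ks).fit()

        # independent MBAR: self-consistent per-sample reweighting
        allz = np.concatenate(series)
        n_i = np.array([len(z) for z in series], float)
        u = 0.5 * ks[:, None] * (allz[None, :] - np.asarray(centers)[:, None]) ** 2
        logn = np.log(n_i)
        f = np.zeros(len(series))
        for _ in range(2000):
            denom = np.logaddexp.reduce(
                logn[:, None] + BETA * f[:, None] - BETA * u, axis=0
            )
            fnew = -np.log(np.exp(-BETA * u - denom[None, :]).sum(axis=1)) / BETA
            fnew -= fnew[0]
            if np.max(np.abs(fnew - f)) < 1e-10:
                f = fnew
                break
            f = fnew
        wlog = -np.logaddexp.reduce(logn[:, None] + BETA * f[:, None] - BETA * u, axis=0)
        w = np.exp(wlog - wlog.max())
        edges = np.linspace(0, 1, 101)
        idx = np.clip(np.digitize(allz, edges) - 1, 0, 99)
        p = np.bincount(idx, weights=w, minlength=100)
        with np.errstate(divide="ignore"):
            g_mbar = np.where(p > 0, -np.log(np.where(p > 0, p, 1)) / BETA, np.nan)
        g_mbar -= np.nanmin(g_mbar)
        mask = np.isfinite(res.profile.G) & np.isfinite(g_mbar)
        assert np.nanmax(np.abs(res.profile.G[mask] - g_mbar[mask])) < 0.5


class TestDiscardEquilibration:
    def _segments(self, n=2500, stride=10):
        rng = np.random.default_rng(0)
        return [make_segment(rng.uniform(0, 1, n), 0.5, stride=stride)]

    def test_standard_protocol_keeps_eighty_percent(self):
        # 0.5 ns window with the first 0.1 ns discarded
        segs = self._segments(n=50000)
        out = discard_equilibration(segs, duration=100.0)
        assert len(out[0]) == 40000

    def test_one_ns_window_keeps_ninety_percent(self):
        segs = self._segments(n=100000)
        out = discard_equilibration(segs, duration=100.0)
        assert len(out[0]) == 90000

    def test_zero_fraction_is_identity(self):
        segs = self._segments()
        out = discard_equilibration(segs, fraction=0.0)
        np.testing.assert_array_equal(out[0].zeta, segs[0].zeta)

    def test_overlong_duration_rejected(self):
        segs = self._segments(n=100)
        with pytest.raises(ValueError, match="discard"):
            discard_equilibration(segs, duration=1e6)


class TestCheckOverlap:
    def _hist(self, counts, zeta0, wid=0):
        counts = np.asarray(counts, float)
        edges = np.linspace(0, 1, len(counts) + 1)
        return WindowHistogram(wid, zeta0, 1000.0, edges, counts, int(counts.sum()))

    def test_identical_histograms_overlap_fully(self):
        h = [self._hist([5, 5, 0, 0], 0.2, 0), self._hist([5, 5, 0, 0], 0.3, 1)]
        mat, report = check_overlap(h)
        assert report[0]["overlap"] == pytest.approx(1.0)
        assert report[0]["ok"]

    def test_disjoint_histograms_overlap_zero(self):
        h = [self._hist([5, 0, 0, 0], 0.1, 0), self._hist([0, 0, 0, 5], 0.9, 1)]
        _, report = check_overlap(h)
        assert report[0]["overlap"] == 0.0
        assert not report[0]["ok"]

    def test_gaussian_pair_matches_quadrature(self):
        edges = np.linspace(0, 1, 101)
        mid = 0.5 * (edges[:-1] + edges[1:])
        sig = 0.03
        pa = np.exp(-0.5 * ((mid - 0.45) / sig) ** 2)
        pb = np.exp(-0.5 * ((mid - 0.55) / sig) ** 2)
        n = 10_000_000
        ha = self._hist(np.round(pa / pa.sum() * n), 0.45, 0)
        hb = self._hist(np.round(pb / pb.sum() * n), 0.55, 1)
        _, report = check_overlap([ha, hb])
        exact = np.minimum(pa / pa.sum(), pb / pb.sum()).sum()
        assert report[0]["overlap"] == pytest.approx(exact, abs=1e-4)

    def test_needs_at_least_two_windows(self):
        with pytest.raises(ValueError):
            check_overlap([self._hist([1, 0], 0.5)])


class TestBootstrap:
    def test_zero_variance_input_gives_zero_width_bands(self):
        z = np.full(500, 0.305)
        model = UmbrellaWHAM([z], [0.3], [1000.0])
        res = model.fit().bootstrap(n_cycles=10, seed=0)
        mask = np.isfinite(res.profile.G)
        width = res.profile.ci_high[mask] - res.profile.ci_low[mask]
        np.testing.assert_allclose(width, 0.0, atol=1e-12)

    def test_bands_are_finite_and_ordered(self, double_well_series):
        series, centers = double_well_series
        model = UmbrellaWHAM(series, centers, np.full(len(centers), 1000.0))
        res = model.fit().bootstrap(n_cycles=30, seed=1)
        p = res.profile
        mask = np.isfinite(p.G)
        assert np.all(np.isfinite(p.ci_low[mask]))
        assert np.all(p.ci_low[mask] <= p.G[mask] + 1e-12)
        assert np.all(p.G[mask] <= p.ci_high[mask] + 1e-12)
        assert res.profile.metadata["bootstrap_cycles"] == 30

    def test_short_window_falls_back_to_whole_resampling(self):
        rng = np.random.default_rng(2)
        z = rng.uniform(0.28, 0.32, 12)
        model = UmbrellaWHAM([z], [0.3], [1000.0])
        with pytest.warns(UserWarning, match="short"):
            model.fit().bootstrap(n_cycles=5, seed=0)


class TestAutocorrelation:
    def test_white_noise_has_unit_scale_tau(self):
        rng = np.random.default_rng(0)
        tau = integrated_autocorr_time(rng.standard_normal(20000))
        assert 0.4 < tau < 0.8

    def test_ar1_process_tau_matches_closed_form(self):
        rng = np.random.default_rng(1)
        phi = 0.9
        x = np.zeros(200000)
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        # tau = (1 + phi) / (2 (1 - phi)) = 9.5 for phi = 0.9
        tau = integrated_autocorr_time(x)
        assert tau == pytest.approx(9.5, rel=0.2)


def test_wham_solve_accepts_segments_and_histograms(double_well_series):
    series, centers = double_well_series
    segs = [make_segment(z, c, wid=i) for i, (z, c) in enumerate(zip(series, centers))]
    prof = wham_solve(segs)
    assert isinstance(prof, FreeEnergyProfile)
    assert np.nanmin(prof.G) == pytest.approx(0.0)
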