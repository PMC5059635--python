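"""Histogramming, the WHAM solver, and uncertainty estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pmfbind as pb
from pmfbind.wham import DEFAULT_BURN_IN

from _reference import reference_wham

KT = pb.ThermoParams().kt


def series_from_counts(edges, counts, window, seed=0):
    """Turn integer bin counts into a TimeSeries of bin-centre samples
    (shuffled), so histogramming reproduces the counts exactly."""
    centres = 0.5 * (edges[:-1] + edges[1:])
    samples = np.repeat(centres, counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(samples)
    return pb.TimeSeries(samples=samples, window=window, seed=seed)


class TestHistograms:
    def test_default_burn_in_keeps_last_20_of_22(self):
        w = pb.WindowSpec(0.0, 10.0)
        ts = pb.TimeSeries(samples=np.arange(22.0), window=w, seed=0)
        hists = pb.build_histograms([ts], bin_width=1.0,
                                    burn_in_fraction=DEFAULT_BURN_IN)
        assert hists[0].n_total == 20
        # the first two samples (0 and 1) were dropped
        assert hists[0].edges[0] >= 2.0

    def test_zero_burn_in_conserves_all_samples(self):
        w = pb.WindowSpec(0.0, 10.0)
        rng = np.random.default_rng(1)
        ts = pb.TimeSeries(samples=rng.normal(0, 0.3, 500), window=w, seed=0)
        hists = pb.build_histograms([ts], bin_width=0.1, burn_in_fraction=0.0)
        assert hists[0].n_total == 500

    @given(n=st.integers(5, 200), burn=st.floats(0.0, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_sample_conservation_property(self, n, burn):
        import math
        from hypothesis import assume
        assume(math.ceil(burn * n) < n)
        w = pb.WindowSpec(0.0, 10.0)
        rng = np.random.default_rng(7)
        ts = pb.TimeSeries(samples=rng.normal(0, 0.3, n), window=w, seed=0)
        hists = pb.build_histograms([ts], bin_width=0.1, burn_in_fraction=burn)
        assert hists[0].n_total == n - math.ceil(burn * n)

    def test_edge_sample_goes_right_and_is_conserved(self):
        w = pb.WindowSpec(0.0, 10.0)
        ts = pb.TimeSeries(samples=np.array([0.5, 0.2, 0.7]), window=w, seed=0)
        hists = pb.build_histograms([ts], bin_width=0.5, burn_in_fraction=0.0,
                                    hist_range=(0.0, 1.0))
        # 0.5 sits on the shared edge: assigned to the right-closed bin [0.5, 1.0)
        assert hists[0].counts.tolist() == [1, 2]
        assert hists[0].n_total == 3

    def test_out_of_range_counted_not_dropped(self):
        w = pb.WindowSpec(0.0, 10.0)
        ts = pb.TimeSeries(samples=np.array([0.1, 0.2, 5.0]), window=w, seed=0)
        hists = pb.build_histograms([ts], bin_width=0.1, burn_in_fraction=0.0,
                                    hist_range=(0.0, 1.0))
        assert hists[0].n_out_of_range == 1
        assert hists[0].n_total == 2

    def test_empty_after_burn_in_names_window(self):
        w = pb.WindowSpec(-3.25, 10.0)
        ts = pb.TimeSeries(samples=np.array([1.0]), window=w, seed=0)
        with pytest.raises(ValueError, match="-3.25"):
            pb.build_histograms([ts], bin_width=0.1, burn_in_fraction=0.5)


class TestSolver:
    def test_single_unbiased_window_uniform_counts_flat_pmf(self):
        edges = np.arange(0.0, 1.01, 0.1)
        w = pb.WindowSpec(0.5, 0.0)  # zero force constant: unbiased
        hist = pb.WindowHistogram(edges=edges,
                                  counts=np.full(10, 100), window=w)
        res = pb.solve_wham([hist])
        pmf = res.pmf()
        vals = pmf.w[pmf.supported]
        assert np.ptp(vals) < 1e-10

    def test_two_windows_analytic_counts_flat_within_3_stderr(self):
        """Counts drawn from the exact biased Gaussians of a flat potential
        must reconstruct a flat PMF to within 3x the bootstrap stderr.

        The sampling law uses the bin-centre density, matching the mid-bin
        convention of the histogram WHAM equations, so the only deviation
        from flatness is multinomial noise.
        """
        edges = np.arange(-22.0, -17.99, 0.1)
        centres = 0.5 * (edges[:-1] + edges[1:])
        windows = [pb.WindowSpec(-20.5, 10.0), pb.WindowSpec(-19.5, 10.0)]
        n = 100_000
        rng = np.random.default_rng(42)
        hists, series = [], []
        for i, w in enumerate(windows):
            p = np.exp(-w.bias(centres) / KT)
            p /= p.sum()
            counts = rng.multinomial(n, p)
            hist = pb.WindowHistogram(edges=edges, counts=counts, window=w)
            hists.append(hist)
            series.append(series_from_counts(edges, counts, w, seed=i))
        res = pb.solve_wham(hists)
        pmf = pb.estimate_uncertainty(series, hists, res, n_boot=40, seed=3,
                                      burn_in_fraction=0.0)
        m = pmf.supported & (pmf.counts >= 20)
        dev = pmf.w[m] - np.mean(pmf.w[m])
        assert np.all(np.abs(dev) <= 3.0 * pmf.stderr[m])

    @pytest.mark.parametrize("anderson", [True, False])
    def test_oracle_equivalence_small_instances(self, anderson,
                                                flat_umbrella_run):
        """Converged f_i agree with an independent direct fixed-point
        implementation of the WHAM equations to <= 1e-6 kcal/mol."""
        series, hists = flat_umbrella_run
        small = hists[:5]
        res = pb.solve_wham(small, anderson=anderson)
        assert res.converged
        f_ref, _ = reference_wham(
            [h.counts.tolist() for h in small],
            small[0].centres.tolist(),
            [h.window.centre for h in small],
            [h.window.force_constant for h in small],
            KT, tolerance=1e-9,
        )
        assert np.max(np.abs(res.f - np.array(f_ref))) <= 1e-6

    def test_anderson_matches_plain_iteration(self, flat_umbrella_run):
        # tight tolerance: the stopping rule bounds the per-sweep change, so
        # route comparison needs both routes close to the true fixed point
        _, hists = flat_umbrella_run
        fast = pb.solve_wham(hists, anderson=True, tolerance=1e-10)
        slow = pb.solve_wham(hists, anderson=False, tolerance=1e-10)
        assert fast.converged and slow.converged
        assert np.max(np.abs(fast.f - slow.f)) < 1e-6
        assert fast.n_iter < slow.n_iter

    def test_count_doubling_is_pure_gauge(self, flat_umbrella_run):
        """Doubling every count (doubling the density) must leave the PMF
        shape and the f_i differences unchanged."""
        _, hists = flat_umbrella_run
        doubled = [pb.WindowHistogram(edges=h.edges, counts=2 * h.counts,
                                      window=h.window) for h in hists]
        a = pb.solve_wham(hists, tolerance=1e-10)
        b = pb.solve_wham(doubled, tolerance=1e-10)
        assert np.allclose(np.diff(a.f), np.diff(b.f), atol=1e-6)
        wa, wb = a.pmf().w, b.pmf().w
        m = np.isfinite(wa)
        shape_a = wa[m] - np.nanmean(wa[m])
        shape_b = wb[m] - np.nanmean(wb[m])
        assert np.allclose(shape_a, shape_b, atol=1e-6)

    def test_f_init_shift_converges_to_same_solution(self, flat_umbrella_run):
        _, hists = flat_umbrella_run
        a = pb.solve_wham(hists, tolerance=1e-10)
        b = pb.solve_wham(hists, f_init=a.f + 3.0, tolerance=1e-10)
        assert np.max(np.abs(a.f - b.f)) < 1e-6

    def test_disconnected_windows_error_lists_components(self):
        edges = np.arange(-30.0, -9.99, 0.1)
        far = [pb.WindowSpec(-28.0, 10.0), pb.WindowSpec(-12.0, 10.0)]
        hists = []
        for w in far:
            counts = np.zeros(edges.size - 1, dtype=int)
            centres = 0.5 * (edges[:-1] + edges[1:])
            counts[np.abs(centres - w.centre) < 0.3] = 50
            hists.append(pb.WindowHistogram(edges=edges, counts=counts, window=w))
        with pytest.raises(ValueError, match="disconnected"):
            pb.solve_wham(hists)

    def test_unconverged_flagged_not_raised(self, flat_umbrella_run):
        _, hists = flat_umbrella_run
        res = pb.solve_wham(hists, max_iter=2)
        assert not res.converged
        assert res.final_residual > 1e-7
        with pytest.raises(RuntimeError, match="converge"):
            res.pmf()
        pmf = res.pmf(allow_unconverged=True)
        assert np.any(pmf.supported)

    def test_tolerance_semantics(self, flat_umbrella_run):
        _, hists = flat_umbrella_run
        res = pb.solve_wham(hists, tolerance=1e-7)
        assert res.converged
        assert res.final_residual <= 1e-7

    def test_rms_error_decreases_with_sampling(self, flat_potential):
        """Perfect-sampling consistency: mean RMS error vs the true (flat)
        potential decreases as per-window sampling grows 10x."""
        windows = pb.make_window_layout(-24.0, -16.0, 0.5, 10.0)
        rms = {}
        for n in (2_000, 20_000):
            errs = []
            for seed in (1, 2, 3):
                params = pb.SamplerParams(n_steps=n)
                seeds = pb.derive_window_seeds(seed, len(windows))
                series = pb.sample_umbrella_windows(flat_potential, windows,
                                                    params, seeds)
                hists = pb.build_histograms(series, bin_width=0.1)
                pmf = pb.solve_wham(hists).pmf(bulk_range=(-24.0, -16.0))
                m = pmf.supported & (pmf.counts >= 10)
                errs.append(np.sqrt(np.mean(pmf.w[m] ** 2)))
            rms[n] = np.mean(errs)
        assert rms[20_000] < rms[2_000]


class TestPMFProfile:
    def _uniform_results(self):
        edges = np.arange(0.0, 1.01, 0.1)
        w = pb.WindowSpec(0.5, 0.0)
        hist = pb.WindowHistogram(edges=edges, counts=np.full(10, 50), window=w)
        return pb.solve_wham([hist])

    def test_density_ratio_e_gives_kt_difference(self):
        res = self._uniform_results()
        res.log_density = np.linspace(0.0, 9.0, 9 + 1)  # successive ratio e
        pmf = pb.pmf_from_solution(res)
        diffs = np.diff(pmf.w[pmf.supported])
        assert np.allclose(diffs, -KT, atol=1e-12)
        assert KT == pytest.approx(0.6163, abs=5e-4)

    def test_density_scaling_is_additive_constant(self):
        res = self._uniform_results()
        base = pb.pmf_from_solution(res).w.copy()
        res.log_density = res.log_density + np.log(2.0)
        shifted = pb.pmf_from_solution(res).w
        assert np.allclose(shifted - base, -KT * np.log(2.0), atol=1e-12)

    def test_offset_invariance_and_flat_shift(self):
        z = np.arange(-10.0, 0.0, 0.1)
        pmf = pb.PMFProfile(z=z, w=np.full_like(z, 5.0), temperature=310.15)
        out = pb.offset_to_bulk(pmf, (-10.0, -8.0))
        assert np.allclose(out.w, 0.0, atol=1e-12)
        assert out.offset == "bulk-zero"
        pmf2 = pb.PMFProfile(z=z, w=np.full_like(z, 5.0) + 7.3,
                             temperature=310.15)
        out2 = pb.offset_to_bulk(pmf2, (-10.0, -8.0))
        assert np.allclose(out.w, out2.w, atol=1e-12)

    def test_bulk_mean_exactly_zero(self):
        rng = np.random.default_rng(0)
        z = np.arange(-10.0, 0.0, 0.1)
        pmf = pb.PMFProfile(z=z, w=rng.normal(3.0, 1.0, z.size),
                            temperature=310.15)
        out = pb.offset_to_bulk(pmf, (-10.0, -7.0))
        mask = (out.z >= -10.0) & (out.z <= -7.0)
        assert abs(np.mean(out.w[mask])) < 1e-12

    def test_insufficient_bulk_support_errors(self):
        z = np.arange(-10.0, 0.0, 0.1)
        w = np.full_like(z, 1.0)
        w[z < -5.0] = np.nan  # unsupported on the bulk side
        pmf = pb.PMFProfile(z=z, w=w, temperature=310.15)
        with pytest.raises(ValueError, match="supported"):
            pb.offset_to_bulk(pmf, (-10.0, -8.0))

    def test_stderr_untouched_by_offset(self):
        z = np.arange(-10.0, 0.0, 0.1)
        err = np.abs(np.sin(z)) + 0.1
        pmf = pb.PMFProfile(z=z, w=z * 0.3, stderr=err, temperature=310.15)
        out = pb.offset_to_bulk(pmf, (-10.0, -8.0))
        assert np.array_equal(out.stderr, err)


class TestUncertainty:
    def test_inefficiency_iid_and_duplicated(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20_000)
        g_iid = pb.statistical_inefficiency(x)
        assert g_iid == pytest.approx(1.0, abs=0.15)
        dup = np.repeat(x[:10_000], 2)
        g_dup = pb.statistical_inefficiency(dup)
        assert g_dup == pytest.approx(2.0, abs=0.3)

    def test_stderr_halves_when_n_quadruples(self):
        """i.i.d. sampling (g = 1): quadrupling the sample size should halve
        the bootstrap PMF stderr, within bootstrap noise."""
        from conftest import iid_gaussian_series
        windows = pb.make_window_layout(-22.0, -18.0, 0.5, 10.0)
        med = {}
        for n in (4_000, 16_000):
            series = iid_gaussian_series(windows, n, KT, seed=8)
            hists = pb.build_histograms(series, bin_width=0.1,
                                        burn_in_fraction=0.0)
            res = pb.solve_wham(hists)
            pmf = pb.estimate_uncertainty(series, hists, res, n_boot=60,
                                          seed=2, burn_in_fraction=0.0,
                                          bulk_range=(-22.0, -18.0))
            m = pmf.supported & (pmf.counts >= 50)
            med[n] = np.median(pmf.stderr[m])
        ratio = med[16_000] / med[4_000]
        assert 0.35 < ratio < 0.65

    def test_duplicated_series_matches_original_stderr(self):
        """Duplicating every sample doubles g but leaves the effective sample
        size, and hence the stderr, essentially unchanged."""
        from conftest import iid_gaussian_series
        windows = pb.make_window_layout(-21.0, -19.0, 0.5, 10.0)
        base = iid_gaussian_series(windows, 5_000, KT, seed=12)
        dup = [pb.TimeSeries(samples=np.repeat(s.samples, 2), window=s.window,
                             seed=s.seed) for s in base]
        meds = []
        for series in (base, dup):
            hists = pb.build_histograms(series, bin_width=0.1,
                                        burn_in_fraction=0.0)
            res = pb.solve_wham(hists)
            pmf = pb.estimate_uncertainty(series, hists, res, n_boot=60,
                                          seed=4, burn_in_fraction=0.0)
            m = pmf.supported & (pmf.counts >= 50)
            meds.append(np.median(pmf.stderr[m]))
        assert meds[1] == pytest.approx(meds[0], rel=0.35)

    def test_bootstrap_seed_reproducible(self, flat_umbrella_run):
        series, hists = flat_umbrella_run
        res = pb.solve_wham(hists)
        a = pb.estimate_uncertainty(series, hists, res, n_boot=20, seed=9)
        b = pb.estimate_uncertainty(series, hists, res, n_boot=20, seed=9)
        assert np.array_equal(a.stderr[a.supported], b.stderr[b.supported],
                              equal_nan=True)

    def test_short_series_flagged(self):
        from conftest import iid_gaussian_series
        windows = pb.make_window_layout(-21.0, -20.0, 0.5, 10.0)
        series = iid_gaussian_series(windows, 5_000, KT, seed=3)
        # strongly correlated short series: cumulative random walk scaled in
        series[0].samples = windows[0].centre + 0.01 * np.cumsum(
            np.random.default_rng(0).standard_normal(200))
        hists = pb.build_histograms(series, bin_width=0.1,
                                    burn_in_fraction=0.0)
        res = pb.solve_wham(hists)
        pmf = pb.estimate_uncertainty(series, hists, res, n_boot=20, seed=1,
                                      burn_in_fraction=0.0)
        assert windows[0].centre in pmf.short_series_windows
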