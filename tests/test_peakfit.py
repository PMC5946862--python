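import numpy as np
import pytest

import groovemap as gm
from groovemap.peakfit import LadderError, _estimate_width

from conftest import noiseless_spec, random_duplex


class TestSubtractBaseline:
    @pytest.mark.parametrize("y,expected", [
        ([5, 3, 8], [2, 0, 5]),
        ([7, 7, 7], [0, 0, 0]),
    ])
    def test_known_values(self, y, expected):
        tr = gm.Trace(np.arange(len(y)), np.array(y, dtype=float))
        out = gm.subtract_baseline(tr)
        assert np.array_equal(out.intensity, expected)
        assert out.intensity.min() == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gm.subtract_baseline(gm.Trace(np.array([], dtype=int), np.array([])))

    def test_recovers_generator_baseline(self, small_seq):
        spec = noiseless_spec(small_seq, baseline=80.0)
        tr, truth = gm.simulate_trace(spec, "cleavage")
        out = gm.subtract_baseline(tr)
        clean = gm.gaussian_sum(tr.data_point,
                                [t.amplitude for t in truth],
                                [t.center for t in truth],
                                [t.width for t in truth])
        # noiseless: global min is the baseline itself (far from any peak)
        assert np.allclose(out.intensity, clean, atol=1e-9)


class TestLadderDetection:
    def test_single_gaussian_apex(self):
        x = np.arange(200)
        tr = gm.Trace(x, gm.gaussian_sum(x, 10.0, 100.0, 4.0))
        centers = gm.detect_ladder_peaks(tr, 0.1)
        assert np.array_equal(centers, [100.0])

    def test_two_separated_gaussians(self):
        x = np.arange(300)
        tr = gm.Trace(x, gm.gaussian_sum(x, [10, 8], [80, 220], [4, 4]))
        assert np.array_equal(gm.detect_ladder_peaks(tr, 0.1), [80.0, 220.0])

    def test_plateau_reports_leftmost(self):
        y = np.zeros(11)
        y[4:7] = 5.0
        centers = gm.detect_ladder_peaks(gm.Trace(np.arange(11), y), 0.1)
        assert np.array_equal(centers, [4.0])

    def test_simulated_ladder_centers_within_one_point(self, seq300):
        spec = gm.make_sim_spec(seq300, seed=8, additive_noise=0.02)  # SNR 50
        tr, truth = gm.simulate_trace(spec, "ladder")
        centers = gm.detect_ladder_peaks(gm.subtract_baseline(tr), 0.2)
        assert len(centers) == len(truth)
        for got, t in zip(centers, truth):
            assert abs(got - t.center) <= 1.0


class TestAssignLadder:
    def test_pairs_by_rank(self):
        assert gm.assign_ladder([200, 100], [60, 50]) == {50: 100, 60: 200}

    def test_count_mismatch_reports_both(self):
        with pytest.raises(LadderError, match="19.*20|20.*19"):
            gm.assign_ladder(list(range(19)), list(range(20)))

    def test_simulated_ladder_assignment_matches_generator(self, small_seq):
        spec = noiseless_spec(small_seq)
        tr, truth = gm.simulate_trace(spec, "ladder")
        centers = gm.detect_ladder_peaks(gm.subtract_baseline(tr), 0.2)
        lmap = gm.assign_ladder(centers, spec.ladder)
        for t in truth:
            assert lmap[t.fragment_length] == pytest.approx(t.center, abs=0.5)


class TestFitLadder:
    def test_noiseless_recovery_and_width_regression(self, seq300):
        spec = noiseless_spec(seq300)  # widths follow w = 2 + 0.001*c
        tr, truth = gm.simulate_trace(spec, "ladder")
        tr = gm.subtract_baseline(tr)
        centers = gm.detect_ladder_peaks(tr, 0.2)
        peaks, wreg = gm.fit_ladder(tr, centers)
        for p, t in zip(peaks, truth):
            assert abs(p.a - t.amplitude) / t.amplitude < 1e-3
            assert abs(p.c - t.center) / t.center < 1e-3
            assert abs(p.w - t.width) / t.width < 1e-3
        assert wreg.slope == pytest.approx(0.001, rel=0.01)
        assert wreg.intercept == pytest.approx(2.0, rel=0.01)

    def test_single_peak_degenerate(self):
        x = np.arange(200)
        tr = gm.Trace(x, gm.gaussian_sum(x, 10.0, 100.0, 4.0))
        with pytest.raises(LadderError):
            gm.fit_ladder(tr, [100.0])


class TestInitializePeaks:
    @pytest.fixture()
    def wreg(self):
        c = np.array([500.0, 1000.0, 1500.0, 2000.0])
        return gm.WidthRegression.from_points(c, 2.0 + 0.001 * c)

    def test_linear_interpolation(self, wreg):
        tr = gm.Trace(np.arange(1200), np.full(1200, 37.2))
        init = gm.initialize_peaks(tr, {100: 1000.0, 110: 1100.0}, [105], wreg)
        assert init[0].c == pytest.approx(1050.0)
        assert init[0].a == pytest.approx(37.2)  # trace value at the center

    def test_exact_ladder_point(self, wreg):
        tr = gm.Trace(np.arange(1200), np.zeros(1200))
        init = gm.initialize_peaks(tr, {100: 1000.0, 110: 1100.0}, [100], wreg)
        assert init[0].c == pytest.approx(1000.0)

    def test_outside_span_rejected(self, wreg):
        tr = gm.Trace(np.arange(1200), np.zeros(1200))
        with pytest.raises(ValueError, match="outside ladder span"):
            gm.initialize_peaks(tr, {100: 1000.0, 110: 1100.0}, [99], wreg)


class TestFitPeaks:
    def test_noiseless_recovery(self, small_seq):
        spec = noiseless_spec(small_seq, baseline=0.0)
        tr, truth = gm.simulate_trace(spec, "cleavage")
        peaks = gm.fit_cleavage_run(
            tr, gm.simulate_trace(spec, "ladder")[0],
            spec.ladder, range(1, small_seq.length))
        tmap = {t.fragment_length: t for t in truth}
        for p in peaks:
            t = tmap[p.fragment_length]
            assert abs(p.a - t.amplitude) / t.amplitude < 1e-3
            assert abs(p.c - t.center) < 0.1
            assert abs(p.w - t.width) / t.width < 1e-3

    def test_truth_init_is_fixed_point(self, small_seq):
        spec = noiseless_spec(small_seq, baseline=0.0)
        tr, truth = gm.simulate_trace(spec, "cleavage")
        init = gm.PeakSet([gm.GaussianPeak(t.fragment_length, t.amplitude,
                                           t.center, t.width) for t in truth])
        fitted, _ = gm.fit_peaks(tr, init)
        assert np.allclose(fitted.amplitudes, init.amplitudes, rtol=1e-4)
        assert np.allclose(fitted.centers, init.centers, atol=1e-3)
        assert np.allclose(fitted.widths, init.widths, rtol=1e-4)

    def test_invariant_to_constant_offset(self, small_seq):
        spec = noiseless_spec(small_seq, baseline=0.0)
        tr, truth = gm.simulate_trace(spec, "cleavage")
        shifted = gm.Trace(tr.data_point, tr.intensity + 123.4)
        init = gm.PeakSet([gm.GaussianPeak(t.fragment_length, t.amplitude,
                                           t.center, t.width) for t in truth])
        f1, _ = gm.fit_peaks(gm.subtract_baseline(tr), init)
        f2, _ = gm.fit_peaks(gm.subtract_baseline(shifted), init)
        assert np.allclose(f1.amplitudes, f2.amplitudes)
        assert np.allclose(f1.centers, f2.centers)

    def test_matches_brute_force_grid_oracle(self):
        """For two isolated peaks the fit agrees with a dense grid search."""
        x = np.arange(400)
        true = [(12.0, 120.0, 4.0), (7.0, 280.0, 5.0)]
        y = gm.gaussian_sum(x, *zip(*true))
        tr = gm.Trace(x, y)
        init = gm.PeakSet([gm.GaussianPeak(1, 10.0, 118.0, 4.5),
                           gm.GaussianPeak(2, 8.0, 282.0, 4.5)])
        cfg = gm.FitConfig(window=400, shift=400, edge_discard=0)
        fitted, _ = gm.fit_peaks(tr, init, cfg)
        # independent oracle: exhaustive SSE minimization, one peak at a time
        for k, (lo, hi) in enumerate([(0, 200), (200, 400)]):
            seg = slice(lo, hi)
            best, best_sse = None, np.inf
            for a in np.arange(5.0, 15.01, 0.25):
                for c in np.arange(true[k][1] - 3, true[k][1] + 3.01, 0.1):
                    for w in np.arange(3.0, 6.01, 0.1):
                        sse = np.sum((gm.gaussian_sum(x[seg], a, c, w) - y[seg]) ** 2)
                        if sse < best_sse:
                            best, best_sse = (a, c, w), sse
            assert fitted[k].a == pytest.approx(best[0], abs=0.25)
            assert fitted[k].c == pytest.approx(best[1], abs=0.1)
            assert fitted[k].w == pytest.approx(best[2], abs=0.1)


class TestIntegration:
    def test_gaussian_closed_form(self):
        p = gm.PeakSet([gm.GaussianPeak(1, 1.0, 100.0, 10.0)])
        out = gm.integrate_peaks(p, (0.0, 200.0))
        assert out[0].area == pytest.approx(25.066, rel=1e-3)

    def test_zero_amplitude_and_linearity(self):
        p = gm.PeakSet([gm.GaussianPeak(1, 0.0, 50.0, 5.0),
                        gm.GaussianPeak(2, 3.0, 150.0, 5.0),
                        gm.GaussianPeak(3, 6.0, 250.0, 5.0)])
        out = gm.integrate_peaks(p, (0.0, 400.0))
        assert out[0].area == 0.0
        assert out[2].area == pytest.approx(2 * out[1].area, rel=1e-9)


class TestNormalization:
    def _peaks(self, areas, start_len=1):
        return gm.PeakSet([
            gm.GaussianPeak(start_len + i, 1.0, 10.0 * (i + 1), 2.0, area=float(a))
            for i, a in enumerate(areas)])

    def test_equal_areas_normalize_to_one(self):
        out = gm.normalize_areas(self._peaks([5.0] * 50))
        assert all(p.normalized_area == 1.0 for p in out)

    def test_block_median_is_exactly_one(self):
        rng = np.random.default_rng(4)
        areas = rng.lognormal(mean=2.0, sigma=0.5, size=137)
        out = gm.normalize_areas(self._peaks(areas), norm_window=50)
        norm = np.array([p.normalized_area for p in out])
        for b in range(3):
            block = norm[50 * b:50 * (b + 1)]
            assert np.median(block) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        areas = rng.lognormal(size=60)
        n1 = gm.normalize_areas(self._peaks(areas))
        n2 = gm.normalize_areas(self._peaks(areas * 7.3))
        assert np.allclose([p.normalized_area for p in n1],
                           [p.normalized_area for p in n2])

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError, match="zero median"):
            gm.normalize_areas(self._peaks([0.0, 0.0, 1.0]))


class TestPeaksToProfile:
    def _peakset(self, lengths):
        return gm.PeakSet([
            gm.GaussianPeak(l, 1.0, 10.0 * l, 2.0, area=1.0,
                            normalized_area=float(l))
            for l in lengths])

    def test_forward_convention(self):
        seq = random_duplex(10, seed=1)
        prof = gm.peaks_to_profile(self._peakset([1, 2, 3]), "forward", seq)
        assert sorted(prof.values) == [1, 2, 3]
        assert prof[2] == 2.0

    def test_reverse_convention(self):
        seq = random_duplex(10, seed=1)
        prof = gm.peaks_to_profile(self._peakset([1, 2, 3]), "reverse", seq)
        # fragment k maps to forward coordinate L - k + 1
        assert sorted(prof.values) == [8, 9, 10]
        assert prof[10] == 1.0

    def test_round_trip_with_simulator_positions(self, small_seq):
        spec = noiseless_spec(small_seq, strand="reverse")
        from groovemap.simulate import truth_to_peakset
        _, truth = gm.simulate_trace(spec, "cleavage")
        peaks = gm.normalize_areas(truth_to_peakset(truth))
        prof = gm.peaks_to_profile(peaks, "reverse", small_seq)
        assert sorted(prof.values) == sorted(t.position for t in truth)


def test_peakset_tsv_round_trip(tmp_path):
    peaks = gm.PeakSet([
        gm.GaussianPeak(5, 1.5, 100.0, 2.5, area=9.4, normalized_area=1.1,
                        base="A"),
        gm.GaussianPeak(6, 2.5, 110.0, 2.6, flag="edge_only"),
    ])
    path = tmp_path / "peaks.tsv"
    gm.write_peakset(path, peaks)
    back = gm.read_peakset(path)
    assert back.peaks == peaks.peaks


def test_composite_model_is_sum_of_single_peaks():
    x = np.arange(100)
    a, c, w = [3.0, 5.0], [30.0, 70.0], [4.0, 6.0]
    total = gm.gaussian_sum(x, a, c, w, baseline=2.0)
    singles = sum(gm.gaussian_sum(x, a[i], c[i], w[i]) for i in range(2))
    assert np.allclose(total, singles + 2.0)
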