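import numpy as np
import pytest

import glottikit as gk
from glottikit.enhance import enhance_cube
from glottikit.roi_tracker import (GaussianFit, MotionParams, NoSignalError,
                                   VariationProfile, column_variation,
                                   estimate_cycle_frames, fit_gaussian,
                                   glottal_center, min_intensity_frame,
                                   plan_block_length, roi_from_fits,
                                   row_variation, track_roi)


def _cube(frames, fps=4000.0):
    return gk.VideoCube(np.asarray(frames, dtype=float), frame_rate=fps)


class TestVariationProfiles:
    def test_static_block_has_zero_tiv(self):
        cube = _cube(np.tile(np.arange(64.0).reshape(8, 8), (5, 1, 1)))
        assert column_variation(cube).tiv.max() == 0
        assert row_variation(cube, 1, 6).tiv.max() == 0

    def test_single_oscillating_column(self):
        frames = np.full((2, 4, 6), 10.0)
        frames[0, :, 2] = 0.0
        frames[1, :, 2] = 255.0
        prof = column_variation(_cube(frames))
        assert prof.tiv[2] == pytest.approx(127.5)   # mean |+-127.5|
        assert np.delete(prof.tiv, 2).max() == 0

    def test_single_frame_block_is_its_own_mean(self):
        cube = _cube(np.random.default_rng(0).integers(0, 255, (3, 8, 8)))
        assert column_variation(cube, 0, 1).tiv.max() == 0

    def test_offset_invariance(self, rng):
        frames = rng.integers(0, 200, (6, 10, 12)).astype(float)
        t1 = column_variation(_cube(frames)).tiv
        t2 = column_variation(_cube(frames + 50.0)).tiv
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_block_range_checked(self):
        cube = _cube(np.zeros((4, 4, 4)))
        with pytest.raises(IndexError):
            column_variation(cube, 2, 5)


class TestGaussianFit:
    def test_exact_parameter_recovery(self):
        x = np.arange(120.0)
        tiv = 10.0 * np.exp(-0.5 * ((x - 60) / 8) ** 2)
        fit = fit_gaussian(VariationProfile(None, None, tiv, "columns"))
        assert fit.mu == pytest.approx(60.0, abs=0.1)
        assert fit.sigma == pytest.approx(8.0, abs=0.1)

    def test_symmetric_triangle_centers(self):
        tiv = np.concatenate([np.linspace(0, 10, 41), np.linspace(10, 0, 41)[1:]])
        fit = fit_gaussian(VariationProfile(None, None, tiv, "columns"))
        assert fit.mu == pytest.approx(40.0, abs=0.5)

    def test_noisy_recovery_within_one_pixel(self):
        """Monte-Carlo at SNR 10: fitted center within 1 px, 100 seeds."""
        x = np.arange(120.0)
        clean = 10.0 * np.exp(-0.5 * ((x - 60) / 8) ** 2)
        for seed in range(100):
            noisy = np.clip(clean + np.random.default_rng(seed).normal(0, 1.0, 120), 0, None)
            fit = fit_gaussian(VariationProfile(None, None, noisy, "columns"))
            assert abs(fit.mu - 60.0) < 1.0

    def test_bimodal_profile_covered_by_one_gaussian(self):
        x = np.arange(100.0)
        two_lobes = (np.exp(-0.5 * ((x - 35) / 5) ** 2)
                     + np.exp(-0.5 * ((x - 65) / 5) ** 2))
        fit = fit_gaussian(VariationProfile(None, None, two_lobes, "rows"))
        assert 35 <= fit.mu <= 65                     # center between the lobes

    def test_zero_profile_raises(self):
        with pytest.raises(NoSignalError):
            fit_gaussian(VariationProfile(None, None, np.zeros(32), "columns"))


class TestROIWindow:
    def test_cutoff_arithmetic(self):
        win = roi_from_fits(GaussianFit(100, 12, 1, 0), GaussianFit(100, 12, 1, 0),
                            2, 2, (256, 256))
        assert (win.x_cl, win.x_cr) == (76, 124)      # mu +/- kappa*sigma

    def test_clipping_at_frame_edge(self):
        win = roi_from_fits(GaussianFit(5, 10, 1, 0), GaussianFit(100, 12, 1, 0),
                            2, 2, (256, 256))
        assert win.x_cl == 0

    def test_width_linear_in_kappa(self):
        fx, fy = GaussianFit(120, 10, 1, 0), GaussianFit(120, 10, 1, 0)
        w2 = roi_from_fits(fx, fy, 2, 2, (256, 256))
        w3 = roi_from_fits(fx, fy, 3, 3, (256, 256))
        # ceil/floor rounding adds at most 2 px to the exact 1.5x ratio
        assert w3.width == pytest.approx(1.5 * w2.width, abs=2)


class TestBlockPlanning:
    def test_paper_rate_example(self):
        assert plan_block_length(236.0, 15.0, 6665.0).gc_o == 28

    def test_cycles_per_endoscope_cycle(self):
        p = plan_block_length(100.0, 15.0, 6665.0)
        assert p.mc_e // p.gc_o >= 6                  # >= 6 glottal cycles

    def test_simple_ratio(self):
        assert plan_block_length(100.0, 15.0, 4000.0).gc_o == 40

    def test_default_block_within_bounds(self):
        p = plan_block_length(120.0, 15.0, 4000.0)
        assert p.gc_o <= p.n_frames <= p.mc_e
        assert p.n_frames == min(3 * p.gc_o, p.mc_e)

    def test_cycle_ordering_enforced(self):
        with pytest.raises(ValueError):
            MotionParams(f0=10.0, fe=15.0, frame_rate=4000.0)

    def test_cycle_estimate_from_autocorrelation(self):
        spec = gk.PhantomSpec(n_frames=120, seed=6, noise_sigma=1.0)
        cube, _ = gk.generate(spec)
        est = estimate_cycle_frames(cube)
        assert abs(est - round(spec.frame_rate / spec.f0)) <= 2


class TestTracking:
    def test_static_camera_gives_stable_windows(self, clean_run):
        spec, cube, truth, track = clean_run
        wins = [w for w in track.roi_trace if w is not None]
        xs = [w.center[0] for w in wins]
        ys = [w.center[1] for w in wins]
        assert max(xs) - min(xs) <= 2 and max(ys) - min(ys) <= 2

    def test_drift_is_tracked_by_block_centers(self, drift_phantom):
        spec, cube, truth = drift_phantom
        enh = enhance_cube(cube)
        params = plan_block_length(spec.f0, spec.drift_freq, spec.frame_rate,
                                   n_frames=plan_block_length(
                                       spec.f0, 15.0, spec.frame_rate).gc_o)
        wins = track_roi(enh, params)
        errs = []
        for w in wins:
            mid = (w.t_start + w.t_end) // 2
            true_cx = spec.glottis_center[0] + truth.drift_trace[mid, 0]
            errs.append(abs(w.center[0] - true_cx))
        assert np.mean(errs) < 3.0

    def test_roi_recall_under_drift(self, drift_phantom):
        """>= 99% of true glottal pixels stay inside the active window."""
        spec, cube, truth = drift_phantom
        enh = enhance_cube(cube)
        params = plan_block_length(spec.f0, spec.drift_freq, spec.frame_rate)
        wins = track_roi(enh, params, 2.0, 2.0)
        total = inside = 0
        for w in wins:
            for t in range(w.t_start, w.t_end + 1):
                m = truth.masks[t]
                total += m.sum()
                inside += m[w.y_cu:w.y_cd + 1, w.x_cl:w.x_cr + 1].sum()
        assert inside / total >= 0.99

    def test_min_intensity_frame_rules(self):
        frames = np.full((10, 6, 6), 200.0)
        frames[7] = 0.0
        cube = _cube(frames)
        win = roi_from_fits(GaussianFit(3, 1.5, 1, 0), GaussianFit(3, 1.5, 1, 0),
                            2, 2, (6, 6))
        win.t_start, win.t_end = 0, 9
        assert min_intensity_frame(cube, win) == 7
        brightening = _cube(np.arange(10)[:, None, None] * np.ones((6, 6)) * 20)
        assert min_intensity_frame(brightening, win) == 0

    def test_max_opening_frame_found_on_phantom(self, clean_run):
        spec, cube, truth, track = clean_run
        enh = enhance_cube(cube)
        w = track.roi_trace[0]
        t = min_intensity_frame(enh, w)
        # the darkest ROI frame must be a max-opening frame of SOME cycle
        assert np.min(np.abs(truth.max_open_frames - t)) <= 2


class TestGlottalCenter:
    def test_center_is_the_fit_means(self):
        assert glottal_center(GaussianFit(100, 5, 1, 0),
                              GaussianFit(128, 5, 1, 0)) == (100, 128)

    def test_center_near_phantom_truth(self, clean_run):
        spec, cube, truth, track = clean_run
        fx, fy = track.roi_trace[0].fits
        g0 = glottal_center(fx, fy)
        assert abs(g0[0] - spec.glottis_center[0]) < 3
        assert abs(g0[1] - spec.glottis_center[1]) < 3

    def test_translation_equivariance(self):
        spec = gk.PhantomSpec(n_frames=68, seed=7, noise_sigma=0.0,
                              corner_artifacts=False)
        cube, _ = gk.generate(spec)
        enh = enhance_cube(cube)
        dx, dy = 12, 9
        shifted = np.roll(np.roll(enh.intensities, dy, axis=1), dx, axis=2)
        enh2 = gk.VideoCube(shifted, frame_rate=cube.frame_rate)
        params = plan_block_length(spec.f0, 15.0, spec.frame_rate, n_frames=68)
        w1 = track_roi(enh, params)[0]
        w2 = track_roi(enh2, params)[0]
        assert w2.fits[0].mu - w1.fits[0].mu == pytest.approx(dx, abs=1)
        assert w2.fits[1].mu - w1.fits[1].mu == pytest.approx(dy, abs=1)
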