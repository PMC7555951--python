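"""MSD estimation, diffusion-coefficient fitting, curvature classification,
intensity time series and kernel density normalization."""

import numpy as np
import pytest

import focitrack as ft
from focitrack.segmentation import Focus
from focitrack.tracking import FocusTrack


def make_track(positions, dt=20.0, start=0):
    foci = [
        Focus(frame_index=start + i, label=1, com=(float(x), float(y)),
              area=1.0, mean_intensity=10.0, total_intensity=10.0)
        for i, (x, y) in enumerate(positions)
    ]
    return FocusTrack(track_id=0, foci=foci, frame_interval=dt)


class TestMSD:
    def test_stationary_track_zero_msd(self):
        c = ft.compute_msd(np.zeros((10, 2)), 20.0)
        assert np.allclose(c.msd, 0.0)
        assert c.lag_times[0] == 0.0 and c.msd[0] == 0.0

    def test_ballistic_motion_quadratic_msd(self):
        s = 0.3
        pos = np.column_stack([s * np.arange(8), np.zeros(8)])
        c = ft.compute_msd(pos, 20.0)
        for n in range(1, 8):
            assert c.msd[n] == pytest.approx((n * s) ** 2)

    def test_three_point_hand_example(self):
        c = ft.compute_msd(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]), 20.0)
        assert c.msd[1] == pytest.approx(1.0)
        assert c.msd[2] == pytest.approx(4.0)
        assert c.n_pairs[1] == 2 and c.n_pairs[2] == 1

    def test_single_focus_track_empty_curve(self):
        assert len(ft.compute_track_msd(make_track([(0.0, 0.0)]))) == 0

    def test_ensemble_of_one_equals_track_curve(self):
        tr = make_track([(0, 0), (1, 0), (2, 0), (3, 0)])
        single = ft.compute_track_msd(tr)
        ens = ft.ensemble_msd([tr])
        assert np.allclose(ens.msd, single.msd)

    def test_ensemble_truncated_at_support(self):
        long = make_track([(0.1 * i, 0) for i in range(10)])
        shorts = [make_track([(0, 0), (0.1, 0), (0.2, 0)]) for _ in range(3)]
        ens = ft.ensemble_msd([long] + shorts, min_tracks_per_lag=3)
        assert len(ens) == 3  # lags 0, dt, 2dt supported by >= 3 tracks


class TestDiffusionFit:
    def test_exact_line_recovers_slope(self):
        lags = np.arange(7) * 20.0
        curve = ft.MSDCurve(lags, 0.04 * lags, np.zeros(7), np.ones(7, int))
        fit = ft.fit_diffusion_coefficient(curve)
        assert fit.slope == pytest.approx(0.04)
        assert fit.D == pytest.approx(0.01)
        assert fit.n_points == 4
        assert fit.D == fit.slope / 4.0

    def test_zero_msd_gives_zero_d(self):
        lags = np.arange(5) * 20.0
        fit = ft.fit_diffusion_coefficient(ft.MSDCurve(lags, np.zeros(5), np.zeros(5), np.ones(5, int)))
        assert fit.D == 0.0

    def test_too_short_curve_rejected(self):
        curve = ft.MSDCurve(np.array([0.0, 20.0]), np.array([0.0, 1.0]),
                            np.zeros(2), np.ones(2, int))
        with pytest.raises(ValueError):
            ft.fit_diffusion_coefficient(curve)

    def test_recovers_known_diffusion_coefficient(self):
        D, dt = 0.005, 20.0
        rng = np.random.default_rng(2024)
        tracks = [ft.simulate_brownian_track(D, 9, dt, rng=rng) for _ in range(500)]
        fit = ft.fit_diffusion_coefficient(ft.ensemble_msd(tracks, dt=dt))
        assert fit.D == pytest.approx(D, rel=0.10)


class TestShapeClassification:
    def test_exact_line_is_linear(self):
        lags = np.arange(10) * 20.0
        c = ft.MSDCurve(lags, 0.01 * lags, np.zeros(10), np.ones(10, int))
        assert ft.classify_msd_shape(c).label == "linear"

    def test_exponential_plateau_is_saturating(self):
        lags = np.arange(12) * 20.0
        y = 0.3 * (1 - np.exp(-lags / 15.0))
        c = ft.MSDCurve(lags, y, np.zeros(12), np.ones(12, int))
        assert ft.classify_msd_shape(c).label == "saturating"

    def test_short_curve_indeterminate(self):
        lags = np.arange(4) * 20.0
        c = ft.MSDCurve(lags, 0.01 * lags, np.zeros(4), np.ones(4, int))
        assert ft.classify_msd_shape(c).label == "indeterminate"

    def test_simulated_free_and_confined_motion(self):
        rng = np.random.default_rng(55)
        free = [ft.simulate_brownian_track(0.005, 9, 20.0, rng=rng) for _ in range(400)]
        conf = [
            ft.simulate_brownian_track(0.05, 50, 20.0, confinement_radius=0.5, rng=rng)
            for _ in range(300)
        ]
        assert ft.classify_msd_shape(ft.ensemble_msd(free, dt=20.0)).label == "linear"
        assert ft.classify_msd_shape(ft.ensemble_msd(conf, dt=20.0)).label == "saturating"

    def test_confined_msd_respects_geometric_bound(self):
        radius = 0.5
        rng = np.random.default_rng(7)
        conf = [
            ft.simulate_brownian_track(0.05, 50, 20.0, confinement_radius=radius, rng=rng)
            for _ in range(300)
        ]
        c = ft.ensemble_msd(conf, dt=20.0)
        assert np.all(c.msd <= (2 * radius) ** 2 + 3 * c.sem)

    def test_apparent_d_decreases_with_confinement(self):
        D_true, fits = 0.02, []
        for i, radius in enumerate([0.2, 0.4, 0.8]):
            tracks = [
                ft.simulate_brownian_track(D_true, 20, 20.0, confinement_radius=radius,
                                           rng=np.random.default_rng(300 + 7 * i + j))
                for j in range(200)
            ]
            fits.append(ft.fit_diffusion_coefficient(ft.ensemble_msd(tracks, dt=20.0)).D)
        assert fits[0] < fits[1] < fits[2] < D_true


class TestTimeseries:
    def test_identical_foci_constant_total(self):
        foci = {
            t: [Focus(t, i, (0.0, 0.0), 2.0, 10.0, 20.0) for i in range(3)]
            for t in range(4)
        }
        ts = ft.focus_timeseries(foci)
        assert np.allclose(ts["mean_total"], 20.0)
        assert np.allclose(ts["sem_total"], 0.0)

    def test_empty_frame_reports_missing_not_zero(self):
        foci = {0: [Focus(0, 1, (0.0, 0.0), 2.0, 10.0, 20.0)], 1: []}
        ts = ft.focus_timeseries(foci, n_frames=2)
        assert np.isnan(ts.loc[1, "mean_intensity"])

    def test_intensity_growth_visible_in_measurements(self):
        cfg = ft.SimConfig(
            image_size=(128, 128), n_frames=8, nucleus_center=(64.0, 64.0),
            nucleus_axes=(46.0, 38.0), n_initial_foci=4, birth_rate=0.0,
            death_prob=0.0, diffusion_coefficient=0.0, amplitude_growth=0.05,
            bleach_rate=0.0, noise_poisson_scale=0.0, noise_gaussian_sd=0.0, seed=8,
        )
        stack, _ = ft.simulate_timelapse(cfg)
        rc = ft.RunConfig(manual_threshold=90.0, register=False, write_plots=False)
        res = ft.run_pipeline(rc, stack=stack, output_dir=None)
        means = res.timeseries["mean_intensity"].to_numpy()
        assert np.all(np.diff(means) > 0)


class TestKDE:
    def test_repeated_value_peaks_at_value(self):
        curve = ft.kde_distribution([5.0] * 10 + [5.0000001], bandwidth=0.5)
        assert curve.grid[np.argmax(curve.density)] == pytest.approx(5.0, abs=0.1)

    def test_area_matches_histogram_within_one_percent(self):
        rng = np.random.default_rng(3)
        values = rng.normal(100.0, 15.0, size=400)
        curve = ft.kde_distribution(values, bandwidth=6.0)
        expected = curve.hist_area * curve.norm_factor
        assert curve.area == pytest.approx(expected, rel=0.01)

    def test_equal_area_scaling_equalizes_integrals(self):
        rng = np.random.default_rng(4)
        a = rng.normal(100.0, 15.0, size=500)
        b = rng.normal(130.0, 25.0, size=200)
        ca = ft.kde_distribution(a, bandwidth=6.0)
        cb = ft.kde_distribution(b, bandwidth=6.0, target_area=ca.hist_area,
                                 t0_values=a)
        assert cb.area == pytest.approx(ca.area, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ft.kde_distribution([1.0, 2.0], bandwidth=0.0)
        with pytest.raises(ValueError):
            ft.kde_distribution([1.0], bandwidth=1.0)
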