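import numpy as np
import pytest
from scipy import stats as sps
from skimage.draw import polygon2mask

from pgcprot import ParameterError
from pgcprot import synthetic as sy


class TestCellMovie:
    def test_rate_zero_no_events_and_constant_contour(self):
        params = sy.CellMovieParams(bleb_rate_per_min=0.0, noise_sd=0.0, speed_px_per_frame=0.5)
        scene = sy.generate_cell_movie(params, seed=3)
        truth = scene.truth
        assert truth.bleb_events == []
        # contour constant up to translation of the center
        c0 = truth.contour_per_frame[0]
        for t, ct in enumerate(truth.contour_per_frame):
            shift = ct.mean(axis=0) - c0.mean(axis=0)
            np.testing.assert_allclose(ct - shift, c0, atol=1e-9)

    def test_determinism_same_seed(self):
        params = sy.CellMovieParams(bleb_rate_per_min=2.0, noise_sd=0.05)
        a = sy.generate_cell_movie(params, seed=7)
        b = sy.generate_cell_movie(params, seed=7)
        np.testing.assert_array_equal(a.stack().data, b.stack().data)
        assert [e.start_frame for e in a.truth.bleb_events] == [
            e.start_frame for e in b.truth.bleb_events
        ]

    def test_different_seed_differs(self):
        params = sy.CellMovieParams(noise_sd=0.05)
        a = sy.generate_cell_movie(params, seed=1)
        b = sy.generate_cell_movie(params, seed=2)
        assert not np.array_equal(a.stack().data, b.stack().data)

    def test_event_count_matches_poisson_mean(self):
        # 2 events/min over a 10-min movie, truth-only fast path
        params = sy.CellMovieParams(
            n_frames=120, frame_interval_s=5.0, bleb_rate_per_min=2.0, render=False
        )
        counts = [
            len(sy.generate_cell_movie(params, seed=s).truth.bleb_events) for s in range(200)
        ]
        mean = np.mean(counts)
        # mean of 200 Poisson(20) replicates: 3 sigma of the replicate mean
        assert abs(mean - 20.0) < 3.0 * np.sqrt(20.0 / 200)

    def test_poisson_gof_over_replicates(self):
        params = sy.CellMovieParams(
            n_frames=60, frame_interval_s=5.0, bleb_rate_per_min=2.0, render=False
        )
        lam = 2.0 * 60 * 5.0 / 60.0  # rate * duration_min = 10
        counts = np.array(
            [len(sy.generate_cell_movie(params, seed=s).truth.bleb_events) for s in range(500)]
        )
        edges = np.array([-0.5, 5.5, 7.5, 9.5, 11.5, 13.5, np.inf])
        obs = np.histogram(counts, bins=edges)[0]
        probs = np.diff(sps.poisson.cdf(edges, lam))
        stat, p = sps.chisquare(obs, probs * len(counts))
        assert p > 0.01

    def test_mask_matches_rasterized_contour(self):
        params = sy.CellMovieParams(n_frames=10, bleb_rate_per_min=3.0, noise_sd=0.0)
        scene = sy.generate_cell_movie(params, seed=5)
        truth = scene.truth
        for t in range(10):
            raster = polygon2mask(scene.stack().data.shape[1:], truth.contour_per_frame[t])
            np.testing.assert_array_equal(raster, truth.masks[t])

    def test_cortical_ring_profile_values(self):
        # ring pixel intensity equals c + A exp(-d^2/2 sigma^2) at that pixel's angle
        params = sy.CellMovieParams(n_frames=2, noise_sd=0.0, bleb_rate_per_min=0.0)
        scene = sy.generate_cell_movie(params, seed=0)
        frame = scene.stack().data[0]
        A, mu, sigma, c = scene.truth.cortical_profile_params
        yy, xx = np.nonzero(frame > params.body_level + 1e-9)
        cy, cx = params.center
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        d = (theta - mu + 180.0) % 360.0 - 180.0
        expected = c + A * np.exp(-(d**2) / (2 * sigma**2))
        np.testing.assert_allclose(frame[yy, xx], expected, atol=1e-12)

    def test_polarity_defined_for_polarized_frames(self):
        scene = sy.generate_cell_movie(sy.CellMovieParams(bleb_rate_per_min=2.0, render=False), seed=9)
        truth = scene.truth
        for t, label in enumerate(truth.front_type_per_frame):
            if label in ("actin_rich", "bleb"):
                assert 0.0 <= truth.polarity_angle_per_frame[t] < 360.0

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_frames": 1},
            {"bleb_rate_per_min": -1.0},
            {"profile_sigma_deg": 0.0},
            {"profile_sigma_deg": 200.0},
            {"profile_amplitude": -0.1},
            {"radius_px": 0.0},
        ],
    )
    def test_parameter_errors(self, bad):
        with pytest.raises(ParameterError):
            sy.generate_cell_movie(sy.CellMovieParams(**bad), seed=0)


class TestNucleiField:
    def test_cubic_lattice_construction(self):
        scene = sy.generate_nuclei_field("cubic_lattice", spacing_um=10.0, box_um=(40, 40, 40))
        pts = scene.truth["centroids"].to_numpy()
        assert len(pts) == 125
        np.testing.assert_allclose(np.sort(np.unique(pts[:, 0])), np.arange(0, 41, 10.0))

    def test_uniform_random_determinism(self):
        a = sy.generate_nuclei_field("uniform_random", n=100, seed=4)
        b = sy.generate_nuclei_field("uniform_random", n=100, seed=4)
        np.testing.assert_array_equal(
            a.truth["centroids"].to_numpy(), b.truth["centroids"].to_numpy()
        )

    def test_points_distinct(self):
        scene = sy.generate_nuclei_field("uniform_random", n=500, seed=8)
        pts = scene.truth["centroids"].to_numpy()
        from scipy.spatial.distance import pdist

        assert pdist(pts).min() > 0

    def test_too_few_points_error(self):
        with pytest.raises(ParameterError):
            sy.generate_nuclei_field("uniform_random", n=5)


class TestRatioStack:
    def test_constant_ratio_exact(self):
        scene = sy.generate_ratio_stack(ratio=2.0, noise_sd=0.0)
        t = scene.truth
        donor = scene.stacks["donor"].data[0]
        acceptor = scene.stacks["acceptor"].data[0]
        np.testing.assert_allclose(acceptor[t["mask"]] / donor[t["mask"]], 2.0)

    def test_gradient_quarter_means_closed_form(self):
        # lo + (hi-lo)*(i+0.5)/w at pixel centers: first/last quarter means
        # integrate to exactly 1.25 and 2.75 for lo=1, hi=3
        scene = sy.generate_ratio_stack(ratio=(1.0, 3.0), mask_extent=(20, 40))
        t = scene.truth
        field, mask = t["ratio_field"], t["mask"]
        xs = np.nonzero(mask)[1]
        x0 = xs.min()
        first = field[mask & (np.indices(mask.shape)[1] < x0 + 10)]
        last = field[mask & (np.indices(mask.shape)[1] >= x0 + 30)]
        assert first.mean() == pytest.approx(1.25, abs=1e-12)
        assert last.mean() == pytest.approx(2.75, abs=1e-12)

    def test_zero_donor_error(self):
        with pytest.raises(ParameterError):
            sy.generate_ratio_stack(donor_level=0.0)

    def test_empty_mask_error(self):
        with pytest.raises(ParameterError):
            sy.generate_ratio_stack(mask_extent=(0, 10))


class TestStripeMovie:
    def test_speed_zero_static(self):
        scene = sy.generate_stripe_movie(speed_px_per_frame=0.0, n_frames=5)
        data = scene.stack().data
        for t in range(1, 5):
            np.testing.assert_array_equal(data[t], data[0])

    def test_integer_speed_correlation_peak(self):
        # brute-force correlation oracle: peak of row-vs-row correlation at lag 2
        scene = sy.generate_stripe_movie(speed_px_per_frame=2.0, n_frames=4)
        row0 = scene.stack().data[0, 0] - scene.stack().data[0, 0].mean()
        row1 = scene.stack().data[1, 0] - scene.stack().data[1, 0].mean()
        lags = range(-6, 7)
        cors = [np.dot(np.roll(row0, k), row1) for k in lags]
        assert list(lags)[int(np.argmax(cors))] == 2

    def test_noninteger_speed_cumulative_shift(self):
        # 1.5 px/frame over 10 frame steps: frame 10 equals frame 0 shifted 15 px
        # period divides the width so the circular roll is exact
        scene = sy.generate_stripe_movie(speed_px_per_frame=1.5, n_frames=11, period_px=32.0)
        data = scene.stack().data
        np.testing.assert_allclose(data[10, 0], np.roll(data[0, 0], 15), atol=1e-9)

    def test_frames_minimum(self):
        with pytest.raises(ParameterError):
            sy.generate_stripe_movie(n_frames=1)


class TestTracks:
    def test_persistence_one_straight(self):
        scene = sy.generate_tracks(n_tracks=3, persistence=1.0, tissue_drift_um_min=(0, 0), seed=2)
        for tr in scene.truth["pgc_tracks"]:
            steps = np.diff(tr.positions_um, axis=0)
            # all steps parallel: cross products vanish
            cross = np.cross(steps[:-1], steps[1:])
            np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    def test_path_length_exact(self):
        scene = sy.generate_tracks(
            n_tracks=2, mean_speed_um_min=3.0, persistence=1.0, duration_s=600, interval_s=60, seed=5
        )
        tr = scene.truth["pgc_tracks"][0]
        assert tr.path_length_um() == pytest.approx(3.0 * 10.0, rel=1e-12)

    def test_somatic_tracks_drift_only(self):
        scene = sy.generate_tracks(n_tracks=2, tissue_drift_um_min=(1.2, -0.6), seed=6)
        for tr in scene.truth["somatic_tracks"]:
            steps = np.diff(tr.positions_um, axis=0)
            np.testing.assert_allclose(steps - steps[0], 0.0, atol=1e-9)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            sy.generate_tracks(interval_s=0.0)
        with pytest.raises(ParameterError):
            sy.generate_tracks(duration_s=10.0, interval_s=60.0)


class TestGelEncounter:
    def test_no_change_constant_polarity(self):
        scene = sy.generate_gel_encounter_movie(behavior="no_change", seed=1)
        angles = scene.truth["polarity_angle_per_frame"]
        assert np.ptp(angles) == 0
        assert set(scene.truth["front_type_per_frame"]) == {"actin_rich"}

    def test_turn_by_construction(self):
        scene = sy.generate_gel_encounter_movie(behavior="turn", turn_angle_deg=90.0, seed=1)
        angles = scene.truth["polarity_angle_per_frame"]
        d = (angles[-1] - angles[0] + 180.0) % 360.0 - 180.0
        assert abs(abs(d) - 90.0) < 1e-9

    def test_loss_of_polarity_by_construction(self):
        scene = sy.generate_gel_encounter_movie(behavior="loss_of_polarity", seed=1)
        t = scene.truth
        assert t["front_type_per_frame"][t["response_frame"]] == "unpolarized"
        assert all(l == "actin_rich" for l in t["front_type_per_frame"][: t["encounter_frame"]])

    def test_window_fit_error(self):
        with pytest.raises(ParameterError):
            sy.generate_gel_encounter_movie(encounter_frame=5, n_frames=120, frame_interval_s=5.0)
        with pytest.raises(ParameterError):
            sy.generate_gel_encounter_movie(encounter_frame=100, n_frames=120, frame_interval_s=5.0)
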