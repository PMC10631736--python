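import numpy as np
import pytest

from patterncells.sta import (
    compute_sta,
    contrast_index,
    count_lobes,
    decorrelate,
    fit_gabor,
    permutation_zscore,
    spikes_to_frame_counts,
    sta_spatial_frequency,
    stimulus_power_spectrum,
)
from patterncells.stimuli import DisplayGeometry, StimulusMovie, make_noise_movie
from patterncells.units import make_drifting_gabor_filter


@pytest.fixture(scope="module")
def small_geom():
    return DisplayGeometry(pixels_x=32, pixels_y=24)


@pytest.fixture(scope="module")
def toy_movie(small_geom):
    rng = np.random.default_rng(5)
    frames = 0.5 + 0.2 * rng.standard_normal(
        (200, small_geom.pixels_y, small_geom.pixels_x)
    )
    return StimulusMovie(np.clip(frames, 0, 1).astype(np.float32), 30.0,
                         small_geom, {"kind": "noise"})


class TestComputeSTA:
    def test_matches_naive_averaging(self, toy_movie, rng):
        """Oracle: explicit loop over spikes averaging lagged frames."""
        counts = np.random.default_rng(0).poisson(0.8, toy_movie.n_frames)
        frames, n = compute_sta([counts], [toy_movie], n_lags=4)
        C = toy_movie.contrast_frames()
        for k in range(4):
            num = np.zeros_like(C[0])
            den = 0.0
            for t in range(toy_movie.n_frames):
                if t - k < 0 or counts[t] == 0:
                    continue
                num = num + counts[t] * C[t - k]
                den += counts[t]
            np.testing.assert_allclose(frames[k], num / den, atol=1e-10)
        assert n == counts.sum()

    def test_duplicated_spike_train_invariance(self, toy_movie):
        counts = np.random.default_rng(1).poisson(0.5, toy_movie.n_frames)
        a, _ = compute_sta([counts], [toy_movie], n_lags=3)
        b, _ = compute_sta([2 * counts], [toy_movie], n_lags=3)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_random_spikes_give_near_zero_sta(self, toy_movie):
        counts = np.random.default_rng(2).poisson(5.0, toy_movie.n_frames)
        frames, _ = compute_sta([counts], [toy_movie], n_lags=3)
        # null limit: every pixel within 5 SE of zero contrast
        se = 0.2 * np.sqrt((counts**2).sum()) / counts.sum()
        assert np.abs(frames).max() < 5 * se

    def test_low_spike_count_warns(self, toy_movie):
        counts = np.zeros(toy_movie.n_frames, dtype=int)
        counts[10] = 5
        with pytest.warns(UserWarning, match="low-confidence"):
            compute_sta([counts], [toy_movie], n_lags=3)


class TestDecorrelate:
    def test_white_noise_is_identity_up_to_scale(self, toy_movie, small_geom):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((3, small_geom.pixels_y,
                                   small_geom.pixels_x))
        P = stimulus_power_spectrum([toy_movie])  # approximately flat
        dec = decorrelate(raw, P, ridge_fraction=0.1)
        for k in range(3):
            r = np.corrcoef(raw[k].ravel(), dec[k].ravel())[0, 1]
            assert r > 0.98

    def test_recovers_filter_from_correlated_stimulus(self, geometry):
        # rate-weighted STA of a known filter under correlated noise:
        # decorrelation must increase the match to the ground-truth filter
        filt = make_drifting_gabor_filter(0.0, geometry=geometry)
        movies = [
            make_noise_movie(50 + i, duration=30.0, geometry=geometry)
            for i in range(4)
        ]
        from patterncells.units import filter_drive

        counts = [np.maximum(filter_drive(filt, m), 0.0) for m in movies]
        raw, _ = compute_sta(counts, movies)
        dec = decorrelate(raw, stimulus_power_spectrum(movies), 0.1)

        def best_r(frames):
            return max(
                np.corrcoef(frames[k].ravel(), filt.weights[k].ravel())[0, 1]
                for k in range(frames.shape[0])
            )

        assert best_r(dec) > best_r(raw)
        assert best_r(dec) > 0.7

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError):
            decorrelate(np.zeros((2, 4, 4)), np.zeros((4, 4)))


class TestPermutationZscore:
    def test_null_calibration_on_shuffled_spikes(self, small_geom):
        movies = [make_noise_movie(60 + i, duration=30.0,
                                   geometry=small_geom) for i in range(2)]
        rng = np.random.default_rng(4)
        counts = [rng.poisson(0.2, m.n_frames) for m in movies]
        seq = permutation_zscore(counts, movies, n_perm=120, seed=9)
        z = seq.z_frames
        assert -0.1 < z.mean() < 0.1
        assert 0.85 < z.std() < 1.15
        frac = (np.abs(z) > 2).mean()
        assert 0.02 < frac < 0.09  # ~5% two-sided tail

    def test_determinism(self, small_geom):
        movies = [make_noise_movie(70, duration=20.0, geometry=small_geom)]
        counts = [np.random.default_rng(5).poisson(0.3, movies[0].n_frames)]
        a = permutation_zscore(counts, movies, n_perm=100, seed=3)
        b = permutation_zscore(counts, movies, n_perm=100, seed=3)
        np.testing.assert_array_equal(a.z_frames, b.z_frames)

    def test_too_few_permutations_rejected(self, small_geom):
        movies = [make_noise_movie(71, duration=10.0, geometry=small_geom)]
        with pytest.raises(ValueError):
            permutation_zscore([np.ones(movies[0].n_frames)], movies,
                               n_perm=10)


class TestContrastIndex:
    def test_zero_frame(self):
        assert contrast_index(np.zeros((24, 32))) == 0.0

    def test_homogeneity(self, rng):
        frame = rng.standard_normal((24, 32))
        assert contrast_index(3.0 * frame) == pytest.approx(
            3.0 * contrast_index(frame)
        )

    def test_increases_with_peak_signal(self, rng):
        frame = rng.standard_normal((24, 32))
        boosted = frame.copy()
        boosted[10:14, 10:14] += 10.0
        assert contrast_index(boosted) > contrast_index(frame)


class TestGaborFit:
    def test_recovers_noiseless_gabor(self, geometry):
        filt = make_drifting_gabor_filter(30.0, geometry=geometry)
        frame = filt.weights[5] / np.abs(filt.weights[5]).max() * 6.0
        fit = fit_gabor(frame, geometry)
        assert fit.r2 > 0.99
        # filter orientation (stripes) is orthogonal to the 30-deg drift
        expected = (30.0 + 90.0) % 180.0
        err = abs((fit.orientation - expected + 90.0) % 180.0 - 90.0)
        assert err < 5.0

    def test_noise_frame_fits_poorly(self, rng):
        frame = np.random.default_rng(8).standard_normal((36, 48))
        fit = fit_gabor(frame)
        assert fit.r2 < 0.3

    def test_sign_flip_preserves_quality(self, geometry):
        filt = make_drifting_gabor_filter(0.0, geometry=geometry)
        frame = filt.weights[5] * 10.0
        a = fit_gabor(frame, geometry)
        b = fit_gabor(-frame, geometry)
        assert a.r2 == pytest.approx(b.r2, abs=0.02)


class TestLobesAndSF:
    def test_two_lobed_gabor(self, geometry):
        # explicit two-lobed pattern: flanking excitatory/inhibitory blobs
        x, y = geometry.grids()
        z = 6.0 * (
            np.exp(-((x - 10) ** 2 + y**2) / (2 * 6.0**2))
            - np.exp(-((x + 10) ** 2 + y**2) / (2 * 6.0**2))
        )
        best, n = count_lobes(z[None])
        assert best == 0
        assert n == 2

    def test_single_blob(self, geometry):
        x, y = geometry.grids()
        z = 6.0 * np.exp(-(x**2 + y**2) / (2 * 8.0**2))
        _, n = count_lobes(z[None])
        assert n == 1

    def test_noise_frames_have_no_lobes(self):
        z = np.random.default_rng(9).standard_normal((3, 36, 48))
        _, n = count_lobes(z)
        assert n == 0

    def test_spatial_frequency_recovery(self, geometry):
        filt = make_drifting_gabor_filter(0.0, sf=0.02, geometry=geometry)
        sf = sta_spatial_frequency(filt.weights[5][None], geometry)
        assert abs(sf - 0.02) / 0.02 < 0.25

    def test_sf_amplitude_invariance(self, geometry):
        filt = make_drifting_gabor_filter(90.0, sf=0.02, geometry=geometry)
        a = sta_spatial_frequency(filt.weights[5][None], geometry)
        b = sta_spatial_frequency(10.0 * filt.weights[5][None], geometry)
        assert a == b


def test_spikes_to_frame_counts_alignment():
    spikes = np.array([0.01, 0.5, 0.51, 2.0, 9.99, 10.5])
    counts = spikes_to_frame_counts(spikes, onset=0.0, n_frames=300,
                                    frame_rate=30.0)
    assert counts.sum() == 5  # spike at 10.5 s falls outside the movie
    assert counts[0] == 1 and counts[15] == 2 and counts[60] == 1
    assert counts[299] == 1  # 9.99 s lands in the final frame


def test_sta_sequence_hdf5_roundtrip(tmp_path, small_geom):
    movies = [make_noise_movie(80, duration=15.0, geometry=small_geom)]
    counts = [np.random.default_rng(6).poisson(0.3, movies[0].n_frames)]
    seq = permutation_zscore(counts, movies, n_perm=100, seed=1)
    path = tmp_path / "sta.h5"
    seq.to_hdf5(path)
    from patterncells.sta import STASequence

    back = STASequence.from_hdf5(path)
    np.testing.assert_allclose(back.z_frames, seq.z_frames)
    np.testing.assert_allclose(back.ci_per_lag, seq.ci_per_lag)
    assert back.n_spikes == seq.n_spikes
    assert back.seed == seq.seed
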