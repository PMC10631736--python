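import numpy as np
import pytest

from patterncells.stimuli import (
    DisplayGeometry,
    make_grating,
    make_noise_movie,
    make_plaid,
)


class TestGrating:
    def test_protocol_frame_count(self, geometry):
        m = make_grating(90.0, 0.02, 2.0, 1.0, 1.5, 60.0, geometry)
        assert m.n_frames == 90
        assert m.frames.min() >= 0.0 and m.frames.max() <= 1.0

    def test_zero_contrast_is_uniform_gray(self, geometry):
        m = make_grating(0.0, 0.02, 2.0, 0.0, 0.5, 30.0, geometry)
        assert np.allclose(m.frames, 0.5)

    def test_pixel_trace_oscillates_at_tf(self, geometry):
        # FFT oracle: any pixel's time series is a sinusoid at exactly tf
        tf, fr, dur = 2.0, 60.0, 3.0
        m = make_grating(45.0, 0.02, tf, 1.0, dur, fr, geometry)
        trace = m.frames[:, 10, 20] - m.frames[:, 10, 20].mean()
        spec = np.abs(np.fft.rfft(trace.astype(float)))
        freqs = np.fft.rfftfreq(m.n_frames, d=1.0 / fr)
        assert freqs[np.argmax(spec)] == pytest.approx(tf)

    def test_full_cycle_temporal_mean_is_midgray(self, geometry):
        # 1.5 s at 2 Hz = 3 full cycles
        m = make_grating(210.0, 0.02, 2.0, 1.0, 1.5, 60.0, geometry)
        assert np.abs(m.frames.mean(axis=0) - 0.5).max() < 1e-6

    def test_drift_direction_convention(self, geometry):
        # Fourier shift theorem: the inter-frame displacement vector of the
        # dominant spatial component points along the requested direction
        # (0 deg = rightward, CCW positive), within half a pixel
        d = geometry.degrees_per_pixel
        for direction in (0.0, 90.0, 150.0, 240.0):
            m = make_grating(direction, 0.02, 2.0, 1.0, 0.5, 60.0, geometry)
            f0 = np.fft.fft2(m.frames[0].astype(float) - 0.5)
            f3 = np.fft.fft2(m.frames[3].astype(float) - 0.5)
            amp = np.abs(f0)
            amp[0, 0] = 0.0
            iy, ix = np.unravel_index(np.argmax(amp), amp.shape)
            ky = np.fft.fftfreq(geometry.pixels_y, d=d)[iy]
            kx = np.fft.fftfreq(geometry.pixels_x, d=d)[ix]
            dphase = np.angle(f3[iy, ix] / f0[iy, ix])
            # displacement along the wave vector, in degrees of visual angle
            k2 = kx**2 + ky**2
            disp = -dphase / (2 * np.pi * k2) * np.array([kx, ky])
            expected_speed = (2.0 / 0.02) * (3 / 60.0)  # tf/sf * dt
            measured = np.rad2deg(np.arctan2(disp[1], disp[0])) % 360.0
            err = abs((measured - direction + 180.0) % 360.0 - 180.0)
            assert err < np.rad2deg(0.5 * d / expected_speed)
            # magnitude agrees up to the discrete-frequency-bin quantization
            assert np.linalg.norm(disp) == pytest.approx(
                expected_speed, rel=0.15
            )

    @pytest.mark.parametrize("bad", [
        {"duration": 0.0}, {"frame_rate": -1.0}, {"sf": 0.0},
    ])
    def test_invalid_arguments_raise(self, geometry, bad):
        kwargs = dict(direction=0.0, sf=0.02, tf=2.0, contrast=1.0,
                      duration=1.0, frame_rate=30.0, geometry=geometry)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_grating(**kwargs)

    def test_nyquist_guard(self):
        coarse = DisplayGeometry(pixels_x=8, pixels_y=6)
        with pytest.raises(ValueError, match="undersampled"):
            make_grating(0.0, 0.04, 2.0, 1.0, 1.0, 30.0, coarse)


class TestPlaid:
    def test_equals_sum_of_components(self, geometry):
        p = make_plaid(135.0, 120.0, 0.5, 0.02, 2.0, 1.0, 30.0, geometry)
        g1 = make_grating(75.0, 0.02, 2.0, 0.5, 1.0, 30.0, geometry)
        g2 = make_grating(195.0, 0.02, 2.0, 0.5, 1.0, 30.0, geometry)
        recon = 0.5 + (g1.frames - 0.5) + (g2.frames - 0.5)
        assert np.abs(p.frames - recon).max() < 1e-6

    def test_zero_cross_angle_degenerates_to_grating(self, geometry):
        p = make_plaid(30.0, 0.0, 0.5, 0.02, 2.0, 1.0, 30.0, geometry)
        g = make_grating(30.0, 0.02, 2.0, 1.0, 1.0, 30.0, geometry)
        assert np.abs(p.frames - g.frames).max() < 1e-6

    def test_full_cycle_mean_luminance(self, geometry):
        p = make_plaid(0.0, 120.0, 0.5, 0.02, 2.0, 1.5, 60.0, geometry)
        assert np.abs(p.frames.mean(axis=0) - 0.5).max() < 1e-6

    def test_overrange_contrast_clips_with_warning(self, geometry):
        with pytest.warns(UserWarning, match="clipping"):
            m = make_plaid(0.0, 120.0, 0.9, 0.02, 2.0, 0.5, 30.0, geometry)
        assert m.frames.min() >= 0.0 and m.frames.max() <= 1.0

    def test_invalid_cross_angle(self, geometry):
        with pytest.raises(ValueError):
            make_plaid(0.0, 180.0, 0.5, 0.02, 2.0, 1.0, 30.0, geometry)


class TestNoiseMovie:
    def test_frame_count_and_determinism(self, geometry):
        a = make_noise_movie(7, duration=10.0, frame_rate=30.0,
                             geometry=geometry)
        b = make_noise_movie(7, duration=10.0, frame_rate=30.0,
                             geometry=geometry)
        assert a.n_frames == 300
        assert np.array_equal(a.frames, b.frames)

    def test_distinct_seeds_differ(self, geometry):
        a = make_noise_movie(1, duration=5.0, geometry=geometry)
        b = make_noise_movie(2, duration=5.0, geometry=geometry)
        assert not np.array_equal(a.frames, b.frames)

    def test_marginal_symmetry_and_range(self, geometry):
        m = make_noise_movie(3, duration=60.0, geometry=geometry)
        x = m.frames.astype(float).ravel() - 0.5
        skew = np.mean(x**3) / np.mean(x**2) ** 1.5
        assert abs(skew) < 0.1
        assert m.frames.min() >= 0.0 and m.frames.max() <= 1.0
        assert abs(m.frames.mean() - 0.5) < 0.01

    def test_temporal_lag1_correlation(self, geometry):
        tau = 0.08
        m = make_noise_movie(11, duration=60.0, frame_rate=30.0,
                             temporal_corr=tau, geometry=geometry)
        x = m.frames.reshape(m.n_frames, -1).astype(float)
        x = x - x.mean(axis=0)
        r1 = (x[1:] * x[:-1]).sum() / (x[:-1] ** 2).sum()
        target = np.exp(-1.0 / (tau * 30.0))
        assert abs(r1 - target) / target < 0.15

    def test_spatial_autocorrelation_halfwidth(self, geometry):
        # FFT-based autocorrelation half-width matches spatial_corr (HWHM)
        corr_deg = 12.0
        m = make_noise_movie(13, duration=30.0, spatial_corr=corr_deg,
                             contrast_mod_depth=0.0, geometry=geometry)
        x = m.frames.astype(float) - m.frames.astype(float).mean()
        F = np.fft.fft2(x, axes=(1, 2))
        ac = np.real(np.fft.ifft2((np.abs(F) ** 2).mean(axis=0)))
        row = ac[0, : geometry.pixels_x // 2] / ac[0, 0]
        half_px = np.interp(0.5, row[::-1], np.arange(len(row))[::-1])
        half_deg = half_px * geometry.degrees_per_pixel
        assert abs(half_deg - corr_deg) / corr_deg < 0.15

    def test_overlarge_correlation_scale_rejected(self, geometry):
        with pytest.raises(ValueError):
            make_noise_movie(1, spatial_corr=200.0, geometry=geometry)


def test_hdf5_roundtrip(tmp_path, geometry):
    m = make_grating(60.0, 0.02, 2.0, 1.0, 0.5, 30.0, geometry)
    path = tmp_path / "movie.h5"
    m.to_hdf5(path)
    from patterncells.stimuli import StimulusMovie

    back = StimulusMovie.from_hdf5(path)
    assert np.allclose(back.frames, m.frames)
    assert back.meta["kind"] == "grating"
    assert back.frame_rate == 30.0
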