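import numpy as np
import pytest

from patterncells.classification import classify_curve_pair
from patterncells.stimuli import make_grating
from patterncells.units import (
    generate_spikes,
    make_drifting_gabor_filter,
    make_regressor_bank,
    make_unit,
    noiseless_tuning,
    simulate_rate,
)


class TestGaborFilter:
    def test_static_filter_when_tf_zero(self, geometry):
        f = make_drifting_gabor_filter(0.0, tf=0.0, geometry=geometry)
        for k in range(1, f.n_lags):
            # identical spatial pattern up to the temporal envelope gain
            a, b = f.weights[0].ravel(), f.weights[k].ravel()
            r = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_aspect_ratio_controls_elongation(self, geometry):
        lo = make_drifting_gabor_filter(0.0, aspect_ratio=0.3,
                                        geometry=geometry)
        hi = make_drifting_gabor_filter(0.0, aspect_ratio=3.0,
                                        geometry=geometry)
        # spatial second moment along the orientation axis (rows here)
        def extent_y(f):
            frame = np.abs(f.weights[5])
            y = np.arange(frame.shape[0])[:, None]
            mu = (frame * y).sum() / frame.sum()
            return np.sqrt((frame * (y - mu) ** 2).sum() / frame.sum())

        assert extent_y(hi) > 2 * extent_y(lo)

    def test_oversized_filter_rejected(self, geometry):
        with pytest.raises(ValueError, match="exceeds"):
            make_drifting_gabor_filter(0.0, envelope_sigma=50.0,
                                       geometry=geometry)

    def test_direction_selectivity_vanishes_for_static_filter(self, geometry):
        from patterncells.metrics import TuningCurve, direction_selectivity_index

        u = make_unit("ln_component", {"pref_direction": 0.0, "tf": 2.0},
                      geometry=geometry)
        static = make_unit("ln_component",
                           {"pref_direction": 0.0, "tf": 2.0},
                           geometry=geometry)
        static.filters = [make_drifting_gabor_filter(
            0.0, tf=0.0, geometry=geometry)]
        def dsi_of(unit):
            g, _ = noiseless_tuning(unit)
            curve = TuningCurve(np.arange(0.0, 360.0, 30.0),
                                np.clip(g, 0, None), g, "grating", 0.02,
                                2.0, 1)
            return direction_selectivity_index(curve)

        assert dsi_of(u) > 0.33
        assert dsi_of(static) < 0.1


class TestMakeUnit:
    @pytest.mark.parametrize("kind,expected", [
        ("ln_component", "component"),
        ("ln_blobby", "pattern"),
        ("pooled_pattern", "pattern"),
        ("energy_complex", "component"),
    ])
    def test_noiseless_classification_by_kind(self, geometry, kind, expected):
        unit = make_unit(kind, {"pref_direction": 90.0}, seed=1,
                         geometry=geometry)
        g, p = noiseless_tuning(unit)
        cl = classify_curve_pair(g, p)
        assert cl.label == expected

    def test_component_plaid_peaks_at_pm60(self, geometry):
        unit = make_unit("ln_component", {"pref_direction": 90.0},
                         geometry=geometry)
        g, p = noiseless_tuning(unit)
        assert np.argmax(g) == 3
        assert set(np.argsort(p)[-2:]) == {1, 5}  # 30 and 150 deg

    def test_blobby_plaid_peak_merges_with_grating_peak(self, geometry):
        unit = make_unit("ln_blobby", {"pref_direction": 90.0},
                         geometry=geometry)
        g, p = noiseless_tuning(unit)
        assert np.argmax(g) == np.argmax(p) == 3

    def test_unknown_kind_rejected(self, geometry):
        with pytest.raises(ValueError):
            make_unit("grandmother_cell", {}, geometry=geometry)

    def test_gain_calibration_hits_target_peak(self, geometry):
        unit = make_unit("ln_component",
                         {"pref_direction": 0.0, "target_peak_rate": 30.0,
                          "baseline_rate": 1.0}, geometry=geometry)
        cal = make_grating(0.0, 0.02, 2.0, 1.0, 1.5, 30.0, geometry)
        assert simulate_rate(unit, cal).max() == pytest.approx(31.0)


class TestSimulateRate:
    def test_gray_movie_returns_baseline(self, geometry):
        unit = make_unit("ln_component", {"baseline_rate": 1.5},
                         geometry=geometry)
        gray = make_grating(0.0, 0.02, 2.0, 0.0, 1.0, 30.0, geometry)
        assert np.allclose(simulate_rate(unit, gray), 1.5)

    def test_ln_rate_modulates_at_tf_energy_does_not(self, geometry):
        # FFT oracle on the rate trace of the preferred grating
        movie = make_grating(0.0, 0.02, 2.0, 1.0, 3.0, 30.0, geometry)

        def f1_f0(unit):
            rate = simulate_rate(unit, movie)[30:] - unit.baseline_rate
            spec = np.abs(np.fft.rfft(rate - rate.mean()))
            freqs = np.fft.rfftfreq(len(rate), d=1 / 30.0)
            i1 = np.argmin(np.abs(freqs - 2.0))
            return spec[i1] / (len(rate) * max(rate.mean(), 1e-9))

        simple = make_unit("ln_component", {"pref_direction": 0.0},
                           geometry=geometry)
        complex_ = make_unit("energy_complex", {"pref_direction": 0.0},
                             geometry=geometry)
        assert f1_f0(simple) > 0.5
        assert f1_f0(complex_) < 0.2

    def test_geometry_mismatch_rejected(self, geometry):
        from patterncells.stimuli import DisplayGeometry

        unit = make_unit("ln_component", {}, geometry=geometry)
        other = make_grating(0.0, 0.02, 2.0, 1.0, 1.0, 30.0,
                             DisplayGeometry(pixels_x=32, pixels_y=24))
        with pytest.raises(ValueError):
            simulate_rate(unit, other)


class TestGenerateSpikes:
    def test_zero_rate_gives_no_spikes(self):
        trains = generate_spikes(np.zeros(100), 30.0, n_trials=5, seed=0)
        assert all(len(t) == 0 for t in trains)

    def test_poisson_mean_and_variance(self):
        # 10 spikes/s for 1.5 s -> mean 15; Fano factor ~ 1
        rate = np.full(45, 10.0)
        trains = generate_spikes(rate, 30.0, n_trials=1000, seed=1)
        counts = np.array([len(t) for t in trains])
        assert counts.mean() == pytest.approx(15.0, abs=3 * np.sqrt(15 / 1000))
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_determinism(self):
        rate = np.full(60, 5.0)
        a = generate_spikes(rate, 30.0, 3, seed=42)
        b = generate_spikes(rate, 30.0, 3, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes(np.array([-1.0, 2.0]), 30.0)

    def test_times_sorted_within_trace(self):
        rate = np.linspace(0, 50, 90)
        for t in generate_spikes(rate, 30.0, 5, seed=3):
            assert np.all(np.diff(t) >= 0)
            assert t.min() >= 0 and t.max() <= 3.0


class TestSession:
    def test_trial_table_protocol_counts(self, tiny_session):
        sess = tiny_session
        param = sess.trials[sess.trials.kind != "noise"]
        # 2 classes x 2 SFs x 2 TFs x 12 directions x 8 trials
        assert len(param) == 2 * 2 * 2 * 12 * 8
        assert len(sess.trials[sess.trials.kind == "noise"]) == 2
        # trials non-overlapping, 1-s ISIs
        t = sess.trials.sort_values("onset")
        gaps = t.onset.to_numpy()[1:] - t.offset.to_numpy()[:-1]
        assert np.allclose(gaps, 1.0)

    def test_ground_truth_covers_population(self, tiny_session):
        assert len(tiny_session.ground_truth) == len(tiny_session.units)
        assert set(tiny_session.ground_truth.ground_truth_label) == {
            "component", "blobby_linear", "pattern", "complex"
        }

    def test_spike_times_sorted(self, tiny_session):
        for uid in tiny_session.spike_times:
            st = tiny_session.unit_spikes(uid)
            assert np.all(np.diff(st) >= 0)

    def test_session_determinism(self, geometry):
        from patterncells.units import make_session

        kwargs = dict(
            population_config={"n_component": 1, "n_blobby": 0,
                               "n_pattern": 0, "n_complex": 0},
            protocol_config={"n_trials": 2,
                             "noise": {"n_movies": 1, "duration": 5.0}},
            seed=7,
            geometry=geometry,
        )
        a = make_session(**kwargs)
        b = make_session(**kwargs)
        np.testing.assert_array_equal(a.unit_spikes(0), b.unit_spikes(0))

    def test_hdf5_roundtrip(self, tiny_session, tmp_path):
        path = tmp_path / "session.h5"
        tiny_session.to_hdf5(path)
        from patterncells.units import Session

        back = Session.from_hdf5(path)
        assert len(back.units) == len(tiny_session.units)
        np.testing.assert_allclose(
            back.unit_spikes(0), tiny_session.unit_spikes(0)
        )
        assert back.noise_seeds == tiny_session.noise_seeds


class TestRegressorBank:
    def test_component_bank_members_are_bimodal(self, geometry):
        bank = make_regressor_bank(12, "component", seed=0,
                                   geometry=geometry)
        for row in bank.curves:
            g, p = row[:12], row[12:]
            peak = np.argmax(g)
            top2 = set(np.argsort(p)[-2:])
            assert top2 == {(peak - 2) % 12, (peak + 2) % 12}

    def test_pattern_bank_members_peak_together(self, geometry):
        bank = make_regressor_bank(12, "pattern", seed=0, geometry=geometry)
        for row in bank.curves:
            g, p = row[:12], row[12:]
            # the grating peak bin carries the plaid maximum too; the plaid
            # curve has a flat top (near-ties at the pixel-sampling level),
            # so compare values rather than argmax
            assert p[np.argmax(g)] >= 0.98 * p.max()

    def test_preferred_directions_tile_all_bins(self, geometry):
        bank = make_regressor_bank(12, "component", seed=0,
                                   geometry=geometry)
        assert set(bank.pref_directions) == set(np.arange(0.0, 360.0, 30.0))

    def test_unclassified_bank_fails_both_criteria(self, geometry):
        bank = make_regressor_bank(12, "unclassified", seed=0,
                                   geometry=geometry)
        labels = [
            classify_curve_pair(row[:12], row[12:]).label
            for row in bank.curves
        ]
        assert labels.count("unclassified") >= 10

    def test_undersized_bank_rejected(self, geometry):
        with pytest.raises(ValueError):
            make_regressor_bank(6, "component", geometry=geometry)
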