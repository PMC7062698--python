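import warnings

import numpy as np
import pytest
from scipy.special import eval_legendre

import simondecode as sd
from simondecode.core import ContinuousRecording, Event, TrialClass
from simondecode.preprocess import csd_matrix


def _sine_recording(freq_hz, montage, sfreq=500.0, seconds=10.0):
    t = np.arange(int(sfreq * seconds)) / sfreq
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (len(montage), 1))
    ev = [Event(int(sfreq * 2), TrialClass("left", False), True, 400.0)]
    return ContinuousRecording("s", sfreq, data, ev, montage)


def _rms(x):
    return np.sqrt(np.mean(x**2))


class TestBandpass:
    def test_stopband_attenuation_at_40hz(self, montage8):
        rec = _sine_recording(40.0, montage8)
        out = sd.bandpass_filter(rec)
        mid = slice(1000, 4000)  # avoid filter edge transients
        db = 20 * np.log10(_rms(out.data[0, mid]) / _rms(rec.data[0, mid]))
        assert db <= -24.0

    def test_passband_flat_at_10hz(self, montage8):
        rec = _sine_recording(10.0, montage8)
        out = sd.bandpass_filter(rec)
        mid = slice(1000, 4000)
        db = 20 * np.log10(_rms(out.data[0, mid]) / _rms(rec.data[0, mid]))
        assert abs(db) <= 1.0

    def test_dc_removed(self, montage8):
        rec = _sine_recording(10.0, montage8)
        rec.data[:] = 7.5
        out = sd.bandpass_filter(rec)
        assert np.abs(out.data[:, 1000:4000]).max() < 0.1

    def test_invalid_band_errors(self, montage8):
        rec = _sine_recording(10.0, montage8)
        with pytest.raises(ValueError, match="band"):
            sd.bandpass_filter(rec, low=20.0, high=0.5)


class TestSegment:
    def test_epoch_geometry_at_500hz(self, montage8):
        cfg = sd.SimulationConfig(n_trials=12, n_channels=8, sfreq=500.0,
                                  seed=0)
        rec, _ = sd.simulate_subject(cfg, "s")
        epochs = sd.segment(rec)
        assert epochs.n_times == 800  # 1600 ms at 500 Hz
        assert epochs.time_ms[0] == -100.0

    def test_correct_only_filter(self, montage8):
        cfg = sd.desk_scale_config(n_trials=60, n_channels=8, sfreq=125.0,
                                   seed=1, err_conflict=0.5,
                                   err_nonconflict=0.5)
        rec, beh = sd.simulate_subject(cfg, "s")
        kept = sd.segment(rec, correct_only=True)
        full = sd.segment(rec, correct_only=False)
        assert kept.n_trials == int(beh["correct"].sum())
        assert full.n_trials == 60

    def test_correct_only_noop_when_all_correct(self, montage8):
        cfg = sd.desk_scale_config(n_trials=20, n_channels=8, sfreq=125.0,
                                   seed=2, err_conflict=0.0,
                                   err_nonconflict=0.0)
        rec, _ = sd.simulate_subject(cfg, "s")
        a = sd.segment(rec, correct_only=True)
        b = sd.segment(rec, correct_only=False)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_out_of_bounds_epoch_dropped_with_warning(self, montage8):
        data = np.zeros((8, 1000))
        events = [
            Event(30, TrialClass("left", False), True, 300.0),   # pre-stim
            Event(900, TrialClass("right", False), True, 300.0),  # runs over
        ]
        rec = ContinuousRecording("s", 500.0, data, events, montage8)
        with pytest.warns(UserWarning, match="dropped 2"):
            epochs = sd.segment(rec)
        assert epochs.n_trials == 0


def _noise_epochs(montage, n=6, n_times=250, sfreq=500.0, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return sd.EpochSet(
        "s", scale * rng.standard_normal((n, len(montage), n_times)) * 0.3,
        np.arange(n_times) * 1000.0 / sfreq, np.zeros(n, dtype=int),
        montage, sfreq,
    )


class TestArtifactRejection:
    def test_clean_epochs_all_kept(self, montage8):
        epochs = _noise_epochs(montage8)
        kept, log = sd.reject_artifacts(epochs)
        assert kept.n_trials == epochs.n_trials
        assert all(not r for r in log.reasons)

    def test_single_large_jump_triggers_step_and_range(self, montage8):
        epochs = _noise_epochs(montage8)
        epochs.data[2, 3, 100:] += 300.0  # 300 uV step
        kept, log = sd.reject_artifacts(epochs)
        assert kept.n_trials == epochs.n_trials - 1
        assert {"step", "range"} <= log.reasons[2]

    def test_flat_channel_rejected(self, montage8):
        epochs = _noise_epochs(montage8)
        epochs.data[4, 0, :] = 0.0
        kept, log = sd.reject_artifacts(epochs)
        assert not log.kept[4]
        assert log.reasons[4] == {"flat"}

    def test_kept_iff_no_reasons(self, montage8):
        epochs = _noise_epochs(montage8)
        epochs.data[1, 2, 50:] += 300.0
        _, log = sd.reject_artifacts(epochs)
        for k, r in zip(log.kept, log.reasons):
            assert k == (len(r) == 0)

    def test_tightening_thresholds_never_keeps_more(self, montage8):
        epochs = _noise_epochs(montage8, n=20, seed=3, scale=40.0)
        epochs.data[5, 1, 80:] += 150.0
        base, _ = sd.reject_artifacts(epochs)
        for kwargs in (
            {"max_step_uv_per_ms": 10.0},
            {"max_range_uv": 60.0},
            {"min_activity_uv": 5.0},
        ):
            tighter, _ = sd.reject_artifacts(epochs, **kwargs)
            assert tighter.n_trials <= base.n_trials


class TestBaseline:
    def test_baseline_window_mean_zero_and_idempotent(self, montage8):
        epochs = _noise_epochs(montage8, n_times=300)
        epochs.time_ms -= 100.0  # span -100..500 ms
        out = sd.baseline_correct(epochs)
        window = (out.time_ms >= -100) & (out.time_ms < 0)
        assert np.allclose(out.data[:, :, window].mean(axis=2), 0.0,
                           atol=1e-9)
        again = sd.baseline_correct(out)
        assert np.allclose(again.data, out.data, atol=1e-12)

    def test_constant_offset_removed(self, montage8):
        epochs = _noise_epochs(montage8, n_times=300)
        epochs.time_ms -= 100.0
        epochs.data[:] = 42.0
        out = sd.baseline_correct(epochs)
        assert np.allclose(out.data, 0.0)

    def test_empty_window_errors(self, montage8):
        epochs = _noise_epochs(montage8)
        with pytest.raises(ValueError, match="empty"):
            sd.baseline_correct(epochs, window_ms=(-500.0, -400.0))


def _dense_csd_oracle(positions, v, m=4, lam=1e-5, n_terms=50):
    """Independent spherical-spline surface Laplacian.

    Evaluates the G/H Legendre series with scipy's polynomials and
    solves the augmented (zero-sum constrained) spline system directly.
    """
    n = len(positions)
    cosang = np.clip(positions @ positions.T, -1, 1)
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    for deg in range(1, n_terms + 1):
        p = eval_legendre(deg, cosang)
        g += (2 * deg + 1) / (deg * (deg + 1)) ** m * p
        h += (2 * deg + 1) / (deg * (deg + 1)) ** (m - 1) * p
    g /= 4 * np.pi
    h /= 4 * np.pi
    gs = g + lam * np.eye(n)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = gs
    aug[:n, n] = 1.0
    aug[n, :n] = 1.0
    sol = np.linalg.solve(aug, np.concatenate([v, [0.0]]))
    return h @ sol[:n]


class TestCSD:
    def test_constant_potential_maps_to_zero(self, montage8):
        epochs = _noise_epochs(montage8)
        epochs.data[:] = 5.0
        out = sd.csd_transform(epochs)
        assert np.abs(out.data).max() < 1e-6

    def test_reference_free(self, montage16):
        epochs = _noise_epochs(montage16)
        shifted = _noise_epochs(montage16)
        shifted.data = epochs.data + 123.4
        a = sd.csd_transform(epochs)
        b = sd.csd_transform(shifted)
        assert np.allclose(a.data, b.data, atol=1e-8)

    def test_linearity(self, montage8):
        x = _noise_epochs(montage8, seed=1)
        y = _noise_epochs(montage8, seed=2)
        combo = _noise_epochs(montage8, seed=3)
        combo.data = 2.0 * x.data - 0.5 * y.data
        lhs = sd.csd_transform(combo).data
        rhs = (2.0 * sd.csd_transform(x).data
               - 0.5 * sd.csd_transform(y).data)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_matches_dense_spline_oracle(self, montage8):
        rng = np.random.default_rng(7)
        v = rng.standard_normal(8)
        mat = csd_matrix(montage8)
        expected = _dense_csd_oracle(montage8.positions, v)
        assert np.allclose(mat @ v, expected, rtol=1e-8, atol=1e-10)

    def test_too_few_channels_error(self, montage8):
        epochs = _noise_epochs(montage8)
        small = epochs.select(np.arange(epochs.n_trials))
        # build a 4-channel montage view
        from simondecode.montage import Montage

        mon4 = Montage(names=montage8.names[:4],
                       positions=montage8.positions[:4])
        bad = sd.EpochSet("s", epochs.data[:, :4], epochs.time_ms,
                          epochs.labels, mon4, epochs.sfreq)
        with pytest.raises(ValueError, match="8 channels"):
            sd.csd_transform(bad)


class TestCrop:
    def test_crop_to_model_window(self, montage8):
        cfg = sd.SimulationConfig(n_trials=8, n_channels=8, sfreq=500.0,
                                  seed=0)
        rec, _ = sd.simulate_subject(cfg, "s")
        epochs = sd.segment(rec)
        out = sd.crop_for_model(epochs)
        assert epochs.n_times == 800 and out.n_times == 750
        assert out.time_ms[0] == 0.0
        again = sd.crop_for_model(out)
        assert np.array_equal(again.data, out.data)

    def test_empty_or_outside_window_errors(self, montage8):
        epochs = _noise_epochs(montage8)
        with pytest.raises(ValueError):
            sd.crop_for_model(epochs, from_ms=100.0, to_ms=100.0)
        with pytest.raises(ValueError, match="outside"):
            sd.crop_for_model(epochs, from_ms=-1000.0, to_ms=100.0)


def test_pipeline_is_bit_stable(montage8):
    cfg = sd.desk_scale_config(n_trials=16, n_channels=8, sfreq=125.0, seed=9)
    rec, _ = sd.simulate_subject(cfg, "s")
    a, _ = sd.preprocess_recording(rec)
    b, _ = sd.preprocess_recording(rec)
    assert np.array_equal(a.data, b.data)
    assert a.csd_applied
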