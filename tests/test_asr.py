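"""Artifact subspace reconstruction: calibration, detection, reconstruction,
and the flatline / correlation / window quality criteria."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import welch

import flightload as fl
from flightload.asr import riemannian_mean
from flightload.config import CleanRawParams
from flightload.preprocessing import design_fir, filter_array
from flightload.recording_io import Recording

FS = 500.0
CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4")


@pytest.fixture(scope="module")
def flight_like():
    """0.5-30 Hz filtered recording with artifacts plus its clean twin."""
    cfg = fl.SimulationConfig(
        duration_per_condition=120.0, n_stimuli=40, seed=3,
        artifact_rates={"blink": 8.0, "burst": 2.0},
    )
    ev = fl.generate_events(cfg, "low")
    rec, log = fl.generate_recording(cfg, ev, "low")
    k = design_fir((0.5, 30.0), 250, FS)
    raw = filter_array(rec.data, k)
    clean = filter_array(rec.meta["pre_artifact_data"], k)
    return cfg, raw, clean, log


@pytest.fixture(scope="module")
def asr_model(flight_like):
    cfg, raw, _, _ = flight_like
    calib = Recording(raw[:, : int(30 * FS)], FS, CHANNELS)
    return fl.asr_calibrate(calib, variant="riemannian"), calib


class TestRiemannianMean:
    def test_mean_of_identical_matrices_is_fixed_point(self):
        C = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert np.allclose(riemannian_mean(np.stack([C] * 4)), C, atol=1e-10)

    def test_mean_of_matrix_and_inverse_is_identity(self):
        D = np.diag([4.0, 0.25, 9.0])
        covs = np.stack([D, np.linalg.inv(D)])
        assert np.allclose(riemannian_mean(covs), np.eye(3), atol=1e-6)

    def test_congruence_invariance(self):
        """Geometric mean commutes with congruence by an invertible matrix."""
        rng = np.random.default_rng(4)
        covs = np.stack(
            [np.cov(rng.standard_normal((3, 100))) + 0.5 * np.eye(3)
             for _ in range(5)]
        )
        A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        lhs = riemannian_mean(np.stack([A @ C @ A.T for C in covs]))
        rhs = A @ riemannian_mean(covs) @ A.T
        assert np.allclose(lhs, rhs, atol=1e-5 * np.abs(rhs).max())


class TestCalibration:
    def test_white_noise_gives_identity_mixing_and_flat_thresholds(self):
        rng = np.random.default_rng(0)
        calib = Recording(rng.standard_normal((6, 30000)), FS, CHANNELS)
        model = fl.asr_calibrate(calib, variant="classic")
        off = model.mixing - np.diag(np.diag(model.mixing))
        assert np.abs(off).max() < 0.1
        assert model.thresholds.max() / model.thresholds.min() < 1.3

    def test_classic_and_riemannian_agree_on_stationary_gaussian(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 6)) * 0.3 + np.eye(6)
        calib = Recording(A @ rng.standard_normal((6, 30000)), FS, CHANNELS)
        classic = fl.asr_calibrate(calib, variant="classic")
        riem = fl.asr_calibrate(calib, variant="riemannian")
        assert np.allclose(classic.thresholds, riem.thresholds, rtol=0.05)

    def test_flat_channel_rejected(self):
        data = np.random.default_rng(2).standard_normal((6, 20000))
        data[3] = 0.0
        with pytest.raises(ValueError, match="flat"):
            fl.asr_calibrate(Recording(data, FS, CHANNELS))

    def test_too_short_calibration_rejected(self):
        data = np.random.default_rng(2).standard_normal((6, 1000))
        with pytest.raises(ValueError, match="10 windows"):
            fl.asr_calibrate(Recording(data, FS, CHANNELS))

    def test_rank_deficient_calibration_rejected(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 20000))
        data[1] = data[0]  # bridged channels
        with pytest.raises(ValueError, match="rank"):
            fl.asr_calibrate(Recording(data, FS, CHANNELS))


class TestProcessing:
    def test_identity_on_own_calibration_data(self, asr_model):
        model, calib = asr_model
        out, flags = fl.asr_process(calib, model)
        assert flags.sum() == 0
        assert np.abs(out.data - calib.data).max() < 1e-9

    def test_idempotent_on_clean_data(self, asr_model):
        model, calib = asr_model
        once, _ = fl.asr_process(calib, model)
        twice, _ = fl.asr_process(once, model)
        rms = np.sqrt(((twice.data - once.data) ** 2).mean())
        assert rms < 1e-6

    def test_burst_suppressed_background_untouched(self, flight_like, asr_model):
        cfg, raw, clean, log = flight_like
        model, _ = asr_model
        out, _ = fl.asr_process(Recording(raw, FS, CHANNELS), model)
        bursts = [e for e in log if e.kind == "burst"]
        assert bursts
        num = den = 0.0
        for e in bursts:
            sl = slice(int(e.onset * FS), int((e.onset + e.duration) * FS))
            num += ((out.data[:, sl] - clean[:, sl]) ** 2).sum()
            den += ((raw[:, sl] - clean[:, sl]) ** 2).sum()
        assert 1 - np.sqrt(num / den) >= 0.8
        # outside artifacts (one ASR window of slack for the overlap-add
        # blend) the signal passes through essentially unchanged
        margin = int(model.window_len * FS)
        mask = np.ones(raw.shape[1], dtype=bool)
        for e in log:
            i0 = int(e.onset * FS) - margin
            i1 = int((e.onset + e.duration) * FS) + margin
            mask[max(i0, 0) : i1] = False
        change = np.sqrt(((out.data[:, mask] - raw[:, mask]) ** 2).mean())
        assert change < 0.05 * np.sqrt((raw[:, mask] ** 2).mean())

    def test_oscillation_band_power_preserved(self, asr_model):
        model, _ = asr_model
        t = np.arange(int(60 * FS)) / FS
        rng = np.random.default_rng(9)
        # 10 Hz oscillation at calibration-level amplitude over mild noise
        data = 5.0 * np.sin(2 * np.pi * 10 * t)[None, :] * np.ones((6, 1))
        data += rng.standard_normal((6, len(t)))
        rec = Recording(data, FS, CHANNELS)
        out, _ = fl.asr_process(rec, model)
        f, p_in = welch(rec.data[2], fs=FS, nperseg=2048)
        _, p_out = welch(out.data[2], fs=FS, nperseg=2048)
        band = (f >= 8) & (f < 12)
        assert p_out[band].sum() == pytest.approx(p_in[band].sum(), rel=0.05)

    def test_channel_mismatch_rejected(self, asr_model):
        model, _ = asr_model
        rec = Recording(np.zeros((3, 1000)) + 1.0, FS, ("Fz", "Cz", "Pz"))
        rec.data[:] = np.random.default_rng(0).standard_normal((3, 1000))
        with pytest.raises(ValueError, match="channel mismatch"):
            fl.asr_process(rec, model)

    def test_output_length_equals_input_length(self, asr_model):
        model, _ = asr_model
        rng = np.random.default_rng(5)
        for n in (1000, 1003, 1249):
            rec = Recording(rng.standard_normal((6, n)), FS, CHANNELS)
            out, _ = fl.asr_process(rec, model)
            assert out.data.shape == (6, n)

    def test_per_epoch_processing_matches_continuous_on_epochs(self, asr_model):
        from conftest import make_epochs

        model, _ = asr_model
        rng = np.random.default_rng(6)
        ep = make_epochs(rng.standard_normal((3, 6, 1000)), fs=FS,
                         channels=CHANNELS)
        cleaned, counts = fl.asr_process_epochs(ep, model)
        assert cleaned.data.shape == ep.data.shape
        assert len(counts) == 3


class TestFlatlines:
    def test_zero_variance_channel_removed(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((3, 10000))
        data[1] = 4.2
        rec = Recording(data, FS, ("Fz", "Cz", "Pz"))
        out, report = fl.remove_flatlines(rec, 5.0)
        assert report["dropped_channels"] == ["Cz"]
        assert out.channel_names == ("Fz", "Pz")

    def test_run_shorter_than_criterion_retained(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 10000))
        data[0, 1000 : 1000 + int(4.9 * FS)] = 0.5
        rec = Recording(data, FS, ("Fz", "Cz"))
        out, report = fl.remove_flatlines(rec, 5.0)
        assert report["dropped_channels"] == []

    def test_six_second_flat_fz_dropped_exactly(self, short_session):
        _, _, rec, _ = short_session
        data = rec.data.copy()
        data[0, 5000 : 5000 + int(6 * FS)] = data[0, 5000]
        out, report = fl.remove_flatlines(
            Recording(data, FS, rec.channel_names), 5.0
        )
        assert report["dropped_channels"] == ["Fz"]

    def test_all_flat_is_fatal(self):
        rec = Recording(np.ones((2, 10000)), FS, ("Fz", "Cz"))
        with pytest.raises(ValueError, match="all channels"):
            fl.remove_flatlines(rec, 5.0)


class TestWindowRejection:
    def test_clean_synthetic_data_mostly_retained(self, clean_recording):
        _, _, rec = clean_recording
        retained, report = fl.reject_bad_windows(rec)
        assert (~retained).mean() < 0.02

    def test_uncorrelated_channel_span_flagged(self, clean_recording):
        _, _, rec = clean_recording
        data = rec.data.copy()
        rng = np.random.default_rng(8)
        i0, i1 = int(50 * FS), int(53 * FS)
        pz = rec.channel_index("Pz")
        data[pz, i0:i1] = rng.standard_normal(i1 - i0) * data[pz].std()
        _, report = fl.reject_bad_windows(Recording(data, FS, rec.channel_names))
        flags = report["channel_flags"]
        assert flags[50:53, pz].all()

    def test_vacuous_threshold_drops_nothing(self, short_session):
        _, _, rec, _ = short_session
        params = CleanRawParams(window_bad_fraction=1.0)
        retained, _ = fl.reject_bad_windows(rec, params)
        assert retained.all()


def test_invalid_params_rejected():
    with pytest.raises(Exception):
        CleanRawParams(channel_correlation=1.5).validate()
    with pytest.raises(Exception):
        CleanRawParams(burst_k=0.0).validate()
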