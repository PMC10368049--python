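"""Signal-conditioning chain: filtering, GLM clutter removal, TGC, envelope."""

import numpy as np
import pytest

from opusmon.records import RFRecord
from opusmon.preprocess import (
    FilterSpec,
    bandpass,
    envelope_logcompress,
    fit_crosstalk_glm,
    remove_crosstalk,
    tgc,
)
from opusmon.simulate import simulate_mmode

from conftest import make_small_config


def tone_record(freq_hz, fs, n=4096, n_acq=3):
    t = np.arange(n) / fs
    data = np.tile(np.sin(2 * np.pi * freq_hz * t)[:, None], (1, n_acq))
    return RFRecord(data, sampling_rate=fs, sound_speed=1540.0, prf=100.0)


class TestBandpass:
    def test_dc_is_rejected(self):
        rec = RFRecord(np.ones((2048, 2)), 125e6, 1540.0, prf=100.0)
        out = bandpass(rec, FilterSpec())
        assert np.max(np.abs(out.data)) < 1e-6

    def test_passband_tone_preserved_within_1db(self):
        rec = tone_record(20e6, 125e6)
        out = bandpass(rec, FilterSpec())
        interior = slice(1024, 3072)
        ratio = np.abs(out.data[interior, 0]).max() / np.abs(rec.data[interior, 0]).max()
        assert 20 * np.log10(ratio) > -1.0
        # and the designed response itself
        assert FilterSpec().response_db(125e6, [20e6])[0] > -1.0

    def test_stopband_tone_attenuated_40db(self):
        fs = 200e6  # 80 MHz lies below Nyquist here
        rec = tone_record(80e6, fs)
        out = bandpass(rec, FilterSpec())
        interior = slice(1024, 3072)
        ratio = np.abs(out.data[interior, 0]).max() / np.abs(rec.data[interior, 0]).max()
        assert 20 * np.log10(ratio) < -40.0
        assert FilterSpec().response_db(fs, [80e6])[0] < -40.0

    def test_band_edge_at_nyquist_errors_with_edge_name(self):
        rec = tone_record(10e6, 60e6, n=256)
        with pytest.raises(ValueError, match="high_cut"):
            bandpass(rec, FilterSpec())

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = RFRecord(rng.normal(size=(512, 3)), 125e6, 1540.0, prf=100.0)
        b = RFRecord(rng.normal(size=(512, 3)), 125e6, 1540.0, prf=100.0)
        spec = FilterSpec()
        lhs = bandpass(a.copy_with(2.0 * a.data + b.data), spec).data
        rhs = 2.0 * bandpass(a, spec).data + bandpass(b, spec).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(low_cut=5e6, high_cut=2e6)
        with pytest.raises(ValueError):
            FilterSpec(order=0)
        with pytest.raises(ValueError):
            FilterSpec(family="chebyshev")


class TestCrosstalkGLM:
    def test_reference_equal_record_gives_zero_residual(self):
        rng = np.random.default_rng(1)
        template = rng.normal(size=256)
        data = np.tile(template[:, None], (1, 8))
        rec = RFRecord(data, 125e6, 1540.0, prf=100.0)
        model = fit_crosstalk_glm(rec, range(8))
        out = remove_crosstalk(rec, model)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_scaled_template_in_regressor_span(self):
        rng = np.random.default_rng(2)
        template = rng.normal(size=256)
        scales = rng.uniform(0.5, 2.0, 16)
        rec = RFRecord(template[:, None] * scales[None, :], 125e6, 1540.0, prf=100.0)
        model = fit_crosstalk_glm(rec, range(16))
        out = remove_crosstalk(rec, model)
        assert np.sum(out.data**2) < 1e-10 * np.sum(rec.data**2)

    def test_residual_orthogonal_to_regressors(self):
        rng = np.random.default_rng(3)
        rec = RFRecord(rng.normal(size=(128, 6)), 125e6, 1540.0, prf=100.0)
        model = fit_crosstalk_glm(rec, range(3))
        resid = remove_crosstalk(rec, model).data
        gram = model.regressors.T @ resid
        assert np.max(np.abs(gram)) < 1e-8

    def test_remove_is_linear_given_fixed_model(self):
        rng = np.random.default_rng(4)
        rec = RFRecord(rng.normal(size=(128, 6)), 125e6, 1540.0, prf=100.0)
        model = fit_crosstalk_glm(rec, range(3))
        a, b = rng.normal(size=(128, 6)), rng.normal(size=(128, 6))
        lhs = remove_crosstalk(rec.copy_with(a + b), model).data
        rhs = remove_crosstalk(rec.copy_with(a), model).data + \
            remove_crosstalk(rec.copy_with(b), model).data - \
            remove_crosstalk(rec.copy_with(np.zeros_like(a)), model).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_too_few_references_rejected(self):
        rec = RFRecord(np.random.default_rng(0).normal(size=(64, 5)),
                       125e6, 1540.0, prf=100.0)
        with pytest.raises(ValueError, match="regressors"):
            fit_crosstalk_glm(rec, range(2), n_shifts=1)
        with pytest.raises(ValueError, match="empty"):
            fit_crosstalk_glm(rec, [])

    def test_suppresses_static_clutter_but_not_lesion_signal(self):
        """Labelled synthetic data: the static early-sample block drops by
        >= 20 dB while the lesion-band signal passes through within 1 dB."""
        cfg = make_small_config(rng_seed=11)
        cfg_null = make_small_config(rng_seed=11, lesion_max_extent=0.0)
        record, truth = simulate_mmode(cfg)
        record_null, _ = simulate_mmode(cfg_null)

        spec = FilterSpec()
        filt = bandpass(record, spec)
        lesion_only = filt.data - bandpass(record_null, spec).data  # exact label

        n_fit = record.depth_to_sample(cfg.surface_depth + 0.5)
        model = fit_crosstalk_glm(filt, range(truth.laser_on_index),
                                  fit_samples=np.arange(n_fit))
        resid = remove_crosstalk(filt, model).data

        block = slice(0, truth.crosstalk_n_samples)
        suppression_db = 10 * np.log10(
            np.sum(filt.data[block] ** 2) / np.sum(resid[block] ** 2)
        )
        assert suppression_db >= 20.0

        d = record.depth_axis_mm
        half = truth.final_extent_mm / 2.0
        band = (d > truth.fibre_tip_depth_mm - half) & (d < truth.fibre_tip_depth_mm + half)
        cols = slice(truth.laser_on_index, None)
        change_db = 10 * np.log10(
            np.sum(resid[band][:, cols] ** 2) / np.sum(lesion_only[band][:, cols] ** 2)
        )
        assert abs(change_db) < 1.0


class TestTGC:
    def test_zero_attenuation_is_identity(self):
        rec = tone_record(10e6, 125e6, n=1024)
        out = tgc(rec, 0.0, 15e6)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_closed_form_gain_ratio_over_1cm(self):
        n = 4096
        rec = RFRecord(np.ones((n, 1)), 125e6, 1540.0, prf=100.0)
        out = tgc(rec, 0.5, 15e6, max_gain_db=1000.0)
        d = rec.depth_axis_mm
        i1 = int(np.argmin(np.abs(d - 5.0)))
        i2 = int(np.argmin(np.abs(d - 15.0)))  # 1 cm deeper
        expected = 10 ** (0.5 * 15 * 2 / 20)
        ratio = out.data[i2, 0] / out.data[i1, 0]
        # sample depths land within half a pitch of the nominal 1 cm
        assert ratio == pytest.approx(expected, rel=1e-3)

    def test_gain_monotone_then_capped(self):
        rec = RFRecord(np.ones((4096, 1)), 125e6, 1540.0, prf=100.0)
        out = tgc(rec, 1.0, 30e6, max_gain_db=20.0)
        gains = out.data[:, 0]
        assert np.all(np.diff(gains) >= -1e-12)
        assert gains.max() == pytest.approx(10.0)  # 20 dB cap


class TestEnvelope:
    def test_sinusoid_envelope_constant_away_from_edges(self):
        rec = tone_record(10e6, 125e6, n=4096, n_acq=1)
        img = envelope_logcompress(rec, dynamic_range_db=60.0)
        interior = img[1024:3072, 0]
        # < 1% envelope ripple is < 0.09 dB
        assert interior.max() - interior.min() < 20 * np.log10(1.01) + 0.09

    def test_envelope_bounds_signal_modulus(self):
        from scipy.signal import hilbert

        rng = np.random.default_rng(5)
        data = rng.normal(size=(512, 4))
        env = np.abs(hilbert(data, axis=0))
        assert np.all(env >= np.abs(data) - 1e-9)

    def test_normalization_and_floor(self):
        rng = np.random.default_rng(6)
        rec = RFRecord(rng.normal(size=(512, 4)), 125e6, 1540.0, prf=100.0)
        img = envelope_logcompress(rec, dynamic_range_db=40.0)
        assert img.max() == 0.0
        assert img.min() >= -40.0
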