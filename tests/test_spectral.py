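"""Welch PSD against direct-DFT oracles, normalization, band powers, asymmetry
features and the feature-table contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anxeeg import (band_power, build_feature_table, compute_ai, compute_rasm,
                    normalize_psd, welch_psd)
from anxeeg.preprocessing import EpochMatrix
from anxeeg.spectral import BandDefinition, feature_columns, parse_feature_name


def oracle_welch(x, fs, seg_len=64, overlap=0.5):
    """Hand-rolled averaged tapered periodogram (density scaling): the
    independent reference for welch_psd."""
    from scipy.signal import get_window
    step = seg_len - int(seg_len * overlap)
    w = get_window("hamming", seg_len)   # periodic taper, as Welch uses
    scale = 1.0 / (fs * (w ** 2).sum())
    spectra = []
    for start in range(0, len(x) - seg_len + 1, step):
        seg = x[start:start + seg_len] * w
        p = np.abs(np.fft.rfft(seg)) ** 2 * scale
        p[1:-1] *= 2                      # one-sided
        spectra.append(p)
    return np.fft.rfftfreq(seg_len, 1 / fs), np.mean(spectra, axis=0)


class TestWelch:
    def test_zero_signal(self):
        psd = welch_psd(np.zeros(128), fs=128)
        assert np.all(psd.values == 0)

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=128) + np.sin(2 * np.pi * 10 * np.arange(128) / 128)
        psd = welch_psd(x, fs=128)
        of, ov = oracle_welch(x, fs=128)
        np.testing.assert_array_equal(psd.freqs, of)
        np.testing.assert_allclose(psd.values, ov, rtol=1e-10)

    def test_sinusoid_peak_at_its_bin(self):
        t = np.arange(128) / 128
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), fs=128, seg_len=64)
        assert psd.freqs[np.argmax(psd.values)] == pytest.approx(10.0)

    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        psd = welch_psd(x, fs=128)
        df = psd.freqs[1] - psd.freqs[0]
        assert psd.values.sum() * df == pytest.approx(np.var(x), rel=0.05)

    def test_segment_longer_than_signal(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(32), fs=128, seg_len=64)


class TestNormalizePsd:
    def test_endpoints_and_fixed_point(self):
        out = normalize_psd(np.array([0.0, 7.0, 14.0]))
        np.testing.assert_allclose(out, [0.0, 7.0, 14.0])
        assert out.min() == 0.0 and out.max() == 14.0

    def test_min_zero_max_fourteen(self):
        rng = np.random.default_rng(2)
        out = normalize_psd(rng.uniform(3, 9, size=50))
        assert out.min() == 0.0
        assert out.max() == 14.0

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            normalize_psd(np.full(5, 3.3))


class TestBandPower:
    def test_flat_psd(self):
        psd = welch_psd(np.zeros(128), fs=128)
        psd.values = np.ones_like(psd.values)
        assert band_power(psd, "alpha") == 1.0

    def test_ramp_mean(self):
        psd = welch_psd(np.zeros(128), fs=128)
        psd.values = psd.freqs.copy()      # PSD equals frequency
        assert band_power(psd, "alpha") == pytest.approx(10.0)  # bins 8,10,12

    def test_forty_hz_tone_lives_in_gamma(self):
        t = np.arange(128) / 128
        psd = welch_psd(np.sin(2 * np.pi * 40 * t), fs=128)
        assert band_power(psd, "delta") < 0.01 * band_power(psd, "gamma")

    def test_empty_band_error(self):
        psd = welch_psd(np.zeros(128), fs=128)
        with pytest.raises(ValueError):
            band_power(psd, BandDefinition("custom", 0.1, 0.2))


class TestAsymmetry:
    @pytest.mark.parametrize("l,r,expected", [(1, 1, 1.0), (2, 1, 2.0)])
    def test_rasm_values(self, l, r, expected):
        assert compute_rasm(l, r) == expected

    @pytest.mark.parametrize("l,r,expected", [(1, 1, 0.0), (2, 1, 1 / 3)])
    def test_ai_values(self, l, r, expected):
        assert compute_ai(l, r) == pytest.approx(expected)

    @given(l=st.floats(1e-3, 1e3), r=st.floats(1e-3, 1e3))
    @settings(derandomize=True)
    def test_rasm_reciprocal_and_ai_antisymmetry(self, l, r):
        assert compute_rasm(l, r) * compute_rasm(r, l) == pytest.approx(1.0)
        assert compute_ai(l, r) == pytest.approx(-compute_ai(r, l))
        assert -1 <= compute_ai(l, r) <= 1

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            compute_rasm(1, 0)
        with pytest.raises(ValueError):
            compute_ai(0, 0)


class TestFeatureTable:
    def test_full_configuration_sixty_columns(self, small_epochs):
        table = build_feature_table(
            small_epochs, channels=["AF3", "AF4", "FC5", "FC6", "P7", "P8"])
        assert table.shape == (small_epochs.n_epochs, 60)
        assert sum(c.startswith("MP_") for c in table.columns) == 30
        assert sum(c.startswith("RASM_") for c in table.columns) == 15
        assert sum(c.startswith("AI_") for c in table.columns) == 15
        assert "MP_AF3_beta" in table.columns
        assert "RASM_AF3-AF4_theta" in table.columns
        assert "AI_P7-P8_beta" in table.columns
        assert table.columns.is_unique

    def test_theta_beta_gives_24_columns(self, small_epochs):
        table = build_feature_table(
            small_epochs, channels=["AF3", "AF4", "FC5", "FC6", "P7", "P8"],
            bands=["theta", "beta"])
        assert table.shape[1] == 24        # 12 MP + 6 RASM + 6 AI

    def test_zero_epochs_keeps_header(self):
        ep = EpochMatrix(epochs=np.empty((0, 14, 128)), fs=128,
                         channels=tuple(f"c{i}" for i in range(14)),
                         provenance=[])
        cols = feature_columns(["c0"], ["alpha"], [])
        table = build_feature_table(ep, channels=["c0"], bands=["alpha"],
                                    pairs=[])
        assert list(table.columns) == cols and len(table) == 0

    def test_unknown_channel_error(self, small_epochs):
        with pytest.raises(ValueError, match="XX"):
            build_feature_table(small_epochs, channels=["XX"])

    def test_scale_covariance(self, small_epochs):
        """x -> c*x multiplies MP by c^2 and leaves RASM and AI unchanged."""
        sub = small_epochs
        scaled = EpochMatrix(epochs=3.0 * sub.epochs, fs=sub.fs,
                             channels=sub.channels,
                             provenance=sub.provenance)
        a = build_feature_table(sub, channels=["AF3", "AF4"])
        b = build_feature_table(scaled, channels=["AF3", "AF4"])
        mp = [c for c in a.columns if c.startswith("MP_")]
        rest = [c for c in a.columns if not c.startswith("MP_")]
        np.testing.assert_allclose(b[mp].to_numpy(), 9.0 * a[mp].to_numpy(),
                                   rtol=1e-10)
        np.testing.assert_allclose(b[rest].to_numpy(), a[rest].to_numpy(),
                                   rtol=1e-10)

    def test_parse_feature_name(self):
        assert parse_feature_name("MP_AF3_beta") == ("MP", "AF3", "beta")
        assert parse_feature_name("RASM_AF3-AF4_theta") == ("RASM", "AF3-AF4",
                                                            "theta")
        with pytest.raises(ValueError):
            parse_feature_name("XX_AF3_beta")
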