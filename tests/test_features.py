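"""Wavelet decomposition, band powers, matrix assembly, normalization."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegaffect as ea
from eegaffect.features import (
    FeatureMatrix,
    apply_norm_params,
    band_power,
    dwt_band_decompose,
    dyadic_scheme,
)


def _sine_window(freq, fs=128.0, n=128):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


class TestBandScheme:
    def test_dyadic_edges_at_128hz(self):
        scheme = dyadic_scheme(128.0)
        edges = {b.name: (b.f_low, b.f_high) for b in scheme.bands}
        assert edges == {
            "delta": (0.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 16.0),
            "beta": (16.0, 32.0), "gamma": (32.0, 64.0),
        }
        codes = {b.name: b.subband_code for b in scheme.bands}
        assert codes == {
            "delta": "A4", "theta": "D4", "alpha": "D3", "beta": "D2", "gamma": "D1",
        }

    def test_first_detail_level_covers_upper_half_spectrum(self):
        # the D1 band edge is sampling_rate/4 .. sampling_rate/2, analytically
        scheme = dyadic_scheme(256.0)
        assert scheme.bands[-1].f_low == 64.0
        assert scheme.bands[-1].f_high == 128.0


class TestDecomposition:
    def test_zero_window_gives_zero_coefficients(self):
        sub = dwt_band_decompose(np.zeros((3, 128)))
        for c in sub.values():
            np.testing.assert_array_equal(c, 0.0)

    def test_periodized_db4_coefficient_counts_are_dyadic(self):
        sub = dwt_band_decompose(np.random.default_rng(0).standard_normal((1, 128)))
        counts = {b: c.shape[-1] for b, c in sub.items()}
        assert counts == {"delta": 8, "theta": 8, "alpha": 16, "beta": 32, "gamma": 64}

    def test_alpha_tone_concentrates_in_alpha_subband(self):
        sub = dwt_band_decompose(_sine_window(10.0))
        energy = {b: float((c ** 2).sum()) for b, c in sub.items()}
        assert energy["alpha"] / sum(energy.values()) >= 0.60

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError):
            dwt_band_decompose(np.zeros((1, 8)))

    def test_parseval_for_orthogonal_wavelet(self):
        """Subband energies sum to the window's time-domain energy."""
        x = np.random.default_rng(1).standard_normal((4, 128))
        sub = dwt_band_decompose(x)
        subband_energy = sum((c ** 2).sum() for c in sub.values())
        assert subband_energy == pytest.approx((x ** 2).sum(), rel=0.05)


class TestBandPower:
    def test_zero_and_empty(self):
        assert band_power(np.zeros(16)) == 0.0
        with pytest.raises(ValueError):
            band_power(np.array([]))

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_quadratic_homogeneity(self, scale):
        c = np.random.default_rng(2).standard_normal(32)
        assert band_power(scale * c) == pytest.approx(scale ** 2 * band_power(c))

    def test_gamma_tone_dominates_gamma_band(self):
        # at the gamma band centre the gamma power exceeds 10x every other band
        sub = dwt_band_decompose(_sine_window(48.0))
        p = {b: float(band_power(c[0])) for b, c in sub.items()}
        others = max(v for b, v in p.items() if b != "gamma")
        assert p["gamma"] >= 10 * others
        # nearer the 32 Hz edge the dyadic filters leak, but gamma still wins
        sub40 = dwt_band_decompose(_sine_window(40.0))
        p40 = {b: float(band_power(c[0])) for b, c in sub40.items()}
        assert max(p40, key=p40.get) == "gamma"


class TestAssembly:
    def test_feature_counts(self, protocol_trial):
        ws = ea.epoch(protocol_trial, 1.0)
        fm = ea.assemble_features(ws)
        assert fm.values.shape == (120, 70)  # 14 channels x 5 bands
        pair = ea.assemble_features(ws, channels=["T7", "T8"])
        assert pair.n_features == 10  # 2 channels x 5 bands

    def test_column_order_is_channel_major_band_minor(self, protocol_trial):
        ws = ea.epoch(protocol_trial, 1.0)
        fm = ea.assemble_features(ws, channels=["T7", "T8"])
        assert fm.column_names == [
            "T7:delta", "T7:theta", "T7:alpha", "T7:beta", "T7:gamma",
            "T8:delta", "T8:theta", "T8:alpha", "T8:beta", "T8:gamma",
        ]

    def test_unknown_channel_raises(self, protocol_trial):
        ws = ea.epoch(protocol_trial, 1.0)
        with pytest.raises(KeyError):
            ea.assemble_features(ws, channels=["T7", "XX"])

    def test_csv_round_trip(self, tmp_path, protocol_trial):
        ws = ea.epoch(protocol_trial, 1.0)
        fm = ea.assemble_features(ws, channels=["T7", "T8"])
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.columns == fm.columns
        assert list(back.labels) == list(fm.labels)


class TestNormalization:
    def _tiny(self, values):
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        bands = ("delta", "theta", "alpha", "beta", "gamma")
        return FeatureMatrix(
            values=values,
            columns=[("T7", b) for b in bands[: values.shape[1]]],
            labels=np.array(["happy"] * n),
            subject_ids=np.zeros(n, dtype=int),
            trial_ids=np.zeros(n, dtype=int),
            window_indices=np.arange(n),
        )

    def test_minmax_maps_column_to_unit_interval(self):
        fm = self._tiny([[2.0], [4.0], [6.0]])
        out = ea.minmax_normalize(fm)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        assert out.normalized

    def test_constant_column_maps_to_zero_with_warning(self):
        fm = self._tiny([[5.0], [5.0]])
        with pytest.warns(UserWarning):
            out = ea.minmax_normalize(fm)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_reapplying_stored_params_is_idempotent(self):
        fm = self._tiny([[2.0, 1.0], [4.0, 3.0], [6.0, 2.0]])
        out = ea.minmax_normalize(fm)
        again = apply_norm_params(fm, out.norm_params)
        np.testing.assert_allclose(again.values, out.values)

    def test_rows_outside_fit_set_are_clipped(self):
        fm = self._tiny([[2.0], [4.0], [9.0]])
        out = ea.minmax_normalize(fm, fit_rows=np.array([True, True, False]))
        assert out.values[2, 0] == 1.0  # 9 > fit max 4, clipped
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    @given(
        data=st.lists(
            st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=2),
            min_size=2, max_size=8,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_normalized_values_always_in_unit_interval(self, data):
        fm = self._tiny(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = ea.minmax_normalize(fm)
        assert (out.values >= 0.0).all() and (out.values <= 1.0).all()

    def test_per_subject_normalization_is_self_contained(self, protocol_trial):
        ws = ea.epoch(protocol_trial, 1.0)
        fm = ea.assemble_features(ws, channels=["T7"])
        out = ea.normalize_per_subject(fm)
        # a single subject: identical to plain min-max over its own rows
        ref = ea.minmax_normalize(fm)
        np.testing.assert_allclose(out.values, ref.values)
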