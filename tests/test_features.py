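"""Feature extraction: closed-form oracles, DWT reference, normalization."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from enose_stl.features import (
    FeatureSpec,
    FeatureVector,
    MinMaxScaler,
    build_feature_vector,
    integral_feature,
    load_feature_table,
    max_falling_slope,
    max_rising_slope,
    normalize_dataset,
    save_feature_table,
    steady_state_max,
    wavelet_feature,
)
from enose_stl.simulate import (
    BASELINE_END_S,
    EXPOSURE_END_S,
    TOTAL_S,
    SimConfig,
    response_template,
    simulate_curve,
)

from conftest import make_curve, plateau_curve


def ramp_curve(baseline: float, slope: float):
    """Linear rise during exposure, held flat afterwards."""
    t = np.arange(TOTAL_S + 1)
    sig = np.full(t.size, baseline)
    rising = (t >= BASELINE_END_S) & (t <= EXPOSURE_END_S)
    sig[rising] = baseline + slope * (t[rising] - BASELINE_END_S)
    sig[t > EXPOSURE_END_S] = sig[rising][-1]
    return make_curve(sig)


def triangle_curve(peak: float):
    """Triangular pulse spanning the exposure phase, apex at its midpoint."""
    t = np.arange(TOTAL_S + 1)
    mid = (BASELINE_END_S + EXPOSURE_END_S) / 2
    half = (EXPOSURE_END_S - BASELINE_END_S) / 2
    sig = np.maximum(0.0, peak * (1.0 - np.abs(t - mid) / half))
    sig[(t < BASELINE_END_S) | (t > EXPOSURE_END_S)] = 0.0
    return make_curve(sig)


class TestClosedFormOracles:
    def test_steady_state_max_on_plateau(self):
        assert steady_state_max(plateau_curve(1.0, 3.2), 0) == pytest.approx(3.2)

    def test_steady_state_max_flat_curve_is_zero(self):
        assert steady_state_max(plateau_curve(0.8, 0.0), 0) == pytest.approx(0.0)

    def test_rising_slope_on_linear_ramp(self):
        assert max_rising_slope(ramp_curve(1.0, 0.05), 0) == pytest.approx(0.05)

    def test_slopes_vanish_on_constant_curve(self):
        flat = plateau_curve(1.0, 0.0)
        assert max_rising_slope(flat, 0) == 0.0
        assert max_falling_slope(flat, 0) == 0.0

    def test_falling_slope_is_positive_magnitude(self):
        curve = plateau_curve(1.0, 3.2)  # drops 3.2 at recovery onset
        assert max_falling_slope(curve, 0) == pytest.approx(3.2)

    def test_integral_of_constant_exposure(self):
        assert integral_feature(plateau_curve(0.5, 2.0), 0) == pytest.approx(600.0)

    def test_integral_of_zero_curve(self):
        assert integral_feature(plateau_curve(0.5, 0.0), 0) == pytest.approx(0.0)

    def test_integral_of_triangle_matches_riemann_sum(self):
        curve = triangle_curve(1.0)
        assert integral_feature(curve, 0) == pytest.approx(150.0)
        # brute-force trapezoid at 1 Hz
        t = curve.timestamps
        mask = (t >= BASELINE_END_S) & (t <= EXPOSURE_END_S)
        y = curve.readings[mask, 0]
        brute = sum((y[i] + y[i + 1]) / 2 for i in range(y.size - 1))
        assert integral_feature(curve, 0) == pytest.approx(brute)


class TestAgainstSimulatorKinetics:
    def test_steady_max_matches_generator_closed_form(self):
        config = SimConfig(noise_sd=0.0, rise_tau=30.0)
        curve = simulate_curve(
            [1.0] * 5, config, np.random.default_rng(0), baseline=np.full(5, 0.5)
        )
        expected = 1.0 - np.exp(-300.0 / 30.0)  # ~0.99995
        assert steady_state_max(curve, 0) == pytest.approx(expected, rel=1e-9)

    def test_rising_slope_of_exponential_matches_brute_force(self):
        """First 1 Hz increment of A(1-exp(-t/tau)) is A(1-exp(-1/tau))."""
        A, tau = 2.0, 35.0
        config = SimConfig(noise_sd=0.0, rise_tau=tau)
        curve = simulate_curve(
            [A] * 5, config, np.random.default_rng(0), baseline=np.full(5, 0.5)
        )
        t = curve.timestamps
        mask = (t >= BASELINE_END_S) & (t <= EXPOSURE_END_S)
        x = curve.readings[mask, 0]
        brute = max(x[i + 1] - x[i] for i in range(x.size - 1))
        assert max_rising_slope(curve, 0) == pytest.approx(brute)
        assert brute == pytest.approx(A * (1.0 - np.exp(-1.0 / tau)), rel=1e-9)

    def test_steady_max_and_integral_monotone_in_amplitude(self):
        config = SimConfig(noise_sd=0.0)
        rng = np.random.default_rng(0)
        values = []
        for amp in (0.5, 1.0, 1.5, 2.0):
            curve = simulate_curve(
                [amp] * 5, config, rng, baseline=np.full(5, 0.5)
            )
            values.append((steady_state_max(curve, 0), integral_feature(curve, 0)))
        assert all(a[0] < b[0] and a[1] < b[1] for a, b in zip(values, values[1:]))


def reference_dwt_detail(signal, wavelet_name, level):
    """Independent DWT: explicit symmetric extension + convolution cascade.

    Per level: extend the approximation by (filter length - 1) samples on
    each side by symmetric reflection, convolve with the analysis filters,
    and keep every second sample starting at offset 1.
    """
    w = pywt.Wavelet(wavelet_name)
    lo = np.asarray(w.dec_lo)
    hi = np.asarray(w.dec_hi)
    L = w.dec_len
    approx = np.asarray(signal, dtype=float)
    detail = None
    for _ in range(level):
        ext = np.concatenate([approx[: L - 1][::-1], approx, approx[-(L - 1):][::-1]])
        detail = np.convolve(ext, hi, mode="valid")[1::2]
        approx = np.convolve(ext, lo, mode="valid")[1::2]
    return detail


class TestWaveletFeature:
    def test_zero_signal_gives_zero(self):
        assert wavelet_feature(plateau_curve(0.3, 0.0), 0) == pytest.approx(0.0)

    def test_scaling_signal_scales_feature(self):
        base = plateau_curve(0.0, 1.3)
        scaled = make_curve(base.readings[:, 0] * -2.5)
        assert wavelet_feature(scaled, 0) == pytest.approx(
            2.5 * wavelet_feature(base, 0)
        )

    def test_unit_step_matches_reference_transform(self):
        """Step at the exposure/recovery boundary vs the convolution cascade."""
        t = np.arange(TOTAL_S + 1)
        sig = (t >= EXPOSURE_END_S).astype(float)
        curve = make_curve(sig)
        spec = FeatureSpec()
        base = curve.readings[(t >= 120) & (t < 180), 0].mean()
        expected = np.abs(
            reference_dwt_detail(sig - base, spec.wavelet_name, spec.wavelet_level)
        ).max()
        assert wavelet_feature(curve, 0, spec) == pytest.approx(expected, rel=1e-10)

    def test_random_signals_match_reference_transform(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            sig = rng.normal(size=1201)
            curve = make_curve(sig)
            spec = FeatureSpec()
            base = sig[120:180].mean()
            expected = np.abs(
                reference_dwt_detail(sig - base, "db4", 3)
            ).max()
            assert wavelet_feature(curve, 0, spec) == pytest.approx(expected, rel=1e-9)

    def test_too_short_signal_rejected(self):
        spec = FeatureSpec(wavelet_level=12)
        with pytest.raises(ValueError, match="level"):
            wavelet_feature(plateau_curve(0.5, 1.0), 0, spec)


class TestBuildFeatureVector:
    @pytest.mark.parametrize("n,length", [(3, 9), (5, 25)])
    def test_vector_length_is_n_squared(self, n, length, noiseless_sim):
        curve = simulate_curve(
            [1.0] * 5, noiseless_sim, np.random.default_rng(0)
        )
        fv = build_feature_vector(curve, FeatureSpec.for_dim(n))
        assert fv.values.size == length

    def test_flatten_is_row_major_feature_by_sensor(self, noiseless_sim):
        curve = simulate_curve(
            [0.5, 1.0, 1.5, 2.0, 2.5], noiseless_sim, np.random.default_rng(0)
        )
        spec = FeatureSpec.for_dim(3)
        fv = build_feature_vector(curve, spec)
        M = fv.matrix()
        assert M[0, 2] == pytest.approx(steady_state_max(curve, 2))
        assert M[1, 0] == pytest.approx(max_rising_slope(curve, 0))
        np.testing.assert_array_equal(M.ravel(), fv.values)

    def test_identical_curves_identical_vectors(self, noiseless_sim):
        c1 = simulate_curve([1.0] * 5, noiseless_sim, np.random.default_rng(5))
        c2 = simulate_curve([1.0] * 5, noiseless_sim, np.random.default_rng(5))
        spec = FeatureSpec.for_dim(4)
        np.testing.assert_array_equal(
            build_feature_vector(c1, spec).values,
            build_feature_vector(c2, spec).values,
        )

    @given(offset=st.floats(min_value=-5.0, max_value=5.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_features_invariant_to_constant_offset(self, offset):
        """Baseline subtraction makes every feature offset-invariant."""
        config = SimConfig(noise_sd=0.05)
        curve = simulate_curve(
            [1.0, 0.5, 1.5, 0.8, 1.2], config, np.random.default_rng(11),
            baseline=np.full(5, 6.0),  # keep offset curves positive
        )
        shifted = make_curve(curve.readings + offset)
        spec = FeatureSpec.for_dim(5)
        np.testing.assert_allclose(
            build_feature_vector(shifted, spec).values,
            build_feature_vector(curve, spec).values,
            rtol=1e-9, atol=1e-9,
        )


class TestNormalization:
    def _fv(self, values, label=1, n=None):
        values = np.asarray(values, dtype=float)
        n = n or int(round(values.size**0.5))
        return FeatureVector(values=values, n=n, label=label)

    def test_midpoint_maps_to_half(self):
        fit = [self._fv([2.0, 0, 0, 0]), self._fv([4.0, 1, 1, 1])]
        others = [self._fv([3.0, 0.5, 0.5, 0.5])]
        _, (scaled,), _ = normalize_dataset(fit, others)
        assert scaled[0].values[0] == pytest.approx(0.5)

    def test_constant_coordinate_maps_to_zero(self):
        fit = [self._fv([1.0, 7.0, 0, 0]), self._fv([2.0, 7.0, 1, 1])]
        scaled_fit, _, _ = normalize_dataset(fit)
        assert all(v.values[1] == 0.0 for v in scaled_fit)

    def test_refit_on_normalized_data_is_identity(self):
        rng = np.random.default_rng(0)
        fit = [self._fv(rng.uniform(0, 3, 9)) for _ in range(10)]
        scaled, _, _ = normalize_dataset(fit)
        rescaled, _, _ = normalize_dataset(scaled)
        for a, b in zip(scaled, rescaled):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_empty_fit_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_dataset([])

    def test_scaler_text_round_trip(self):
        rng = np.random.default_rng(1)
        scaler = MinMaxScaler().fit(rng.uniform(size=(6, 4)))
        back = MinMaxScaler.from_json(scaler.to_json())
        X = rng.uniform(size=(3, 4))
        np.testing.assert_array_equal(scaler.transform(X), back.transform(X))


def test_feature_table_round_trip(tmp_path, noiseless_sim):
    curves = [
        simulate_curve([1.0] * 5, noiseless_sim, np.random.default_rng(i),
                       sample_id=f"c{i}", label=1 + i % 4)
        for i in range(4)
    ]
    spec = FeatureSpec.for_dim(3)
    vectors = [build_feature_vector(c, spec) for c in curves]
    path = tmp_path / "features.csv"
    save_feature_table(vectors, path)
    loaded = load_feature_table(path)
    assert [v.label for v in loaded] == [v.label for v in vectors]
    for a, b in zip(vectors, loaded):
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
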