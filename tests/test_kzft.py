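"""KZ coefficients, KZFT bandpass behavior and the analytic transfer function."""

import numpy as np
import pytest
import sympy

from vbpbb import (
    KZFTSpec,
    RegularSeries,
    apply_kz,
    apply_kzft,
    default_window,
    gain,
    kz_coefficients,
    reconstruct,
)
from vbpbb.kzft import _kzft_values


def polynomial_weights(m, k):
    """Independent oracle: coefficients of (1 + z + ... + z^(m-1))^k / m^k
    by symbolic polynomial expansion."""
    z = sympy.symbols("z")
    poly = sympy.Poly(sympy.expand(sum(z**i for i in range(m)) ** k), z)
    coeffs = [int(c) for c in reversed(poly.all_coeffs())]
    return np.array(coeffs, dtype=float) / m**k


class TestCoefficients:
    @pytest.mark.parametrize("m", [1, 3, 5, 7, 9])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_match_polynomial_expansion(self, m, k):
        w = kz_coefficients(m, k).weights
        expected = polynomial_weights(m, k)
        assert w.shape == (k * (m - 1) + 1,)
        np.testing.assert_array_equal(w, expected)

    @pytest.mark.parametrize(
        "m, k, expected",
        [
            (3, 1, [1 / 3, 1 / 3, 1 / 3]),
            (1, 5, [1.0]),
            (3, 2, np.array([1, 2, 3, 2, 1]) / 9),
        ],
    )
    def test_worked_examples(self, m, k, expected):
        np.testing.assert_allclose(kz_coefficients(m, k).weights, expected, atol=1e-15)

    @pytest.mark.parametrize("m, k", [(4, 1), (0, 1), (-3, 2), (3, 0)])
    def test_invalid_arguments_rejected(self, m, k):
        with pytest.raises(ValueError):
            kz_coefficients(m, k)

    def test_symmetric_nonnegative_unit_sum(self):
        for m, k in [(5, 3), (9, 2), (21, 1), (7, 4)]:
            w = kz_coefficients(m, k).weights
            np.testing.assert_allclose(w, w[::-1], rtol=0, atol=0)
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) < 1e-12


class TestApplyKZ:
    def test_constant_preserved(self):
        x = RegularSeries(np.full(50, 3.7))
        out = apply_kz(x, KZFTSpec(m=5, k=2))
        np.testing.assert_allclose(out.values[out.valid_mask], 3.7, atol=1e-12)

    def test_linear_trend_preserved(self):
        t = np.arange(40, dtype=float)
        out = apply_kz(RegularSeries(t), KZFTSpec(m=5, k=1))
        np.testing.assert_allclose(out.values[out.valid_mask], t[out.valid_mask], atol=1e-10)

    def test_white_noise_variance_shrinks_by_squared_weights(self, rng):
        # sum of squared weights for (m=3, k=2) is 19/81
        x = RegularSeries(rng.normal(0, 1, 200_000))
        out = apply_kz(x, KZFTSpec(m=3, k=2))
        var = out.values[out.valid_mask].var()
        assert abs(var - 19 / 81) < 0.05 * (19 / 81)

    def test_edge_margin_is_half_window(self):
        for m, k in [(5, 1), (7, 2), (3, 3)]:
            x = RegularSeries(np.ones(60))
            out = apply_kz(x, KZFTSpec(m=m, k=k))
            h = k * (m - 1) // 2
            assert (~out.valid_mask[:h]).all() and (~out.valid_mask[-h:]).all() if h else True
            assert int((~out.valid_mask).sum()) == 2 * h

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            apply_kz(RegularSeries(np.ones(8)), KZFTSpec(m=9, k=2))


class TestApplyKZFT:
    def test_zero_frequency_equals_kz(self, rng):
        x = RegularSeries(rng.normal(0, 1, 200))
        zd = apply_kzft(x, KZFTSpec(m=9, k=2, nu=0.0))
        kz = apply_kz(x, KZFTSpec(m=9, k=2))
        np.testing.assert_allclose(
            zd.z[zd.valid_mask].real, kz.values[kz.valid_mask], atol=1e-12
        )
        np.testing.assert_allclose(zd.z[zd.valid_mask].imag, 0.0, atol=1e-12)

    def test_constant_annihilated_when_num_integer(self):
        x = RegularSeries(np.full(1500, 4.2))
        zd = apply_kzft(x, KZFTSpec(m=721, k=1, nu=1 / 7))
        assert np.abs(zd.z[zd.valid_mask]).max() < 1e-10 * 4.2

    def test_pure_cosine_demodulates_to_half_amplitude(self):
        nu, phi, m = 1 / 7, 0.9, 721
        t = np.arange(1500)
        x = RegularSeries(np.cos(2 * np.pi * nu * t + phi))
        zd = apply_kzft(x, KZFTSpec(m=m, k=1, nu=nu))
        z = zd.z[zd.valid_mask]
        np.testing.assert_allclose(np.abs(z), 0.5, atol=1e-6)
        expected = 0.5 * np.exp(1j * (2 * np.pi * nu * t[zd.valid_mask] + phi))
        np.testing.assert_allclose(z, expected, atol=1e-6)

    def test_linearity(self, rng):
        spec = KZFTSpec(m=21, k=2, nu=1 / 7)
        x = rng.normal(0, 1, 300)
        y = rng.normal(0, 1, 300)
        a, b = 2.5, -1.25
        z1 = apply_kzft(RegularSeries(a * x + b * y), spec).z
        z2 = a * apply_kzft(RegularSeries(x), spec).z + b * apply_kzft(RegularSeries(y), spec).z
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            KZFTSpec(m=21, k=1, nu=0.7)
        with pytest.raises(ValueError):
            KZFTSpec(m=21, k=1, nu=-0.1)

    def test_nonintegral_num_flagged_and_warned(self):
        spec = KZFTSpec(m=741, k=1, nu=1 / 20)  # 741/20 = 37.05
        assert not spec.nu_m_integer
        with pytest.warns(UserWarning, match="not an integer"):
            apply_kzft(RegularSeries(np.ones(1600)), spec)
        assert KZFTSpec(m=721, k=1, nu=1 / 7).nu_m_integer


class TestReconstruct:
    def test_pure_cosine_recovered(self):
        nu, phi = 1 / 7, 1.3
        t = np.arange(1500)
        x = np.cos(2 * np.pi * nu * t + phi)
        pc = reconstruct(apply_kzft(RegularSeries(x), KZFTSpec(m=721, k=1, nu=nu)))
        err = np.abs(pc.values[pc.valid_mask] - x[pc.valid_mask]).max()
        assert err < 0.01
        assert pc.p == 7

    def test_zero_in_zero_out(self):
        pc = reconstruct(apply_kzft(RegularSeries(np.zeros(100)), KZFTSpec(m=21, k=1, nu=1 / 7)))
        np.testing.assert_array_equal(pc.values, 0.0)

    def test_off_frequency_tone_lands_on_dirichlet_null(self):
        # tone at 2/21 with filter at 1/7 = 3/21, m=21: offset 1/21 has m*offset = 1
        t = np.arange(2000)
        x = np.cos(2 * np.pi * (2 / 21) * t)
        pc = reconstruct(apply_kzft(RegularSeries(x), KZFTSpec(m=21, k=1, nu=1 / 7)))
        # both tone images sit on exact nulls of the kernel
        assert np.abs(pc.values[pc.valid_mask]).max() < 1e-6


class TestGain:
    def test_unity_at_center(self):
        for m, k, nu in [(21, 1, 1 / 7), (63, 2, 1 / 21), (1095, 1, 1 / 365)]:
            assert gain(KZFTSpec(m=m, k=k, nu=nu), nu) == pytest.approx(1.0)

    def test_null_at_integer_offsets(self):
        spec = KZFTSpec(m=21, k=1, nu=1 / 7)
        for j in (1, 2, 3):
            assert gain(spec, 1 / 7 + j / 21) == pytest.approx(0.0, abs=1e-12)

    def test_iteration_squares_the_kernel(self):
        probes = 1 / 7 + np.linspace(-0.05, 0.05, 11)
        g1 = gain(KZFTSpec(m=21, k=1, nu=1 / 7), probes)
        g2 = gain(KZFTSpec(m=21, k=2, nu=1 / 7), probes)
        np.testing.assert_allclose(g2, g1**2, atol=1e-12)

    def test_even_in_frequency_offset(self):
        spec = KZFTSpec(m=33, k=1, nu=0.2)
        d = np.linspace(0.001, 0.1, 25)
        np.testing.assert_allclose(gain(spec, 0.2 + d), gain(spec, 0.2 - d), atol=1e-12)

    def test_empirical_gain_matches_analytic(self):
        # complex-exponential probes: one-sided transfer, no mirror leakage
        spec = KZFTSpec(m=63, k=1, nu=1 / 7)
        coeffs = kz_coefficients(63, 1)
        t = np.arange(600)
        for dnu in np.linspace(-0.06, 0.06, 13):
            probe = np.exp(2j * np.pi * (spec.nu + dnu) * t)
            z, mask = _kzft_values(probe, coeffs, spec.nu)
            emp = np.abs(z[mask]).mean()
            assert abs(emp - gain(spec, spec.nu + dnu)) < 1e-8


def test_default_window_is_odd_multiple_of_period():
    assert default_window(7) == 21
    assert default_window(365) == 1095
    assert default_window(20) == 61  # 60 rounded up to odd
    assert default_window(13) == 39
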