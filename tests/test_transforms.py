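"""Transform correctness: closed forms, Haar algebra, and the pywt oracle."""

import numpy as np
import pytest
import pywt

from pearspec import (
    Spectrum,
    TransformedSeries,
    apply_transform,
    first_derivative,
    haar_dwt,
    inverse_reflectance,
    log_reflectance,
)

SQ2 = np.sqrt(2.0)


def spectrum(values, start=400.0):
    values = np.asarray(values, dtype=float)
    return Spectrum("s", "east", start + np.arange(values.size), values)


class TestPointwiseTransforms:
    @pytest.mark.parametrize("r, expected", [
        ([0.5, 0.5], [2.0, 2.0]),
        ([0.25, 0.5], [4.0, 2.0]),
        ([0.0, 0.5], [1e4, 2.0]),  # zero reflectance hits the 1e-4 floor
    ])
    def test_inverse(self, r, expected):
        np.testing.assert_allclose(inverse_reflectance(spectrum(r)).values, expected)

    @pytest.mark.parametrize("r, expected", [
        ([1.0, 1.0], [0.0, 0.0]),
        ([0.1, 1.0], [-1.0, 0.0]),
        ([0.5, 0.5], [-0.30103, -0.30103]),
    ])
    def test_log10(self, r, expected):
        np.testing.assert_allclose(log_reflectance(spectrum(r)).values, expected, atol=1e-5)

    def test_axes_unchanged_and_tags(self):
        s = spectrum([0.2, 0.4, 0.6])
        assert inverse_reflectance(s).transform_tag == "invR"
        assert log_reflectance(s).transform_tag == "logR"
        np.testing.assert_array_equal(inverse_reflectance(s).axis_nm, s.wavelengths_nm)


class TestFirstDerivative:
    def test_linear_ramp_exact(self):
        wl = 400.0 + np.arange(20.0)
        t = TransformedSeries("R", wl, 0.001 * wl)
        out = first_derivative(t)
        np.testing.assert_allclose(out.values, 0.001)
        np.testing.assert_array_equal(out.axis_nm, wl[1:-1])
        assert out.transform_tag == "dR"

    def test_constant_is_zero(self):
        out = first_derivative(TransformedSeries("logR", np.arange(5.0), np.ones(5)))
        np.testing.assert_array_equal(out.values, 0.0)
        assert out.transform_tag == "d_logR"

    def test_hand_example_unit_spacing(self):
        out = first_derivative(TransformedSeries("R", np.arange(4.0), [1.0, 4.0, 9.0, 16.0]))
        np.testing.assert_allclose(out.values, [4.0, 6.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            first_derivative(TransformedSeries("R", np.arange(2.0), [1.0, 2.0]))


class TestHaar:
    def test_constant_signal_scaling(self):
        dec = haar_dwt(np.ones(8), np.arange(8.0))
        for j, expect in [(1, SQ2), (2, 2.0), (3, 2 * SQ2)]:
            np.testing.assert_allclose(dec.approximations[j].values, expect)
            np.testing.assert_allclose(dec.details[j].values, 0.0)

    def test_two_level_hand_example(self):
        dec = haar_dwt(np.array([1.0, 3.0, 5.0, 7.0]), levels=2)
        np.testing.assert_allclose(dec.approximations[1].values, [2 * SQ2, 6 * SQ2])
        np.testing.assert_allclose(dec.details[1].values, [-SQ2, -SQ2])

    def test_parseval_by_hand(self):
        x = np.array([1.0, 3.0, 5.0, 7.0])
        dec = haar_dwt(x, levels=1)
        l1, h1 = dec.approximations[1].values, dec.details[1].values
        assert np.sum(x ** 2) == pytest.approx(np.sum(l1 ** 2) + np.sum(h1 ** 2))
        assert np.sum(l1 ** 2) == pytest.approx(8 + 72)
        assert np.sum(h1 ** 2) == pytest.approx(2 + 2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            haar_dwt(np.ones(7), levels=3)

    def test_resolution_halves_per_level(self):
        for n in (8, 11, 29, 64, 100):
            dec = haar_dwt(np.random.default_rng(n).normal(size=n))
            lengths = [n] + [dec.approximations[j].values.size for j in (1, 2, 3)]
            for prev, cur in zip(lengths, lengths[1:]):
                assert cur == -(-prev // 2)  # ceil halving

    def test_matches_pywt_reference(self):
        rng = np.random.default_rng(0)
        for n in (8, 13, 21, 64, 127, 200):
            x = rng.normal(size=n)
            dec = haar_dwt(x)
            coeffs = pywt.wavedec(x, "haar", mode="symmetric", level=3)
            np.testing.assert_allclose(dec.approximations[3].values, coeffs[0], atol=1e-10)
            for j, ref in zip((3, 2, 1), coeffs[1:]):
                np.testing.assert_allclose(dec.details[j].values, ref, atol=1e-10)

    def test_perfect_reconstruction_oracle(self):
        rng = np.random.default_rng(1)
        for n in (8, 9, 30, 45, 64):
            x = rng.normal(size=n)
            dec = haar_dwt(x)
            cur = dec.approximations[3].values
            for j in (3, 2, 1):
                d = dec.details[j].values
                up = np.empty(2 * cur.size)
                up[0::2] = (cur + d) / SQ2
                up[1::2] = (cur - d) / SQ2
                target = -(-n // 2 ** (j - 1))  # length before level-j padding
                cur = up[:target]
            np.testing.assert_allclose(cur, x, atol=1e-10)

    def test_axis_is_support_midpoint(self):
        wl = 350.0 + np.arange(8.0)
        dec = haar_dwt(np.ones(8), wl)
        np.testing.assert_allclose(dec.approximations[1].axis_nm, [350.5, 352.5, 354.5, 356.5])
        np.testing.assert_allclose(dec.approximations[3].axis_nm, [353.5])

    def test_pad_positions_excluded_from_axis(self):
        wl = np.arange(9.0)
        dec = haar_dwt(np.ones(9), wl, levels=1)
        # last coefficient covers only the real ninth sample
        np.testing.assert_allclose(dec.approximations[1].axis_nm[-1], 8.0)
        assert dec.pad_lengths[0] == 1 and dec.pad_length >= 1

    def test_alternating_noise_lands_in_details_only(self):
        wl = np.arange(256.0)
        base = np.sin(wl / 40.0)
        noise = 0.05 * (-1.0) ** np.arange(256)
        clean, noisy = haar_dwt(base, wl), haar_dwt(base + noise, wl)
        dh1 = noisy.details[1].values - clean.details[1].values
        dl3 = noisy.approximations[3].values - clean.approximations[3].values
        assert np.mean(dh1 ** 2) > 1e-3
        assert np.max(np.abs(dl3)) < 1e-12  # aligned +/- pairs cancel in every average


class TestApplyTransform:
    def test_matrix_dispatch_matches_per_spectrum(self, toy_dataset):
        rep = apply_transform("invR", toy_dataset.wavelengths_nm, toy_dataset.reflectance)
        per = inverse_reflectance(toy_dataset.spectrum(1))
        np.testing.assert_allclose(rep.values[1], per.values)

    @pytest.mark.parametrize("tag, length", [
        ("R", 8), ("logR", 8), ("dR", 6), ("d_logR", 6),
        ("L1", 4), ("H1", 4), ("L2", 2), ("L3", 1),
    ])
    def test_output_lengths(self, toy_dataset, tag, length):
        rep = apply_transform(tag, toy_dataset.wavelengths_nm, toy_dataset.reflectance)
        assert rep.values.shape == (3, length)
        assert rep.transform_tag == tag

    def test_unknown_tag_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="unknown transform"):
            apply_transform("R2", toy_dataset.wavelengths_nm, toy_dataset.reflectance)
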