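"""Spectral integration, MacLeod-Boynton chromaticity, and hue geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromadapt import colorspace as cs
from chromadapt.fundamentals import illuminant_c, judd_vlambda, task_fundamentals
from chromadapt.spectra import DEFAULT_GRID, Spectrum, SpectrumError


def random_spectrum(rng, kind="radiance"):
    return Spectrum(DEFAULT_GRID, rng.uniform(0, 2, DEFAULT_GRID.size), kind)


# ------------------------------------------------------------- cone absorption
class TestConeAbsorptions:
    def test_zero_spectrum_gives_zero(self, task_fund):
        zero = Spectrum(DEFAULT_GRID, np.zeros(DEFAULT_GRID.size))
        assert cs.cone_absorptions(zero, task_fund) == (0.0, 0.0, 0.0)

    def test_linearity(self, task_fund):
        rng = np.random.default_rng(0)
        a, b = random_spectrum(rng), random_spectrum(rng)
        la = np.array(cs.cone_absorptions(a, task_fund))
        lb = np.array(cs.cone_absorptions(b, task_fund))
        lsum = np.array(cs.cone_absorptions(a + b, task_fund))
        lscaled = np.array(cs.cone_absorptions(2.0 * a, task_fund))
        np.testing.assert_allclose(lsum, la + lb, rtol=1e-12)
        np.testing.assert_allclose(lscaled, 2.0 * la, rtol=1e-12)

    def test_disjoint_supports_error(self, task_fund):
        uv = Spectrum([200.0, 300.0], [1.0, 1.0])
        with pytest.raises(SpectrumError):
            cs.cone_absorptions(uv, task_fund)


class TestLuminance:
    def test_zero_and_scaling(self):
        zero = Spectrum(DEFAULT_GRID, np.zeros(DEFAULT_GRID.size))
        assert cs.luminance(zero) == 0.0
        spec = random_spectrum(np.random.default_rng(1))
        assert cs.luminance(3.0 * spec) == pytest.approx(3.0 * cs.luminance(spec))

    def test_monochromatic_line_at_vlambda_peak(self):
        v = judd_vlambda()
        peak_wl = v.wavelengths[np.argmax(v.values)]
        vals = np.zeros(DEFAULT_GRID.size)
        vals[DEFAULT_GRID == peak_wl] = 1.0  # unit power in a 1-nm bin
        line = Spectrum(DEFAULT_GRID, vals)
        assert cs.luminance(line) == pytest.approx(683.0 * v.values.max())

    def test_luminance_equals_l_plus_m_absorption(self, task_fund):
        # the mb_scaled normalisation ties luminance to L+M exactly
        spec = random_spectrum(np.random.default_rng(2))
        lms = cs.cone_absorptions(spec, task_fund)
        assert cs.luminance(spec) == pytest.approx(683.0 * (lms.l + lms.m), rel=1e-12)


# --------------------------------------------------------------- chromaticity
class TestMBChromaticity:
    @pytest.mark.parametrize(
        "lms, expected",
        [
            ((0.5, 0.5, 0.01), (0.5, 0.01)),
            ((0.7, 0.3, 0.0), (0.7, 0.0)),
            ((1.0, 0.0, 0.5), (1.0, 0.5)),
        ],
    )
    def test_formula(self, lms, expected):
        got = cs.mb_chromaticity(cs.LMS(*lms))
        assert got == pytest.approx(expected)

    def test_degenerate(self):
        with pytest.raises(cs.DegenerateInputError):
            cs.mb_chromaticity(cs.LMS(0.0, 0.0, 1.0))

    @given(
        l=st.floats(0.01, 10), m=st.floats(0.01, 10),
        s=st.floats(0, 10), c=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, l, m, s, c):
        """Chromaticity is a ratio: uniform rescaling of L, M, S is invisible."""
        a = cs.mb_chromaticity(cs.LMS(l, m, s))
        b = cs.mb_chromaticity(cs.LMS(c * l, c * m, c * s))
        assert a.rmb == pytest.approx(b.rmb, rel=1e-9)
        assert a.bmb == pytest.approx(b.bmb, rel=1e-9, abs=1e-12)


class TestScaledSpace:
    @pytest.mark.parametrize(
        "chroma, expected",
        [
            ((0.6568, 0.01825), (0.0, 0.0)),
            ((0.6578, 0.01825), (2.168, 0.0)),
            ((0.6568, 0.01825 + 1.0 / 6210.0), (0.0, 1.0)),
        ],
    )
    def test_affine_map(self, chroma, expected):
        got = cs.scale_mb(cs.MBChromaticity(*chroma))
        assert got == pytest.approx(expected, abs=1e-9)

    @given(rmb=st.floats(0, 1), bmb=st.floats(0, 0.1))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, rmb, bmb):
        c = cs.MBChromaticity(rmb, bmb)
        back = cs.unscale_mb(cs.scale_mb(c))
        assert back.rmb == pytest.approx(rmb, abs=1e-12)
        assert back.bmb == pytest.approx(bmb, abs=1e-12)


class TestHueGeometry:
    @pytest.mark.parametrize(
        "angle, expected",
        [
            (360.0, (80.0, 0.0)),
            (270.0, (0.0, -80.0)),
            (200.0, (-75.17540966287267, -27.361611466053496)),
        ],
    )
    def test_polar_to_cartesian(self, angle, expected):
        got = cs.hue_to_scaled_mb(cs.HueSetting(angle))
        assert got == pytest.approx(expected, abs=1e-9)

    @given(angle=st.floats(0, 359.999), radius=st.floats(0.1, 500))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, angle, radius):
        back = cs.scaled_mb_to_hue(cs.hue_to_scaled_mb(cs.HueSetting(angle, radius)))
        assert back.angle == pytest.approx(angle, abs=1e-9)
        assert back.radius == pytest.approx(radius, rel=1e-12)

    def test_origin_has_no_angle(self):
        with pytest.raises(cs.DegenerateInputError):
            cs.scaled_mb_to_hue(cs.ScaledMB(0.0, 0.0))

    def test_task_range_guard(self):
        with pytest.raises(ValueError):
            cs.HueSetting(150.0).require_task_range()


# ----------------------------------------------------------------- white point
class TestWhitePointAnchor:
    """Illuminant C through the packaged fundamentals sits at the space origin."""

    def test_mb_coordinates_of_illuminant_c(self, task_fund):
        c = cs.mb_chromaticity(cs.cone_absorptions(illuminant_c(), task_fund))
        assert c.rmb == pytest.approx(0.6568, abs=5e-3)
        assert c.bmb == pytest.approx(0.01825, abs=5e-3)

    def test_scaled_origin_within_ten_threshold_units(self, task_fund):
        c = cs.mb_chromaticity(cs.cone_absorptions(illuminant_c(), task_fund))
        p = cs.scale_mb(c)
        assert np.hypot(p.LM, p.S) < 10.0

    def test_packaged_tables_reproduce_standard_chromaticities(self):
        """Independent cross-check of the transcribed tables: equal-energy
        white at (1/3, 1/3) and Illuminant C at its published (0.3101, 0.3162)
        under the CIE 1931 observer."""
        from chromadapt.fundamentals import cie1931_cmfs

        xbar, ybar, zbar = cie1931_cmfs()
        for spd, expected, tol in [
            (np.ones(xbar.wavelengths.size), (1 / 3, 1 / 3), 2e-3),
            (illuminant_c().values, (0.3101, 0.3162), 2e-3),
        ]:
            X = float(np.sum(spd * xbar.values))
            Y = float(np.sum(spd * ybar.values))
            Z = float(np.sum(spd * zbar.values))
            x, y = X / (X + Y + Z), Y / (X + Y + Z)
            assert x == pytest.approx(expected[0], abs=tol)
            assert y == pytest.approx(expected[1], abs=tol)
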