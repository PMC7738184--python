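"""Cone-gain k = L/M and the color-constancy fraction."""

import numpy as np
import pytest

from chromadapt import colorspace as cs
from chromadapt.display import FilterModel, apply_filter, render_setting, rgb_to_spectrum
from chromadapt.gain import (
    cone_gain_k,
    constancy_fraction,
    daily_constancy,
    perfect_constancy_k,
)
from chromadapt.pipeline import summarize_tests
from chromadapt.spectra import DEFAULT_GRID, Spectrum


def identity_filter():
    return FilterModel(
        Spectrum(DEFAULT_GRID, np.ones(DEFAULT_GRID.size), "transmittance"), "identity"
    )


def monochromatic_filter(wavelength):
    vals = np.zeros(DEFAULT_GRID.size)
    vals[DEFAULT_GRID == wavelength] = 1.0
    return FilterModel(Spectrum(DEFAULT_GRID, vals, "transmittance"), f"line@{wavelength}")


class TestConeGain:
    def test_identity_filter_equals_no_filter(self, monitor):
        h = cs.HueSetting(290.0)
        k_off = cone_gain_k(h, monitor).k
        k_id = cone_gain_k(h, monitor, filt=identity_filter()).k
        assert k_id == pytest.approx(k_off, rel=1e-12)

    def test_condition_labels(self, monitor, glasses):
        h = cs.HueSetting(290.0)
        assert cone_gain_k(h, monitor).condition == "glasses_off"
        assert cone_gain_k(h, monitor, filt=glasses).condition == "glasses_on"

    def test_scale_invariance_of_k(self, monitor, gain_fund):
        """k is a ratio of absorptions: scaling the whole spectrum cancels."""
        spec = rgb_to_spectrum(render_setting(cs.HueSetting(300.0), monitor), monitor)
        lms1 = cs.cone_absorptions(spec, gain_fund)
        lms2 = cs.cone_absorptions(5.0 * spec, gain_fund)
        assert lms1.l / lms1.m == pytest.approx(lms2.l / lms2.m, rel=1e-12)

    def test_equal_absorptions_give_unit_k(self):
        lms = cs.LMS(0.37, 0.37, 0.02)
        assert lms.l / lms.m == 1.0

    def test_monotone_in_redness(self, monitor):
        """Moving the setting toward the red endpoint strictly raises L/M."""
        ks = [cone_gain_k(cs.HueSetting(a), monitor).k for a in np.arange(200.0, 361.0, 5.0)]
        assert np.all(np.diff(ks) > 0)

    def test_wrong_normalisation_rejected(self, monitor, task_fund):
        with pytest.raises(ValueError):
            cone_gain_k(cs.HueSetting(290.0), monitor, fund=task_fund)

    def test_baseline_k_within_plausible_band(self, monitor):
        """With peak-normalised fundamentals the absolute k level is a
        convention; the packaged set puts baseline unique yellow in a band
        slightly above 1 (see methods note on normalisation dependence)."""
        k = cone_gain_k(cs.HueSetting(297.4), monitor).k
        assert 1.0 < k < 1.5


class TestPerfectConstancy:
    def test_identity_filter_reference_equals_baseline(self, monitor):
        h = cs.HueSetting(297.0)
        assert perfect_constancy_k(h, monitor, identity_filter()) == pytest.approx(
            cone_gain_k(h, monitor).k
        )

    def test_red_filter_raises_reference_above_baseline(self, monitor, glasses):
        h = cs.HueSetting(297.0)
        assert perfect_constancy_k(h, monitor, glasses) > cone_gain_k(h, monitor).k

    def test_monochromatic_filter_limit(self, monitor, gain_fund):
        """A filter passing a single wavelength reduces k to the ratio of the
        two fundamentals at that wavelength."""
        wl = 600.0
        spec = rgb_to_spectrum(render_setting(cs.HueSetting(290.0), monitor), monitor)
        out = apply_filter(spec, monochromatic_filter(wl))
        lms = cs.cone_absorptions(out, gain_fund)
        assert lms.l / lms.m == pytest.approx(gain_fund.L(wl) / gain_fund.M(wl), rel=1e-9)


class TestConstancyFraction:
    def test_no_constancy_anchor(self):
        assert constancy_fraction(1.0, 1.0, 1.5).fraction == 0.0

    def test_perfect_constancy_anchor(self):
        assert constancy_fraction(1.0, 1.5, 1.5).fraction == 1.0

    def test_intermediate_arithmetic(self):
        res = constancy_fraction(1.00, 1.34, 1.50)
        assert res.fraction == pytest.approx(0.68)
        assert res.percent == pytest.approx(68.0)

    def test_degenerate_reference_flagged(self):
        res = constancy_fraction(1.0, 1.2, 1.0)
        assert res.degenerate and np.isnan(res.fraction)


class TestDailyConstancy:
    def test_growth_with_learning(self, noise_free_records, monitor, glasses):
        """A cohort whose rapid adjustment grows across days shows
        nondecreasing constancy of the first on-glasses setting."""
        summaries = summarize_tests(noise_free_records)
        table = daily_constancy(summaries, monitor, glasses)
        assert list(table["day"]) == [1, 2, 3, 4, 5]
        assert np.all(np.diff(table["fraction"]) > 0)
        assert ((table["fraction"] > 0) & (table["fraction"] < 1)).all()

    def test_aggregation_orders_agree_without_heterogeneity(
        self, noise_free_records, monitor, glasses
    ):
        summaries = summarize_tests(noise_free_records)
        a = daily_constancy(summaries, monitor, glasses, order="mean_settings")
        b = daily_constancy(summaries, monitor, glasses, order="per_observer")
        np.testing.assert_allclose(a["fraction"], b["fraction"], rtol=1e-9)
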