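import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quenchbind.assays import (
    DigestionRecord,
    DpphRecord,
    EmulsionRecord,
    FoamRecord,
    GraftingRecord,
    INFINITE_STABILITY,
    SolubilityRecord,
    bioaccessibility,
    conc_from_absorbance,
    dpph_scavenging,
    emulsification,
    fit_standard_curve,
    foaming,
    grafting_efficiency,
    solubility,
)
from quenchbind.errors import QualityWarning, ValidationError

SLOPE, INTERCEPT = 9.935, 0.1077


class TestStandardCurve:
    def test_exact_points_recover_reference_coefficients(self):
        conc = np.linspace(0.0, 0.1, 8)
        pts = list(zip(conc, SLOPE * conc + INTERCEPT))
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(SLOPE, rel=1e-12)
        assert curve.intercept == pytest.approx(INTERCEPT, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolating_line(self):
        curve = fit_standard_curve([(0.0, 0.1), (0.1, 1.1)])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.1)

    def test_duplicated_points_match_closed_form_ols(self):
        pts = [(0.0, 0.1), (0.05, 0.65), (0.1, 1.1), (0.05, 0.65)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        # closed-form OLS on the weighted points
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(slope, rel=1e-12)

    def test_degenerate_concentrations(self):
        with pytest.raises(ValidationError, match="degenerate"):
            fit_standard_curve([(0.05, 0.5), (0.05, 0.6), (0.05, 0.7)])

    def test_inversion_round_trip(self):
        conc = np.linspace(0.01, 0.1, 6)
        curve = fit_standard_curve(list(zip(conc, SLOPE * conc + INTERCEPT)))
        for c in conc:
            back = conc_from_absorbance(curve, SLOPE * c + INTERCEPT)
            assert back == pytest.approx(c, abs=1e-9)

    @pytest.mark.parametrize(
        "absorbance, expected", [(INTERCEPT, 0.0), (1.1012, 0.1000)]
    )
    def test_inversion_values(self, absorbance, expected):
        curve = fit_standard_curve(
            [(c, SLOPE * c + INTERCEPT) for c in (0.0, 0.05, 0.1)]
        )
        assert conc_from_absorbance(curve, absorbance) == pytest.approx(expected, abs=1e-6)

    def test_below_intercept_clamps_with_warning(self):
        curve = fit_standard_curve([(0.0, 0.1), (0.1, 1.1)])
        with pytest.warns(QualityWarning):
            assert conc_from_absorbance(curve, 0.05) == 0.0


class TestCalculators:
    @pytest.mark.parametrize(
        "c, c0, expected", [(1.0, 1.0, 100.0), (0.0, 1.0, 0.0), (0.824, 1.0, 82.40)]
    )
    def test_grafting(self, c, c0, expected):
        assert grafting_efficiency(GraftingRecord(c, c0)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a0, a1, a2, expected",
        [(0.8, 0.3, 0.3, 100.0), (0.8, 0.0, 0.8, 0.0), (0.8, 0.05, 0.65, 25.0)],
    )
    def test_dpph_blank_corrected(self, a0, a1, a2, expected):
        assert dpph_scavenging(DpphRecord(a0, a1, a2)) == pytest.approx(expected)

    def test_dpph_literal_variant(self):
        rec = DpphRecord(0.8, 0.05, 0.65)
        assert dpph_scavenging(rec, "literal") == pytest.approx(
            100 * (0.8 - 0.65 - 0.05) / 0.8
        )
        with pytest.raises(ValidationError):
            dpph_scavenging(rec, "bogus")

    @pytest.mark.parametrize(
        "soluble, total, expected", [(10.0, 10.0, 100.0), (0.0, 10.0, 0.0), (7.5, 10.0, 75.0)]
    )
    def test_solubility(self, soluble, total, expected):
        assert solubility(SolubilityRecord(soluble, total)) == pytest.approx(expected)

    def test_foaming(self):
        fe, fs = foaming(FoamRecord(15.0, 30.0, 22.5))
        assert (fe, fs) == (pytest.approx(200.0), pytest.approx(150.0))
        fe2, fs2 = foaming(FoamRecord(15.0, 15.0, 10.0))
        assert fe2 == pytest.approx(100.0)
        assert fs2 <= fe2  # V30 <= V implies FS <= FE

    def test_emulsification_values(self):
        eai, esi = emulsification(EmulsionRecord(0.5, 0.4, 100.0, 0.01, 0.25, 0.001))
        assert eai == pytest.approx(2 * 2.303 * 0.5 * 100 / (0.01 * 0.25 * 0.001), rel=1e-12)
        assert eai == pytest.approx(9.212e7, rel=1e-3)
        assert esi == pytest.approx(50.0, rel=1e-12)

    def test_emulsification_infinite_stability_sentinel(self):
        _, esi = emulsification(EmulsionRecord(0.5, 0.5, 100.0, 0.01, 0.25, 0.001))
        assert esi == INFINITE_STABILITY

    @pytest.mark.parametrize(
        "cd, ci, expected", [(0.8, 0.8, 100.0), (0.0, 0.8, 0.0), (0.6, 0.8, 75.0)]
    )
    def test_bioaccessibility(self, cd, ci, expected):
        assert bioaccessibility(DigestionRecord(cd, ci)) == pytest.approx(expected)

    def test_soluble_above_total_warns_not_fails(self):
        with pytest.warns(QualityWarning):
            assert solubility(SolubilityRecord(11.0, 10.0)) == pytest.approx(110.0)


class TestHomogeneity:
    """Every percent calculator is scale-free in its unit choice."""

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), num=st.floats(0.0, 10.0), den=st.floats(0.1, 10.0))
    def test_ratio_calculators(self, scale, num, den):
        assert grafting_efficiency(GraftingRecord(num, den)) == pytest.approx(
            grafting_efficiency(GraftingRecord(num * scale, den * scale)), rel=1e-9
        )
        assert solubility(SolubilityRecord(num, den)) == pytest.approx(
            solubility(SolubilityRecord(num * scale, den * scale)), rel=1e-9
        )
        assert bioaccessibility(DigestionRecord(num, den)) == pytest.approx(
            bioaccessibility(DigestionRecord(num * scale, den * scale)), rel=1e-9
        )
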