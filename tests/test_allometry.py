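"""Allometric fits and equation evaluation.

High-precision reference values come from mpmath at 50 significant
digits, evaluated independently of the package's float arithmetic.
"""

import math

import mpmath
import numpy as np
import pytest

from crownmap.allometry import (
    AGB_PLANTATION,
    AGB_SAVANNA,
    AGBEquation,
    AllometricModel,
    BELOW_DOMAIN_FLAG,
    EQ_LINEAR_OPEN,
    EQ_LOG_FOREST,
    agb_from_dbh,
    agc_from_agb,
    apply_carbon,
    dbh_from_cd,
    default_dispatch,
    fit_four_run_average,
    fit_log_ma_baskerville,
    fit_major_axis,
)
from crownmap.geometry import TreeRecord

mpmath.mp.dps = 50


class TestMajorAxisFit:
    def test_noiseless_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = fit_major_axis(x, 2 * x + 1)
        assert m.slope == pytest.approx(2.0, rel=1e-12)
        assert m.intercept == pytest.approx(1.0, rel=1e-12)
        assert m.sigma == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_under_axis_swap(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 200)
        y = 3.0 * x - 2.0 + rng.normal(0, 0.8, 200)
        forward = fit_major_axis(x, y)
        backward = fit_major_axis(y, x)
        assert backward.slope == pytest.approx(1.0 / forward.slope, rel=1e-9)

    def test_scale_equivariance(self):
        # exact on collinear data: rescaling x rescales the slope reciprocally
        x = np.array([1.0, 2.0, 5.0, 9.0])
        y = 5.0 * x - 3.0
        base = fit_major_axis(x, y)
        for k in (0.5, 2.0, 4.0):
            scaled = fit_major_axis(k * x, y)
            assert scaled.slope == pytest.approx(base.slope / k, rel=1e-12)
        # approximate once noise enters (the major axis is not scale-invariant
        # in general, but tight data stays close)
        rng = np.random.default_rng(1)
        xn = rng.uniform(1, 10, 2000)
        yn = 5.0 * xn + rng.normal(0, 0.5, 2000)
        noisy = fit_major_axis(xn, yn)
        rescaled = fit_major_axis(4.0 * xn, yn)
        assert rescaled.slope == pytest.approx(noisy.slope / 4.0, rel=0.02)

    def test_parameter_recovery_with_symmetric_noise(self):
        rng = np.random.default_rng(42)
        n = 10_000
        cd = rng.uniform(1.0, 10.0, n)
        dbh = EQ_LINEAR_OPEN.intercept + EQ_LINEAR_OPEN.slope * cd
        x = cd + rng.normal(0, 0.5, n)
        y = dbh + rng.normal(0, 0.5, n)
        m = fit_major_axis(x, y)
        assert m.slope == pytest.approx(EQ_LINEAR_OPEN.slope, rel=0.02)
        assert m.intercept == pytest.approx(EQ_LINEAR_OPEN.intercept, abs=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_major_axis([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_major_axis([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            # zero covariance
            fit_major_axis([1.0, 2.0, 3.0], [2.0, 4.0, 2.0])


class TestLogBaskervilleFit:
    def test_noiseless_power_law_recovered(self):
        cd = np.linspace(0.5, 20, 300)
        dbh = np.exp(EQ_LOG_FOREST.intercept) * (cd * 1.27) ** EQ_LOG_FOREST.slope
        m = fit_log_ma_baskerville(cd, dbh)
        assert m.intercept == pytest.approx(EQ_LOG_FOREST.intercept, abs=1e-9)
        assert m.slope == pytest.approx(EQ_LOG_FOREST.slope, rel=1e-9)
        assert m.correction == pytest.approx(1.0, abs=1e-9)

    def test_correction_at_least_one(self):
        rng = np.random.default_rng(3)
        cd = rng.lognormal(1.0, 0.5, 400)
        dbh = np.exp(1.0) * (cd * 1.27) ** 1.2 * np.exp(rng.normal(0, 0.4, 400))
        m = fit_log_ma_baskerville(cd, dbh)
        assert m.correction >= 1.0
        assert m.correction == pytest.approx(math.exp(m.sigma**2 / 2), rel=1e-12)

    def test_sigma_recovery(self):
        # identifiable only when the CD spread dominates the noise (log-sd 0.9
        # matches the 1-25 m crown range of natural-forest field samples);
        # with a narrow CD range the MA line tilts to absorb part of the noise
        # and the vertical residual sd is inflated
        rng = np.random.default_rng(8)
        n = 10_000
        cd = rng.lognormal(1.2, 0.9, n)
        dbh = np.exp(EQ_LOG_FOREST.intercept) * (cd * 1.27) ** EQ_LOG_FOREST.slope
        dbh = dbh * np.exp(rng.normal(0, 0.3315, n))
        m = fit_log_ma_baskerville(cd, dbh)
        assert m.sigma == pytest.approx(0.3315, rel=0.05)

    def test_nonpositive_rows_reported(self):
        with pytest.raises(ValueError, match="rows"):
            fit_log_ma_baskerville([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestPrediction:
    def test_linear_printed_coefficients(self):
        assert dbh_from_cd(5.0, EQ_LINEAR_OPEN) == pytest.approx(20.845, abs=1e-9)

    def test_linear_root_gives_zero(self):
        cd0 = 4.665 / 5.102
        assert dbh_from_cd(cd0, EQ_LINEAR_OPEN) == pytest.approx(0.0, abs=1e-12)

    def test_log_form_at_unit_cd(self):
        expected = float(
            mpmath.exp(mpmath.mpf("1.154") + mpmath.mpf("1.248") * mpmath.log(mpmath.mpf("1.27")))
            * mpmath.exp(mpmath.mpf("0.3315") ** 2 / 2)
        )
        got = dbh_from_cd(1.0, EQ_LOG_FOREST)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(4.51, abs=0.01)

    def test_log_form_positive_and_increasing(self):
        cd = np.logspace(-3, 2, 500)
        dbh = dbh_from_cd(cd, EQ_LOG_FOREST)
        assert (dbh > 0).all()
        assert (np.diff(dbh) > 0).all()

    def test_rejects_nonpositive_cd(self):
        with pytest.raises(ValueError, match="> 0"):
            dbh_from_cd(0.0, EQ_LINEAR_OPEN)


class TestBiomass:
    def test_power_forms_at_unit_dbh(self):
        assert agb_from_dbh(1.0, AGB_SAVANNA) == pytest.approx(0.091, rel=1e-12)
        assert agb_from_dbh(1.0, AGB_PLANTATION) == pytest.approx(0.202, rel=1e-12)

    def test_chave_reference_point(self):
        eq = AGBEquation(form="chave", E=0.0, rho=1.0)
        assert agb_from_dbh(1.0, eq) == pytest.approx(math.exp(1.803), rel=1e-12)

    def test_nonpositive_dbh_gives_zero(self):
        assert agb_from_dbh(-3.0, AGB_SAVANNA) == 0.0
        assert agb_from_dbh(0.0, AGB_PLANTATION) == 0.0

    @pytest.mark.parametrize(
        "eq",
        [AGB_SAVANNA, AGB_PLANTATION, AGBEquation(form="chave", E=0.5, rho=0.54)],
        ids=["savanna", "plantation", "chave"],
    )
    def test_monotone_in_dbh(self, eq):
        dbh = np.logspace(-2, 3, 2000)  # up to 1,000 cm
        agb = agb_from_dbh(dbh, eq)
        assert (np.diff(agb) > 0).all()

    def test_high_precision_equivalence(self):
        rng = np.random.default_rng(12)
        dbh = rng.uniform(0.5, 300.0, 2000)
        for eq in (AGB_SAVANNA, AGB_PLANTATION):
            got = agb_from_dbh(dbh, eq)
            for d, g in zip(dbh[:200], got[:200]):
                ref = float(mpmath.mpf(eq.a) * mpmath.mpf(d) ** mpmath.mpf(eq.b))
                assert abs(g - ref) <= 1e-9 * ref

    def test_carbon_fraction(self):
        assert agc_from_agb(0.0) == 0.0
        assert agc_from_agb(100.0) == pytest.approx(47.0, rel=1e-12)
        assert agc_from_agb(1000.0) == pytest.approx(470.0, rel=1e-12)


class TestFourRunProtocol:
    def test_deterministic_given_seeds(self):
        rng = np.random.default_rng(5)
        cd = rng.uniform(1, 10, 400)
        dbh = -4.665 + 5.102 * cd + rng.normal(0, 2.0, 400)
        a = fit_four_run_average(cd, dbh, seeds=(1, 2, 3, 4))
        b = fit_four_run_average(cd, dbh, seeds=(1, 2, 3, 4))
        assert (a.intercept, a.slope, a.sigma) == (b.intercept, b.slope, b.sigma)
        assert a.seeds == (1, 2, 3, 4)

    def test_noiseless_data_reproduces_single_fit(self):
        cd = np.linspace(1, 10, 100)
        dbh = -4.665 + 5.102 * cd
        avg = fit_four_run_average(cd, dbh)
        assert avg.slope == pytest.approx(5.102, rel=1e-12)
        assert avg.intercept == pytest.approx(-4.665, rel=1e-9)


class TestApplyCarbon:
    def _rec(self, cd, landcover):
        return TreeRecord(1, math.pi * (cd / 2) ** 2, cd, (0.0, 0.0), landcover=landcover)

    def test_small_crown_flagged_below_domain(self):
        out = apply_carbon([self._rec(0.6, "farmland")], E=0.5)
        assert out[0].agb_kg == 0.0 and out[0].agc_kg == 0.0
        assert BELOW_DOMAIN_FLAG in out[0].flags

    def test_class_routing(self):
        recs = [
            self._rec(5.0, "natural_forest"),
            self._rec(5.0, "savanna_shrubland"),
            self._rec(5.0, "farmland"),
        ]
        out = apply_carbon(recs, E=0.5)
        forest, savanna, farm = out
        assert forest.equation_id == "log_forest+chave"
        dbh = 20.845
        assert savanna.agb_kg == pytest.approx(0.091 * dbh**2.472, rel=1e-9)
        assert farm.agb_kg == pytest.approx(0.202 * dbh**2.447, rel=1e-9)
        assert farm.agc_kg == pytest.approx(0.47 * farm.agb_kg, rel=1e-12)

    def test_requires_E_and_landcover(self):
        with pytest.raises(ValueError, match="environmental stress"):
            apply_carbon([self._rec(5.0, "natural_forest")])
        with pytest.raises(ValueError, match="land-cover"):
            apply_carbon([self._rec(5.0, None)], E=0.5)
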