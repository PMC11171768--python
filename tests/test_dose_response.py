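"""Probit dose-response analysis: corrections, transform, fit, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecotoxscreen.dose_response import (
    DoseGroup,
    LinearResponseLine,
    abbott_correct,
    classify_clarkson,
    fit_linear_response,
    fit_probit_from_percentages,
    fit_probit_line,
    invert_linear_response,
    lc50,
    lc50_by_replicate,
    miller_tainter_correct,
    mortality_rate,
    pct_to_probit,
    se_log_lc50,
    validate_mortality_series,
)
from ecotoxscreen.errors import (
    EcotoxError,
    InvalidControlError,
    InvalidInputError,
    MustCorrectFirstError,
    NoLC50Error,
    ExtrapolationWarning,
    NonMonotoneResponseWarning,
)

from conftest import DOSES, MORTALITY_24H, MORTALITY_48H, N_PER_GROUP


class TestMortalityAndCorrections:
    @pytest.mark.parametrize(
        "dead,total,expected", [(0, 10, 0.0), (10, 10, 100.0), (37, 100, 37.0)]
    )
    def test_mortality_rate(self, dead, total, expected):
        assert mortality_rate(dead, total) == expected

    def test_mortality_rate_rejects_zero_total(self):
        with pytest.raises(InvalidInputError):
            mortality_rate(0, 0)

    @pytest.mark.parametrize(
        "treated,control,expected",
        [(37.0, 0.0, 37.0), (50.0, 20.0, 37.5), (10.0, 10.0, 0.0)],
    )
    def test_abbott(self, treated, control, expected):
        assert abbott_correct(treated, control) == pytest.approx(expected)

    def test_abbott_clamps_below_zero(self):
        assert abbott_correct(5.0, 10.0) == 0.0

    def test_abbott_rejects_total_control_mortality(self):
        with pytest.raises(InvalidControlError):
            abbott_correct(50.0, 100.0)

    @given(st.floats(0.0, 99.9), st.floats(0.0, 99.0))
    def test_abbott_never_exceeds_100(self, treated, control):
        assert abbott_correct(treated, control) <= 100.0

    @pytest.mark.parametrize(
        "pct,n,expected", [(0.0, 10, 2.5), (100.0, 10, 97.5), (37.0, 10, 37.0)]
    )
    def test_miller_tainter(self, pct, n, expected):
        assert miller_tainter_correct(pct, n) == pytest.approx(expected)

    def test_miller_tainter_scales_with_n(self):
        # 0.25/n replacements: n=100 gives 0.25% and 99.75%
        assert miller_tainter_correct(0.0, 100) == pytest.approx(0.25)
        assert miller_tainter_correct(100.0, 100) == pytest.approx(99.75)


class TestProbitTransform:
    @pytest.mark.parametrize(
        "pct,expected",
        [(50.0, 5.00), (37.0, 4.67), (17.0, 4.05), (2.5, 3.04), (97.5, 6.96), (57.0, 5.18)],
    )
    def test_finney_table_values(self, pct, expected):
        assert pct_to_probit(pct) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pct", [0.0, 100.0, -1.0, 101.0])
    def test_extremes_must_be_corrected_first(self, pct):
        with pytest.raises(MustCorrectFirstError):
            pct_to_probit(pct)

    @given(st.floats(0.01, 99.99))
    def test_symmetry_about_median(self, p):
        """probit(p) + probit(100-p) = 10 from the symmetry of the normal."""
        total = pct_to_probit(p, round_dp=None) + pct_to_probit(100 - p, round_dp=None)
        assert total == pytest.approx(10.0, abs=1e-9)

    @given(st.floats(0.1, 99.8), st.floats(0.05, 0.1))
    def test_strictly_increasing(self, p, dp):
        assert pct_to_probit(p + dp, round_dp=None) > pct_to_probit(p, round_dp=None)


def _normal_equations(x, y):
    """Independent straight-line oracle from the raw normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    slope = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / sxx
    intercept = (np.sum(y) - slope * np.sum(x)) / n
    return slope, intercept


class TestProbitFit:
    def test_24h_line_matches_reference_analysis(self):
        fit = fit_probit_from_percentages(DOSES, MORTALITY_24H, N_PER_GROUP)
        assert fit.slope == pytest.approx(4.4481, abs=5e-5)
        assert fit.intercept == pytest.approx(-8.2472, abs=5e-5)
        assert fit.r_squared == pytest.approx(0.8684, abs=5e-5)
        assert fit.p_value == pytest.approx(0.0681, abs=5e-5)
        assert fit.log_lc50 == pytest.approx(2.9782, abs=5e-5)
        assert fit.lc50 == pytest.approx(951.04, rel=5e-4)

    def test_48h_line_matches_reference_analysis(self):
        fit = fit_probit_from_percentages(DOSES, MORTALITY_48H, N_PER_GROUP)
        assert fit.slope == pytest.approx(3.4913, abs=5e-5)
        assert fit.intercept == pytest.approx(-4.161, abs=5e-4)
        assert fit.r_squared == pytest.approx(0.8999, abs=5e-5)
        assert fit.p_value == pytest.approx(0.0514, abs=5e-5)
        assert fit.lc50 == pytest.approx(420.65, rel=5e-4)

    def test_two_point_line(self):
        fit = fit_probit_from_percentages(
            [1.0, 10.0], [15.87, 84.13], 10000, probit_round=2
        )
        # probits 4.00 and 6.00 at log doses 0 and 1
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(4.0)
        assert fit.log_lc50 == pytest.approx(0.5)

    def test_fit_agrees_with_normal_equations_oracle(self):
        fit = fit_probit_from_percentages(DOSES, MORTALITY_24H, N_PER_GROUP)
        x = [p.log10_dose for p in fit.points]
        y = [p.probit for p in fit.points]
        slope, intercept = _normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_count_based_entry_point_pools_replicates(self):
        groups = [
            DoseGroup(c, 10, d, 24.0, replicate_id=r)
            for c, d24 in [(250.0, (0, 0, 0)), (2000.0, (10, 10, 10)), (1000.0, (4, 4, 3))]
            for r, d in zip("ABC", d24)
        ]
        fit = fit_probit_line(groups)
        at_1000 = [p for p in fit.points if math.isclose(10**p.log10_dose, 1000)][0]
        assert at_1000.raw_pct == pytest.approx(100 * 11 / 30)
        assert fit.slope > 0

    def test_dose_scaling_equivariance(self):
        """Multiplying all doses by c multiplies LC50 by c (log-shift)."""
        fit1 = fit_probit_from_percentages(DOSES, MORTALITY_24H, N_PER_GROUP)
        scaled = [d * 7.0 for d in DOSES]
        fit2 = fit_probit_from_percentages(scaled, MORTALITY_24H, N_PER_GROUP)
        assert fit2.lc50 == pytest.approx(fit1.lc50 * 7.0, rel=1e-9)
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-9)

    def test_lc50_closed_form_and_guard(self):
        fit = fit_probit_from_percentages(DOSES, MORTALITY_24H, N_PER_GROUP)
        assert lc50(fit) == pytest.approx(10 ** ((5 - fit.intercept) / fit.slope))
        with pytest.warns(NonMonotoneResponseWarning):
            bad = fit_probit_from_percentages(DOSES, MORTALITY_24H[::-1], N_PER_GROUP)
        assert math.isnan(bad.lc50)
        with pytest.raises(NoLC50Error):
            lc50(bad)

    def test_rejects_single_concentration(self):
        with pytest.raises(InvalidInputError):
            fit_probit_from_percentages([100.0, 100.0], [10.0, 20.0], 10)

    def test_mixed_time_points_rejected(self):
        groups = [DoseGroup(250, 10, 0, 24.0), DoseGroup(500, 10, 1, 48.0)]
        with pytest.raises(InvalidInputError):
            fit_probit_line(groups)


class TestSeLogLc50:
    @pytest.mark.parametrize(
        "slope,intercept,n,expected", [(1.0, 2.0, 8, 0.5), (2.0, 0.0, 2, 0.5)]
    )
    def test_closed_form(self, slope, intercept, n, expected):
        fit = fit_probit_from_percentages(DOSES, MORTALITY_24H, N_PER_GROUP)
        fit = type(fit)(
            slope=slope, intercept=intercept, r=1.0, r_squared=1.0, p_value=0.0,
            n_points=4, log_lc50=(5 - intercept) / slope,
            lc50=10 ** ((5 - intercept) / slope),
        )
        assert se_log_lc50(fit, n) == pytest.approx(expected)

    def test_24h_fit_value(self):
        fit = fit_probit_from_percentages(DOSES, MORTALITY_24H, N_PER_GROUP)
        # (log LC84 - log LC16)/sqrt(2n) = (2/slope)/sqrt(20)
        assert se_log_lc50(fit, 10) == pytest.approx(
            (2.0 / fit.slope) / math.sqrt(20.0)
        )
        assert se_log_lc50(fit, 10) == pytest.approx(0.1005, abs=5e-4)


class TestClarkson:
    @pytest.mark.parametrize(
        "value,category",
        [
            (951.04, "low"),
            (420.65, "medium"),
            (1000.0, "low"),
            (1000.01, "non-toxic"),
            (100.0, "high"),
            (100.5, "medium"),
            (500.0, "medium"),
            (50.0, "high"),
        ],
    )
    def test_categories_upper_inclusive(self, value, category):
        assert classify_clarkson(value) == category

    def test_rejects_non_positive(self):
        with pytest.raises(InvalidInputError):
            classify_clarkson(0.0)


class TestReplicateSummaries:
    def test_lc50_by_replicate_mean_sd(self):
        rng = np.random.default_rng(7)
        groups = []
        for rid in "ABC":
            for dose, p in zip(DOSES, (0.02, 0.2, 0.6, 0.98)):
                groups.append(
                    DoseGroup(dose, 10, int(rng.binomial(10, p)), 24.0, replicate_id=rid)
                )
        mean, sd, estimates = lc50_by_replicate(groups)
        assert len(estimates) == 3
        assert mean == pytest.approx(np.mean(estimates))
        assert sd == pytest.approx(np.std(estimates, ddof=1))

    def test_monotonicity_validation(self):
        ok = [
            DoseGroup(250, 10, 1, 24.0, replicate_id="A"),
            DoseGroup(250, 10, 3, 48.0, replicate_id="A"),
        ]
        validate_mortality_series(ok)
        bad = [
            DoseGroup(250, 10, 5, 24.0, replicate_id="A"),
            DoseGroup(250, 10, 2, 48.0, replicate_id="A"),
        ]
        with pytest.raises(EcotoxError, match="non-decreasing"):
            validate_mortality_series(bad)


class TestLinearResponse:
    def test_hemolysis_line_inversion(self):
        line = LinearResponseLine(slope=0.0067, intercept=0.414)
        assert invert_linear_response(line, 50.0) == pytest.approx(7400.9, abs=0.05)

    @pytest.mark.parametrize(
        "slope,intercept,level,expected",
        [(1.0, 0.0, 50.0, 50.0), (-0.5, 100.0, 50.0, 100.0)],
    )
    def test_identity_and_descending_lines(self, slope, intercept, level, expected):
        line = LinearResponseLine(slope=slope, intercept=intercept)
        assert invert_linear_response(line, level) == pytest.approx(expected)

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidInputError):
            invert_linear_response(LinearResponseLine(slope=0.0, intercept=1.0))

    def test_extrapolation_warned(self):
        line = fit_linear_response([125, 250, 500, 1000], [1.2, 2.1, 3.8, 7.1])
        with pytest.warns(ExtrapolationWarning):
            invert_linear_response(line, 50.0)

    def test_two_point_fit(self):
        line = fit_linear_response([0.0, 100.0], [0.0, 1.084])
        assert line.slope == pytest.approx(0.01084)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery_exact(self):
        conc = np.array([125.0, 250.0, 500.0, 1000.0])
        resp = 0.0067 * conc + 0.414
        line = fit_linear_response(conc, resp)
        assert line.slope == pytest.approx(0.0067, abs=1e-12)
        assert line.intercept == pytest.approx(0.414, abs=1e-10)
        assert line.r_squared == pytest.approx(1.0)

    @settings(deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_noisy_fit_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        conc = np.array([10.0, 50.0, 100.0, 250.0, 500.0])
        resp = -0.03 * conc + 104 + rng.normal(0, 2, size=conc.size)
        line = fit_linear_response(conc, resp)
        slope, intercept = _normal_equations(conc, resp)
        assert line.slope == pytest.approx(slope, rel=1e-10)
        assert line.intercept == pytest.approx(intercept, rel=1e-10)
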