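"""Tests for the statistical comparison layer: exact binomial CIs, trend
fits, Poisson rate ratios and the step-change decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from isflink import (
    assign_cohorts,
    binomial_ci,
    derive_all_isf,
    fit_linear_trend,
    fit_rate_ratios,
    make_fixture,
    step_change_report,
    stratified_proportions,
)


def exact_ci_by_tail_inversion(k, n, level=0.95):
    """Independent oracle: invert the binomial tail sums directly."""
    alpha = 1 - level
    low = 0.0 if k == 0 else brentq(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-13)
    high = 1.0 if k == n else brentq(
        lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-13)
    return low, high


class TestBinomialCi:
    def test_boundary_cases(self):
        assert binomial_ci(0, 10)[0] == 0.0
        assert binomial_ci(10, 10)[1] == 1.0

    @pytest.mark.parametrize("k, n", [(5, 10), (1, 30), (17, 20), (50, 200)])
    def test_matches_tail_sum_inversion(self, k, n):
        got = binomial_ci(k, n)
        want = exact_ci_by_tail_inversion(k, n)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_wilson_option_differs_but_brackets_estimate(self):
        low, high = binomial_ci(5, 10, method="wilson")
        assert low < 0.5 < high
        assert (low, high) != binomial_ci(5, 10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(1, 0)
        with pytest.raises(ValueError):
            binomial_ci(5, 3)


class TestStratifiedProportions:
    @pytest.fixture()
    def tiny_tables(self):
        cohorts = pd.DataFrame({
            "child_id": ["a", "b", "c", "d"],
            "birth_year": [2000.0, 2001.0, 2002.0, 2003.0],
            "in_A": [True, True, False, False],
            "in_B": [True, True, True, False],
            "in_C": [False, True, True, True],
            "venn_cell": ["AB", "ABC", "BC", "C-only"],
            "parental_composition": ["both", "both", "father_only", "neither"],
            "mns_child_pathway": [False] * 4,
            "included": [True] * 4,
        })
        persons = pd.DataFrame({
            "person_id": ["a", "b", "c", "d"],
            "role": ["child"] * 4,
            "birth_year": [2000.0, 2001.0, 2002.0, 2003.0],
            "irsd_quintile": pd.Series([1, 1, 5, np.nan], dtype=object),
            "remoteness": ["remote", "remote", "major_city", "major_city"],
            "indigenous_region": ["Broome"] * 4,
            "sex": ["female"] * 4,
        })
        return cohorts, persons

    def test_hand_computed_proportions(self, tiny_tables):
        cohorts, persons = tiny_tables
        out = stratified_proportions(cohorts, persons, variables=("irsd_quintile",))
        b = out[(out["cohort"] == "B") & (out["level"] == "1")].iloc[0]
        assert b["count"] == 2 and b["denominator"] == 3
        assert b["proportion"] == pytest.approx(2 / 3)
        assert b["ci_low"] <= b["proportion"] <= b["ci_high"]

    def test_levels_sum_to_one_including_missing(self, tiny_tables):
        cohorts, persons = tiny_tables
        out = stratified_proportions(cohorts, persons,
                                     variables=("irsd_quintile", "remoteness"))
        sums = out.groupby(["cohort", "variable"])["proportion"].sum()
        assert np.allclose(sums, 1.0)
        assert (out[out["cohort"] == "C"]["level"] == "missing").any()

    def test_unknown_variable_rejected(self, tiny_tables):
        cohorts, persons = tiny_tables
        with pytest.raises(KeyError, match="shoe_size"):
            stratified_proportions(cohorts, persons, variables=("shoe_size",))


class TestLinearTrend:
    def test_constant_counts_give_zero_slope(self):
        fit = fit_linear_trend({y: 100 for y in range(2000, 2014)})
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.slope_ci[0] <= 0 <= fit.slope_ci[1]

    def test_exact_line_recovered_with_zero_width_ci(self):
        counts = {y: 100 + 24 * (y - 2000) for y in range(2000, 2014)}
        fit = fit_linear_trend(counts)
        assert fit.slope == pytest.approx(24.0, abs=1e-8)
        assert fit.slope_ci[1] - fit.slope_ci[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exclude_years_drives_sensitivity_analysis(self):
        counts = {y: 100 + 10 * (y - 2000) for y in range(2000, 2014)}
        counts[2012] += 500
        counts[2013] += 500
        full = fit_linear_trend(counts)
        trimmed = fit_linear_trend(counts, exclude_years={2012, 2013})
        assert trimmed.slope == pytest.approx(10.0, abs=1e-8)
        assert full.slope > trimmed.slope
        assert trimmed.outliers_removed == (2012, 2013)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend({2000: 1, 2001: 2})


class TestRateRatios:
    def test_constant_proportion_gives_unit_ratios(self):
        counts = {y: 80 for y in range(2000, 2006)}
        totals = {y: 1000 for y in range(2000, 2006)}
        rr = fit_rate_ratios(counts, totals)
        assert np.allclose(rr["rate_ratio"], 1.0, atol=1e-8)

    def test_two_year_closed_form_to_1e9(self):
        counts = {2000: 30, 2001: 45}
        totals = {2000: 400, 2001: 500}
        rr = fit_rate_ratios(counts, totals).set_index("year")
        closed = (45 / 500) / (30 / 400)
        assert rr.loc[2001, "rate_ratio"] == pytest.approx(closed, abs=1e-9)
        assert rr.loc[2000, "rate_ratio"] == 1.0

    def test_reference_year_must_be_present_and_totals_positive(self):
        with pytest.raises(ValueError):
            fit_rate_ratios({2001: 5}, {2001: 10})
        with pytest.raises(ValueError):
            fit_rate_ratios({2000: 5, 2001: 5}, {2000: 0, 2001: 10})
        with pytest.raises(ValueError):
            fit_rate_ratios({2000: 50, 2001: 5}, {2000: 10, 2001: 10})


class TestStepChange:
    def test_fixture_attributes_exactly_the_2013_child(self):
        persons, links, records, _ = make_fixture("pre-post-2012")
        isf = derive_all_isf(records, persons)
        cohorts = assign_cohorts(persons, isf, links, records)
        report = step_change_report(cohorts).set_index("year")
        assert report.loc[2013, "n_attributed_mns_child_status"] == 1
        assert report.loc[2010, "n_attributed_mns_child_status"] == 0
        assert not report.loc[2010, "field_available"]

    def test_field_disabled_gives_zero_attribution(self):
        """With the midwives' child-status field never collected, no child can
        be identified through it."""
        import dataclasses

        from isflink import SimulationConfig, generate_population

        cfg = dataclasses.replace(
            SimulationConfig(n_families=800, seed=21), mns_child_status_from=2099)
        persons, links, records, _ = generate_population(cfg)
        isf = derive_all_isf(records, persons)
        cohorts = assign_cohorts(persons, isf, links, records)
        report = step_change_report(cohorts, mns_child_status_from=2099)
        assert (report["n_attributed_mns_child_status"] == 0).all()
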