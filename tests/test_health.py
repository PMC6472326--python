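"""Monte-Carlo lookup tables, polynomial evaluators, outcome accounting."""

import numpy as np
import pytest

from fiscalfood import (BiomarkerStrata, HealthCostParameters, PopulationState,
                        build_lookup_tables, evaluate_outcomes, fit_polynomials)
from fiscalfood.demography import N_AGE_BANDS
from fiscalfood.health import (LOCATIONS, LookupTableSet, RiskPolynomialSet,
                               SUPPORT_VALUES, _normalise)


@pytest.fixture(scope="module")
def dists(truth):
    return truth.biomarker_distributions


@pytest.fixture(scope="module")
def risks(truth):
    return truth.risk_functions


@pytest.fixture(scope="module")
def tables(dists, risks):
    return build_lookup_tables(dists, risks, n=10_000, seed=3)


@pytest.fixture(scope="module")
def polys(tables):
    return fit_polynomials(tables)


class TestLookupTables:
    def test_degenerate_sd_limit_matches_risk_function(self, dists, risks):
        """As the biomarker sd collapses, the table entry is the risk
        function evaluated at the support value."""
        tiny = type(dists)(dists.households, dists.locations, dists.mean,
                           np.full_like(dists.sd, 1e-9))
        tab = build_lookup_tables(tiny, risks, n=500, seed=0)
        for (d, a, g, li) in [(0, 10, 0, 0), (1, 12, 1, 1), (0, 5, 1, 0)]:
            expect = risks.incidence(d, a, g, li, SUPPORT_VALUES)
            assert np.max(np.abs(tab.incidence[d, a, g, li] - expect)) < 1e-6

    def test_monotone_risk_gives_monotone_table(self, tables):
        assert (np.diff(tables.incidence, axis=-1) >= -1e-12).all()
        assert (np.diff(tables.mortality, axis=-1) >= -1e-12).all()

    def test_reproducible_given_seed(self, dists, risks):
        a = build_lookup_tables(dists, risks, n=2000, seed=5)
        b = build_lookup_tables(dists, risks, n=2000, seed=5)
        assert np.array_equal(a.incidence, b.incidence)

    def test_sample_mean_within_monte_carlo_error_of_large_n(self, dists, risks):
        """n=10,000 entries agree with an n=10^6 brute-force oracle within
        four Monte-Carlo standard errors."""
        d, a, g, li, s = 0, 11, 0, 0, 5
        tab = build_lookup_tables(dists, risks, n=10_000, seed=7)
        rng = np.random.default_rng(12345)
        sd = dists.location_sd()[li, a, g]
        z = rng.standard_normal(1_000_000)
        vals = risks.incidence(d, a, g, li, SUPPORT_VALUES[s] + sd * z)
        oracle = vals.mean()
        se = vals.std() / np.sqrt(10_000)
        assert abs(tab.incidence[d, a, g, li, s] - oracle) < 4 * se

    def test_too_few_samples_rejected(self, dists, risks):
        with pytest.raises(ValueError):
            build_lookup_tables(dists, risks, n=10, seed=0)


class TestPolynomials:
    def test_constant_table_gives_constant_polynomial(self):
        shape = (2, N_AGE_BANDS, 2, len(LOCATIONS), 11)
        tab = LookupTableSet(SUPPORT_VALUES.copy(),
                             np.full(shape, 0.25), np.full(shape, 0.1))
        ps = fit_polynomials(tab)
        assert abs(ps.incidence_coef[0, 0, 0, 0, 0] - 0.25) < 1e-12
        assert np.max(np.abs(ps.incidence_coef[..., 1:])) < 1e-12

    def test_quadratic_table_reproduced_everywhere(self):
        """A table generated from a quadratic must be matched by the
        interpolant on the whole interval (closed-form oracle)."""
        f = lambda c: 0.01 + 0.002 * (c - 2.0) ** 2 / 25.0 * 20
        vals = f(SUPPORT_VALUES)
        shape = (2, N_AGE_BANDS, 2, len(LOCATIONS), 11)
        tab = LookupTableSet(SUPPORT_VALUES.copy(),
                             np.broadcast_to(vals, shape).copy(),
                             np.broadcast_to(vals, shape).copy())
        ps = fit_polynomials(tab)
        grid = np.linspace(2.0, 7.0, 301)
        got = ps.incidence(0, 0, 0, 0, grid)
        assert np.max(np.abs(got - f(grid))) < 1e-8

    def test_interpolant_exact_at_nodes(self, tables, polys):
        for (d, a, g, li) in [(0, 0, 0, 0), (1, 6, 1, 0), (0, 12, 0, 1)]:
            got = polys.incidence(d, a, g, li, SUPPORT_VALUES)
            assert np.max(np.abs(got - tables.incidence[d, a, g, li])) < 1e-10
            got_m = polys.mortality(d, a, g, li, SUPPORT_VALUES)
            assert np.max(np.abs(got_m - tables.mortality[d, a, g, li])) < 1e-10

    def test_duplicated_support_values_rejected(self, tables):
        sv = tables.support_values.copy()
        sv[1] = sv[0]
        bad = LookupTableSet(sv, tables.incidence, tables.mortality)
        with pytest.raises(ValueError):
            fit_polynomials(bad)

    def test_evaluations_clipped_to_unit_interval(self):
        coef = np.zeros((2, N_AGE_BANDS, 2, 2, 11))
        coef[..., 0] = 2.0                       # would exceed 1 unclipped
        ps = RiskPolynomialSet(coef, -coef)
        assert ps.incidence(0, 0, 0, 0, 4.0) == 1.0
        assert ps.mortality(0, 0, 0, 0, 4.0) == 0.0


def _tiny_pop(count, households=("x_rural",)):
    counts = np.zeros((len(households), N_AGE_BANDS, 2))
    counts[:, 11, 0] = count
    return PopulationState(list(households),
                           ["rural"] * len(households), counts,
                           np.zeros(N_AGE_BANDS), np.zeros((N_AGE_BANDS, 2)),
                           np.zeros(len(households)))


class TestOutcomes:
    def test_zero_population_gives_zero_outcomes(self, polys):
        pop = _tiny_pop(0.0)
        strata = BiomarkerStrata(["x_rural"], [[3.0, 4.0]], [[0.5, 0.5]])
        out = evaluate_outcomes(strata, polys, pop, HealthCostParameters())
        assert out.total_cases == 0.0
        assert out.total_deaths == 0.0
        assert out.hospital_cost.sum() == 0.0

    def test_upward_biomarker_shift_does_not_reduce_cases(self, polys):
        pop = _tiny_pop(1000.0)
        lo = BiomarkerStrata(["x_rural"], [[3.0, 4.0]], [[0.5, 0.5]])
        hi = BiomarkerStrata(["x_rural"], [[4.0, 5.0]], [[0.5, 0.5]])
        params = HealthCostParameters()
        out_lo = evaluate_outcomes(lo, polys, pop, params)
        out_hi = evaluate_outcomes(hi, polys, pop, params)
        assert out_hi.total_cases >= out_lo.total_cases

    def test_single_stratum_arithmetic(self, polys):
        """cases = frequency x population x rate, exactly."""
        pop = _tiny_pop(500.0)
        c = 4.3
        eps = 1e-9
        strata = BiomarkerStrata(["x_rural"], [[c, c + eps]], [[1.0, 0.0]])
        params = HealthCostParameters()
        out = evaluate_outcomes(strata, polys, pop, params)
        rate = polys.incidence(0, 11, 0, 0, np.array([c]))[0]
        assert abs(out.cases[0, 0, 11, 0] - 500.0 * rate) < 1e-9

    def test_deaths_capped_at_population(self, polys):
        coef = np.zeros_like(polys.mortality_coef)
        coef[..., 0] = 5.0                       # clipped to probability 1
        hot = RiskPolynomialSet(polys.incidence_coef, coef)
        pop = _tiny_pop(100.0)
        strata = BiomarkerStrata(["x_rural"], [[3.0, 4.0]], [[0.5, 0.5]])
        out = evaluate_outcomes(strata, hot, pop, HealthCostParameters())
        assert out.deaths.max() <= 100.0 + 1e-9

    def test_out_of_range_support_points_clamped_with_log(self, polys, caplog):
        pop = _tiny_pop(100.0)
        strata = BiomarkerStrata(["x_rural"], [[1.0, 9.0]], [[0.5, 0.5]])
        import logging
        with caplog.at_level(logging.WARNING, logger="fiscalfood.health"):
            evaluate_outcomes(strata, polys, pop, HealthCostParameters())
        assert any("clamped" in r.message for r in caplog.records)
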