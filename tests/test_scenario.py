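"""Scenario orchestration: targeting, decomposition, closures, reporting."""

import numpy as np
import pytest

from fiscalfood import (ScenarioConfig, find_tax_rate, report_indicators,
                        run_scenario, run_sensitivity, trajectory_frame)
from fiscalfood.scenario import palm_energy_per_capita


class TestZeroPolicy:
    def test_zero_tax_scenario_equals_baseline_bitwise(self, model):
        res = run_scenario(model, 0.0)
        for r, b in zip(res.records, model.baseline.records):
            assert np.array_equal(r.eq.QH, b.eq.QH)
            assert np.array_equal(r.eq.PQ, b.eq.PQ)
            assert np.array_equal(r.population.counts, b.population.counts)
            assert np.array_equal(r.outcomes.cases, b.outcomes.cases)

    def test_target_zero_returns_zero_tax(self, model):
        tau, _ = find_tax_rate(model, ScenarioConfig(target=0.0))
        assert tau == 0.0

    def test_small_tax_limit_is_continuous(self, model, policy):
        """Indicator deltas vanish continuously as the tax goes to zero."""
        tau, result, _ = policy
        tiny = run_scenario(model, 1e-6)
        for key in ("real_gdp_cum", "cases_total_cum", "ghg_cum_mt",
                    "delta_cholesterol_horizon"):
            big = abs(result.indicators[key])
            assert abs(tiny.indicators[key]) <= 1e-4 * big + 1e-9


class TestDeterminism:
    def test_same_config_twice_is_bit_identical(self, model):
        a = run_scenario(model, 0.8)
        b = run_scenario(model, 0.8)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.eq.x, rb.eq.x)
            assert np.array_equal(ra.outcomes.cases, rb.outcomes.cases)
        assert a.indicators == b.indicators


class TestClosures:
    def test_iso_household_real_holds_consumption_at_baseline(self, model):
        res = run_scenario(model, 0.8, closure_kind="iso_household_real")
        for r, b in zip(res.records, model.baseline.records):
            dev = np.abs(r.eq.QH.sum(axis=0) - b.eq.QH.sum(axis=0))
            assert dev.max() < 1e-6

    def test_iso_household_budget_holds_nominal_budgets(self, model):
        res = run_scenario(model, 0.8, closure_kind="iso_household_budget")
        for r, b in zip(res.records, model.baseline.records):
            assert np.max(np.abs(r.eq.EH - b.eq.EH)) < 1e-6 * b.eq.EH.max()


class TestReporting:
    def test_baseline_vs_baseline_report_is_zero(self, model):
        res = run_scenario(model, 0.0)
        tables = report_indicators(res, model)
        for name, frame in tables.items():
            vals = frame["value"].drop("sales_tax_rate_pct", errors="ignore")
            assert np.allclose(vals.astype(float), 0.0, atol=1e-9)

    def test_percent_columns_are_ratios_of_baseline(self, model, policy):
        _, result, _ = policy
        base_gdp_cum = sum(r.gdp_real for r in model.baseline.records)
        expect = 100.0 * result.indicators["real_gdp_cum"] / base_gdp_cum
        assert abs(result.indicators["real_gdp_cum_pct"] - expect) < 1e-10

    def test_cumulative_rows_are_period_sums(self, model, policy):
        _, result, _ = policy
        ledger = sum(float(r.eq.QH.sum()) - float(b.eq.QH.sum())
                     for r, b in zip(result.records, model.baseline.records))
        assert abs(result.indicators["private_consumption_cum"] - ledger) < 1e-9

    def test_trajectory_frame_shape(self, model):
        res = run_scenario(model, 0.0)
        df = trajectory_frame(res)
        assert len(df) == model.horizon
        assert {"year", "gdp_real", "cases_total"} <= set(df.columns)


class TestSensitivityMechanics:
    def test_degenerate_participation_grid_collapses_to_default(self, model,
                                                                decomposition):
        """A grid whose lower and upper bounds coincide with the default
        participation rate is a single run equal to the central one."""
        out = run_sensitivity(model, "participation",
                              grid=[0.72, 0.72], central=decomposition)
        assert len(out) == 1
        assert out[0]["error"] is None
        for key in ("real_gdp_cum", "cases_total_cum"):
            assert np.isclose(out[0]["indicators"][key],
                              decomposition.total[key], rtol=1e-9, atol=1e-9)

    def test_unknown_suite_rejected(self, model):
        from fiscalfood.errors import FiscalFoodError
        with pytest.raises(FiscalFoodError):
            run_sensitivity(model, "nonsense")

    def test_iso_consumption_suite_runs_all_closures(self, model, decomposition):
        out = run_sensitivity(model, "iso_consumption", central=decomposition)
        assert [o["point"] for o in out] == ["iso_household_budget",
                                            "iso_household_real",
                                            "iso_household_gov_real"]
        assert all(o["error"] is None for o in out)


class TestTaxSearchDiagnostics:
    def test_achieved_reduction_is_reported_consistently(self, model, policy):
        tau, result, _ = policy
        base = palm_energy_per_capita(model, model.baseline.records[-1])
        scen = palm_energy_per_capita(model, result.records[-1])
        assert np.isclose(result.indicators["palm_energy_reduction_pct"],
                          100.0 * (1.0 - scen / base), atol=1e-9)
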