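"""Within-period equilibrium and recursive dynamics."""

import numpy as np
import pytest

from fiscalfood import (ClosureSpec, DynamicState, EconomyConfig, FiscalFoodError,
                        PeriodExogenous, calibrate_economy, elasticities_to_aids,
                        estimate_aids, reconstruct_sam, solve_equilibrium,
                        step_dynamics)
from fiscalfood.demography import LabourSupply


@pytest.fixture(scope="module")
def params(truth):
    return calibrate_economy(truth)


class TestBenchmark:
    def test_zero_shock_reproduces_sam_flows(self, truth, params):
        eq = solve_equilibrium(params)
        rec = reconstruct_sam(params, eq)
        scale = truth.balanced_sam.values.max()
        diff = np.abs(rec.values - truth.balanced_sam.values) / scale
        assert diff.max() < 1e-8
        assert np.allclose(eq.PD, 1.0, atol=1e-9)
        assert abs(eq.CPI - 1.0) < 1e-12

    def test_benchmark_replicates_under_estimated_demand_system(self, truth,
                                                                noisy_bundle):
        """Calibration re-anchors the demand intercepts at observed base
        shares, so the benchmark replicates even with posterior parameters
        estimated from noisy priors."""
        _, _, priors = noisy_bundle
        prior = elasticities_to_aids(priors, np.exp(truth.aids_parameters.anchor))
        posterior = estimate_aids(prior)
        p2 = calibrate_economy(truth, aids=posterior)
        eq = solve_equilibrium(p2)
        rec = reconstruct_sam(p2, eq)
        scale = truth.balanced_sam.values.max()
        assert np.max(np.abs(rec.values - truth.balanced_sam.values)) / scale < 1e-8

    def test_nominal_homogeneity(self, params):
        """Doubling world prices and all nominal anchors leaves the real
        allocation unchanged and doubles domestic prices."""
        eq1 = solve_equilibrium(params)
        exo = PeriodExogenous(world_price_scale=2.0, nominal_anchor_scale=2.0)
        eq2 = solve_equilibrium(params, ClosureSpec(), exo)
        assert np.max(np.abs(eq2.QA / eq1.QA - 1.0)) < 1e-9
        assert np.max(np.abs(eq2.QH / eq1.QH - 1.0)) < 1e-9
        assert np.max(np.abs(eq2.PD / eq1.PD - 2.0)) < 1e-9


class TestPolicySolve:
    def test_palm_tax_raises_price_and_cuts_demand_everywhere(self, truth, params):
        dims = truth.dims
        pidx = dims.commodities.index(dims.palm_oil)
        eq0 = solve_equilibrium(params)
        ts = np.zeros(params.n)
        ts[pidx] = 0.5
        cl = ClosureSpec("iso_government", sales_tax=ts, qg_real=eq0.QG.copy(),
                         gov_sav_target=eq0.GOV_SAV)
        eq1 = solve_equilibrium(params, cl,
                                x0=np.append(eq0.x[:-1], 0.0))
        assert eq1.PQ[pidx] > eq0.PQ[pidx]
        # demand law: negative own-price elasticity in every household
        assert (eq1.QH[pidx] < eq0.QH[pidx]).all()
        # revenue recycled through lower direct-tax rates
        assert eq1.dtax_shift < 0

    def test_walras_residual_small_under_policy(self, truth, params):
        pidx = truth.dims.commodities.index(truth.dims.palm_oil)
        eq0 = solve_equilibrium(params)
        ts = np.zeros(params.n)
        ts[pidx] = 1.0
        cl = ClosureSpec("iso_government", sales_tax=ts, qg_real=eq0.QG.copy(),
                         gov_sav_target=eq0.GOV_SAV)
        eq1 = solve_equilibrium(params, cl, x0=np.append(eq0.x[:-1], 0.0))
        assert abs(eq1.walras_residual) < 1e-6 * eq1.gdp_nominal


class TestDynamics:
    def _labour(self, u=10.0, s=6.0):
        return LabourSupply(["h"], np.array([s]), np.array([u]),
                            np.full((13, 2), 0.7), 0.4)

    def test_full_depreciation_without_investment_is_error(self, model):
        eq = model.baseline.records[0].eq
        zero_inv = eq
        state = DynamicState(0, 100.0, 10.0, 6.0)
        # construct an equilibrium-like investment of zero via delta=1
        class _E:
            real_investment = 0.0
        with pytest.raises(FiscalFoodError):
            step_dynamics(state, _E(), self._labour(), depreciation=1.0)

    def test_steady_state_capital_constant(self):
        state = DynamicState(0, 200.0, 10.0, 6.0)

        class _E:
            real_investment = 0.05 * 200.0      # delta * K

        nxt = step_dynamics(state, _E(), self._labour(), depreciation=0.05)
        assert np.isclose(nxt.capital, 200.0)

    def test_labour_endowment_tracks_person_years(self):
        state = DynamicState(0, 200.0, 10.0, 6.0)

        class _E:
            real_investment = 20.0

        nxt = step_dynamics(state, _E(), self._labour(u=9.0, s=5.5),
                            depreciation=0.05)
        assert nxt.labour_unskilled == 9.0
        assert nxt.labour_skilled == 5.5


class TestBaselinePath:
    def test_growth_rates_hit_targets(self, model):
        g = np.array([r.gdp_real for r in model.baseline.records])
        gn = np.array([r.gdp_nominal for r in model.baseline.records])
        real_rates = g[1:] / g[:-1] - 1.0
        nom_rates = gn[1:] / gn[:-1] - 1.0
        assert np.max(np.abs(real_rates - 0.039)) < 1e-6
        assert np.max(np.abs(nom_rates - 0.062)) < 1e-6

    def test_baseline_is_reproducible(self, truth, model):
        from fiscalfood import build_model
        again = build_model(truth, seed=1)
        for a, b in zip(again.baseline.records, model.baseline.records):
            assert np.array_equal(a.eq.x, b.eq.x)
            assert a.tfp == b.tfp

    def test_income_expenditure_accounts_close(self, model):
        for r in model.baseline.records:
            audit = r.eq.institution_audit()
            assert max(audit.values()) < 1e-8
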