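"""Scenario orchestration: policy runs, tax targeting, pathway
decomposition, sensitivity suites and indicator reporting.

The policy experiment imposes a product-specific sales tax on the palm
cooking oil commodity, solved so that horizon-year per-capita energy intake
from palm oil falls by the configured fraction (default 50%) relative to the
counterfactual.  Each scenario period iterates the equilibrium with the
health feedbacks (cholesterol-driven outcomes, labour losses, hospital
costs, excess mortality) to a within-period fixed point, advances capital
and demography, and accumulates indicator ledgers.  The decomposition
re-runs the tax with the health feedback frozen (the biomarker change forced
to zero and no labour/population/cost feedback); the health pathway is the
per-indicator difference, additive by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (AIDSParameters, set_cross_price_elasticity,
                          set_income_elasticity, set_own_price_elasticity)
from .cge import (BaselineTrajectory, ClosureSpec, DynamicState, EconomyConfig,
                  PeriodExogenous, PeriodRecord, run_baseline, solve_equilibrium,
                  step_dynamics)
from .demography import derive_labour_supply, project_population
from .errors import ConvergenceError, FiscalFoodError
from .health import evaluate_outcomes
from .luc import LandAccount, land_allocation, luc_emissions
from .nutrition import (CholesterolCoefficients, delta_cholesterol,
                        intake_from_consumption, shift_strata)
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)

TAX_BRACKET = (0.0, 5.0)
TARGET_RTOL = 1e-3          # relative tolerance on the intake target


@dataclass
class ScenarioConfig:
    """Full specification of a policy run."""

    target: float = 0.50                      # fractional intake reduction
    closure: str = "iso_government"
    health_feedback: bool = True
    cholesterol: CholesterolCoefficients = field(default_factory=CholesterolCoefficients)
    tax_rate: float | None = None             # run at a fixed rate if given
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.target < 1.0):
            raise FiscalFoodError("intake-reduction target must lie in [0, 1)")


@dataclass
class Model:
    """Calibrated model bundle: truth, parameters and the solved baseline."""

    truth: SyntheticTruth
    econ_config: EconomyConfig
    baseline: BaselineTrajectory
    baseline_land: list[LandAccount]
    baseline_emissions: np.ndarray
    seed: int = 0

    @property
    def params(self):
        return self.baseline.params

    @property
    def polys(self):
        return self.baseline.polys

    @property
    def horizon(self) -> int:
        return len(self.baseline.records)


def _emissions_path(truth: SyntheticTruth, records) -> tuple[list[LandAccount], np.ndarray]:
    lands = [land_allocation(r.eq, truth.land_yields) for r in records]
    flow = np.zeros(len(records))
    for t in range(1, len(records)):
        flow[t] = luc_emissions(lands[t], lands[t - 1], truth.luc_matrix)
    return lands, flow


def build_model(truth: SyntheticTruth, econ_config: EconomyConfig | None = None,
                seed: int = 0, horizon: int | None = None,
                aids: AIDSParameters | None = None) -> Model:
    """Calibrate and solve the counterfactual baseline for a synthetic truth."""
    econ_config = econ_config or EconomyConfig()
    base = run_baseline(truth, econ_config, aids=aids, horizon=horizon, seed=seed)
    lands, flow = _emissions_path(truth, base.records)
    return Model(truth, econ_config, base, lands, flow, seed=seed)


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Trajectories, ledgers and baseline-relative indicators of one run."""

    label: str
    tax_rate: float
    closure: str
    health_feedback: bool
    records: list[PeriodRecord]
    land: list[LandAccount]
    emissions_flow: np.ndarray
    indicators: dict[str, float]


def _scenario_closure(kind: str, base_rec: PeriodRecord, ts: np.ndarray) -> ClosureSpec:
    eq = base_rec.eq
    if kind == "iso_government":
        return ClosureSpec(kind, sales_tax=ts, qg_real=eq.QG.copy(),
                           gov_sav_target=eq.GOV_SAV)
    if kind == "iso_household_budget":
        return ClosureSpec(kind, sales_tax=ts, gov_nominal=eq.GOV_CONS,
                           eh_target=eq.EH.copy())
    if kind == "iso_household_real":
        return ClosureSpec(kind, sales_tax=ts, gov_nominal=eq.GOV_CONS,
                           real_cons_target=eq.QH.sum(axis=0))
    if kind == "iso_household_gov_real":
        return ClosureSpec(kind, sales_tax=ts, qg_real=eq.QG.copy(),
                           real_cons_target=eq.QH.sum(axis=0))
    raise FiscalFoodError(f"unsupported scenario closure {kind!r}")


def _warm_start(base_rec: PeriodRecord, closure: ClosureSpec, n: int,
                prev: np.ndarray | None, extras_prev: np.ndarray | None,
                residual) -> np.ndarray:
    """Best of two warm starts: the baseline solution for this period (with
    carried-over closure extras) or the previous scenario period's solution.
    Choosing by initial residual keeps a zero-magnitude policy on the
    baseline's exact floating-point path."""
    extras = (extras_prev if extras_prev is not None
              and len(extras_prev) == closure.n_extra else np.zeros(closure.n_extra))
    cand = np.concatenate([base_rec.eq.x[:2 * n + 5], extras])
    if prev is None or len(prev) != len(cand):
        return cand
    return cand if np.max(np.abs(residual(cand))) <= np.max(np.abs(residual(prev))) \
        else prev


def run_scenario(model: Model, tax_rate: float, closure_kind: str = "iso_government",
                 health_feedback: bool = True,
                 cholesterol: CholesterolCoefficients | None = None,
                 label: str = "policy") -> ScenarioResult:
    """Run the full dynamic policy scenario at a given sales-tax rate."""
    truth, params, polys = model.truth, model.params, model.polys
    cfg = model.econ_config
    chol = cholesterol or CholesterolCoefficients()
    dims = truth.dims
    n, m = params.n, params.m
    pidx = dims.commodities.index(dims.palm_oil)
    ts = np.zeros(n)
    ts[pidx] = tax_rate
    T = model.horizon
    costs = truth.cost_parameters
    g_real = truth.growth_targets.real

    pop = truth.population.copy()
    state = DynamicState(0, params.capital_stock0, params.labour_anchor[0],
                         params.labour_anchor[1])
    records: list[PeriodRecord] = []
    x_prev: np.ndarray | None = None
    extras_prev: np.ndarray | None = None

    for t in range(T):
        br = model.baseline.records[t]
        closure = _scenario_closure(closure_kind, br, ts)
        rg = (1.0 + g_real) ** t
        pop_t = br.population if not health_feedback else pop
        cap_ratio = state.capital
        out_guess = br.outcomes
        dC_prev = np.zeros(m)
        lab_prev = 0.0
        strata_t = truth.strata
        intake = None
        eq = None

        sweeps = 1 if not health_feedback else cfg.feedback_max_sweeps
        for sweep in range(sweeps):
            if health_feedback:
                labour_t = derive_labour_supply(
                    pop_t, costs, patient_losses=out_guess.patient_worktime,
                    caregiver_losses=out_guess.caregiver_worktime)
            else:
                labour_t = br.labour
            endow = np.array([
                params.FS0[0] * float(labour_t.unskilled.sum()) / params.labour_anchor[0],
                params.FS0[1] * float(labour_t.skilled.sum()) / params.labour_anchor[1],
                params.FS0[2] * cap_ratio / params.capital_stock0,
                params.FS0[3]])
            hosp = (float(out_guess.hospital_cost.sum()) if health_feedback
                    else br.hospital_cost_real)
            hosp_by_hh = None
            if (cfg.health_payer == "households" and health_feedback
                    and out_guess.hospital_cost_by_hh is not None):
                hosp_by_hh = (out_guess.hospital_cost_by_hh
                              - br.outcomes.hospital_cost_by_hh)
            exo = PeriodExogenous(tfp=br.tfp, endowments=endow,
                                  transfers_real=params.TR0 * rg,
                                  fsav_real=params.FSAV0 * rg,
                                  hospital_cost_real=hosp,
                                  hospital_cost_base=br.hospital_cost_real,
                                  hospital_cost_by_household=hosp_by_hh)
            from .cge import _evaluate

            def _res(x):
                return _evaluate(params, closure, exo, x)[0]

            x0 = _warm_start(br, closure, n, x_prev, extras_prev, _res)
            eq = solve_equilibrium(params, closure, exo, x0=x0)
            x_prev = eq.x.copy()
            extras_prev = eq.x[2 * n + 5:].copy()
            intake = intake_from_consumption(eq.QH.T,
                                             truth.nutrient_coefficients,
                                             pop_t.household_totals())
            if not health_feedback:
                out_t = br.outcomes
                dC = np.zeros(m)
                break
            d_sfa = intake.sfa_share - br.intake.sfa_share
            d_mufa = intake.mufa_share - br.intake.mufa_share
            d_pufa = intake.pufa_share - br.intake.pufa_share
            dC = delta_cholesterol(d_sfa, d_mufa, d_pufa, chol)
            strata_t = shift_strata(truth.strata, dC)
            out_t = evaluate_outcomes(strata_t, polys, pop_t, costs,
                                      remaining_years=float(T - t))
            lab_now = float(labour_t.total)
            lab_change = abs(lab_now - lab_prev) if sweep > 0 else np.inf
            converged = (np.max(np.abs(dC - dC_prev)) < cfg.feedback_tol
                         and lab_change < cfg.feedback_tol * max(lab_now, 1.0))
            lab_prev = lab_now
            out_guess, dC_prev = out_t, dC
            if converged and sweep > 0:
                break
        else:
            if health_feedback:
                logger.warning("period %d: health feedback hit the sweep cap", t)

        records.append(PeriodRecord(
            br.year, eq, pop_t.copy(), labour_t, intake, out_t, strata_t,
            br.tfp, br.nominal_anchor, float(out_t.hospital_cost.sum()),
            eq.gdp_real, eq.gdp_nominal * br.nominal_anchor, delta_c=dC))
        if t < T - 1:
            if health_feedback:
                pop = project_population(pop, out_t.excess_deaths_by_cell())
            state = step_dynamics(state, eq, labour_t, cfg.depreciation)

    lands, em_flow = _emissions_path(truth, records)
    result = ScenarioResult(label, tax_rate, closure_kind, health_feedback,
                            records, lands, em_flow, {})
    result.indicators = compute_indicators(model, result)
    return result


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def palm_energy_per_capita(model_or_truth, record: PeriodRecord) -> float:
    """National per-capita daily energy intake from the palm-oil commodity."""
    truth = getattr(model_or_truth, "truth", model_or_truth)
    dims = truth.dims
    pidx = dims.commodities.index(dims.palm_oil)
    q = record.eq.QH[pidx]                      # (m,) real consumption
    dens = truth.nutrient_coefficients.energy_density[:, pidx]
    pop = record.population.household_totals()
    return float((q * dens).sum() / (pop.sum() * 365.0))


def _national_shares(truth: SyntheticTruth, record: PeriodRecord) -> tuple[float, float, float]:
    it = record.intake
    pop = record.population.household_totals()
    tot = float(it.total_energy @ pop)
    return (100.0 * float(it.sfa_energy @ pop) / tot,
            100.0 * float(it.mufa_energy @ pop) / tot,
            100.0 * float(it.pufa_energy @ pop) / tot)


def compute_indicators(model: Model, result: ScenarioResult) -> dict[str, float]:
    """Baseline-relative indicator ledger mirroring the standard report rows."""
    truth = model.truth
    base = model.baseline.records
    recs = result.records
    T = len(recs)
    ind: dict[str, float] = {"sales_tax_rate_pct": 100.0 * result.tax_rate}

    def cum(f):
        return float(sum(f(recs[t]) - f(base[t]) for t in range(T)))

    ind["real_gdp_cum"] = cum(lambda r: r.gdp_real)
    ind["private_consumption_cum"] = cum(lambda r: float(r.eq.QH.sum()))
    ind["government_consumption_cum"] = cum(lambda r: float(r.eq.QG.sum()))
    ind["investment_cum"] = cum(lambda r: r.eq.real_investment)
    ind["exports_cum"] = cum(lambda r: float(model.params.pwe @ r.eq.QE))
    ind["imports_cum"] = cum(lambda r: float(model.params.pwm @ r.eq.QM))
    base_gdp_cum = float(sum(r.gdp_real for r in base))
    ind["real_gdp_cum_pct"] = 100.0 * ind["real_gdp_cum"] / base_gdp_cum
    base_cons_cum = float(sum(r.eq.QH.sum() for r in base))
    ind["private_consumption_cum_pct"] = (100.0 * ind["private_consumption_cum"]
                                          / base_cons_cum)

    # per-household cumulative real consumption deltas
    for h, hh in enumerate(truth.dims.households):
        ind[f"consumption_cum__{hh}"] = float(
            sum(recs[t].eq.QH[:, h].sum() - base[t].eq.QH[:, h].sum()
                for t in range(T)))

    # nutrition (horizon year, percentage points and percent of base share)
    s_s, s_m, s_p = _national_shares(truth, recs[-1])
    b_s, b_m, b_p = _national_shares(truth, base[-1])
    ind["sfa_share_delta_pp"] = s_s - b_s
    ind["mufa_share_delta_pp"] = s_m - b_m
    ind["pufa_share_delta_pp"] = s_p - b_p
    ind["sfa_share_delta_pct"] = 100.0 * (s_s - b_s) / b_s
    ind["mufa_share_delta_pct"] = 100.0 * (s_m - b_m) / b_m
    ind["pufa_share_delta_pct"] = 100.0 * (s_p - b_p) / b_p
    ind["palm_energy_horizon"] = palm_energy_per_capita(model, recs[-1])
    ind["palm_energy_reduction_pct"] = 100.0 * (
        1.0 - ind["palm_energy_horizon"] / palm_energy_per_capita(model, base[-1]))

    # biomarker: horizon-year population-weighted mean change
    pw = base[-1].population.household_totals()
    ind["delta_cholesterol_horizon"] = float((recs[-1].delta_c @ pw) / pw.sum())
    base_ratio = float((truth.strata.mean() @ pw) / pw.sum())
    ind["delta_cholesterol_horizon_pct"] = (100.0 * ind["delta_cholesterol_horizon"]
                                            / base_ratio)

    # health (cumulative)
    for i, d in enumerate(("mi", "stroke")):
        ind[f"cases_{d}_cum"] = cum(lambda r, i=i: float(r.outcomes.cases[i].sum()))
        ind[f"deaths_{d}_cum"] = cum(lambda r, i=i: float(r.outcomes.deaths[i].sum()))
        ind[f"yld_{d}_cum"] = cum(lambda r, i=i: float(r.outcomes.yld[i]))
        ind[f"hospital_cost_{d}_cum"] = cum(
            lambda r, i=i: float(r.outcomes.hospital_cost[i]))
    ind["cases_total_cum"] = ind["cases_mi_cum"] + ind["cases_stroke_cum"]
    ind["deaths_total_cum"] = ind["deaths_mi_cum"] + ind["deaths_stroke_cum"]
    ind["patient_worktime_cum"] = cum(lambda r: float(r.outcomes.patient_worktime.sum()))
    ind["caregiver_worktime_cum"] = cum(lambda r: float(r.outcomes.caregiver_worktime.sum()))
    ind["caregiver_leisure_cum"] = cum(lambda r: float(r.outcomes.caregiver_leisure.sum()))
    ind["hospital_cost_cum"] = (ind["hospital_cost_mi_cum"]
                                + ind["hospital_cost_stroke_cum"])

    # demography and workforce (cumulative person-years)
    ind["population_person_years"] = cum(lambda r: r.population.national_total)
    ind["workforce_person_years"] = cum(lambda r: float(r.labour.total))

    # environment
    ind["ghg_cum_mt"] = float(result.emissions_flow.sum()
                              - model.baseline_emissions.sum())
    return ind


def report_indicators(result: ScenarioResult, model: Model) -> dict[str, pd.DataFrame]:
    """Indicator tables grouped as economic / nutrition-biomarker-health /
    demographic-environment, with absolute and percent-of-baseline columns."""
    ind = result.indicators
    econ_rows = ["real_gdp_cum", "private_consumption_cum", "government_consumption_cum",
                 "investment_cum", "exports_cum", "imports_cum", "sales_tax_rate_pct"]
    nut_rows = ["sfa_share_delta_pp", "mufa_share_delta_pp", "pufa_share_delta_pp",
                "delta_cholesterol_horizon", "cases_mi_cum", "cases_stroke_cum",
                "deaths_mi_cum", "deaths_stroke_cum", "yld_mi_cum", "yld_stroke_cum",
                "patient_worktime_cum", "caregiver_worktime_cum",
                "caregiver_leisure_cum", "hospital_cost_cum"]
    dem_rows = ["population_person_years", "workforce_person_years", "ghg_cum_mt"]
    pct_map = {"real_gdp_cum": "real_gdp_cum_pct",
               "private_consumption_cum": "private_consumption_cum_pct",
               "sfa_share_delta_pp": "sfa_share_delta_pct",
               "mufa_share_delta_pp": "mufa_share_delta_pct",
               "pufa_share_delta_pp": "pufa_share_delta_pct",
               "delta_cholesterol_horizon": "delta_cholesterol_horizon_pct"}

    def frame(rows):
        return pd.DataFrame({
            "value": [ind[r] for r in rows],
            "pct_of_baseline": [ind.get(pct_map.get(r, ""), np.nan) for r in rows],
        }, index=rows)

    return {"economic": frame(econ_rows), "nutrition_health": frame(nut_rows),
            "demographic_environment": frame(dem_rows)}


def trajectory_frame(result: ScenarioResult) -> pd.DataFrame:
    """Tidy period x variable trajectory table."""
    rows = []
    for r in result.records:
        rows.append({"year": r.year, "gdp_real": r.gdp_real,
                     "gdp_nominal": r.gdp_nominal,
                     "consumption_real": float(r.eq.QH.sum()),
                     "investment_real": r.eq.real_investment,
                     "government_real": float(r.eq.QG.sum()),
                     "population": r.population.national_total,
                     "labour_person_years": float(r.labour.total),
                     "cases_total": r.outcomes.total_cases,
                     "deaths_total": r.outcomes.total_deaths,
                     "mean_delta_cholesterol": float(np.mean(r.delta_c))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tax targeting
# ---------------------------------------------------------------------------

def find_tax_rate(model: Model, config: ScenarioConfig | None = None,
                  rtol: float = TARGET_RTOL) -> tuple[float, ScenarioResult]:
    """Sales-tax rate achieving the horizon-year intake-reduction target.

    Bisection on the bracket followed by secant refinement, on the full
    dynamic model; returns the rate and the converged scenario run.
    """
    config = config or ScenarioConfig()
    if config.target == 0.0:
        return 0.0, run_scenario(model, 0.0, config.closure,
                                 config.health_feedback, config.cholesterol)
    base_intake = palm_energy_per_capita(model, model.baseline.records[-1])
    goal = (1.0 - config.target) * base_intake
    trace: list[tuple[float, float]] = []

    def f(tau: float) -> tuple[float, ScenarioResult]:
        res = run_scenario(model, tau, config.closure, config.health_feedback,
                           config.cholesterol)
        val = palm_energy_per_capita(model, res.records[-1]) - goal
        trace.append((tau, val))
        logger.info("tax search: tau=%.4f, intake gap=%.3e", tau, val)
        return val, res

    a, b = TAX_BRACKET
    fa, _ = f(a)
    fb, _ = f(b)
    if abs(fa) <= rtol * goal:
        return a, run_scenario(model, a, config.closure, config.health_feedback,
                               config.cholesterol)
    if fa * fb > 0:
        raise ConvergenceError(
            "no sign change on the tax bracket; check that palm-oil demand "
            "is downward-sloping (own-price elasticity) at the horizon",
            residuals=trace)
    for it in range(50):
        if it < 6:
            mid = 0.5 * (a + b)                      # bisection phase
        else:
            mid = b - fb * (b - a) / (fb - fa)       # secant refinement
            if not (min(a, b) < mid < max(a, b)):
                mid = 0.5 * (a + b)
        fm, res_m = f(mid)
        if abs(fm) <= rtol * goal:
            return mid, res_m
        if fa * fm <= 0:
            b, fb = mid, fm
        else:
            a, fa = mid, fm
    raise ConvergenceError("tax-rate search did not converge", residuals=trace)


# ---------------------------------------------------------------------------
# Pathway decomposition
# ---------------------------------------------------------------------------

@dataclass
class PathwayDecomposition:
    """Total = sales-tax pathway + health pathway, per indicator."""

    tax_rate: float
    total: dict[str, float]
    tax_only: dict[str, float]
    health_pathway: dict[str, float]
    total_result: ScenarioResult
    tax_only_result: ScenarioResult


def decompose_pathways(model: Model, config: ScenarioConfig | None = None,
                       tax_rate: float | None = None,
                       total_result: ScenarioResult | None = None) -> PathwayDecomposition:
    """Split scenario impacts into the sales-tax and health pathways.

    The tax-only run freezes the health feedback (the biomarker change is
    forced to zero, with no labour, population or cost feedback); the health
    pathway is defined as total minus tax-only, so additivity is exact."""
    config = config or ScenarioConfig()
    if tax_rate is None:
        if config.tax_rate is not None:
            tax_rate = config.tax_rate
        else:
            tax_rate, total_result = find_tax_rate(model, config)
    if total_result is None:
        total_result = run_scenario(model, tax_rate, config.closure, True,
                                    config.cholesterol, label="total")
    tax_only = run_scenario(model, tax_rate, config.closure, False,
                            config.cholesterol, label="tax_only")
    health = {k: total_result.indicators[k] - tax_only.indicators[k]
              for k in total_result.indicators}
    return PathwayDecomposition(tax_rate, total_result.indicators,
                                tax_only.indicators, health,
                                total_result, tax_only)


# ---------------------------------------------------------------------------
# Sensitivity suites
# ---------------------------------------------------------------------------

SUITES = ("biomarker_bounds", "participation", "retirement", "own_price",
          "cross_price", "income", "iso_consumption")

DEFAULT_GRIDS = {
    "participation": [0.65, 0.70, 0.75, 0.80],
    "retirement": [59.0, 64.0, 69.0],
    "own_price": [-0.75, -0.85, -0.95, -1.05, -1.15],
    "cross_price": [0.00, 0.05, 0.10, 0.15, 0.20, 0.25],
    "income": [0.90, 1.00, 1.10, 1.20, 1.30],
}


def _model_variant(model: Model, truth: SyntheticTruth,
                   aids: AIDSParameters | None = None) -> Model:
    return build_model(truth, model.econ_config, seed=model.seed,
                       horizon=model.horizon, aids=aids)


def run_sensitivity(model: Model, suite: str,
                    config: ScenarioConfig | None = None,
                    grid: list | None = None,
                    central: PathwayDecomposition | None = None) -> list[dict]:
    """Run one of the sensitivity suites; failures at individual grid points
    are reported without aborting the rest of the grid."""
    if suite not in SUITES:
        raise FiscalFoodError(f"unknown sensitivity suite {suite!r}; "
                              f"choose from {SUITES}")
    config = config or ScenarioConfig()
    truth = model.truth
    dims = truth.dims
    pidx = dims.commodities.index(dims.palm_oil)
    oidx = dims.commodities.index(dims.other_oils)
    w0 = (model.params.C0 / model.params.EH0[None, :]).T
    if central is None:
        central = decompose_pathways(model, config)
    tau0 = central.tax_rate
    results: list[dict] = []

    def attempt(point, fn):
        try:
            results.append({"point": point, "error": None, **fn()})
        except Exception as err:       # report, keep going
            logger.warning("sensitivity point %r failed: %s", point, err)
            results.append({"point": point, "error": str(err)})

    if suite == "biomarker_bounds":
        variants = {
            "lower": config.cholesterol.at_bounds("lower"),
            "upper": config.cholesterol.at_bounds("upper"),
            "uniform": replace(config.cholesterol,
                               sfa=config.cholesterol.sfa_bounds[1],
                               mufa=config.cholesterol.mufa_bounds[0],
                               pufa=config.cholesterol.pufa_bounds[0]),
            "diverse": replace(config.cholesterol,
                               sfa=config.cholesterol.sfa_bounds[0],
                               mufa=config.cholesterol.mufa_bounds[1],
                               pufa=config.cholesterol.pufa_bounds[1]),
        }
        for name, coeffs in variants.items():
            def fn(coeffs=coeffs):
                total = run_scenario(model, tau0, config.closure, True, coeffs)
                health = {k: total.indicators[k] - central.tax_only[k]
                          for k in total.indicators}
                return {"tax_rate": tau0, "indicators": total.indicators,
                        "health_pathway": health}
            attempt(name, fn)
        return results

    if suite in ("participation", "retirement"):
        points = sorted(set(grid if grid is not None else DEFAULT_GRIDS[suite]))
        for point in points:
            def fn(point=point):
                key = ("participation" if suite == "participation"
                       else "retirement_age")
                costs = replace(truth.cost_parameters, **{key: point})
                truth2 = replace(truth, cost_parameters=costs)
                m2 = _model_variant(model, truth2)
                dec = decompose_pathways(m2, config, tax_rate=tau0)
                return {"tax_rate": tau0, "indicators": dec.total,
                        "health_pathway": dec.health_pathway}
            attempt(point, fn)
        return results

    if suite in ("own_price", "cross_price", "income"):
        points = grid if grid is not None else DEFAULT_GRIDS[suite]
        for point in points:
            def fn(point=point):
                if suite == "own_price":
                    aids2 = set_own_price_elasticity(truth.aids_parameters, w0,
                                                     pidx, point)
                elif suite == "cross_price":
                    aids2 = set_cross_price_elasticity(truth.aids_parameters, w0,
                                                       pidx, oidx, point)
                else:
                    aids2 = set_income_elasticity(truth.aids_parameters, w0,
                                                  pidx, point)
                m2 = _model_variant(model, truth, aids=aids2)
                tau, total = find_tax_rate(m2, config)
                dec = decompose_pathways(m2, config, tax_rate=tau,
                                         total_result=total)
                return {"tax_rate": tau, "indicators": dec.total,
                        "health_pathway": dec.health_pathway}
            attempt(point, fn)
        return results

    # iso-consumption closures: compensating non-distorting transfers
    for kind in ("iso_household_budget", "iso_household_real",
                 "iso_household_gov_real"):
        def fn(kind=kind):
            res = run_scenario(model, tau0, kind, True, config.cholesterol,
                               label=kind)
            return {"tax_rate": tau0, "indicators": res.indicators}
        attempt(kind, fn)
    return results
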