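"""Within-period general equilibrium and recursive dynamics.

The economy is a small open multi-household model with a neoclassical
closure: Leontief intermediates over CES value added (a skilled/unskilled
labour composite, capital and land), Armington CES substitution between
imports and domestic goods, CET transformation between exports and domestic
sales, fixed world prices with a flexible real exchange rate, AIDS private
demand per regional household, savings-driven investment, and the consumer
price index as numeraire.  All goods and factor markets clear by price; the
capital-market equation is omitted and its residual value (Walras's law)
is reported as a model-consistency diagnostic.

Dynamics are recursive: capital follows ``K(t+1) = (1-delta) K(t) + real
investment`` on a steady-state-consistent base stock, labour endowments
track the demographic working-age population corrected for participation,
the fixed skill split and health-related worktime losses, and per-period
Hicks-neutral productivity and nominal anchors are solved so the
counterfactual path reproduces the configured real and nominal GDP growth
rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import AIDSParameters, SAM
from .demography import LabourSupply, PopulationState, derive_labour_supply, project_population
from .errors import ConvergenceError, FiscalFoodError
from .health import (ClinicalOutcomes, HealthCostParameters, RiskPolynomialSet,
                     build_lookup_tables, evaluate_outcomes, fit_polynomials)
from .nutrition import BiomarkerStrata, NutrientIntake, intake_from_consumption
from .synthetic import FACTORS, ModelDimensions, SyntheticTruth

logger = logging.getLogger(__name__)

WALRAS_TOL = 1e-6          # relative to GDP
BENCHMARK_TOL = 1e-8
NEWTON_TOL = 1e-11
FEEDBACK_TOL = 1e-7
FEEDBACK_MAX_SWEEPS = 50


@dataclass
class EconomyConfig:
    """Behavioural elasticities, dynamics and solver settings."""

    sigma_armington: float = 2.0
    sigma_cet: float = 2.0
    sigma_va: float = 0.8
    sigma_labour: float = 1.5
    depreciation: float = 0.05
    lookup_samples: int = 10_000
    health_payer: str = "government"      # or "households"
    newton_tol: float = NEWTON_TOL
    newton_max_iter: int = 60
    feedback_tol: float = FEEDBACK_TOL
    feedback_max_sweeps: int = FEEDBACK_MAX_SWEEPS


@dataclass
class ClosureSpec:
    """Macro closure of a within-period solve.

    ``baseline`` keeps the government consumption-to-absorption ratio fixed;
    ``iso_government`` fixes real government consumption and government
    savings at the counterfactual path, recycling revenue through a uniform
    additive shift in household direct-tax rates; the iso-household variants
    hold household nominal budgets or real consumption at the counterfactual
    via non-distorting lump-sum transfers.
    """

    kind: str = "baseline"
    sales_tax: np.ndarray | None = None      # (n,) policy ad-valorem rates
    qg_real: np.ndarray | None = None        # (n,) fixed real gov consumption
    gov_sav_target: float | None = None
    gov_nominal: float | None = None         # fixed nominal gov budget
    eh_target: np.ndarray | None = None      # (m,) nominal budgets
    real_cons_target: np.ndarray | None = None  # (m,) base-price consumption

    KINDS = ("baseline", "iso_government", "iso_household_budget",
             "iso_household_real", "iso_household_gov_real")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise FiscalFoodError(f"unknown closure {self.kind!r}")

    @property
    def n_extra(self) -> int:
        if self.kind == "baseline":
            return 1                                # gov scale
        if self.kind == "iso_government":
            return 1                                # direct-tax shift
        # iso-household variants: one lump-sum transfer per household
        # (government savings stays endogenous; a simultaneous tax-rate
        # shift would be collinear with income-proportional transfers)
        return len(self.eh_target if self.eh_target is not None
                   else self.real_cons_target)


@dataclass
class PeriodExogenous:
    """Period-specific exogenous drivers of the within-period solve."""

    tfp: float = 1.0                 # Hicks-neutral productivity shifter
    endowments: np.ndarray | None = None   # (4,) factor service endowments
    transfers_real: np.ndarray | None = None
    fsav_real: float | None = None
    hospital_cost_real: float = 0.0  # current-period real hospital bill
    hospital_cost_base: float = 0.0  # period-1 counterfactual bill (anchor)
    world_price_scale: float = 1.0
    nominal_anchor_scale: float = 1.0
    hospital_cost_by_household: np.ndarray | None = None


@dataclass
class Equilibrium:
    """Solved within-period equilibrium (all prices at the CPI numeraire)."""

    dims: ModelDimensions
    x: np.ndarray                    # solver vector, for warm starts
    PD: np.ndarray
    PQS: np.ndarray
    PQ: np.ndarray
    PX: np.ndarray
    PM: np.ndarray
    PE: np.ndarray
    PVA: np.ndarray
    WF: np.ndarray
    EXR: float
    CPI: float
    QA: np.ndarray
    QQ: np.ndarray
    QD: np.ndarray
    QM: np.ndarray
    QE: np.ndarray
    QH: np.ndarray                   # (n, m)
    QG: np.ndarray
    QINV: np.ndarray
    FD: np.ndarray                   # (4, n) factor demands
    YH: np.ndarray
    EH: np.ndarray
    SH: np.ndarray
    DT: np.ndarray
    TR: np.ndarray
    LS: np.ndarray
    REV: float
    GOV_CONS: float
    GOV_SAV: float
    TOTSAV: float
    gdp_real: float
    gdp_nominal: float
    walras_residual: float
    sales_tax: np.ndarray
    dtax_shift: float
    investment_price: float
    real_exchange_rate: float

    @property
    def real_investment(self) -> float:
        return float(self.QINV.sum())

    @property
    def real_consumption_by_household(self) -> np.ndarray:
        """Household consumption valued at base-year (unit) prices."""
        return self.QH.sum(axis=0)

    def land_use_by_crop(self, crops: list[str]) -> np.ndarray:
        land = FACTORS.index("land")
        idx = [self.dims.commodities.index(c) for c in crops]
        return self.FD[land, idx]

    def institution_audit(self) -> dict[str, float]:
        """Income-minus-expenditure residual per institution, relative scale."""
        scale = max(self.gdp_nominal, 1.0)
        hh = self.YH - (self.EH + self.DT + self.SH)
        gov = self.REV - (self.GOV_CONS + self.TR.sum() + self.LS.sum()
                          + self.GOV_SAV + self._hospital_outlay)
        si = self.TOTSAV - float(self.PQ @ self.QINV)
        return {"households": float(np.max(np.abs(hh))) / scale,
                "government": abs(gov) / scale, "savings_investment": abs(si) / scale}

    _hospital_outlay: float = 0.0


@dataclass
class DynamicState:
    """Stock variables advanced between periods."""

    period: int
    capital: float                   # capital stock, real units
    labour_unskilled: float          # person-years
    labour_skilled: float
    cumulative_investment: float = 0.0

    def __post_init__(self):
        if self.capital <= 0:
            raise FiscalFoodError("capital stock must be strictly positive")
        if self.labour_unskilled < 0 or self.labour_skilled < 0:
            raise FiscalFoodError("labour endowments must be non-negative")


# ---------------------------------------------------------------------------
# Calibration from the balanced SAM
# ---------------------------------------------------------------------------

@dataclass
class EconomyParameters:
    """Benchmark-consistent model coefficients calibrated from a balanced SAM."""

    dims: ModelDimensions
    config: EconomyConfig
    aids: AIDSParameters
    # production
    QX0: np.ndarray
    ica: np.ndarray          # (n, n) intermediate coefficients
    vva: np.ndarray          # value-added quantity per unit output
    F0: np.ndarray           # (4, n) base factor payments
    QVA0: np.ndarray
    L0: np.ndarray           # labour composite per activity
    # trade
    D0: np.ndarray
    E0: np.ndarray
    M0: np.ndarray
    QQ0: np.ndarray
    tm: np.ndarray
    pwm: np.ndarray
    pwe: np.ndarray
    # institutions
    C0: np.ndarray           # (n, m)
    EH0: np.ndarray
    G0: np.ndarray
    INV0: np.ndarray
    mps: np.ndarray
    dtax0: np.ndarray
    phi: np.ndarray          # (4, m)
    TR0: np.ndarray
    FSAV0: float
    GS0: float
    GEXP0: float
    gov_abs_ratio: float
    w_cpi: np.ndarray
    FS0: np.ndarray          # (4,) base factor endowments
    capital_stock0: float = 0.0
    labour_anchor: tuple[float, float] = (1.0, 1.0)   # person-years at t=1
    hospital_base_real: float = 0.0

    @property
    def n(self) -> int:
        return len(self.dims.commodities)

    @property
    def m(self) -> int:
        return len(self.dims.households)


def calibrate_economy(truth: SyntheticTruth, config: EconomyConfig | None = None,
                      aids: AIDSParameters | None = None) -> EconomyParameters:
    """Extract benchmark-consistent coefficients from the balanced SAM."""
    config = config or EconomyConfig()
    dims = truth.dims
    sam = truth.balanced_sam.table
    n, m = dims.n_commodities, dims.n_households
    com = [f"com_{c}" for c in dims.commodities]
    act = [f"act_{c}" for c in dims.commodities]
    fac = [f"fac_{f}" for f in FACTORS]
    hh = [f"hh_{h}" for h in dims.households]

    QX0 = np.array([sam.loc[a, c] for a, c in zip(act, com)])
    INT0 = sam.loc[com, act].values
    ica = INT0 / QX0[None, :]
    F0 = sam.loc[fac, act].values
    QVA0 = F0.sum(axis=0)
    vva = QVA0 / QX0
    L0 = F0[0] + F0[1]

    E0 = sam.loc[com, "row"].values
    M_cif = sam.loc["row", com].values
    tariff0 = sam.loc["gov", com].values
    M0 = M_cif + tariff0
    with np.errstate(divide="ignore", invalid="ignore"):
        tm = np.where(M_cif > 0, tariff0 / M_cif, 0.0)
    pwm = 1.0 / (1.0 + tm)
    pwe = np.ones(n)
    C0 = sam.loc[com, hh].values
    G0 = sam.loc[com, "gov"].values
    INV0 = sam.loc[com, "sav"].values
    D0 = QX0 - E0
    QQ0 = D0 + M0

    EH0 = C0.sum(axis=0)
    SH0 = sam.loc["sav", hh].values
    DT0 = sam.loc["gov", hh].values
    FY0 = F0.sum(axis=1)
    phi = sam.loc[hh, fac].values.T / FY0[:, None]
    YH0 = sam.loc[hh].values.sum(axis=1)
    mps = SH0 / (YH0 - DT0)
    dtax0 = DT0 / YH0
    TR0 = sam.loc[hh, "gov"].values
    GS0 = sam.loc["sav", "gov"]
    FSAV0 = sam.loc["sav", "row"]
    GEXP0 = G0.sum()
    ABS0 = C0.sum() + G0.sum() + INV0.sum()
    w_cpi = C0.sum(axis=1) / C0.sum()
    FS0 = F0.sum(axis=1)

    aids = aids if aids is not None else truth.aids_parameters
    # anchor the demand system at the benchmark: intercepts equal observed
    # base budget shares (unit prices, base expenditure), preserving the
    # estimated price and expenditure responses and all regularity conditions
    w0 = (C0 / EH0[None, :]).T
    aids = AIDSParameters(aids.commodities, aids.households, w0,
                          aids.beta.copy(), aids.gamma.copy(), np.log(EH0))
    g_real = truth.growth_targets.real
    cap_stock0 = INV0.sum() / (g_real + config.depreciation)
    return EconomyParameters(dims, config, aids, QX0, ica, vva, F0, QVA0, L0,
                             D0, E0, M0, QQ0, tm, pwm, pwe, C0, EH0, G0, INV0,
                             mps, dtax0, phi, TR0, float(FSAV0), float(GS0),
                             GEXP0, GEXP0 / ABS0, w_cpi, FS0,
                             capital_stock0=cap_stock0)


# ---------------------------------------------------------------------------
# Within-period system
# ---------------------------------------------------------------------------

def _aids_shares_all(params: EconomyParameters, lnp: np.ndarray,
                     EH: np.ndarray) -> np.ndarray:
    """(m, n) budget shares at log consumer prices lnp and expenditures EH."""
    a = params.aids
    Gp = a.gamma @ lnp                           # (m, n)
    lnP = a.anchor + a.alpha @ lnp + 0.5 * (lnp @ a.gamma @ lnp)
    return a.alpha + Gp + a.beta * (np.log(EH) - lnP)[:, None]


def _evaluate(params: EconomyParameters, closure: ClosureSpec,
              exo: PeriodExogenous, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Residuals of the square equilibrium system plus the full solution."""
    p = params
    n, m = p.n, p.m
    cfg = p.config
    sA, sT, sV, sL = (cfg.sigma_armington, cfg.sigma_cet,
                      cfg.sigma_va, cfg.sigma_labour)
    QA = np.exp(x[:n])
    PD = np.exp(x[n:2 * n])
    WF = np.exp(x[2 * n:2 * n + 4])
    EXR = float(np.exp(x[2 * n + 4]))
    extra = x[2 * n + 5:]

    ts = closure.sales_tax if closure.sales_tax is not None else np.zeros(n)
    FS = exo.endowments if exo.endowments is not None else p.FS0
    TRr = exo.transfers_real if exo.transfers_real is not None else p.TR0
    FSAVr = exo.fsav_real if exo.fsav_real is not None else p.FSAV0
    wps = exo.world_price_scale
    A = exo.tfp

    dshift = 0.0
    LS = np.zeros(m)
    if closure.kind == "baseline":
        gscale = float(np.exp(extra[0]))
    elif closure.kind == "iso_government":
        dshift = float(extra[0])
    else:
        LS = extra[:m] * p.EH0          # transfers scaled by base budgets

    # -- price block --
    PE = p.pwe * wps * EXR
    PM = p.pwm * wps * (1.0 + p.tm) * EXR
    dx, ex = p.D0 / p.QX0, p.E0 / p.QX0
    PX = (dx * PD ** (1.0 + sT) + ex * PE ** (1.0 + sT)) ** (1.0 / (1.0 + sT))
    dq, mq = p.D0 / p.QQ0, p.M0 / p.QQ0
    PQS = (dq * PD ** (1.0 - sA) + mq * PM ** (1.0 - sA)) ** (1.0 / (1.0 - sA))
    PQ = PQS * (1.0 + ts)

    # -- government consumption under the chosen closure --
    if closure.kind == "baseline":
        QG = p.G0 * gscale
    elif closure.gov_nominal is not None:
        # nominal budget fixed at the counterfactual; real content adjusts
        QG = (p.G0 / p.G0.sum()) * closure.gov_nominal / PQ
    else:
        QG = closure.qg_real

    WU, WS, WK, WN = WF
    ush, ssh = p.F0[0] / np.maximum(L0 := p.L0, 1e-300), p.F0[1] / np.maximum(p.L0, 1e-300)
    PL = (ush * WU ** (1.0 - sL) + ssh * WS ** (1.0 - sL)) ** (1.0 / (1.0 - sL))
    lsh, ksh, nsh = p.L0 / p.QVA0, p.F0[2] / p.QVA0, p.F0[3] / p.QVA0
    cva = (lsh * PL ** (1.0 - sV) + ksh * WK ** (1.0 - sV)
           + nsh * WN ** (1.0 - sV)) ** (1.0 / (1.0 - sV))
    PVA = cva / A

    # -- production and factor demands --
    QVA = p.vva * QA
    QLc = (QVA / A) * lsh * (cva / PL) ** sV
    FDK = (QVA / A) * ksh * (cva / WK) ** sV
    FDN = (QVA / A) * nsh * (cva / WN) ** sV
    FDU = QLc * ush * (PL / WU) ** sL
    FDS = QLc * ssh * (PL / WS) ** sL
    FD = np.vstack([FDU, FDS, FDK, FDN])

    # -- trade flows --
    QX = QA
    QD_s = QX * dx * np.where(dx > 0, (PD / PX) ** sT, 0.0)
    QE = QX * ex * np.where(ex > 0, (PE / PX) ** sT, 0.0)

    # -- incomes --
    # the hospital-bill deviation from the counterfactual is spending on
    # domestically provided care: it accrues to households as provider
    # income (in proportion to factor income) and is paid either by the
    # government budget or by patient households
    hosp_delta = exo.hospital_cost_real - exo.hospital_cost_base
    fac_inc = WF * FS
    base_inc = p.phi.T @ fac_inc
    provider = hosp_delta * base_inc / base_inc.sum()
    YH = base_inc + TRr * exo.nominal_anchor_scale + LS + provider
    if cfg.health_payer == "households":
        patient = (exo.hospital_cost_by_household
                   if exo.hospital_cost_by_household is not None
                   else hosp_delta * base_inc / base_inc.sum())
        YH = YH - patient
    dtax = p.dtax0 + dshift
    DT = dtax * YH
    disp = YH - DT
    SH = p.mps * disp
    EH = disp - SH
    lnPQ = np.log(PQ)
    shares = _aids_shares_all(p, lnPQ, EH)
    QH = (shares * EH[:, None]).T / PQ[:, None]

    # -- demand, government and savings (tax base solved in closed form) --
    QINT = p.ica @ QA
    B = QINT + QH.sum(axis=1) + QG               # all but investment
    m_rate = mq * (PQS / PM) ** sA               # imports per unit composite
    gov_hosp = hosp_delta if cfg.health_payer == "government" else 0.0
    tax_per_unit = ts * PQS + p.tm * p.pwm * wps * EXR * m_rate
    rev_fixed = float(tax_per_unit @ B) + DT.sum()
    inv_val_shr = p.INV0 / p.INV0.sum()
    inv_q_per_sav = inv_val_shr / PQ             # quantities per unit savings
    rev_slope = float(tax_per_unit @ inv_q_per_sav)
    out_gov = float(PQ @ QG) + (TRr * exo.nominal_anchor_scale).sum() + LS.sum() + gov_hosp
    # TOTSAV = SH + (REV - out_gov) + EXR*FSAV with REV = rev_fixed + rev_slope*TOTSAV
    TOTSAV = (SH.sum() + rev_fixed - out_gov + EXR * FSAVr * exo.nominal_anchor_scale) \
        / (1.0 - rev_slope)
    QINV = inv_q_per_sav * TOTSAV
    QQ = B + QINV
    QM = QQ * m_rate
    QD_d = QQ * dq * (PQS / PD) ** sA
    REV = rev_fixed + rev_slope * TOTSAV
    GOV_CONS = float(PQ @ QG)
    GOV_SAV = REV - GOV_CONS - (TRr * exo.nominal_anchor_scale).sum() - LS.sum() - gov_hosp

    # -- residuals --
    res = np.empty(2 * n + 5 + closure.n_extra)
    res[:n] = (PX - (p.ica.T @ PQ + p.vva * PVA))            # zero profit
    res[n:2 * n] = (QD_s - QD_d) / p.D0                      # domestic market
    for k, f in enumerate((0, 1, 3)):                        # u, s, land
        res[2 * n + k] = (FD[f].sum() - FS[f]) / p.FS0[f]
    res[2 * n + 3] = p.w_cpi @ PQ - exo.nominal_anchor_scale  # CPI numeraire
    res[2 * n + 4] = (p.pwm * wps) @ QM - (p.pwe * wps) @ QE - FSAVr * exo.nominal_anchor_scale
    res[2 * n + 4] /= p.M0.sum()
    j = 2 * n + 5
    scale = max(p.GEXP0, 1.0)
    if closure.kind == "baseline":
        absorption = float(PQ @ (QH.sum(axis=1) + QG + QINV))
        res[j] = (GOV_CONS - p.gov_abs_ratio * absorption) / scale
    elif closure.kind == "iso_government":
        res[j] = (GOV_SAV - closure.gov_sav_target) / scale
    elif closure.kind == "iso_household_budget":
        res[j:j + m] = (EH - closure.eh_target) / p.EH0
    else:   # iso_household_real / iso_household_gov_real
        res[j:j + m] = (QH.sum(axis=0) - closure.real_cons_target) / p.EH0

    walras = WK * (FD[2].sum() - FS[2])
    gdp_real = float(QH.sum() + QG.sum() + QINV.sum()
                     + p.pwe @ QE - p.pwm @ QM)    # base market prices
    gdp_nom = float(PQ @ (QH.sum(axis=1) + QG + QINV)
                    + PE @ QE - (p.pwm * wps * EXR) @ QM)
    sol = {"QA": QA, "PD": PD, "WF": WF, "EXR": EXR, "PE": PE, "PM": PM,
           "PX": PX, "PQS": PQS, "PQ": PQ, "PVA": PVA, "FD": FD, "QD": QD_d,
           "QE": QE, "QM": QM, "QQ": QQ, "QH": QH, "QG": QG, "QINV": QINV,
           "YH": YH, "EH": EH, "SH": SH, "DT": DT, "TR": TRr * exo.nominal_anchor_scale,
           "LS": np.asarray(LS, float), "REV": REV, "GOV_CONS": GOV_CONS,
           "GOV_SAV": GOV_SAV, "TOTSAV": TOTSAV, "walras": walras,
           "gdp_real": gdp_real, "gdp_nominal": gdp_nom, "ts": ts,
           "dshift": dshift, "hosp_delta": gov_hosp}
    return res, sol


def _newton(fun, x0: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Damped Newton with finite-difference Jacobian.

    Returns the initial point untouched when it already satisfies the
    tolerance, so warm-started re-solves are bit-reproducible.
    """
    x = np.array(x0, dtype=float)
    f = fun(x)
    norm = np.max(np.abs(f))
    if norm <= tol:
        return x
    for _ in range(max_iter):
        J = np.empty((len(f), len(x)))
        h = 1e-7 * np.maximum(1.0, np.abs(x))
        for i in range(len(x)):
            xp = x.copy()
            xp[i] += h[i]
            J[:, i] = (fun(xp) - f) / h[i]
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -f, rcond=None)[0]
        smax = np.max(np.abs(dx))
        if smax > 2.0:
            dx *= 2.0 / smax                       # bounded step
        lam, f_new = 1.0, None
        while lam > 1e-8:
            cand = fun(x + lam * dx)
            if np.all(np.isfinite(cand)) and np.max(np.abs(cand)) < norm:
                f_new = cand
                break
            lam *= 0.5
        if f_new is None:
            raise ConvergenceError(
                f"equilibrium line search stalled (residual {norm:.2e})",
                residuals=f)
        x = x + lam * dx
        f = f_new
        norm = np.max(np.abs(f))
        if norm <= tol:
            return x
    raise ConvergenceError(f"equilibrium solver failed (residual {norm:.2e})",
                           residuals=f)


def benchmark_guess(params: EconomyParameters, closure: ClosureSpec) -> np.ndarray:
    n = params.n
    x = np.zeros(2 * n + 5 + closure.n_extra)
    x[:n] = np.log(params.QX0)
    return x


def solve_equilibrium(params: EconomyParameters,
                      closure: ClosureSpec | None = None,
                      exo: PeriodExogenous | None = None,
                      x0: np.ndarray | None = None) -> Equilibrium:
    """Solve the square within-period system by damped Newton iteration."""
    closure = closure or ClosureSpec()
    exo = exo or PeriodExogenous()
    if x0 is None:
        x0 = benchmark_guess(params, closure)

    def fun(x):
        return _evaluate(params, closure, exo, x)[0]

    try:
        x = _newton(fun, x0, params.config.newton_tol,
                    params.config.newton_max_iter)
    except ConvergenceError:
        # fall back to the trust-region hybrid solver on narrow valleys
        from scipy import optimize as _opt

        def safe_fun(x):
            with np.errstate(all="ignore"):
                f = fun(x)
            return np.where(np.isfinite(f), f, 1e6)

        sol_fb = _opt.root(safe_fun, x0, method="hybr",
                           options={"xtol": 1e-13, "maxfev": 20000})
        x = _newton(fun, sol_fb.x, params.config.newton_tol, 10)
    _, s = _evaluate(params, closure, exo, x)
    eq = Equilibrium(
        params.dims, x, s["PD"], s["PQS"], s["PQ"], s["PX"], s["PM"], s["PE"],
        s["PVA"], s["WF"], s["EXR"], float(params.w_cpi @ s["PQ"]), s["QA"],
        s["QQ"], s["QD"], s["QM"], s["QE"], s["QH"], s["QG"], s["QINV"], s["FD"],
        s["YH"], s["EH"], s["SH"], s["DT"], s["TR"], s["LS"], s["REV"],
        s["GOV_CONS"], s["GOV_SAV"], s["TOTSAV"], s["gdp_real"],
        s["gdp_nominal"], s["walras"], s["ts"], s["dshift"],
        investment_price=float((params.INV0 / params.INV0.sum()) @ s["PQ"]),
        real_exchange_rate=float(s["EXR"] / (params.w_cpi @ s["PQ"])))
    eq._hospital_outlay = s["hosp_delta"]
    if abs(eq.walras_residual) > WALRAS_TOL * max(eq.gdp_nominal, 1.0):
        raise ConvergenceError(
            f"Walras residual {eq.walras_residual:.3e} exceeds tolerance",
            residuals=eq.walras_residual)
    return eq


def reconstruct_sam(params: EconomyParameters, eq: Equilibrium) -> SAM:
    """Assemble the SAM implied by a solved equilibrium (benchmark audit)."""
    import pandas as pd
    from .synthetic import account_names
    dims = params.dims
    n, m = params.n, params.m
    names = account_names(dims)
    pos = {a: i for i, a in enumerate(names)}
    t = np.zeros((len(names), len(names)))
    com = [pos[f"com_{c}"] for c in dims.commodities]
    act = [pos[f"act_{c}"] for c in dims.commodities]
    fac = [pos[f"fac_{f}"] for f in FACTORS]
    hh = [pos[f"hh_{h}"] for h in dims.households]
    gov, sav, row = pos["gov"], pos["sav"], pos["row"]
    for c in range(n):
        for a in range(n):
            t[com[c], act[a]] = params.ica[c, a] * eq.QA[a] * eq.PQ[c]
        for h in range(m):
            t[com[c], hh[h]] = eq.PQ[c] * eq.QH[c, h]
        t[com[c], gov] = eq.PQ[c] * eq.QG[c]
        t[com[c], sav] = eq.PQ[c] * eq.QINV[c]
        t[com[c], row] = eq.PE[c] * eq.QE[c]
        t[act[c], com[c]] = eq.PX[c] * eq.QA[c]
        t[row, com[c]] = params.pwm[c] * eq.EXR * eq.QM[c]
        t[gov, com[c]] = (params.tm[c] * params.pwm[c] * eq.EXR * eq.QM[c]
                          + eq.sales_tax[c] * eq.PQS[c] * eq.QQ[c])
        for f in range(4):
            t[fac[f], act[c]] = eq.WF[f] * eq.FD[f, c]
    FS = eq.FD.sum(axis=1)
    for h in range(m):
        for f in range(4):
            t[hh[h], fac[f]] = params.phi[f, h] * eq.WF[f] * FS[f]
        t[gov, hh[h]] = eq.DT[h]
        t[sav, hh[h]] = eq.SH[h]
        t[hh[h], gov] = eq.TR[h] + eq.LS[h]
    t[sav, gov] = eq.GOV_SAV
    t[sav, row] = eq.TOTSAV - eq.SH.sum() - eq.GOV_SAV
    return SAM(pd.DataFrame(np.maximum(t, 0.0), index=names, columns=names))


# ---------------------------------------------------------------------------
# Recursive dynamics
# ---------------------------------------------------------------------------

def step_dynamics(state: DynamicState, eq: Equilibrium,
                  labour_next: LabourSupply,
                  depreciation: float) -> DynamicState:
    """Advance the stock variables one period.

    Capital follows the accumulation identity on the stock; next-period
    labour endowments come from the (health-corrected) demographic labour
    supply, so worktime losses reduce them one-for-one in person-years.
    """
    k_next = (1.0 - depreciation) * state.capital + eq.real_investment
    if k_next <= 0:
        raise FiscalFoodError("capital stock would become non-positive "
                              f"(depreciation {depreciation}, investment "
                              f"{eq.real_investment:.3f})")
    return DynamicState(state.period + 1, k_next,
                        float(labour_next.unskilled.sum()),
                        float(labour_next.skilled.sum()),
                        state.cumulative_investment + eq.real_investment)


@dataclass
class PeriodRecord:
    """Everything the scenario engine needs about one solved period."""

    year: int
    eq: Equilibrium
    population: PopulationState
    labour: LabourSupply
    intake: NutrientIntake
    outcomes: ClinicalOutcomes
    strata: BiomarkerStrata
    tfp: float
    nominal_anchor: float
    hospital_cost_real: float
    gdp_real: float
    gdp_nominal: float
    emissions_mt: float = 0.0
    delta_c: np.ndarray | None = None


@dataclass
class BaselineTrajectory:
    """Counterfactual growth path with calibrated shifters and ledgers."""

    params: EconomyParameters
    polys: RiskPolynomialSet
    records: list[PeriodRecord]
    states: list[DynamicState]

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.records]

    def record(self, t: int) -> PeriodRecord:
        return self.records[t]


def _endowments(params: EconomyParameters, state: DynamicState) -> np.ndarray:
    """Factor service endowments implied by the stocks (SAM units)."""
    anc_u, anc_s = params.labour_anchor
    return np.array([
        params.FS0[0] * state.labour_unskilled / anc_u,
        params.FS0[1] * state.labour_skilled / anc_s,
        params.FS0[2] * state.capital / params.capital_stock0,
        params.FS0[3],
    ])


def _household_consumption_matrix(eq: Equilibrium) -> np.ndarray:
    return eq.QH.T                       # (m, n) real consumption


def baseline_period_inputs(truth: SyntheticTruth, params: EconomyParameters,
                           polys: RiskPolynomialSet, pop: PopulationState,
                           horizon_left: float) -> tuple[ClinicalOutcomes, LabourSupply]:
    """Counterfactual health outcomes and labour supply for one period.

    Baseline biomarker strata are stationary, so outcomes depend only on the
    evolving population.
    """
    out = evaluate_outcomes(truth.strata, polys, pop, truth.cost_parameters,
                            remaining_years=horizon_left)
    labour = derive_labour_supply(pop, truth.cost_parameters,
                                  patient_losses=out.patient_worktime,
                                  caregiver_losses=out.caregiver_worktime)
    return out, labour


def run_baseline(truth: SyntheticTruth, config: EconomyConfig | None = None,
                 aids: AIDSParameters | None = None, horizon: int | None = None,
                 seed: int = 0) -> BaselineTrajectory:
    """Solve the counterfactual growth path.

    Per period, the Hicks-neutral productivity shifter is solved so real GDP
    grows at the configured real rate, and the nominal anchor (the CPI path)
    is set so nominal GDP grows at the nominal rate; both are exact to the
    solver tolerance.  Period 1 replicates the benchmark SAM.
    """
    config = config or EconomyConfig()
    params = calibrate_economy(truth, config, aids)
    dims = truth.dims
    years = dims.periods if horizon is None else dims.periods[:horizon]
    T = len(years)
    g_real, g_nom = truth.growth_targets.real, truth.growth_targets.nominal

    tables = build_lookup_tables(truth.biomarker_distributions,
                                 truth.risk_functions,
                                 n=config.lookup_samples, seed=seed)
    polys = fit_polynomials(tables)

    pop = truth.population.copy()
    out1, labour1 = baseline_period_inputs(truth, params, polys, pop, float(T))
    params.labour_anchor = (float(labour1.unskilled.sum()),
                            float(labour1.skilled.sum()))
    params.hospital_base_real = float(out1.hospital_cost.sum())

    state = DynamicState(0, params.capital_stock0,
                         float(labour1.unskilled.sum()),
                         float(labour1.skilled.sum()))
    records: list[PeriodRecord] = []
    states: list[DynamicState] = [state]
    x_warm = None
    gdp0 = None
    tfp = 1.0

    for t, year in enumerate(years):
        out_t, labour_t = (out1, labour1) if t == 0 else baseline_period_inputs(
            truth, params, polys, pop, float(T - t))
        rg = (1.0 + g_real) ** t
        # the counterfactual carries its own hospital bill inside the
        # calibrated government accounts, so its budget deviation is zero
        exo = PeriodExogenous(tfp=1.0 if t == 0 else tfp,
                              endowments=_endowments(params, state),
                              transfers_real=params.TR0 * rg,
                              fsav_real=params.FSAV0 * rg,
                              hospital_cost_real=float(out_t.hospital_cost.sum()),
                              hospital_cost_base=float(out_t.hospital_cost.sum()))
        closure = ClosureSpec("baseline")

        if t == 0:
            eq = solve_equilibrium(params, closure, exo, x0=x_warm)
            gdp0 = eq.gdp_real
            tfp_used = 1.0
        else:
            target = gdp0 * (1.0 + g_real) ** t
            eq, tfp = _solve_tfp(params, closure, exo, x_warm, target, tfp)
            tfp_used = tfp
        x_warm = eq.x.copy()

        nominal_target = gdp0 * (1.0 + g_nom) ** t
        anchor = nominal_target / eq.gdp_nominal

        intake = intake_from_consumption(_household_consumption_matrix(eq),
                                         truth.nutrient_coefficients,
                                         pop.household_totals())
        records.append(PeriodRecord(year, eq, pop.copy(), labour_t, intake,
                                    out_t, truth.strata, tfp_used, anchor,
                                    exo.hospital_cost_real, eq.gdp_real,
                                    eq.gdp_nominal * anchor,
                                    delta_c=np.zeros(params.m)))
        if t < T - 1:
            pop = project_population(pop, out_t.excess_deaths_by_cell())
            _, labour_next = baseline_period_inputs(truth, params, polys, pop,
                                                    float(T - t - 1))
            state = step_dynamics(state, eq, labour_next, config.depreciation)
            states.append(state)
    return BaselineTrajectory(params, polys, records, states)


def _solve_tfp(params, closure, exo, x_warm, target, tfp_guess):
    """Secant search on the productivity shifter for the real-GDP target."""
    tfp = tfp_guess * (1.0 + 0.0)
    exo1 = replace(exo, tfp=tfp)
    eq = solve_equilibrium(params, closure, exo1, x0=x_warm)
    f = eq.gdp_real - target
    if abs(f) <= 1e-9 * target:
        return eq, tfp
    tfp2 = tfp * (target / eq.gdp_real) ** 0.7
    for _ in range(40):
        exo2 = replace(exo, tfp=tfp2)
        eq2 = solve_equilibrium(params, closure, exo2, x0=eq.x)
        f2 = eq2.gdp_real - target
        if abs(f2) <= 1e-9 * target:
            return eq2, tfp2
        step = f2 * (tfp2 - tfp) / (f2 - f)
        tfp, f, eq = tfp2, f2, eq2
        tfp2 = tfp2 - step
    raise ConvergenceError(f"growth-path shifter failed for target {target:.4f}",
                           residuals=f2)
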