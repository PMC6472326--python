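"""Seeded synthetic calibration data with known ground truth.

The real study calibrated to national accounts, consumption surveys, a
health examination survey, official population projections and land-use
emission coefficients.  None of those datasets travel with the method, so
this module generates statistically structured stand-ins for every input:
a balanced social accounting matrix (SAM) built from a consistent circular-
flow fixed point, regular AIDS demand parameters per household, nutrient
energy coefficients, normal biomarker distributions with strata, logistic
risk functions, a cohort population with vital rates, a crop-conversion
emission matrix, unit health costs and growth targets.  Every generator is
deterministic given (dims, seed), and `generate_synthetic_economy` also
returns deliberately noised priors (an unbalanced SAM and irregular
elasticities) for calibration-recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (SAM, AIDSParameters, ElasticityPriors, aids_elasticities,
                          set_cross_price_elasticity, set_own_price_elasticity)
from .demography import AGE_BANDS, AGE_BAND_STARTS, N_AGE_BANDS, PopulationState
from .errors import DimensionError
from .health import (BiomarkerDistributionSet, HealthCostParameters, LOCATIONS,
                     RiskFunctionSet)
from .luc import LandYields, LUCMatrix
from .nutrition import BiomarkerStrata, NutrientCoefficientTable

FACTORS = ("labour_unskilled", "labour_skilled", "capital", "land")

DEFAULT_COMMODITIES = ["oil_palm_crop", "rice_crop", "maize_crop", "palm_oil",
                       "other_oils", "other_food", "fuel", "manufactures",
                       "services", "transport"]
DEFAULT_HOUSEHOLDS = ["south_rural", "south_urban", "central_rural", "central_urban"]


@dataclass
class ModelDimensions:
    """Index sets of the model; defaults are the desk-scale configuration."""

    commodities: list[str] = field(default_factory=lambda: list(DEFAULT_COMMODITIES))
    households: list[str] = field(default_factory=lambda: list(DEFAULT_HOUSEHOLDS))
    palm_oil: str = "palm_oil"
    other_oils: str = "other_oils"
    oil_palm_crop: str = "oil_palm_crop"
    crops: list[str] = field(default_factory=lambda: ["oil_palm_crop", "rice_crop",
                                                      "maize_crop"])
    periods: list[int] = field(default_factory=lambda: list(range(2016, 2036)))
    strata_count: int = 10
    factors: tuple = FACTORS
    age_bands: tuple = AGE_BANDS
    genders: tuple = ("male", "female")

    def __post_init__(self):
        if len(self.commodities) < 6:
            raise DimensionError("need at least 6 commodities")
        if len(self.households) < 2:
            raise DimensionError("need at least 2 households")
        if len(self.periods) < 2:
            raise DimensionError("need at least 2 periods")
        if self.strata_count < 2:
            raise DimensionError("need at least 2 biomarker strata")
        if len(self.age_bands) != N_AGE_BANDS:
            raise DimensionError("exactly 13 five-year age bands are required")
        for label in (self.palm_oil, self.other_oils, self.oil_palm_crop):
            if label not in self.commodities:
                raise DimensionError(f"designated commodity {label!r} missing")
        if self.oil_palm_crop not in self.crops:
            raise DimensionError("oil-palm crop must be listed among the primary crops")
        if len([c for c in self.crops if c != self.oil_palm_crop]) < 2:
            raise DimensionError("need at least 2 primary crops besides oil palm")
        if any(c not in self.commodities for c in self.crops):
            raise DimensionError("crops must be a subset of the commodity list")

    @property
    def locations(self) -> list[str]:
        """Location ('rural'/'urban') per household, from the label suffix."""
        return ["rural" if h.endswith("rural") else "urban" for h in self.households]

    @property
    def n_commodities(self) -> int:
        return len(self.commodities)

    @property
    def n_households(self) -> int:
        return len(self.households)

    @classmethod
    def desk_scale(cls) -> "ModelDimensions":
        return cls()

    @classmethod
    def paper_scale(cls) -> "ModelDimensions":
        """Full-size index sets: 49 commodities, 9 regional households."""
        extra = [f"commodity_{i:02d}" for i in range(len(DEFAULT_COMMODITIES) + 1, 50)]
        commodities = list(DEFAULT_COMMODITIES) + extra
        households = (["bangkok_urban"]
                      + [f"{r}_{loc}" for r in ("south", "central", "north", "northeast")
                         for loc in ("rural", "urban")])
        return cls(commodities=commodities, households=households)


@dataclass
class GrowthTargets:
    """Counterfactual per-annum GDP growth rates."""

    real: float = 0.039
    nominal: float = 0.062


@dataclass
class SyntheticTruth:
    """Ground-truth calibration inputs, all mutually consistent."""

    dims: ModelDimensions
    balanced_sam: SAM
    aids_parameters: AIDSParameters
    nutrient_coefficients: NutrientCoefficientTable
    biomarker_distributions: BiomarkerDistributionSet
    strata: BiomarkerStrata
    risk_functions: RiskFunctionSet
    population: PopulationState
    luc_matrix: LUCMatrix
    land_yields: LandYields
    cost_parameters: HealthCostParameters
    growth_targets: GrowthTargets


# ---------------------------------------------------------------------------
# commodity roles
# ---------------------------------------------------------------------------

def _commodity_roles(dims: ModelDimensions) -> dict[str, list[str]]:
    """Classify commodities into crops / oils / other food / non-food."""
    oils = [dims.palm_oil, dims.other_oils]
    crops = list(dims.crops)
    rest = [c for c in dims.commodities if c not in oils + crops]
    # a third of the residual commodities count as processed food
    n_food = max(1, len(rest) // 3)
    food = rest[:n_food]
    nonfood = rest[n_food:]
    return {"crops": crops, "oils": oils, "food": food, "nonfood": nonfood}


# ---------------------------------------------------------------------------
# SAM construction
# ---------------------------------------------------------------------------

def _jitter(rng, base, rel=0.15):
    return base * (1.0 + rel * (2.0 * rng.random(np.shape(base)) - 1.0))


def _build_flow_structure(dims: ModelDimensions, rng) -> dict:
    """Draw the behavioural coefficients that define the base-year economy."""
    n, m = dims.n_commodities, dims.n_households
    com = dims.commodities
    roles = _commodity_roles(dims)
    idx = {c: i for i, c in enumerate(com)}

    # -- intermediate input coefficients (columns = activities) --
    ica = np.zeros((n, n))
    for a, ca in enumerate(com):
        if ca == dims.palm_oil:
            ica[idx[dims.oil_palm_crop], a] = 0.45
        elif ca == dims.other_oils:
            other_crop = [c for c in roles["crops"] if c != dims.oil_palm_crop][-1]
            ica[idx[other_crop], a] = 0.30
        elif ca in roles["food"]:
            crop2 = [c for c in roles["crops"] if c != dims.oil_palm_crop]
            ica[idx[crop2[0]], a] = 0.22
            ica[idx[dims.palm_oil], a] = 0.03
            ica[idx[dims.other_oils], a] = 0.02
        # generic non-designated inputs from the non-food block
        pool = [c for c in roles["nonfood"] if c != ca] or [c for c in com if c != ca]
        picks = rng.choice(len(pool), size=min(3, len(pool)), replace=False)
        for p in picks:
            ica[idx[pool[p]], a] += 0.04 + 0.06 * rng.random()
    colsum = ica.sum(axis=0)
    over = colsum > 0.6
    ica[:, over] *= 0.6 / colsum[over]
    iva = 1.0 - ica.sum(axis=0)

    # -- factor shares of value added --
    fshare = np.zeros((len(FACTORS), n))
    for a, ca in enumerate(com):
        if ca in roles["crops"]:
            base = np.array([0.45, 0.10, 0.20, 0.25])
        else:
            base = np.array([0.35, 0.28, 0.37, 0.0])
        base = _jitter(rng, base, 0.1)
        fshare[:, a] = base / base.sum()

    # -- trade and tax structure --
    e_shr = np.full(n, 0.06)
    m_shr = np.full(n, 0.10)
    for i, c in enumerate(com):
        if c in roles["nonfood"]:
            e_shr[i], m_shr[i] = 0.20, 0.25
        if c == dims.palm_oil:
            e_shr[i], m_shr[i] = 0.12, 0.10
        if c == dims.other_oils:
            e_shr[i], m_shr[i] = 0.05, 0.22
    e_shr = np.clip(_jitter(rng, e_shr, 0.3), 0.01, 0.45)
    m_shr = np.clip(_jitter(rng, m_shr, 0.3), 0.02, 0.45)
    tm = np.zeros(n)
    tm[idx[dims.palm_oil]] = 0.05
    tm[idx[dims.other_oils]] = 0.05

    # -- household budget shares (AIDS intercepts at base) --
    w0 = np.zeros((m, n))
    for h, (hh, loc) in enumerate(zip(dims.households, dims.locations)):
        base = np.full(n, 0.02)
        rural = loc == "rural"
        base[idx[dims.palm_oil]] = 0.024 if rural else 0.016
        base[idx[dims.other_oils]] = 0.012
        base[idx[dims.oil_palm_crop]] = 0.003
        for c in roles["crops"]:
            if c != dims.oil_palm_crop:
                base[idx[c]] = 0.07 if rural else 0.045
        for c in roles["food"]:
            base[idx[c]] = 0.24 / max(1, len(roles["food"]))
        nf = roles["nonfood"]
        for c in nf:
            base[idx[c]] = (0.55 if not rural else 0.45) / max(1, len(nf))
        base = _jitter(rng, base, 0.12)
        w0[h] = base / base.sum()

    # -- institutions --
    mps = 0.12 + 0.06 * rng.random(m)
    dtax = 0.08 + 0.04 * rng.random(m)
    phi = np.zeros((len(FACTORS), m))          # factor income distribution
    rural_mask = np.array([loc == "rural" for loc in dims.locations], dtype=float)
    for f, fac in enumerate(FACTORS):
        base = np.ones(m)
        if fac == "land":
            base = 0.3 + 1.4 * rural_mask
        if fac == "labour_skilled":
            base = 1.4 - 0.8 * rural_mask
        base = _jitter(rng, base, 0.2)
        phi[f] = base / base.sum()

    gshare_c = np.zeros(n)
    gov_targets = roles["nonfood"][-2:] or com[-2:]
    for c in gov_targets:
        gshare_c[idx[c]] = 1.0
    gshare_c[idx[roles["food"][0]]] += 0.2
    gshare_c /= gshare_c.sum()
    inv_c = np.zeros(n)
    for c in roles["nonfood"]:
        inv_c[idx[c]] = 1.0
    inv_c = inv_c if inv_c.sum() > 0 else np.ones(n)
    inv_c /= inv_c.sum()

    return {"ica": ica, "iva": iva, "fshare": fshare, "e_shr": e_shr,
            "m_shr": m_shr, "tm": tm, "w0": w0, "mps": mps, "dtax": dtax,
            "phi": phi, "gshare_c": gshare_c, "inv_c": inv_c,
            "tr_share": 0.20, "gcons_share": 0.60, "roles": roles}


def _solve_circular_flow(dims: ModelDimensions, s: dict, rng) -> dict:
    """Fixed point of the base-year circular flow at unit prices."""
    n, m = dims.n_commodities, dims.n_households
    for attempt in range(6):
        QX = np.full(n, 100.0)
        M = np.zeros(n)
        E = s["e_shr"] * QX
        for _ in range(4000):
            INT = s["ica"] @ QX
            VA = s["iva"] * QX
            F = s["fshare"] * VA[None, :]
            FY = F.sum(axis=1)
            HY = s["phi"].T @ FY
            tariff = (M * s["tm"] / (1.0 + s["tm"])).sum()
            DT = s["dtax"] * HY
            REV = tariff + DT.sum()
            TR = s["tr_share"] * REV * np.ones(m) / m
            G_val = s["gcons_share"] * REV
            GS = REV - TR.sum() - G_val
            disp = HY + TR - DT
            SH = s["mps"] * disp
            EH = disp - SH
            C = s["w0"].T * EH[None, :]
            FSAV = (M / (1.0 + s["tm"])).sum() - E.sum()
            TOTSAV = SH.sum() + GS + FSAV
            G_c = s["gshare_c"] * G_val
            INV = s["inv_c"] * TOTSAV
            QQ = INT + C.sum(axis=1) + G_c + INV
            M_new = s["m_shr"] * QQ
            D = QQ - M_new
            QX_new = D / (1.0 - s["e_shr"])
            E_new = s["e_shr"] * QX_new
            if max(np.max(np.abs(QX_new - QX)), np.max(np.abs(M_new - M))) < 1e-12:
                QX, M, E = QX_new, M_new, E_new
                break
            QX, M, E = QX_new, M_new, E_new
        gdp = VA.sum()
        if FSAV > 0.002 * gdp and TOTSAV > 0.02 * gdp and (INV >= 0).all():
            break
        s["e_shr"] = s["e_shr"] * 0.7      # deterministic feasibility adjustment
    flows = {"QX": QX, "INT": s["ica"] @ QX, "VA": s["iva"] * QX,
             "F": s["fshare"] * (s["iva"] * QX)[None, :], "E": E, "M": M,
             "C": C, "G_c": G_c, "INV": INV, "TR": TR, "DT": DT, "SH": SH,
             "GS": GS, "FSAV": FSAV, "EH": EH, "HY": HY, "QQ": QQ, "D": D,
             "tariff_c": M * s["tm"] / (1.0 + s["tm"]), "REV": REV, "gdp": gdp}
    return flows


def account_names(dims: ModelDimensions) -> list[str]:
    return ([f"com_{c}" for c in dims.commodities]
            + [f"act_{c}" for c in dims.commodities]
            + [f"fac_{f}" for f in FACTORS]
            + [f"hh_{h}" for h in dims.households]
            + ["gov", "sav", "row"])


def _assemble_sam(dims: ModelDimensions, s: dict, fl: dict) -> SAM:
    n, m = dims.n_commodities, dims.n_households
    names = account_names(dims)
    N = len(names)
    pos = {a: i for i, a in enumerate(names)}
    t = np.zeros((N, N))
    com = [pos[f"com_{c}"] for c in dims.commodities]
    act = [pos[f"act_{c}"] for c in dims.commodities]
    fac = [pos[f"fac_{f}"] for f in FACTORS]
    hh = [pos[f"hh_{h}"] for h in dims.households]
    gov, sav, row = pos["gov"], pos["sav"], pos["row"]

    for c in range(n):
        for a in range(n):
            t[com[c], act[a]] = s["ica"][c, a] * fl["QX"][a]
        for h in range(m):
            t[com[c], hh[h]] = fl["C"][c, h]
        t[com[c], gov] = fl["G_c"][c]
        t[com[c], sav] = fl["INV"][c]
        t[com[c], row] = fl["E"][c]
        t[act[c], com[c]] = fl["QX"][c]
        t[row, com[c]] = fl["M"][c] / (1.0 + s["tm"][c])
        t[gov, com[c]] = fl["tariff_c"][c]
        for f in range(len(FACTORS)):
            t[fac[f], act[c]] = fl["F"][f, c]
    FY = fl["F"].sum(axis=1)
    for h in range(m):
        for f in range(len(FACTORS)):
            t[hh[h], fac[f]] = s["phi"][f, h] * FY[f]
        t[gov, hh[h]] = fl["DT"][h]
        t[sav, hh[h]] = fl["SH"][h]
        t[hh[h], gov] = fl["TR"][h]
    t[sav, gov] = fl["GS"]
    t[sav, row] = fl["FSAV"]
    t[np.abs(t) < 1e-13] = 0.0
    sam = SAM(pd.DataFrame(t, index=names, columns=names))
    assert sam.max_imbalance() < 1e-9, "internal error: synthetic SAM unbalanced"
    return sam


# ---------------------------------------------------------------------------
# AIDS truth
# ---------------------------------------------------------------------------

def _generate_aids_truth(dims: ModelDimensions, w0: np.ndarray,
                         EH0: np.ndarray, rng) -> AIDSParameters:
    n, m = dims.n_commodities, dims.n_households
    pidx = dims.commodities.index(dims.palm_oil)
    alpha = w0.copy()
    eta = 0.85 + 0.45 * rng.random((m, n))
    eta[:, pidx] = 1.13
    eta += (1.0 - (w0 * eta).sum(axis=1))[:, None]        # Engel aggregation
    beta = w0 * (eta - 1.0)
    gamma = np.empty((m, n, n))
    for h in range(m):
        u = rng.random((n, n))
        S = 0.5 * (u + u.T) * np.outer(w0[h], w0[h]) * 0.5
        S = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
        # keep implied own-price elasticities strictly negative and moderate
        cap = 0.25 * w0[h]
        scale = min(1.0, float(np.min(cap / np.maximum(np.abs(np.diag(S)), 1e-12))))
        gamma[h] = S * scale
    params = AIDSParameters(list(dims.commodities), list(dims.households),
                            alpha, beta, gamma, np.log(EH0))
    # anchor the designated substitution structure: elastic palm-oil demand
    # and positive substitution toward the polyunsaturate-dense oils
    oidx = dims.commodities.index(dims.other_oils)
    params = set_cross_price_elasticity(params, w0, oidx, pidx,
                                        OILS_CROSS_PRICE_ELASTICITY)
    params = set_own_price_elasticity(params, w0, pidx,
                                      PALM_OWN_PRICE_ELASTICITY)
    assert params.is_regular(1e-10)
    return params


# ---------------------------------------------------------------------------
# Nutrition, biomarker and risk inputs
# ---------------------------------------------------------------------------

# Relative energy densities (kcal per currency unit before rescaling) and
# fatty-acid energy fractions.  Palm cooking oil is palmitic-acid dense (the
# highest SFA fraction among the edible oils); the competing edible oils are
# polyunsaturate-dense (soybean-oil-like); the processed-food composite
# reflects a fish- and vegetable-oil-containing diet.  Palm oil ends up
# around 4% of total dietary energy, in line with it supplying roughly
# three-quarters of edible-oil energy in a diet where oils contribute a few
# percent of calories.
_BASE_DENSITY = {"palm_oil": 2.8, "other_oils": 8.0, "crop": 5.5, "food": 3.0}
_FAT_FRACTIONS = {
    "palm_oil": (0.49, 0.37, 0.10),
    "other_oils": (0.13, 0.27, 0.58),
    "crop": (0.015, 0.010, 0.010),
    "food": (0.07, 0.09, 0.11),
}
TARGET_KCAL_PER_DAY = 2000.0
#: Truth demand-system anchors: palm-oil own-price elasticity and the
#: cross-price elasticity of other edible oils with respect to the palm-oil
#: price.  The substitution toward polyunsaturate-dense oils is the pivotal
#: mechanism of the health pathway.
PALM_OWN_PRICE_ELASTICITY = -0.95
OILS_CROSS_PRICE_ELASTICITY = 0.20


def _generate_nutrients(dims: ModelDimensions, C0: np.ndarray,
                        pop_h: np.ndarray, rng) -> NutrientCoefficientTable:
    n, m = dims.n_commodities, dims.n_households
    roles = _commodity_roles(dims)
    density = np.zeros((m, n))
    sfa = np.zeros((m, n)); mufa = np.zeros((m, n)); pufa = np.zeros((m, n))
    for i, c in enumerate(dims.commodities):
        if c == dims.palm_oil:
            key = "palm_oil"
        elif c == dims.other_oils:
            key = "other_oils"
        elif c in roles["crops"] and c != dims.oil_palm_crop:
            key = "crop"
        elif c in roles["food"]:
            key = "food"
        else:
            continue   # oil-palm fruit and non-food: no direct dietary energy
        density[:, i] = _jitter(rng, np.full(m, _BASE_DENSITY[key]), 0.10)
        fr = _FAT_FRACTIONS[key]
        sfa[:, i] = _jitter(rng, np.full(m, fr[0]), 0.05)
        mufa[:, i] = _jitter(rng, np.full(m, fr[1]), 0.05)
        pufa[:, i] = _jitter(rng, np.full(m, fr[2]), 0.05)
    total_fr = sfa + mufa + pufa
    over = total_fr > 0.98
    for arr in (sfa, mufa, pufa):
        arr[over] *= 0.98 / total_fr[over]
    # scale densities so base diets hit the energy target per capita per day
    raw = (C0.T * density).sum(axis=1) / (pop_h * 365.0)
    density *= (TARGET_KCAL_PER_DAY / raw)[:, None]
    return NutrientCoefficientTable(list(dims.commodities), list(dims.households),
                                    density, sfa, mufa, pufa)


def _generate_biomarkers(dims: ModelDimensions, pop: PopulationState,
                         rng) -> tuple[BiomarkerDistributionSet, BiomarkerStrata]:
    m = dims.n_households
    age_idx = np.arange(N_AGE_BANDS)
    hh_off = 0.4 * (rng.random(m) - 0.5)
    mean = (3.2 + 0.9 * (age_idx / 12.0))[None, :, None] \
        + np.array([0.15, 0.0])[None, None, :] + hh_off[:, None, None]
    mean = np.clip(mean, 2.2, 6.0)
    sd = np.clip(0.7 + 0.2 * (rng.random((m, N_AGE_BANDS, 2)) - 0.5), 0.3, 1.2)
    dists = BiomarkerDistributionSet(list(dims.households), list(dims.locations),
                                     mean, sd)
    # household strata: decile mid-quantiles of the pooled normal
    wts = pop.counts / pop.counts.sum(axis=(1, 2), keepdims=True)
    mu_h = (mean * wts).sum(axis=(1, 2))
    sd_h = (sd * wts).sum(axis=(1, 2))
    S = dims.strata_count
    z = stats.norm.ppf((np.arange(S) + 0.5) / S)
    support = mu_h[:, None] + sd_h[:, None] * z[None, :]
    freq = np.full((m, S), 1.0 / S)
    return dists, BiomarkerStrata(list(dims.households), support, freq)


def _generate_risks(dims: ModelDimensions, rng) -> RiskFunctionSet:
    nd, nl = 2, len(LOCATIONS)
    a = np.arange(N_AGE_BANDS, dtype=float)
    base = 2.0e-5 * np.exp(0.55 * a)               # rises steeply with age
    scale = np.zeros((nd, N_AGE_BANDS, 2, nl))
    for d, dscale in enumerate((1.0, 0.45)):        # MI, stroke
        for g, gscale in enumerate((1.3, 1.0)):     # male, female
            for li, lscale in enumerate((1.0, 1.1)):
                scale[d, :, g, li] = np.clip(base * dscale * gscale * lscale, 0.0, 0.9)
    scale = np.clip(_jitter(rng, scale, 0.10), 0.0, 0.95)
    slope = np.clip(_jitter(rng, np.full_like(scale, 1.2), 0.10), 0.5, 3.0)
    mid = np.clip(_jitter(rng, 5.5 - 0.05 * a[None, :, None, None]
                          * np.ones_like(scale), 0.05), 3.0, 6.5)
    mort_scale = np.clip(scale * 0.5, 0.0, 0.95)
    return RiskFunctionSet(scale, slope, mid, mort_scale, slope.copy(), mid.copy())


def _expected_base_cases(dims, strata, risks, pop) -> np.ndarray:
    """Expected annual incident cases per disease at baseline strata."""
    cases = np.zeros(2)
    loc_index = [LOCATIONS.index(l) for l in dims.locations]
    for h in range(dims.n_households):
        li = loc_index[h]
        for d in range(2):
            for a in range(N_AGE_BANDS):
                for g in range(2):
                    r = risks.incidence(d, a, g, li, strata.support[h])
                    cases[d] += pop.counts[h, a, g] * float(strata.frequency[h] @ r)
    return cases


def _generate_costs(dims, strata, risks, pop, gdp: float) -> HealthCostParameters:
    cases = np.maximum(_expected_base_cases(dims, strata, risks, pop), 1e-9)
    hosp_budget = 0.0030 * gdp                      # annual formal hospital bill
    return HealthCostParameters(
        hospital_unit_cost={"mi": 0.6 * hosp_budget / cases[0],
                            "stroke": 0.4 * hosp_budget / cases[1]})


# ---------------------------------------------------------------------------
# Population and land
# ---------------------------------------------------------------------------

def generate_population(dims: ModelDimensions, seed: int) -> PopulationState:
    """Synthetic cohort population with plausible vital-rate schedules.

    Counts are strictly positive; mortality rises with age (non-decreasing
    across the oldest bands by construction) and fertility is concentrated in
    the female reproductive bands.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    m = dims.n_households
    mids = AGE_BAND_STARTS + 2.5
    age_w = np.exp(-0.018 * (mids - 10.0))
    age_w /= age_w.sum()
    base_pop = 2.0e6 * (0.7 + 0.6 * rng.random(m))
    counts = base_pop[:, None, None] * age_w[None, :, None] \
        * np.array([0.497, 0.503])[None, None, :]
    counts *= 1.0 + 0.05 * (rng.random(counts.shape) - 0.5)

    fert = np.zeros(N_AGE_BANDS)
    fert[1:8] = np.array([0.012, 0.055, 0.085, 0.070, 0.038, 0.014, 0.003])
    fert *= 0.9 + 0.2 * rng.random()

    mort = 4.0e-4 * np.exp(0.082 * (mids - 10.0))[:, None] * np.array([1.3, 1.0])[None, :]
    mort *= 1.0 + 0.1 * (rng.random(mort.shape) - 0.5)
    mort = np.maximum.accumulate(np.minimum(mort, 0.45), axis=0)

    mig = 0.0008 * base_pop * rng.standard_normal(m)
    mig -= mig.mean()                               # zero national sum
    return PopulationState(list(dims.households), list(dims.locations),
                           counts, fert, mort, mig)


def generate_luc_matrix(dims: ModelDimensions, seed: int) -> LUCMatrix:
    """Crop-conversion emission coefficients from per-crop carbon stocks.

    ``m[i, j] = stock_i - stock_j`` (tonnes CO2-eq per hectare) is
    antisymmetric with zero diagonal; oil palm carries the largest standing
    stock, so conversion from an annual crop into oil palm sequesters carbon.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    k = len(dims.crops)
    stocks = 2.0 + 6.0 * rng.random(k)
    stocks[dims.crops.index(dims.oil_palm_crop)] = 40.0 + 8.0 * rng.random()
    mat = stocks[:, None] - stocks[None, :]
    return LUCMatrix(list(dims.crops), mat)


def _generate_land_yields(dims: ModelDimensions, sam: SAM,
                          total_ha: float = 2.0e6) -> LandYields:
    land_row = sam.table.loc["fac_land"]
    land_use = np.array([land_row[f"act_{c}"] for c in dims.crops])
    qx = np.array([sam.table.loc[f"act_{c}", f"com_{c}"] for c in dims.crops])
    total_service = land_use.sum()
    kappa = total_ha / total_service
    ha0 = kappa * land_use
    return LandYields(list(dims.crops), ha0 / qx, np.full(len(dims.crops), kappa),
                      endowment_ha=total_ha * 1.25)


# ---------------------------------------------------------------------------
# Top-level generators
# ---------------------------------------------------------------------------

def generate_synthetic_economy(dims: ModelDimensions, seed: int,
                               noise_level: float = 0.0
                               ) -> tuple[SyntheticTruth, SAM, ElasticityPriors]:
    """Generate the full ground truth plus noised calibration priors.

    The unbalanced SAM applies multiplicative lognormal noise of standard
    deviation ``noise_level`` to nonzero cells (zeros are structural and
    preserved).  Elasticity priors are the true AIDS-implied values with
    additive noise on off-diagonal cross-price entries and income
    elasticities, so symmetry and adding-up fail whenever noise is positive
    while own-price signs are preserved.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    s = _build_flow_structure(dims, rng)
    fl = _solve_circular_flow(dims, s, rng)
    sam = _assemble_sam(dims, s, fl)

    pop = generate_population(dims, seed)
    aids = _generate_aids_truth(dims, s["w0"], fl["EH"], rng)
    nutrients = _generate_nutrients(dims, fl["C"], pop.household_totals(), rng)
    dists, strata = _generate_biomarkers(dims, pop, rng)
    risks = _generate_risks(dims, rng)
    costs = _generate_costs(dims, strata, risks, pop, fl["gdp"])
    luc = generate_luc_matrix(dims, seed)
    yields = _generate_land_yields(dims, sam)
    truth = SyntheticTruth(dims, sam, aids, nutrients, dists, strata, risks,
                           pop, luc, yields, costs, GrowthTargets())

    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    vals = sam.values.copy()
    nz = vals > 0
    vals[nz] *= np.exp(noise_level * noise_rng.standard_normal(nz.sum()))
    unbalanced = SAM(pd.DataFrame(vals, index=sam.accounts, columns=sam.accounts))

    eps_true, eta_true = aids_elasticities(aids, s["w0"])
    eps = eps_true.copy()
    if noise_level > 0:
        off = ~np.eye(dims.n_commodities, dtype=bool)
        for h in range(dims.n_households):
            eps[h][off] += noise_level * noise_rng.standard_normal(off.sum())
    eta = eta_true + (noise_level * noise_rng.standard_normal(eta_true.shape)
                      if noise_level > 0 else 0.0)
    priors = ElasticityPriors(list(dims.commodities), list(dims.households),
                              eps, eta, s["w0"].copy())
    return truth, unbalanced, priors


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def export_dataset(truth: SyntheticTruth, unbalanced: SAM,
                   priors: ElasticityPriors, outdir, seed: int,
                   noise_level: float) -> None:
    """Write every component as CSV plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.balanced_sam.to_csv(out / "sam_balanced.csv")
    unbalanced.to_csv(out / "sam_unbalanced.csv")
    truth.aids_parameters.to_json(out / "aids_parameters.json")
    truth.nutrient_coefficients.to_csv(out / "nutrient_coefficients.csv")
    truth.population.to_csv(out / "population.csv")
    truth.luc_matrix.to_csv(out / "luc_matrix.csv")
    for name, arr in (("epsilon", priors.epsilon), ("eta", priors.eta),
                      ("shares", priors.shares)):
        pd.DataFrame(arr.reshape(arr.shape[0], -1),
                     index=priors.households).to_csv(out / f"priors_{name}.csv")
    manifest = {
        "seed": int(seed), "noise_level": float(noise_level),
        "commodities": truth.dims.commodities, "households": truth.dims.households,
        "periods": truth.dims.periods, "strata_count": truth.dims.strata_count,
        "growth_targets": {"real": truth.growth_targets.real,
                           "nominal": truth.growth_targets.nominal},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
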