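"""Clinical outcome machinery for the cardiovascular pathway.

Stratified incidence and excess-mortality rates for myocardial infarction
(MI) and stroke are obtained in three steps: (1) Monte-Carlo lookup tables —
for each age x gender x location cell and each of 11 support values spanning
the Total:HDL ratio interval [2.0, 7.0], the mean risk over simulated
individuals drawn from a normal biomarker distribution recentred at the
support value; (2) a degree-10 polynomial interpolant through the 11 table
values (domain affinely normalised to [-1, 1] for conditioning, outputs
clipped to [0, 1]); (3) outcome accounting that converts household biomarker
strata and population counts into incident cases, premature deaths, years
lost to disability (YLD), caregiver time, hospital costs and patient
worktime losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import AGE_BANDS, N_AGE_BANDS, PopulationState, working_age_fractions

logger = logging.getLogger(__name__)

DISEASES = ("mi", "stroke")
LOCATIONS = ("rural", "urban")
RATIO_INTERVAL = (2.0, 7.0)
N_SUPPORT = 11          # end-points of the 10 equidistant sub-intervals
POLY_DEGREE = 10
DEFAULT_SAMPLES = 10_000

SUPPORT_VALUES = np.linspace(*RATIO_INTERVAL, N_SUPPORT)


def _normalise(c: np.ndarray) -> np.ndarray:
    """Affine map of the ratio interval [2, 7] onto [-1, 1]."""
    lo, hi = RATIO_INTERVAL
    return (2.0 * np.asarray(c, dtype=float) - (lo + hi)) / (hi - lo)


# ---------------------------------------------------------------------------
# Input distributions and risk functions
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerDistributionSet:
    """Normal Total:HDL ratio distributions per household x age x gender."""

    households: list[str]
    locations: list[str]         # location label per household
    mean: np.ndarray             # (H, 13, 2)
    sd: np.ndarray               # (H, 13, 2)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if ((self.mean < RATIO_INTERVAL[0]) | (self.mean > RATIO_INTERVAL[1])).any():
            raise ValueError("biomarker means must lie within the ratio interval [2, 7]")
        if (self.sd <= 0).any():
            raise ValueError("biomarker standard deviations must be positive")

    def location_sd(self) -> np.ndarray:
        """Mean sd per (location, age, gender), averaged over households."""
        out = np.empty((len(LOCATIONS), N_AGE_BANDS, 2))
        for li, loc in enumerate(LOCATIONS):
            members = [h for h, l in enumerate(self.locations) if l == loc]
            out[li] = self.sd[members].mean(axis=0) if members else self.sd.mean(axis=0)
        return out


@dataclass
class RiskFunctionSet:
    """Bounded monotone logistic risk maps from the cholesterol ratio to
    annual incidence and excess-mortality probabilities.

    Shapes are (disease, age, gender, location); the logistic form
    ``scale / (1 + exp(-slope * (C - mid)))`` is non-decreasing for positive
    slope and bounded in [0, scale] with scale <= 1.
    """

    inc_scale: np.ndarray
    inc_slope: np.ndarray
    inc_mid: np.ndarray
    mort_scale: np.ndarray
    mort_slope: np.ndarray
    mort_mid: np.ndarray

    def __post_init__(self):
        for name in ("inc_scale", "inc_slope", "inc_mid",
                     "mort_scale", "mort_slope", "mort_mid"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.inc_scale < 0).any() or (self.inc_scale > 1).any() \
                or (self.mort_scale < 0).any() or (self.mort_scale > 1).any():
            raise ValueError("risk scales must lie in [0, 1]")
        if (self.inc_slope < 0).any() or (self.mort_slope < 0).any():
            raise ValueError("risk slopes must be non-negative (monotone risk)")

    @staticmethod
    def _logistic(scale, slope, mid, c):
        return scale / (1.0 + np.exp(-slope * (c - mid)))

    def incidence(self, d: int, a: int, g: int, loc: int, c) -> np.ndarray:
        return self._logistic(self.inc_scale[d, a, g, loc], self.inc_slope[d, a, g, loc],
                              self.inc_mid[d, a, g, loc], np.asarray(c, dtype=float))

    def mortality(self, d: int, a: int, g: int, loc: int, c) -> np.ndarray:
        return self._logistic(self.mort_scale[d, a, g, loc], self.mort_slope[d, a, g, loc],
                              self.mort_mid[d, a, g, loc], np.asarray(c, dtype=float))


# ---------------------------------------------------------------------------
# Lookup tables and polynomial evaluators
# ---------------------------------------------------------------------------

@dataclass
class LookupTableSet:
    """Simulated rates at the 11 ratio support values.

    Arrays have shape (disease, age, gender, location, support).
    """

    support_values: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray

    def __post_init__(self):
        for name in ("incidence", "mortality"):
            v = np.asarray(getattr(self, name), dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} rates must lie in [0, 1]")
            setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, dis in enumerate(DISEASES):
            for a, band in enumerate(AGE_BANDS):
                for g in range(2):
                    for li, loc in enumerate(LOCATIONS):
                        for s, c in enumerate(self.support_values):
                            rows.append({"disease": dis, "age_band": band,
                                         "gender": ("male", "female")[g], "location": loc,
                                         "ratio": c,
                                         "incidence": self.incidence[d, a, g, li, s],
                                         "mortality": self.mortality[d, a, g, li, s]})
        return pd.DataFrame(rows)


def build_lookup_tables(dists: BiomarkerDistributionSet, risks: RiskFunctionSet,
                        n: int = DEFAULT_SAMPLES, seed: int = 0) -> LookupTableSet:
    """Monte-Carlo lookup tables from ``n`` simulated individuals per cell.

    For each cell and support value ``c`` the table entry is the mean risk
    over ``n`` draws from a normal distribution recentred at ``c`` with the
    cell's (location-level) standard deviation.  Deterministic given ``seed``.
    """
    if n < 100:
        raise ValueError("need at least 100 simulated individuals per cell")
    rng = np.random.default_rng(seed)
    loc_sd = dists.location_sd()
    shape = (len(DISEASES), N_AGE_BANDS, 2, len(LOCATIONS), N_SUPPORT)
    inc = np.empty(shape)
    mort = np.empty(shape)
    for a in range(N_AGE_BANDS):
        for g in range(2):
            for li in range(len(LOCATIONS)):
                z = rng.standard_normal(n)
                samples = SUPPORT_VALUES[:, None] + loc_sd[li, a, g] * z[None, :]
                for d in range(len(DISEASES)):
                    inc[d, a, g, li] = risks.incidence(d, a, g, li, samples).mean(axis=1)
                    mort[d, a, g, li] = risks.mortality(d, a, g, li, samples).mean(axis=1)
    return LookupTableSet(SUPPORT_VALUES.copy(), inc, mort)


@dataclass
class RiskPolynomialSet:
    """Degree-10 interpolants of the lookup tables on the normalised domain.

    Coefficient arrays have shape (disease, age, gender, location, 11) in
    increasing power order; evaluations are clipped to [0, 1].
    """

    incidence_coef: np.ndarray
    mortality_coef: np.ndarray

    def _eval(self, coef: np.ndarray, c) -> np.ndarray:
        x = np.clip(_normalise(np.clip(c, *RATIO_INTERVAL)), -1.0, 1.0)
        val = np.polynomial.polynomial.polyval(x, np.moveaxis(coef, -1, 0), tensor=True)
        return np.clip(val, 0.0, 1.0)

    def incidence(self, d: int, a: int, g: int, loc: int, c) -> np.ndarray:
        return self._eval(self.incidence_coef[d, a, g, loc], c)

    def mortality(self, d: int, a: int, g: int, loc: int, c) -> np.ndarray:
        return self._eval(self.mortality_coef[d, a, g, loc], c)

    def to_json_dict(self) -> dict:
        return {"incidence_coef": self.incidence_coef.tolist(),
                "mortality_coef": self.mortality_coef.tolist(),
                "domain": list(RATIO_INTERVAL)}


def _interpolate(y: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Exact degree-10 interpolation with one step of iterative refinement."""
    coef = np.linalg.solve(V, y)
    coef += np.linalg.solve(V, y - V @ coef)
    return coef


def fit_polynomials(tables: LookupTableSet) -> RiskPolynomialSet:
    """Fit the degree-10 polynomial through each cell's 11 table values."""
    sv = np.asarray(tables.support_values, dtype=float)
    if len(sv) != N_SUPPORT:
        raise ValueError(f"expected {N_SUPPORT} support values")
    if len(np.unique(sv)) != len(sv):
        raise ValueError("duplicated support values; interpolation is ill-posed")
    x = _normalise(sv)
    V = np.vander(x, POLY_DEGREE + 1, increasing=True)
    shape = tables.incidence.shape
    inc = np.empty(shape)
    mort = np.empty(shape)
    flat_i = tables.incidence.reshape(-1, N_SUPPORT)
    flat_m = tables.mortality.reshape(-1, N_SUPPORT)
    out_i = inc.reshape(-1, N_SUPPORT)
    out_m = mort.reshape(-1, N_SUPPORT)
    for k in range(flat_i.shape[0]):
        out_i[k] = _interpolate(flat_i[k], V)
        out_m[k] = _interpolate(flat_m[k], V)
    return RiskPolynomialSet(inc, mort)


# ---------------------------------------------------------------------------
# Outcome accounting
# ---------------------------------------------------------------------------

@dataclass
class HealthCostParameters:
    """Unit costs and rates for outcome valuation and labour feedback.

    Durations are in years, times in person-years per case, costs in model
    currency per case.  MI disability is brief and acute; stroke disability
    is chronic (duration capped at the remaining horizon when evaluating).
    """

    yld_weight: dict = field(default_factory=lambda: {"mi": 0.04, "stroke": 0.30})
    yld_duration: dict = field(default_factory=lambda: {"mi": 0.04, "stroke": 3.0})
    caregiver_worktime_per_stroke: float = 0.74
    caregiver_leisure_per_stroke: float = 1.09
    hospital_unit_cost: dict = field(default_factory=lambda: {"mi": 0.0, "stroke": 0.0})
    patient_worktime_per_case: dict = field(default_factory=lambda: {"mi": 0.002, "stroke": 0.40})
    participation: np.ndarray | float = 0.72
    retirement_age: float = 65.0
    skill_split: float = 0.40

    def __post_init__(self):
        for d in DISEASES:
            if not (0.0 <= self.yld_weight[d] <= 1.0):
                raise ValueError("disability weights must lie in [0, 1]")
            if self.hospital_unit_cost[d] < 0:
                raise ValueError("hospital unit costs must be non-negative")
        p = np.asarray(self.participation, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("participation rates must lie in [0, 1]")

    def participation_grid(self) -> np.ndarray:
        p = np.asarray(self.participation, dtype=float)
        return np.full((N_AGE_BANDS, 2), float(p)) if p.ndim == 0 else p


@dataclass
class ClinicalOutcomes:
    """Single-period clinical outcomes and their economic footprints."""

    households: list[str]
    cases: np.ndarray                 # (disease, H, 13, 2) incident cases
    deaths: np.ndarray                # (disease, H, 13, 2) premature deaths
    yld: np.ndarray                   # (disease,) person-years
    patient_worktime: np.ndarray      # (H,) person-years
    caregiver_worktime: np.ndarray    # (H,) person-years
    caregiver_leisure: np.ndarray     # (H,) person-years
    hospital_cost: np.ndarray         # (disease,) currency
    hospital_cost_by_hh: np.ndarray | None = None   # (H,) currency

    @property
    def total_cases(self) -> float:
        return float(self.cases.sum())

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    def excess_deaths_by_cell(self) -> np.ndarray:
        """Deaths summed over diseases, per (household, age, gender)."""
        return self.deaths.sum(axis=0)

    def scale(self, k: float) -> "ClinicalOutcomes":
        return ClinicalOutcomes(self.households, self.cases * k, self.deaths * k,
                                self.yld * k, self.patient_worktime * k,
                                self.caregiver_worktime * k, self.caregiver_leisure * k,
                                self.hospital_cost * k,
                                None if self.hospital_cost_by_hh is None
                                else self.hospital_cost_by_hh * k)


def evaluate_outcomes(strata, polys: RiskPolynomialSet, pop: PopulationState,
                      params: HealthCostParameters,
                      remaining_years: float | None = None) -> ClinicalOutcomes:
    """Convert biomarker strata and population into clinical outcomes.

    Incident cases per cell are ``sum_s freq_s * pop * incidence(C_s)``;
    premature deaths use the excess-mortality polynomials and are capped at
    the cell population.  Support points outside [2, 7] are clamped (counted
    in a warning log).  Worktime losses are corrected for participation rates
    and restricted to working-age cells.
    """
    H = len(pop.households)
    loc_index = np.array([LOCATIONS.index(l) for l in pop.locations])
    support = np.asarray(strata.support, dtype=float)
    freq = np.asarray(strata.frequency, dtype=float)
    n_clamped = int(np.sum((support < RATIO_INTERVAL[0]) | (support > RATIO_INTERVAL[1])))
    if n_clamped:
        logger.warning("clamped %d biomarker support points to [%.1f, %.1f]",
                       n_clamped, *RATIO_INTERVAL)
    support = np.clip(support, *RATIO_INTERVAL)

    nd = len(DISEASES)
    cases = np.zeros((nd, H, N_AGE_BANDS, 2))
    deaths = np.zeros((nd, H, N_AGE_BANDS, 2))
    for h in range(H):
        li = loc_index[h]
        for d in range(nd):
            for a in range(N_AGE_BANDS):
                for g in range(2):
                    inc = polys.incidence(d, a, g, li, support[h])
                    mor = polys.mortality(d, a, g, li, support[h])
                    p = pop.counts[h, a, g]
                    cases[d, h, a, g] = p * float(freq[h] @ inc)
                    deaths[d, h, a, g] = min(p * float(freq[h] @ mor), p)

    dur = {d: params.yld_duration[d] for d in DISEASES}
    if remaining_years is not None:
        dur["stroke"] = min(dur["stroke"], max(remaining_years, 0.0))
    yld = np.array([cases[i].sum() * params.yld_weight[d] * dur[d]
                    for i, d in enumerate(DISEASES)])

    part = params.participation_grid()
    wfrac = working_age_fractions(params.retirement_age)
    work_weight = wfrac[None, :, None] * part[None, :, :]          # (1, 13, 2)
    patient_work = np.zeros(H)
    for i, d in enumerate(DISEASES):
        patient_work += (cases[i] * work_weight).sum(axis=(1, 2)) \
            * params.patient_worktime_per_case[d]
    stroke_cases_h = cases[DISEASES.index("stroke")].sum(axis=(1, 2))
    mean_part = float(part[working_age_fractions(params.retirement_age) > 0].mean())
    caregiver_work = stroke_cases_h * params.caregiver_worktime_per_stroke * mean_part
    caregiver_leisure = stroke_cases_h * params.caregiver_leisure_per_stroke
    hosp = np.array([cases[i].sum() * params.hospital_unit_cost[d]
                     for i, d in enumerate(DISEASES)])
    hosp_hh = sum(cases[i].sum(axis=(1, 2)) * params.hospital_unit_cost[d]
                  for i, d in enumerate(DISEASES))
    return ClinicalOutcomes(list(pop.households), cases, deaths, yld,
                            patient_work, caregiver_work, caregiver_leisure,
                            hosp, hosp_hh)
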