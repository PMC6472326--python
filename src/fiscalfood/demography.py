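"""Cohort-component population projection by region-location, five-year age
band and gender, with an annual time step, plus labour-supply derivation.

The population is modelled from the first band relevant to the adult
biomarker pathway upward (13 bands, last open-ended).  Each annual step
applies background mortality plus allocated cardiovascular excess deaths,
fertility-driven inflow into the first band, one-fifth-per-year graduation
between five-year bands, and net migration.  The accounting identity
``pop(t+1) = pop(t) + births - deaths + migration`` holds exactly per
region-location cell and is exposed through the step ledger.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ClosureError

if TYPE_CHECKING:  # pragma: no cover
    from .health import HealthCostParameters

logger = logging.getLogger(__name__)

N_AGE_BANDS = 13
#: Five-year bands; the model covers the adult pathway so the first band
#: starts at age 10 and the last is open-ended.
AGE_BANDS = ("10-14", "15-19", "20-24", "25-29", "30-34", "35-39", "40-44",
             "45-49", "50-54", "55-59", "60-64", "65-69", "70+")
AGE_BAND_STARTS = np.array([10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70], float)
GENDERS = ("male", "female")
MALE_BIRTH_FRACTION = 0.512


@dataclass
class PopulationState:
    """Counts and vital rates by region-location household, age band, gender."""

    households: list[str]                    # region x location composites
    locations: list[str]                     # 'rural'/'urban' per household
    counts: np.ndarray                       # (H, 13, 2) persons
    fertility: np.ndarray                    # (13,) annual births per woman
    mortality: np.ndarray                    # (13, 2) annual background rate
    migration: np.ndarray                    # (H,) net annual persons
    person_year_ledger: float = 0.0          # cumulative person-years lived
    last_flows: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.migration = np.asarray(self.migration, dtype=float)
        if self.counts.shape != (len(self.households), N_AGE_BANDS, 2):
            raise ValueError("counts must have shape (households, 13 age bands, 2 genders)")
        if (self.counts < 0).any():
            raise ValueError("population counts must be non-negative")
        if not np.all(np.isfinite(self.fertility)) or not np.all(np.isfinite(self.mortality)):
            raise ValueError("vital rates must be finite")
        if (self.mortality < 0).any() or (self.mortality > 1).any():
            raise ValueError("mortality rates must lie in [0, 1]")

    @property
    def national_total(self) -> float:
        return float(self.counts.sum())

    def household_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def copy(self) -> "PopulationState":
        return PopulationState(list(self.households), list(self.locations),
                               self.counts.copy(), self.fertility.copy(),
                               self.mortality.copy(), self.migration.copy(),
                               self.person_year_ledger)

    def to_csv(self, path) -> None:
        rows = []
        for h, hh in enumerate(self.households):
            for a, band in enumerate(AGE_BANDS):
                for g, gender in enumerate(GENDERS):
                    rows.append({"household": hh, "location": self.locations[h],
                                 "age_band": band, "gender": gender,
                                 "count": self.counts[h, a, g],
                                 "mortality": self.mortality[a, g],
                                 "fertility": self.fertility[a]})
        pd.DataFrame(rows).to_csv(path, index=False)


FEMALE = GENDERS.index("female")


def project_population(state: PopulationState,
                       excess_deaths: np.ndarray | None = None,
                       dt: float = 1.0) -> PopulationState:
    """Advance the population one annual step.

    ``excess_deaths`` are cardiovascular deaths per (household, age, gender)
    cell in persons for the year, on top of background mortality; cells where
    they would exceed the surviving population are capped with a warning.
    """
    c = state.counts
    deaths = c * state.mortality[None, :, :] * dt
    if excess_deaths is not None:
        ex = np.asarray(excess_deaths, dtype=float)
        room = np.maximum(c - deaths, 0.0)
        capped = np.minimum(ex, room)
        n_over = int(np.sum(ex > room + 1e-9))
        if n_over:
            warnings.warn(f"excess deaths exceeded cell population in {n_over} cells; capped",
                          stacklevel=2)
        deaths = deaths + capped
    survivors = c - deaths

    births_h = (state.fertility[None, :] * c[:, :, FEMALE]).sum(axis=1) * dt

    # one-fifth-per-year graduation between five-year bands; last band open
    grad = survivors * (dt / 5.0)
    grad[:, -1, :] = 0.0
    aged = survivors - grad
    aged[:, 1:, :] += grad[:, :-1, :]
    aged[:, 0, 0] += births_h * MALE_BIRTH_FRACTION
    aged[:, 0, 1] += births_h * (1.0 - MALE_BIRTH_FRACTION)

    mig = state.migration * dt
    hh_tot = aged.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(hh_tot[:, None, None] > 0, aged / hh_tot[:, None, None], 0.0)
    aged = aged + mig[:, None, None] * shares
    aged = np.maximum(aged, 0.0)

    flows = {"births": births_h, "deaths": deaths.sum(axis=(1, 2)),
             "migration": mig, "deaths_by_cell": deaths}
    new = PopulationState(list(state.households), list(state.locations), aged,
                          state.fertility.copy(), state.mortality.copy(),
                          state.migration.copy(),
                          state.person_year_ledger + state.national_total * dt)
    new.last_flows = flows
    return new


# ---------------------------------------------------------------------------
# Labour supply
# ---------------------------------------------------------------------------

@dataclass
class LabourSupply:
    """Skilled/unskilled person-years per household for one period."""

    households: list[str]
    skilled: np.ndarray      # (H,)
    unskilled: np.ndarray    # (H,)
    participation: np.ndarray
    skill_split: float

    @property
    def total(self) -> float:
        return float(self.skilled.sum() + self.unskilled.sum())


def working_age_fractions(retirement_age: float) -> np.ndarray:
    """Fraction of each age band inside the working span [15, retirement)."""
    lo, hi = AGE_BAND_STARTS, AGE_BAND_STARTS + 5.0
    hi[-1] = 200.0
    frac = (np.minimum(hi, retirement_age) - np.maximum(lo, 15.0)) / (hi - lo)
    return np.clip(frac, 0.0, 1.0)


def derive_labour_supply(state: PopulationState, params: "HealthCostParameters",
                         patient_losses: np.ndarray | float = 0.0,
                         caregiver_losses: np.ndarray | float = 0.0,
                         allow_any_retirement_age: bool = False) -> LabourSupply:
    """Labour endowment in person-years: working-age population corrected for
    participation and the fixed skill split, net of patient and caregiver
    worktime losses."""
    R = params.retirement_age
    if not allow_any_retirement_age and not (59.0 <= R <= 69.0):
        raise ClosureError(f"retirement age {R} outside supported grid [59, 69]; "
                           "pass allow_any_retirement_age=True to override")
    frac = working_age_fractions(R)
    part = np.asarray(params.participation, dtype=float)
    if part.ndim == 0:
        part = np.full((N_AGE_BANDS, 2), float(part))
    working = (state.counts * frac[None, :, None] * part[None, :, :]).sum(axis=(1, 2))
    losses = np.broadcast_to(np.asarray(patient_losses, float), working.shape) \
        + np.broadcast_to(np.asarray(caregiver_losses, float), working.shape)
    effective = np.maximum(working - losses, 0.0)
    split = params.skill_split
    return LabourSupply(list(state.households), effective * split,
                        effective * (1.0 - split), part, split)
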