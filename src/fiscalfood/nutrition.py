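"""Diet-to-biomarker pathway: fatty-acid energy-intake accounting and the
linear serum-cholesterol response.

Household consumption quantities are mapped to per-capita daily energy from
saturated (SFA), monounsaturated (MUFA) and polyunsaturated (PUFA) fatty
acids via commodity energy densities and energy fractions.  Changes in the
percentage energy-intake shares (measured against the same-period baseline
run) move the population-mean Total:HDL cholesterol ratio linearly:

    dC = a_SFA * dSFA + a_MUFA * dMUFA + a_PUFA * dPUFA

with central coefficients (0.003, -0.026, -0.032) per percentage point of
energy share.  Intra-household biomarker distributions are represented by
support points (strata) with fixed frequencies; the mean change shifts every
support point additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NutrientCoefficientTable", "CholesterolCoefficients", "NutrientIntake",
    "BiomarkerStrata", "intake_from_consumption", "delta_cholesterol",
    "shift_strata",
]


@dataclass
class NutrientCoefficientTable:
    """Energy density and fatty-acid energy fractions per household x commodity.

    ``energy_density`` is kcal per currency unit of real consumption;
    fractions are dimensionless shares of a commodity's energy, with
    SFA + MUFA + PUFA <= 1 per cell.
    """

    commodities: list[str]
    households: list[str]
    energy_density: np.ndarray   # (H, n) kcal per currency unit
    sfa_frac: np.ndarray         # (H, n)
    mufa_frac: np.ndarray        # (H, n)
    pufa_frac: np.ndarray        # (H, n)

    def __post_init__(self):
        for name in ("energy_density", "sfa_frac", "mufa_frac", "pufa_frac"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.energy_density < 0).any():
            raise ValueError("energy density must be non-negative")
        fr = self.sfa_frac + self.mufa_frac + self.pufa_frac
        if (fr > 1.0 + 1e-12).any():
            raise ValueError("SFA+MUFA+PUFA energy fractions must not exceed 1")
        if ((self.sfa_frac < 0) | (self.mufa_frac < 0) | (self.pufa_frac < 0)).any():
            raise ValueError("energy fractions must be non-negative")

    def to_csv(self, path) -> None:
        rows = []
        for h, hh in enumerate(self.households):
            for c, com in enumerate(self.commodities):
                rows.append({"household": hh, "commodity": com,
                             "energy_density": self.energy_density[h, c],
                             "sfa_frac": self.sfa_frac[h, c],
                             "mufa_frac": self.mufa_frac[h, c],
                             "pufa_frac": self.pufa_frac[h, c]})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class CholesterolCoefficients:
    """Change in the Total:HDL ratio per percentage-point energy-share change.

    Central defaults follow the meta-analytic estimates linking fatty-acid
    substitution to the serum cholesterol ratio; bounds are the confidence
    limits used by the biomarker sensitivity suite.
    """

    sfa: float = 0.003
    mufa: float = -0.026
    pufa: float = -0.032
    sfa_bounds: tuple[float, float] = (-0.001, 0.007)
    mufa_bounds: tuple[float, float] = (-0.044, -0.008)
    pufa_bounds: tuple[float, float] = (-0.050, -0.014)

    def __post_init__(self):
        for c, (lo, hi) in ((self.sfa, self.sfa_bounds), (self.mufa, self.mufa_bounds),
                            (self.pufa, self.pufa_bounds)):
            if not (lo <= c <= hi):
                raise ValueError("confidence bounds must bracket the central value")

    def at_bounds(self, which: str) -> "CholesterolCoefficients":
        """Coefficients with all three parameters at 'lower' or 'upper' bounds."""
        k = 0 if which == "lower" else 1
        return CholesterolCoefficients(
            sfa=self.sfa_bounds[k], mufa=self.mufa_bounds[k], pufa=self.pufa_bounds[k],
            sfa_bounds=self.sfa_bounds, mufa_bounds=self.mufa_bounds,
            pufa_bounds=self.pufa_bounds)


@dataclass
class NutrientIntake:
    """Per-household per-capita daily energy and fatty-acid shares."""

    households: list[str]
    total_energy: np.ndarray     # (H,) kcal/person/day
    sfa_energy: np.ndarray       # (H,) kcal/person/day
    mufa_energy: np.ndarray
    pufa_energy: np.ndarray

    @property
    def sfa_share(self) -> np.ndarray:
        """SFA energy as percent of total energy."""
        return 100.0 * self.sfa_energy / self.total_energy

    @property
    def mufa_share(self) -> np.ndarray:
        return 100.0 * self.mufa_energy / self.total_energy

    @property
    def pufa_share(self) -> np.ndarray:
        return 100.0 * self.pufa_energy / self.total_energy


def intake_from_consumption(quantities: np.ndarray,
                            coeffs: NutrientCoefficientTable,
                            population: np.ndarray) -> NutrientIntake:
    """Convert real consumption quantities into per-capita daily intakes.

    ``quantities`` is (H, n) annual real consumption by household and
    commodity; ``population`` is persons per household.
    """
    q = np.asarray(quantities, dtype=float)
    pop = np.asarray(population, dtype=float)
    if (q < 0).any():
        raise ValueError("consumption quantities must be non-negative")
    denom = pop * 365.0
    energy = (q * coeffs.energy_density)
    total = energy.sum(axis=1) / denom
    if (total <= 0).any():
        bad = [coeffs.households[i] for i in np.where(total <= 0)[0]]
        raise ZeroDivisionError(f"zero total energy intake for households {bad}; "
                                "energy shares undefined")
    sfa = (energy * coeffs.sfa_frac).sum(axis=1) / denom
    mufa = (energy * coeffs.mufa_frac).sum(axis=1) / denom
    pufa = (energy * coeffs.pufa_frac).sum(axis=1) / denom
    return NutrientIntake(list(coeffs.households), total, sfa, mufa, pufa)


def delta_cholesterol(d_sfa, d_mufa, d_pufa,
                      coeffs: CholesterolCoefficients | None = None):
    """Mean Total:HDL ratio change from percentage-point share changes.

    Exact linear combination; inputs may be scalars or arrays.
    """
    coeffs = coeffs or CholesterolCoefficients()
    out = (coeffs.sfa * np.asarray(d_sfa, dtype=float)
           + coeffs.mufa * np.asarray(d_mufa, dtype=float)
           + coeffs.pufa * np.asarray(d_pufa, dtype=float))
    return out if out.ndim else float(out)


@dataclass
class BiomarkerStrata:
    """Support-point representation of intra-household Total:HDL distributions.

    ``support`` holds strictly increasing ratio values per household;
    ``frequency`` the fixed population weight of each stratum (rows sum to 1).
    """

    households: list[str]
    support: np.ndarray      # (H, S)
    frequency: np.ndarray    # (H, S)

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if (np.diff(self.support, axis=1) <= 0).any():
            raise ValueError("support points must be strictly increasing")
        if (self.frequency < 0).any():
            raise ValueError("stratum frequencies must be non-negative")
        if not np.allclose(self.frequency.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("stratum frequencies must sum to one per household")

    def mean(self) -> np.ndarray:
        """Frequency-weighted mean ratio per household."""
        return (self.support * self.frequency).sum(axis=1)

    def copy(self) -> "BiomarkerStrata":
        return BiomarkerStrata(list(self.households), self.support.copy(),
                               self.frequency.copy())


def shift_strata(strata: BiomarkerStrata, delta) -> BiomarkerStrata:
    """Shift every support point by the household's mean change ``delta``.

    Frequencies are unchanged; ordering is preserved (additive shift).
    ``delta`` may be a scalar or a per-household vector.
    """
    d = np.asarray(delta, dtype=float)
    if d.ndim == 0:
        d = np.full(len(strata.households), float(d))
    return BiomarkerStrata(list(strata.households),
                           strata.support + d[:, None], strata.frequency.copy())
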