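"""Direct land-use-change (dLUC) greenhouse-gas accounting.

Crop land areas are derived from the equilibrium allocation of the land
factor across primary-crop activities.  Period-to-period net area losses are
matched to net area gains by proportional allocation (no transition
preference data), and each hectare converted from crop i to crop j emits
``m[i, j]`` tonnes CO2-eq, where ``m`` is antisymmetric with zero diagonal —
converting land into a higher-carbon-stock crop (e.g. establishing oil palm)
sequesters carbon and carries a negative coefficient.  Only direct LUC is
computed; indirect LUC and non-GHG indicators are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FiscalFoodError

TONNES_PER_MEGATONNE = 1e6


@dataclass
class LUCMatrix:
    """Crop-to-crop emission coefficients, tonnes CO2-eq per hectare converted."""

    crops: list[str]
    coefficients: np.ndarray     # (k, k), antisymmetric, zero diagonal

    def __post_init__(self):
        m = np.asarray(self.coefficients, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.crops):
            raise ValueError("LUC matrix must be square over the crop set")
        if not np.allclose(m + m.T, 0.0, atol=1e-10):
            raise ValueError("LUC matrix must be antisymmetric (m[i,j] = -m[j,i])")
        self.coefficients = m

    def to_csv(self, path) -> None:
        pd.DataFrame(self.coefficients, index=self.crops, columns=self.crops).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LUCMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.values)


@dataclass
class LandYields:
    """Hectares per unit of real crop output, plus the benchmark mapping from
    land-factor services (currency at base prices) to physical hectares."""

    crops: list[str]
    ha_per_output: np.ndarray        # (k,)
    ha_per_land_service: np.ndarray  # (k,) calibrated at benchmark
    endowment_ha: float              # total physical cropland


@dataclass
class LandAccount:
    """Hectares by crop for one period."""

    crops: list[str]
    hectares: np.ndarray

    def __post_init__(self):
        self.hectares = np.asarray(self.hectares, dtype=float)
        if (self.hectares < -1e-9).any():
            raise ValueError("crop areas must be non-negative")

    @property
    def total(self) -> float:
        return float(self.hectares.sum())


def land_allocation(eq, yields: LandYields) -> LandAccount:
    """Crop areas implied by the equilibrium land-factor allocation.

    Land is a fixed, fully employed factor, so total area is conserved;
    at benchmark the areas equal real output times the yield coefficients.
    """
    land_use = np.asarray(eq.land_use_by_crop(yields.crops), dtype=float)
    ha = land_use * yields.ha_per_land_service
    total = ha.sum()
    if total > yields.endowment_ha * (1.0 + 1e-6):
        raise FiscalFoodError(f"allocated cropland {total:.1f} ha exceeds the "
                              f"endowment {yields.endowment_ha:.1f} ha")
    return LandAccount(list(yields.crops), ha)


def luc_emissions(land_t: LandAccount, land_prev: LandAccount, m: LUCMatrix,
                  imbalance_tol: float = 0.05) -> float:
    """Net dLUC emissions (Mt CO2-eq) from the land reallocation between two
    periods.

    Net per-crop area losses are allocated to net gains proportionally;
    emissions are ``sum_ij transition[i, j] * m[i, j]``.  A total land change
    beyond ``imbalance_tol`` of turnover is an error (land should be
    conserved up to calibration slack).
    """
    if list(land_t.crops) != list(land_prev.crops) or list(land_t.crops) != list(m.crops):
        raise ValueError("land accounts and LUC matrix must share the same crop set")
    d = land_t.hectares - land_prev.hectares
    losses = np.maximum(-d, 0.0)
    gains = np.maximum(d, 0.0)
    turnover = losses.sum() + gains.sum()
    if turnover == 0.0:
        return 0.0
    if abs(losses.sum() - gains.sum()) > imbalance_tol * turnover + 1e-9:
        raise FiscalFoodError(
            f"unbalanced land change: losses {losses.sum():.3f} ha vs gains "
            f"{gains.sum():.3f} ha exceed tolerance")
    matched = min(losses.sum(), gains.sum())
    if matched == 0.0:
        return 0.0
    transition = np.outer(losses / losses.sum(), gains / gains.sum()) * matched
    return float((transition * m.coefficients).sum()) / TONNES_PER_MEGATONNE
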