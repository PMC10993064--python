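"""Domain containers for foods, diets, nutrient composition and GHGE accounting.

Conventions used throughout the package:

* consumption is in g per capita per day (``g/cap/day``),
* dietary energy is in kJ per capita per day,
* nutrient densities are in *nutrient unit per gram of food* (so a density of
  0.05 for protein means 5 g protein per 100 g food),
* GHGE coefficients are stored in kg CO2e per kg food; :func:`compute_ghge`
  performs the g -> kg conversion and returns kg CO2e/cap/day,
* milk-equivalent coefficients are grams of raw milk per gram of product.

All accounting operations are linear in the consumption vector; diets are
represented as :class:`pandas.Series` indexed by food id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FoodCategory",
    "FoodTable",
    "GroupDiet",
    "CompositionMatrix",
    "GHGETable",
    "NutrientProfile",
    "ValidationWarning",
    "compute_energy",
    "compute_nutrients",
    "compute_ghge",
    "aggregate_diet",
    "milk_equivalents",
    "relative_reduction",
]

#: nutrient id used for energy density (kJ per g food) inside the composition matrix
ENERGY_ID = "energy"


class ValidationWarning(UserWarning):
    """Raised (as a warning) for suspicious but legal data, e.g. mean outside [p10, p90]."""


@dataclass(frozen=True)
class FoodCategory:
    """One of the (typically 74) food categories of the intake survey.

    ``milk_eq`` converts grams of the product into grams of raw milk (0 for
    non-dairy foods); ``beef_content`` is the fraction of the product that is
    beef carcass (1.0 for beef, 0.88 for offals, 0.5 for meat products,
    0.075 for sausages and cold cuts, 0 otherwise).
    """

    id: str
    name: str
    main_group: str
    milk_eq: float = 0.0
    beef_content: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beef_content <= 1.0):
            raise ValueError(f"{self.id}: beef_content must be in [0, 1], got {self.beef_content}")
        if self.milk_eq < 0:
            raise ValueError(f"{self.id}: milk_eq must be >= 0, got {self.milk_eq}")


class FoodTable:
    """Ordered collection of food categories plus the aggregation map to main groups.

    The table owns the mapping from the detailed categories to the (typically
    13) main reporting groups; every food maps to exactly one main group.
    """

    def __init__(self, foods: Iterable[FoodCategory]):
        foods = list(foods)
        ids = [f.id for f in foods]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate food ids: {dupes}")
        self._foods = {f.id: f for f in foods}
        self._frame = pd.DataFrame(
            {
                "name": [f.name for f in foods],
                "main_group": [f.main_group for f in foods],
                "milk_eq": [f.milk_eq for f in foods],
                "beef_content": [f.beef_content for f in foods],
            },
            index=pd.Index(ids, name="food_id"),
        )

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    def __getitem__(self, food_id: str) -> FoodCategory:
        return self._foods[food_id]

    def __iter__(self):
        return iter(self._foods.values())

    @property
    def ids(self) -> pd.Index:
        return self._frame.index

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def main_groups(self) -> list[str]:
        """Main reporting groups in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self._frame["main_group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def aggregation_map(self) -> pd.Series:
        """food_id -> main_group, total over all foods."""
        return self._frame["main_group"].copy()

    @property
    def milk_eq(self) -> pd.Series:
        return self._frame["milk_eq"].copy()

    @property
    def beef_content(self) -> pd.Series:
        return self._frame["beef_content"].copy()


@dataclass
class GroupDiet:
    """Observed diet of one socio-demographic group.

    ``group_id`` follows the ``sex/stratum`` convention, e.g. ``male/all``,
    ``female/Educ1``, ``male/IncQ5``.  ``mean`` is the observed average
    consumption x-bar (the optimisation anchor), ``p10``/``p90`` the 10th and
    90th centiles of the group's consumption distribution (the food-habit
    bounds) and ``energy_obs`` the observed mean energy intake E0 in kJ/cap/day.
    """

    group_id: str
    mean: pd.Series
    p10: pd.Series
    p90: pd.Series
    energy_obs: float

    def __post_init__(self) -> None:
        idx = self.mean.index
        for attr in ("p10", "p90"):
            s = getattr(self, attr)
            if not s.index.equals(idx):
                raise ValueError(f"{self.group_id}: {attr} index differs from mean index")
        for attr in ("mean", "p10", "p90"):
            s = getattr(self, attr).astype(float)
            object.__setattr__(self, attr, s)
            if not np.isfinite(s.to_numpy()).all():
                raise ValueError(f"{self.group_id}: non-finite values in {attr}")
            if (s.to_numpy() < 0).any():
                bad = s.index[s.to_numpy() < 0][0]
                raise ValueError(f"{self.group_id}: negative {attr} for food {bad!r}")
        if (self.p10.to_numpy() > self.p90.to_numpy() + 1e-12).any():
            bad = self.p10.index[self.p10.to_numpy() > self.p90.to_numpy()][0]
            raise ValueError(f"{self.group_id}: p10 > p90 for food {bad!r}")
        if not np.isfinite(self.energy_obs) or self.energy_obs < 0:
            raise ValueError(f"{self.group_id}: energy_obs must be finite and >= 0")
        outside = (self.mean < self.p10 - 1e-9) | (self.mean > self.p90 + 1e-9)
        if outside.any():
            foods = list(self.mean.index[outside])
            warnings.warn(
                f"{self.group_id}: mean outside [p10, p90] for {len(foods)} food(s) "
                f"(e.g. {foods[:3]}); expected only for strongly skewed consumption",
                ValidationWarning,
                stacklevel=2,
            )

    @property
    def sex(self) -> str:
        return self.group_id.split("/", 1)[0]

    @property
    def stratum(self) -> str:
        parts = self.group_id.split("/", 1)
        return parts[1] if len(parts) > 1 else "all"

    @property
    def foods(self) -> pd.Index:
        return self.mean.index


class CompositionMatrix:
    """Nutrient densities a_ji (nutrient unit per g food) plus energy density.

    Energy density c_i (kJ/g) is stored under the nutrient id ``"energy"``.
    ``nutrients`` is a frame indexed by nutrient id with columns ``unit`` and
    ``energy_factor`` (k_j, kJ per g of nutrient; 0 for non energy-yielding
    nutrients), used to express intakes as shares of total energy (E%).
    """

    def __init__(self, densities: pd.DataFrame, nutrients: pd.DataFrame):
        if ENERGY_ID not in densities.columns:
            raise ValueError(f"composition matrix must contain an {ENERGY_ID!r} column (kJ/g)")
        if (densities.to_numpy() < 0).any():
            raise ValueError("nutrient densities must be >= 0")
        missing = densities.columns.difference(nutrients.index)
        if len(missing):
            raise ValueError(f"nutrients metadata missing for: {sorted(missing)}")
        self._dens = densities.astype(float)
        self._dens.index.name = "food_id"
        self._nutrients = nutrients.copy()
        # energy density must be able to pay for each energy-yielding nutrient alone
        for j in self._dens.columns:
            k = float(self._nutrients.at[j, "energy_factor"]) if j != ENERGY_ID else 0.0
            if k > 0:
                implied = k * self._dens[j]
                bad = implied > self._dens[ENERGY_ID] * (1 + 1e-6) + 1e-9
                if bad.any():
                    food = self._dens.index[bad][0]
                    raise ValueError(
                        f"food {food!r}: energy implied by {j} alone "
                        f"({implied[food]:.3f} kJ/g) exceeds its energy density"
                    )

    @property
    def foods(self) -> pd.Index:
        return self._dens.index

    @property
    def nutrient_ids(self) -> list[str]:
        return [c for c in self._dens.columns if c != ENERGY_ID]

    @property
    def nutrients(self) -> pd.DataFrame:
        return self._nutrients.copy()

    @property
    def energy_density(self) -> pd.Series:
        """c_i, kJ per g food."""
        return self._dens[ENERGY_ID].copy()

    def density(self, nutrient: str) -> pd.Series:
        """a_ji for one nutrient, unit per g food."""
        if nutrient not in self._dens.columns:
            raise KeyError(f"nutrient {nutrient!r} not in composition matrix")
        return self._dens[nutrient].copy()

    def energy_factor(self, nutrient: str) -> float:
        """k_j, kJ per g nutrient (0 for non energy-yielding nutrients)."""
        return float(self._nutrients.at[nutrient, "energy_factor"])

    def unit(self, nutrient: str) -> str:
        return str(self._nutrients.at[nutrient, "unit"])

    @property
    def frame(self) -> pd.DataFrame:
        return self._dens.copy()


class GHGETable:
    """Per-food GHGE coefficients e_i in kg CO2e per kg food, for one variant.

    The default variant (``"lca"``) holds life-cycle-assessment coefficients
    excluding land-use CO2; the sensitivity variant (``"eeio_landuse"``) holds
    input-output coefficients including land-use emissions.
    """

    def __init__(self, coeffs: pd.Series, variant: str = "lca"):
        coeffs = coeffs.astype(float)
        if (coeffs.to_numpy() < 0).any():
            bad = coeffs.index[coeffs.to_numpy() < 0][0]
            raise ValueError(f"negative GHGE coefficient for food {bad!r}")
        self.coeffs = coeffs
        self.coeffs.index.name = "food_id"
        self.variant = variant

    @property
    def foods(self) -> pd.Index:
        return self.coeffs.index

    def scaled(self, factor: float, variant: str | None = None) -> "GHGETable":
        return GHGETable(self.coeffs * factor, variant or self.variant)


@dataclass
class NutrientProfile:
    """Total daily intakes per nutrient, plus E% shares for energy-yielding ones."""

    intake: pd.Series          # nutrient unit / day
    e_percent: pd.Series       # % of total energy, only energy-yielding nutrients
    energy: float              # kJ/day

    def __getitem__(self, nutrient: str) -> float:
        return float(self.intake[nutrient])

    def check_energy_partition(self, partition: Iterable[str], tol: float = 1.0) -> bool:
        """True when the E% of an exhaustive partition sums to 100 within ``tol`` points."""
        total = float(self.e_percent[list(partition)].sum())
        return abs(total - 100.0) <= tol


# ---------------------------------------------------------------------------
# accounting operations (all linear in the diet vector)
# ---------------------------------------------------------------------------

def _check_index(diet: pd.Series, other: pd.Index, what: str) -> None:
    if not diet.index.equals(other):
        missing = diet.index.difference(other)
        extra = other.difference(diet.index)
        raise ValueError(
            f"diet index does not match {what} "
            f"(missing={list(missing)[:5]}, extra={list(extra)[:5]})"
        )


def compute_energy(diet: pd.Series, comp: CompositionMatrix) -> float:
    """Total dietary energy sum_i c_i x_i in kJ/cap/day."""
    _check_index(diet, comp.foods, "composition matrix")
    return float(comp.energy_density.to_numpy() @ diet.to_numpy())


def compute_nutrients(
    diet: pd.Series,
    comp: CompositionMatrix,
    *,
    zero_energy: str = "error",
) -> NutrientProfile:
    """Nutrient intakes sum_i a_ji x_i and E% shares of the diet.

    E%_j = 100 * k_j * intake_j / energy.  With zero total energy the E% shares
    are undefined; ``zero_energy`` selects ``"error"`` (raise) or ``"zero"``
    (report 0 for every share).
    """
    _check_index(diet, comp.foods, "composition matrix")
    x = diet.to_numpy()
    intakes = pd.Series(
        {j: float(comp.density(j).to_numpy() @ x) for j in comp.nutrient_ids},
        name=diet.name,
    )
    energy = compute_energy(diet, comp)
    energetic = [j for j in comp.nutrient_ids if comp.energy_factor(j) > 0]
    if energy <= 0:
        if any(intakes[j] > 0 for j in energetic) and zero_energy == "error":
            raise ValueError("cannot express E% shares: total energy of the diet is zero")
        shares = pd.Series(0.0, index=energetic)
    else:
        shares = pd.Series(
            {j: 100.0 * comp.energy_factor(j) * intakes[j] / energy for j in energetic}
        )
    return NutrientProfile(intake=intakes, e_percent=shares, energy=energy)


def compute_ghge(diet: pd.Series, ghge: GHGETable) -> float:
    """Dietary GHGE sum_i e_i x_i / 1000 in kg CO2e/cap/day.

    Coefficients are kg CO2e per kg food, consumption g/day, hence the /1000.
    """
    _check_index(diet, ghge.foods, f"GHGE table ({ghge.variant})")
    return float(ghge.coeffs.to_numpy() @ diet.to_numpy()) / 1000.0


def aggregate_diet(diet: pd.Series, table: FoodTable) -> pd.Series:
    """Sum consumption into the main reporting groups; conserves total grams."""
    _check_index(diet, table.ids, "food table")
    agg = diet.groupby(table.aggregation_map).sum()
    return agg.reindex(table.main_groups)


def milk_equivalents(diet: pd.Series, table: FoodTable) -> float:
    """Raw-milk-equivalent grams sum_i m_i x_i of the diet's dairy content."""
    _check_index(diet, table.ids, "food table")
    return float(table.milk_eq.to_numpy() @ diet.to_numpy())


def relative_reduction(baseline: float, new: float) -> float:
    """Fractional reduction (baseline - new) / baseline; positive when new < baseline."""
    if baseline == 0:
        raise ZeroDivisionError("relative reduction undefined for zero baseline")
    return (baseline - new) / baseline
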