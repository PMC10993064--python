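"""Linear constraint system of the diet optimisation model.

Five constraint families are assembled per socio-demographic group and
scenario:

* **energy equality** — total energy fixed at its observed level E0, so every
  simulated diet is isoenergetic with the observed one;
* **nutrient bounds** — minimum recommended/safe and maximum intakes, either
  absolute (unit/day) or as a share of energy (E%), the latter linear because
  E0 is fixed;
* **food-habit boxes** — consumption of each food between the group's 10th and
  90th consumption centiles, enforcing cultural acceptability;
* **GHGE cap** — total emissions at most (1 - r) times the group's observed
  baseline;
* **beef-dairy jointness** — dairy and beef are co-produced (about 33.9 g raw
  milk per g beef carcass in the Finnish dairy chain), so the diet's raw-milk
  demand implies a minimum beef supply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import pandas as pd

from .foods import CompositionMatrix, FoodTable, GHGETable, GroupDiet, compute_ghge
from .optimise import LinearConstraint, QPProblem

if TYPE_CHECKING:  # pragma: no cover
    from .io import DataBundle

__all__ = [
    "RecommendationSet",
    "ScenarioSpec",
    "LinearConstraint",
    "DEFAULT_MILK_PER_BEEF",
    "build_energy_constraint",
    "build_nutrient_constraints",
    "build_food_habit_bounds",
    "build_ghge_cap",
    "build_beef_dairy_constraint",
    "assemble",
]

#: grams of raw milk co-produced with one gram of beef carcass (Finnish dairy chain)
DEFAULT_MILK_PER_BEEF = 33.9

_BOUND_TYPES = ("min", "max")
_FORMS = ("absolute", "energy_percent")


class RecommendationSet:
    """Per-nutrient, per-sex intake bounds.

    Backed by a long-format frame with columns ``nutrient_id, sex, bound_type
    (min|max), form (absolute|energy_percent), value, source, policy``.  The
    ``policy`` column resolves alternative bound levels for the same nutrient:
    rows with an empty policy always apply, rows tagged ``observed`` or
    ``recommended`` apply only under the matching iron policy (the model's
    female iron minimum is 10 mg/d at the observed intake level by default,
    15 mg/d under the recommended level).
    """

    POLICIES = ("observed", "recommended")

    def __init__(self, frame: pd.DataFrame):
        required = {"nutrient_id", "sex", "bound_type", "form", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"recommendations table missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "source" not in frame.columns:
            frame["source"] = ""
        if "policy" not in frame.columns:
            frame["policy"] = ""
        frame["policy"] = frame["policy"].fillna("").astype(str)
        bad = ~frame["bound_type"].isin(_BOUND_TYPES)
        if bad.any():
            raise ValueError(f"invalid bound_type values: {frame.loc[bad, 'bound_type'].unique()}")
        bad = ~frame["form"].isin(_FORMS)
        if bad.any():
            raise ValueError(f"invalid form values: {frame.loc[bad, 'form'].unique()}")
        ep = frame["form"] == "energy_percent"
        if ((frame.loc[ep, "value"] <= 0) | (frame.loc[ep, "value"] >= 100)).any():
            raise ValueError("energy_percent bounds must lie in (0, 100)")
        self._frame = frame
        # L <= U whenever both are set for a nutrient/sex/form under one policy
        for (nut, sex, form, pol), g in frame.groupby(
            ["nutrient_id", "sex", "form", "policy"]
        ):
            mins = g.loc[g.bound_type == "min", "value"]
            maxs = g.loc[g.bound_type == "max", "value"]
            if len(mins) and len(maxs) and float(mins.max()) > float(maxs.min()):
                raise ValueError(f"{nut} ({sex}, {form}): min bound exceeds max bound")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def nutrient_ids(self) -> list[str]:
        return sorted(self._frame["nutrient_id"].unique())

    def bounds_for(self, sex: str, fe_policy: str = "observed") -> pd.DataFrame:
        """Rows applicable to one sex under the given iron policy."""
        if fe_policy not in self.POLICIES:
            raise ValueError(f"fe_policy must be one of {self.POLICIES}, got {fe_policy!r}")
        f = self._frame
        rows = f[(f["sex"] == sex) & (f["policy"].isin(["", fe_policy]))]
        return rows.reset_index(drop=True)


@dataclass(frozen=True)
class ScenarioSpec:
    """One optimisation scenario.

    ``ghge_reduction`` is the fractional cut r of baseline emissions
    (``None`` for the nutrition-only scenario, 1/3 and 1/2 for the standard
    emission-cap scenarios); ``ghge_variant`` selects the coefficient set;
    ``fe_policy`` selects the female iron minimum level.
    """

    name: str
    ghge_reduction: float | None = None
    include_beef_dairy: bool = True
    fe_policy: str = "observed"
    ghge_variant: str = "lca"

    def __post_init__(self) -> None:
        r = self.ghge_reduction
        if r is not None and not (0.0 <= r < 1.0):
            raise ValueError(f"ghge_reduction must be in [0, 1), got {r}")
        if self.fe_policy not in RecommendationSet.POLICIES:
            raise ValueError(f"invalid fe_policy {self.fe_policy!r}")

    def with_(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


#: the three study scenarios: nutritional adequacy alone, then increasingly
#: stringent emission caps at one third and one half of current levels
STANDARD_SCENARIOS = (
    ScenarioSpec("nutrition_only"),
    ScenarioSpec("ghge_minus_33", ghge_reduction=1.0 / 3.0),
    ScenarioSpec("ghge_minus_50", ghge_reduction=0.5),
)


def load_scenarios(path) -> tuple[ScenarioSpec, ...]:
    """Read scenario specs from a YAML file.

    The file holds a list of mappings with a required ``name`` and optional
    ``ghge_reduction``, ``include_beef_dairy``, ``fe_policy`` and
    ``ghge_variant`` keys, e.g.::

        - name: nutrition_only
        - name: ghge_minus_40
          ghge_reduction: 0.4
          ghge_variant: eeio_landuse
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a YAML list of scenario mappings")
    specs = []
    for entry in raw:
        if not isinstance(entry, dict) or "name" not in entry:
            raise ValueError(f"{path}: each scenario needs at least a 'name' key")
        allowed = {"name", "ghge_reduction", "include_beef_dairy", "fe_policy",
                   "ghge_variant"}
        unknown = set(entry) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown scenario key(s) {sorted(unknown)}")
        specs.append(ScenarioSpec(**entry))
    return tuple(specs)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_energy_constraint(group: GroupDiet, comp: CompositionMatrix) -> LinearConstraint:
    """Isoenergetic constraint sum_i c_i x_i = E0 at the observed energy level."""
    if group.energy_obs <= 0:
        raise ValueError(f"{group.group_id}: observed energy must be positive")
    return LinearConstraint(comp.energy_density, "=", float(group.energy_obs), "energy")


def build_nutrient_constraints(
    recs: RecommendationSet,
    comp: CompositionMatrix,
    energy_obs: float,
    sex: str,
    fe_policy: str = "observed",
) -> list[LinearConstraint]:
    """Min/max intake constraints for one sex.

    Absolute form:        sum_j a_ji x_i  >=/<= value.
    Energy-percent form:  k_j sum_j a_ji x_i >=/<= (value/100) * E0, linear
    because E0 is fixed by the energy constraint.
    """
    out: list[LinearConstraint] = []
    for _, row in recs.bounds_for(sex, fe_policy).iterrows():
        nut = row["nutrient_id"]
        if nut not in comp.frame.columns:
            raise KeyError(f"recommended nutrient {nut!r} absent from composition matrix")
        a = comp.density(nut)
        sense = ">=" if row["bound_type"] == "min" else "<="
        if row["form"] == "absolute":
            coeffs, rhs = a, float(row["value"])
        else:
            k = comp.energy_factor(nut)
            if k <= 0:
                raise ValueError(
                    f"{nut}: energy_percent bound requires a positive energy factor"
                )
            coeffs, rhs = k * a, float(row["value"]) / 100.0 * energy_obs
        out.append(LinearConstraint(coeffs, sense, rhs, f"nut:{nut}:{row['bound_type']}"))
    return out


def build_food_habit_bounds(group: GroupDiet) -> tuple[pd.Series, pd.Series]:
    """Per-food box p10_i <= x_i <= p90_i (foods with p10 = p90 end up fixed)."""
    return group.p10.copy(), group.p90.copy()


def build_ghge_cap(
    ghge: GHGETable, group: GroupDiet, reduction: float
) -> LinearConstraint:
    """Emission cap sum_i e_i x_i / 1000 <= (1 - r) * baseline.

    The baseline is the GHGE of the group's observed mean diet computed with
    the same coefficient variant, so relative caps are consistent across
    coefficient sets.
    """
    if not (0.0 <= reduction < 1.0):
        raise ValueError(f"reduction must be in [0, 1), got {reduction}")
    baseline = compute_ghge(group.mean, ghge)
    return LinearConstraint(
        ghge.coeffs / 1000.0, "<=", (1.0 - reduction) * baseline, "ghge_cap"
    )


def build_beef_dairy_constraint(
    table: FoodTable, milk_per_beef: float = DEFAULT_MILK_PER_BEEF
) -> LinearConstraint:
    """Co-production floor: rho * (beef carcass in diet) >= raw-milk equivalents.

    With rho grams of raw milk per gram of beef carcass, the constraint
    ``rho * sum_i b_i x_i - sum_i m_i x_i >= 0`` keeps the diet's implied
    beef-to-dairy ratio at or above the production system's minimum.
    """
    if milk_per_beef <= 0:
        raise ValueError("milk_per_beef must be positive")
    b = table.beef_content
    m = table.milk_eq
    if (b.to_numpy() == 0).all() and (m.to_numpy() > 0).any():
        warnings.warn(
            "no food carries beef content while dairy foods are present: the "
            "beef-dairy constraint can only be satisfied with zero dairy",
            stacklevel=2,
        )
    return LinearConstraint(milk_per_beef * b - m, ">=", 0.0, "beef_dairy")


def assemble(
    group: GroupDiet,
    scenario: ScenarioSpec,
    bundle: "DataBundle",
    milk_per_beef: float = DEFAULT_MILK_PER_BEEF,
) -> QPProblem:
    """Assemble the full QP for one group under one scenario.

    Decision foods are those with a positive observed mean and a
    non-degenerate habit box; the rest are fixed at their (unique or zero)
    habit level and folded into the constraint right-hand sides at solve time.
    """
    comp = bundle.composition
    lo, hi = build_food_habit_bounds(group)
    decision = (group.mean > 0) & (lo < hi)
    fixed = lo[~decision]

    cons: list[LinearConstraint] = [build_energy_constraint(group, comp)]
    cons.extend(
        build_nutrient_constraints(
            bundle.recommendations, comp, group.energy_obs, group.sex, scenario.fe_policy
        )
    )
    if scenario.ghge_reduction is not None:
        ghge = bundle.ghge[scenario.ghge_variant]
        cons.append(build_ghge_cap(ghge, group, scenario.ghge_reduction))
    if scenario.include_beef_dairy:
        cons.append(build_beef_dairy_constraint(bundle.foods, milk_per_beef))

    return QPProblem(
        anchor=group.mean[decision],
        lower=lo[decision],
        upper=hi[decision],
        constraints=cons,
        fixed=fixed,
    )
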