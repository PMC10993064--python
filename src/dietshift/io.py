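"""CSV dataset reading/writing and cross-validation.

A dataset directory holds seven UTF-8 CSV files ("." decimal point):

==================  =========================================================
foods.csv           id, name, main_group, milk_eq, beef_content
group_diets.csv     group_id, food_id, mean, p10, p90          (g/cap/day)
energy.csv          group_id, energy_kj                        (kJ/cap/day)
composition.csv     food_id, nutrient_id, density              (unit per g;
                    nutrient_id "energy" carries kJ/g)
nutrients.csv       nutrient_id, unit, energy_factor           (kJ/g nutrient)
ghge.csv            food_id, variant, coeff                    (kg CO2e/kg)
recommendations.csv nutrient_id, sex, bound_type, form, value, source, policy
==================  =========================================================

:func:`read_dataset` cross-validates the files (consistent food and nutrient
id sets across tables, every diet group present in energy.csv, both GHGE
variants covering all foods) and returns an immutable :class:`DataBundle`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import pandas as pd

from .constraints import RecommendationSet
from .foods import (
    CompositionMatrix,
    FoodCategory,
    FoodTable,
    GHGETable,
    GroupDiet,
)

__all__ = ["DataBundle", "LoadError", "read_dataset", "write_bundle"]

FILES = {
    "foods": "foods.csv",
    "diets": "group_diets.csv",
    "energy": "energy.csv",
    "composition": "composition.csv",
    "nutrients": "nutrients.csv",
    "ghge": "ghge.csv",
    "recommendations": "recommendations.csv",
}

_SCHEMAS = {
    "foods": ["id", "name", "main_group", "milk_eq", "beef_content"],
    "diets": ["group_id", "food_id", "mean", "p10", "p90"],
    "energy": ["group_id", "energy_kj"],
    "composition": ["food_id", "nutrient_id", "density"],
    "nutrients": ["nutrient_id", "unit", "energy_factor"],
    "ghge": ["food_id", "variant", "coeff"],
    "recommendations": ["nutrient_id", "sex", "bound_type", "form", "value"],
}


class LoadError(ValueError):
    """Schema violation or cross-reference failure while reading a dataset."""


@dataclass(frozen=True)
class DataBundle:
    """Immutable, cross-validated dataset for the optimisation pipeline."""

    foods: FoodTable
    diets: Mapping[str, GroupDiet]
    composition: CompositionMatrix
    ghge: Mapping[str, GHGETable]
    recommendations: RecommendationSet

    def __post_init__(self) -> None:
        object.__setattr__(self, "diets", MappingProxyType(dict(self.diets)))
        object.__setattr__(self, "ghge", MappingProxyType(dict(self.ghge)))

    @property
    def group_ids(self) -> list[str]:
        return list(self.diets)

    def group(self, group_id: str) -> GroupDiet:
        try:
            return self.diets[group_id]
        except KeyError:
            raise KeyError(
                f"unknown group {group_id!r}; available: {self.group_ids}"
            ) from None


def _read(path: Path, key: str) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"missing dataset file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"{path.name}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _SCHEMAS[key] if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing column(s) {missing}")
    return df


def read_dataset(directory: str | Path) -> DataBundle:
    """Load and cross-validate a dataset directory into a :class:`DataBundle`."""
    d = Path(directory)
    foods_df = _read(d / FILES["foods"], "foods")
    try:
        foods = FoodTable(
            FoodCategory(
                id=str(r.id),
                name=str(r.name),
                main_group=str(r.main_group),
                milk_eq=float(r.milk_eq),
                beef_content=float(r.beef_content),
            )
            for r in foods_df.itertuples()
        )
    except ValueError as exc:
        raise LoadError(f"foods.csv: {exc}") from exc
    food_ids = foods.ids

    nut_df = _read(d / FILES["nutrients"], "nutrients").set_index("nutrient_id")
    comp_df = _read(d / FILES["composition"], "composition")
    dens = comp_df.pivot_table(
        index="food_id", columns="nutrient_id", values="density", fill_value=0.0
    )
    missing = food_ids.difference(dens.index)
    if len(missing):
        raise LoadError(f"composition.csv: no rows for food id(s) {sorted(missing)[:5]}")
    extra = dens.index.difference(food_ids)
    if len(extra):
        raise LoadError(f"composition.csv: unknown food id(s) {sorted(extra)[:5]}")
    try:
        comp = CompositionMatrix(dens.reindex(food_ids), nut_df)
    except ValueError as exc:
        raise LoadError(f"composition.csv: {exc}") from exc

    ghge_df = _read(d / FILES["ghge"], "ghge")
    ghge: dict[str, GHGETable] = {}
    for variant, g in ghge_df.groupby("variant"):
        s = g.set_index("food_id")["coeff"]
        missing = food_ids.difference(s.index)
        if len(missing):
            raise LoadError(
                f"ghge.csv: variant {variant!r} missing food id(s) {sorted(missing)[:5]}"
            )
        extra = s.index.difference(food_ids)
        if len(extra):
            raise LoadError(f"ghge.csv: unknown food id(s) {sorted(extra)[:5]}")
        try:
            ghge[str(variant)] = GHGETable(s.reindex(food_ids), str(variant))
        except ValueError as exc:
            raise LoadError(f"ghge.csv ({variant}): {exc}") from exc

    energy_df = _read(d / FILES["energy"], "energy").set_index("group_id")
    diets_df = _read(d / FILES["diets"], "diets")
    diets: dict[str, GroupDiet] = {}
    for gid, g in diets_df.groupby("group_id", sort=False):
        g = g.set_index("food_id")
        missing = food_ids.difference(g.index)
        if len(missing):
            raise LoadError(
                f"group_diets.csv: group {gid!r} missing food id(s) {sorted(missing)[:5]}"
            )
        extra = g.index.difference(food_ids)
        if len(extra):
            raise LoadError(f"group_diets.csv: unknown food id(s) {sorted(extra)[:5]}")
        if gid not in energy_df.index:
            raise LoadError(f"energy.csv: no observed energy for group {gid!r}")
        g = g.reindex(food_ids)
        try:
            diets[str(gid)] = GroupDiet(
                group_id=str(gid),
                mean=g["mean"],
                p10=g["p10"],
                p90=g["p90"],
                energy_obs=float(energy_df.at[gid, "energy_kj"]),
            )
        except ValueError as exc:
            raise LoadError(f"group_diets.csv: {exc}") from exc

    rec_df = _read(d / FILES["recommendations"], "recommendations")
    try:
        recs = RecommendationSet(rec_df)
    except ValueError as exc:
        raise LoadError(f"recommendations.csv: {exc}") from exc
    for nut in recs.nutrient_ids:
        if nut not in comp.frame.columns:
            raise LoadError(
                f"recommendations.csv: nutrient {nut!r} absent from composition.csv"
            )

    return DataBundle(
        foods=foods, diets=diets, composition=comp, ghge=ghge, recommendations=recs
    )


def write_bundle(bundle: DataBundle, directory: str | Path) -> dict[str, str]:
    """Write a bundle back to the CSV schemas; returns file -> sha256 digests."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"

    foods = bundle.foods.frame.reset_index().rename(columns={"food_id": "id"})
    foods.to_csv(d / FILES["foods"], index=False, float_format=fmt)

    rows = []
    energies = []
    for gid, diet in bundle.diets.items():
        f = pd.DataFrame({"mean": diet.mean, "p10": diet.p10, "p90": diet.p90})
        f.insert(0, "group_id", gid)
        rows.append(f.reset_index())
        energies.append({"group_id": gid, "energy_kj": diet.energy_obs})
    pd.concat(rows).to_csv(d / FILES["diets"], index=False, float_format=fmt)
    pd.DataFrame(energies).to_csv(d / FILES["energy"], index=False, float_format=fmt)

    comp_long = (
        bundle.composition.frame.stack()
        .rename_axis(["food_id", "nutrient_id"])
        .rename("density")
        .reset_index()
    )
    comp_long = comp_long[comp_long["density"] != 0.0]
    comp_long.to_csv(d / FILES["composition"], index=False, float_format=fmt)
    bundle.composition.nutrients.reset_index().rename(
        columns={"index": "nutrient_id"}
    ).to_csv(d / FILES["nutrients"], index=False, float_format=fmt)

    ghge_rows = []
    for variant, table in bundle.ghge.items():
        f = table.coeffs.rename("coeff").reset_index()
        f.insert(1, "variant", variant)
        ghge_rows.append(f)
    pd.concat(ghge_rows).to_csv(d / FILES["ghge"], index=False, float_format=fmt)

    bundle.recommendations.frame.to_csv(
        d / FILES["recommendations"], index=False, float_format=fmt
    )

    digests = {}
    for name in FILES.values():
        digests[name] = hashlib.sha256((d / name).read_bytes()).hexdigest()
    return digests
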