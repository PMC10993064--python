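"""Scenario grid runner and reporting tables.

Runs the three study scenarios (nutritional adequacy only, then emission caps
at one third and one half of current levels) over the socio-demographic
groups, and renders the study-style reports: per-group GHGE of current and
optimised diets, per-category adjustment tables, and binding-constraint
reports with duals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .constraints import DEFAULT_MILK_PER_BEEF, STANDARD_SCENARIOS, ScenarioSpec
from .foods import NutrientProfile
from .io import DataBundle, write_bundle
from .model import DietProblem

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "run_all",
    "report_changes",
    "binding_report",
    "summary_table",
    "write_results",
]

log = logging.getLogger("dietshift")


@dataclass
class ScenarioResult:
    """Outcome of one (group, scenario) optimisation run.

    Summaries are recomputed from the optimised diet at construction so that
    stored values and the diet always agree exactly.
    """

    group_id: str
    scenario: ScenarioSpec
    status: str
    baseline_diet: pd.Series
    baseline_ghge: float
    baseline_energy: float
    baseline_nutrients: NutrientProfile
    baseline_milk_eq: float
    diet: pd.Series | None = None
    ghge: float | None = None
    energy: float | None = None
    nutrients: NutrientProfile | None = None
    milk_eq: float | None = None
    objective: float | None = None
    changes: pd.DataFrame | None = None
    duals: pd.Series | None = None
    slacks: pd.Series | None = None
    active: pd.Series | None = None
    kkt_residual: float | None = None
    diagnosis: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def ghge_cap(self) -> float | None:
        r = self.scenario.ghge_reduction
        return None if r is None else (1.0 - r) * self.baseline_ghge


def run_scenario(
    bundle: DataBundle,
    group_id: str,
    spec: ScenarioSpec,
    milk_per_beef: float = DEFAULT_MILK_PER_BEEF,
    tol: float = 1e-9,
) -> ScenarioResult:
    """Assemble, solve and summarise one group x scenario run.

    Infeasible or numerically failed runs are returned flagged with a
    diagnosis, never silently skipped.
    """
    model = DietProblem(bundle, group_id, spec, milk_per_beef)
    group = model.group
    baseline_nutrients = _nutrients(bundle, group.mean)
    base = dict(
        group_id=group.group_id,
        scenario=spec,
        baseline_diet=group.mean,
        baseline_ghge=model.baseline_ghge(),
        baseline_energy=float(
            bundle.composition.energy_density.to_numpy() @ group.mean.to_numpy()
        ),
        baseline_nutrients=baseline_nutrients,
        baseline_milk_eq=float(
            bundle.foods.milk_eq.to_numpy() @ group.mean.to_numpy()
        ),
    )
    result = model.fit(tol=tol)
    if not result.optimal:
        log.warning("%s / %s: %s", group.group_id, spec.name, result.status)
        return ScenarioResult(status=result.status,
                              diagnosis=result.solution.diagnosis, **base)
    log.info(
        "%s / %s: optimal, objective %.4f, GHGE %.2f -> %.2f",
        group.group_id, spec.name, result.objective, base["baseline_ghge"],
        result.ghge(),
    )
    return ScenarioResult(
        status="optimal",
        diet=result.params,
        ghge=result.ghge(),
        energy=result.energy,
        nutrients=result.nutrients(),
        milk_eq=result.milk_equivalents(),
        objective=result.objective,
        changes=result.changes(),
        duals=result.duals,
        slacks=result.solution.slacks,
        active=result.solution.active,
        kkt_residual=result.kkt["max_residual"],
        **base,
    )


def _nutrients(bundle: DataBundle, diet: pd.Series) -> NutrientProfile:
    from .foods import compute_nutrients

    return compute_nutrients(diet, bundle.composition)


def run_all(
    bundle: DataBundle,
    groups: list[str] | None = None,
    specs: tuple[ScenarioSpec, ...] = STANDARD_SCENARIOS,
    milk_per_beef: float = DEFAULT_MILK_PER_BEEF,
) -> list[ScenarioResult]:
    """Map :func:`run_scenario` over the group x scenario grid.

    Failures are collected in the returned results (``status != "optimal"``),
    so a partial failure never aborts the grid.
    """
    groups = list(bundle.group_ids) if groups is None else groups
    return [
        run_scenario(bundle, gid, spec, milk_per_beef)
        for gid in groups
        for spec in specs
    ]


def report_changes(result: ScenarioResult) -> pd.DataFrame:
    """Per-main-category adjustment table of one optimal run.

    Rows: the main reporting groups, a raw-milk-equivalent dairy row and a
    grand total; columns: baseline and optimised g/cap/day, absolute change
    and percent change (NaN where the baseline is zero).
    """
    if not result.optimal:
        raise ValueError(f"run {result.group_id}/{result.scenario.name} is {result.status}")
    return result.changes.copy()


def binding_report(result: ScenarioResult, tol: float = 1e-7) -> pd.DataFrame:
    """Active constraints of an optimal run, with duals and slacks."""
    if not result.optimal:
        raise ValueError(f"run {result.group_id}/{result.scenario.name} is {result.status}")
    f = pd.DataFrame(
        {"slack": result.slacks, "dual": result.duals, "active": result.active}
    )
    f.index.name = "constraint"
    return f[f["active"]]


def summary_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format per-run summary (one row per group x scenario)."""
    rows = []
    for r in results:
        rows.append(
            {
                "group_id": r.group_id,
                "scenario": r.scenario.name,
                "status": r.status,
                "objective": r.objective,
                "baseline_ghge": r.baseline_ghge,
                "ghge": r.ghge,
                "ghge_cap": r.ghge_cap,
                "baseline_energy": r.baseline_energy,
                "energy": r.energy,
                "baseline_milk_eq": r.baseline_milk_eq,
                "milk_eq": r.milk_eq,
                "kkt_residual": r.kkt_residual,
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: list[ScenarioResult],
    outdir: str | Path,
    bundle: DataBundle | None = None,
) -> None:
    """Write deterministic long-format CSV reports plus a JSON manifest.

    ``summary.csv`` (one row per run), ``changes.csv`` (per category),
    ``constraints.csv`` (per constraint with slack/dual/active) and
    ``manifest.json`` (run grid and, when the bundle is given, sha256 digests
    of its CSV serialisation).  Output is byte-reproducible for identical
    inputs: fixed float formatting, fixed ordering, no timestamps.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    summary_table(results).to_csv(out / "summary.csv", index=False, float_format=fmt)

    ch_rows = []
    con_rows = []
    for r in results:
        if not r.optimal:
            continue
        ch = r.changes.reset_index()
        ch.insert(0, "scenario", r.scenario.name)
        ch.insert(0, "group_id", r.group_id)
        ch_rows.append(ch)
        con = pd.DataFrame(
            {"slack": r.slacks, "dual": r.duals, "active": r.active}
        ).reset_index(names="constraint")
        con.insert(0, "scenario", r.scenario.name)
        con.insert(0, "group_id", r.group_id)
        con_rows.append(con)
    (pd.concat(ch_rows) if ch_rows else pd.DataFrame()).to_csv(
        out / "changes.csv", index=False, float_format=fmt
    )
    (pd.concat(con_rows) if con_rows else pd.DataFrame()).to_csv(
        out / "constraints.csv", index=False, float_format=fmt
    )
    manifest = {
        "runs": [
            {"group_id": r.group_id, "scenario": r.scenario.name, "status": r.status}
            for r in results
        ],
    }
    if bundle is not None:
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            manifest["input_digests"] = write_bundle(bundle, tmp)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
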