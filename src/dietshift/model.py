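"""Model/Results interface to the diet optimisation QP.

:class:`DietProblem` binds a dataset bundle, a socio-demographic group and a
:class:`~dietshift.constraints.ScenarioSpec` into a fitted-model workflow in
the statsmodels style: ``DietProblem(bundle, "male/all", scenario).fit()``
returns a :class:`DietResult` carrying the optimised diet, constraint duals,
KKT diagnostics and summary tables.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .constraints import DEFAULT_MILK_PER_BEEF, ScenarioSpec, assemble
from .foods import (
    GroupDiet,
    NutrientProfile,
    aggregate_diet,
    compute_energy,
    compute_ghge,
    compute_nutrients,
    milk_equivalents,
)
from .optimise import QPProblem, Solution, solve

if TYPE_CHECKING:  # pragma: no cover
    from .io import DataBundle

__all__ = ["DietProblem", "DietResult"]


class DietProblem:
    """Diet optimisation model for one group under one scenario."""

    def __init__(
        self,
        bundle: "DataBundle",
        group: str | GroupDiet,
        scenario: ScenarioSpec,
        milk_per_beef: float = DEFAULT_MILK_PER_BEEF,
    ):
        self.bundle = bundle
        self.group = bundle.group(group) if isinstance(group, str) else group
        self.scenario = scenario
        self.milk_per_beef = milk_per_beef
        self._qp: QPProblem | None = None

    @classmethod
    def from_dataset(cls, directory, group: str, scenario: ScenarioSpec,
                     **kwargs) -> "DietProblem":
        from .io import read_dataset

        return cls(read_dataset(directory), group, scenario, **kwargs)

    @property
    def qp(self) -> QPProblem:
        if self._qp is None:
            self._qp = assemble(self.group, self.scenario, self.bundle,
                                self.milk_per_beef)
        return self._qp

    @property
    def ghge_table(self):
        return self.bundle.ghge[self.scenario.ghge_variant]

    def baseline_ghge(self) -> float:
        return compute_ghge(self.group.mean, self.ghge_table)

    def fit(self, tol: float = 1e-9) -> "DietResult":
        """Solve the QP and wrap the outcome in a :class:`DietResult`."""
        solution = solve(self.qp, tol=tol)
        return DietResult(self, solution)


class DietResult:
    """Optimised diet with uncertainty-free point estimates and diagnostics.

    ``params`` is the optimised consumption vector in g/cap/day over all
    foods (decision and fixed).  Duals carry the marginal objective cost of
    each binding constraint.
    """

    def __init__(self, model: DietProblem, solution: Solution):
        self.model = model
        self.solution = solution

    # -- core accessors -----------------------------------------------------

    @property
    def status(self) -> str:
        return self.solution.status

    @property
    def optimal(self) -> bool:
        return self.solution.optimal

    def _require_optimal(self):
        if not self.optimal:
            raise ValueError(
                f"no optimal solution ({self.status}): {self.solution.diagnosis}"
            )

    @property
    def params(self) -> pd.Series:
        self._require_optimal()
        return self.solution.x.reindex(self.model.bundle.foods.ids)

    @property
    def objective(self) -> float:
        self._require_optimal()
        return float(self.solution.objective)

    @property
    def duals(self) -> pd.Series:
        self._require_optimal()
        return self.solution.duals

    @property
    def kkt(self) -> dict:
        self._require_optimal()
        return self.solution.kkt

    # -- derived summaries --------------------------------------------------

    @property
    def energy(self) -> float:
        return compute_energy(self.params, self.model.bundle.composition)

    def ghge(self, variant: str | None = None) -> float:
        table = (
            self.model.bundle.ghge[variant]
            if variant is not None
            else self.model.ghge_table
        )
        return compute_ghge(self.params, table)

    def nutrients(self) -> NutrientProfile:
        return compute_nutrients(self.params, self.model.bundle.composition)

    def milk_equivalents(self) -> float:
        return milk_equivalents(self.params, self.model.bundle.foods)

    def changes(self) -> pd.DataFrame:
        """Per-main-category dietary adjustment table.

        Columns: baseline and optimised g/cap/day, absolute change ``delta``
        and ``percent`` change (NaN where the baseline is zero, reported as
        "n/a" in formatted output).  A ``milk_eq`` row aggregates dairy in
        raw-milk equivalents and a ``total`` row sums grams.
        """
        self._require_optimal()
        foods = self.model.bundle.foods
        base = aggregate_diet(self.model.group.mean, foods)
        new = aggregate_diet(self.params, foods)
        out = pd.DataFrame({"baseline": base, "optimised": new})
        me_base = milk_equivalents(self.model.group.mean, foods)
        me_new = self.milk_equivalents()
        out.loc["milk_eq"] = [me_base, me_new]
        out.loc["total"] = [base.sum(), new.sum()]
        out["delta"] = out["optimised"] - out["baseline"]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * out["delta"] / out["baseline"]
        out["percent"] = pct.where(out["baseline"] > 0)
        out.index.name = "category"
        return out

    def binding_constraints(self, tol: float = 1e-7) -> pd.DataFrame:
        """Active constraints (|slack| <= tol, equalities always) with duals."""
        self._require_optimal()
        f = pd.DataFrame(
            {
                "slack": self.solution.slacks,
                "dual": self.solution.duals,
                "active": self.solution.active,
            }
        )
        f.index.name = "constraint"
        return f[f["active"]]

    def summary(self) -> str:
        """Human-readable run report."""
        m = self.model
        lines = [
            "Diet optimisation result",
            "========================",
            f"group:      {m.group.group_id}",
            f"scenario:   {m.scenario.name} "
            f"(r={m.scenario.ghge_reduction}, variant={m.scenario.ghge_variant}, "
            f"beef_dairy={m.scenario.include_beef_dairy}, fe={m.scenario.fe_policy})",
            f"status:     {self.status}",
        ]
        if not self.optimal:
            lines.append(f"diagnosis:  {self.solution.diagnosis}")
            return "\n".join(lines)
        base_ghge = m.baseline_ghge()
        lines += [
            f"objective:  {self.objective:.6f} (sum of squared relative deviations)",
            f"energy:     {self.energy:,.0f} kJ/cap/day (observed {m.group.energy_obs:,.0f})",
            f"GHGE:       {base_ghge:.2f} -> {self.ghge():.2f} kg CO2e/cap/day "
            f"({100 * (self.ghge() / base_ghge - 1):+.1f} %)",
            f"KKT:        max residual {self.kkt['max_residual']:.2e}",
            "",
            "Dietary adjustments by main category (g/cap/day):",
        ]
        ch = self.changes()
        pct = ch["percent"].map(lambda v: "n/a" if pd.isna(v) else f"{v:+.1f} %")
        tab = ch.assign(percent=pct)
        lines.append(tab.to_string(float_format=lambda v: f"{v:10.1f}"))
        lines.append("")
        lines.append("Binding constraints:")
        b = self.binding_constraints()
        lines.append(
            b.to_string(float_format=lambda v: f"{v:12.4g}") if len(b) else "  none"
        )
        return "\n".join(lines)
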