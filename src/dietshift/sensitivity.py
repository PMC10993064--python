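"""Sensitivity analyses as scenario-spec transformations.

Three registered variants probe the model's key assumptions:

* ``ghge_landuse`` — swap the LCA emission coefficients (which exclude
  land-use CO2) for input-output coefficients that include land-use
  emissions; the diet data are untouched and the relative cap is recomputed
  against the variant's own baseline;
* ``no_beef_dairy`` — drop the beef-dairy co-production constraint,
  relaxing the assumption of perfectly inelastic excess beef demand;
* ``fe_recommended`` — raise the female iron minimum from its observed
  intake level (10 mg/cap/day) to the recommended level for pre-menopausal
  women (15 mg/cap/day).

Variants are composable: applying several in sequence yields their joint
spec, although the study applies them singly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .constraints import ScenarioSpec
from .scenarios import ScenarioResult

__all__ = ["SensitivityVariant", "VARIANTS", "apply_variant", "compare_runs"]


@dataclass(frozen=True)
class SensitivityVariant:
    """A named set of ScenarioSpec field overrides."""

    name: str
    deltas: Mapping[str, object]


VARIANTS: dict[str, SensitivityVariant] = {
    v.name: v
    for v in (
        SensitivityVariant("ghge_landuse", {"ghge_variant": "eeio_landuse"}),
        SensitivityVariant("no_beef_dairy", {"include_beef_dairy": False}),
        SensitivityVariant("fe_recommended", {"fe_policy": "recommended"}),
    )
}


def apply_variant(spec: ScenarioSpec, variant: str | SensitivityVariant) -> ScenarioSpec:
    """Apply one sensitivity variant to a base scenario spec."""
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise KeyError(
                f"unknown sensitivity variant {variant!r}; registered: {sorted(VARIANTS)}"
            ) from None
    return spec.with_(name=f"{spec.name}+{variant.name}", **dict(variant.deltas))


def compare_runs(base: ScenarioResult, variant: ScenarioResult) -> pd.DataFrame:
    """Side-by-side category table for a base run and a sensitivity run.

    Requires both runs to be optimal and to concern the same group.  Rows are
    the main categories plus milk-equivalent and total rows; columns give the
    optimised quantities under each assumption and their difference.  The
    frame's ``attrs`` carry the baseline-GHGE ratio (variant / base, e.g.
    ~1.22 when land-use emissions are included for an average male) and the
    two objective values.
    """
    if base.group_id != variant.group_id:
        raise ValueError(
            f"cannot compare runs of different groups: "
            f"{base.group_id!r} vs {variant.group_id!r}"
        )
    for r in (base, variant):
        if not r.optimal:
            raise ValueError(f"run {r.group_id}/{r.scenario.name} is {r.status}")
    out = pd.DataFrame(
        {
            "baseline": base.changes["baseline"],
            base.scenario.name: base.changes["optimised"],
            variant.scenario.name: variant.changes["optimised"],
        }
    )
    out["difference"] = out[variant.scenario.name] - out[base.scenario.name]
    out.attrs["baseline_ghge_ratio"] = variant.baseline_ghge / base.baseline_ghge
    out.attrs["objective_base"] = base.objective
    out.attrs["objective_variant"] = variant.objective
    return out
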