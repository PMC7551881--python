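"""Per-variable efficiency indices from optimal frontier projections.

Each index compares a variable's frontier target with its observation, per
DMU and period. For inputs, undesirable outputs and input-kind links the
target is ``observed - slack`` and the index is target/actual; for
desirable outputs the target is ``observed + slack`` and the index is
actual/target. Either way the index lies in (0, 1] and equals 1 exactly
when the corresponding slack vanishes.

The default mapping names the eight indices of the two-stage
wastewater -> health application: labor, water consumption and treatment
expense (inputs); GDP and treatment capacity (desirable outputs);
wastewater, COD and the number of water diseases (undesirable quantities,
COD being the inter-stage link whose index is computed from the link
slack).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .panel import PanelDataset, PanelError
from .solver import SolveResult

#: index name -> variable name for the two-stage study schema
DEFAULT_INDEX_MAP: dict[str, str] = {
    "labor": "labor",
    "water_consumption": "water_consumption",
    "treatment_expense": "treatment_expense",
    "gdp": "gdp",
    "treatment_capacity": "treatment_capacity",
    "wastewater": "wastewater",
    "cod": "cod",
    "water_diseases": "water_diseases",
}


@dataclass
class EfficiencyIndices:
    """Index values per (dmu, period, index name), with a flag marking
    observations whose actual value had been zero-repaired."""

    dmu: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def value(self, index_name: str, period: str) -> float:
        sel = self.table[(self.table["index_name"] == index_name)
                         & (self.table["period"] == period)]
        return float(sel["value"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_indices(
    result: SolveResult,
    ds: PanelDataset,
    variable_map: dict[str, str] | None = None,
) -> EfficiencyIndices:
    """Evaluate the target/actual ratio indices at a DMU's optimal slacks.

    ``variable_map`` maps index names to schema variable names (defaults to
    the two-stage study mapping restricted to variables present in the
    schema). The slack used for each index is the one attached to the
    variable's declared role.
    """
    if variable_map is None:
        names = {s.name for s in ds.specs}
        variable_map = {k: v for k, v in DEFAULT_INDEX_MAP.items() if v in names}
    repaired = {(r.dmu, r.variable, r.period) for r in ds.repairs}

    rows = []
    for index_name, var in variable_map.items():
        spec = ds.spec(var)  # raises PanelError when the mapping is stale
        if spec.role == "carryover":
            raise PanelError(
                f"index {index_name!r}: carry-over {var!r} has per-transition "
                "slacks, not per-period indices")
        for period in ds.periods:
            actual = ds.value(result.dmu, var, period)
            slack = result.slacks.get((var, period), 0.0)
            if spec.role == "desirable_output":
                value = actual / (actual + slack)
            else:  # input, undesirable_output, link
                value = (actual - slack) / actual
            rows.append({
                "dmu": result.dmu,
                "period": period,
                "index_name": index_name,
                "value": min(1.0, max(0.0, value)),
                "zero_repaired": (result.dmu, var, period) in repaired,
            })
    return EfficiencyIndices(dmu=result.dmu, table=pd.DataFrame(rows))
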