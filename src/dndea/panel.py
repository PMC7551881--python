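"""Panel data model for dynamic network DEA.

A panel records, for every decision-making unit (DMU), a set of variables
observed in every period. Each variable belongs to one internal division of
the DMU and plays one of five roles:

``input``
    resource consumed by the division (less is better);
``desirable_output``
    valued product of the division (more is better);
``undesirable_output``
    unwanted by-product, e.g. pollution (less is better);
``link``
    quantity passed from one division to another within a period;
``carryover``
    quantity a division transmits from period *t* to *t+1*; observed per
    adjacent-period transition rather than per period.

Links and carry-overs additionally carry a *kind* that decides how the
frontier treats them: an input-kind link/carry-over is a cost whose slack
counts against efficiency; a good-kind carry-over is an asset; free kinds
are discretionary (signed slack); fix kinds are non-discretionary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROLES = ("input", "desirable_output", "undesirable_output", "link", "carryover")
LINK_KINDS = ("fix", "free", "in")
CARRYOVER_KINDS = ("input", "good", "free", "fix")
REGIONS = ("eastern", "central", "western", "northeastern")

#: relative LP feasibility/optimality tolerance handed to the solver
LP_TOLERANCE = 1e-9
#: absolute tolerance for comparing efficiency scores
SCORE_TOLERANCE = 1e-6
#: a DMU counts as efficient when its largest relative slack is below this
EFFICIENT_TOLERANCE = 1e-7
#: zero observations are replaced by this fraction of the within-period mean
ZERO_REPAIR_FRACTION = 1e-6
#: dynamic range above which a conditioning warning is attached to a variable
CONDITIONING_RANGE = 1e6


class PanelError(ValueError):
    """Raised for schema or completeness violations in a panel."""


@dataclass(frozen=True)
class VariableSpec:
    """Declares one model variable: its division, role and (for links and
    carry-overs) its kind.

    Parameters
    ----------
    name : str
        Variable identifier, unique within a schema.
    division : int
        1-based index of the division the variable belongs to.
    role : str
        One of :data:`ROLES`.
    link_kind : str, optional
        ``fix`` | ``free`` | ``in``; required iff ``role == "link"``.
    carryover_kind : str, optional
        ``input`` | ``good`` | ``free`` | ``fix``; required iff
        ``role == "carryover"``.
    target_division : int, optional
        Destination division of a link; required iff ``role == "link"`` and
        must differ from ``division``.
    units : str
        Free-text unit annotation.
    """

    name: str
    division: int
    role: str
    link_kind: str | None = None
    carryover_kind: str | None = None
    target_division: int | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.role == "link":
            if self.link_kind not in LINK_KINDS:
                raise PanelError(
                    f"link {self.name!r} needs link_kind in {LINK_KINDS}, got {self.link_kind!r}"
                )
            if self.target_division is None:
                raise PanelError(f"link {self.name!r} needs a target_division")
            if self.target_division == self.division:
                raise PanelError(
                    f"link {self.name!r}: source and target divisions coincide ({self.division})"
                )
        elif self.link_kind is not None or (
            self.role != "carryover" and self.carryover_kind is not None
        ):
            raise PanelError(f"variable {self.name!r}: kind set but role is {self.role!r}")
        if self.role == "carryover" and self.carryover_kind not in CARRYOVER_KINDS:
            raise PanelError(
                f"carryover {self.name!r} needs carryover_kind in {CARRYOVER_KINDS}, "
                f"got {self.carryover_kind!r}"
            )


def transition_token(t1: str, t2: str) -> str:
    return f"{t1}->{t2}"


@dataclass
class ZeroRepair:
    """Record of one zero observation replaced before solving."""

    dmu: str
    variable: str
    period: str
    replacement: float
    rule: str = "zero -> 1e-6 x within-period mean"


@dataclass
class PanelDataset:
    """Complete n (DMUs) x K (divisions) x T (periods) observation panel.

    ``values`` maps ``(dmu, variable, token)`` to a positive real, where the
    token is a period label for per-period variables and ``"t1->t2"`` for
    carry-overs. ``period_weights`` / ``division_weights`` are normalized to
    sum to one on construction.
    """

    dmus: list[str]
    divisions: int
    periods: list[str]
    specs: list[VariableSpec]
    values: dict[tuple[str, str, str], float]
    period_weights: np.ndarray | None = None
    division_weights: np.ndarray | None = None
    regions: dict[str, str] = field(default_factory=dict)
    repairs: list[ZeroRepair] = field(default_factory=list)

    def __post_init__(self) -> None:
        T, K = len(self.periods), self.divisions
        if self.period_weights is None:
            self.period_weights = np.full(T, 1.0 / T)
        if self.division_weights is None:
            self.division_weights = np.full(K, 1.0 / K)
        self.period_weights = np.asarray(self.period_weights, dtype=float)
        self.division_weights = np.asarray(self.division_weights, dtype=float)
        if len(self.period_weights) != T or len(self.division_weights) != K:
            raise PanelError("weight vector length does not match periods/divisions")
        if (self.period_weights < 0).any() or (self.division_weights < 0).any():
            raise PanelError("weights must be nonnegative")
        self.period_weights = self.period_weights / self.period_weights.sum()
        self.division_weights = self.division_weights / self.division_weights.sum()
        for s in self.specs:
            if not (1 <= s.division <= K):
                raise PanelError(f"variable {s.name!r}: division {s.division} not in 1..{K}")
            if s.role == "link" and not (1 <= s.target_division <= K):
                raise PanelError(f"link {s.name!r}: target division out of range")

    # -- structure helpers -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.dmus)

    @property
    def T(self) -> int:
        return len(self.periods)

    @property
    def transitions(self) -> list[str]:
        return [
            transition_token(a, b) for a, b in zip(self.periods[:-1], self.periods[1:])
        ]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise PanelError(f"unknown variable {name!r}")

    def tokens_for(self, spec: VariableSpec) -> list[str]:
        return self.transitions if spec.role == "carryover" else list(self.periods)

    def by_role(self, division: int, role: str, **kinds) -> list[VariableSpec]:
        out = []
        for s in self.specs:
            if s.division != division or s.role != role:
                continue
            if all(getattr(s, k) == v for k, v in kinds.items()):
                out.append(s)
        return out

    def value(self, dmu: str, variable: str, token: str) -> float:
        return self.values[(dmu, variable, token)]

    def vector(self, variable: str, token: str) -> np.ndarray:
        """Observation vector over all DMUs (in ``dmus`` order)."""
        return np.array([self.values[(j, variable, token)] for j in self.dmus])

    def copy(self) -> "PanelDataset":
        return replace(
            self,
            dmus=list(self.dmus),
            periods=list(self.periods),
            specs=list(self.specs),
            values=dict(self.values),
            regions=dict(self.regions),
            repairs=list(self.repairs),
        )


@dataclass
class RegionScheme:
    """DMU -> region partition used by the regional analytics."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {r for r in self.mapping.values() if r not in REGIONS}
        if bad:
            raise PanelError(f"unknown region labels: {sorted(bad)}")

    def members(self, region: str) -> list[str]:
        if region not in REGIONS:
            raise KeyError(region)
        return [d for d, r in self.mapping.items() if r == region]

    def region_of(self, dmu: str) -> str:
        return self.mapping[dmu]

    def check_covers(self, dmus: list[str]) -> None:
        missing = [d for d in dmus if d not in self.mapping]
        if missing:
            raise PanelError(f"DMUs without a region: {missing}")


# National Bureau of Statistics four-region partition of the 31 provincial
# administrative regions (10 eastern / 6 central / 12 western / 3 northeastern).
CHINA_REGIONS: dict[str, str] = {
    **{p: "eastern" for p in (
        "Beijing", "Tianjin", "Hebei", "Shanghai", "Jiangsu", "Zhejiang",
        "Fujian", "Shandong", "Guangdong", "Hainan")},
    **{p: "central" for p in ("Shanxi", "Anhui", "Jiangxi", "Henan", "Hubei", "Hunan")},
    **{p: "western" for p in (
        "Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Guizhou", "Yunnan",
        "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang", "Tibet")},
    **{p: "northeastern" for p in ("Liaoning", "Jilin", "Heilongjiang")},
}


def china_region_scheme() -> RegionScheme:
    return RegionScheme(dict(CHINA_REGIONS))


# -- validation ------------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`; empty iff the panel is clean."""

    missing: list[tuple[str, str, str]] = field(default_factory=list)
    zeros: list[tuple[str, str, str]] = field(default_factory=list)
    negative: list[tuple[str, str, str]] = field(default_factory=list)
    conditioning: list[str] = field(default_factory=list)
    zero_rule: str = "zero -> 1e-6 x within-period mean (applied before solving)"

    @property
    def ok(self) -> bool:
        return not (self.missing or self.zeros or self.negative)

    def raise_on_hard_errors(self) -> None:
        if self.missing:
            raise PanelError(f"incomplete panel; missing cells: {self.missing[:20]}")
        if self.negative:
            raise PanelError(f"negative observations: {self.negative[:20]}")


def validate_panel(ds: PanelDataset) -> ValidationReport:
    """Check completeness, positivity and dynamic range of a panel.

    Zeros are reported together with the repair rule that
    :func:`repair_zeros` would apply; negatives are hard violations.
    """
    rep = ValidationReport()
    for s in ds.specs:
        for tok in ds.tokens_for(s):
            vals = []
            for j in ds.dmus:
                key = (j, s.name, tok)
                if key not in ds.values:
                    rep.missing.append(key)
                    continue
                v = ds.values[key]
                vals.append(v)
                if v < 0:
                    rep.negative.append(key)
                elif v == 0:
                    rep.zeros.append(key)
        allv = [ds.values[k] for k in ds.values if k[1] == s.name and ds.values[k] > 0]
        if allv and max(allv) / min(allv) > CONDITIONING_RANGE:
            rep.conditioning.append(
                f"{s.name}: dynamic range {max(allv) / min(allv):.2e} exceeds "
                f"{CONDITIONING_RANGE:.0e}; LP conditioning may suffer"
            )
    return rep


def repair_zeros(ds: PanelDataset) -> PanelDataset:
    """Replace zero observations by ``1e-6 x`` the variable's within-period
    mean (over the DMUs with positive values), logging each repair.

    Slacks-based ratios divide by observations, so exact zeros would make the
    program ill-posed.
    """
    out = ds.copy()
    for s in ds.specs:
        for tok in ds.tokens_for(s):
            vec = [ds.values.get((j, s.name, tok), 0.0) for j in ds.dmus]
            pos = [v for v in vec if v > 0]
            if not pos:
                continue
            eps = ZERO_REPAIR_FRACTION * float(np.mean(pos))
            for j in ds.dmus:
                key = (j, s.name, tok)
                if ds.values.get(key) == 0.0:
                    out.values[key] = eps
                    out.repairs.append(ZeroRepair(j, s.name, tok, eps))
    return out


# -- I/O ---------------------------------------------------------------------

CSV_COLUMNS = ["dmu", "region", "division", "variable", "role", "period", "value"]


def load_panel(
    path,
    schema: list[VariableSpec] | None = None,
    repair: bool = True,
    period_weights=None,
    division_weights=None,
) -> PanelDataset:
    """Read a long-format panel CSV into a validated :class:`PanelDataset`.

    The file must have columns ``dmu,region,division,variable,role,period,value``;
    carry-over rows use the transition token ``"t1->t2"`` in the period
    column. Row order never affects the result: DMUs and periods are ordered
    by first appearance, values are keyed.

    When ``schema`` is given, link/carry-over kinds are taken from it and the
    file's (division, role) declarations are checked against it; otherwise a
    schema is inferred (links default to kind ``free`` toward the next
    division, carry-overs to kind ``input``).
    """
    df = pd.read_csv(path, dtype={"period": str, "dmu": str})
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelError(f"panel CSV missing columns {missing_cols}")

    dmus = sorted(set(df["dmu"]))  # deterministic under row shuffles
    divisions = int(df["division"].max())
    period_rows = df[~df["period"].str.contains("->")]
    periods = sorted(set(period_rows["period"]))

    if schema is None:
        schema = []
        seen = {}
        for _, row in df.drop_duplicates(["variable"]).iterrows():
            role = row["role"]
            if role not in ROLES:
                raise PanelError(f"unknown role {role!r} for variable {row['variable']!r}")
            kw = {}
            if role == "link":
                kw = dict(link_kind="free",
                          target_division=1 + (int(row["division"]) % divisions))
            elif role == "carryover":
                kw = dict(carryover_kind="input")
            seen[row["variable"]] = VariableSpec(
                row["variable"], int(row["division"]), role, **kw)
        schema = list(seen.values())
    else:
        declared = {s.name: s for s in schema}
        for _, row in df.drop_duplicates(["variable"]).iterrows():
            s = declared.get(row["variable"])
            if s is None:
                raise PanelError(f"variable {row['variable']!r} not in schema")
            if s.role != row["role"] or s.division != int(row["division"]):
                raise PanelError(
                    f"variable {row['variable']!r}: file declares "
                    f"(division={row['division']}, role={row['role']}) but schema says "
                    f"(division={s.division}, role={s.role})")

    values = {
        (r.dmu, r.variable, r.period): float(r.value) for r in df.itertuples()
    }
    regions = {}
    if df["region"].notna().any():
        regions = dict(df.drop_duplicates("dmu")[["dmu", "region"]].values)

    ds = PanelDataset(
        dmus=dmus, divisions=divisions, periods=periods, specs=schema,
        values=values, period_weights=period_weights,
        division_weights=division_weights, regions=regions,
    )
    rep = validate_panel(ds)
    rep.raise_on_hard_errors()
    if repair and rep.zeros:
        ds = repair_zeros(ds)
    return ds


def write_panel(ds: PanelDataset, path) -> None:
    """Write a dataset back to the long CSV format (12-significant-digit
    round-trip stable)."""
    rows = []
    for s in ds.specs:
        for tok in ds.tokens_for(s):
            for j in ds.dmus:
                rows.append({
                    "dmu": j,
                    "region": ds.regions.get(j, ""),
                    "division": s.division,
                    "variable": s.name,
                    "role": s.role,
                    "period": tok,
                    "value": float(f"{ds.values[(j, s.name, tok)]:.12g}"),
                })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# -- descriptive summaries ---------------------------------------------------


def summarize(ds: PanelDataset) -> pd.DataFrame:
    """Per-variable, per-period descriptive statistics.

    Returns a frame indexed by ``(variable, statistic)`` with one column per
    period token, statistics being ``average``, ``min``, ``max`` and the
    sample (n-1) standard deviation ``sd`` — the layout of a yearbook-style
    summary table.
    """
    blocks = {}
    for s in ds.specs:
        for tok in ds.tokens_for(s):
            v = ds.vector(s.name, tok)
            blocks[(s.name, "average", tok)] = float(np.mean(v))
            blocks[(s.name, "min", tok)] = float(np.min(v))
            blocks[(s.name, "max", tok)] = float(np.max(v))
            blocks[(s.name, "sd", tok)] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    idx = sorted({(k[0], k[1]) for k in blocks}, key=lambda p: ([s.name for s in ds.specs].index(p[0]), p[1]))
    cols = list(dict.fromkeys([k[2] for k in blocks]))
    data = [[blocks.get((v, st, c), np.nan) for c in cols] for v, st in idx]
    return pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(idx, names=["variable", "statistic"]),
        columns=cols,
    )


def summary_to_csv(summary: pd.DataFrame) -> str:
    buf = io.StringIO()
    summary.to_csv(buf)
    return buf.getvalue()
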