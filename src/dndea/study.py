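"""Two-stage wastewater -> water-disease efficiency study pipeline.

Instantiates the dynamic network SBM on the two-stage provincial schema
(production stage: labor and water consumption in, GDP and wastewater out,
fixed assets carried over, COD linking into the health stage; health stage:
treatment expense in, treatment capacity and water-disease counts out) and
derives the regional analytics: per-year stage scores, total scores and
competition ranks, regional and multi-year means, year-over-year growth,
and a Kruskal-Wallis comparison of the four regions.

The total score of a province-year is the arithmetic mean of its two stage
scores (the published score tables satisfy this identity on every row; a
non-oriented overall score would not generally equal that mean, so the
solver's overall score is carried alongside for comparison, not used as
the total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import (
    PanelDataset,
    PanelError,
    RegionScheme,
    VariableSpec,
    china_region_scheme,
)
from .solver import solve_all

STUDY_YEARS = ["2013", "2014", "2015", "2016", "2017"]


def study_schema() -> list[VariableSpec]:
    """The two-stage variable scheme: exactly two divisions."""
    return [
        VariableSpec("labor", 1, "input", units="10,000 persons"),
        VariableSpec("water_consumption", 1, "input", units="100 million tons"),
        VariableSpec("gdp", 1, "desirable_output", units="100 million RMB"),
        VariableSpec("wastewater", 1, "undesirable_output", units="10,000 tons"),
        VariableSpec("cod", 1, "link", link_kind="in", target_division=2,
                     units="10,000 tons"),
        VariableSpec("fixed_assets", 1, "carryover", carryover_kind="input",
                     units="100 million RMB"),
        VariableSpec("treatment_expense", 2, "input", units="10,000 RMB"),
        VariableSpec("treatment_capacity", 2, "desirable_output", units="10,000 tons"),
        VariableSpec("water_diseases", 2, "undesirable_output", units="persons"),
    ]


@dataclass
class StudyConfig:
    """Schema, regions, periods and weights of the two-stage study."""

    schema: list[VariableSpec] = field(default_factory=study_schema)
    regions: RegionScheme = field(default_factory=china_region_scheme)
    periods: list[str] = field(default_factory=lambda: list(STUDY_YEARS))
    period_weights: np.ndarray | None = None
    division_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        divisions = {s.division for s in self.schema} | {
            s.target_division for s in self.schema if s.role == "link"}
        if divisions != {1, 2}:
            raise PanelError("study schema must span exactly two divisions")


@dataclass
class ScoreTable:
    """Per-(dmu, year) stage/total scores with ranks, plus regional and
    multi-year means. ``scores`` columns: dmu, region, year, stage1,
    stage2, total, overall, rank."""

    scores: pd.DataFrame
    regional_means: pd.DataFrame   # region, year, mean
    dmu_means: pd.DataFrame        # dmu, mean over years

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


# -- scalar operations -------------------------------------------------------


def total_score(stage1: float, stage2: float) -> float:
    """Equal-weight arithmetic mean of the two stage scores."""
    for s in (stage1, stage2):
        if not (0.0 < s <= 1.0 + 1e-12):
            raise ValueError(f"stage score {s} outside (0, 1]")
    return (stage1 + stage2) / 2.0


def percent_change(score_prev: float, score_next: float) -> float:
    """Year-over-year growth in percent: 100 (next - prev) / prev."""
    if score_prev <= 0:
        raise ValueError("previous score must be positive")
    return 100.0 * (score_next - score_prev) / score_prev


def multi_year_average(values) -> float:
    """Unweighted mean over years."""
    values = list(values)
    if not values:
        raise ValueError("need at least one year")
    return float(np.mean(values))


def rank_scores(scores: dict[str, float]) -> dict[str, int]:
    """Descending competition ranking: ties share the minimal rank and the
    next distinct score's rank skips accordingly (1, 1, 1, 4, ...)."""
    return {
        d: 1 + sum(1 for v in scores.values() if v > s + 1e-12)
        for d, s in scores.items()
    }


def regional_average(
    scores: pd.DataFrame, region: str, year: str,
    scheme: RegionScheme | None = None, column: str = "total",
) -> float:
    """Unweighted mean of member DMU scores for one region-year."""
    if scheme is not None:
        members = scheme.members(region)
        sel = scores[(scores["dmu"].isin(members)) & (scores["year"] == year)]
    else:
        sel = scores[(scores["region"] == region) & (scores["year"] == year)]
    if sel.empty:
        raise KeyError(f"no scores for region {region!r}, year {year!r}")
    return float(sel[column].mean())


@dataclass
class KruskalResult:
    statistic: float
    pvalue: float
    significance: str  # "***" at 0.05, "**" at 0.1, "" otherwise


def kruskal_wallis(groups: dict[str, list[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H across score groups, chi-square
    p-value with (#groups - 1) degrees of freedom.

    Degenerate all-identical samples yield H = 0, p = 1 (scipy raises on
    zero variance, which for this use means "no evidence of difference").
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = []
    for name, vals in groups.items():
        vals = list(vals)
        if not vals:
            raise ValueError(f"group {name!r} is empty")
        samples.append(vals)
    flat = [v for g in samples for v in g]
    if len(set(flat)) == 1:
        return KruskalResult(0.0, 1.0, "")
    H, p = stats.kruskal(*samples)
    stars = "***" if p <= 0.05 else ("**" if p <= 0.1 else "")
    return KruskalResult(float(H), float(p), stars)


# -- table construction ------------------------------------------------------


def score_table_from_stage_scores(
    stage_scores: pd.DataFrame, scheme: RegionScheme | None = None,
) -> ScoreTable:
    """Build totals, ranks and means from a frame with columns
    ``dmu, region, year, stage1, stage2`` (and optionally ``overall``)."""
    df = stage_scores.copy()
    if scheme is not None:
        df["region"] = df["dmu"].map(scheme.mapping)
    df["total"] = [total_score(a, b) for a, b in zip(df["stage1"], df["stage2"])]
    if "overall" not in df.columns:
        df["overall"] = np.nan
    ranks = []
    for year, grp in df.groupby("year"):
        r = rank_scores(dict(zip(grp["dmu"], grp["total"])))
        ranks.append(pd.DataFrame({"dmu": list(r), "year": year, "rank": list(r.values())}))
    df = df.merge(pd.concat(ranks), on=["dmu", "year"])

    regional = (
        df.groupby(["region", "year"])["total"].mean().reset_index(name="mean"))
    dmu_means = df.groupby("dmu")["total"].mean().reset_index(name="mean")
    cols = ["dmu", "region", "year", "stage1", "stage2", "total", "overall", "rank"]
    return ScoreTable(df[cols].sort_values(["year", "dmu"]).reset_index(drop=True),
                      regional, dmu_means)


def run_study(ds: PanelDataset, cfg: StudyConfig | None = None) -> ScoreTable:
    """Solve the dynamic network SBM for every DMU and assemble the score
    table: stage scores are the per-year division-period efficiencies,
    totals their means, ranks per year, plus regional/multi-year means."""
    cfg = cfg or StudyConfig()
    cfg.regions.check_covers(ds.dmus)
    results = solve_all(
        ds, weights=(
            cfg.period_weights if cfg.period_weights is not None else ds.period_weights,
            cfg.division_weights if cfg.division_weights is not None else ds.division_weights,
        ),
    )
    rows = []
    for dmu, res in results.items():
        for year in ds.periods:
            rows.append({
                "dmu": dmu,
                "region": cfg.regions.region_of(dmu),
                "year": year,
                "stage1": res.division_period[(1, year)],
                "stage2": res.division_period[(2, year)],
                "overall": res.overall,
            })
    return score_table_from_stage_scores(pd.DataFrame(rows))


def kruskal_by_year(scores: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis comparison of regional total scores, one row per
    year: year, H, p, significance."""
    rows = []
    for year, grp in scores.groupby("year"):
        groups = {r: g["total"].tolist() for r, g in grp.groupby("region")}
        kr = kruskal_wallis(groups)
        rows.append({"year": year, "H": kr.statistic, "p": kr.pvalue,
                     "significance": kr.significance})
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
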