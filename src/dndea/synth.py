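"""Seeded synthetic panels with the statistical structure of the provincial
wastewater -> health study.

The generator emulates a 31-DMU x 2-division x 5-period panel whose
per-variable, per-year moments (mean / min / max / sample SD) match the
published yearbook summary statistics, and whose cross-variable structure
follows the two-stage causal scheme: wastewater scales with water
consumption, COD with wastewater, water-disease counts with COD, GDP with
labor and water, treatment capacity with treatment expense. A shared
per-DMU scale factor induces the cross-sectional dependence of large
provinces being large on all volumes.

Marginals are moment-matched lognormals (all variables are positive and
right-skewed: max >> mean) clipped to the published [min, max] envelope.
The carry-over (fixed assets) evolves as an AR(1) in its latent score
across transitions so the carry-over continuity constraints are exercised
nontrivially. One seeded generator drives all randomness.

Summary statistics for GDP, fixed assets and treatment capacity are not
published; their calibration targets here were chosen once at realistic
provincial-China magnitudes (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel import PanelDataset, RegionScheme, REGIONS
from .study import STUDY_YEARS, study_schema


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class CalTarget:
    """Per-variable, per-year calibration: mean / min / max / sample SD."""

    mean: float
    min: float
    max: float
    sd: float

    def check(self, variable: str, year: str) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ConfigError(
                f"{variable} {year}: mean {self.mean} outside [{self.min}, {self.max}]")
        # a distribution on [min, max] with this mean has SD at most
        # sqrt((mean-min)(max-mean))
        if self.sd ** 2 > (self.mean - self.min) * (self.max - self.mean) + 1e-9:
            raise ConfigError(
                f"{variable} {year}: SD {self.sd} infeasible for "
                f"[{self.min}, {self.max}] with mean {self.mean}")


def _targets(means, mins, maxs, sds) -> dict[str, CalTarget]:
    return {y: CalTarget(m, lo, hi, s)
            for y, m, lo, hi, s in zip(STUDY_YEARS, means, mins, maxs, sds)}


# Published yearbook summary statistics (six observed variables) plus
# chosen calibrations for the three unpublished ones.
DEFAULT_CALIBRATION: dict[str, dict[str, CalTarget]] = {
    "water_consumption": _targets(
        [199.468, 196.606, 196.890, 200.307, 194.948],
        [23.800, 24.100, 25.700, 26.400, 25.800],
        [588.000, 591.300, 577.200, 577.400, 591.300],
        [149.015, 149.289, 147.533, 145.104, 145.923]),
    "labor": _targets(
        [584.144, 589.606, 582.661, 577.035, 569.156],
        [31.020, 32.540, 33.390, 31.510, 33.300],
        [1966.980, 1973.280, 1948.040, 1957.570, 1963.100],
        [430.829, 439.135, 431.505, 428.209, 426.971]),
    "wastewater": _targets(
        [224336.539, 231024.211, 237200.839, 229385.609, 225697.096],
        [5004.680, 5449.680, 5883.000, 6142.750, 7175.650],
        [862471.080, 905082.060, 911523.000, 938261.030, 882020.480],
        [184430.104, 190473.093, 195601.802, 194225.740, 185112.232]),
    "cod": _targets(
        [75.887, 74.019, 71.726, 33.755, 32.971],
        [2.600, 2.800, 2.900, 2.700, 2.500],
        [184.600, 178.000, 175.800, 96.400, 100.100],
        [49.657, 48.145, 46.941, 22.542, 23.151]),
    "treatment_expense": _targets(
        [40284.613, 37176.581, 38198.000, 34916.000, 24637.387],
        [572.000, 90.000, 893.000, 15.000, 280.000],
        [150634.000, 175141.000, 164862.000, 158518.000, 105626.000],
        [38242.050, 37554.249, 41606.657, 38104.037, 28491.368]),
    "water_diseases": _targets(
        [639241.806, 481404.129, 498569.323, 515184.581, 478087.710],
        [673.000, 673.000, 49.000, 881.000, 1394.000],
        [4894181.000, 4960904.000, 4908054.000, 2710593.000, 2197461.000],
        [1033514.768, 1002811.200, 1022375.107, 738905.138, 690593.449]),
    # unpublished; chosen at provincial-China magnitudes (100 million RMB /
    # 10,000 tons), right-skewed like the published variables
    "gdp": _targets(
        [20486, 22336, 23920, 25705, 28135],
        [808, 921, 1026, 1151, 1311],
        [62164, 67810, 72813, 80855, 89879],
        [15600, 16900, 18100, 19600, 21400]),
    "fixed_assets": _targets(
        [14238, 16178, 17823, 19336, 20756],
        [744, 856, 977, 1104, 1249],
        [42495, 46720, 48312, 52365, 55203],
        [10400, 11600, 12300, 13200, 14000]),
    "treatment_capacity": _targets(
        [179469, 184819, 189760, 183508, 180557],
        [4003, 4359, 4706, 4914, 5740],
        [689976, 724065, 729218, 750608, 705616],
        [147544, 152378, 156481, 155380, 148089]),
}

#: variable -> (driver variables, coupling weight on the standardized
#: log-driver score); generation follows this (acyclic) order
DEFAULT_COUPLINGS: dict[str, tuple[tuple[str, ...], float]] = {
    "labor": ((), 0.0),
    "water_consumption": ((), 0.0),
    "gdp": (("labor", "water_consumption"), 0.80),
    "wastewater": (("water_consumption",), 0.85),
    "cod": (("wastewater",), 0.85),
    "fixed_assets": ((), 0.0),
    "treatment_expense": ((), 0.0),
    "treatment_capacity": (("treatment_expense",), 0.80),
    "water_diseases": (("cod",), 0.80),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic panel.

    Defaults reproduce the published setting: 31 DMUs split 10/6/12/3 over
    the four regions, five periods, published per-year moment targets.
    """

    n_dmus: int = 31
    region_sizes: tuple[int, ...] = (10, 6, 12, 3)
    periods: list[str] = field(default_factory=lambda: list(STUDY_YEARS))
    calibration: dict[str, dict[str, CalTarget]] = field(
        default_factory=lambda: {v: dict(t) for v, t in DEFAULT_CALIBRATION.items()})
    couplings: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS))
    latent_weight: float = 0.65   # weight of the shared per-DMU scale factor
    ar_rho: float = 0.9           # carry-over latent persistence across transitions
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.region_sizes) != self.n_dmus:
            raise ConfigError(
                f"region sizes {self.region_sizes} do not sum to n_dmus={self.n_dmus}")
        for var, per_year in self.calibration.items():
            for year, tgt in per_year.items():
                tgt.check(var, year)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_panel(cfg: GeneratorConfig | None = None, seed: int | None = None) -> PanelDataset:
    """Generate one complete, strictly positive panel.

    Identical ``(cfg, seed)`` gives an identical dataset. ``seed`` overrides
    ``cfg.seed`` when given.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_dmus
    dmus = [f"P{i + 1:02d}" for i in range(n)]
    regions = {}
    i = 0
    for size, label in zip(cfg.region_sizes, REGIONS):
        for _ in range(size):
            regions[dmus[i]] = label
            i += 1

    schema = study_schema()
    latent = rng.standard_normal(n)
    periods = list(cfg.periods)
    transitions = [f"{a}->{b}" for a, b in zip(periods[:-1], periods[1:])]

    values: dict[tuple[str, str, str], float] = {}

    def standardized(v: np.ndarray) -> np.ndarray:
        lv = np.log(v)
        s = lv.std()
        return (lv - lv.mean()) / s if s > 0 else np.zeros_like(lv)

    ar_state: dict[str, np.ndarray] = {}
    for spec in schema:
        var = spec.name
        per_year = cfg.calibration[var]
        drivers, w_d = cfg.couplings.get(var, ((), 0.0))
        w_l = cfg.latent_weight if not drivers else 0.3
        w_e = math.sqrt(max(0.0, 1.0 - w_d ** 2 - w_l ** 2))
        tokens = transitions if spec.role == "carryover" else periods
        for ti, tok in enumerate(tokens):
            year = tok.split("->")[0]
            tgt = per_year[year]
            if drivers:
                d = np.mean([standardized(
                    np.array([values[(j, dv, tok)] for j in dmus])) for dv in drivers], axis=0)
                d = d / d.std() if d.std() > 0 else d
            else:
                d = np.zeros(n)
            eps = rng.standard_normal(n)
            if spec.role == "carryover":
                prev = ar_state.get(var)
                if prev is not None:
                    eps = cfg.ar_rho * prev + math.sqrt(1 - cfg.ar_rho ** 2) * eps
                ar_state[var] = eps
            z = w_d * d + w_l * latent + w_e * eps
            # standardize within the cross-section so the sample log-moments
            # hit the calibration exactly (n = 31 sampling error would
            # otherwise dominate the moment match)
            z = (z - z.mean()) / z.std()
            mu, sigma = _lognormal_params(tgt.mean, tgt.sd)
            v = np.clip(np.exp(mu + sigma * z), tgt.min, tgt.max)
            for j, dmu in enumerate(dmus):
                values[(dmu, var, tok)] = float(v[j])

    return PanelDataset(
        dmus=dmus, divisions=2, periods=periods, specs=schema,
        values=values, regions=regions,
    )


def region_scheme_for(ds: PanelDataset) -> RegionScheme:
    return RegionScheme(dict(ds.regions))


def plant_frontier(ds: PanelDataset, dmu: str) -> PanelDataset:
    """Rewrite one DMU to weakly dominate all others in every period: 10%
    below the minimum on inputs, undesirables, links and cost-type
    carry-overs; 10% above the maximum on desirables. Dominance forces all
    its slacks to zero, so the planted DMU scores exactly 1."""
    if dmu not in ds.dmus:
        raise KeyError(dmu)
    out = ds.copy()
    for s in ds.specs:
        better_is_high = s.role == "desirable_output" or (
            s.role == "carryover" and s.carryover_kind == "good")
        for tok in ds.tokens_for(s):
            others = [ds.value(j, s.name, tok) for j in ds.dmus if j != dmu]
            if better_is_high:
                out.values[(dmu, s.name, tok)] = 1.1 * max(others)
            else:
                out.values[(dmu, s.name, tok)] = 0.9 * min(others)
    return out


def add_inflated_clone(
    ds: PanelDataset, dmu: str, delta: float, name: str | None = None,
) -> PanelDataset:
    """Add a copy of ``dmu`` with every input inflated by ``1 + delta``.

    Applied to a planted frontier DMU, the clone's score decreases strictly
    in ``delta`` (its input slack toward the planted original grows)."""
    name = name or f"{dmu}+{delta:g}"
    out = ds.copy()
    out.dmus = ds.dmus + [name]
    if dmu in ds.regions:
        out.regions[name] = ds.regions[dmu]
    for s in ds.specs:
        for tok in ds.tokens_for(s):
            v = ds.value(dmu, s.name, tok)
            if s.role == "input":
                v *= 1.0 + delta
            out.values[(name, s.name, tok)] = v
    return out


def calibration_csv(calibration=None) -> str:
    """Calibration table in the yearbook summary layout:
    variable, statistic, one column per year."""
    calibration = calibration or DEFAULT_CALIBRATION
    lines = ["variable,statistic," + ",".join(STUDY_YEARS)]
    for var, per_year in calibration.items():
        for stat in ("mean", "min", "max", "sd"):
            vals = [f"{getattr(per_year[y], stat):.6g}" for y in STUDY_YEARS]
            lines.append(f"{var},{stat}," + ",".join(vals))
    return "\n".join(lines) + "\n"


def load_calibration_csv(path) -> dict[str, dict[str, CalTarget]]:
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, dict[str, CalTarget]] = {}
    for var, grp in df.groupby("variable", sort=False):
        stats = {r["statistic"]: r for _, r in grp.iterrows()}
        out[var] = {
            y: CalTarget(float(stats["mean"][y]), float(stats["min"][y]),
                         float(stats["max"][y]), float(stats["sd"][y]))
            for y in STUDY_YEARS}
    return out
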