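# dndea

Dynamic network slacks-based DEA (data envelopment analysis) with
undesirable outputs, built for two-stage environmental-health efficiency
panels: a "production" stage (labor and water consumption producing GDP and
wastewater, with fixed assets carried between years) linked by chemical
oxygen demand (COD) into a "health" stage (wastewater treatment expense
producing treatment capacity and, undesirably, water-borne endemic disease
cases such as fluorosis and arsenicosis). It is aimed at efficiency and
environmental-health researchers who want a reproducible, testable
implementation of this model class rather than a spreadsheet workflow.

## The model

Each decision-making unit (DMU, here a provincial region) contains `K`
divisions observed over `T` periods. Per division `k` and period `t` an
intensity vector `λ_k^t ≥ 0`, `eλ_k^t = 1` (variable returns to scale)
spans the frontier, and the evaluated DMU's observations decompose into
frontier activity plus slacks: `x_o = Xλ + s⁻` (inputs),
`y_o = Yλ − s⁺` (desirable outputs), `y_o = Yλ + s⁻` (undesirable
outputs), with link constraints tying divisions together within a period
and carry-over continuity `Zλ_k^t = Zλ_k^{t+1}` tying periods together.
The overall score is the minimized ratio

```
θ* = min  Σ_t W^t Σ_k W^k [ 1 − mean relative slack of inputs, in-links, input carry-overs ]
          ────────────────────────────────────────────────────────────────────────────────
          Σ_t W^t Σ_k W^k [ 1 + mean relative slack of desirable and undesirable outputs ]
```

solved as one LP per DMU via the Charnes–Cooper transformation. θ* ∈ (0, 1]
and θ* = 1 iff every slack is zero. Period (`∂*`), division (`φ*`) and
division-period (`ρ*`) efficiencies are partial aggregations of the same
optimal slacks, and eight per-variable indices (target/actual ratios) are
derived from the projections. Regional analytics — total scores as the
mean of the two stage scores, competition ranks, regional and five-year
means, growth rates, and a Kruskal–Wallis comparison of regions — complete
the pipeline. See `docs/methods.md` for the full formulation and design
choices.

## Worked example

```python
from dndea import (GeneratorConfig, RegionScheme, StudyConfig,
                   generate_panel, kruskal_by_year, run_study)

ds = generate_panel(GeneratorConfig(seed=1))       # 31 DMUs x 2 stages x 5 years
table = run_study(ds, StudyConfig(regions=RegionScheme(dict(ds.regions))))
print(table.scores.head(6).round(4).to_string(index=False))
```

```
dmu  region year  stage1  stage2  total  overall  rank
P01 eastern 2013  0.5824  0.4518 0.5171   0.6501    23
P02 eastern 2013  0.6126  1.0000 0.8063   0.6942    12
P03 eastern 2013  0.5680  0.4046 0.4863   0.7236    25
P04 eastern 2013  0.4806  1.0000 0.7403   0.6025    15
P05 eastern 2013  1.0000  0.8507 0.9253   0.9055    10
P06 eastern 2013  0.5611  0.5686 0.5649   0.6697    22
```

`stage1`/`stage2` are the division-period efficiencies for that year
(1.0000 = on the frontier of that stage), `total` their mean — the
headline score a province is ranked by that year — and `overall` the
solver's five-year overall θ*, shown for comparison. P05 is nearly
efficient overall (0.9055) and fully efficient in stage 1 in 2013; P03
wastes about half of its stage-2 potential (0.4046).

The same analytics run on the published provincial score table shipped
with the package:

```python
from dndea import (published_stage_scores, score_table_from_stage_scores,
                   regional_average, total_score, percent_change)

df = score_table_from_stage_scores(published_stage_scores()).scores
regional_average(df, "eastern", "2013")   # 0.7031
total_score(1.0, 0.089786)                # 0.544893  (Tibet 2013)
percent_change(0.7369, 1.0)               # 35.70     (Beijing 2015 -> 2016, %)
```

A command-line interface mirrors the library
(`dndea generate | validate | summarize | solve | indices | report |
kruskal`); every output directory gets a manifest (seed, digests, solver,
tolerances) sufficient to re-run bit-identically.

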