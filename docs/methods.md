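# Methods

## The model

`dndea` implements a non-oriented, slacks-based dynamic network DEA model
with undesirable outputs, under variable returns to scale. Each
decision-making unit (DMU) `j = 1..n` contains `K` internal divisions
observed over `T` periods. Per division `k` and period `t` the evaluated
DMU `o` is compared against the convex hull of all DMUs through an
intensity vector `λ_k^t ≥ 0` with `e λ_k^t = 1` (VRS). Observations are
written as frontier activity plus slack:

| quantity             | constraint                              | slack sign |
|----------------------|-----------------------------------------|-----------|
| input                | `x_o = X λ + s_x`                       | `s_x ≥ 0` |
| desirable output     | `y_o = Y λ − s_g`                       | `s_g ≥ 0` |
| undesirable output   | `y_o = Y λ + s_b`                       | `s_b ≥ 0` |
| input-kind link      | `z_o = Z λ_k + s_in`, `Z λ_k = Z λ_h`   | `s_in ≥ 0`|
| free link            | `Z λ_h = Z λ_k`                         | none      |
| fix link             | `z_o = Z λ_k`, `z_o = Z λ_h`            | none      |
| carry-over (any kind)| `Z λ_k^t = Z λ_k^{t+1}`, `t = 1..T−1`   | —         |
| carry-over, input    | `z_o = Z λ_k^t + s_c` per transition    | `s_c ≥ 0` |
| carry-over, good     | `z_o = Z λ_k^t − s_c`                   | `s_c ≥ 0` |
| carry-over, free     | `z_o = Z λ_k^t + s_c`                   | signed    |

The overall efficiency is the minimized linear-fractional objective

```
θ* = min  Σ_t W^t Σ_k W^k [1 − (Σ s_x/x + Σ s_in/z + Σ s_c/z) / (m_k + linkin_k + ninput_k)]
          ─────────────────────────────────────────────────────────────────────────────────
          Σ_t W^t Σ_k W^k [1 + (Σ s_g/y + Σ s_b/y) / (r1_k + r2_k)]
```

with `m_k` inputs, `linkin_k` input-kind links (attributed to their source
division), `ninput_k` input-kind carry-overs, `r1_k`/`r2_k`
desirable/undesirable outputs of division `k`, and period/division weights
`W^t`, `W^k` normalized to sum to one (equal by default). Undesirable
outputs are penalized through denominator slacks — a less-is-better output
drags the score down exactly like an unproduced desirable output. θ* lies
in (0, 1] and equals 1 iff every slack vanishes (to tolerance 1e−7
relative).

Period, division and division-period efficiencies evaluate partial
aggregations of the *same* optimal slacks: the division-period score is the
per-cell numerator/denominator ratio; the division score aggregates those
brackets over `t` with `W^t`; the period score aggregates over `k` with
`W^k`. The model definition we implement carries a deliberate asymmetry,
reproduced as defined rather than "repaired": the period decomposition's
numerator divides by `m_k + linkin_k` (no carry-over term), while its
denominator adds good-kind carry-over slacks over `r1_k + r2_k + ngood_k`;
the overall/division decompositions instead put input-kind carry-over
slacks in the numerator and no carry-over in the denominator. With the
default two-stage schema (no good-kind carry-over) only the numerator
difference is active. Carry-over slacks of transition `(t, t+1)` are
attributed to period `t`; the final period has no transition term but keeps
the constant divisor.

A related definitional wrinkle: one common prose convention treats an
undesirable output as "an input of the division". We follow the objective
above (undesirable slacks in the denominator); the two conventions produce
different scores and ours is the one all decompositions here are consistent
with.

## Solving

The fractional program is linearized by the Charnes–Cooper substitution:
scale every intensity and slack by `φ > 0`, normalize the denominator to 1,
and minimize the numerator — one LP per DMU, solved with HiGHS through
`scipy.optimize.linprog`. The evaluated DMU's own unit intensity is always
feasible, so no valid dataset is reported infeasible. A Dinkelbach
parametric iteration (`method="dinkelbach"`) is kept as an independent
cross-check; the two agree to 1e−7 in the test suite.

Numerical choices:

* Every variable is normalized by its cross-sectional mean inside the
  program builder. Scores are units-invariant, so this is a pure
  conditioning transform; it keeps coefficient ranges near 1 even when raw
  magnitudes span seven orders (persons vs. 10⁴-ton volumes). If the tight
  tolerance solve (1e−9) still fails, one retry at the solver's default
  tolerances is attempted before raising.
* Scores are clipped to [1e−6, 1]; score comparisons use 1e−6, efficiency
  classification 1e−7 (relative slack).
* Optimal slack decompositions need not be unique at alternate optima.
  Determinism comes from the fixed solver and fixed variable ordering; an
  optional second LP (`maximize_slacks=True`) maximizes total normalized
  slack at the optimal score to pin the decomposition down. Division-level
  decompositions may differ between solvers even when θ* agrees.
* Zero observations are replaced by `1e−6 ×` the variable's within-period
  mean before solving (the ratios divide by observations); each repair is
  logged per cell. Negative values are hard errors.

### What a dominated entrant can and cannot change

For production constraints (inputs, outputs) the usual dominance argument
holds: a new DMU weakly worse everywhere cannot expand the frontier, and
incumbents' scores are unchanged. Link and carry-over *continuity*
constraints are equalities, however, and equalities admit no monotone
"worse" direction: an entrant whose link profile differs from every
incumbent's genuinely enlarges the set of attainable equality values and
can change scores (we verified this numerically). The frontier-invariance
property is therefore stated, and tested, for entrants whose link and
carry-over values coincide with an incumbent's — then every feasible point
using the entrant is weakly improved by shifting its weight to the
incumbent, and all scores are unchanged.

## Per-variable efficiency indices

For each mapped variable the index compares the frontier target with the
observation per DMU-year: `target/actual` for inputs, undesirable outputs
and the input-kind link (target = actual − slack), `actual/target` for
desirable outputs (target = actual + slack). Indices lie in (0, 1] and all
equal 1 exactly for an efficient DMU. In the two-stage schema the eight
named indices are labor, water consumption, treatment expense, GDP,
treatment capacity, wastewater, COD (from the link slack) and the
water-disease count. Indices for zero-repaired observations are computed
against the repaired value and flagged.

## The two-stage study pipeline

Stage 1 ("production"): labor and water consumption in; GDP (desirable) and
wastewater (undesirable) out; fixed assets carried over as an input-kind
carry-over; COD links into Stage 2 as an input-kind (undesirable) link.
Stage 2 ("health"): wastewater treatment expense in; treatment capacity
(desirable) and the number of water-borne endemic disease cases —
fluorosis and arsenicosis — (undesirable) out.

The **total score** of a province-year is the arithmetic mean of its two
division-period scores. This is a deliberate design choice: the published
provincial score tables satisfy the identity `total = (stage1 + stage2)/2`
on every row, while a non-oriented overall score is a ratio of weighted
sums and does not generally equal that mean. The solver's overall θ* is
emitted alongside for comparison. Ranks are descending competition ranks
(ties share the minimal rank; the next distinct score skips). Regional
means are unweighted over member provinces (10 eastern / 6 central / 12
western / 3 northeastern, the National Bureau of Statistics partition);
five-year means are unweighted over years; growth is
`100 (next − prev)/prev` percent. Display rounding is 4 decimals for
scores and 2 for percents; internal arithmetic is full precision.

The regional comparison uses the tie-corrected Kruskal–Wallis H with the
chi-square approximation on `#regions − 1` degrees of freedom
(`scipy.stats.kruskal`); the published comparison-table entries are
p-values (stars at 0.05/0.1), and recomputing from the published totals
reproduces all five to the printed precision. An all-identical degenerate
sample returns H = 0, p = 1. A full permutation-enumeration oracle on a
small fixture bounds the chi-square approximation error in the tests.

## Synthetic data

The raw provincial panel (yearbook data) is not deposited, so the
generator emulates its published structure: 31 DMUs × 2 divisions × 5
periods, with per-variable, per-year mean/min/max/sample-SD targets equal
to the published summary table for the six variables it covers. Targets
for GDP, fixed assets and treatment capacity are not published; they were
chosen once at realistic provincial-China magnitudes (e.g. mean GDP ≈
2×10¹² RMB with the observed right skew) and are not tuned.

Marginals are lognormal — all variables are positive with max ≫ mean —
moment-matched to (mean, SD) and clipped to [min, max]. Latent scores are
standardized within each cross-section so the sample log-moments match the
calibration exactly rather than up to n = 31 sampling error. Cross-sectional
dependence comes from a shared per-DMU scale factor (large provinces are
large on every volume); the two-stage causal structure is induced by mixing
each downstream variable's score with its drivers' standardized log-scores
(wastewater ← water consumption, COD ← wastewater, diseases ← COD,
GDP ← labor + water, capacity ← expense; coupling weights 0.80–0.85,
giving level correlations above 0.5). Fixed assets follow an AR(1)
(ρ = 0.9) in their latent score across transitions so carry-over
continuity binds nontrivially. A single seeded `numpy` generator drives
all randomness; identical seeds give identical panels.

Calibration feasibility is checked up front: the mean must lie inside
[min, max] and the SD cannot exceed `sqrt((mean−min)(max−min ... mean))`
(the maximum SD of any distribution on the interval with that mean);
violations name the variable and year.

What the generator does *not* emulate: the true inter-province correlation
structure, any deflation or per-capita adjustment of yearbook values, and
the apparent reporting-unit break in the COD series between 2015 and 2016
(each year is calibrated independently). For the most heavily skewed
variable (water diseases, CV ≈ 1.6 with a tight published maximum) the
realized sample mean of a single panel can sit up to ~20% from its target
because the envelope clip truncates the tail; the envelope itself is always
respected. Passing tests on these panels show the solver and analytics
behave correctly under realistic magnitudes and dependence — they do not
certify the published provincial scores, whose raw inputs are unavailable.

`plant_frontier` rewrites one DMU to 0.9× the minimum on all
less-is-better variables and 1.1× the maximum on desirable outputs in
every period; dominance then forces all its slacks to zero, so it scores
exactly 1 — a known ground truth for recovery tests. Inflating the planted
DMU's inputs by `1 + δ` produces a clone whose score decreases strictly in
δ (verified over a 10-seed suite for δ ∈ {0.1, 0.25, 0.5}).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `W^t`, `W^k` | equal, normalized | period/division weights in all aggregations |
| LP tolerance | 1e−9 (retry at solver default) | HiGHS feasibility/optimality |
| score tolerance | 1e−6 | comparisons, lower clip |
| efficiency tolerance | 1e−7 | relative-slack threshold for "efficient" |
| zero repair | 1e−6 × within-period mean | replacement for exact zeros |
| coupling weights | 0.80–0.85 | generator causal strength |
| latent weight | 0.65 (0.3 with drivers) | shared province-size factor |
| AR(1) ρ | 0.9 | carry-over persistence |

## Known limitations

* Values are stored as given — no deflation or per-capita adjustment; a
  diagnostic warns when a variable spans a >10⁶ dynamic range.
* No super-efficiency, Malmquist index, bootstrap confidence intervals, or
  oriented model variants.
* Slack decompositions at alternate optima are solver-dependent (see
  above); only θ* itself is solver-invariant.
* The published provincial efficiency tables shipped with the package
  support the derived analytics only; the underlying observations cannot be
  reconstructed from them.
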