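"""Dynamic network slacks-based DEA solver with undesirable outputs.

For each evaluated DMU *o* the model builds one linear-fractional program.
The production possibility set is spanned, per division *k* and period *t*,
by an intensity vector ``lambda_k^t`` over all DMUs under variable returns
to scale (``e lambda_k^t = 1``). Observations of *o* are expressed as
frontier activity plus slack:

* inputs                 ``x_o = X lambda + s_x``            (s_x >= 0)
* desirable outputs      ``y_o = Y lambda - s_good``         (s_good >= 0)
* undesirable outputs    ``y_o = Y lambda + s_bad``          (s_bad >= 0)
* input-kind links       ``z_o = Z lambda_k + s_in`` plus flow continuity
  ``Z lambda_k = Z lambda_h`` between the source and target divisions
* free links             ``Z lambda_h = Z lambda_k`` (no slack)
* fix links              ``z_o = Z lambda_k`` and ``z_o = Z lambda_h``
* carry-overs            continuity ``Z lambda_k^t = Z lambda_k^{t+1}`` for
  every adjacent pair of periods, plus a slack equation per transition whose
  sign depends on the kind (input: cost, ``+s``; good: asset, ``-s``;
  free: signed slack; fix: none).

The overall score minimizes a ratio of weighted averages: the numerator
discounts 1 by the mean relative slack of inputs, input-kind links and
input-kind carry-overs of each division; the denominator inflates 1 by the
mean relative slack of desirable and undesirable outputs. The fractional
program is solved as a single LP per DMU via the Charnes-Cooper variable
substitution (all intensities and slacks scaled by a factor ``phi``, the
denominator normalized to 1); a Dinkelbach parametric iteration is kept as
an independent cross-check mode.

Period, division and division-period efficiencies are the corresponding
partial aggregations of the same optimal slack solution. Note one asymmetry
inherited from the model definition: the *period* decomposition excludes
carry-over slacks from its numerator but adds good-kind carry-over slacks
to its denominator, whereas the overall/division decompositions do the
opposite; both are evaluated exactly as defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .panel import (
    EFFICIENT_TOLERANCE,
    LP_TOLERANCE,
    SCORE_TOLERANCE,
    PanelDataset,
    PanelError,
)

SOLVER_BACKEND = "scipy-linprog-highs"


class SolverError(RuntimeError):
    """LP failure, carrying the solver status and the DMU id."""

    def __init__(self, dmu: str, status: str):
        super().__init__(f"LP solve failed for DMU {dmu!r}: {status}")
        self.dmu = dmu
        self.status = status


@dataclass
class SlackVar:
    """One slack column of the program (in mean-normalized units)."""

    col: int
    variable: str
    token: str           # period label, or "t1->t2" for carry-overs
    tag: str             # input | good | bad | link_in | co_input | co_good | co_free
    division: int        # division whose bracket the slack belongs to
    t_index: int         # period index used for the weight W^t
    obs: float           # observed value of the evaluated DMU (original units)
    scale: float = 1.0   # conditioning factor: constraint rows hold scale*value
    free: bool = False


@dataclass
class DivisionCounts:
    """Index-set sizes per division: m (inputs), linkin (input-kind links
    attributed to their source division), ninput/ngood (carry-over kinds),
    r1/r2 (desirable/undesirable outputs)."""

    m: int
    linkin: int
    ninput: int
    ngood: int
    r1: int
    r2: int

    @property
    def num_divisor(self) -> int:
        return self.m + self.linkin + self.ninput

    @property
    def den_divisor(self) -> int:
        return self.r1 + self.r2


def division_counts(ds: PanelDataset) -> dict[int, DivisionCounts]:
    out = {}
    for k in range(1, ds.divisions + 1):
        out[k] = DivisionCounts(
            m=len(ds.by_role(k, "input")),
            linkin=len(ds.by_role(k, "link", link_kind="in")),
            ninput=len(ds.by_role(k, "carryover", carryover_kind="input")),
            ngood=len(ds.by_role(k, "carryover", carryover_kind="good")),
            r1=len(ds.by_role(k, "desirable_output")),
            r2=len(ds.by_role(k, "undesirable_output")),
        )
    return out


@dataclass
class ProgramSpec:
    """Assembled Charnes-Cooper LP for one evaluated DMU.

    Column 0 is the scale factor ``phi``; then one intensity block of length
    n per (division, period); then the slack columns in ``slack_vars``.
    """

    dmu: str
    n: int
    K: int
    T: int
    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    bounds: list[tuple[float | None, float | None]]
    slack_vars: list[SlackVar]
    row_labels: list[str]
    counts: dict[int, DivisionCounts]

    @property
    def n_lambda_blocks(self) -> int:
        return self.K * self.T

    @property
    def n_convexity_rows(self) -> int:
        return sum(lbl.startswith("convexity") for lbl in self.row_labels)

    @property
    def n_continuity_rows(self) -> int:
        return sum(lbl.startswith("carryover-continuity") for lbl in self.row_labels)

    def lam_col(self, k: int, t: int, j: int) -> int:
        return 1 + ((k - 1) * self.T + t) * self.n + j


def build_program(ds: PanelDataset, dmu_o: str, weights=None) -> ProgramSpec:
    """Assemble the per-DMU linear program (already Charnes-Cooper scaled).

    ``weights`` optionally overrides ``(period_weights, division_weights)``.
    The evaluated DMU's own unit intensity with zero slacks satisfies every
    constraint, so the program is always feasible.
    """
    if dmu_o not in ds.dmus:
        raise PanelError(f"unknown DMU {dmu_o!r}")
    n, K, T = ds.n, ds.divisions, ds.T
    Wt, Wk = (weights if weights is not None
              else (ds.period_weights, ds.division_weights))
    Wt = np.asarray(Wt, float) / np.sum(Wt)
    Wk = np.asarray(Wk, float) / np.sum(Wk)
    counts = division_counts(ds)

    n_lambda = K * T * n
    slack_vars: list[SlackVar] = []
    rows: list[dict[int, float]] = []
    rhs: list[float] = []
    labels: list[str] = []

    def new_slack(variable, token, tag, division, t_index, obs, scale, free=False) -> int:
        col = 1 + n_lambda + len(slack_vars)
        slack_vars.append(
            SlackVar(col, variable, token, tag, division, t_index, obs, scale, free))
        return col

    def scaled(name, tok):
        # scores are units-invariant; normalizing every variable by its
        # cross-sectional mean keeps the LP well conditioned
        v = ds.vector(name, tok)
        f = 1.0 / float(np.mean(v))
        return v * f, ds.value(dmu_o, name, tok), f

    def add_row(coefs: dict[int, float], b: float, label: str) -> None:
        rows.append(coefs)
        rhs.append(b)
        labels.append(label)

    def lam_col(k, t, j):
        return 1 + ((k - 1) * T + t) * n + j

    def lam_terms(k, t, vec, sign=1.0):
        return {lam_col(k, t, j): sign * float(vec[j]) for j in range(n)}

    # production-possibility and convexity rows
    for k in range(1, K + 1):
        for t, tok in enumerate(ds.periods):
            for s in ds.by_role(k, "input"):
                v, obs, f = scaled(s.name, tok)
                col = new_slack(s.name, tok, "input", k, t, obs, f)
                add_row({**lam_terms(k, t, v), col: 1.0, 0: -obs * f},
                        0.0, f"input[{s.name},{tok}]")
            for s in ds.by_role(k, "desirable_output"):
                v, obs, f = scaled(s.name, tok)
                col = new_slack(s.name, tok, "good", k, t, obs, f)
                add_row({**lam_terms(k, t, v), col: -1.0, 0: -obs * f},
                        0.0, f"good[{s.name},{tok}]")
            for s in ds.by_role(k, "undesirable_output"):
                v, obs, f = scaled(s.name, tok)
                col = new_slack(s.name, tok, "bad", k, t, obs, f)
                add_row({**lam_terms(k, t, v), col: 1.0, 0: -obs * f},
                        0.0, f"bad[{s.name},{tok}]")
            add_row({**{lam_col(k, t, j): 1.0 for j in range(n)}, 0: -1.0},
                    0.0, f"convexity[{k},{tok}]")

    # link rows
    for s in ds.specs:
        if s.role != "link":
            continue
        k, h = s.division, s.target_division
        for t, tok in enumerate(ds.periods):
            v, obs, f = scaled(s.name, tok)
            if s.link_kind == "fix":
                add_row({**lam_terms(k, t, v), 0: -obs * f}, 0.0,
                        f"link-fix-src[{s.name},{tok}]")
                add_row({**lam_terms(h, t, v), 0: -obs * f}, 0.0,
                        f"link-fix-dst[{s.name},{tok}]")
            else:
                cont = lam_terms(h, t, v)
                for c, val in lam_terms(k, t, v, sign=-1.0).items():
                    cont[c] = cont.get(c, 0.0) + val
                add_row(cont, 0.0, f"link-continuity[{s.name},{tok}]")
                if s.link_kind == "in":
                    col = new_slack(s.name, tok, "link_in", k, t, obs, f)
                    add_row({**lam_terms(k, t, v), col: 1.0, 0: -obs * f},
                            0.0, f"link-in[{s.name},{tok}]")

    # carry-over rows
    for s in ds.specs:
        if s.role != "carryover":
            continue
        k = s.division
        for ti, tok in enumerate(ds.transitions):
            v, obs, f = scaled(s.name, tok)
            cont = lam_terms(k, ti, v)
            for c, val in lam_terms(k, ti + 1, v, sign=-1.0).items():
                cont[c] = cont.get(c, 0.0) + val
            add_row(cont, 0.0, f"carryover-continuity[{s.name},{tok}]")
            kind = s.carryover_kind
            if kind == "fix":
                add_row({**lam_terms(k, ti, v), 0: -obs * f}, 0.0,
                        f"carryover-fix[{s.name},{tok}]")
            elif kind == "input":
                col = new_slack(s.name, tok, "co_input", k, ti, obs, f)
                add_row({**lam_terms(k, ti, v), col: 1.0, 0: -obs * f},
                        0.0, f"carryover-input[{s.name},{tok}]")
            elif kind == "good":
                col = new_slack(s.name, tok, "co_good", k, ti, obs, f)
                add_row({**lam_terms(k, ti, v), col: -1.0, 0: -obs * f},
                        0.0, f"carryover-good[{s.name},{tok}]")
            elif kind == "free":
                col = new_slack(s.name, tok, "co_free", k, ti, obs, f, free=True)
                add_row({**lam_terms(k, ti, v), col: 1.0, 0: -obs * f},
                        0.0, f"carryover-free[{s.name},{tok}]")

    n_vars = 1 + n_lambda + len(slack_vars)

    # objective (numerator) and denominator-normalization row
    c = np.zeros(n_vars)
    c[0] = 1.0
    den_row = {0: 1.0}
    for sv in slack_vars:
        w = Wt[sv.t_index] * Wk[sv.division - 1]
        cnt = counts[sv.division]
        if sv.tag in ("input", "link_in", "co_input") and cnt.num_divisor > 0:
            c[sv.col] = -w / (cnt.num_divisor * sv.obs * sv.scale)
        elif sv.tag in ("good", "bad") and cnt.den_divisor > 0:
            den_row[sv.col] = w / (cnt.den_divisor * sv.obs * sv.scale)

    A = np.zeros((len(rows) + 1, n_vars))
    b = np.zeros(len(rows) + 1)
    A[0, list(den_row)] = list(den_row.values())
    b[0] = 1.0
    for i, row in enumerate(rows, start=1):
        A[i, list(row)] = list(row.values())
        b[i] = rhs[i - 1]
    labels = ["denominator-normalization"] + labels

    bounds: list[tuple[float | None, float | None]] = [(LP_TOLERANCE, None)]
    bounds += [(0.0, None)] * n_lambda
    for sv in slack_vars:
        bounds.append((None, None) if sv.free else (0.0, None))

    return ProgramSpec(
        dmu=dmu_o, n=n, K=K, T=T, c=c, A_eq=A, b_eq=b, bounds=bounds,
        slack_vars=slack_vars, row_labels=labels, counts=counts,
    )


@dataclass
class SolveResult:
    """Optimal decompositions, slacks and intensities for one DMU.

    Efficiencies are ratio evaluations of the same optimal slack solution:
    ``overall`` aggregates over periods and divisions, ``period[t]`` over
    divisions, ``division[k]`` over periods, ``division_period[(k, t)]`` is
    the per-cell ratio. All lie in (0, 1]; the DMU is efficient (score 1)
    iff every relative slack is at numerical zero.
    """

    dmu: str
    overall: float
    period: dict[str, float]
    division: dict[int, float]
    division_period: dict[tuple[int, str], float]
    slacks: dict[tuple[str, str], float]
    intensities: dict[tuple[int, str], np.ndarray]
    projections: dict[tuple[str, str], float]
    status: str = "optimal"
    objective_check: float = field(default=np.nan)

    @property
    def max_relative_slack(self) -> float:
        rel = [abs(v) for v in self.slacks.values()]
        return max(rel) if rel else 0.0

    @property
    def is_efficient(self) -> bool:
        return self.max_relative_slack <= EFFICIENT_TOLERANCE


def _bracket_terms(ds: PanelDataset, dmu_o: str, rel_slack) -> dict:
    """Per-(division, period) numerator/denominator brackets.

    ``num1/den1`` follow the overall/division/division-period definition
    (carry-over input slack in the numerator, outputs only in the
    denominator); ``num2/den2`` follow the period definition (no carry-over
    term in the numerator, good-kind carry-over slack in the denominator).
    ``rel_slack(variable, token)`` returns slack / observed.
    """
    counts = division_counts(ds)
    T = ds.T
    out = {"num1": {}, "den1": {}, "num2": {}, "den2": {}}
    for k in range(1, ds.divisions + 1):
        cnt = counts[k]
        for t, tok in enumerate(ds.periods):
            in_terms = sum(rel_slack(s.name, tok) for s in ds.by_role(k, "input"))
            in_terms += sum(rel_slack(s.name, tok)
                            for s in ds.by_role(k, "link", link_kind="in"))
            co_in = 0.0
            co_good = 0.0
            if t < T - 1:
                tr = ds.transitions[t]
                co_in = sum(rel_slack(s.name, tr)
                            for s in ds.by_role(k, "carryover", carryover_kind="input"))
                co_good = sum(rel_slack(s.name, tr)
                              for s in ds.by_role(k, "carryover", carryover_kind="good"))
            out_terms = sum(rel_slack(s.name, tok)
                            for s in ds.by_role(k, "desirable_output"))
            out_terms += sum(rel_slack(s.name, tok)
                             for s in ds.by_role(k, "undesirable_output"))

            d1 = cnt.num_divisor
            out["num1"][(k, tok)] = 1.0 - (in_terms + co_in) / d1 if d1 else 1.0
            d2 = cnt.den_divisor
            out["den1"][(k, tok)] = 1.0 + out_terms / d2 if d2 else 1.0
            dp = cnt.m + cnt.linkin
            out["num2"][(k, tok)] = 1.0 - in_terms / dp if dp else 1.0
            dq = cnt.r1 + cnt.r2 + cnt.ngood
            out["den2"][(k, tok)] = 1.0 + (out_terms + co_good) / dq if dq else 1.0
    return out


def _clip_score(x: float) -> float:
    return float(min(1.0, max(SCORE_TOLERANCE, x)))


def overall_from_slacks(ds, dmu_o, rel_slack, Wt, Wk) -> float:
    br = _bracket_terms(ds, dmu_o, rel_slack)
    num = den = 0.0
    for k in range(1, ds.divisions + 1):
        for t, tok in enumerate(ds.periods):
            w = Wt[t] * Wk[k - 1]
            num += w * br["num1"][(k, tok)]
            den += w * br["den1"][(k, tok)]
    return _clip_score(num / den)


def period_efficiency(ds, dmu_o, rel_slack, Wk) -> dict[str, float]:
    """Period scores: division-weighted ratio per period at given slacks."""
    br = _bracket_terms(ds, dmu_o, rel_slack)
    out = {}
    for t, tok in enumerate(ds.periods):
        num = sum(Wk[k - 1] * br["num2"][(k, tok)] for k in range(1, ds.divisions + 1))
        den = sum(Wk[k - 1] * br["den2"][(k, tok)] for k in range(1, ds.divisions + 1))
        out[tok] = _clip_score(num / den)
    return out


def division_efficiency(ds, dmu_o, rel_slack, Wt) -> dict[int, float]:
    """Division scores: period-weighted ratio per division at given slacks."""
    br = _bracket_terms(ds, dmu_o, rel_slack)
    out = {}
    for k in range(1, ds.divisions + 1):
        num = sum(Wt[t] * br["num1"][(k, tok)] for t, tok in enumerate(ds.periods))
        den = sum(Wt[t] * br["den1"][(k, tok)] for t, tok in enumerate(ds.periods))
        out[k] = _clip_score(num / den)
    return out


def division_period_efficiency(ds, dmu_o, rel_slack) -> dict[tuple[int, str], float]:
    """Per-(division, period) ratio at given slacks."""
    br = _bracket_terms(ds, dmu_o, rel_slack)
    return {
        (k, tok): _clip_score(br["num1"][(k, tok)] / br["den1"][(k, tok)])
        for k in range(1, ds.divisions + 1)
        for tok in ds.periods
    }


def solve_overall(
    ds: PanelDataset,
    dmu_o: str,
    weights=None,
    method: str = "charnes-cooper",
    maximize_slacks: bool = False,
) -> SolveResult:
    """Solve the dynamic network SBM for one DMU and decompose the optimum.

    ``method="charnes-cooper"`` (default) solves a single LP;
    ``method="dinkelbach"`` iterates the parametric LP as an independent
    cross-check. ``maximize_slacks`` runs a secondary LP that, holding the
    optimal score fixed, maximizes total normalized slack to pin down an
    otherwise possibly non-unique slack decomposition.
    """
    prog = build_program(ds, dmu_o, weights)
    Wt, Wk = (weights if weights is not None
              else (ds.period_weights, ds.division_weights))
    Wt = np.asarray(Wt, float) / np.sum(Wt)
    Wk = np.asarray(Wk, float) / np.sum(Wk)

    if method == "charnes-cooper":
        x, theta = _solve_charnes_cooper(prog, maximize_slacks)
        phi = x[0]
        lam = x[1:1 + prog.n * prog.K * prog.T] / phi
        slack_raw = {sv.col: x[sv.col] / phi / sv.scale for sv in prog.slack_vars}
    elif method == "dinkelbach":
        lam, slack_raw, theta = _solve_dinkelbach(prog)
    else:
        raise ValueError(f"unknown method {method!r}")

    slacks = {(sv.variable, sv.token): float(slack_raw[sv.col]) for sv in prog.slack_vars}
    rel = {(sv.variable, sv.token): float(slack_raw[sv.col]) / sv.obs
           for sv in prog.slack_vars}

    def rel_slack(name, token):
        return rel.get((name, token), 0.0)

    intensities = {}
    for k in range(1, prog.K + 1):
        for t, tok in enumerate(ds.periods):
            base = ((k - 1) * prog.T + t) * prog.n
            intensities[(k, tok)] = np.asarray(lam[base:base + prog.n])

    projections = {}
    for s in ds.specs:
        for tok in ds.tokens_for(s):
            obs = ds.value(dmu_o, s.name, tok)
            sl = slacks.get((s.name, tok), 0.0)
            if s.role == "desirable_output":
                projections[(s.name, tok)] = obs + sl
            elif s.role in ("input", "undesirable_output"):
                projections[(s.name, tok)] = obs - sl
            elif s.role == "link":
                projections[(s.name, tok)] = obs - sl  # fix/free: sl == 0
            else:  # carryover
                sign = -1.0 if s.carryover_kind == "good" else 1.0
                projections[(s.name, tok)] = obs - sign * sl

    overall = overall_from_slacks(ds, dmu_o, rel_slack, Wt, Wk)
    return SolveResult(
        dmu=dmu_o,
        overall=overall,
        period=period_efficiency(ds, dmu_o, rel_slack, Wk),
        division=division_efficiency(ds, dmu_o, rel_slack, Wt),
        division_period=division_period_efficiency(ds, dmu_o, rel_slack),
        slacks=slacks,
        intensities=intensities,
        projections=projections,
        objective_check=float(theta),
    )


def _solve_charnes_cooper(prog: ProgramSpec, maximize_slacks: bool):
    res = linprog(
        prog.c, A_eq=prog.A_eq, b_eq=prog.b_eq, bounds=prog.bounds,
        method="highs", options={"primal_feasibility_tolerance": LP_TOLERANCE,
                                 "dual_feasibility_tolerance": LP_TOLERANCE},
    )
    if not res.success:  # retry at the solver's default tolerances
        res = linprog(prog.c, A_eq=prog.A_eq, b_eq=prog.b_eq,
                      bounds=prog.bounds, method="highs")
    if not res.success:
        raise SolverError(prog.dmu, res.message)
    x, theta = res.x, float(res.fun)
    if maximize_slacks and prog.slack_vars:
        c2 = np.zeros_like(prog.c)
        for sv in prog.slack_vars:
            if not sv.free:
                c2[sv.col] = -1.0 / sv.obs  # maximize total normalized slack
        A2 = np.vstack([prog.A_eq, prog.c])
        b2 = np.concatenate([prog.b_eq, [theta]])
        res2 = linprog(c2, A_eq=A2, b_eq=b2, bounds=prog.bounds, method="highs")
        if res2.success:
            x = res2.x
    return x, theta


def _solve_dinkelbach(prog: ProgramSpec, max_iter: int = 60):
    """Parametric-iteration solve in the original (unscaled) variables.

    The Charnes-Cooper program stores homogeneous rows ``A [phi, v] = 0``
    with the evaluated DMU's observations on the phi column; fixing phi = 1
    recovers the original constraints. Iterates q -> min N(s) - q D(s).
    """
    A = prog.A_eq[1:, 1:]          # drop normalization row and phi column
    b = -prog.A_eq[1:, 0]          # move phi column to the RHS (phi = 1)
    bounds = prog.bounds[1:]
    a_num = -prog.c[1:]            # numerator slack coefficients (positive)
    b_den = prog.A_eq[0, 1:]       # denominator slack coefficients

    q = 1.0
    for _ in range(max_iter):
        res = linprog(-(a_num + q * b_den), A_eq=A, b_eq=b, bounds=bounds,
                      method="highs")
        if not res.success:
            raise SolverError(prog.dmu, f"dinkelbach: {res.message}")
        v = res.x
        num = 1.0 - float(a_num @ v)
        den = 1.0 + float(b_den @ v)
        f = num - q * den
        q_new = num / den
        if abs(f) < 1e-10 or abs(q_new - q) < 1e-12:
            q = q_new
            break
        q = q_new
    lam = v[: prog.n * prog.K * prog.T]
    slack_raw = {sv.col: v[sv.col - 1] / sv.scale for sv in prog.slack_vars}
    return lam, slack_raw, q


def solve_all(ds: PanelDataset, weights=None, **kw) -> dict[str, SolveResult]:
    """Solve every DMU in the panel; deterministic given the dataset."""
    return {j: solve_overall(ds, j, weights=weights, **kw) for j in ds.dmus}
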