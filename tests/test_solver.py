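"""Dynamic network SBM solver: program structure, oracle equivalence,
frontier properties, decompositions."""

import numpy as np
import pytest

from dndea import (
    PanelDataset,
    VariableSpec,
    build_program,
    solve_all,
    solve_overall,
)
from dndea.solver import division_counts

from conftest import dataset_from_arrays, random_static_instance, sbm_oracle, static_dataset

ABC = {"A": (1.0, 1.0), "B": (2.0, 1.0), "C": (2.0, 2.0)}


def two_stage_dataset(n=4, T=5, seed=0):
    """Small two-division panel with one input-kind link and one input-kind
    carry-over per division pattern of the study schema."""
    rng = np.random.default_rng(seed)
    specs = [
        VariableSpec("x1", 1, "input"),
        VariableSpec("g1", 1, "desirable_output"),
        VariableSpec("b1", 1, "undesirable_output"),
        VariableSpec("ln", 1, "link", link_kind="in", target_division=2),
        VariableSpec("co", 1, "carryover", carryover_kind="input"),
        VariableSpec("x2", 2, "input"),
        VariableSpec("g2", 2, "desirable_output"),
    ]
    periods = [f"t{i}" for i in range(1, T + 1)]
    ds = PanelDataset([f"D{j}" for j in range(n)], 2, periods, specs, {})
    for s in specs:
        for tok in ds.tokens_for(s):
            for j in ds.dmus:
                ds.values[(j, s.name, tok)] = float(rng.uniform(1.0, 5.0))
    return ds


class TestProgramStructure:
    def test_degenerate_single_block(self):
        ds = static_dataset(ABC)
        prog = build_program(ds, "B")
        assert prog.n_lambda_blocks == 1
        assert prog.n_convexity_rows == 1
        assert prog.n_continuity_rows == 0

    def test_two_division_five_period_counts(self):
        ds = two_stage_dataset(T=5)
        prog = build_program(ds, "D0")
        assert prog.n_lambda_blocks == 10
        assert prog.n_convexity_rows == 10
        assert prog.n_continuity_rows == 4  # one carry-over, T-1 transitions

    def test_self_evaluation_is_feasible_point(self):
        """The evaluated DMU's own unit intensity with zero slacks satisfies
        every constraint of the scaled program (phi = 1)."""
        ds = two_stage_dataset()
        prog = build_program(ds, "D1")
        x0 = np.zeros(prog.A_eq.shape[1])
        x0[0] = 1.0
        j = ds.dmus.index("D1")
        for k in range(1, 3):
            for t in range(ds.T):
                x0[prog.lam_col(k, t, j)] = 1.0
        assert np.allclose(prog.A_eq @ x0, prog.b_eq, atol=1e-9)

    def test_link_with_coinciding_divisions_rejected(self):
        from dndea import PanelError
        with pytest.raises(PanelError, match="coincide"):
            VariableSpec("z", 2, "link", link_kind="fix", target_division=2)

    def test_division_counts_for_study_schema(self, study_panel):
        cnt = division_counts(study_panel)
        assert (cnt[1].m, cnt[1].linkin, cnt[1].ninput) == (2, 1, 1)
        assert (cnt[1].r1, cnt[1].r2) == (1, 1)
        assert (cnt[2].m, cnt[2].r1, cnt[2].r2) == (1, 1, 1)


class TestFrontierBasics:
    def test_single_dmu_is_its_own_frontier(self):
        ds = static_dataset({"A": (1.0, 1.0)})
        assert solve_overall(ds, "A").overall == 1.0

    def test_duplicate_dmus_both_efficient(self):
        ds = two_stage_dataset(n=2, seed=3)
        for j in ds.dmus:
            for s in ds.specs:
                for tok in ds.tokens_for(s):
                    ds.values[(j, s.name, tok)] = ds.values[(ds.dmus[0], s.name, tok)]
        for j in ds.dmus:
            res = solve_overall(ds, j)
            assert res.overall == pytest.approx(1.0, abs=1e-9)
            assert res.is_efficient

    def test_efficiency_iff_zero_slacks(self, study_panel, study_results):
        for res in study_results.values():
            rel = max((abs(s) / study_panel.value(res.dmu, v, tok)
                       for (v, tok), s in res.slacks.items()), default=0.0)
            assert (res.overall >= 1.0 - 1e-9) == (rel <= 1e-7)


class TestOracleEquivalence:
    def test_abc_instance_matches_oracle(self):
        ds = static_dataset(ABC)
        X = np.array([[1.0, 2.0, 2.0]])
        Y = np.array([[1.0, 1.0, 2.0]])
        for o, dmu in enumerate(ds.dmus):
            assert solve_overall(ds, dmu).overall == pytest.approx(
                sbm_oracle(X, Y, o), abs=1e-7)

    def test_random_instances_match_oracle(self):
        """Static reduction: with one division, one period and no links the
        score equals the classic non-oriented VRS SBM."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            X, Y = random_static_instance(rng)
            ds = dataset_from_arrays(X, Y)
            o = int(rng.integers(0, X.shape[1]))
            ours = solve_overall(ds, ds.dmus[o]).overall
            assert ours == pytest.approx(sbm_oracle(X, Y, o), abs=1e-6)

    def test_dinkelbach_mode_agrees_with_charnes_cooper(self):
        ds = two_stage_dataset(n=5, T=3, seed=9)
        for dmu in ds.dmus:
            cc = solve_overall(ds, dmu, method="charnes-cooper").overall
            dk = solve_overall(ds, dmu, method="dinkelbach").overall
            assert cc == pytest.approx(dk, abs=1e-7)


class TestInvariances:
    def test_units_invariance(self):
        """Rescaling any one variable for all DMUs and periods leaves every
        efficiency unchanged (slacks scale with their observations)."""
        ds = two_stage_dataset(n=5, T=3, seed=11)
        base = {j: solve_overall(ds, j) for j in ds.dmus}
        rng = np.random.default_rng(1)
        for var in ("x1", "g1", "b1", "ln", "co"):
            scaled = ds.copy()
            c = float(rng.uniform(0.1, 10))
            for key in list(scaled.values):
                if key[1] == var:
                    scaled.values[key] = scaled.values[key] * c
            for j in ds.dmus:
                res = solve_overall(scaled, j)
                assert res.overall == pytest.approx(base[j].overall, abs=1e-6)
                for kt, v in res.division_period.items():
                    assert v == pytest.approx(base[j].division_period[kt], abs=1e-6)

    def test_dominated_entrant_leaves_scores_unchanged(self):
        """Adding a DMU weakly worse on inputs, desirable and undesirable
        outputs — with link and carry-over values identical to an incumbent's
        — does not move any score: the continuity equalities are untouched
        and every production constraint only tightens."""
        ds = two_stage_dataset(n=4, T=2, seed=5)
        base = {j: solve_overall(ds, j).overall for j in ds.dmus}
        worse = ds.copy()
        worse.dmus = ds.dmus + ["W"]
        ref = ds.dmus[0]
        for s in ds.specs:
            for tok in ds.tokens_for(s):
                v = ds.value(ref, s.name, tok)
                if s.role == "desirable_output":
                    v *= 0.8
                elif s.role == "input" or s.role == "undesirable_output":
                    v *= 1.3
                worse.values[("W", s.name, tok)] = v
        for j in ds.dmus:
            assert solve_overall(worse, j).overall == pytest.approx(base[j], abs=1e-7)

    def test_dominated_entrant_without_coupling(self):
        """In a panel with no links or carry-overs, a DMU weakly worse on
        every variable leaves every incumbent score unchanged."""
        rng = np.random.default_rng(5)
        specs = [VariableSpec("x1", 1, "input"),
                 VariableSpec("g1", 1, "desirable_output"),
                 VariableSpec("b1", 1, "undesirable_output")]
        ds = PanelDataset([f"D{j}" for j in range(4)], 1, ["t1", "t2"], specs, {})
        for s in specs:
            for tok in ds.periods:
                for j in ds.dmus:
                    ds.values[(j, s.name, tok)] = float(rng.uniform(1, 5))
        base = {j: solve_overall(ds, j).overall for j in ds.dmus}
        worse = ds.copy()
        worse.dmus = ds.dmus + ["W"]
        for s in specs:
            for tok in ds.periods:
                v = ds.value("D0", s.name, tok)
                worse.values[("W", s.name, tok)] = v * (
                    0.8 if s.role == "desirable_output" else 1.3)
        for j in ds.dmus:
            assert solve_overall(worse, j).overall == pytest.approx(base[j], abs=1e-7)

    def test_input_monotonicity(self):
        """Increasing one input of the evaluated DMU never increases its
        overall score."""
        ds = two_stage_dataset(n=5, T=2, seed=13)
        dmu = "D2"
        prev = solve_overall(ds, dmu).overall
        for bump in (1.1, 1.5, 2.5):
            mod = ds.copy()
            for tok in ds.periods:
                mod.values[(dmu, "x1", tok)] = ds.value(dmu, "x1", tok) * bump
            cur = solve_overall(mod, dmu).overall
            assert cur <= prev + 1e-8
            prev = cur


class TestLinkAndCarryoverKinds:
    def _with_kinds(self, link_kind, co_kind, seed=31):
        rng = np.random.default_rng(seed)
        specs = [
            VariableSpec("x1", 1, "input"),
            VariableSpec("g1", 1, "desirable_output"),
            VariableSpec("lk", 1, "link", link_kind=link_kind, target_division=2),
            VariableSpec("co", 1, "carryover", carryover_kind=co_kind),
            VariableSpec("x2", 2, "input"),
            VariableSpec("g2", 2, "desirable_output"),
        ]
        ds = PanelDataset([f"D{j}" for j in range(4)], 2, ["t1", "t2", "t3"],
                          specs, {})
        for s in specs:
            for tok in ds.tokens_for(s):
                for j in ds.dmus:
                    ds.values[(j, s.name, tok)] = float(rng.uniform(1, 4))
        return ds

    @pytest.mark.parametrize("link_kind", ["fix", "free", "in"])
    @pytest.mark.parametrize("co_kind", ["input", "good", "free", "fix"])
    def test_all_kind_combinations_solve_in_range(self, link_kind, co_kind):
        ds = self._with_kinds(link_kind, co_kind)
        for j in ds.dmus:
            res = solve_overall(ds, j)
            assert 0.0 < res.overall <= 1.0

    def test_fix_link_projection_equals_observation(self):
        """Non-discretionary links carry no slack: the projection is the
        observed value."""
        ds = self._with_kinds("fix", "fix")
        for j in ds.dmus:
            res = solve_overall(ds, j)
            for tok in ds.periods:
                assert res.projections[("lk", tok)] == ds.value(j, "lk", tok)
            assert ("lk", ds.periods[0]) not in res.slacks

    def test_good_carryover_slack_raises_projection(self):
        """A desirable carry-over projects upward (target >= observed)."""
        ds = self._with_kinds("free", "good")
        for j in ds.dmus:
            res = solve_overall(ds, j)
            for tr in ds.transitions:
                assert res.projections[("co", tr)] >= ds.value(j, "co", tr) - 1e-9


class TestDecompositions:
    def test_all_slack_free_dmu_scores_one_everywhere(self):
        from dndea import plant_frontier
        ds = plant_frontier(two_stage_dataset(n=4, T=3, seed=2), "D0")
        res = solve_overall(ds, "D0")
        assert res.overall == 1.0
        assert all(v == 1.0 for v in res.period.values())
        assert all(v == 1.0 for v in res.division.values())
        assert all(v == 1.0 for v in res.division_period.values())

    def test_identical_periods_give_equal_period_scores(self):
        """With the same data in every period and no carry-overs, the period
        scores coincide by symmetry."""
        specs = [VariableSpec("x", 1, "input"),
                 VariableSpec("y", 1, "desirable_output")]
        values = {}
        for tok in ("t1", "t2", "t3"):
            for d, (x, y) in ABC.items():
                values[(d, "x", tok)] = x
                values[(d, "y", tok)] = y
        ds = PanelDataset(list(ABC), 1, ["t1", "t2", "t3"], specs, values)
        res = solve_overall(ds, "B")
        vals = list(res.period.values())
        assert all(v == pytest.approx(vals[0], abs=1e-8) for v in vals)
        assert res.overall == pytest.approx(sbm_oracle(
            np.array([[1.0, 2, 2]]), np.array([[1.0, 1, 2]]), 1), abs=1e-7)

    def test_doubled_second_period_replicates_static_scores(self):
        """Scaling a whole period's data by a constant leaves that period's
        score at the single-period value (units/replication property)."""
        specs = [VariableSpec("x", 1, "input"),
                 VariableSpec("y", 1, "desirable_output")]
        values = {}
        for tok, scale in (("t1", 1.0), ("t2", 2.0)):
            for d, (x, y) in ABC.items():
                values[(d, "x", tok)] = x * scale
                values[(d, "y", tok)] = y * scale
        ds = PanelDataset(list(ABC), 1, ["t1", "t2"], specs, values)
        static = sbm_oracle(np.array([[1.0, 2, 2]]), np.array([[1.0, 1, 2]]), 1)
        res = solve_overall(ds, "B")
        for tok in ("t1", "t2"):
            assert res.period[tok] == pytest.approx(static, abs=1e-7)

    def test_single_division_collapse(self):
        """K=1: the division score equals the overall; K=1 and T=1: all four
        decompositions coincide."""
        ds = static_dataset(ABC)
        res = solve_overall(ds, "B")
        assert res.division[1] == pytest.approx(res.overall, abs=1e-9)
        assert res.period["t1"] == pytest.approx(res.overall, abs=1e-9)
        assert res.division_period[(1, "t1")] == pytest.approx(res.overall, abs=1e-9)

    def test_symmetric_division_data_scores_one(self):
        """A division whose data are identical across DMUs admits no slack
        under the convexity constraint, so its division score is 1."""
        ds = two_stage_dataset(n=4, T=2, seed=21)
        for s in ds.specs:
            if s.division == 2 and s.role != "link":
                for tok in ds.tokens_for(s):
                    for j in ds.dmus:
                        ds.values[(j, s.name, tok)] = ds.values[(ds.dmus[0], s.name, tok)]
        for j in ds.dmus:
            res = solve_overall(ds, j)
            assert res.division[2] == pytest.approx(1.0, abs=1e-8)

    def test_projections_bracket_observations(self, study_panel, study_results):
        for res in study_results.values():
            for s in study_panel.specs:
                for tok in study_panel.tokens_for(s):
                    obs = study_panel.value(res.dmu, s.name, tok)
                    proj = res.projections[(s.name, tok)]
                    if s.role == "desirable_output":
                        assert proj >= obs - 1e-9 * obs
                    elif s.role in ("input", "undesirable_output", "link") or (
                            s.role == "carryover" and s.carryover_kind == "input"):
                        assert proj <= obs + 1e-9 * obs

    def test_scores_in_unit_interval(self, study_results):
        for res in study_results.values():
            for v in ([res.overall] + list(res.period.values())
                      + list(res.division.values())
                      + list(res.division_period.values())):
                assert 0.0 < v <= 1.0
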