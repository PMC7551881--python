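"""Shared fixtures and the independent static-SBM oracle.

The oracle solves the classic non-oriented slacks-based measure under
variable returns to scale by Dinkelbach's parametric iteration, with its
own constraint assembly — a deliberately separate code path from the
package's Charnes-Cooper program builder, so the two can check each other.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from dndea import PanelDataset, VariableSpec, generate_panel, GeneratorConfig


def static_dataset(data: dict[str, tuple], n_inputs: int = 1) -> PanelDataset:
    """One-division, one-period dataset from ``{dmu: (x..., y...)}`` tuples:
    the first ``n_inputs`` entries are inputs, the rest desirable outputs."""
    any_row = next(iter(data.values()))
    n_outputs = len(any_row) - n_inputs
    specs = [VariableSpec(f"x{i}", 1, "input") for i in range(n_inputs)]
    specs += [VariableSpec(f"y{r}", 1, "desirable_output") for r in range(n_outputs)]
    values = {}
    for dmu, row in data.items():
        for s, v in zip(specs, row):
            values[(dmu, s.name, "t1")] = float(v)
    return PanelDataset(list(data), 1, ["t1"], specs, values)


def sbm_oracle(X: np.ndarray, Y: np.ndarray, o: int, tol: float = 1e-11) -> float:
    """Non-oriented VRS SBM score of DMU ``o`` by Dinkelbach iteration.

    ``X`` is (m, n) inputs, ``Y`` is (q, n) desirable outputs. Minimizes
    (1 - mean input slack ratio) / (1 + mean output slack ratio) over the
    convex production set; each iteration is one generic LP assembled here.
    """
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    m, n = X.shape
    q_out = Y.shape[0]
    nv = n + m + q_out  # lambda, s-, s+
    A = np.zeros((m + q_out + 1, nv))
    b = np.zeros(m + q_out + 1)
    for i in range(m):
        A[i, :n] = X[i]
        A[i, n + i] = 1.0
        b[i] = X[i, o]
    for r in range(q_out):
        A[m + r, :n] = Y[r]
        A[m + r, n + m + r] = -1.0
        b[m + r] = Y[r, o]
    A[m + q_out, :n] = 1.0
    b[m + q_out] = 1.0
    a_num = np.concatenate([np.zeros(n), 1.0 / (m * X[:, o]), np.zeros(q_out)])
    b_den = np.concatenate([np.zeros(n + m), 1.0 / (q_out * Y[:, o])])

    rho = 1.0
    for _ in range(100):
        res = linprog(-(a_num + rho * b_den), A_eq=A, b_eq=b,
                      bounds=[(0, None)] * nv, method="highs")
        assert res.success, res.message
        num = 1.0 - float(a_num @ res.x)
        den = 1.0 + float(b_den @ res.x)
        new = num / den
        if abs(num - rho * den) < tol:
            return new
        rho = new
    return rho


def random_static_instance(rng, n_max: int = 6):
    """Random (X, Y) with 2 inputs, 2 outputs, n <= n_max DMUs."""
    n = int(rng.integers(3, n_max + 1))
    X = rng.uniform(0.5, 5.0, size=(2, n))
    Y = rng.uniform(0.5, 5.0, size=(2, n))
    return X, Y


def dataset_from_arrays(X: np.ndarray, Y: np.ndarray) -> PanelDataset:
    data = {f"D{j}": tuple(X[:, j]) + tuple(Y[:, j]) for j in range(X.shape[1])}
    return static_dataset(data, n_inputs=X.shape[0])


@pytest.fixture(scope="session")
def study_panel() -> PanelDataset:
    """Default-condition synthetic panel: 31 DMUs x 2 divisions x 5 periods."""
    return generate_panel(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def study_results(study_panel):
    from dndea import solve_all

    return solve_all(study_panel)
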