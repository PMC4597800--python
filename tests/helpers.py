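"""Shared builders for randomized discrete scenarios (exposure x outcome x
one categorical confounder) used to machine-verify the factorization
equivalence: CRA exposure-coefficient bias vanishes iff the mechanism
factorizes as s(X,C) t(Y,C)."""

import numpy as np
import pandas as pd

from crabias import DiscreteJoint, MechanismSpec, expit
from crabias.mechanisms import BranchTerm, LinearTerm

N_X, N_C = 3, 4

SCENARIO_GRID = {
    "x": np.arange(N_X, dtype=float),
    "y": np.array([0.0, 1.0]),
    "c": np.arange(N_C, dtype=float),
}


def scenario_design(records: pd.DataFrame):
    """Intercept + exposure dummies + confounder dummies (saturated in C)."""
    x = records["x"].to_numpy(dtype=int)
    c = records["c"].to_numpy(dtype=int)
    n = len(records)
    X = np.ones((n, 1 + (N_X - 1) + (N_C - 1)))
    names = ["intercept"]
    for j in range(1, N_X):
        X[:, j] = x == j
        names.append(f"x_{j}")
    for j in range(1, N_C):
        X[:, N_X - 1 + j] = c == j
        names.append(f"c_{j}")
    return X, names


def random_scenario(rng: np.random.Generator):
    """Random joint over (x, c) with a logistic outcome law.

    Returns (joint, truth) where truth is the coefficient Series of the
    additive logistic model generating P(Y=1 | x, c).
    """
    cells = pd.DataFrame(
        [(float(x), float(c)) for x in range(N_X) for c in range(N_C)],
        columns=["x", "c"],
    )
    mass = rng.dirichlet(np.full(len(cells), 4.0))
    mass = np.clip(mass, 1e-3, None)
    cells["mass"] = mass / mass.sum()
    b0 = rng.uniform(-1.5, 0.0)
    bx = rng.uniform(-1.0, 1.0, size=N_X - 1)
    bc = rng.uniform(-1.0, 1.0, size=N_C - 1)
    truth = pd.Series(
        np.concatenate([[b0], bx, bc]),
        index=["intercept"] + [f"x_{j}" for j in range(1, N_X)]
        + [f"c_{j}" for j in range(1, N_C)],
    )
    X, _ = scenario_design(cells)
    p_y = expit(X @ truth.to_numpy())
    return DiscreteJoint(cells=cells, p_y=np.asarray(p_y)), truth


def _linear_xc(rng, x_slope=None):
    return LinearTerm.make(
        rng.uniform(-0.5, 0.5),
        slopes={"x": rng.uniform(-1.0, 1.0) if x_slope is None else x_slope,
                "c": rng.uniform(-0.8, 0.8)},
        centers={"x": 1.0, "c": 1.5},
    )


def random_mechanism(rng: np.random.Generator, factorizable: bool) -> MechanismSpec:
    """Random selection mechanism depending jointly on X, Y and C.

    Factorizable mechanisms are built as a product s(X,C) * t(Y,C); clearly
    non-factorizable ones branch on Y with exposure slopes differing by at
    least 0.3 between the branches.
    """
    if factorizable:
        s = _linear_xc(rng)
        t = BranchTerm.make({
            0: LinearTerm.make(rng.uniform(-0.5, 0.5),
                               slopes={"c": rng.uniform(-0.8, 0.8)},
                               centers={"c": 1.5}),
            1: LinearTerm.make(rng.uniform(-0.5, 0.5),
                               slopes={"c": rng.uniform(-0.8, 0.8)},
                               centers={"c": 1.5}),
        })
        return MechanismSpec.make("fact", s, t)
    b0 = rng.uniform(-1.0, 1.0)
    gap = rng.uniform(0.3, 1.2) * rng.choice([-1.0, 1.0])
    return MechanismSpec.make(
        "nonfact",
        BranchTerm.make({0: _linear_xc(rng, x_slope=b0),
                         1: _linear_xc(rng, x_slope=b0 + gap)}),
    )
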