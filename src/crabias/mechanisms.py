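"""Missingness mechanisms P(R=1 | X, Y, C): representation, catalog, classification.

A mechanism gives, for each participant, the probability of having a complete
record, as a product of factor terms.  Two term families cover every mechanism
used in this package:

* linear-index terms — ``expit(intercept + sum_v coef_v * (v - center_v) / scale_v)``
  over cohort variables ``v``;
* branch terms — a mapping from the value of a discrete variable (the outcome
  Y, in practice) to a sub-term or a constant.

The taxonomy of complete-records-analysis (CRA) bias depends only on which of
{X, Y, C} the mechanism actually varies with, plus one special case: when the
selection probability depends jointly on exposure and outcome but factorizes
as ``s(X, C) * t(Y, C)``, the exposure log odds ratio is still estimated
without asymptotic bias.  :func:`check_factorization` tests this by the
log-odds-ratio (cross-ratio) criterion: a positive matrix ``M[x, y]`` is a
rank-one product exactly when every 2x2 log cross-ratio vanishes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import CATEGORY_LEVELS, CohortSchemaError, ConfigurationError, expit

__all__ = [
    "ConstantTerm",
    "LinearTerm",
    "BranchTerm",
    "MechanismSpec",
    "MechanismClassification",
    "FactorizationResult",
    "PAPER_MECHANISM_NAMES",
    "paper_mechanism",
    "evaluate_mechanism",
    "dependence_set",
    "check_factorization",
    "classify_mechanism",
    "draw_missingness",
    "default_probe_grid",
    "UNBIASED",
    "BIASED",
]

UNBIASED = "asymptotically_unbiased"
BIASED = "biased"


def _records_frame(record) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    return pd.DataFrame({k: [v] for k, v in dict(record).items()})


def _require(records: pd.DataFrame, var: str) -> np.ndarray:
    if var not in records.columns:
        raise CohortSchemaError(f"mechanism references unknown variable '{var}'")
    vals = records[var].to_numpy(dtype=float)
    if np.any(np.isnan(vals)):
        raise CohortSchemaError(
            f"mechanism evaluation requires '{var}' to be observed for every record"
        )
    return vals


@dataclass(frozen=True)
class ConstantTerm:
    """A constant selection probability in [0, 1]."""

    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ConfigurationError(f"constant term {self.value} outside [0, 1]")

    def variables(self) -> frozenset:
        return frozenset()

    def evaluate(self, records: pd.DataFrame) -> np.ndarray:
        return np.full(len(records), float(self.value))

    def to_dict(self) -> dict:
        return {"kind": "constant", "value": self.value}


@dataclass(frozen=True)
class LinearTerm:
    """``expit`` of a linear index in (possibly standardized) cohort variables.

    ``slopes`` maps variable names to coefficients; each variable enters as
    ``(v - centers[v]) / scales[v]`` with center 0 and scale 1 by default.
    An empty index gives the MCAR constant ``expit(intercept)``.
    """

    intercept: float = 0.0
    slopes: tuple = ()          # ((var, coef), ...)
    centers: tuple = ()         # ((var, center), ...)
    scales: tuple = ()          # ((var, scale), ...)

    @classmethod
    def make(cls, intercept: float = 0.0, slopes: Mapping[str, float] | None = None,
             centers: Mapping[str, float] | None = None,
             scales: Mapping[str, float] | None = None) -> "LinearTerm":
        return cls(
            intercept=float(intercept),
            slopes=tuple(sorted((slopes or {}).items())),
            centers=tuple(sorted((centers or {}).items())),
            scales=tuple(sorted((scales or {}).items())),
        )

    def variables(self) -> frozenset:
        return frozenset(v for v, c in self.slopes if c != 0.0)

    def evaluate(self, records: pd.DataFrame) -> np.ndarray:
        centers = dict(self.centers)
        scales = dict(self.scales)
        idx = np.full(len(records), float(self.intercept))
        for var, coef in self.slopes:
            vals = _require(records, var)
            idx = idx + coef * (vals - centers.get(var, 0.0)) / scales.get(var, 1.0)
        return np.asarray(expit(idx), dtype=float)

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "intercept": self.intercept,
            "slopes": dict(self.slopes),
            "centers": dict(self.centers),
            "scales": dict(self.scales),
        }


@dataclass(frozen=True)
class BranchTerm:
    """Value-keyed branching, e.g. one sub-term per outcome status.

    ``branches`` maps each value of the branching variable (``on``, the
    outcome Y unless stated otherwise) to a sub-term or a bare probability.
    """

    on: str = "y"
    branches: tuple = ()        # ((value, term-or-float), ...)

    @classmethod
    def make(cls, branches: Mapping[int, object], on: str = "y") -> "BranchTerm":
        items = []
        for val, sub in sorted(branches.items()):
            if isinstance(sub, (int, float)):
                sub = ConstantTerm(float(sub))
            items.append((int(val), sub))
        return cls(on=on, branches=tuple(items))

    def variables(self) -> frozenset:
        out = {self.on}
        for _, sub in self.branches:
            out |= sub.variables()
        return frozenset(out)

    def evaluate(self, records: pd.DataFrame) -> np.ndarray:
        vals = _require(records, self.on)
        out = np.full(len(records), np.nan)
        seen = np.zeros(len(records), dtype=bool)
        for val, sub in self.branches:
            mask = vals == val
            if mask.any():
                out[mask] = sub.evaluate(records.loc[mask])
            seen |= mask
        if not seen.all():
            bad = sorted(set(vals[~seen]))
            raise CohortSchemaError(
                f"branch term on '{self.on}' has no branch for value(s) {bad}"
            )
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "branch",
            "on": self.on,
            "branches": {str(v): (s.to_dict() if hasattr(s, "to_dict") else s)
                         for v, s in self.branches},
        }


def _term_from_dict(d: Mapping) -> object:
    kind = d.get("kind")
    if kind == "constant":
        return ConstantTerm(float(d["value"]))
    if kind == "linear":
        return LinearTerm.make(d.get("intercept", 0.0), d.get("slopes"),
                               d.get("centers"), d.get("scales"))
    if kind == "branch":
        return BranchTerm.make({int(v): (_term_from_dict(s) if isinstance(s, Mapping) else s)
                                for v, s in d["branches"].items()}, on=d.get("on", "y"))
    raise ConfigurationError(f"unknown mechanism term kind {kind!r}")


@dataclass(frozen=True)
class MechanismSpec:
    """A missingness mechanism as a product of factor terms."""

    name: str
    terms: tuple

    @classmethod
    def make(cls, name: str, *terms) -> "MechanismSpec":
        return cls(name=name, terms=tuple(terms))

    def variables(self) -> frozenset:
        out: frozenset = frozenset()
        for t in self.terms:
            out |= t.variables()
        return out

    def evaluate(self, records) -> np.ndarray:
        """Per-record selection probability; product of all factor terms."""
        records = _records_frame(records)
        prob = np.ones(len(records))
        for t in self.terms:
            prob = prob * t.evaluate(records)
        return prob

    def to_dict(self) -> dict:
        return {"name": self.name, "terms": [t.to_dict() for t in self.terms]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MechanismSpec":
        return cls(name=str(d["name"]),
                   terms=tuple(_term_from_dict(t) for t in d["terms"]))


def evaluate_mechanism(spec: MechanismSpec, record) -> np.ndarray | float:
    """Evaluate P(R=1) for one record (mapping) or many (DataFrame)."""
    out = spec.evaluate(record)
    return float(out[0]) if not isinstance(record, pd.DataFrame) else out


# --------------------------------------------------------------------------
# Benchmark catalog: eight mechanisms spanning the bias taxonomy, indexed by
# what the selection probability depends on.  Age is standardized by the
# cohort mean 37.32 and SD 10.79; the exposure enters as its category code
# (0, 1, 2) centered at 1, so the middle category has index contribution 0.
# --------------------------------------------------------------------------

_AGE_STD = dict(slopes={"age": 1.0}, centers={"age": 37.32}, scales={"age": 10.79})
_AGE_STD_NEG = dict(slopes={"age": -1.0}, centers={"age": 37.32}, scales={"age": 10.79})


def _catalog() -> dict[str, MechanismSpec]:
    lin = LinearTerm.make
    br = BranchTerm.make
    return {
        # MCAR: constant expit(0) = 0.5
        "m1": MechanismSpec.make("m1", lin(0.0)),
        # outcome only: certain selection for cases, 0.485 for non-cases
        "m2": MechanismSpec.make("m2", br({1: 1.0, 0: 0.485})),
        # age only
        "m3": MechanismSpec.make("m3", lin(**_AGE_STD)),
        # exposure only: expit(-(x - 1))
        "m4": MechanismSpec.make("m4", lin(slopes={"x": -1.0}, centers={"x": 1.0})),
        # age and exposure jointly (still covariate-only)
        "m5": MechanismSpec.make(
            "m5",
            lin(slopes={"x": -1.0, "age": 1.0},
                centers={"x": 1.0, "age": 37.32},
                scales={"x": 1.0, "age": 10.79})),
        # outcome and age: age effect reverses sign with outcome status
        "m6": MechanismSpec.make("m6", br({0: lin(**_AGE_STD), 1: lin(**_AGE_STD_NEG)})),
        # outcome and exposure, non-factorizable: exposure effect reverses
        "m7": MechanismSpec.make(
            "m7",
            br({0: lin(slopes={"x": -1.0}, centers={"x": 1.0}),
                1: lin(slopes={"x": 1.0}, centers={"x": 1.0})})),
        # outcome and exposure, conditionally independent (factorizable):
        # s(x) = expit(-(x - 1)), t(y) = 1 if y = 1 else 0.485
        "m8": MechanismSpec.make(
            "m8",
            lin(slopes={"x": -1.0}, centers={"x": 1.0}),
            br({1: 1.0, 0: 0.485})),
    }


PAPER_MECHANISM_NAMES = tuple(f"m{i}" for i in range(1, 9))


def paper_mechanism(name: str) -> MechanismSpec:
    """Return one of the eight benchmark mechanisms ``m1`` .. ``m8``."""
    cat = _catalog()
    if name not in cat:
        raise KeyError(
            f"unknown mechanism {name!r}; valid names: {', '.join(sorted(cat))}"
        )
    return cat[name]


def default_probe_grid(
    *,
    age_mean: float = 37.32,
    age_sd: float = 10.79,
    age_bounds: tuple = (18.0, 65.0),
    bmi_mean: float = 25.0,
    bmi_sd: float = 3.5,
    n_quantiles: int = 9,
    ) -> dict[str, np.ndarray]:
    """Deterministic probe grid over the cohort schema.

    Categorical variables contribute their full code range; continuous
    confounders a 9-point equal-probability quantile grid (a heuristic that is
    exact for mechanisms monotone in the confounder).
    """
    from scipy.stats import norm, truncnorm

    q = (np.arange(n_quantiles) + 0.5) / n_quantiles
    a, b = (age_bounds[0] - age_mean) / age_sd, (age_bounds[1] - age_mean) / age_sd
    grid = {
        "x": np.arange(CATEGORY_LEVELS["x"], dtype=float),
        "y": np.arange(CATEGORY_LEVELS["y"], dtype=float),
        "age": truncnorm.ppf(q, a, b, loc=age_mean, scale=age_sd),
        "sex": np.arange(2, dtype=float),
        "smoking": np.arange(3, dtype=float),
        "bmi": norm.ppf(q, loc=bmi_mean, scale=bmi_sd),
        "route": np.arange(4, dtype=float),
    }
    return grid


def _mesh(grid: Mapping[str, Sequence[float]], variables: Sequence[str]) -> pd.DataFrame:
    for v in variables:
        if v not in grid or len(grid[v]) == 0:
            raise ConfigurationError(f"probe grid is empty for variable '{v}'")
    combos = itertools.product(*(grid[v] for v in variables))
    return pd.DataFrame(list(combos), columns=list(variables), dtype=float)


def dependence_set(
    spec: MechanismSpec,
    grid: Mapping[str, Sequence[float]] | None = None,
    tol: float = 1e-12,
    ) -> frozenset:
    """Variables the selection probability actually varies with on the grid."""
    if grid is None:
        grid = default_probe_grid()
    ref = sorted(spec.variables())
    if not ref:
        return frozenset()
    for v in ref:
        if v in grid and len(grid[v]) < 2:
            raise ConfigurationError(f"grid needs >= 2 values for probed variable '{v}'")
    mesh = _mesh(grid, ref)
    vals = spec.evaluate(mesh).reshape([len(grid[v]) for v in ref])
    out = set()
    for axis, v in enumerate(ref):
        if float(np.max(np.ptp(vals, axis=axis))) > tol:
            out.add(v)
    return frozenset(out)


@dataclass(frozen=True)
class FactorizationResult:
    factorizable: bool
    max_violation: float

    def __iter__(self):  # allow tuple unpacking
        yield self.factorizable
        yield self.max_violation


def check_factorization(
    spec: MechanismSpec,
    grid: Mapping[str, Sequence[float]] | None = None,
    tol: float = 1e-8,
    ) -> FactorizationResult:
    """Test whether P(R=1|X,Y,C) = s(X,C) * t(Y,C) on an evaluation grid.

    For each confounder combination ``c`` the matrix ``M[x, y]`` factorizes
    into a product of an x-function and a y-function exactly when every 2x2
    log cross-ratio ``log M[x,y] + log M[x',y'] - log M[x,y'] - log M[x',y]``
    vanishes. ``max_violation`` is the largest absolute log cross-ratio seen.

    Zeros: a whole zero x-row or y-column is removed (the condition is tested
    on the positive submatrix); isolated zeros make the cross-ratio undefined
    and the mechanism is reported non-factorizable with a warning.
    """
    if grid is None:
        grid = default_probe_grid()
    ref = spec.variables()
    xvals = np.asarray(grid.get("x", [0.0, 1.0, 2.0]), dtype=float)
    yvals = np.asarray(grid.get("y", [0.0, 1.0]), dtype=float)
    if len(xvals) < 2 or len(yvals) < 2:
        warnings.warn("factorization grid has < 2 exposure or outcome values; "
                      "trivially factorizable", stacklevel=2)
        return FactorizationResult(True, 0.0)
    cvars = sorted(v for v in ref if v not in ("x", "y"))
    cmesh = _mesh(grid, cvars) if cvars else pd.DataFrame({"_": [0.0]})

    max_viol = 0.0
    for _, crow in cmesh.iterrows():
        rec = pd.DataFrame(
            [{**({} if not cvars else crow[cvars].to_dict()), "x": xv, "y": yv}
             for xv in xvals for yv in yvals]
        )
        M = spec.evaluate(rec).reshape(len(xvals), len(yvals))
        zero = M <= 0.0
        if zero.any():
            keep_rows = ~zero.all(axis=1)
            keep_cols = ~zero.all(axis=0)
            M = M[np.ix_(keep_rows, keep_cols)]
            if M.size == 0 or M.shape[0] < 2 or M.shape[1] < 2:
                continue
            if (M <= 0.0).any():
                warnings.warn(
                    f"mechanism '{spec.name}' has isolated zero selection "
                    "probabilities; log cross-ratio undefined, reported "
                    "non-factorizable", stacklevel=2)
                return FactorizationResult(False, np.inf)
        L = np.log(M)
        # max |2x2 log cross-ratio| over row and column pairs
        for i, j in itertools.combinations(range(L.shape[0]), 2):
            d = L[i] - L[j]
            viol = float(np.max(d) - np.min(d))
            max_viol = max(max_viol, viol)
    return FactorizationResult(max_viol <= tol, max_viol)


#: Table of CRA bias verdicts (beta0, betaX, betaC) per dependence class.
_VERDICT_TABLE = {
    "none": (UNBIASED, UNBIASED, UNBIASED),
    "outcome_only": (BIASED, UNBIASED, UNBIASED),
    "covariate_only": (UNBIASED, UNBIASED, UNBIASED),
    "outcome_and_confounder": (BIASED, UNBIASED, BIASED),
    "outcome_and_exposure": (BIASED, BIASED, BIASED),
}


@dataclass(frozen=True)
class MechanismClassification:
    """Bias taxonomy verdict for a mechanism.

    ``dependence_set`` holds cohort variable names; ``roles`` the
    corresponding subset of {X, Y, C}. ``verdicts`` maps 'beta0', 'betaX',
    'betaC' to asymptotic-bias verdicts; for joint X-and-Y dependence the
    exposure verdict is unbiased exactly when the mechanism factorizes as
    s(X,C) t(Y,C).
    """

    name: str
    dependence_set: frozenset
    roles: frozenset
    taxonomy_row: str
    factorizable: bool
    max_violation: float
    verdicts: Mapping[str, str] = field(default_factory=dict)


def classify_mechanism(
    spec: MechanismSpec,
    grid: Mapping[str, Sequence[float]] | None = None,
    ) -> MechanismClassification:
    """Classify a mechanism into the bias taxonomy and emit per-parameter verdicts."""
    if grid is None:
        grid = default_probe_grid()
    deps = dependence_set(spec, grid)
    roles = frozenset(("X" if v == "x" else "Y" if v == "y" else "C") for v in deps)
    if not roles:
        row = "none"
    elif roles == {"Y"}:
        row = "outcome_only"
    elif "Y" not in roles:
        row = "covariate_only"
    elif "X" not in roles:
        row = "outcome_and_confounder"
    else:
        row = "outcome_and_exposure"
    fact = check_factorization(spec, grid)
    b0, bx, bc = _VERDICT_TABLE[row]
    if row == "outcome_and_exposure" and fact.factorizable:
        bx = UNBIASED
    return MechanismClassification(
        name=spec.name,
        dependence_set=deps,
        roles=roles,
        taxonomy_row=row,
        factorizable=fact.factorizable,
        max_violation=fact.max_violation,
        verdicts={"beta0": b0, "betaX": bx, "betaC": bc},
    )


def draw_missingness(
    spec: MechanismSpec,
    cohort: pd.DataFrame,
    rng: np.random.Generator | int,
    ) -> np.ndarray:
    """Draw independent Bernoulli complete-record indicators for a cohort."""
    rng = np.random.default_rng(rng)
    p = spec.evaluate(cohort)
    return (rng.random(len(cohort)) < p).astype(np.int8)
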