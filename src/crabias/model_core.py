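"""Logistic outcome model: design construction, ML fitting, complete-record bookkeeping.

The analysis model throughout the package is a logistic regression of a binary
outcome (e.g. death during follow-up) on a categorical exposure and a set of
confounders,

    logit P(Y = 1 | X, C) = beta0 + betaX * X + betaC * C,

with the exposure entered as dummy variables against the lowest category, age
as a continuous piecewise-linear (hinge) function, BMI as categories defined by
cutpoints, and sex, smoking status and flight-route type as categorical codes.
Optionally the exposure log odds ratio may vary linearly with age
(exposure x age interaction), which is how the package represents effect
modification and, when the interaction is omitted from the fitted model,
model misspecification.

Complete-records analysis (CRA) means fitting this model to the subset of
participants with no missing value in any analysis variable; the module keeps
explicit count of how many records were dropped.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as _scipy_expit

__all__ = [
    "COHORT_COLUMNS",
    "ANALYSIS_VARIABLES",
    "CATEGORY_LEVELS",
    "CohortSchemaError",
    "ConfigurationError",
    "OutcomeModelSpec",
    "FittedLogisticModel",
    "DesignMatrix",
    "expit",
    "age_basis",
    "bmi_category",
    "design_columns",
    "build_design",
    "fit_logistic",
    "fit_outcome_model",
    "complete_record_indicator",
    "validate_cohort",
]

#: canonical cohort column order (``id`` plus the analysis variables)
COHORT_COLUMNS = ("id", "y", "x", "age", "sex", "smoking", "bmi", "route")

#: variables entering the outcome model (outcome first)
ANALYSIS_VARIABLES = ("y", "x", "age", "sex", "smoking", "bmi", "route")

#: number of levels of each categorical cohort column (code range 0..K-1)
CATEGORY_LEVELS = {"y": 2, "x": 3, "sex": 2, "smoking": 3, "route": 4}


class CohortSchemaError(ValueError):
    """A cohort table violates the declared schema (columns, codes, types)."""


class ConfigurationError(ValueError):
    """A model or generator specification is internally inconsistent."""


def expit(t):
    """Inverse logit, ``exp(t) / (1 + exp(t))``, evaluated overflow-safely.

    Accepts scalars or arrays; satisfies ``expit(t) + expit(-t) == 1``.
    """
    return _scipy_expit(t)


def age_basis(age, knots: Sequence[float] = (30.0, 40.0, 50.0, 60.0)) -> np.ndarray:
    """Piecewise-linear (hinge) basis for age.

    Returns ``[age, (age - k)_+ for each knot k]`` so a coefficient vector on
    this basis describes a continuous, piecewise-linear log-odds trend whose
    slope may change at each knot.

    Parameters
    ----------
    age : scalar or array of ages in years.
    knots : strictly increasing knot locations in years.

    Returns
    -------
    ndarray of shape ``(..., 1 + len(knots))``.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size == 0 or np.any(np.diff(knots) <= 0):
        raise ConfigurationError(f"age knots must be strictly increasing, got {knots!r}")
    a = np.asarray(age, dtype=float)
    cols = [a] + [np.clip(a - k, 0.0, None) for k in knots]
    return np.stack(cols, axis=-1)


def bmi_category(bmi, cutpoints: Sequence[float] = (20.0, 25.0, 30.0)) -> np.ndarray:
    """Categorize BMI with left-closed/right-open bins ``[c_i, c_{i+1})``.

    Category 0 is below the first cutpoint; category ``len(cutpoints)`` is at
    or above the last one.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.ndim != 1 or cuts.size == 0 or np.any(np.diff(cuts) <= 0):
        raise ConfigurationError(f"bmi cutpoints must be strictly increasing, got {cuts!r}")
    return np.searchsorted(cuts, np.asarray(bmi, dtype=float), side="right")


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Coefficients and basis definitions for the logistic outcome model.

    ``beta_x`` holds one log odds ratio per non-reference exposure category
    (versus category 0). ``beta_age`` has one coefficient per column of the
    hinge basis, i.e. ``1 + len(age_knots)`` entries. ``interaction``, when
    set, gives per-exposure-category slopes on ``(age - age_center)`` in
    log-odds per year, so a negative value makes the exposure log odds ratio
    decline with age.

    A spec also serves as a pure model *structure* for fitting (the
    coefficient values are then ignored); see :func:`build_design`.
    """

    beta0: float = 0.0
    beta_x: tuple = (0.0, 0.0)
    beta_age: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    beta_sex: float = 0.0
    beta_smoking: tuple = (0.0, 0.0)
    beta_bmi: tuple = (0.0, 0.0, 0.0)
    beta_route: tuple = (0.0, 0.0, 0.0)
    interaction: tuple | None = None
    age_knots: tuple = (30.0, 40.0, 50.0, 60.0)
    bmi_cutpoints: tuple = (20.0, 25.0, 30.0)
    age_center: float = 37.32

    def __post_init__(self):
        knots = np.asarray(self.age_knots, float)
        cuts = np.asarray(self.bmi_cutpoints, float)
        if knots.size == 0 or np.any(np.diff(knots) <= 0):
            raise ConfigurationError("age_knots must be strictly increasing")
        if cuts.size == 0 or np.any(np.diff(cuts) <= 0):
            raise ConfigurationError("bmi_cutpoints must be strictly increasing")
        if len(self.beta_age) != 1 + len(self.age_knots):
            raise ConfigurationError(
                f"beta_age must have {1 + len(self.age_knots)} entries "
                f"(one per hinge-basis column), got {len(self.beta_age)}"
            )
        if len(self.beta_bmi) != len(self.bmi_cutpoints):
            raise ConfigurationError(
                "beta_bmi needs one coefficient per non-reference BMI category"
            )
        if self.interaction is not None and len(self.interaction) != len(self.beta_x):
            raise ConfigurationError(
                "interaction needs one slope per non-reference exposure category"
            )
        flat = [self.beta0, self.beta_sex, *self.beta_x, *self.beta_age,
                *self.beta_smoking, *self.beta_bmi, *self.beta_route,
                *(self.interaction or ())]
        if not np.all(np.isfinite(flat)):
            raise ConfigurationError("all coefficients must be finite")

    @property
    def n_exposure_levels(self) -> int:
        return len(self.beta_x) + 1

    def coefficient_names(self) -> list[str]:
        names = ["intercept"]
        names += [f"x_{j}" for j in range(1, self.n_exposure_levels)]
        names += ["age"] + [f"age_{int(k)}" for k in self.age_knots]
        names += ["sex", "smoking_1", "smoking_2"]
        names += [f"bmi_{j}" for j in range(1, len(self.bmi_cutpoints) + 1)]
        names += [f"route_{j}" for j in range(1, CATEGORY_LEVELS["route"])]
        if self.interaction is not None:
            names += [f"x_{j}:age" for j in range(1, self.n_exposure_levels)]
        return names

    def coefficients(self) -> pd.Series:
        """Coefficient vector aligned with :meth:`coefficient_names`."""
        vals = [self.beta0, *self.beta_x, *self.beta_age, self.beta_sex,
                *self.beta_smoking, *self.beta_bmi, *self.beta_route]
        if self.interaction is not None:
            vals += list(self.interaction)
        return pd.Series(vals, index=self.coefficient_names(), dtype=float)

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """Evaluate ``beta0 + betaX X + betaC C`` row-wise on complete records."""
        X, names, _ = design_columns(records, self)
        return X @ self.coefficients().to_numpy()


def validate_cohort(cohort: pd.DataFrame, *, require_complete: bool = False) -> None:
    """Check the cohort schema invariants.

    Missingness must be explicit (NaN); every non-missing categorical code
    must lie in its declared range; participant ids must be unique.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise CohortSchemaError(f"cohort is missing columns {missing_cols}")
    if cohort["id"].duplicated().any():
        raise CohortSchemaError("participant ids are not unique")
    for col, k in CATEGORY_LEVELS.items():
        vals = cohort[col].dropna().to_numpy(dtype=float)
        if vals.size and (np.any(vals != np.round(vals)) or vals.min() < 0 or vals.max() > k - 1):
            raise CohortSchemaError(
                f"column '{col}': category codes must be integers in 0..{k - 1}"
            )
    if require_complete:
        n_bad = int(cohort[list(ANALYSIS_VARIABLES)].isna().any(axis=1).sum())
        if n_bad:
            raise CohortSchemaError(f"{n_bad} rows contain missing analysis values")


def _dummies(codes: np.ndarray, n_levels: int, col: str, row_ids) -> np.ndarray:
    codes = np.asarray(codes, dtype=float)
    ints = codes.astype(int)
    bad = (codes != ints) | (ints < 0) | (ints >= n_levels)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise CohortSchemaError(
            f"column '{col}': unknown category code {codes[i]!r} at row {row_ids[i]!r}"
        )
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[:, j - 1] = ints == j
    return out


# Design-column group names in their fixed order of appearance.
DESIGN_GROUPS = ("y", "exposure", "age", "sex", "smoking", "bmi", "route", "interaction")


def design_columns(
    records: pd.DataFrame,
    spec: OutcomeModelSpec,
    include: Sequence[str] | None = None,
    ) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Assemble design-matrix columns for complete records.

    ``include`` selects variable groups from :data:`DESIGN_GROUPS`; by default
    every group except ``y`` is used (plus ``interaction`` when the spec
    defines one).  The outcome group is available so the same bases can be
    reused by the missingness-diagnostics models, where Y is a predictor.
    An intercept column always comes first; the column order is deterministic:
    intercept, exposure dummies (reference = category 0), age hinge basis,
    sex, smoking dummies, BMI dummies (reference = lowest category), route
    dummies, then exposure-by-age interaction columns.

    Returns ``(X, names, groups)`` where ``groups`` maps each included group
    to the list of its column names.
    """
    if include is None:
        include = [g for g in DESIGN_GROUPS if g not in ("y",)]
    include = [g for g in include if g != "interaction" or spec.interaction is not None]
    unknown = set(include) - set(DESIGN_GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown design groups {sorted(unknown)}")

    n = len(records)
    row_ids = (records["id"].to_numpy() if "id" in records.columns
               else records.index.to_numpy())
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    groups: dict[str, list[str]] = {}

    def add(group: str, block: np.ndarray, cols: list[str]) -> None:
        blocks.append(block)
        names.extend(cols)
        groups[group] = cols

    xdum = None
    for group in DESIGN_GROUPS:
        if group not in include:
            continue
        if group == "y":
            yv = records["y"].to_numpy(dtype=float)
            add("y", yv.reshape(-1, 1), ["y"])
        elif group == "exposure":
            xdum = _dummies(records["x"].to_numpy(), spec.n_exposure_levels, "x", row_ids)
            add("exposure", xdum, [f"x_{j}" for j in range(1, spec.n_exposure_levels)])
        elif group == "age":
            basis = age_basis(records["age"].to_numpy(dtype=float), spec.age_knots)
            add("age", basis, ["age"] + [f"age_{int(k)}" for k in spec.age_knots])
        elif group == "sex":
            sv = _dummies(records["sex"].to_numpy(), 2, "sex", row_ids)
            add("sex", sv, ["sex"])
        elif group == "smoking":
            add("smoking", _dummies(records["smoking"].to_numpy(), 3, "smoking", row_ids),
                ["smoking_1", "smoking_2"])
        elif group == "bmi":
            cat = bmi_category(records["bmi"].to_numpy(dtype=float), spec.bmi_cutpoints)
            k = len(spec.bmi_cutpoints) + 1
            add("bmi", _dummies(cat, k, "bmi", row_ids),
                [f"bmi_{j}" for j in range(1, k)])
        elif group == "route":
            add("route", _dummies(records["route"].to_numpy(), CATEGORY_LEVELS["route"],
                                  "route", row_ids),
                [f"route_{j}" for j in range(1, CATEGORY_LEVELS["route"])])
        elif group == "interaction":
            if xdum is None:
                xdum = _dummies(records["x"].to_numpy(), spec.n_exposure_levels, "x", row_ids)
            dev = (records["age"].to_numpy(dtype=float) - spec.age_center)[:, None]
            add("interaction", xdum * dev,
                [f"x_{j}:age" for j in range(1, spec.n_exposure_levels)])
    X = np.hstack(blocks)
    return X, names, groups


@dataclass
class DesignMatrix:
    """Design matrix plus outcome vector restricted to complete records."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    index: np.ndarray  # positional indices of the rows used
    n_dropped: int
    groups: dict[str, list[str]] = dataclasses.field(default_factory=dict)


def build_design(
    cohort: pd.DataFrame,
    spec: OutcomeModelSpec,
    *,
    drop_incomplete: bool = True,
    ) -> DesignMatrix:
    """Build the outcome-model design matrix and outcome vector.

    Rows with any missing value among the analysis variables are excluded
    first (complete-records definition) and their count reported.
    """
    used = list(ANALYSIS_VARIABLES)
    sub = cohort
    n_dropped = 0
    if drop_incomplete:
        keep = ~cohort[used].isna().any(axis=1)
        n_dropped = int((~keep).sum())
        sub = cohort.loc[keep]
    X, names, groups = design_columns(sub, spec)
    y = sub["y"].to_numpy(dtype=float)
    if np.any(np.isnan(X)) or np.any(np.isnan(y)):
        raise CohortSchemaError("missing values encountered in design construction")
    idx = np.flatnonzero(keep.to_numpy()) if drop_incomplete else np.arange(len(cohort))
    return DesignMatrix(X=X, y=y, names=names, index=idx, n_dropped=n_dropped,
                        groups=groups)


@dataclass
class FittedLogisticModel:
    """Maximum-likelihood logistic fit with model-based (Wald) uncertainty.

    ``bse`` is the square root of the diagonal of ``cov_params`` (inverse
    observed information at the solution). ``separated`` is set when any
    coefficient left the divergence bound during iteration, the signature of
    (quasi-)complete separation: the MLE is then not finite and the reported
    numbers are the last iterate, not estimates.
    """

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    n_used: int
    converged: bool
    separated: bool
    iterations: int
    max_abs_score: float
    n_dropped: int = 0

    @property
    def ok(self) -> bool:
        return self.converged and not self.separated


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    names: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    divergence_bound: float = 15.0,
    ) -> FittedLogisticModel:
    """Fit logistic regression by Newton iteration on the (weighted) score.

    Solves ``sum_i w_i (y_i - expit(x_i' b)) x_i = 0``; convergence is declared
    when the largest score component falls below ``tol``. Each Newton step is
    halved until the (weighted) log-likelihood does not decrease; a coefficient
    passing ``divergence_bound`` in absolute value flags separation. Prior
    ``weights`` make the same routine solve population weighted-score
    equations exactly (used by the asymptotic oracle).

    When the first column is a constant intercept, the remaining columns are
    centered at their weighted means internally (and the solution mapped
    back), so the divergence bound is judged against the log-odds at the
    covariate mean rather than an extrapolated intercept, and conditioning
    improves.

    Raises
    ------
    ConfigurationError
        If the (weighted) design is rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if names is None:
        names = [f"b{j}" for j in range(p)]
    names = list(names)
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)

    # internal centering (intercept column only when present and constant)
    centered = p > 1 and np.all(X[:, 0] == 1.0)
    if centered:
        m = (w @ X[:, 1:]) / w.sum()
        X = X.copy()
        X[:, 1:] -= m
        beta = beta.copy()
        beta[0] += m @ beta[1:]

    def loglik(b):
        eta = X @ b
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    converged = False
    separated = False
    score_max = math.inf
    ll = loglik(beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _scipy_expit(eta)
        score = X.T @ (w * (y - mu))
        score_max = float(np.max(np.abs(score)))
        if score_max < tol:
            converged = True
            break
        wv = w * mu * (1.0 - mu)
        H = (X * wv[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            if it == 1:
                raise ConfigurationError(
                    "design matrix is rank deficient (singular information)"
                ) from None
            separated = True
            break
        # step-halving: never accept a likelihood decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12 * (1.0 + abs(ll)):
                break
            step *= 0.5
        beta = cand
        ll = ll_new
        if np.max(np.abs(beta)) > divergence_bound:
            separated = True
            break

    eta = X @ beta
    mu = _scipy_expit(eta)
    wv = w * mu * (1.0 - mu)
    H = (X * wv[:, None]).T @ X
    if converged:
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "design matrix is rank deficient (singular information)"
            ) from None
    else:
        cov = np.full((p, p), np.nan)
    if centered:
        beta = beta.copy()
        beta[0] -= m @ beta[1:]
        if converged:
            T = np.eye(p)
            T[0, 1:] = -m
            cov = T @ cov @ T.T
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return FittedLogisticModel(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        n_used=n,
        converged=converged,
        separated=separated,
        iterations=it,
        max_abs_score=score_max,
    )


def fit_outcome_model(
    cohort: pd.DataFrame,
    spec: OutcomeModelSpec,
    *,
    start: np.ndarray | None = None,
    **fit_options,
    ) -> FittedLogisticModel:
    """Complete-records fit of the outcome model to a cohort table."""
    dm = build_design(cohort, spec)
    model = fit_logistic(dm.X, dm.y, names=dm.names, start=start, **fit_options)
    model.n_dropped = dm.n_dropped
    return model


def complete_record_indicator(
    cohort: pd.DataFrame, variables: Iterable[str]
    ) -> np.ndarray:
    """Binary indicator R: 1 iff every listed variable is observed in a row."""
    variables = list(variables)
    unknown = [v for v in variables if v not in cohort.columns]
    if unknown:
        raise CohortSchemaError(f"unknown variables {unknown}")
    return (~cohort[variables].isna().any(axis=1)).to_numpy().astype(np.int8)
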