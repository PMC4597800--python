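"""Observed-data diagnostics for missingness assumptions.

For each partially observed analysis variable, fit a logistic regression of
the indicator "variable observed" on the remaining, fully observed analysis
variables (same bases and codings as the outcome model).  The set of variables
found associated with missingness — judged jointly per variable group by a
Wald test AND a minimum standardized magnitude, never by significance alone —
is then mapped to a guidance table of plausible mechanisms and the implied
complete-records-analysis (CRA) verdict for the exposure odds ratio:

Missingness in a confounder C1 (C2 = the other confounders):
    associated with C2 only, X (and C2), or Y (and C2)  -> asymptotically unbiased
    associated with both X and Y                        -> generally biased
Missingness in the exposure X:
    associated with C, Y, or C and Y                    -> asymptotically unbiased
    dependence on X itself plus Y plausible             -> generally biased
Missingness in the outcome Y:
    associated with X, C, or X and C                    -> asymptotically unbiased
    dependence on Y itself plus X plausible             -> generally biased

A favorable verdict can never be definitive: mechanisms in the bias-causing
class (joint X and Y dependence) can produce observed associations that cancel
into an innocuous-looking pattern, so every favorable report carries a
cancellation caveat.  Dependence of missingness on the partially observed
variable itself is unobservable; it is surfaced through the plausible-
mechanism list (and can be declared contextually), not through the fitted
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model_core import (
    ANALYSIS_VARIABLES,
    CohortSchemaError,
    ConfigurationError,
    FittedLogisticModel,
    OutcomeModelSpec,
    design_columns,
    fit_logistic,
)

__all__ = [
    "MissingnessModel",
    "AssociationFindings",
    "GuidanceVerdict",
    "DiagnosisReport",
    "CohortDiagnosis",
    "fit_missingness_model",
    "infer_association_set",
    "guidance_verdict",
    "diagnose_cohort",
    "CANCELLATION_CAVEAT",
    "MULTIVARIABLE_CAVEAT",
]

CANCELLATION_CAVEAT = (
    "A favorable verdict cannot be definitive: a mechanism depending jointly on "
    "exposure and outcome can produce observed associations that cancel into a "
    "pattern indistinguishable from a non-bias-causing class. Combine with "
    "contextual knowledge and sensitivity analysis."
)
MULTIVARIABLE_CAVEAT = (
    "Multiple variables are partially observed; each was diagnosed among records "
    "complete on the others. This per-variable strategy is an approximation."
)

#: role labels for the partially observed variable
ROLES = ("confounder_C1", "exposure_X", "outcome_Y")

_VARIABLE_CLASS = {"x": "X", "y": "Y", "age": "C", "sex": "C", "smoking": "C",
                   "bmi": "C", "route": "C"}
_VARIABLE_GROUP = {"y": "y", "x": "exposure", "age": "age", "sex": "sex",
                   "smoking": "smoking", "bmi": "bmi", "route": "route"}


@dataclass
class MissingnessModel:
    """Missingness-indicator regression plus the metadata needed to judge it."""

    target: str
    fit: FittedLogisticModel
    X: np.ndarray
    groups: Mapping[str, Sequence[str]]   # predictor variable -> design columns
    names: Sequence[str]
    n_dropped_predictors: int
    n_missing_target: int


def fit_missingness_model(
    cohort: pd.DataFrame,
    target: str,
    spec: OutcomeModelSpec | None = None,
    ) -> MissingnessModel:
    """Regress the indicator "``target`` observed" on the other analysis variables.

    The predictors reuse the outcome-model bases (exposure dummies, age hinge
    basis, BMI categories, ...), with the outcome itself entering as a binary
    predictor.  Rows with a missing value in any *predictor* are dropped with
    a warning and a count.
    """
    spec = spec or OutcomeModelSpec()
    if target not in ANALYSIS_VARIABLES:
        raise CohortSchemaError(f"unknown analysis variable {target!r}")
    r = (~cohort[target].isna()).to_numpy().astype(float)
    n_missing = int(len(cohort) - r.sum())
    if n_missing == 0:
        raise ConfigurationError(f"'{target}' is fully observed: nothing to diagnose")
    if r.sum() == 0:
        raise ConfigurationError(f"'{target}' is never observed: nothing to model")

    predictors = [v for v in ANALYSIS_VARIABLES if v != target]
    keep = ~cohort[predictors].isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} rows with missing predictor values dropped while "
            f"diagnosing '{target}'", stacklevel=2)
    sub = cohort.loc[keep]
    include = [_VARIABLE_GROUP[v] for v in predictors]
    X, names, groups = design_columns(sub, spec, include=include)
    fit = fit_logistic(X, r[keep.to_numpy()], names=names)
    var_groups = {v: groups[_VARIABLE_GROUP[v]] for v in predictors}
    return MissingnessModel(target=target, fit=fit, X=X, groups=var_groups,
                            names=names, n_dropped_predictors=n_dropped,
                            n_missing_target=n_missing)


@dataclass
class AssociationFindings:
    """Per-variable judgement of association with missingness.

    ``association_set`` contains the variables judged associated (Wald p < alpha
    AND standardized magnitude >= min_effect).  ``negligible`` lists variables
    that are statistically significant but too small to matter;
    ``imprecise`` lists variables with large point estimates that did not reach
    significance (flagged, not silently discarded). ``detail`` has one row per
    variable with chi2, df, p, magnitude and status.
    """

    association_set: frozenset
    classes: frozenset
    negligible: tuple
    imprecise: tuple
    detail: pd.DataFrame
    indeterminate: bool = False


def infer_association_set(
    model: MissingnessModel,
    *,
    alpha: float = 0.05,
    min_effect: float = 0.1,
    ) -> AssociationFindings:
    """Judge which variables are associated with missingness in the target.

    Grouped columns (dummy sets, the age basis) are tested jointly by a Wald
    chi-square on the group.  The magnitude measure is the standard deviation
    of the group's contribution to the linear predictor across the analysis
    rows — a per-SD log-odds scale comparable across continuous and
    categorical variables.
    """
    fit = model.fit
    if not fit.ok:
        warnings.warn("missingness model did not converge; association set "
                      "indeterminate", stacklevel=2)
        return AssociationFindings(frozenset(), frozenset(), (), (),
                                   pd.DataFrame(), indeterminate=True)
    rows = []
    associated, negligible, imprecise = [], [], []
    name_pos = {n: i for i, n in enumerate(model.names)}
    for var, cols in model.groups.items():
        idx = [name_pos[c] for c in cols]
        b = fit.params.iloc[idx].to_numpy()
        C = fit.cov_params.iloc[idx, idx].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df = len(idx)
        p = float(chi2.sf(stat, df)) if np.isfinite(stat) else np.nan
        contrib = model.X[:, idx] @ b
        magnitude = float(np.std(contrib))
        if p < alpha and magnitude >= min_effect:
            status = "associated"
            associated.append(var)
        elif p < alpha:
            status = "significant, negligible magnitude"
            negligible.append(var)
        elif magnitude >= min_effect:
            status = "large but imprecise"
            imprecise.append(var)
        else:
            status = "no evidence"
        rows.append({"variable": var, "chi2": stat, "df": df, "p": p,
                     "magnitude": magnitude, "status": status})
    classes = frozenset(_VARIABLE_CLASS[v] for v in associated)
    return AssociationFindings(
        association_set=frozenset(associated),
        classes=classes,
        negligible=tuple(negligible),
        imprecise=tuple(imprecise),
        detail=pd.DataFrame(rows).set_index("variable"),
    )


@dataclass(frozen=True)
class GuidanceVerdict:
    verdict: str                      # asymptotically_unbiased | generally_biased | indeterminate
    plausible_mechanisms: tuple
    caveats: tuple


def guidance_verdict(role: str, association_set: Sequence[str] | frozenset) -> GuidanceVerdict:
    """Map (role of the partially observed variable, detected associations)
    to the plausible mechanisms and the CRA verdict for the exposure log OR.

    ``association_set`` contains quantity classes from {"X", "Y", "C"} (for a
    confounder target, "C" means the *other* confounders C2).  Including the
    target's own class (e.g. "X" for an exposure target) declares contextual
    plausibility of self-dependent missingness, which the observed data alone
    cannot reveal.
    """
    if role not in ROLES:
        raise ConfigurationError(f"unknown role {role!r}; expected one of {ROLES}")
    s = frozenset(association_set)
    unknown = s - {"X", "Y", "C"}
    if unknown:
        raise ConfigurationError(f"unknown quantity classes {sorted(unknown)}")

    self_class = {"confounder_C1": "C1", "exposure_X": "X", "outcome_Y": "Y"}[role]
    biased = {"X", "Y"} <= s
    c_label = "C2" if role == "confounder_C1" else "C"

    plaus = []
    if biased:
        plaus.append("X and Y (jointly; generally biased unless it factorizes "
                     "as s(X,C)t(Y,C))")
        if role == "confounder_C1":
            plaus.append("C1 and X (asymptotically unbiased)")
            plaus.append("C1 and Y (asymptotically unbiased)")
    else:
        detected = [q if q != "C" else c_label for q in sorted(s)]
        base = " and ".join(detected) if detected else "none (MCAR)"
        if role != "outcome_Y" or "Y" not in s:
            # self-dependence is always possible and (alone) harmless
            plaus.append(f"{base}, possibly together with {self_class} itself")
        else:
            plaus.append(base)

    caveats = [CANCELLATION_CAVEAT] if not biased else ()
    verdict = "generally_biased" if biased else "asymptotically_unbiased"
    return GuidanceVerdict(verdict=verdict,
                           plausible_mechanisms=tuple(plaus),
                           caveats=tuple(caveats))


@dataclass
class DiagnosisReport:
    """Diagnosis of one partially observed variable."""

    target: str
    role: str
    missing_fraction: float
    skipped: bool = False
    skip_reason: str = ""
    model: MissingnessModel | None = None
    findings: AssociationFindings | None = None
    verdict: str = "indeterminate"
    plausible_mechanisms: tuple = ()
    caveats: tuple = ()

    def to_dict(self) -> dict:
        out = {
            "target": self.target,
            "role": self.role,
            "missing_fraction": self.missing_fraction,
            "skipped": self.skipped,
            "verdict": self.verdict,
            "plausible_mechanisms": list(self.plausible_mechanisms),
            "caveats": list(self.caveats),
        }
        if self.skipped:
            out["skip_reason"] = self.skip_reason
        if self.findings is not None and not self.findings.detail.empty:
            out["associations"] = {
                v: {"p": float(r["p"]), "magnitude": float(r["magnitude"]),
                    "status": r["status"]}
                for v, r in self.findings.detail.iterrows()
            }
        return out


@dataclass
class CohortDiagnosis:
    reports: list
    overall_verdict: str
    notes: tuple = ()

    def to_dict(self) -> dict:
        return {"overall_verdict": self.overall_verdict,
                "notes": list(self.notes),
                "reports": [r.to_dict() for r in self.reports]}


def _role_of(variable: str) -> str:
    return {"x": "exposure_X", "y": "outcome_Y"}.get(variable, "confounder_C1")


def diagnose_cohort(
    cohort: pd.DataFrame,
    spec: OutcomeModelSpec | None = None,
    *,
    alpha: float = 0.05,
    min_effect: float = 0.1,
    negligible_fraction: float = 0.005,
    ) -> CohortDiagnosis:
    """Diagnose every partially observed analysis variable in a cohort.

    Variables with a missingness fraction below ``negligible_fraction`` are
    reported as negligible and skipped (documented, mirroring standard
    practice for trace missingness).  Verdicts combine conservatively: any
    generally-biased diagnosis makes the overall verdict generally biased;
    any indeterminate one makes it indeterminate (unless something worse).
    """
    spec = spec or OutcomeModelSpec()
    n = len(cohort)
    partially = [v for v in ANALYSIS_VARIABLES if cohort[v].isna().any()]
    notes = []
    if not partially:
        return CohortDiagnosis(reports=[], overall_verdict="no_missing_data",
                               notes=("no missingness in any analysis variable",))
    if len(partially) > 1:
        notes.append(MULTIVARIABLE_CAVEAT)

    reports = []
    for target in partially:
        frac = float(cohort[target].isna().mean())
        role = _role_of(target)
        if frac < negligible_fraction:
            reports.append(DiagnosisReport(
                target=target, role=role, missing_fraction=frac, skipped=True,
                skip_reason=(f"missingness fraction {frac:.4f} below the "
                             f"negligibility threshold {negligible_fraction}")))
            continue
        model = fit_missingness_model(cohort, target, spec)
        findings = infer_association_set(model, alpha=alpha, min_effect=min_effect)
        if findings.indeterminate:
            reports.append(DiagnosisReport(
                target=target, role=role, missing_fraction=frac, model=model,
                findings=findings, verdict="indeterminate",
                caveats=("missingness model did not converge",)))
            continue
        gv = guidance_verdict(role, findings.classes)
        caveats = list(gv.caveats)
        if len(partially) > 1:
            caveats.append(MULTIVARIABLE_CAVEAT)
        if findings.imprecise:
            caveats.append(
                "large but imprecise associations for: "
                + ", ".join(findings.imprecise))
        reports.append(DiagnosisReport(
            target=target, role=role, missing_fraction=frac, model=model,
            findings=findings, verdict=gv.verdict,
            plausible_mechanisms=gv.plausible_mechanisms,
            caveats=tuple(caveats)))

    order = {"generally_biased": 2, "indeterminate": 1}
    worst = max((order.get(r.verdict, 0) for r in reports if not r.skipped),
                default=0)
    overall = {2: "generally_biased", 1: "indeterminate",
               0: "asymptotically_unbiased"}[worst]
    return CohortDiagnosis(reports=reports, overall_verdict=overall,
                           notes=tuple(notes))
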