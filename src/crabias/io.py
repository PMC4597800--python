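"""Cohort CSV reader/writer, config loading and report rendering."""

from __future__ import annotations

import hashlib
import json
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .mc_simulator import SimulationSummary
from .mechanisms import MechanismSpec, paper_mechanism
from .model_core import COHORT_COLUMNS, CohortSchemaError, validate_cohort

__all__ = [
    "read_cohort",
    "write_cohort",
    "load_config",
    "config_digest",
    "mechanism_from_config",
    "render_study_report",
]

_MISSING_TOKENS = ("", "NA")
_INT_COLUMNS = ("id", "y", "x", "sex", "smoking", "route")
_FLOAT_COLUMNS = ("age", "bmi")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells and "NA" parse as missing.

    Raises a schema error naming the offending column and line for unknown
    columns or unparseable cells. The row count of the file is preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      skipinitialspace=True)
    unknown = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise CohortSchemaError(f"unknown columns {unknown}; expected a subset "
                                f"of {list(COHORT_COLUMNS)}")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns {missing}")
    out = {}
    for col in COHORT_COLUMNS:
        s = raw[col].where(~raw[col].isin(_MISSING_TOKENS), other=np.nan)
        vals = pd.to_numeric(s, errors="coerce")
        bad = vals.isna() & ~s.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortSchemaError(
                f"unparseable value {s.iloc[i]!r} in column '{col}' on line "
                f"{i + 2} of {path}"
            )
        out[col] = vals.astype(float)
    cohort = pd.DataFrame(out)
    if cohort["id"].isna().any():
        raise CohortSchemaError("participant id may not be missing")
    cohort["id"] = cohort["id"].astype(np.int64)
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing cells are written empty."""
    out = cohort.copy()
    for col in _INT_COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for col in _FLOAT_COLUMNS:
        # shortest repr round-trips float64 exactly
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out[list(COHORT_COLUMNS)].to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file into a plain mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise CohortSchemaError(f"config file {path} must contain a mapping at "
                                "the top level")
    return dict(cfg)


def config_digest(cfg: Mapping) -> str:
    """Stable short digest of a configuration mapping (for log provenance)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def mechanism_from_config(entry) -> MechanismSpec:
    """A mechanism from a catalog name ("m1".."m8") or a config mapping."""
    if isinstance(entry, str):
        return paper_mechanism(entry)
    return MechanismSpec.from_dict(entry)


def render_study_report(summary: SimulationSummary) -> tuple[str, pd.DataFrame]:
    """Render a simulation summary as a text table and a CSV-ready frame.

    One row per mechanism; log odds ratios and SEs to 2 decimals, percent
    bias to 1 decimal; both renderings carry identical numbers.
    """
    t = summary.table
    if t.empty:
        raise CohortSchemaError("cannot render an empty simulation summary")
    contrasts = list(dict.fromkeys(t["contrast"]))
    rows = []
    for mech in dict.fromkeys(t["mechanism"]):
        sub = t[t["mechanism"] == mech].set_index("contrast")
        row = {"mechanism": mech, "dependence": sub["dependence"].iloc[0]}
        for c in contrasts:
            row[f"logOR_{c}"] = round(float(sub.loc[c, "mean_logOR"]), 2)
            row[f"SE_{c}"] = round(float(sub.loc[c, "mean_SE"]), 2)
            row[f"pct_bias_{c}"] = round(float(sub.loc[c, "percent_bias"]), 1)
        row["complete_fraction"] = round(float(sub["mean_complete_fraction"].iloc[0]), 3)
        row["n_failed"] = int(sub["n_failed"].iloc[0])
        rows.append(row)
    frame = pd.DataFrame(rows)

    lines = []
    header = f"{'mech':<6}{'dependence':<14}"
    for c in contrasts:
        header += f"{c + ' logOR (SE)':>20}{'% bias':>9}"
    header += f"{'P(R=1)':>9}{'failed':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    for row in rows:
        line = f"{row['mechanism']:<6}{row['dependence']:<14}"
        for c in contrasts:
            cell = f"{row[f'logOR_{c}']:.2f} ({row[f'SE_{c}']:.2f})"
            line += f"{cell:>20}{row[f'pct_bias_{c}']:>9.1f}"
        line += f"{row['complete_fraction']:>9.3f}{row['n_failed']:>8d}"
        lines.append(line)
    for w in summary.warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines), frame
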