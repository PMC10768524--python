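"""Cohort CSV reading/writing with schema validation, plan/config parsing.

Cohort files are comma-delimited UTF-8 with a header row using the
canonical column names.  Lines starting with ``#`` are provenance
comments written by :func:`write_cohort` and skipped (and re-parsed) on
read.  Loading is all-or-nothing: every row-level violation is collected
and reported with its row number before the load is rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .records import Cohort, Diagnosis, SchemaError, Sex

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_cohort",
    "write_cohort",
    "write_metrics",
    "load_simulation_config",
    "load_plan",
]

logger = logging.getLogger(__name__)

METRICS_SCHEMA_VERSION = "1"

#: Columns that must be present (patient_id is auto-generated when absent).
REQUIRED_COLUMNS = (
    "diagnosis",
    "sex",
    "age",
    "fvc_pct_pred",
    "monocyte_ratio",
    "followup_days",
    "event",
)

OPTIONAL_COLUMNS = (
    "patient_id",
    "dlco_pct_pred",
    "dlco_unmeasurable",
    "monocyte_count",
    "ccis",
    "honeycomb_score",
    "ggo_score",
)

#: Canonical on-disk column order.
COLUMN_ORDER = (
    "patient_id",
    "diagnosis",
    "sex",
    "age",
    "fvc_pct_pred",
    "dlco_pct_pred",
    "dlco_unmeasurable",
    "monocyte_ratio",
    "monocyte_count",
    "ccis",
    "honeycomb_score",
    "ggo_score",
    "followup_days",
    "event",
)

_DX_VOCAB = tuple(d.value for d in Diagnosis)
_SEX_VOCAB = tuple(s.value for s in Sex)


def _check_numeric(
    series: pd.Series,
    name: str,
    errors: list,
    *,
    minimum: Optional[float] = None,
    strict_min: bool = False,
    integer: bool = False,
    allow_missing: bool = False,
) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    raw_missing = series.isna() | (series.astype(str).str.strip() == "")
    bad_parse = vals.isna() & ~raw_missing
    for row in series.index[bad_parse]:
        errors.append(f"row {row + 1}: {name}: not numeric: {series[row]!r}")
    if not allow_missing:
        for row in series.index[raw_missing]:
            errors.append(f"row {row + 1}: {name}: missing value")
    if minimum is not None:
        ok = vals.notna()
        viol = ok & ((vals <= minimum) if strict_min else (vals < minimum))
        cmp = ">" if strict_min else ">="
        for row in series.index[viol]:
            errors.append(f"row {row + 1}: {name}: must be {cmp} {minimum}, got {vals[row]}")
    if integer:
        nonint = vals.notna() & (vals != np.floor(vals))
        for row in series.index[nonint]:
            errors.append(f"row {row + 1}: {name}: must be an integer, got {vals[row]}")
    return vals


def read_cohort(path: Union[str, Path]) -> Cohort:
    """Read and validate a cohort CSV; raises SchemaError listing all violations."""
    path = Path(path)
    provenance: dict[str, Any] = {"source": "file", "path": str(path)}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# provenance:"):
                try:
                    provenance.update(json.loads(line[len("# provenance:"):].strip()))
                except json.JSONDecodeError:
                    logger.warning("unparseable provenance comment in %s", path)
    raw = pd.read_csv(path, comment="#", dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "dlco_pct_pred" not in raw.columns and "dlco_unmeasurable" not in raw.columns:
        raise SchemaError(
            "cohort needs a dlco_pct_pred column or a dlco_unmeasurable flag column"
        )

    errors: list[str] = []
    n = len(raw)
    out = pd.DataFrame(index=raw.index)

    if "patient_id" in raw.columns:
        out["patient_id"] = raw["patient_id"].fillna("").astype(str)
    else:
        out["patient_id"] = [f"P{i + 1:05d}" for i in range(n)]

    dx = raw["diagnosis"].astype(str).str.strip()
    for row in dx.index[~dx.isin(_DX_VOCAB)]:
        errors.append(
            f"row {row + 1}: diagnosis: {dx[row]!r} not in {{{', '.join(_DX_VOCAB)}}}"
        )
    out["diagnosis"] = dx

    sex = raw["sex"].astype(str).str.strip()
    for row in sex.index[~sex.isin(_SEX_VOCAB)]:
        errors.append(f"row {row + 1}: sex: {sex[row]!r} not in {{male, female}}")
    out["sex"] = sex

    out["age"] = _check_numeric(raw["age"], "age", errors, minimum=0.0)
    out["fvc_pct_pred"] = _check_numeric(
        raw["fvc_pct_pred"], "fvc_pct_pred", errors, minimum=0.0, strict_min=True
    )
    out["monocyte_ratio"] = _check_numeric(
        raw["monocyte_ratio"], "monocyte_ratio", errors, minimum=0.0
    )
    out["followup_days"] = _check_numeric(
        raw["followup_days"], "followup_days", errors, minimum=0.0
    )

    ev = raw["event"].astype(str).str.strip()
    bad_ev = ~ev.isin(["0", "1"])
    for row in ev.index[bad_ev]:
        errors.append(f"row {row + 1}: event: must be 0 or 1, got {ev[row]!r}")
    out["event"] = pd.to_numeric(ev.where(~bad_ev, "0")).astype(int)

    if "dlco_unmeasurable" in raw.columns:
        um = raw["dlco_unmeasurable"].fillna("0").astype(str).str.strip().replace("", "0")
        bad_um = ~um.isin(["0", "1"])
        for row in um.index[bad_um]:
            errors.append(
                f"row {row + 1}: dlco_unmeasurable: must be 0 or 1, got {um[row]!r}"
            )
        out["dlco_unmeasurable"] = pd.to_numeric(um.where(~bad_um, "0")).astype(int)
    else:
        out["dlco_unmeasurable"] = 0

    if "dlco_pct_pred" in raw.columns:
        dlco = _check_numeric(
            raw["dlco_pct_pred"],
            "dlco_pct_pred",
            errors,
            minimum=0.0,
            strict_min=True,
            allow_missing=True,
        )
    else:
        dlco = pd.Series(np.nan, index=raw.index)
    # a numeric DLco is required unless the row is flagged unmeasurable
    need_dlco = (out["dlco_unmeasurable"] == 0) & dlco.isna()
    for row in dlco.index[need_dlco]:
        errors.append(
            f"row {row + 1}: dlco_pct_pred: missing value without dlco_unmeasurable=1"
        )
    out["dlco_pct_pred"] = dlco

    for col, integer in (
        ("monocyte_count", False),
        ("ccis", True),
        ("honeycomb_score", True),
        ("ggo_score", True),
    ):
        if col in raw.columns:
            out[col] = _check_numeric(
                raw[col], col, errors, minimum=0.0, integer=integer, allow_missing=True
            )
        else:
            out[col] = np.nan

    if errors:
        shown = "\n".join(errors[:50])
        more = "" if len(errors) <= 50 else f"\n... and {len(errors) - 50} more"
        raise SchemaError(f"cohort file {path} failed validation:\n{shown}{more}")

    return Cohort(data=out[list(COLUMN_ORDER)].reset_index(drop=True), provenance=provenance)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort CSV with a provenance comment header.

    Round-trips: ``read_cohort(write_cohort(c))`` reproduces the data and
    provenance (simulation seed included).
    """
    path = Path(path)
    df = cohort.data.copy()
    cols = [c for c in COLUMN_ORDER if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ildgapm cohort v1\n")
        prov = {k: v for k, v in cohort.provenance.items()}
        fh.write("# provenance: " + json.dumps(prov, default=_json_default) + "\n")
        df[cols + extra].to_csv(fh, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_metrics(
    metrics: dict, path: Union[str, Path], seed: Optional[int] = None
) -> None:
    """Write a metrics JSON document with schema version and seed provenance."""
    doc = {"schema_version": METRICS_SCHEMA_VERSION, "seed": seed}
    doc.update(metrics)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def load_simulation_config(path: Union[str, Path], **overrides):
    """Load a flat YAML/JSON document into a SimulationConfig."""
    from .simulate import SimulationConfig

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"simulation config {path} must be a mapping")
    raw.update(overrides)
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"unknown simulation config key(s): {', '.join(sorted(unknown))}")
    for key in ("subtype_probs", "male_prob_by_subtype"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)
    config.validate()
    return config


def load_plan(path: Union[str, Path], **overrides):
    """Load a YAML/JSON analysis plan."""
    from .pipeline import AnalysisPlan

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"analysis plan {path} must be a mapping")
    raw.update(overrides)
    valid = {f.name for f in dataclasses.fields(AnalysisPlan)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"unknown plan key(s): {', '.join(sorted(unknown))}")
    if "predictors" in raw and isinstance(raw["predictors"], list):
        raw["predictors"] = tuple(raw["predictors"])
    plan = AnalysisPlan(**raw)
    plan.validate()
    return plan
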