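"""ILD-GAP and ILD-GAPM point tables, staging, and HRCT score aggregation.

The ILD-GAP index assigns points for Gender, Age and Physiology (%FVC and
%DLco), with a -2 adjustment for the better-prognosis non-IPF/non-UC
diagnoses (CVD-IP, iNSIP, CHP).  ILD-GAPM adds one point when the blood
monocyte ratio exceeds 8.5% of leukocytes.  Both totals map to stages
I-IV with the same cut-offs (<=1, 2-3, 4-5, >5).

Bin-boundary conventions for continuous covariates
--------------------------------------------------
The printed point table uses integer-looking bins ("61-65", "50-75",
"36-55").  To make the partition exhaustive over real-valued inputs the
inner bins are taken as left-open/right-closed against the adjacent
strict inequalities:

* age:   <=60 -> 0, (60, 65] -> 1, >65 -> 2
* %FVC:  >75 -> 0, [50, 75] -> 1, <50 -> 2
* %DLco: >55 -> 0, (35, 55] -> 1, <=35 -> 2, unmeasurable -> 3

Integer inputs reproduce the printed table exactly.
"""

from __future__ import annotations

from dataclasses import replace
from numbers import Real
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .records import (
    ADJUSTED_DIAGNOSES,
    UNMEASURABLE,
    Diagnosis,
    PatientRecord,
    SchemaError,
    ScoreBreakdown,
    Sex,
)

__all__ = [
    "MONOCYTE_CUT",
    "component_points",
    "score_record",
    "ild_gap_score",
    "ild_gapm_score",
    "assign_stage",
    "hrct_global_score",
    "grade_from_extent",
    "score_dataframe",
]

#: Monocyte-ratio dichotomisation cut (%): the development cohort's median.
#: A fixed model constant; cohort-median mode is a pipeline option.
MONOCYTE_CUT = 8.5

#: Stage cut-offs: total <= 1 -> I, 2-3 -> II, 4-5 -> III, >= 6 -> IV.
STAGES = ("I", "II", "III", "IV")


def _diagnosis_points(diagnosis: Diagnosis) -> int:
    return -2 if diagnosis in ADJUSTED_DIAGNOSES else 0


def _sex_points(sex: Sex) -> int:
    return 1 if sex is Sex.MALE else 0


def _age_points(age: float) -> int:
    if age <= 60:
        return 0
    if age <= 65:
        return 1
    return 2


def _fvc_points(fvc: float) -> int:
    if fvc > 75:
        return 0
    if fvc >= 50:
        return 1
    return 2


def _dlco_points(dlco: Union[float, str]) -> int:
    if isinstance(dlco, str):  # validated as "unmeasurable" upstream
        return 3
    if dlco > 55:
        return 0
    if dlco > 35:
        return 1
    return 2


def _monocyte_points(ratio: float, cut: float = MONOCYTE_CUT) -> int:
    return 0 if ratio <= cut else 1


def component_points(
    record: PatientRecord, monocyte_cut: float = MONOCYTE_CUT
) -> ScoreBreakdown:
    """Per-component points for one patient; totals and stages left unset."""
    return ScoreBreakdown(
        diagnosis_points=_diagnosis_points(record.diagnosis),
        sex_points=_sex_points(record.sex),
        age_points=_age_points(record.age),
        fvc_points=_fvc_points(record.fvc_pct_pred),
        dlco_points=_dlco_points(record.dlco_pct_pred),
        monocyte_points=_monocyte_points(record.monocyte_ratio, monocyte_cut),
    )


def ild_gap_score(record: PatientRecord) -> int:
    """Total ILD-GAP score (diagnosis + sex + age + %FVC + %DLco points).

    Range -2 (adjusted diagnosis, all best bins) to 8 (worst bins with
    unmeasurable DLco).
    """
    b = component_points(record)
    return (
        b.diagnosis_points + b.sex_points + b.age_points + b.fvc_points + b.dlco_points
    )


def ild_gapm_score(record: PatientRecord, monocyte_cut: float = MONOCYTE_CUT) -> int:
    """Total ILD-GAPM score: ILD-GAP plus the monocyte point. Range -2..9."""
    return ild_gap_score(record) + _monocyte_points(record.monocyte_ratio, monocyte_cut)


def assign_stage(total) -> str:
    """Map an integer total score to stage I/II/III/IV.

    Cut-offs: <=1 -> I; 2 or 3 -> II; 4 or 5 -> III; >5 -> IV.  The same
    mapping applies to ILD-GAP and ILD-GAPM totals; negative totals
    (possible for adjusted diagnoses) fall in stage I.
    """
    if isinstance(total, bool) or not isinstance(total, Real):
        raise SchemaError(f"total: expected an integer score, got {total!r}")
    if not np.isfinite(total) or float(total) != int(total):
        raise SchemaError(f"total: expected an integer score, got {total!r}")
    total = int(total)
    if total <= 1:
        return "I"
    if total <= 3:
        return "II"
    if total <= 5:
        return "III"
    return "IV"


def score_record(
    record: PatientRecord, monocyte_cut: float = MONOCYTE_CUT
) -> ScoreBreakdown:
    """Full breakdown: components, both totals, and both stage labels."""
    b = component_points(record, monocyte_cut)
    gap = (
        b.diagnosis_points + b.sex_points + b.age_points + b.fvc_points + b.dlco_points
    )
    gapm = gap + b.monocyte_points
    return replace(
        b,
        ild_gap_total=gap,
        ild_gapm_total=gapm,
        ild_gap_stage=assign_stage(gap),
        ild_gapm_stage=assign_stage(gapm),
    )


def hrct_global_score(zones: Sequence[int]) -> int:
    """Global semiquantitative HRCT score: sum of six per-zone grades.

    The lungs are divided into six zones (upper/middle/lower per lung);
    each zone carries an extent grade 0-4 for one abnormality (GGO or
    honeycombing).  The global score is the sum over zones, range 0-24,
    computed separately per abnormality.
    """
    zones = list(zones)
    if len(zones) != 6:
        raise SchemaError(f"zones: expected exactly 6 zone grades, got {len(zones)}")
    for i, g in enumerate(zones):
        if isinstance(g, bool) or not isinstance(g, Real) or float(g) != int(g):
            raise SchemaError(f"zones[{i}]: grade must be an integer 0-4, got {g!r}")
        if not 0 <= int(g) <= 4:
            raise SchemaError(f"zones[{i}]: grade must be in 0..4, got {g}")
    return int(sum(int(g) for g in zones))


def grade_from_extent(
    percent_extent: float, bin_edges: Sequence[float] = (25.0, 50.0, 75.0)
) -> int:
    """Convert a per-zone percent disease extent to a 0-4 grade.

    Default dialect uses quartile bins: 0% -> 0, (0,25] -> 1, (25,50] -> 2,
    (50,75] -> 3, (75,100] -> 4.  Other semiquantitative dialects can be
    expressed by passing three ascending interior ``bin_edges``.
    """
    if not isinstance(percent_extent, Real) or isinstance(percent_extent, bool):
        raise SchemaError(f"percent_extent: expected a number, got {percent_extent!r}")
    if not 0 <= percent_extent <= 100:
        raise SchemaError(
            f"percent_extent: must be within [0, 100], got {percent_extent}"
        )
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) != 3 or not (0 < edges[0] < edges[1] < edges[2] < 100):
        raise SchemaError(f"bin_edges: need 3 ascending edges in (0, 100), got {edges}")
    if percent_extent == 0:
        return 0
    # grade g covers (edges[g-2], edges[g-1]] with edges extended by 0 and 100
    return 1 + int(np.searchsorted(edges, percent_extent, side="left"))


# ---------------------------------------------------------------------------
# Vectorised scoring over a cohort DataFrame


def score_dataframe(
    df: pd.DataFrame, monocyte_cut: float = MONOCYTE_CUT
) -> pd.DataFrame:
    """Append component points, totals and stages to a cohort DataFrame.

    Expects the canonical cohort columns (``diagnosis``, ``sex``, ``age``,
    ``fvc_pct_pred``, ``dlco_pct_pred``, ``dlco_unmeasurable``,
    ``monocyte_ratio``); returns a copy with ``*_points``,
    ``ild_gap_score``, ``ild_gapm_score``, ``ild_gap_stage`` and
    ``ild_gapm_stage`` columns added.  Rows are never dropped.
    """
    out = df.copy()
    dx = out["diagnosis"].astype(str)
    adjusted = dx.isin([d.value for d in ADJUSTED_DIAGNOSES])
    out["diagnosis_points"] = np.where(adjusted, -2, 0)
    out["sex_points"] = np.where(out["sex"].astype(str) == Sex.MALE.value, 1, 0)

    age = out["age"].to_numpy(dtype=float)
    out["age_points"] = np.select([age <= 60, age <= 65], [0, 1], default=2)

    fvc = out["fvc_pct_pred"].to_numpy(dtype=float)
    out["fvc_points"] = np.select([fvc > 75, fvc >= 50], [0, 1], default=2)

    if "dlco_unmeasurable" in out.columns:
        unmeas = out["dlco_unmeasurable"].fillna(0).astype(int).to_numpy() == 1
    else:
        unmeas = np.zeros(len(out), dtype=bool)
    dlco = out["dlco_pct_pred"].to_numpy(dtype=float)
    if np.any(~unmeas & ~np.isfinite(dlco)):
        bad = np.flatnonzero(~unmeas & ~np.isfinite(dlco))
        raise SchemaError(
            f"dlco_pct_pred: missing value in rows {bad.tolist()[:10]} "
            "without dlco_unmeasurable flag"
        )
    dlco_filled = np.where(unmeas, 1.0, dlco)  # placeholder, overridden below
    out["dlco_points"] = np.where(
        unmeas,
        3,
        np.select([dlco_filled > 55, dlco_filled > 35], [0, 1], default=2),
    )

    mono = out["monocyte_ratio"].to_numpy(dtype=float)
    out["monocyte_points"] = np.where(mono > monocyte_cut, 1, 0)

    out["ild_gap_score"] = (
        out["diagnosis_points"]
        + out["sex_points"]
        + out["age_points"]
        + out["fvc_points"]
        + out["dlco_points"]
    )
    out["ild_gapm_score"] = out["ild_gap_score"] + out["monocyte_points"]
    stage_map = np.vectorize(assign_stage)
    out["ild_gap_stage"] = stage_map(out["ild_gap_score"].to_numpy())
    out["ild_gapm_stage"] = stage_map(out["ild_gapm_score"].to_numpy())
    return out
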