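"""Core domain types: patients, cohorts, score breakdowns.

A cohort is a thin wrapper around a pandas DataFrame in the canonical
column layout (see :mod:`ildgapm.io`), plus provenance metadata recording
where the rows came from (a file on disk, or a simulation seed/config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Optional, Union

import pandas as pd

__all__ = [
    "Diagnosis",
    "Sex",
    "UNMEASURABLE",
    "SchemaError",
    "PatientRecord",
    "ScoreBreakdown",
    "Cohort",
]

#: Sentinel for a DLco that could not be measured (patient unable to
#: perform the manoeuvre).  Distinct from a missing value, which is a
#: schema error.
UNMEASURABLE = "unmeasurable"


class SchemaError(ValueError):
    """A record or cohort violates the schema; the message names the field."""


class Diagnosis(str, Enum):
    """ILD diagnosis subtypes recognised by the scoring models.

    IPF and unclassifiable ILD score 0 diagnosis points; the remaining
    subtypes (CVD-IP, iNSIP, CHP) receive the -2 adjustment.
    """

    IPF = "IPF"
    UC_ILD = "UC_ILD"
    CVD_IP = "CVD_IP"
    INSIP = "iNSIP"
    CHP = "CHP"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: Diagnoses that take the -2 point adjustment.
ADJUSTED_DIAGNOSES = frozenset({Diagnosis.CVD_IP, Diagnosis.INSIP, Diagnosis.CHP})


def _coerce_enum(value: Any, enum_cls: type[Enum], fieldname: str) -> Enum:
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except (ValueError, TypeError):
        allowed = ", ".join(e.value for e in enum_cls)
        raise SchemaError(
            f"{fieldname}: invalid value {value!r}; expected one of {allowed}"
        ) from None


@dataclass(frozen=True)
class PatientRecord:
    """One subject's covariates, follow-up and 3-year ILD-event flag.

    ``dlco_pct_pred`` is either a positive percent-predicted value or the
    string sentinel ``"unmeasurable"`` when the patient could not perform
    the diffusing-capacity test (this maps to the highest DLco point bin,
    it is not missing data).  ``event`` flags an ILD-related death or a
    first acute exacerbation within three years of pulmonary function
    testing.
    """

    diagnosis: Diagnosis
    sex: Sex
    age: float
    fvc_pct_pred: float
    dlco_pct_pred: Union[float, str]
    monocyte_ratio: float
    followup_days: float = 0.0
    event: bool = False
    patient_id: str = ""
    monocyte_count: Optional[float] = None
    ccis: Optional[int] = None
    honeycomb_score: Optional[int] = None
    ggo_score: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "diagnosis", _coerce_enum(self.diagnosis, Diagnosis, "diagnosis")
        )
        object.__setattr__(self, "sex", _coerce_enum(self.sex, Sex, "sex"))
        for name in ("age", "fvc_pct_pred", "monocyte_ratio", "followup_days"):
            v = getattr(self, name)
            if v is None or not isinstance(v, (int, float)) or v != v:
                raise SchemaError(f"{name}: missing or non-numeric value {v!r}")
        if self.age < 0:
            raise SchemaError(f"age: must be non-negative, got {self.age}")
        if self.fvc_pct_pred <= 0:
            raise SchemaError(f"fvc_pct_pred: must be positive, got {self.fvc_pct_pred}")
        if self.monocyte_ratio < 0:
            raise SchemaError(
                f"monocyte_ratio: must be non-negative, got {self.monocyte_ratio}"
            )
        if self.followup_days < 0:
            raise SchemaError(
                f"followup_days: must be non-negative, got {self.followup_days}"
            )
        d = self.dlco_pct_pred
        if isinstance(d, str):
            if d != UNMEASURABLE:
                raise SchemaError(
                    f"dlco_pct_pred: string value must be {UNMEASURABLE!r}, got {d!r}"
                )
        elif d is None or not isinstance(d, (int, float)) or d != d:
            raise SchemaError(f"dlco_pct_pred: missing or non-numeric value {d!r}")
        elif d <= 0:
            raise SchemaError(f"dlco_pct_pred: must be positive, got {d}")

    @property
    def dlco_unmeasurable(self) -> bool:
        return isinstance(self.dlco_pct_pred, str)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-component points and (optionally) totals and stage labels.

    ``ild_gap_total`` is the sum of the first five components;
    ``ild_gapm_total`` additionally adds the monocyte point.  Totals and
    stages are ``None`` when only the components were requested.
    """

    diagnosis_points: int
    sex_points: int
    age_points: int
    fvc_points: int
    dlco_points: int
    monocyte_points: int
    ild_gap_total: Optional[int] = None
    ild_gapm_total: Optional[int] = None
    ild_gap_stage: Optional[str] = None
    ild_gapm_stage: Optional[str] = None

    def components(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.diagnosis_points,
            self.sex_points,
            self.age_points,
            self.fvc_points,
            self.dlco_points,
            self.monocyte_points,
        )


@dataclass
class Cohort:
    """Ordered collection of patients as a DataFrame plus provenance.

    ``data`` uses the canonical cohort column layout; ``provenance``
    records either ``{"source": "file", "path": ...}`` or
    ``{"source": "simulation", "seed": ..., "config": {...}}``.
    """

    data: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def copy_with(self, data: pd.DataFrame) -> "Cohort":
        return Cohort(data=data, provenance=dict(self.provenance))

    def subset(self, mask) -> "Cohort":
        return self.copy_with(self.data.loc[mask].reset_index(drop=True))
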