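"""Patient records, cohorts, and CSV I/O for AML coagulation panels.

A :class:`PatientRecord` holds one patient's diagnostic laboratory panel
(the four ISTH components plus the candidate add-on markers LDH,
hemoglobin and INR), the AML subgroup (APL/M3 versus non-M3), the
genetic-positivity flag, and the DIC-related bleeding outcome.

Units are canonical throughout the package:

* prothrombin time in seconds,
* D-dimer in ng/mL (files may carry mg/L; the reader converts ×1000),
* fibrinogen in mg/dL,
* platelets in 10^9/L,
* hemoglobin in g/dL,
* LDH on the reported assay scale, treated as a bare number (score
  thresholds apply to the reported value).
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "Subgroup",
    "DDimerUnit",
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "RecordValidationError",
    "KNOWN_MUTATIONS",
    "derive_genetic_positivity",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]


class Subgroup(str, enum.Enum):
    """AML subgroup: acute promyelocytic leukemia (M3) or any other FAB subtype."""

    M3 = "M3"
    NON_M3 = "non_M3"


class DDimerUnit(str, enum.Enum):
    """Unit a cohort file reports D-dimer in; canonical unit is ng/mL."""

    NG_ML = "ng_ml"
    MG_L = "mg_l"


MG_L_TO_NG_ML = 1000.0

# exact header of the cohort CSV schema, in order
COHORT_COLUMNS = [
    "patient_id",
    "subgroup",
    "pt_seconds",
    "d_dimer",
    "fibrinogen_mg_dl",
    "platelet_1e9_l",
    "ldh",
    "hemoglobin_g_dl",
    "inr",
    "genetic_positive",
    "bleeding",
]

_LAB_FIELDS = [
    "pt_seconds",
    "d_dimer_ng_ml",
    "fibrinogen_mg_dl",
    "platelet_1e9_l",
    "ldh",
    "hemoglobin_g_dl",
    "inr",
]


class CohortSchemaError(ValueError):
    """A cohort file does not match the documented schema."""


class RecordValidationError(ValueError):
    """A row/record violates a field guard; carries patient_id and field."""

    def __init__(self, patient_id: str, field: str, message: str):
        self.patient_id = patient_id
        self.field = field
        super().__init__(f"patient {patient_id!r}, field {field!r}: {message}")


# Physiologic guards: values outside these are considered data errors, not
# extreme pathology, and are rejected rather than clamped.
_GUARDS = {
    "pt_seconds": (5.0, 120.0, "open"),
    "inr": (0.5, 20.0, "open"),
}
_NONNEGATIVE = {"d_dimer_ng_ml", "fibrinogen_mg_dl", "platelet_1e9_l", "ldh"}
_POSITIVE = {"hemoglobin_g_dl"}


class PatientRecord(BaseModel):
    """One patient's diagnostic panel, subgroup, genetic flag and outcome.

    Lab fields may be individually ``None`` (missing); whether a missing
    value is an error is decided by the operation that needs it (e.g. a
    score that does not use D-dimer can still be computed).
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    subgroup: Subgroup
    pt_seconds: Optional[float] = None
    d_dimer_ng_ml: Optional[float] = None
    fibrinogen_mg_dl: Optional[float] = None
    platelet_1e9_l: Optional[float] = None
    ldh: Optional[float] = None
    hemoglobin_g_dl: Optional[float] = None
    inr: Optional[float] = None
    genetic_positive: bool
    bleeding: bool

    @field_validator(*_LAB_FIELDS)
    @classmethod
    def _check_guards(cls, v, info):
        if v is None:
            return v
        if not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be finite, got {v!r}")
        if info.field_name in _GUARDS:
            lo, hi, _ = _GUARDS[info.field_name]
            if not (lo < v < hi):
                raise ValueError(
                    f"{info.field_name}={v!r} outside physiologic guard ({lo}, {hi})"
                )
        elif info.field_name in _POSITIVE:
            if v <= 0:
                raise ValueError(f"{info.field_name} must be positive, got {v!r}")
        elif v < 0:
            raise ValueError(f"{info.field_name} must be nonnegative, got {v!r}")
        return v


class Cohort(BaseModel):
    """An ordered collection of patient records with unique IDs."""

    records: list[PatientRecord]
    provenance: str = ""

    @field_validator("records")
    @classmethod
    def _unique_ids(cls, v):
        seen: set[str] = set()
        for r in v:
            if r.patient_id in seen:
                raise ValueError(f"duplicate patient_id {r.patient_id!r}")
            seen.add(r.patient_id)
        return v

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, subgroup: Subgroup) -> "Cohort":
        return Cohort(
            records=[r for r in self.records if r.subgroup == subgroup],
            provenance=f"{self.provenance}|subset={subgroup.value}",
        )


#: Recurrent genetic abnormalities screened at diagnosis.
KNOWN_MUTATIONS = frozenset(
    {"t(15;17)", "t(8;21)", "t(12;21)", "inv16", "FLT3", "NPM1", "CEBPA"}
)


def derive_genetic_positivity(subgroup: Subgroup, mutations: Iterable[str]) -> bool:
    """Classify a patient as genetic-positive from detected abnormalities.

    For APL (M3) patients the defining t(15;17) does not count: only a
    secondary abnormality makes the patient genetic-positive.  For non-M3
    patients any detected abnormality counts.

    Parameters
    ----------
    subgroup
        AML subgroup of the patient.
    mutations
        Detected abnormality labels, drawn from :data:`KNOWN_MUTATIONS`.

    Raises
    ------
    ValueError
        If a label is not a recognised abnormality.
    """
    muts = set(mutations)
    unknown = muts - KNOWN_MUTATIONS
    if unknown:
        raise ValueError(
            f"unknown mutation label(s) {sorted(unknown)}; "
            f"accepted labels: {sorted(KNOWN_MUTATIONS)}"
        )
    if subgroup == Subgroup.M3:
        muts = muts - {"t(15;17)"}
    return bool(muts)


def _parse_bool(raw, patient_id: str, field: str) -> bool:
    s = str(raw).strip()
    if s in {"0", "1"}:
        return s == "1"
    raise RecordValidationError(patient_id, field, f"expected 0/1, got {raw!r}")


def _parse_float(raw, patient_id: str, field: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise RecordValidationError(
            patient_id, field, f"unparseable numeric value {raw!r}"
        ) from None


def read_cohort_csv(path, d_dimer_unit: DDimerUnit = DDimerUnit.NG_ML) -> Cohort:
    """Read a cohort CSV, canonicalizing D-dimer to ng/mL.

    The header must match :data:`COHORT_COLUMNS` exactly (order-insensitive);
    a missing or renamed column raises :class:`CohortSchemaError` naming it.
    Row order is preserved.
    """
    d_dimer_unit = DDimerUnit(d_dimer_unit)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise CohortSchemaError(f"unrecognised column(s): {extra}")

    records = []
    for _, row in df.iterrows():
        pid = row["patient_id"].strip()
        if not pid:
            raise CohortSchemaError("empty patient_id")
        try:
            subgroup = Subgroup(row["subgroup"].strip())
        except ValueError:
            raise RecordValidationError(
                pid, "subgroup",
                f"expected one of {[s.value for s in Subgroup]}, got {row['subgroup']!r}",
            ) from None
        d_dimer = _parse_float(row["d_dimer"], pid, "d_dimer")
        if d_dimer is not None and d_dimer_unit == DDimerUnit.MG_L:
            d_dimer = d_dimer * MG_L_TO_NG_ML
        kwargs = dict(
            patient_id=pid,
            subgroup=subgroup,
            pt_seconds=_parse_float(row["pt_seconds"], pid, "pt_seconds"),
            d_dimer_ng_ml=d_dimer,
            fibrinogen_mg_dl=_parse_float(row["fibrinogen_mg_dl"], pid, "fibrinogen_mg_dl"),
            platelet_1e9_l=_parse_float(row["platelet_1e9_l"], pid, "platelet_1e9_l"),
            ldh=_parse_float(row["ldh"], pid, "ldh"),
            hemoglobin_g_dl=_parse_float(row["hemoglobin_g_dl"], pid, "hemoglobin_g_dl"),
            inr=_parse_float(row["inr"], pid, "inr"),
            genetic_positive=_parse_bool(row["genetic_positive"], pid, "genetic_positive"),
            bleeding=_parse_bool(row["bleeding"], pid, "bleeding"),
        )
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as e:
            raise RecordValidationError(pid, "record", str(e)) from None
    try:
        return Cohort(records=records, provenance=str(path))
    except ValueError as e:
        raise CohortSchemaError(str(e)) from None


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(v) if v != int(v) else str(int(v))


def write_cohort_csv(cohort: Cohort, path, d_dimer_unit: DDimerUnit = DDimerUnit.NG_ML) -> None:
    """Write a cohort in the documented CSV schema.

    D-dimer is written in the requested unit; round-tripping through
    :func:`read_cohort_csv` with the same unit flag reproduces all values.
    """
    d_dimer_unit = DDimerUnit(d_dimer_unit)
    rows = []
    for r in cohort.records:
        dd = r.d_dimer_ng_ml
        if dd is not None and d_dimer_unit == DDimerUnit.MG_L:
            dd = dd / MG_L_TO_NG_ML
        rows.append(
            {
                "patient_id": r.patient_id,
                "subgroup": r.subgroup.value,
                "pt_seconds": _fmt(r.pt_seconds),
                "d_dimer": _fmt(dd),
                "fibrinogen_mg_dl": _fmt(r.fibrinogen_mg_dl),
                "platelet_1e9_l": _fmt(r.platelet_1e9_l),
                "ldh": _fmt(r.ldh),
                "hemoglobin_g_dl": _fmt(r.hemoglobin_g_dl),
                "inr": _fmt(r.inr),
                "genetic_positive": int(r.genetic_positive),
                "bleeding": int(r.bleeding),
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
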