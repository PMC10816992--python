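"""Cohort data model, CSV I/O, and deterministic classification rules.

A cohort row is one study participant: demographics, clinical group
(community volunteer without dementia, AD patient, or non-AD patient),
plasma A-beta 42 and 40 concentrations (pg/mL) measured by single-molecule
array, and -- for the subset who underwent a confirmatory exam -- either a
CSF A-beta-42 concentration or an amyloid-PET Centiloid value together
with the date of that measurement.

The rules implemented here are fixed, not fitted:

* amyloid positivity: CSF A-beta-42 < 438 pg/mL, or Centiloid > 26;
* dementia: MMSE < 24 out of 30;
* APOE epsilon-4 carriage: at least one e4 allele in the genotype;
* eligibility for supervised analyses: blood draw and amyloid measurement
  at most ``window_days`` apart, with an exception for amyloid-positive
  measurements that predate the blood draw (amyloid positivity is
  considered persistent in an untreated cohort).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "ApoE",
    "AmyloidStatus",
    "Modality",
    "AmyloidCall",
    "Participant",
    "Cohort",
    "CohortError",
    "CSF_AB42_POSITIVE_BELOW",
    "CENTILOID_POSITIVE_ABOVE",
    "MMSE_DEMENTIA_BELOW",
    "DEFAULT_WINDOW_DAYS",
    "read_cohort",
    "write_cohort",
    "write_analysis_set",
    "call_amyloid",
    "has_dementia",
    "is_e4_carrier",
    "is_eligible",
]

#: CSF A-beta-42 below this concentration (pg/mL) is amyloid positive.
CSF_AB42_POSITIVE_BELOW = 438.0
#: Centiloid strictly above this value is amyloid positive.
CENTILOID_POSITIVE_ABOVE = 26.0
#: MMSE strictly below this score defines dementia.
MMSE_DEMENTIA_BELOW = 24
#: Two years, counted as a fixed number of days.
DEFAULT_WINDOW_DAYS = 730


class CohortError(ValueError):
    """Raised for malformed cohort files or undecidable classifications."""


class Group(str, Enum):
    VOLUNTEER = "volunteer"
    AD = "ad"
    NON_AD = "non_ad"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class ApoE(str, Enum):
    E2E2 = "e2e2"
    E2E3 = "e2e3"
    E3E3 = "e3e3"
    E2E4 = "e2e4"
    E3E4 = "e3e4"
    E4E4 = "e4e4"


class AmyloidStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class Modality(str, Enum):
    CSF = "csf"
    FLUTEMETAMOL_PET = "flutemetamol_pet"
    PIB_PET = "pib_pet"
    NONE = "none"


@dataclass(frozen=True)
class AmyloidCall:
    """Ground-truth amyloid status plus the modality that produced it."""

    status: AmyloidStatus
    modality: Modality

    def __post_init__(self) -> None:
        if (self.status is AmyloidStatus.UNKNOWN) != (self.modality is Modality.NONE):
            raise CohortError("status is unknown iff modality is none")


@dataclass(frozen=True)
class Participant:
    """One cohort row.

    ``ratio`` is the plasma A-beta 42/40 ratio; it is computed from the two
    concentrations when both are present and not given explicitly.
    ``pet_tracer`` distinguishes the two PET radiotracers used for the
    Centiloid measurement and defaults to flutemetamol when a Centiloid
    value is present without a tracer label.
    """

    id: str
    group: Group
    age: float
    sex: Sex
    blood_date: _dt.date
    mmse: Optional[int] = None
    apoe: Optional[ApoE] = None
    ab42_plasma: Optional[float] = None
    ab40_plasma: Optional[float] = None
    ratio: Optional[float] = None
    csf_ab42: Optional[float] = None
    centiloid: Optional[float] = None
    pet_tracer: Optional[str] = None  # "flutemetamol" or "pib"
    amyloid_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if self.ratio is None and self.ab42_plasma is not None and self.ab40_plasma is not None:
            object.__setattr__(self, "ratio", self.ab42_plasma / self.ab40_plasma)
        for name in ("ab42_plasma", "ab40_plasma", "ratio", "csf_ab42"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise CohortError(f"{name} must be > 0, got {v!r} (participant {self.id})")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise CohortError(f"mmse must be in [0, 30], got {self.mmse} (participant {self.id})")
        if self.pet_tracer is not None and self.pet_tracer not in ("flutemetamol", "pib"):
            raise CohortError(f"unknown PET tracer {self.pet_tracer!r} (participant {self.id})")


@dataclass
class Cohort:
    """Ordered collection of participants with unique ids."""

    participants: list[Participant] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.participants:
            if p.id in seen:
                raise CohortError(f"duplicate participant id {p.id!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[Participant]:
        return iter(self.participants)

    def __getitem__(self, i: int) -> Participant:
        return self.participants[i]

    def ratios(self) -> list[float]:
        """Plasma 42/40 ratios of participants that have one, in cohort order."""
        return [p.ratio for p in self.participants if p.ratio is not None]

    def subset(self, predicate) -> "Cohort":
        return Cohort([p for p in self.participants if predicate(p)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "id": p.id,
                    "group": p.group.value,
                    "age": p.age,
                    "sex": p.sex.value,
                    "mmse": p.mmse,
                    "apoe": None if p.apoe is None else p.apoe.value,
                    "ab42_plasma": p.ab42_plasma,
                    "ab40_plasma": p.ab40_plasma,
                    "ratio": p.ratio,
                    "csf_ab42": p.csf_ab42,
                    "centiloid": p.centiloid,
                    "pet_tracer": p.pet_tracer,
                    "blood_date": p.blood_date.isoformat(),
                    "amyloid_date": None if p.amyloid_date is None else p.amyloid_date.isoformat(),
                }
            )
        return pd.DataFrame(rows, columns=_CANONICAL_COLUMNS)


_CANONICAL_COLUMNS = [
    "id",
    "group",
    "age",
    "sex",
    "mmse",
    "apoe",
    "ab42_plasma",
    "ab40_plasma",
    "ratio",
    "csf_ab42",
    "centiloid",
    "pet_tracer",
    "blood_date",
    "amyloid_date",
]


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return isinstance(cell, str) and cell.strip() == ""


def _parse_float(cell, row: int, col: str) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(cell)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"row {row}: malformed numeric value {cell!r} in column {col!r}") from exc


def _parse_int(cell, row: int, col: str) -> Optional[int]:
    v = _parse_float(cell, row, col)
    if v is None:
        return None
    if v != int(v):
        raise CohortError(f"row {row}: expected integer in column {col!r}, got {cell!r}")
    return int(v)


def _parse_date(cell, row: int, col: str) -> Optional[_dt.date]:
    if _is_missing(cell):
        return None
    try:
        return _dt.date.fromisoformat(str(cell).strip())
    except ValueError as exc:
        raise CohortError(f"row {row}: malformed date {cell!r} in column {col!r}") from exc


def _parse_enum(cell, enum_cls, row: int, col: str):
    if _is_missing(cell):
        return None
    try:
        return enum_cls(str(cell).strip().lower())
    except ValueError as exc:
        valid = ", ".join(e.value for e in enum_cls)
        raise CohortError(f"row {row}: {cell!r} is not one of [{valid}] in column {col!r}") from exc


def read_cohort(path, column_map: Optional[Mapping[str, str]] = None) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path
        CSV file with one header row. Canonical column names are
        ``id, group, age, sex, mmse, apoe, ab42_plasma, ab40_plasma, ratio,
        csf_ab42, centiloid, pet_tracer, blood_date, amyloid_date``.
    column_map
        Optional mapping of canonical name -> actual header name, for files
        whose headers differ (typically loaded from a YAML config).

    Missing cells become missing values; the 42/40 ratio is computed when
    absent but both concentrations are present. Malformed cells and
    duplicate ids raise :class:`CohortError` carrying the row index
    (0-based over data rows).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {actual: canon for canon, actual in column_map.items()}
        missing = [a for a in rename if a not in frame.columns]
        if missing:
            raise CohortError(f"mapped columns not found in file: {missing}")
        frame = frame.rename(columns=rename)
    for required in ("id", "group", "age", "sex", "blood_date"):
        if required not in frame.columns:
            raise CohortError(f"required column {required!r} missing from header")

    def cell(record, col):
        return record.get(col) if col in frame.columns else None

    participants = []
    for i, record in enumerate(frame.to_dict(orient="records")):
        pid = str(record["id"]).strip()
        if not pid:
            raise CohortError(f"row {i}: empty participant id")
        group = _parse_enum(record["group"], Group, i, "group")
        sex = _parse_enum(record["sex"], Sex, i, "sex")
        if group is None or sex is None:
            raise CohortError(f"row {i}: group and sex are required")
        age = _parse_float(record["age"], i, "age")
        blood_date = _parse_date(record["blood_date"], i, "blood_date")
        if age is None or blood_date is None:
            raise CohortError(f"row {i}: age and blood_date are required")
        tracer = cell(record, "pet_tracer")
        try:
            participants.append(
                Participant(
                    id=pid,
                    group=group,
                    age=age,
                    sex=sex,
                    mmse=_parse_int(cell(record, "mmse"), i, "mmse"),
                    apoe=_parse_enum(cell(record, "apoe"), ApoE, i, "apoe"),
                    ab42_plasma=_parse_float(cell(record, "ab42_plasma"), i, "ab42_plasma"),
                    ab40_plasma=_parse_float(cell(record, "ab40_plasma"), i, "ab40_plasma"),
                    ratio=_parse_float(cell(record, "ratio"), i, "ratio"),
                    csf_ab42=_parse_float(cell(record, "csf_ab42"), i, "csf_ab42"),
                    centiloid=_parse_float(cell(record, "centiloid"), i, "centiloid"),
                    pet_tracer=None if _is_missing(tracer) else str(tracer).strip().lower(),
                    blood_date=blood_date,
                    amyloid_date=_parse_date(cell(record, "amyloid_date"), i, "amyloid_date"),
                )
            )
        except CohortError as exc:
            raise CohortError(f"row {i}: {exc}") from exc
    return Cohort(participants)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV with canonical columns (round-trip safe)."""
    cohort.to_frame().to_csv(path, index=False)


def call_amyloid(p: Participant, csf_precedence: bool = True) -> AmyloidCall:
    """Ground-truth amyloid call from CSF A-beta-42 or amyloid-PET Centiloid.

    CSF < 438 pg/mL or Centiloid > 26 is positive. When both measurements
    are present, ``csf_precedence`` selects which one decides (CSF by
    default). With neither present the status is unknown.
    """
    modalities = []
    if p.csf_ab42 is not None:
        modalities.append("csf")
    if p.centiloid is not None:
        modalities.append("pet")
    if not modalities:
        return AmyloidCall(AmyloidStatus.UNKNOWN, Modality.NONE)
    use_csf = "csf" in modalities and (csf_precedence or "pet" not in modalities)
    if use_csf:
        status = AmyloidStatus.POSITIVE if p.csf_ab42 < CSF_AB42_POSITIVE_BELOW else AmyloidStatus.NEGATIVE
        return AmyloidCall(status, Modality.CSF)
    status = AmyloidStatus.POSITIVE if p.centiloid > CENTILOID_POSITIVE_ABOVE else AmyloidStatus.NEGATIVE
    modality = Modality.PIB_PET if p.pet_tracer == "pib" else Modality.FLUTEMETAMOL_PET
    return AmyloidCall(status, modality)


def has_dementia(p: Participant) -> bool:
    """True iff MMSE < 24/30. Raises when MMSE is missing."""
    if p.mmse is None:
        raise CohortError(f"participant {p.id}: dementia status undecidable without MMSE")
    return p.mmse < MMSE_DEMENTIA_BELOW


def is_e4_carrier(p: Participant) -> bool:
    """True iff the APOE genotype carries at least one epsilon-4 allele."""
    if p.apoe is None:
        raise CohortError(f"participant {p.id}: e4 carriage undecidable without APOE genotype")
    return "e4" in p.apoe.value


def is_eligible(p: Participant, window_days: int = DEFAULT_WINDOW_DAYS,
                csf_precedence: bool = True) -> bool:
    """Eligibility of a participant for the supervised analyses.

    Requires a known amyloid status whose measurement date lies within
    ``window_days`` of the blood draw. A measurement older than the window
    still qualifies when it preceded the blood draw and was positive:
    without anti-amyloid treatment, a past positive status persists.
    Participants with unknown status are ineligible (never an error).
    """
    call = call_amyloid(p, csf_precedence=csf_precedence)
    if call.status is AmyloidStatus.UNKNOWN:
        return False
    if p.amyloid_date is None:
        raise CohortError(
            f"participant {p.id}: amyloid measurement present but its date is missing"
        )
    delay = abs((p.amyloid_date - p.blood_date).days)
    if delay <= window_days:
        return True
    return p.amyloid_date < p.blood_date and call.status is AmyloidStatus.POSITIVE


def write_analysis_set(cohort: Cohort, path, window_days: int = DEFAULT_WINDOW_DAYS,
                       csf_precedence: bool = True) -> pd.DataFrame:
    """Write the eligibility-filtered analysis set as CSV.

    Appends ``amyloid_status``, ``modality``, ``dementia`` and
    ``e4_carrier`` columns (the latter two empty where undecidable).
    Returns the written frame.
    """
    kept = [p for p in cohort if is_eligible(p, window_days, csf_precedence)]
    frame = Cohort(kept).to_frame()
    calls = [call_amyloid(p, csf_precedence) for p in kept]
    frame["amyloid_status"] = [c.status.value for c in calls]
    frame["modality"] = [c.modality.value for c in calls]
    frame["dementia"] = [None if p.mmse is None else has_dementia(p) for p in kept]
    frame["e4_carrier"] = [None if p.apoe is None else is_e4_carrier(p) for p in kept]
    frame.to_csv(path, index=False)
    return frame
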