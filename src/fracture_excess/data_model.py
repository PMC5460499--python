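"""Domain types and delimited-text I/O for person and claims tables.

The pipeline consumes two flat tables shaped like administrative-claims
extracts:

``persons``
    one row per insured person — identifier, sex, birth year, optional
    death date, and the coverage window during which claims can be
    observed.

``claims``
    one row per health-care claim — person identifier, first day of
    care, in/outpatient setting, a primary ICD-10 diagnosis, optional
    secondary diagnoses and provider specialty.

Readers validate row by row: structurally broken rows (bad dates,
malformed ICD-10 codes, unknown categorical values) are rejected and
recorded in a :class:`ValidationReport` rather than aborting the load,
mirroring how claims extracts are cleaned in practice.  ICD-10 codes are
normalised to upper case with the dot retained (``S72.0``); all
downstream code matching is prefix-based on that dotted form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

__all__ = [
    "ICD10_PATTERN",
    "SchemaError",
    "ValidationReport",
    "read_persons",
    "read_claims",
    "write_persons",
    "write_claims",
    "validate_linkage",
    "normalize_icd10",
]

#: letter + two digits, optionally a dot and one or two further digits
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9]{1,2})?$")

PERSON_COLUMNS = ["person_id", "sex", "birth_year", "death_date",
                  "coverage_start", "coverage_end"]
CLAIM_COLUMNS = ["person_id", "service_date", "setting", "primary_dx",
                 "secondary_dx", "specialty"]

BIRTH_YEAR_RANGE = (1890, 2000)
#: plausibility bounds on claim service dates
SERVICE_DATE_RANGE = (date(1990, 1, 1), date(2030, 12, 31))


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class ValidationReport:
    """Row-level accounting for one table read or linkage check."""

    rows_read: int = 0
    rows_accepted: int = 0
    rows_rejected: int = 0
    violations: list[str] = field(default_factory=list)

    def reject(self, locator: str, message: str) -> None:
        self.rows_rejected += 1
        self.violations.append(f"{locator}: {message}")

    @property
    def conserved(self) -> bool:
        return self.rows_read == self.rows_accepted + self.rows_rejected


def normalize_icd10(code: str) -> str:
    """Upper-case an ICD-10 code, keeping the dotted form."""
    return str(code).strip().upper()


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    return date.fromisoformat(s)


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def read_persons(path, delimiter: str = ",") -> tuple[pd.DataFrame, ValidationReport]:
    """Read a person table, returning accepted rows and a report.

    Rows violating the person invariants (unparseable dates, sex outside
    {male, female}, implausible birth year, death before coverage start,
    inverted coverage window) are rejected, not raised.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _require_columns(raw, PERSON_COLUMNS, "persons")
    report = ValidationReport(rows_read=len(raw))
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # 1-based + header
        loc = f"persons row {i}"
        try:
            birth_year = int(row.birth_year)
            death = _parse_date(row.death_date)
            cov_start = _parse_date(row.coverage_start)
            cov_end = _parse_date(row.coverage_end)
        except (ValueError, TypeError) as exc:
            report.reject(loc, f"unparseable field: {exc}")
            continue
        sex = str(row.sex).strip().lower()
        if sex not in ("male", "female"):
            report.reject(loc, f"sex must be male/female, got {row.sex!r}")
            continue
        if not (BIRTH_YEAR_RANGE[0] <= birth_year <= BIRTH_YEAR_RANGE[1]):
            report.reject(loc, f"implausible birth_year {birth_year}")
            continue
        if cov_start is None or cov_end is None:
            report.reject(loc, "coverage_start and coverage_end are required")
            continue
        if cov_start > cov_end:
            report.reject(loc, "coverage_start after coverage_end")
            continue
        if death is not None and death < cov_start:
            report.reject(loc, "death_date before coverage_start")
            continue
        rows.append((str(row.person_id), sex, birth_year, death, cov_start, cov_end))
    report.rows_accepted = len(rows)
    df = pd.DataFrame(rows, columns=PERSON_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in PERSON_COLUMNS})
        df["birth_year"] = df["birth_year"].astype(int)
    return df, report


def read_claims(path, delimiter: str = ",") -> tuple[pd.DataFrame, ValidationReport]:
    """Read a claims table with ICD-10 syntax validation.

    ``secondary_dx`` is parsed from a ``;``-joined field into a list of
    normalised codes.  A row is rejected if its primary or any secondary
    code fails ICD-10 syntax, or the service date is unparseable or
    implausible.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _require_columns(raw, CLAIM_COLUMNS, "claims")
    report = ValidationReport(rows_read=len(raw))
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        loc = f"claims row {i}"
        try:
            service = _parse_date(row.service_date)
        except (ValueError, TypeError) as exc:
            report.reject(loc, f"unparseable service_date: {exc}")
            continue
        if service is None:
            report.reject(loc, "service_date is required")
            continue
        if not (SERVICE_DATE_RANGE[0] <= service <= SERVICE_DATE_RANGE[1]):
            report.reject(loc, f"service_date {service} outside plausible window")
            continue
        setting = str(row.setting).strip().lower()
        if setting not in ("inpatient", "outpatient"):
            report.reject(loc, f"setting must be inpatient/outpatient, got {row.setting!r}")
            continue
        primary = normalize_icd10(row.primary_dx)
        if not ICD10_PATTERN.match(primary):
            report.reject(loc, f"primary_dx {row.primary_dx!r} violates ICD-10 syntax")
            continue
        secondary = [normalize_icd10(c) for c in str(row.secondary_dx).split(";")
                     if c.strip()]
        bad = [c for c in secondary if not ICD10_PATTERN.match(c)]
        if bad:
            report.reject(loc, f"secondary_dx {bad[0]!r} violates ICD-10 syntax")
            continue
        specialty = str(row.specialty).strip() or None
        rows.append((str(row.person_id), service, setting, primary, secondary,
                     specialty))
    report.rows_accepted = len(rows)
    df = pd.DataFrame(rows, columns=CLAIM_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in CLAIM_COLUMNS})
    return df, report


def _date_str(value) -> str:
    return "" if value is None or pd.isna(value) else value.isoformat()


def write_persons(persons: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = persons.copy()
    out["death_date"] = out["death_date"].map(_date_str)
    for col in ("coverage_start", "coverage_end"):
        out[col] = out[col].map(lambda d: d.isoformat())
    out.to_csv(path, sep=delimiter, index=False)


def write_claims(claims: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = claims.copy()
    out["service_date"] = out["service_date"].map(lambda d: d.isoformat())
    out["secondary_dx"] = out["secondary_dx"].map(";".join)
    out["specialty"] = out["specialty"].map(lambda s: s or "")
    out.to_csv(path, sep=delimiter, index=False)


def validate_linkage(persons: pd.DataFrame, claims: pd.DataFrame) -> ValidationReport:
    """Cross-check claims against the person table.

    Flags claims whose person is unknown, claims dated outside the
    person's coverage window, and claims dated after the person's death.
    All claims count as read; flagged claims count as rejected.
    """
    report = ValidationReport(rows_read=len(claims))
    idx = persons.set_index("person_id")
    for i, row in enumerate(claims.itertuples(index=False), start=2):
        loc = f"claims row {i}"
        pid = row.person_id
        if pid not in idx.index:
            report.reject(loc, f"orphan claim: person_id {pid!r} not in person table")
            continue
        person = idx.loc[pid]
        death = person["death_date"]
        if death is not None and not pd.isna(death) and row.service_date > death:
            report.reject(loc, f"post-death claim for person_id {pid!r}")
            continue
        if not (person["coverage_start"] <= row.service_date <= person["coverage_end"]):
            report.reject(loc, f"claim outside coverage window for person_id {pid!r}")
            continue
        report.rows_accepted += 1
    return report
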