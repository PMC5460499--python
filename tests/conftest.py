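"""Shared builders for in-memory person/claim tables.

These construct frames with the same schema and dtypes the CSV readers
produce (date objects, secondary-diagnosis lists), so pipeline stages
can be tested without touching the filesystem.
"""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest


def person_row(
    person_id: str,
    sex: str = "female",
    birth_year: int = 1935,
    death_date: date | None = None,
    coverage_start: date = date(2004, 1, 1),
    coverage_end: date = date(2016, 5, 4),
) -> dict:
    return dict(person_id=person_id, sex=sex, birth_year=birth_year,
                death_date=death_date, coverage_start=coverage_start,
                coverage_end=coverage_end)


def claim_row(
    person_id: str,
    service_date: date,
    setting: str = "outpatient",
    primary_dx: str = "Z00.0",
    secondary_dx: list[str] | None = None,
    specialty: str | None = None,
) -> dict:
    return dict(person_id=person_id, service_date=service_date, setting=setting,
                primary_dx=primary_dx, secondary_dx=secondary_dx or [],
                specialty=specialty)


def persons_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["person_id", "sex", "birth_year", "death_date", "coverage_start",
            "coverage_end"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def claims_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["person_id", "service_date", "setting", "primary_dx",
            "secondary_dx", "specialty"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


@pytest.fixture
def simple_cohort():
    """A four-person matched set with hand-computable follow-up."""
    idx = date(2006, 6, 1)
    rows = []
    for pid, arm, death in [
        ("c1", "case", date(2006, 9, 1)),       # dies ~3 months in
        ("r1", "reference", None),
        ("r2", "reference", date(2010, 6, 1)),  # dies 4 years in
        ("r3", "reference", None),
    ]:
        rows.append(dict(person_id=pid, index_date=idx, arm=arm,
                         matched_set_id="c1", sex="female", birth_year=1930,
                         age_at_index=76, cci_score=0))
    cohort = pd.DataFrame(rows)
    persons = persons_frame([
        person_row("c1", death_date=date(2006, 9, 1)),
        person_row("r1"),
        person_row("r2", death_date=date(2010, 6, 1)),
        person_row("r3"),
    ])
    return cohort, persons
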