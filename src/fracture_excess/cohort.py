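"""Incident hip-fracture ascertainment, 1:4 matching, and follow-up.

A case is a person's first inpatient claim carrying a hip-fracture code
(S72.0 femoral neck, S72.1 pertrochanteric, S72.2 subtrochanteric) as
the primary diagnosis, with no earlier hip-fracture claim of any kind in
the claims history, within the enrolment window and at or above the
minimum age.  Each case is matched to up to four reference subjects of
the same sex and birth year who, at the case's index date, are alive,
within insurance coverage, and free of any prior hip-fracture claim.
Sampling is without replacement across the whole study, so a person
serves as a reference at most once; candidate order is randomised by the
run seed.  Follow-up runs from the index date to death or the study
closure date, whichever comes first.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "MONTH_DAYS",
    "FRACTURE_PREFIXES",
    "find_incident_fractures",
    "match_references",
    "build_follow_up",
    "build_cohort",
    "expected_reference_total",
]

logger = logging.getLogger(__name__)

#: fixed month length (days) used for all month arithmetic
MONTH_DAYS = 365.25 / 12

FRACTURE_PREFIXES = ("S72.0", "S72.1", "S72.2")

DEFAULT_ENROLMENT = (date(2005, 1, 1), date(2013, 12, 31))
DEFAULT_CLOSURE = date(2016, 5, 4)
DEFAULT_MIN_AGE = 50
#: minimum follow-up (days) credited to subjects dying on the index date
MIN_DURATION_DAYS = 0.5


def _is_fracture(codes: pd.Series, prefixes=FRACTURE_PREFIXES) -> pd.Series:
    return codes.str.startswith(prefixes)


def _fracture_evidence_dates(claims: pd.DataFrame, prefixes) -> pd.Series:
    """Earliest claim date per person carrying a fracture code anywhere."""
    primary_hit = _is_fracture(claims["primary_dx"], prefixes)
    secondary_hit = claims["secondary_dx"].map(
        lambda codes: any(c.startswith(prefixes) for c in codes)
    )
    hits = claims[primary_hit | secondary_hit]
    return hits.groupby("person_id")["service_date"].min()


def find_incident_fractures(
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    enrolment_window: tuple[date, date] = DEFAULT_ENROLMENT,
    min_age: int = DEFAULT_MIN_AGE,
    fracture_prefixes=FRACTURE_PREFIXES,
) -> pd.DataFrame:
    """One case row per person with an incident hip fracture.

    The index date is the service date of the first inpatient claim with
    a fracture code as primary diagnosis; persons with any earlier
    fracture-coded claim (any setting or diagnosis position) are
    excluded as non-incident, as are fractures outside the enrolment
    window or below ``min_age`` at the index year.
    """
    if claims.empty:
        return pd.DataFrame(columns=["person_id", "index_date", "arm",
                                     "matched_set_id", "sex", "birth_year",
                                     "age_at_index"])
    candidates = claims[
        (claims["setting"] == "inpatient")
        & _is_fracture(claims["primary_dx"], fracture_prefixes)
    ]
    first_primary = candidates.groupby("person_id")["service_date"].min()
    evidence = _fracture_evidence_dates(claims, fracture_prefixes)
    prior = evidence.reindex(first_primary.index) < first_primary
    n_prior = int(prior.sum())
    incident = first_primary[~prior].rename("index_date").reset_index()

    start, end = enrolment_window
    in_window = (incident["index_date"] >= start) & (incident["index_date"] <= end)
    n_window = int((~in_window).sum())
    incident = incident[in_window]

    cases = incident.merge(
        persons[["person_id", "sex", "birth_year"]], on="person_id", how="inner"
    )
    cases["age_at_index"] = cases["index_date"].map(lambda d: d.year) - cases["birth_year"]
    n_young = int((cases["age_at_index"] < min_age).sum())
    cases = cases[cases["age_at_index"] >= min_age].reset_index(drop=True)
    cases["arm"] = "case"
    cases["matched_set_id"] = cases["person_id"]
    logger.info(
        "incident fracture ascertainment: %d cases; excluded %d prior-fracture, "
        "%d outside enrolment window, %d below age %d",
        len(cases), n_prior, n_window, n_young, min_age,
    )
    return cases[["person_id", "index_date", "arm", "matched_set_id", "sex",
                  "birth_year", "age_at_index"]]


def match_references(
    cases: pd.DataFrame,
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    ratio: int = 4,
    seed: int = 0,
    fracture_prefixes=FRACTURE_PREFIXES,
) -> pd.DataFrame:
    """Sample sex- and birth-year-matched references for each case.

    Without-replacement sampling across the whole study: once chosen, a
    person is never reused for another matched set.  Eligibility is
    evaluated at each case's index date (alive, within coverage, no
    fracture claim on or before the index date).  Short sets (< ratio
    eligible) keep whatever is available and are logged.

    Returns the full cohort table: the case rows plus reference rows
    that inherit their case's index date and matched-set id.
    """
    rng = np.random.default_rng(seed)
    evidence = _fracture_evidence_dates(claims, fracture_prefixes) if len(claims) \
        else pd.Series(dtype=object)

    pool = persons.set_index("person_id")
    frac_date = evidence.reindex(pool.index)
    out_rows = []
    shortfall = 0
    for (sex, birth_year), stratum_cases in cases.groupby(["sex", "birth_year"]):
        stratum = pool[(pool["sex"] == sex) & (pool["birth_year"] == birth_year)]
        ids = stratum.index.to_numpy()
        death = np.array([d if d is not None else date.max
                          for d in stratum["death_date"]])
        cov_start = stratum["coverage_start"].to_numpy()
        cov_end = stratum["coverage_end"].to_numpy()
        frac = np.array([d if isinstance(d, date) else date.max
                         for d in frac_date.reindex(ids)])
        used = np.zeros(len(ids), dtype=bool)
        # cases are processed in chronological index order (ties broken
        # randomly, never by identifier): prior consumption of the pool
        # then depends only on survival to dates every current candidate
        # has already reached, so selection is independent of survival
        # after the index date.  Random processing order would let
        # early-index cases scoop up short-lived candidates that
        # later-index cases cannot use, biasing reference mortality up.
        tiebreak = rng.random(len(stratum_cases))
        chrono = np.lexsort((tiebreak, stratum_cases["index_date"].to_numpy()))
        stratum_cases = stratum_cases.iloc[chrono]
        for case in stratum_cases.itertuples(index=False):
            idx = case.index_date
            eligible = (
                ~used
                & (ids != case.person_id)
                & (death > idx)
                & (cov_start <= idx)
                & (cov_end >= idx)
                & (frac > idx)
            )
            avail = np.nonzero(eligible)[0]
            chosen = rng.choice(avail, size=min(ratio, len(avail)), replace=False)
            used[chosen] = True
            if len(chosen) < ratio:
                shortfall += ratio - len(chosen)
                level = logging.ERROR if len(chosen) == 0 else logging.WARNING
                logger.log(level, "short matched set for case %s (%s %d): "
                           "%d of %d references", case.person_id, sex,
                           birth_year, len(chosen), ratio)
            for pid in ids[chosen]:
                out_rows.append((pid, idx, "reference", case.matched_set_id,
                                 sex, birth_year, case.age_at_index))
    references = pd.DataFrame(out_rows, columns=["person_id", "index_date",
                                                 "arm", "matched_set_id", "sex",
                                                 "birth_year", "age_at_index"])
    logger.info("matched %d references to %d cases (total shortfall %d)",
                len(references), len(cases), shortfall)
    cohort = pd.concat([cases, references], ignore_index=True)
    return cohort.sort_values(["matched_set_id", "arm", "person_id"],
                              kind="stable").reset_index(drop=True)


def build_follow_up(
    index_events: pd.DataFrame,
    persons: pd.DataFrame,
    closure_date: date = DEFAULT_CLOSURE,
) -> pd.DataFrame:
    """Attach end date, event flag, and duration in months to each subject.

    Follow-up ends at death or study closure, whichever is earlier.
    Subjects dying on the index date are credited half a day at risk so
    that they contribute positive person-time to the first interval.
    """
    merged = index_events.merge(
        persons[["person_id", "death_date"]], on="person_id", how="left"
    )
    rows = []
    for s in merged.itertuples(index=False):
        death = s.death_date if isinstance(s.death_date, date) else None
        if death is not None and death < s.index_date:
            raise ValueError(
                f"person {s.person_id}: death_date {death} precedes "
                f"index_date {s.index_date}"
            )
        if death is not None and death <= closure_date:
            end, event = death, "death"
        else:
            end, event = closure_date, "censored"
        duration_days = (end - s.index_date).days
        if event == "death" and duration_days == 0:
            duration_days = MIN_DURATION_DAYS
        rows.append((end, event, duration_days / MONTH_DAYS))
    out = index_events.copy()
    out[["end_date", "event", "duration_months"]] = pd.DataFrame(
        rows, index=out.index
    )
    return out


def build_cohort(
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    ratio: int = 4,
    min_age: int = DEFAULT_MIN_AGE,
    enrolment_window: tuple[date, date] = DEFAULT_ENROLMENT,
    closure_date: date = DEFAULT_CLOSURE,
    seed: int = 0,
    charlson_weights: dict | None = None,
) -> pd.DataFrame:
    """Full cohort assembly: cases, references, CCI scores, follow-up."""
    from .comorbidity import comorbidity_profiles

    cases = find_incident_fractures(claims, persons, enrolment_window, min_age)
    cohort = match_references(cases, persons, claims, ratio=ratio, seed=seed)
    profiles = comorbidity_profiles(claims, cohort, weights=charlson_weights)
    cohort = cohort.assign(cci_score=profiles["cci_score"].to_numpy())
    return build_follow_up(cohort, persons, closure_date)


def expected_reference_total(n_cases: int, ratio: int = 4, shortfall: int = 0) -> int:
    """Reference-arm size implied by the matching design."""
    return n_cases * ratio - shortfall
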