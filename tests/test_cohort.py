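"""Case ascertainment, matching and follow-up bookkeeping."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from fracture_excess.cohort import (
    MONTH_DAYS,
    build_follow_up,
    expected_reference_total,
    find_incident_fractures,
    match_references,
)

from conftest import claim_row, claims_frame, person_row, persons_frame

WINDOW = (date(2005, 1, 1), date(2013, 12, 31))


def frac_claim(pid, d, code="S72.1", setting="inpatient", secondary=None):
    return claim_row(pid, d, setting, code, secondary)


class TestIncidentAscertainment:
    def test_inpatient_primary_s72_becomes_case(self):
        persons = persons_frame([person_row("a", sex="male", birth_year=1937)])
        claims = claims_frame([frac_claim("a", date(2007, 3, 10))])
        cases = find_incident_fractures(claims, persons, WINDOW)
        assert len(cases) == 1
        row = cases.iloc[0]
        assert row["index_date"] == date(2007, 3, 10)
        assert row["age_at_index"] == 70
        assert row["arm"] == "case"

    def test_secondary_diagnosis_is_not_a_case(self):
        persons = persons_frame([person_row("a")])
        claims = claims_frame([
            claim_row("a", date(2007, 3, 10), "inpatient", "I21.9", ["S72.0"]),
        ])
        assert len(find_incident_fractures(claims, persons, WINDOW)) == 0

    def test_outpatient_primary_is_not_a_case(self):
        persons = persons_frame([person_row("a")])
        claims = claims_frame([
            frac_claim("a", date(2007, 3, 10), setting="outpatient"),
        ])
        assert len(find_incident_fractures(claims, persons, WINDOW)) == 0

    def test_prior_fracture_claim_excludes_as_non_incident(self):
        persons = persons_frame([person_row("a")])
        claims = claims_frame([
            frac_claim("a", date(2004, 5, 1), code="S72.0", setting="outpatient"),
            frac_claim("a", date(2010, 3, 10), code="S72.2"),
        ])
        assert len(find_incident_fractures(claims, persons, WINDOW)) == 0

    def test_below_minimum_age_excluded(self):
        persons = persons_frame([person_row("a", birth_year=1960)])
        claims = claims_frame([frac_claim("a", date(2007, 3, 10))])  # age 47
        assert len(find_incident_fractures(claims, persons, WINDOW)) == 0

    def test_fracture_outside_enrolment_window_excluded(self):
        persons = persons_frame([person_row("a")])
        claims = claims_frame([frac_claim("a", date(2014, 3, 10))])
        assert len(find_incident_fractures(claims, persons, WINDOW)) == 0


def _matching_setup(n_candidates, case_death=None, claims_extra=()):
    persons = [person_row("case0", sex="female", birth_year=1930,
                          death_date=case_death)]
    persons += [person_row(f"cand{i}", sex="female", birth_year=1930)
                for i in range(n_candidates)]
    cases = pd.DataFrame([dict(
        person_id="case0", index_date=date(2008, 7, 1), arm="case",
        matched_set_id="case0", sex="female", birth_year=1930, age_at_index=78,
    )])
    claims = claims_frame([frac_claim("case0", date(2008, 7, 1), "S72.0")]
                          + list(claims_extra))
    return cases, persons_frame(persons), claims


class TestMatching:
    def test_full_set_sampled_and_reproducible(self):
        cases, persons, claims = _matching_setup(10)
        out1 = match_references(cases, persons, claims, ratio=4, seed=11)
        out2 = match_references(cases, persons, claims, ratio=4, seed=11)
        refs = out1[out1["arm"] == "reference"]
        assert len(refs) == 4
        pd.testing.assert_frame_equal(out1, out2)
        out3 = match_references(cases, persons, claims, ratio=4, seed=12)
        assert not out3.equals(out1)  # seed drives the draw

    def test_short_stratum_takes_all_available(self):
        cases, persons, claims = _matching_setup(3)
        out = match_references(cases, persons, claims, ratio=4, seed=0)
        assert (out["arm"] == "reference").sum() == 3

    def test_candidate_with_prior_fracture_claim_never_selected(self):
        extra = [frac_claim("cand0", date(2006, 1, 1), "S72.2",
                            setting="outpatient")]
        cases, persons, claims = _matching_setup(5, claims_extra=extra)
        for seed in range(10):
            out = match_references(cases, persons, claims, ratio=4, seed=seed)
            assert "cand0" not in set(out.loc[out["arm"] == "reference",
                                              "person_id"])

    def test_dead_or_uncovered_candidates_never_selected(self):
        persons = [person_row("case0", sex="male", birth_year=1940)]
        persons.append(person_row("dead", sex="male", birth_year=1940,
                                  death_date=date(2008, 1, 1)))
        persons.append(person_row("late", sex="male", birth_year=1940,
                                  coverage_start=date(2010, 1, 1)))
        persons.append(person_row("ok", sex="male", birth_year=1940))
        cases = pd.DataFrame([dict(
            person_id="case0", index_date=date(2008, 7, 1), arm="case",
            matched_set_id="case0", sex="male", birth_year=1940,
            age_at_index=68,
        )])
        claims = claims_frame([frac_claim("case0", date(2008, 7, 1))])
        out = match_references(cases, persons_frame(persons), claims,
                               ratio=4, seed=3)
        refs = set(out.loc[out["arm"] == "reference", "person_id"])
        assert refs == {"ok"}

    def test_matched_sets_share_sex_and_birth_year_and_no_reuse(self):
        rng = np.random.default_rng(0)
        persons, cases, claims_rows = [], [], []
        for i in range(12):
            by = 1925 + int(rng.integers(0, 3))
            persons.append(person_row(f"case{i}", sex="female", birth_year=by))
            d = date(2006 + int(rng.integers(0, 6)), 3, 1)
            cases.append(dict(person_id=f"case{i}", index_date=d, arm="case",
                              matched_set_id=f"case{i}", sex="female",
                              birth_year=by, age_at_index=d.year - by))
            claims_rows.append(frac_claim(f"case{i}", d))
        for i in range(120):
            persons.append(person_row(f"cand{i}", sex="female",
                                      birth_year=1925 + i % 3))
        out = match_references(pd.DataFrame(cases), persons_frame(persons),
                               claims_frame(claims_rows), ratio=4, seed=5)
        refs = out[out["arm"] == "reference"]
        assert refs["person_id"].is_unique  # global without-replacement
        merged = refs.merge(out[out["arm"] == "case"], on="matched_set_id",
                            suffixes=("_ref", "_case"))
        assert (merged["sex_ref"] == merged["sex_case"]).all()
        assert (merged["birth_year_ref"] == merged["birth_year_case"]).all()
        n_cases = (out["arm"] == "case").sum()
        shortfall = 4 * n_cases - len(refs)
        assert len(refs) == expected_reference_total(n_cases, 4, shortfall)


class TestFollowUp:
    def test_death_ninety_days_in(self, simple_cohort):
        cohort, persons = simple_cohort
        fu = build_follow_up(cohort, persons, closure_date=date(2016, 5, 4))
        c1 = fu[fu["person_id"] == "c1"].iloc[0]
        assert c1["event"] == "death"
        assert c1["duration_months"] == pytest.approx(92 / MONTH_DAYS)

    def test_survivor_censored_at_closure(self, simple_cohort):
        cohort, persons = simple_cohort
        fu = build_follow_up(cohort, persons, closure_date=date(2016, 5, 4))
        r1 = fu[fu["person_id"] == "r1"].iloc[0]
        assert r1["event"] == "censored"
        assert r1["end_date"] == date(2016, 5, 4)

    def test_death_on_index_date_gets_half_day(self):
        cohort = pd.DataFrame([dict(person_id="x", index_date=date(2008, 1, 1),
                                    arm="case", matched_set_id="x",
                                    sex="male", birth_year=1930,
                                    age_at_index=78, cci_score=0)])
        persons = persons_frame([person_row("x", death_date=date(2008, 1, 1))])
        fu = build_follow_up(cohort, persons, closure_date=date(2016, 5, 4))
        assert fu.iloc[0]["event"] == "death"
        assert fu.iloc[0]["duration_months"] == pytest.approx(0.5 / MONTH_DAYS)

    def test_death_before_index_is_an_error(self):
        cohort = pd.DataFrame([dict(person_id="x", index_date=date(2008, 1, 1),
                                    arm="case", matched_set_id="x",
                                    sex="male", birth_year=1930,
                                    age_at_index=78, cci_score=0)])
        persons = persons_frame([person_row("x", death_date=date(2007, 1, 1))])
        with pytest.raises(ValueError, match="x"):
            build_follow_up(cohort, persons, closure_date=date(2016, 5, 4))


def test_reference_total_bookkeeping():
    assert expected_reference_total(8298, 4, 1) == 33191
    assert expected_reference_total(10, 4, 0) == 40
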