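"""Charlson comorbidity index from ICD-10 claims.

Implements the ICD-10 coding algorithm of Quan and colleagues for the 17
Charlson condition categories, with a choice of the re-estimated
("updated", default) or original disease weights.  Evidence rules follow
the administrative-claims convention used for pre-fracture comorbidity
ascertainment:

* secondary/other diagnoses on the index-date inpatient claim count;
* any diagnosis on an inpatient claim in the 365 days before the index
  date counts;
* outpatient diagnoses in that window count only when the category
  appears on two or more claims whose service dates are at least 7 days
  apart (a guard against rule-out and duplicate coding).

Hierarchy pairs (mild vs moderate/severe liver disease, any malignancy
vs metastatic solid tumour, diabetes without vs with complications) are
resolved so that only the severer member of a co-occurring pair scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources

import pandas as pd

from .data_model import normalize_icd10

__all__ = [
    "CATEGORIES",
    "HIERARCHY",
    "load_charlson_map",
    "load_charlson_weights",
    "map_code_to_categories",
    "eligible_category_evidence",
    "charlson_score",
    "ComorbidityProfile",
    "comorbidity_profiles",
]

#: milder member -> severer member; only the severer scores when both present
HIERARCHY = {
    "mild_liver_disease": "moderate_severe_liver_disease",
    "diabetes_without_complications": "diabetes_with_complications",
    "malignancy": "metastatic_solid_tumour",
}

LOOKBACK_DAYS = 365
MIN_OUTPATIENT_GAP_DAYS = 7


class CharlsonConfigError(ValueError):
    """Unknown category name or malformed mapping/weight table."""


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("fracture_excess.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_charlson_map(path=None) -> pd.DataFrame:
    """ICD-10 prefix table: columns ``category``, ``icd10_prefix``."""
    df = pd.read_csv(path) if path is not None else _read_packaged("charlson_map.csv")
    if set(df.columns) != {"category", "icd10_prefix"}:
        raise CharlsonConfigError("map table must have columns category,icd10_prefix")
    return df


def load_charlson_weights(variant: str = "updated", path=None) -> dict[str, int]:
    """Category weights; ``variant`` is ``updated`` (default) or ``original``."""
    if path is not None:
        df = pd.read_csv(path)
    else:
        if variant not in ("updated", "original"):
            raise CharlsonConfigError(f"unknown weight variant {variant!r}")
        df = _read_packaged(f"charlson_weights_{variant}.csv")
    return dict(zip(df["category"], df["weight"].astype(int)))


CATEGORIES = tuple(load_charlson_map()["category"].unique())

# prefix lookup grouped by prefix length, so a code is matched by O(1)
# dictionary probes on its truncations rather than a scan of all prefixes
def _prefix_index(mapping: pd.DataFrame) -> dict[int, dict[str, str]]:
    index: dict[int, dict[str, str]] = {}
    for cat, prefix in mapping.itertuples(index=False):
        index.setdefault(len(prefix), {})[prefix] = cat
    return index


_DEFAULT_INDEX = _prefix_index(load_charlson_map())


def map_code_to_categories(code: str, mapping: pd.DataFrame | None = None) -> set[str]:
    """Map one ICD-10 code to the Charlson categories it evidences.

    Matching is prefix-based on the dotted upper-case form; codes
    matching no prefix return the empty set.
    """
    index = _DEFAULT_INDEX if mapping is None else _prefix_index(mapping)
    code = normalize_icd10(code)
    hits = set()
    for length, table in index.items():
        cat = table.get(code[:length])
        if cat is not None and len(code) >= length:
            hits.add(cat)
    return hits


def _claim_categories(claim, include_primary: bool) -> set[str]:
    codes = list(claim.secondary_dx)
    if include_primary:
        codes.append(claim.primary_dx)
    cats: set[str] = set()
    for c in codes:
        cats |= map_code_to_categories(c)
    return cats


def eligible_category_evidence(
    claims_for_person: pd.DataFrame,
    index_date: date,
    lookback_days: int = LOOKBACK_DAYS,
    min_gap_days: int = MIN_OUTPATIENT_GAP_DAYS,
) -> set[str]:
    """Charlson categories with qualifying evidence at ``index_date``.

    The lookback window is the half-open interval
    ``[index_date - lookback_days, index_date)``; the index-date
    inpatient claim contributes only its secondary/other diagnoses.
    """
    window_start = index_date - timedelta(days=lookback_days)
    present: set[str] = set()
    outpatient_dates: dict[str, list[date]] = {}
    for claim in claims_for_person.itertuples(index=False):
        d = claim.service_date
        if d == index_date and claim.setting == "inpatient":
            present |= _claim_categories(claim, include_primary=False)
        if not (window_start <= d < index_date):
            continue
        cats = _claim_categories(claim, include_primary=True)
        if claim.setting == "inpatient":
            present |= cats
        else:
            for cat in cats:
                outpatient_dates.setdefault(cat, []).append(d)
    for cat, dates in outpatient_dates.items():
        if (max(dates) - min(dates)).days >= min_gap_days:
            present.add(cat)
    return present


def charlson_score(
    categories_present: set[str],
    weights: dict[str, int] | None = None,
) -> int:
    """Hierarchy-resolved weighted sum over present categories."""
    if weights is None:
        weights = load_charlson_weights("updated")
    unknown = set(categories_present) - set(CATEGORIES)
    if unknown:
        raise CharlsonConfigError(f"unknown Charlson category: {sorted(unknown)}")
    effective = resolve_hierarchy(categories_present)
    return sum(weights[c] for c in effective)


def resolve_hierarchy(categories_present: set[str]) -> set[str]:
    """Drop the milder member of each co-occurring hierarchy pair."""
    effective = set(categories_present)
    for mild, severe in HIERARCHY.items():
        if mild in effective and severe in effective:
            effective.discard(mild)
    return effective


@dataclass
class ComorbidityProfile:
    person_id: str
    index_date: date
    categories_present: set[str]
    cci_score: int


def _explode_claim_categories(claims: pd.DataFrame) -> pd.DataFrame:
    """One row per (claim, matched Charlson category).

    Columns: person_id, service_date (datetime64), setting, is_primary,
    category.  Codes matching no prefix are dropped.
    """
    pieces = []
    for is_primary, codes in (
        (True, claims["primary_dx"]),
        (False, claims["secondary_dx"]),
    ):
        frame = claims[["person_id", "service_date", "setting"]].copy()
        frame["is_primary"] = is_primary
        frame["code"] = codes
        if not is_primary:
            frame = frame.explode("code").dropna(subset=["code"])
        pieces.append(frame)
    flat = pd.concat(pieces, ignore_index=True)
    flat["service_date"] = pd.to_datetime(flat["service_date"])
    matched = []
    for length, table in _DEFAULT_INDEX.items():
        cat = flat["code"].str.slice(0, length).map(table)
        hit = flat[cat.notna()].copy()
        hit["category"] = cat[cat.notna()]
        matched.append(hit.drop(columns="code"))
    return pd.concat(matched, ignore_index=True)


def comorbidity_profiles(
    claims: pd.DataFrame,
    index_events: pd.DataFrame,
    weights: dict[str, int] | None = None,
    lookback_days: int = LOOKBACK_DAYS,
    min_gap_days: int = MIN_OUTPATIENT_GAP_DAYS,
) -> pd.DataFrame:
    """Score every subject in ``index_events`` (person_id, index_date).

    Vectorised equivalent of calling :func:`eligible_category_evidence`
    and :func:`charlson_score` per subject (that equivalence is tested).
    Returns a frame with columns person_id, index_date, categories and
    cci_score — one row per index event, in input order, zero score for
    subjects with no qualifying claims.
    """
    if weights is None:
        weights = load_charlson_weights("updated")
    events = index_events[["person_id", "index_date"]].copy()
    events["event_id"] = range(len(events))
    out = events.copy()
    out["categories"] = [frozenset()] * len(out)
    out["cci_score"] = 0
    if len(claims) == 0 or len(events) == 0:
        return out[["person_id", "index_date", "categories", "cci_score"]]

    cat_rows = _explode_claim_categories(claims)
    ev = events.copy()
    ev["index_date"] = pd.to_datetime(ev["index_date"])
    merged = cat_rows.merge(ev, on="person_id", how="inner")
    if merged.empty:
        return out[["person_id", "index_date", "categories", "cci_score"]]
    window_start = merged["index_date"] - pd.Timedelta(days=lookback_days)
    in_window = (merged["service_date"] >= window_start) & (
        merged["service_date"] < merged["index_date"]
    )
    inpatient = merged["setting"] == "inpatient"
    index_secondary = (
        inpatient & (merged["service_date"] == merged["index_date"])
        & ~merged["is_primary"]
    )
    direct = merged[(inpatient & in_window) | index_secondary]
    present = direct.groupby(["event_id", "category"]).size().reset_index()[
        ["event_id", "category"]
    ]
    outp = merged[~inpatient & in_window]
    if len(outp):
        span = outp.groupby(["event_id", "category"])["service_date"].agg(
            ["min", "max"]
        )
        qualified = span[
            (span["max"] - span["min"]) >= pd.Timedelta(days=min_gap_days)
        ].reset_index()[["event_id", "category"]]
        present = pd.concat([present, qualified], ignore_index=True).drop_duplicates()

    indicator = (
        present.assign(flag=True)
        .pivot_table(index="event_id", columns="category", values="flag",
                     aggfunc="any", fill_value=False)
        .reindex(columns=list(CATEGORIES), fill_value=False)
        .reindex(index=events["event_id"], fill_value=False)
    )
    for mild, severe in HIERARCHY.items():
        indicator[mild] &= ~indicator[severe]
    weight_vec = pd.Series(weights).reindex(indicator.columns)
    scores = indicator.to_numpy() @ weight_vec.to_numpy()
    cats_by_event = present.groupby("event_id")["category"].agg(frozenset)
    reindexed = cats_by_event.reindex(events["event_id"])
    out["categories"] = [c if isinstance(c, frozenset) else frozenset()
                         for c in reindexed]
    out["cci_score"] = scores.astype(int)
    return out[["person_id", "index_date", "categories", "cci_score"]]
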