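"""Synthetic claims-shaped populations with known mortality hazards.

The generator emulates the raw material of a national-claims mortality
study of people aged 50+: a person registry, ICD-10-coded comorbidity
claims with in/outpatient repeat patterns, incident hip-fracture
hospitalisations, and death times driven by planted hazards.  Every
planted quantity has a closed-form truth function, so the full analysis
pipeline can be checked for parameter recovery without external data.

Planted structure (all times in months from ``data_start``):

* baseline death hazard, Gompertz in attained age per sex:
  ``lambda0(age) = b * exp(theta * age)`` per person-year, multiplied by
  ``cci_hr_per_point ** CCI``;
* fracture incidence, piecewise constant over 10-year age bands per
  sex, multiplied by ``fracture_cci_hr_per_point ** CCI`` (planted
  confounding between comorbidity and fracture);
* post-fracture hazard ratio ``h(u) = 1 + A * exp(-u / tau) + B`` at
  ``u`` months after fracture — a large early excess decaying with time
  constant ``tau`` onto a persistent plateau ``1 + B``.

Death times are drawn by exact inversion of the closed-form cumulative
hazard (bisection for the post-fracture branch), so sampled data and
truth functions describe exactly the same process.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import MONTH_DAYS

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "estonia_like",
    "constant_effect_params",
    "null_effect_params",
    "simulate",
    "write_simulation",
    "true_cumulative_risk",
    "subject_true_risk",
    "cohort_truth",
    "recovery_report",
]

AGE_BANDS = (50, 60, 70, 80, 90)

#: representative ICD-10 codes emitted for each Charlson category
REP_CODES = {
    "myocardial_infarction": ["I21.9", "I25.2"],
    "congestive_heart_failure": ["I50.0", "I11.0"],
    "peripheral_vascular_disease": ["I70.2", "I73.9"],
    "cerebrovascular_disease": ["I63.9", "I69.4"],
    "dementia": ["F00.1", "G30.9"],
    "chronic_pulmonary_disease": ["J44.9", "J45.0"],
    "rheumatic_disease": ["M05.9", "M06.9"],
    "peptic_ulcer_disease": ["K25.9", "K27.9"],
    "mild_liver_disease": ["K74.6", "B18.2"],
    "diabetes_without_complications": ["E11.9", "E11.8"],
    "diabetes_with_complications": ["E11.2", "E11.5"],
    "hemiplegia_paraplegia": ["G81.9", "G82.2"],
    "renal_disease": ["N18.3", "N18.5"],
    "malignancy": ["C34.9", "C50.9"],
    "moderate_severe_liver_disease": ["K72.9", "I85.0"],
    "metastatic_solid_tumour": ["C78.0", "C79.5"],
    "aids_hiv": ["B20", "B21"],
}

#: non-Charlson background codes (check-ups, back pain, URTI, hypertension)
NOISE_CODES = ["Z00.0", "M54.5", "J06.9", "I10"]

S72_CODES = ("S72.0", "S72.1", "S72.2")


class SimulationParams(BaseModel):
    """Planted population, hazard and claims-process parameters."""

    n_persons: int = Field(ge=0)
    sex_ratio_male: float = Field(default=0.41, ge=0.0, le=1.0)
    #: 10-year age-band weights at ``data_start`` (band lower bound -> weight)
    age_band_weights: dict[int, float] = {50: 0.36, 60: 0.28, 70: 0.21,
                                          80: 0.11, 90: 0.04}
    #: Gompertz scale b (per person-year at age 0) and shape theta per sex
    gompertz_b: dict[str, float] = {"male": 3.2e-5, "female": 1.75e-5}
    gompertz_theta: dict[str, float] = {"male": 0.095, "female": 0.095}
    #: Charlson category prevalences at baseline
    comorbidity_prevalence: dict[str, float] = {}
    cci_hr_per_point: float = Field(default=1.4, ge=0.0)
    #: fracture incidence per person-year by sex and age band
    fracture_incidence: dict[str, dict[int, float]] = {
        "male": {50: 0.001, 60: 0.002, 70: 0.004, 80: 0.009, 90: 0.018},
        "female": {50: 0.0008, 60: 0.002, 70: 0.006, 80: 0.014, 90: 0.025},
    }
    fracture_cci_hr_per_point: float = Field(default=1.0, ge=0.0)
    #: post-fracture hazard ratio h(u) = 1 + A exp(-u/tau) + B
    fracture_hr_a: float = Field(default=0.0, ge=0.0)
    fracture_hr_b: float = Field(default=0.0, ge=0.0)
    fracture_hr_tau: float = Field(default=2.0, gt=0.0)
    s72_mix: tuple[float, float, float] = (0.55, 0.35, 0.10)
    #: claims-process intensities (per person-year, while alive)
    outpatient_rate_py: float = Field(default=3.0, ge=0.0)
    inpatient_rate_py: float = Field(default=0.15, ge=0.0)
    noise_claim_rate_py: float = Field(default=0.5, ge=0.0)
    #: fraction of persons given a decoy category whose claims must NOT
    #: satisfy the outpatient repeat rule (single claim, or a pair < 7
    #: days apart)
    decoy_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    data_start: date = date(2004, 1, 1)
    enrol_start: date = date(2005, 1, 1)
    enrol_end: date = date(2013, 12, 31)
    closure: date = date(2016, 5, 4)

    @model_validator(mode="after")
    def _check(self):
        for cat, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {cat} outside [0, 1]")
        for sex_rates in self.fracture_incidence.values():
            if any(r < 0 for r in sex_rates.values()):
                raise ValueError("fracture incidence rates must be >= 0")
        if abs(sum(self.s72_mix) - 1.0) > 1e-9:
            raise ValueError("s72_mix must sum to 1")
        return self

    @property
    def horizon_months(self) -> float:
        return (self.closure - self.data_start).days / MONTH_DAYS


def estonia_like(n_persons: int = 50_000, **overrides) -> SimulationParams:
    """Preset emulating the order of magnitude of a Baltic 50+ claims
    population: Gompertz background mortality, comorbidity that raises
    both fracture incidence and death rates, and a post-fracture hazard
    with a large early excess (h(0) about 20) decaying over a couple of
    months onto a persistent 1.5-fold plateau.  Tuned only so that crude
    one-year case mortality lands in the 20-35% range; it is a
    convenience preset, not a calibration claim.
    """
    base = dict(
        n_persons=n_persons,
        comorbidity_prevalence={
            "myocardial_infarction": 0.06,
            "congestive_heart_failure": 0.10,
            "peripheral_vascular_disease": 0.05,
            "cerebrovascular_disease": 0.10,
            "dementia": 0.05,
            "chronic_pulmonary_disease": 0.08,
            "rheumatic_disease": 0.02,
            "peptic_ulcer_disease": 0.03,
            "mild_liver_disease": 0.02,
            "diabetes_without_complications": 0.10,
            "diabetes_with_complications": 0.03,
            "hemiplegia_paraplegia": 0.01,
            "renal_disease": 0.04,
            "malignancy": 0.06,
            "moderate_severe_liver_disease": 0.005,
            "metastatic_solid_tumour": 0.01,
            "aids_hiv": 0.001,
        },
        cci_hr_per_point=1.4,
        fracture_cci_hr_per_point=1.3,
        fracture_hr_a=18.0,
        fracture_hr_b=0.5,
        fracture_hr_tau=2.0,
    )
    base.update(overrides)
    return SimulationParams(**base)


def constant_effect_params(
    n_persons: int = 50_000, rate_ratio: float = 2.0, **overrides
) -> SimulationParams:
    """Flat-hazard scenario with a constant post-fracture rate ratio.

    No age trend (theta = 0), no comorbidity effect on death or
    fracture, and h(u) = rate_ratio at all u — the regime in which the
    adjusted model's fracture main effect estimates log(rate_ratio) and
    every interaction is null.  Fracture incidence is raised well above
    the realistic presets so that a cohort of a given size yields enough
    cases for coefficient recovery.
    """
    base = dict(
        n_persons=n_persons,
        gompertz_b={"male": 0.055, "female": 0.045},
        gompertz_theta={"male": 0.0, "female": 0.0},
        comorbidity_prevalence={
            "congestive_heart_failure": 0.10,
            "diabetes_without_complications": 0.10,
            "chronic_pulmonary_disease": 0.08,
        },
        cci_hr_per_point=1.0,
        fracture_incidence={
            sex: {band: 0.012 for band in AGE_BANDS} for sex in ("male", "female")
        },
        fracture_cci_hr_per_point=1.0,
        fracture_hr_a=0.0,
        fracture_hr_b=rate_ratio - 1.0,
        fracture_hr_tau=2.0,
    )
    base.update(overrides)
    return SimulationParams(**base)


def null_effect_params(n_persons: int = 50_000, **overrides) -> SimulationParams:
    """Flat-hazard scenario in which fracture has no effect on death."""
    return constant_effect_params(n_persons, rate_ratio=1.0, **overrides)


# ---------------------------------------------------------------------------
# closed-form hazard machinery


def _cumhaz_unexposed(params, sex, age, cci, t):
    """Cumulative baseline hazard over ``t`` months from attained ``age``."""
    t = np.asarray(t, dtype=float)
    b = params.gompertz_b[sex] / 12.0
    theta = params.gompertz_theta[sex]
    k = theta / 12.0
    scale = b * np.exp(theta * np.asarray(age, dtype=float)) * (
        params.cci_hr_per_point ** np.asarray(cci, dtype=float)
    )
    if abs(k) < 1e-12:
        return scale * t
    return scale * (np.exp(k * t) - 1.0) / k


def _cumhaz_post(params, sex, age_at_fracture, cci, u):
    """Cumulative hazard over ``u`` months after fracture at that age."""
    u = np.asarray(u, dtype=float)
    b = params.gompertz_b[sex] / 12.0
    theta = params.gompertz_theta[sex]
    k = theta / 12.0
    a, bp, tau = params.fracture_hr_a, params.fracture_hr_b, params.fracture_hr_tau
    scale = b * np.exp(theta * np.asarray(age_at_fracture, dtype=float)) * (
        params.cci_hr_per_point ** np.asarray(cci, dtype=float)
    )
    if abs(k) < 1e-12:
        plateau = (1.0 + bp) * u
        decay = a * tau * (1.0 - np.exp(-u / tau))
    else:
        plateau = (1.0 + bp) * (np.exp(k * u) - 1.0) / k
        km = k - 1.0 / tau
        if abs(km) < 1e-12:
            decay = a * u
        else:
            decay = a * (np.exp(km * u) - 1.0) / km
    return scale * (plateau + decay)


def _invert_cumhaz(fn, targets, hi=4000.0, iters=80):
    """Vectorised bisection: smallest u with fn(u) >= target."""
    targets = np.asarray(targets, dtype=float)
    lo = np.zeros_like(targets)
    hi = np.full_like(targets, hi)
    beyond = fn(hi) < targets  # never reached within the bracket
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = fn(mid) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(beyond, np.inf, out)


def true_cumulative_risk(
    params: SimulationParams,
    exposed: bool,
    sex: str,
    age: float,
    t_months,
    cci: float = 0.0,
) -> np.ndarray | float:
    """Planted probability of death within ``t_months`` of the index.

    ``age`` is the attained age (years) at the index date; for the
    exposed curve the post-fracture hazard multiplier applies from the
    index onward.  Evaluated in closed form.
    """
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    if exposed:
        lam = _cumhaz_post(params, sex, age, cci, t)
    else:
        lam = _cumhaz_unexposed(params, sex, age, cci, t)
    out = 1.0 - np.exp(-lam)
    return float(out) if np.isscalar(t_months) else out


def subject_true_risk(
    params: SimulationParams,
    sex: np.ndarray,
    age_at_index: np.ndarray,
    cci: np.ndarray,
    t_months: float,
    mode: str = "unexposed",
    n_quad: int = 240,
) -> np.ndarray:
    """Per-subject planted risk of death within ``t_months`` of index.

    ``mode``:

    * ``"exposed"`` — the post-fracture hazard multiplier applies from
      the index date (a case);
    * ``"unexposed"`` — the counterfactual never-fracture risk;
    * ``"marginal"`` — an unexposed-at-index subject who may still
      fracture during follow-up, with the fracture time integrated out
      over the planted incidence (the estimand of the crude
      reference-arm contrast, since references are only required to be
      fracture-free up to the index date).

    The marginal branch evaluates S(t) = S_frac-free(t) · S0(t) +
    ∫ f(v) S0(v) S_post(v, t − v) dv by composite Simpson quadrature on
    ``n_quad`` panels; the other branches are closed-form.
    """
    sex = np.asarray(sex)
    age = np.asarray(age_at_index, dtype=float)
    cci = np.asarray(cci, dtype=float)
    out = np.zeros(len(age))
    for s in ("male", "female"):
        m = sex == s
        if not m.any():
            continue
        if mode == "exposed":
            lam = _cumhaz_post(params, s, age[m], cci[m], t_months)
            out[m] = 1.0 - np.exp(-lam)
        elif mode == "unexposed":
            lam = _cumhaz_unexposed(params, s, age[m], cci[m], t_months)
            out[m] = 1.0 - np.exp(-lam)
        elif mode == "marginal":
            out[m] = _marginal_risk(params, s, age[m], cci[m], t_months, n_quad)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def _fracture_rate_at(params, sex: str, age, cci):
    """Instantaneous fracture hazard (per month) at attained ``age``."""
    rates_by_band = params.fracture_incidence[sex]
    bands = np.array(AGE_BANDS, dtype=float)
    idx = np.clip(np.searchsorted(bands, np.asarray(age, dtype=float),
                                  side="right") - 1, 0, len(bands) - 1)
    seg = np.array([rates_by_band[b] for b in AGE_BANDS]) / 12.0
    return seg[idx] * params.fracture_cci_hr_per_point ** np.asarray(cci,
                                                                     dtype=float)


def _marginal_risk(params, sex: str, age, cci, t_months: float, n_quad: int):
    """Death risk by ``t_months`` integrating out a possible future fracture."""
    age = np.asarray(age, dtype=float)
    cci = np.asarray(cci, dtype=float)
    if t_months == 0:
        return np.zeros(len(age))
    v = np.linspace(0.0, t_months, n_quad + 1)  # quadrature nodes (fracture time)
    # per-node quantities, shape (n_subjects, n_nodes)
    lam0_v = np.stack([_cumhaz_unexposed(params, sex, age, cci, vi) for vi in v],
                      axis=1)
    phi_v = np.stack([_fracture_rate_at(params, sex, age + vi / 12.0, cci)
                      for vi in v], axis=1)
    big_phi_v = _fracture_cumhaz_grid(params, sex, age, cci, v)
    lam_post = np.stack([
        _cumhaz_post(params, sex, age + vi / 12.0, cci, t_months - vi)
        for vi in v
    ], axis=1)
    integrand = phi_v * np.exp(-(big_phi_v + lam0_v + lam_post))
    weights = np.full(n_quad + 1, 2.0)
    weights[1:-1:2] = 4.0
    weights[0] = weights[-1] = 1.0
    h = t_months / n_quad
    integral = (integrand @ weights) * h / 3.0  # Simpson (n_quad even)
    s_nofrac = np.exp(-(big_phi_v[:, -1] + lam0_v[:, -1]))
    return 1.0 - (s_nofrac + integral)


def _fracture_cumhaz_grid(params, sex: str, age, cci, v):
    """Cumulative fracture hazard at each node of ``v`` (subjects x nodes)."""
    age = np.asarray(age, dtype=float)
    cci = np.asarray(cci, dtype=float)
    rates_by_band = params.fracture_incidence[sex]
    seg_rates = np.array([rates_by_band[b] for b in AGE_BANDS]) / 12.0
    edges = np.array(AGE_BANDS, dtype=float)
    starts = np.maximum((edges[None, :] - age[:, None]) * 12.0, 0.0)
    ends = np.concatenate([starts[:, 1:], np.full((len(age), 1), np.inf)], axis=1)
    occ = np.clip(v[None, :, None] - starts[:, None, :], 0.0,
                  (ends - starts)[:, None, :])
    mult = params.fracture_cci_hr_per_point ** cci
    return (occ @ seg_rates) * mult[:, None]


# ---------------------------------------------------------------------------
# sampling


def _sample_fracture_times(params, rng, sex, age0, cci):
    """Time (months from data_start) of first fracture, inf if none.

    The fracture hazard is piecewise constant over the 10-year age bands
    the person traverses; exact inversion segment by segment.
    """
    n = len(age0)
    t_frac = np.full(n, np.inf)
    e = rng.exponential(size=n)
    for s in ("male", "female"):
        m = sex == s
        if not m.any():
            continue
        rates_by_band = params.fracture_incidence[s]
        mult = params.fracture_cci_hr_per_point ** cci[m]
        a0 = age0[m]
        edges = np.array(AGE_BANDS, dtype=float)
        # segment j covers ages [edges[j], edges[j+1]) (last open-ended,
        # capped at 200 months x 12 years for the inversion)
        starts = np.maximum((edges[None, :] - a0[:, None]) * 12.0, 0.0)
        ends = np.concatenate([starts[:, 1:], np.full((m.sum(), 1), 2400.0)], axis=1)
        widths = np.maximum(ends - starts, 0.0)
        seg_rates = np.array([rates_by_band[b] for b in AGE_BANDS]) / 12.0
        seg_haz = widths * seg_rates[None, :] * mult[:, None]
        cum = np.cumsum(seg_haz, axis=1)
        cum_before = np.concatenate([np.zeros((m.sum(), 1)), cum[:, :-1]], axis=1)
        em = e[m]
        seg = np.argmax(cum >= em[:, None], axis=1)
        reached = cum[:, -1] >= em
        rows = np.arange(m.sum())
        rate_sel = seg_rates[seg] * mult
        with np.errstate(divide="ignore", invalid="ignore"):
            within = (em - cum_before[rows, seg]) / rate_sel
        t = starts[rows, seg] + within
        t_frac[m] = np.where(reached & np.isfinite(t), t, np.inf)
    return t_frac


def _sample_death_times(params, rng, sex, age0, cci, t_frac):
    """Death time (months from data_start) with the fracture multiplier
    applied from the fracture time onward."""
    n = len(age0)
    t_death = np.full(n, np.inf)
    e = rng.exponential(size=n)
    for s in ("male", "female"):
        m = sex == s
        if not m.any():
            continue
        theta = params.gompertz_theta[s]
        k = theta / 12.0
        # unexposed death time by closed-form inversion
        scale = (params.gompertz_b[s] / 12.0) * np.exp(theta * age0[m]) * (
            params.cci_hr_per_point ** cci[m]
        )
        if abs(k) < 1e-12:
            t0 = e[m] / scale
        else:
            t0 = np.log1p(e[m] * k / scale) / k
        t_death[m] = t0
    # persons fracturing before their unexposed death time restart with
    # the multiplied hazard (valid sequential sampling: the death process
    # is memoryless given survival to the fracture)
    fractured = t_frac < t_death
    if fractured.any():
        e2 = rng.exponential(size=int(fractured.sum()))
        idx = np.nonzero(fractured)[0]
        for s in ("male", "female"):
            m = sex[idx] == s
            if not m.any():
                continue
            sel = idx[m]
            age_f = age0[sel] + t_frac[sel] / 12.0
            u = _invert_cumhaz(
                lambda uu: _cumhaz_post(params, s, age_f, cci[sel], uu),
                e2[m],
            )
            t_death[sel] = t_frac[sel] + u
    return t_death, fractured


@dataclass
class SimulationResult:
    """Simulated tables plus the hidden per-person ground truth."""

    params: SimulationParams
    persons: pd.DataFrame
    claims: pd.DataFrame
    #: person_id, sex, birth_year, age0, true_cci, t_fracture_months,
    #: t_death_months (months from data_start; inf = never observed)
    truth: pd.DataFrame


def _months_to_date(start: date, months: np.ndarray) -> list[date | None]:
    out = []
    for t in months:
        if not np.isfinite(t):
            out.append(None)
        else:
            out.append(start + timedelta(days=int(np.floor(t * MONTH_DAYS))))
    return out


def simulate(params: SimulationParams, seed: int = 0) -> SimulationResult:
    """Draw a full synthetic population; deterministic given ``seed``."""
    from .comorbidity import CATEGORIES, HIERARCHY, load_charlson_weights

    rng = np.random.default_rng(seed)
    n = params.n_persons
    horizon = params.horizon_months
    weights = load_charlson_weights("updated")

    cols_p = ["person_id", "sex", "birth_year", "death_date",
              "coverage_start", "coverage_end"]
    cols_c = ["person_id", "service_date", "setting", "primary_dx",
              "secondary_dx", "specialty"]
    if n == 0:
        empty_truth = pd.DataFrame(columns=["person_id", "sex", "birth_year",
                                            "age0", "true_cci",
                                            "t_fracture_months",
                                            "t_death_months"])
        return SimulationResult(params, pd.DataFrame(columns=cols_p),
                                pd.DataFrame(columns=cols_c), empty_truth)

    person_id = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < params.sex_ratio_male, "male", "female")
    bands = np.array(sorted(params.age_band_weights))
    w = np.array([params.age_band_weights[b] for b in bands], dtype=float)
    band = rng.choice(bands, size=n, p=w / w.sum())
    age0 = band + rng.random(n) * 10.0
    birth_year = params.data_start.year - np.floor(age0).astype(int)

    # planted comorbidity and its hierarchy-resolved score
    cat_list = list(CATEGORIES)
    present = np.zeros((n, len(cat_list)), dtype=bool)
    for j, cat in enumerate(cat_list):
        p = params.comorbidity_prevalence.get(cat, 0.0)
        if p > 0:
            present[:, j] = rng.random(n) < p
    effective = present.copy()
    for mild, severe in HIERARCHY.items():
        i_mild, i_sev = cat_list.index(mild), cat_list.index(severe)
        effective[:, i_mild] &= ~effective[:, i_sev]
    weight_vec = np.array([weights[c] for c in cat_list], dtype=float)
    cci = effective @ weight_vec

    t_frac = _sample_fracture_times(params, rng, sex, age0, cci)
    t_death, _ = _sample_death_times(params, rng, sex, age0, cci, t_frac)
    t_frac = np.where(t_frac < t_death, t_frac, np.inf)  # no fracture after death
    observed_death = t_death <= horizon
    observed_frac = t_frac <= horizon

    death_dates = _months_to_date(params.data_start, np.where(observed_death,
                                                              t_death, np.inf))
    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "birth_year": birth_year,
        "death_date": death_dates,
        "coverage_start": params.data_start,
        "coverage_end": params.closure,
    })

    claims_parts = []

    # fracture hospitalisations
    if observed_frac.any():
        idx = np.nonzero(observed_frac)[0]
        frac_days = np.floor(t_frac[idx] * MONTH_DAYS).astype(int)
        primary = rng.choice(S72_CODES, size=len(idx), p=params.s72_mix)
        secondary = []
        for i in idx:
            cats = [cat_list[j] for j in np.nonzero(present[i])[0]]
            picked = [REP_CODES[c][0] for c in cats if rng.random() < 0.5][:2]
            secondary.append(picked)
        claims_parts.append(pd.DataFrame({
            "person_id": person_id[idx],
            "service_date": [params.data_start + timedelta(days=int(d))
                             for d in frac_days],
            "setting": "inpatient",
            "primary_dx": primary,
            "secondary_dx": secondary,
            "specialty": "orthopaedics",
        }))

    # comorbidity claims over each person's observed lifetime
    alive_months = np.minimum(t_death, horizon)
    alive_years = alive_months / 12.0
    for setting, rate in (("outpatient", params.outpatient_rate_py),
                          ("inpatient", params.inpatient_rate_py)):
        if rate <= 0:
            continue
        pids, code_arrs, times = [], [], []
        for j, cat in enumerate(cat_list):
            who = np.nonzero(present[:, j])[0]
            if len(who) == 0:
                continue
            counts = rng.poisson(rate * alive_years[who])
            rep = np.repeat(who, counts)
            pids.append(rep)
            code_arrs.append(
                np.array(REP_CODES[cat])[rng.integers(0, len(REP_CODES[cat]),
                                                      size=len(rep))]
            )
            times.append(rng.random(len(rep)) * np.repeat(alive_months[who], counts))
        if pids:
            rep = np.concatenate(pids)
            tt = np.concatenate(times)
            codes = np.concatenate(code_arrs)
            claims_parts.append(pd.DataFrame({
                "person_id": person_id[rep],
                "service_date": [params.data_start + timedelta(days=int(d))
                                 for d in np.floor(tt * MONTH_DAYS).astype(int)],
                "setting": setting,
                "primary_dx": codes,
                "secondary_dx": [[] for _ in range(len(rep))],
                "specialty": "internal medicine",
            }))

    # decoy categories: claims that must NOT satisfy the outpatient
    # repeat rule (single visit, or a pair under 7 days apart)
    decoys = np.nonzero(rng.random(n) < params.decoy_rate)[0]
    drows = []
    for i in decoys:
        absent = [cat_list[j] for j in range(len(cat_list)) if not present[i, j]]
        if not absent:
            continue
        cat = absent[rng.integers(len(absent))]
        code = REP_CODES[cat][0]
        day0 = int(rng.random() * alive_months[i] * MONTH_DAYS)
        drows.append((person_id[i], params.data_start + timedelta(days=day0),
                      "outpatient", code, [], "general practice"))
        if rng.random() < 0.5:  # pair too close together
            gap = int(rng.integers(1, 7))
            drows.append((person_id[i],
                          params.data_start + timedelta(days=day0 + gap),
                          "outpatient", code, [], "general practice"))
    if drows:
        claims_parts.append(pd.DataFrame(drows, columns=cols_c))

    # background non-Charlson noise
    if params.noise_claim_rate_py > 0:
        counts = rng.poisson(params.noise_claim_rate_py * alive_years)
        rep = np.repeat(np.arange(n), counts)
        if len(rep):
            tt = rng.random(len(rep)) * alive_months[rep]
            claims_parts.append(pd.DataFrame({
                "person_id": person_id[rep],
                "service_date": [params.data_start + timedelta(days=int(d))
                                 for d in np.floor(tt * MONTH_DAYS).astype(int)],
                "setting": "outpatient",
                "primary_dx": rng.choice(NOISE_CODES, size=len(rep)),
                "secondary_dx": [[] for _ in range(len(rep))],
                "specialty": "general practice",
            }))

    if claims_parts:
        claims = pd.concat(claims_parts, ignore_index=True)
        claims = claims.sort_values(["person_id", "service_date"],
                                    kind="stable").reset_index(drop=True)
    else:
        claims = pd.DataFrame(columns=cols_c)

    truth = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "birth_year": birth_year,
        "age0": age0,
        "true_cci": cci.astype(int),
        "t_fracture_months": t_frac,
        "t_death_months": t_death,
    })
    return SimulationResult(params, persons, claims, truth)


def write_simulation(result: SimulationResult, out_dir, delimiter: str = ",") -> None:
    from pathlib import Path

    from .data_model import write_claims, write_persons

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_persons(result.persons, out / "persons.csv", delimiter)
    write_claims(result.claims, out / "claims.csv", delimiter)


def cohort_truth(
    params: SimulationParams,
    result: SimulationResult,
    follow_up: pd.DataFrame,
    horizon_months: float,
    standardized: bool = False,
) -> tuple[float, float]:
    """Planted (case, reference) cumulative risks for a realised cohort.

    Case truth is the exposed risk averaged over case subjects' true
    covariates.  Reference truth is either the case arm's counterfactual
    unexposed risk (``standardized=True``, the estimand of the adjusted
    standardised pipeline) or the reference arm's marginal risk with
    future fractures integrated out (the estimand of the crude
    contrast).
    """
    merged = follow_up.merge(result.truth[["person_id", "age0", "true_cci"]],
                             on="person_id", how="left")
    t_index = np.array([
        (d - params.data_start).days / MONTH_DAYS for d in merged["index_date"]
    ])
    age = merged["age0"].to_numpy() + t_index / 12.0
    sex = merged["sex"].to_numpy()
    cci = merged["true_cci"].to_numpy(dtype=float)
    is_case = (merged["arm"] == "case").to_numpy()
    cr_case = subject_true_risk(params, sex[is_case], age[is_case],
                                cci[is_case], horizon_months,
                                mode="exposed").mean()
    if standardized:
        cr_ref = subject_true_risk(params, sex[is_case], age[is_case],
                                   cci[is_case], horizon_months,
                                   mode="unexposed").mean()
    else:
        cr_ref = subject_true_risk(params, sex[~is_case], age[~is_case],
                                   cci[~is_case], horizon_months,
                                   mode="marginal").mean()
    return float(cr_case), float(cr_ref)


def recovery_report(
    params: SimulationParams,
    result: SimulationResult,
    follow_up: pd.DataFrame,
    curves: dict[str, np.ndarray],
    grid: np.ndarray,
    horizons=(60.0, 120.0),
    standardized: bool = False,
) -> pd.DataFrame:
    """Estimates vs planted truth for each effect measure and horizon.

    Truth is evaluated per cohort subject from the planted hazards using
    the subject's true covariates and realised fracture time, then
    averaged by arm.  With ``standardized=True`` the reference truth is
    the case arm's counterfactual unexposed risk (the estimand of the
    marginally standardised adjusted pipeline); otherwise it is the
    reference arm's own realised risk, including the contribution of
    references who fracture after their index date (the estimand of the
    crude contrast).
    """
    from .effects import attributable_fraction, excess_risk, risk_ratio

    grid = np.asarray(grid, dtype=float)
    rows = []
    for h in horizons:
        k = int(np.searchsorted(grid, h))
        if k >= len(grid) or not np.isclose(grid[k], h):
            raise ValueError(f"horizon {h} is not a grid cut-point")
        cr_case_true, cr_ref_true = cohort_truth(params, result, follow_up, h,
                                                 standardized=standardized)
        est_case = float(curves["case"][k])
        est_ref = float(curves["reference"][k])
        triples = [
            ("cumulative_risk_exposed", 100 * cr_case_true, 100 * est_case),
            ("cumulative_risk_reference", 100 * cr_ref_true, 100 * est_ref),
            ("excess_risk",
             excess_risk(100 * cr_case_true, 100 * cr_ref_true),
             excess_risk(100 * est_case, 100 * est_ref)),
            ("risk_ratio",
             risk_ratio(cr_case_true, cr_ref_true, unit="proportion"),
             risk_ratio(est_case, est_ref, unit="proportion")),
            ("attributable_fraction",
             100 * attributable_fraction(cr_case_true, cr_ref_true,
                                         unit="proportion"),
             100 * attributable_fraction(est_case, est_ref, unit="proportion")),
        ]
        for measure, truth_val, est in triples:
            rows.append({
                "horizon_months": h,
                "measure": measure,
                "truth": truth_val,
                "estimate": est,
                "abs_error": abs(est - truth_val),
                "rel_error": abs(est - truth_val) / abs(truth_val)
                if truth_val != 0 else np.nan,
            })
    return pd.DataFrame(rows)
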