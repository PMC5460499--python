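"""Excess risk, risk ratio and attributable fraction with bootstrap CIs.

Point measures are simple contrasts of the case-arm and reference-arm
cumulative risks at a horizon:

* excess risk      ER  = CR_case - CR_ref (percentage points)
* risk ratio       RR  = CR_case / CR_ref
* attributable     AF  = (CR_case - CR_ref) / CR_case = 1 - 1/RR
  fraction

Confidence intervals come from a nonparametric bootstrap that resamples
whole matched sets (a case together with its references), preserving the
matched design.  Risks and risk differences use bias-corrected (BC,
median-bias only, no acceleration) intervals; risk ratios use plain
percentile intervals.  The matched sets are resampled as observed —
matching is not redone inside replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mortality import fit_risk_curves, rates_to_risk, split_person_time

__all__ = [
    "excess_risk",
    "risk_ratio",
    "attributable_fraction",
    "EffectEstimate",
    "bc_interval",
    "percentile_interval",
    "bootstrap_effects",
]

logger = logging.getLogger(__name__)

#: bootstrap risk ratios whose coefficient of variation exceeds this are
#: flagged as unreliable in the output
RR_CV_THRESHOLD = 0.5


def _check_unit(values, unit: str) -> None:
    hi = 1.0 if unit == "proportion" else 100.0
    for v in values:
        if not (0.0 <= v <= hi):
            raise ValueError(
                f"cumulative risk {v} outside [0, {hi:g}] for unit={unit!r}; "
                "mixed percent/proportion inputs?"
            )


def excess_risk(cr_exposed: float, cr_reference: float, unit: str = "percent") -> float:
    """Difference in cumulative risk, in the input unit."""
    _check_unit((cr_exposed, cr_reference), unit)
    return cr_exposed - cr_reference


def risk_ratio(cr_exposed: float, cr_reference: float, unit: str = "percent") -> float:
    """Ratio of exposed to reference cumulative risk."""
    _check_unit((cr_exposed, cr_reference), unit)
    if cr_reference == 0:
        raise ZeroDivisionError("risk ratio undefined: reference risk is zero")
    return cr_exposed / cr_reference


def attributable_fraction(
    cr_exposed: float, cr_reference: float, unit: str = "percent"
) -> float:
    """Share of exposed-group risk attributable to the exposure.

    Returned as a proportion (may be negative when the exposed risk is
    below the reference risk).
    """
    _check_unit((cr_exposed, cr_reference), unit)
    if cr_exposed == 0:
        raise ZeroDivisionError("attributable fraction undefined: exposed risk is zero")
    return (cr_exposed - cr_reference) / cr_exposed


@dataclass
class EffectEstimate:
    """One horizon's effect measures with 95% bootstrap intervals.

    Risks and differences are in percentage points; the attributable
    fraction is in percent; intervals are (low, high) pairs under the
    method named in ``methods``.
    """

    horizon_months: float
    cr_exposed: float
    cr_reference: float
    excess_risk: float
    risk_ratio: float
    attributable_fraction: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    methods: dict[str, str] = field(default_factory=dict)
    rr_unreliable: bool = False
    n_boot: int = 0
    seed: int | None = None


def bc_interval(
    boot: np.ndarray, point: float, level: float = 0.95
) -> tuple[float, float]:
    """Bias-corrected (BC) bootstrap interval.

    The percentile interval shifted by the median-bias constant
    z0 = Phi^-1(fraction of replicates below the point estimate); no
    acceleration term.  Degenerate bootstrap distributions collapse to a
    zero-width interval at the point estimate.
    """
    boot = np.asarray(boot, dtype=float)
    if np.ptp(boot) == 0.0:
        return float(boot[0]), float(boot[0])
    prop = ((boot < point).sum() + 0.5 * (boot == point).sum()) / len(boot)
    prop = min(max(prop, 0.5 / len(boot)), 1 - 0.5 / len(boot))
    z0 = norm.ppf(prop)
    z = norm.ppf([(1 - level) / 2, (1 + level) / 2])
    lo_q, hi_q = norm.cdf(2 * z0 + z)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    if not (lo <= point <= hi):
        warnings.warn(
            "BC interval does not bracket the point estimate; the bootstrap "
            "distribution may be strongly skewed or bimodal", RuntimeWarning,
            stacklevel=2,
        )
    return float(lo), float(hi)


def percentile_interval(boot: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo, hi = np.quantile(np.asarray(boot, dtype=float),
                         [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def _horizon_indices(grid: np.ndarray, horizons) -> np.ndarray:
    idx = np.searchsorted(grid, np.asarray(horizons, dtype=float))
    if np.any(idx >= len(grid)) or np.any(~np.isclose(grid[idx], horizons)):
        raise ValueError(f"horizons {horizons} must be grid cut-points")
    return idx


def _per_set_cells(rows: pd.DataFrame, n_intervals: int):
    """Per-matched-set deaths and person-time arrays for fast resampling.

    Returns (set_ids, D, T) where D and T have shape
    (n_sets, 2 arms x n_intervals); a bootstrap replicate's cell totals
    are a weighted sum of set rows.
    """
    rows = rows.copy()
    set_codes, set_ids = pd.factorize(rows["matched_set_id"])
    arm_code = (rows["arm"] == "case").astype(int).to_numpy()
    flat = arm_code * n_intervals + rows["interval"].to_numpy()
    shape = (len(set_ids), 2 * n_intervals)
    D = np.zeros(shape)
    T = np.zeros(shape)
    np.add.at(D, (set_codes, flat), rows["death"].to_numpy(dtype=float))
    np.add.at(T, (set_codes, flat), rows["time"].to_numpy(dtype=float))
    return set_ids, D, T


def _measures_from_cells(D, T, grid, h_idx):
    """Crude measures at each horizon from stacked cell arrays.

    D, T: (..., 2 x n_intervals); returns dict of arrays (..., n_horizons).
    """
    k = len(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(T > 0, D / np.maximum(T, 1e-300), np.nan)
    ref = rates_to_risk(rates[..., :k], grid)[..., h_idx]
    case = rates_to_risk(rates[..., k:], grid)[..., h_idx]
    return {
        "cr_exposed": 100 * case,
        "cr_reference": 100 * ref,
        "excess_risk": 100 * (case - ref),
        "risk_ratio": case / ref,
        "attributable_fraction": 100 * (case - ref) / case,
    }


def bootstrap_effects(
    follow_up: pd.DataFrame,
    grid: np.ndarray,
    horizons=(120.0,),
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "crude",
    level: float = 0.95,
    max_failure_rate: float = 0.05,
) -> list[EffectEstimate]:
    """Effect measures with bootstrap CIs at each horizon.

    Resampling unit is the matched set.  For the crude model, per-set
    exposure cells are precomputed so each replicate is a weighted sum;
    for the adjusted model every replicate refits the full pipeline
    (slow, but faithful).  Replicates whose statistic is undefined
    (e.g. an empty reference cell up to the horizon) are redrawn, up to
    a failure budget of ``max_failure_rate``.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    h_idx = _horizon_indices(grid, horizons)
    rows = split_person_time(follow_up, grid)

    if model == "crude":
        set_ids, D, T = _per_set_cells(rows, len(grid))
        n_sets = len(set_ids)
        point = _measures_from_cells(D.sum(0), T.sum(0), grid, h_idx)
        boots = {key: [] for key in point}
        drawn = failures = 0
        while len(boots["excess_risk"]) < n_boot:
            budget = n_boot - len(boots["excess_risk"])
            counts = rng.multinomial(n_sets, np.full(n_sets, 1.0 / n_sets),
                                     size=budget).astype(float)
            rep = _measures_from_cells(counts @ D, counts @ T, grid, h_idx)
            ok = np.isfinite(rep["risk_ratio"]).all(axis=-1)
            drawn += budget
            failures += int((~ok).sum())
            if failures > max_failure_rate * max(drawn, n_boot):
                raise RuntimeError(
                    f"bootstrap aborted: {failures}/{drawn} replicates failed "
                    "(undefined statistic)"
                )
            for key in boots:
                boots[key].extend(rep[key][ok])
        boot_arr = {key: np.asarray(v)[:n_boot] for key, v in boots.items()}
    elif model == "adjusted":
        sets = {sid: g for sid, g in follow_up.groupby("matched_set_id")}
        set_ids = list(sets)
        curves = fit_risk_curves(follow_up, grid, model="adjusted")
        point = _point_from_curves(curves, h_idx)
        boots = {key: [] for key in point}
        failures = 0
        for b in range(n_boot):
            for _ in range(20):  # redraw budget per replicate
                chosen = rng.choice(len(set_ids), size=len(set_ids), replace=True)
                resampled = pd.concat(
                    [sets[set_ids[i]] for i in chosen], ignore_index=True
                )
                try:
                    rep_curves = fit_risk_curves(resampled, grid, model="adjusted")
                    rep = _point_from_curves(rep_curves, h_idx)
                except Exception:
                    failures += 1
                    if failures > max_failure_rate * n_boot + 10:
                        raise RuntimeError("bootstrap aborted: too many failed "
                                           "replicates")
                    continue
                break
            for key in boots:
                boots[key].append(rep[key])
        boot_arr = {key: np.asarray(v) for key, v in boots.items()}
    else:
        raise ValueError(f"unknown model {model!r}")

    estimates = []
    for j, h in enumerate(horizons):
        ci, methods = {}, {}
        for key in ("cr_exposed", "cr_reference", "excess_risk"):
            ci[key] = bc_interval(boot_arr[key][..., j], point[key][..., j], level)
            methods[key] = "bias_corrected"
        for key in ("risk_ratio", "attributable_fraction"):
            ci[key] = percentile_interval(boot_arr[key][..., j], level)
            methods[key] = "percentile"
        rr_boot = boot_arr["risk_ratio"][..., j]
        cv = rr_boot.std() / rr_boot.mean() if rr_boot.mean() > 0 else np.inf
        estimates.append(EffectEstimate(
            horizon_months=float(h),
            cr_exposed=float(point["cr_exposed"][..., j]),
            cr_reference=float(point["cr_reference"][..., j]),
            excess_risk=float(point["excess_risk"][..., j]),
            risk_ratio=float(point["risk_ratio"][..., j]),
            attributable_fraction=float(point["attributable_fraction"][..., j]),
            ci=ci, methods=methods, rr_unreliable=bool(cv > RR_CV_THRESHOLD),
            n_boot=n_boot, seed=seed,
        ))
    return estimates


def _point_from_curves(curves: dict[str, np.ndarray], h_idx: np.ndarray) -> dict:
    case = curves["case"][h_idx]
    ref = curves["reference"][h_idx]
    return {
        "cr_exposed": 100 * case,
        "cr_reference": 100 * ref,
        "excess_risk": 100 * (case - ref),
        "risk_ratio": case / ref,
        "attributable_fraction": 100 * (case - ref) / case,
    }


def effects_table(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Long-format summary: one row per (horizon, measure)."""
    rows = []
    for est in estimates:
        for key in ("cr_exposed", "cr_reference", "excess_risk", "risk_ratio",
                    "attributable_fraction"):
            lo, hi = est.ci.get(key, (np.nan, np.nan))
            rows.append({
                "horizon_months": est.horizon_months,
                "measure": key,
                "estimate": getattr(est, key) if key != "cr_exposed" else est.cr_exposed,
                "ci_low": lo,
                "ci_high": hi,
                "method": est.methods.get(key, ""),
                "n_boot": est.n_boot,
                "seed": est.seed,
            })
    return pd.DataFrame(rows)
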