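"""Piecewise-exponential mortality modelling on a graduated interval grid.

Follow-up is divided into discrete intervals that are short early on —
where post-fracture mortality changes fastest — and widen later:
half-month steps to 3 months, monthly to 12, quarterly to 24,
half-yearly to 48 and yearly to 120 months.  Within each interval the
hazard is treated as constant, so deaths in an (arm x interval) cell
follow a Poisson law with the log person-time as offset.

Two models are provided. The *crude* model is saturated in
arm x interval, so its fitted rates equal deaths / person-time cell-wise
and are computed in closed form.  The *adjusted* model is a log-linear
Poisson regression with main effects of fracture, Charlson index, age
and interval plus the fracture x interval, fracture x CCI,
fracture x age and interval x age interactions.  Interval rates are
converted to interval death probabilities via 1 - exp(-rate * width) and
chained into cumulative risk; adjusted curves are marginally
standardised to the case arm's covariate distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DEFAULT_GRID_RULE",
    "build_grid",
    "split_person_time",
    "aggregate_cells",
    "fit_crude",
    "fit_adjusted",
    "rates_to_risk",
    "crude_risk_curves",
    "standardize",
    "aggregate_curves",
    "fit_risk_curves",
]

logger = logging.getLogger(__name__)

#: (upper bound in months, step): 0.5-steps to 3, monthly to 12,
#: quarterly to 24, half-yearly to 48, yearly to 120
DEFAULT_GRID_RULE = ((3, 0.5), (12, 1.0), (24, 3.0), (48, 6.0), (120, 12.0))

#: Charlson score cap applied before modelling, for numerical stability
CCI_CAP = 10

ADJUSTED_FORMULA = (
    "deaths ~ fx * C(interval) + cci + age_c + fx:cci + fx:age_c "
    "+ C(interval):age_c"
)


def build_grid(rule=DEFAULT_GRID_RULE, custom: list[float] | None = None) -> np.ndarray:
    """Interval cut-points in months (upper bounds; intervals open at 0).

    The default rule yields 29 strictly increasing cut-points from 0.5
    to 120.  A ``custom`` list bypasses the rule; it must be strictly
    increasing and positive.
    """
    if custom is not None:
        cuts = np.asarray(custom, dtype=float)
    else:
        cuts, prev = [], 0.0
        for upper, step in rule:
            cuts.extend(np.arange(prev + step, upper + step / 2, step))
            prev = upper
        cuts = np.asarray(cuts)
    if cuts.ndim != 1 or len(cuts) == 0 or cuts[0] <= 0 or np.any(np.diff(cuts) <= 0):
        raise ValueError("grid cut-points must be positive and strictly increasing")
    return cuts


def split_person_time(follow_up: pd.DataFrame, grid: np.ndarray) -> pd.DataFrame:
    """Expand subjects into subject-interval rows with time at risk.

    Each subject contributes the full width of every interval survived,
    a partial width to the interval containing the end of follow-up and
    nothing beyond; the death indicator sits in the interval containing
    the death time.  Follow-up beyond the last cut-point is truncated
    (deaths there are treated as censored at the grid end).  Intervals
    with zero time for a subject are omitted.
    """
    cuts = np.asarray(grid, dtype=float)
    lower = np.concatenate([[0.0], cuts[:-1]])
    width = cuts - lower
    dur = follow_up["duration_months"].to_numpy(dtype=float)
    death = (follow_up["event"] == "death").to_numpy()
    time = np.clip(dur[:, None] - lower[None, :], 0.0, width[None, :])
    death_interval = np.searchsorted(cuts, dur, side="left")  # == len(cuts) if beyond
    n, k = time.shape
    subj_idx, interval_idx = np.nonzero(time > 0)
    out = pd.DataFrame({
        "interval": interval_idx,
        "time": time[subj_idx, interval_idx],
        "death": death[subj_idx] & (death_interval[subj_idx] == interval_idx),
    })
    carried = ["person_id", "arm", "matched_set_id", "sex", "birth_year",
               "age_at_index", "cci_score"]
    for col in carried:
        if col in follow_up.columns:
            out[col] = follow_up[col].to_numpy()[subj_idx]
    return out


def aggregate_cells(subject_rows: pd.DataFrame, by: tuple[str, ...] = ()) -> pd.DataFrame:
    """Collapse subject-interval rows into exposure cells.

    Cells are keyed by arm x interval plus any extra stratification
    columns; mean age and mean CCI are person-time-weighted.
    """
    keys = ["arm", *by, "interval"]
    g = subject_rows.assign(
        deaths=subject_rows["death"].astype(int),
        _wage=subject_rows.get("age_at_index", 0) * subject_rows["time"],
        _wcci=subject_rows.get("cci_score", 0) * subject_rows["time"],
    ).groupby(keys, observed=True)
    cells = g.agg(
        deaths=("deaths", "sum"),
        person_months=("time", "sum"),
        _wage=("_wage", "sum"),
        _wcci=("_wcci", "sum"),
    ).reset_index()
    cells["mean_age"] = cells["_wage"] / cells["person_months"]
    cells["mean_cci"] = cells["_wcci"] / cells["person_months"]
    return cells.drop(columns=["_wage", "_wcci"])


def fit_crude(cells: pd.DataFrame, grid: np.ndarray) -> pd.DataFrame:
    """Saturated arm x interval Poisson rates, in closed form.

    The crude model contains only arm, interval and their interaction
    with a log person-time offset, so the maximum-likelihood rate in
    each cell is deaths / person-time exactly; cells with zero
    person-time yield a missing rate (excluded later from risk
    chaining, with a warning).
    """
    cells = cells.groupby(["arm", "interval"], observed=True)[
        ["deaths", "person_months"]
    ].sum().reset_index()
    full = (
        pd.MultiIndex.from_product(
            [cells["arm"].unique(), range(len(grid))], names=["arm", "interval"]
        )
        .to_frame(index=False)
        .merge(cells, on=["arm", "interval"], how="left")
        .fillna({"deaths": 0, "person_months": 0.0})
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        full["rate"] = np.where(
            full["person_months"] > 0,
            full["deaths"] / full["person_months"],
            np.nan,
        )
    n_empty = int(full["rate"].isna().sum())
    if n_empty:
        logger.warning("%d arm x interval cells have zero person-time; "
                       "their rates are missing", n_empty)
    return full


@dataclass
class AdjustedModel:
    """Fitted adjusted Poisson model plus the centring used for age."""

    result: object  # statsmodels GLMResults
    age_center: float
    grid: np.ndarray

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def predict_rates(self, patterns: pd.DataFrame, fx: int) -> np.ndarray:
        """Rates (deaths per person-month) for covariate ``patterns``.

        ``patterns`` has columns age_at_index and cci_score; the return
        value has shape (n_patterns, n_intervals).
        """
        n, k = len(patterns), len(self.grid)
        frame = pd.DataFrame({
            "fx": fx,
            "interval": np.tile(np.arange(k), n),
            "age_c": np.repeat(
                patterns["age_at_index"].to_numpy(dtype=float) - self.age_center, k
            ),
            "cci": np.repeat(
                np.minimum(patterns["cci_score"].to_numpy(dtype=float), CCI_CAP), k
            ),
            "time": 1.0,
        })
        rates = self.result.predict(frame, offset=np.zeros(len(frame)))
        return np.asarray(rates).reshape(n, k)


def fit_adjusted(
    subject_rows: pd.DataFrame,
    grid: np.ndarray | None = None,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> AdjustedModel:
    """Adjusted log-linear Poisson model on subject-interval data.

    Terms: main effects of fracture, CCI (integer, capped at 10), age
    (continuous, centred at the cohort mean) and interval, plus
    fracture x interval, fracture x CCI, fracture x age and
    interval x age interactions, with log person-time as offset.
    Subject-interval rows are first aggregated over identical covariate
    patterns, which leaves the likelihood unchanged.
    """
    age_center = float(subject_rows["age_at_index"].mean())
    data = pd.DataFrame({
        "fx": (subject_rows["arm"] == "case").astype(int),
        "interval": subject_rows["interval"].to_numpy(),
        "age_c": subject_rows["age_at_index"].to_numpy(dtype=float) - age_center,
        "cci": np.minimum(subject_rows["cci_score"].to_numpy(dtype=float), CCI_CAP),
        "deaths": subject_rows["death"].astype(int).to_numpy(),
        "time": subject_rows["time"].to_numpy(dtype=float),
    })
    agg = data.groupby(["fx", "interval", "age_c", "cci"], as_index=False).agg(
        deaths=("deaths", "sum"), time=("time", "sum")
    )
    agg = agg[agg["time"] > 0]
    pattern_deaths = agg.groupby(["fx", "interval"])["deaths"].sum()
    if (pattern_deaths == 0).any():
        warnings.warn(
            "some arm x interval patterns contain no deaths; the fit may be "
            "separated for those levels", RuntimeWarning, stacklevel=2,
        )
    model = smf.glm(
        ADJUSTED_FORMULA, data=agg, family=sm.families.Poisson(),
        offset=np.log(agg["time"].to_numpy()),
    )
    result = model.fit(maxiter=maxiter, tol=tol)
    if not result.converged:
        raise RuntimeError(
            f"adjusted Poisson model failed to converge; deviance {result.deviance:.6g}"
        )
    if grid is None:
        grid = build_grid()
    return AdjustedModel(result=result, age_center=age_center,
                         grid=np.asarray(grid, dtype=float))


def rates_to_risk(rates: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Chain interval rates into cumulative risk at each cut-point.

    Interval death probability is 1 - exp(-rate * width); cumulative
    risk at cut-point k is 1 - prod_{i<=k} (1 - p_i).  Missing rates
    contribute no mortality (logged upstream); negative rates raise.
    """
    rates = np.asarray(rates, dtype=float)
    cuts = np.asarray(grid, dtype=float)
    width = np.diff(np.concatenate([[0.0], cuts]))
    if np.any(rates[~np.isnan(rates)] < 0):
        raise ValueError("negative interval rate")
    p = 1.0 - np.exp(-np.nan_to_num(rates) * width)
    return 1.0 - np.cumprod(1.0 - p, axis=-1)


def crude_risk_curves(cells: pd.DataFrame, grid: np.ndarray) -> dict[str, np.ndarray]:
    """Per-arm cumulative risk from the saturated crude model."""
    rates = fit_crude(cells, grid)
    return {
        arm: rates_to_risk(
            g.sort_values("interval")["rate"].to_numpy(), grid
        )
        for arm, g in rates.groupby("arm")
    }


def standardize(
    model: AdjustedModel,
    standard_population: pd.DataFrame,
    grid: np.ndarray,
) -> dict[str, np.ndarray]:
    """Marginal standardisation of both arms to one covariate mix.

    For each arm, interval rates are predicted for every covariate
    pattern in ``standard_population`` (columns age_at_index, cci_score,
    optional weight), converted to interval probabilities and chained
    into a per-pattern survival curve; the cumulative risk curve is the
    weighted mean of the per-pattern risks.  (Averaging interval
    probabilities before chaining would overstate cumulative risk under
    covariate heterogeneity, because a subject's interval survivals are
    chained within subject.)
    """
    if len(standard_population) == 0:
        raise ValueError("empty standard population")
    weights = standard_population.get(
        "weight", pd.Series(1.0, index=standard_population.index)
    ).to_numpy(dtype=float)
    weights = weights / weights.sum()
    cuts = np.asarray(grid, dtype=float)
    width = np.diff(np.concatenate([[0.0], cuts]))
    curves = {}
    for arm, fx in (("case", 1), ("reference", 0)):
        rates = model.predict_rates(standard_population, fx=fx)
        survival = np.exp(-np.cumsum(rates * width[None, :], axis=1))
        curves[arm] = 1.0 - weights @ survival
    return curves


def aggregate_curves(
    curves: list[np.ndarray], sizes: list[float]
) -> np.ndarray:
    """Point-wise weighted mean of risk curves on a common grid."""
    arr = np.asarray(curves, dtype=float)
    if arr.ndim != 2 or len(set(len(c) for c in curves)) != 1:
        raise ValueError("curves must share a common grid")
    w = np.asarray(sizes, dtype=float)
    return (w / w.sum()) @ arr


def fit_risk_curves(
    follow_up: pd.DataFrame,
    grid: np.ndarray,
    model: str = "crude",
    stratify: tuple[str, ...] = (),
) -> dict[str, np.ndarray]:
    """End-to-end: split person-time, fit, return per-arm risk curves.

    With ``stratify`` (e.g. ``("sex",)``) the model is fitted within
    each stratum and the stratum curves are averaged with weights equal
    to the stratum's case count.  The adjusted model is marginally
    standardised to the case arm's covariate distribution, so its
    case-reference contrast is an exposed-standardised (attributable)
    comparison.
    """
    rows = split_person_time(follow_up, grid)
    if not stratify:
        groups = [((), rows)]
    else:
        groups = list(rows.groupby(list(stratify)))
    per_arm: dict[str, list[np.ndarray]] = {"case": [], "reference": []}
    sizes = []
    for _, g in groups:
        n_cases = g.loc[g["arm"] == "case", "person_id"].nunique()
        if n_cases == 0:
            continue
        sizes.append(n_cases)
        if model == "crude":
            curves = crude_risk_curves(aggregate_cells(g), grid)
        elif model == "adjusted":
            fitted = fit_adjusted(g, grid=grid)
            std_pop = (
                g[g["arm"] == "case"]
                .drop_duplicates("person_id")[["age_at_index", "cci_score"]]
            )
            curves = standardize(fitted, std_pop, grid)
        else:
            raise ValueError(f"unknown model {model!r}")
        for arm in per_arm:
            per_arm[arm].append(curves[arm])
    return {
        arm: aggregate_curves(curve_list, sizes)
        for arm, curve_list in per_arm.items()
    }
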