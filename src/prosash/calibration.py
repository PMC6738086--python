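"""Observed-versus-predicted survival: Kaplan–Meier curves and risk tables.

Calibration of the prognostic model is assessed within risk categories: the
observed Kaplan–Meier curve of each category is compared with the
*model-predicted mean survival curve* — the pointwise arithmetic mean of the
members' individual predicted curves.  This is deliberately not the curve at
the category's mean prognostic index: the two differ because
``eta -> S0(t)**exp(eta)`` is convex, and the mean curve is what a mixture of
those patients would actually exhibit.

The risk table summarises, per category: N, observed and predicted median
overall survival, observed and predicted percentage surviving 12 months, and
the hazard ratio against the lowest-risk category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.optimize import brentq

from . import flexpar
from .model_core import (
    NOT_REACHED,
    ProsashModel,
    SurvivalCurve,
    linear_predictor_batch,
    risk_category,
    spline_log_cum_hazard,
)

__all__ = [
    "KMCurve",
    "RiskTable",
    "build_risk_table",
    "group_hazard_ratio",
    "kaplan_meier",
    "predicted_mean_survival",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood uncertainty.

    ``median`` is the first time the estimate drops to or below 0.5;
    the median CI comes from where the pointwise confidence band crosses 0.5
    (Brookmeyer–Crowley); :data:`~prosash.model_core.NOT_REACHED` marks bands
    that never cross.
    """

    times: np.ndarray            # event-time grid
    survival: np.ndarray
    variance: np.ndarray         # Greenwood variance of S(t)
    ci_lower: np.ndarray         # log(-log)-scale pointwise 95% band
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    median: float
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        """Step-function value at ``t`` (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan–Meier estimate with Greenwood variance and median CI."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival data")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter().fit(t, d)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    S = kmf.survival_function_at_times(grid).to_numpy()
    # Greenwood: var S(t) = S(t)^2 * cumsum d / (n (n - d))
    n_risk = tbl["at_risk"].to_numpy(dtype=float)
    d_t = tbl["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d_t, d_t / (n_risk * (n_risk - d_t)), 0.0)
    var = S ** 2 * np.cumsum(terms)
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    med = kmf.median_survival_time_
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    m_lo, m_hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    return KMCurve(
        times=grid, survival=S, variance=var, ci_lower=lo, ci_upper=hi,
        n_at_risk=n_risk,
        median=NOT_REACHED if math.isinf(med) else float(med),
        median_ci=(NOT_REACHED if math.isinf(m_lo) else m_lo,
                   NOT_REACHED if math.isinf(m_hi) else m_hi),
    )


def predicted_mean_survival(etas, model: ProsashModel, grid) -> SurvivalCurve:
    """Mean of the members' individual survival curves on a time grid."""
    etas = np.asarray(etas, dtype=float)
    if etas.size == 0:
        raise ValueError("empty cohort")
    grid = np.asarray(list(grid), dtype=float)
    exp_eta = np.exp(etas)
    s = np.empty_like(grid)
    for i, t in enumerate(grid):
        h0 = math.exp(spline_log_cum_hazard(t, model.spline))
        s[i] = np.mean(np.exp(-h0 * exp_eta))
    return SurvivalCurve(times=grid, survival=s)


def _mean_curve_median(etas: np.ndarray, model: ProsashModel,
                       horizon: float = 120.0) -> float:
    """First time the cohort mean survival curve crosses 0.5."""
    exp_eta = np.exp(np.asarray(etas, dtype=float))

    def f(x: float) -> float:
        h0 = math.exp(float(model.spline(x)[0]))
        return float(np.mean(np.exp(-h0 * exp_eta))) - 0.5

    hi = math.log(horizon)
    if f(hi) > 0:
        return NOT_REACHED
    lo = hi - 1.0
    while f(lo) < 0:
        lo -= 1.0
        if lo < -30.0:  # pragma: no cover
            return math.exp(-30.0)
    return math.exp(brentq(f, lo, hi, xtol=1e-10))


def group_hazard_ratio(data: pd.DataFrame, category_labels,
                       reference, spline_df: int = 2) -> pd.DataFrame:
    """Hazard ratio of each category against a reference category.

    A single-factor spline fit (``spline_df`` baseline degrees of freedom);
    categories without any events are reported with NaN estimates and the
    ``infinite_ci`` flag set.
    """
    labels = pd.Series(np.asarray(category_labels), index=data.index)
    cats = [reference] + sorted(set(labels) - {reference}, key=str)
    ev = data["event"].to_numpy(dtype=int)
    dead_by_cat = {c: int(ev[(labels == c).to_numpy()].sum()) for c in cats}
    usable = [c for c in cats if dead_by_cat[c] > 0]
    if len(usable) < 2 or reference not in usable:
        raise ValueError("need events in the reference and at least one other "
                         "category")
    mask = labels.isin(usable).to_numpy()
    sub = data.loc[mask, ["time", "event"]].copy()
    sub["category"] = pd.Categorical(labels[mask],
                                     categories=[c for c in cats if c in usable])
    fitted = flexpar.fit(sub, flexpar.FlexParSpec(df=spline_df,
                                                  covariates=["category"]))
    hrs = flexpar.hazard_ratios(fitted)
    rows = [{"category": reference, "hr": 1.0, "hr_lower": np.nan,
             "hr_upper": np.nan, "p": np.nan, "infinite_ci": False}]
    for c in cats[1:]:
        name = f"category[{c}]"
        if c in usable and name in hrs.index:
            r = hrs.loc[name]
            rows.append({"category": c, "hr": r["hr"], "hr_lower": r["hr_lower"],
                         "hr_upper": r["hr_upper"], "p": r["p"],
                         "infinite_ci": False})
        else:
            rows.append({"category": c, "hr": np.nan, "hr_lower": np.nan,
                         "hr_upper": np.nan, "p": np.nan, "infinite_ci": True})
    return pd.DataFrame(rows).set_index("category")


@dataclass
class RiskTable:
    """Per-risk-category calibration summary (the published table's shape)."""

    table: pd.DataFrame
    cutoffs: tuple[float, float, float]
    mode: str
    curves: dict[int, KMCurve] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def centile_cutoffs(etas, centiles=(15.0, 50.0, 85.0)) -> tuple[float, ...]:
    """Inverse-empirical-CDF (type-1) centiles of the prognostic index.

    At n = 500 the 15/50/85 cuts split the cohort exactly 75/175/175/75.
    """
    etas = np.sort(np.asarray(etas, dtype=float))
    n = len(etas)
    out = []
    for c in centiles:
        k = max(1, math.ceil(n * c / 100.0))
        out.append(float(etas[k - 1]))
    return tuple(out)


def build_risk_table(data: pd.DataFrame, model: ProsashModel,
                     mode: str = "published", t_check: float = 12.0,
                     median_horizon: float = 120.0) -> RiskTable:
    """Observed vs predicted survival by risk category.

    ``mode='published'`` stratifies by the model's frozen cutoffs (external
    validation); ``mode='centile'`` re-derives cutoffs at the 15th/50th/85th
    centiles of the prognostic index in this cohort (training-style use).
    Empty categories yield NA rows.
    """
    etas = linear_predictor_batch(data, model)
    if mode == "published":
        cuts = model.cutoffs.values
    elif mode == "centile":
        cuts = centile_cutoffs(etas)
    else:
        raise ValueError("mode must be 'published' or 'centile'")
    from .model_core import RiskCutoffs
    cutobj = RiskCutoffs(tuple(cuts))
    cats = np.array([risk_category(e, cutobj) for e in etas])

    rows = []
    curves: dict[int, KMCurve] = {}
    for c in (1, 2, 3, 4):
        m = cats == c
        n_c = int(m.sum())
        if n_c == 0:
            rows.append({"category": c, "n": 0})
            continue
        km = kaplan_meier(data.loc[m, "time"], data.loc[m, "event"])
        curves[c] = km
        pred_med = _mean_curve_median(etas[m], model, horizon=median_horizon)
        s12_obs = km.survival_at(t_check)
        s12_pred = float(predicted_mean_survival(etas[m], model,
                                                 [t_check]).survival[0])
        rows.append({
            "category": c,
            "n": n_c,
            "observed_median": km.median,
            "observed_median_lo": km.median_ci[0],
            "observed_median_hi": km.median_ci[1],
            "predicted_median": pred_med,
            "observed_pct_12m": 100.0 * s12_obs,
            "predicted_pct_12m": 100.0 * s12_pred,
        })
    table = pd.DataFrame(rows).set_index("category")

    # hazard ratios vs the lowest occupied category
    occupied = [c for c in (1, 2, 3, 4) if (cats == c).any()]
    try:
        hrs = group_hazard_ratio(data[["time", "event"]], cats,
                                 reference=occupied[0])
        for c in occupied:
            if c in hrs.index:
                table.loc[c, "hr"] = hrs.loc[c, "hr"]
                table.loc[c, "hr_lower"] = hrs.loc[c, "hr_lower"]
                table.loc[c, "hr_upper"] = hrs.loc[c, "hr_upper"]
                table.loc[c, "hr_p"] = hrs.loc[c, "p"]
    except ValueError:
        pass  # too few events for a between-group fit; table stays NA
    return RiskTable(table=table, cutoffs=tuple(cuts), mode=mode, curves=curves)
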