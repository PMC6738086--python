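"""Discrimination measures for survival prognostic indices.

Two measures quantify how well a prognostic index separates patients:

* **Harrell's c-index** — the proportion of comparable patient pairs in which
  the member predicted to be at higher risk dies first.  0.5 is chance, 1 is
  perfect rank agreement.
* **Royston–Sauerbrei D** and its **R²_D** — D is the log hazard ratio
  between "prognostically above-average" and "below-average" halves of the
  cohort, estimated by regressing survival on the standardised rankits of the
  index; R²_D = (D²/κ²) / (σ² + D²/κ²) with κ = sqrt(8/π) and σ² = π²/6
  translates it into explained variation on the log relative-hazard scale.

Confidence intervals use the nonparametric percentile bootstrap over
patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import flexpar

__all__ = [
    "KAPPA",
    "SIGMA2",
    "DiscriminationResult",
    "bootstrap_ci",
    "discrimination",
    "harrells_c",
    "r2_from_D",
    "royston_sauerbrei_D",
]

KAPPA = math.sqrt(8.0 / math.pi)
SIGMA2 = math.pi ** 2 / 6.0


def harrells_c(times, events, risk_scores) -> float:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) with ``t_i < t_j`` is comparable iff subject i died; the
    pair is concordant when the shorter-lived member carries the higher risk
    score, and ties in score count 1/2.  Pairs tied on time are comparable
    only when exactly one member is an event (that member must rank riskier).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    r = np.asarray(risk_scores, dtype=float)
    if not (len(t) == len(d) == len(r)):
        raise ValueError("times, events and risk_scores must have equal length")
    # vectorised over the full pair grid; cohorts here are small enough
    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    ri, rj = r[:, None], r[None, :]
    comp = (ti < tj) & (di == 1)
    comp |= (ti == tj) & (di == 1) & (dj == 0)
    np.fill_diagonal(comp, False)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    concordant = int((comp & (ri > rj)).sum())
    tied = int((comp & (ri == rj)).sum())
    return (concordant + 0.5 * tied) / n_comp


def _blom_rankits(values: np.ndarray) -> np.ndarray:
    """Normal order statistics via Blom's approximation, averaging ties."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def royston_sauerbrei_D(times, events, prognostic_index,
                        spline_df: int = 2) -> float:
    """The D discrimination statistic of a prognostic index.

    The index values are replaced by their standard-normal rankits scaled by
    1/κ, and D is the estimated log hazard ratio per unit of this constructed
    covariate in an auxiliary proportional-hazards fit (the spline engine with
    ``spline_df`` baseline degrees of freedom).  Under a normally distributed
    index with multiplicative effect on the hazard, D estimates κ times the
    index's standard deviation on the log-hazard scale.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    pi = np.asarray(prognostic_index, dtype=float)
    if len(t) < 10 or d.sum() < 2:
        raise ValueError("need >= 10 subjects and >= 2 events for D")
    if np.ptp(pi) == 0.0:
        warnings.warn("constant prognostic index: D = 0", stacklevel=2)
        return 0.0
    z = _blom_rankits(pi) / KAPPA
    data = pd.DataFrame({"time": t, "event": d, "rankit": z})
    fitted = flexpar.fit(data, flexpar.FlexParSpec(df=spline_df,
                                                   covariates=["rankit"]))
    return float(fitted.beta["rankit"])


def r2_from_D(D: float) -> float:
    """Explained variation on the log relative-hazard scale, from D."""
    a = D * D / (KAPPA * KAPPA)
    return a / (SIGMA2 + a)


def bootstrap_ci(statistic: Callable[[pd.DataFrame], float],
                 data: pd.DataFrame, reps: int = 200, seed: int = 0,
                 max_retries: int = 10) -> tuple[float, float]:
    """Percentile 95% bootstrap interval of ``statistic`` over row resamples.

    A resample on which the statistic fails (e.g. a degenerate fit) is
    redrawn, up to ``max_retries`` times each, and logged via a warning.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(data)
    vals = []
    failures = 0
    for _ in range(reps):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            try:
                vals.append(float(statistic(data.iloc[idx].reset_index(drop=True))))
                break
            except Exception:
                failures += 1
                if attempt == max_retries:
                    raise
    if failures:
        warnings.warn(f"{failures} bootstrap resample(s) redrawn after "
                      "statistic failure", stacklevel=2)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass(frozen=True)
class DiscriminationResult:
    """c-index, D and R²_D with bootstrap CIs for one cohort/model pairing."""

    c_index: float
    c_index_ci: tuple[float, float]
    D: float
    r2_d: float
    r2_d_ci: tuple[float, float]
    n_comparable_pairs: int
    reps: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "D": self.D,
            "r2_d": self.r2_d,
            "r2_d_ci": list(self.r2_d_ci),
            "n_comparable_pairs": self.n_comparable_pairs,
            "reps": self.reps,
            "seed": self.seed,
        }


def discrimination(times, events, prognostic_index, reps: int = 200,
                   seed: int = 0) -> DiscriminationResult:
    """Full discrimination report: c-index and R²_D with bootstrap CIs."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    pi = np.asarray(prognostic_index, dtype=float)
    data = pd.DataFrame({"time": t, "event": d, "pi": pi})

    c = harrells_c(t, d, pi)
    D = royston_sauerbrei_D(t, d, pi)
    # comparable-pair count, recomputed for the report
    ti, tj = t[:, None], t[None, :]
    comp = ((ti < tj) & (d[:, None] == 1)) | \
           ((ti == tj) & (d[:, None] == 1) & (d[None, :] == 0))
    np.fill_diagonal(comp, False)

    c_ci = bootstrap_ci(
        lambda b: harrells_c(b["time"], b["event"], b["pi"]),
        data, reps=reps, seed=seed)
    r2_ci = bootstrap_ci(
        lambda b: r2_from_D(royston_sauerbrei_D(b["time"], b["event"], b["pi"])),
        data, reps=reps, seed=seed + 1)
    return DiscriminationResult(
        c_index=c, c_index_ci=c_ci, D=D, r2_d=r2_from_D(D), r2_d_ci=r2_ci,
        n_comparable_pairs=int(comp.sum()), reps=reps, seed=seed)
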