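"""Evaluation of the published PROSASH survival model.

PROSASH predicts overall survival of patients with advanced hepatocellular
carcinoma treated with sorafenib, from nine baseline clinical features.  It is
a flexible parametric (Royston–Parmar) model: the log cumulative baseline
hazard is a restricted cubic spline in log time,

    log H0(t) = s(log t) = gamma0 + gamma1 * log t + sum_j gamma_{j+1} * z_j,

and an individual's survival is ``S(t) = S0(t) ** exp(eta)`` where ``eta`` is
the linear predictor (prognostic index) over the covariates.  Time is in
months and all logarithms are natural; the published spline reproduces the
printed baseline survival values only under this convention.

This module evaluates the *frozen* published model; re-estimation lives in
:mod:`prosash.flexpar`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "AETIOLOGIES",
    "ExtrapolationWarning",
    "NOT_REACHED",
    "PatientCovariates",
    "ProsashModel",
    "RestrictedCubicSplineLogTime",
    "RiskCutoffs",
    "SurvivalCurve",
    "baseline_survival",
    "cumulative_hazard",
    "linear_predictor",
    "load_published_model",
    "predict_batch",
    "predicted_median_survival",
    "risk_category",
    "spline_log_cum_hazard",
    "survival_curve",
    "survival_probability",
    "truncated_cube",
]

AETIOLOGIES = ("HCV", "HBV", "other")

#: Sentinel returned when the survival curve never crosses 50% before the
#: requested horizon (mirrors "median not reached" in survival tables).
NOT_REACHED = float("inf")


class ExtrapolationWarning(UserWarning):
    """Prediction requested beyond the follow-up range the model was fitted on."""


def truncated_cube(x: float, knot: float) -> float:
    """Truncated cubic ``max(0, x - knot) ** 3``, the spline building block."""
    d = x - knot
    return d * d * d if d > 0.0 else 0.0


@dataclass(frozen=True)
class RestrictedCubicSplineLogTime:
    """Restricted cubic spline on the log-time axis.

    The basis is linear beyond the boundary knots (the "restricted" part), so
    extrapolation in log time is linear — no extra damping is applied.

    Parameters
    ----------
    boundary_knots
        ``(k_min, k_max)`` on the log-months scale.
    internal_knots
        Ordered internal knots, strictly inside the boundary.
    gamma
        Coefficients ``(gamma_0, ..., gamma_{m+1})`` for the basis
        ``(1, log t, z_1, ..., z_m)`` with ``m`` internal knots.
    """

    boundary_knots: tuple[float, float]
    internal_knots: tuple[float, ...]
    gamma: tuple[float, ...]

    def __post_init__(self) -> None:
        k_min, k_max = self.boundary_knots
        if not k_min < k_max:
            raise ValueError("boundary knots must satisfy k_min < k_max")
        for k in self.internal_knots:
            if not (k_min < k < k_max):
                raise ValueError(f"internal knot {k} outside ({k_min}, {k_max})")
        if list(self.internal_knots) != sorted(self.internal_knots):
            raise ValueError("internal knots must be ordered")
        if len(self.gamma) != len(self.internal_knots) + 2:
            raise ValueError("need len(gamma) == number of internal knots + 2")

    @property
    def lambdas(self) -> np.ndarray:
        """Weights ``lambda_j = (k_max - k_j) / (k_max - k_min)``, in (0, 1)."""
        k_min, k_max = self.boundary_knots
        ks = np.asarray(self.internal_knots, dtype=float)
        return (k_max - ks) / (k_max - k_min)

    def basis(self, x) -> np.ndarray:
        """Design row(s) ``(1, x, z_1, ..., z_m)`` at log-time ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k_min, k_max = self.boundary_knots
        cols = [np.ones_like(x), x]
        for k_j, lam in zip(self.internal_knots, self.lambdas):
            z = (
                np.maximum(0.0, x - k_j) ** 3
                - lam * np.maximum(0.0, x - k_min) ** 3
                - (1.0 - lam) * np.maximum(0.0, x - k_max) ** 3
            )
            cols.append(z)
        return np.column_stack(cols)

    def basis_deriv(self, x) -> np.ndarray:
        """d/dx of :meth:`basis` — needed for the hazard in the fitted model."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        k_min, k_max = self.boundary_knots
        cols = [np.zeros_like(x), np.ones_like(x)]
        for k_j, lam in zip(self.internal_knots, self.lambdas):
            dz = 3.0 * (
                np.maximum(0.0, x - k_j) ** 2
                - lam * np.maximum(0.0, x - k_min) ** 2
                - (1.0 - lam) * np.maximum(0.0, x - k_max) ** 2
            )
            cols.append(dz)
        return np.column_stack(cols)

    def __call__(self, x) -> np.ndarray:
        """Evaluate ``s(x)`` at log-time ``x``."""
        return self.basis(x) @ np.asarray(self.gamma, dtype=float)


@dataclass(frozen=True)
class RiskCutoffs:
    """Thresholds on the prognostic index separating the four risk groups.

    Categories are closed above: ``eta <= cutoffs[0]`` is category 1,
    ``cutoffs[0] < eta <= cutoffs[1]`` category 2, and so on.
    """

    values: tuple[float, float, float]

    def __post_init__(self) -> None:
        a, b, c = self.values
        if not (a < b < c):
            raise ValueError("risk cutoffs must be strictly increasing")


@dataclass(frozen=True)
class PatientCovariates:
    """The nine PROSASH baseline predictors, in the units the model expects.

    ``afp`` (ng/ml), ``creatinine`` (µmol/L) and ``ast`` (U/L) are
    log-transformed downstream and must be strictly positive.  Fields the
    final model does not use (sex, bilirubin, INR, tumour burden, ...) are
    deliberately absent: pass them around in your DataFrame, not here.
    """

    age: float                    # years
    vascular_invasion: bool
    ecog: int                     # 0 or 1
    afp: float                    # ng/ml
    albumin: float                # g/l
    creatinine: float             # umol/L
    ast: float                    # U/L
    ehs: bool                     # extra-hepatic spread
    aetiology: str                # "HCV" | "HBV" | "other"

    def __post_init__(self) -> None:
        if not 18.0 <= self.age <= 100.0:
            raise ValueError(f"age {self.age} outside plausible range [18, 100]")
        if self.ecog not in (0, 1):
            raise ValueError("ecog must be 0 or 1")
        if self.aetiology not in AETIOLOGIES:
            raise ValueError(f"aetiology must be one of {AETIOLOGIES}")
        for name in ("afp", "creatinine", "ast"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be strictly positive (got {v}); "
                                 "it is log-transformed by the model")


@dataclass(frozen=True)
class SurvivalCurve:
    """An ordered grid of (time in months, survival probability) pairs."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must align")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ProsashModel:
    """A frozen PROSASH-style model: coefficients, spline baseline, cutoffs."""

    coefficients: dict[str, float]
    spline: RestrictedCubicSplineLogTime
    cutoffs: RiskCutoffs
    age_center: float = 60.0
    version: str = "unversioned"
    follow_up_horizon: float = 31.28
    units: dict[str, str] = field(default_factory=dict)

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "ProsashModel":
        sp = doc["spline"]
        return cls(
            coefficients=dict(doc["coefficients"]),
            spline=RestrictedCubicSplineLogTime(
                boundary_knots=tuple(sp["boundary_knots"]),
                internal_knots=tuple(sp.get("internal_knots", ())),
                gamma=tuple(sp["gamma"]),
            ),
            cutoffs=RiskCutoffs(tuple(doc["risk_cutoffs"])),
            age_center=float(doc.get("age_center", 60.0)),
            version=doc.get("version", "unversioned"),
            follow_up_horizon=float(doc.get("follow_up_horizon_months", 31.28)),
            units=dict(doc.get("units", {})),
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "age_center": self.age_center,
            "coefficients": dict(self.coefficients),
            "spline": {
                "boundary_knots": list(self.spline.boundary_knots),
                "internal_knots": list(self.spline.internal_knots),
                "gamma": list(self.spline.gamma),
            },
            "risk_cutoffs": list(self.cutoffs.values),
            "follow_up_horizon_months": self.follow_up_horizon,
            "units": dict(self.units),
        }

    @classmethod
    def from_json(cls, path) -> "ProsashModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_published_model() -> ProsashModel:
    """The published model constants, read from the versioned JSON asset."""
    doc = json.loads(
        resources.files("prosash.data").joinpath("published_model.json").read_text()
    )
    return ProsashModel.from_dict(doc)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _check_time(t: float) -> None:
    if not t > 0.0:
        raise ValueError(f"time must be positive (got {t}); the spline lives on log t")


def spline_log_cum_hazard(t: float, spline: RestrictedCubicSplineLogTime) -> float:
    """``s(log t)``, the log cumulative baseline hazard at ``t`` months."""
    _check_time(t)
    return float(spline(math.log(t))[0])


def baseline_survival(t: float, spline: RestrictedCubicSplineLogTime) -> float:
    """``S0(t) = exp(-exp(s(log t)))``."""
    return math.exp(-math.exp(spline_log_cum_hazard(t, spline)))


def linear_predictor(cov: PatientCovariates, model: ProsashModel) -> float:
    """The prognostic index ``eta`` on the log relative-hazard scale.

    Age is centred at ``model.age_center`` years; AFP, creatinine and AST
    enter on the natural-log scale; the age term changes slope under vascular
    invasion through the interaction coefficient; HCV is the reference
    aetiology (coefficient 0).
    """
    b = model.coefficients
    vi = 1.0 if cov.vascular_invasion else 0.0
    age_c = cov.age - model.age_center
    eta = (
        b["vascular_invasion"] * vi
        + b["age_centered"] * age_c
        + b["age_x_vi"] * age_c * vi
        + b["ecog1"] * cov.ecog
        + b["ln_afp"] * math.log(cov.afp)
        + b["albumin"] * cov.albumin
        + b["ln_creatinine"] * math.log(cov.creatinine)
        + b["ln_ast"] * math.log(cov.ast)
        + b["ehs"] * (1.0 if cov.ehs else 0.0)
    )
    if cov.aetiology == "HBV":
        eta += b["hbv"]
    elif cov.aetiology == "other":
        eta += b["other_aetiology"]
    return eta


def cumulative_hazard(cov: PatientCovariates, t: float, model: ProsashModel) -> float:
    """``H(t) = exp(s(log t) + eta) = -log S(t)``."""
    return math.exp(spline_log_cum_hazard(t, model.spline)
                    + linear_predictor(cov, model))


def survival_probability(cov: PatientCovariates, t: float,
                         model: ProsashModel) -> float:
    """Individual survival ``S(t) = S0(t) ** exp(eta)``."""
    if t > model.follow_up_horizon:
        warnings.warn(
            f"prediction at t={t:g} months is beyond the {model.follow_up_horizon:g}"
            "-month follow-up range the model was built on (linear log-time "
            "extrapolation)", ExtrapolationWarning, stacklevel=2)
    return math.exp(-cumulative_hazard(cov, t, model))


def risk_category(eta: float, cutoffs: RiskCutoffs) -> int:
    """Risk group 1-4 by the closed-above cutoff intervals."""
    a, b, c = cutoffs.values
    if eta <= a:
        return 1
    if eta <= b:
        return 2
    if eta <= c:
        return 3
    return 4


def survival_curve(cov: PatientCovariates, model: ProsashModel,
                   grid: Sequence[float]) -> SurvivalCurve:
    """Pointwise individual survival on an ascending positive time grid."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size and (np.any(grid <= 0) or np.any(np.diff(grid) < 0)):
        raise ValueError("time grid must be positive and ascending")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        s = np.array([survival_probability(cov, t, model) for t in grid])
    return SurvivalCurve(times=grid, survival=s)


def predicted_median_survival(cov: PatientCovariates, model: ProsashModel,
                              horizon: float = 31.28) -> float:
    """Smallest ``t`` with ``S(t) <= 0.5``, or :data:`NOT_REACHED`.

    Root-finding is done on log time, where ``-log S`` is monotone increasing,
    so the solution is unique when it exists within the horizon.
    """
    if not horizon > 0.0:
        raise ValueError("horizon must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        if survival_probability(cov, horizon, model) > 0.5:
            return NOT_REACHED
        eta = linear_predictor(cov, model)
        target = math.log(math.log(2.0)) - eta  # s(log t) at the median

        def f(x: float) -> float:
            return float(model.spline(x)[0]) - target

        lo = math.log(horizon)
        # bracket downward; s is increasing in x wherever the hazard is valid
        hi = lo
        lo = lo - 1.0
        while f(lo) > 0.0:
            lo -= 1.0
            if lo < -60.0:  # pragma: no cover - pathological spline
                return math.exp(-60.0)
        return math.exp(brentq(f, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# batch interface
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("age", "vascular_invasion", "ecog", "afp", "albumin",
                "creatinine", "ast", "ehs", "aetiology")


def linear_predictor_batch(df: pd.DataFrame, model: ProsashModel) -> np.ndarray:
    """Vectorised ``eta`` over a DataFrame with the canonical covariate columns."""
    b = model.coefficients
    for name in ("afp", "creatinine", "ast"):
        if not np.all(df[name].to_numpy(dtype=float) > 0):
            raise ValueError(f"{name} must be strictly positive for the log "
                             "transform")
    vi = df["vascular_invasion"].to_numpy(dtype=float)
    age_c = df["age"].to_numpy(dtype=float) - model.age_center
    aet = np.asarray(df["aetiology"], dtype=object)
    eta = (
        b["vascular_invasion"] * vi
        + b["age_centered"] * age_c
        + b["age_x_vi"] * age_c * vi
        + b["ecog1"] * df["ecog"].to_numpy(dtype=float)
        + b["ln_afp"] * np.log(df["afp"].to_numpy(dtype=float))
        + b["albumin"] * df["albumin"].to_numpy(dtype=float)
        + b["ln_creatinine"] * np.log(df["creatinine"].to_numpy(dtype=float))
        + b["ln_ast"] * np.log(df["ast"].to_numpy(dtype=float))
        + b["ehs"] * df["ehs"].to_numpy(dtype=float)
        + b["hbv"] * (aet == "HBV")
        + b["other_aetiology"] * (aet == "other")
    )
    return eta


def survival_from_eta(eta: np.ndarray, t: float, model: ProsashModel) -> np.ndarray:
    """``S(t)`` for an array of prognostic-index values at a single time."""
    h0 = math.exp(spline_log_cum_hazard(t, model.spline))
    return np.exp(-h0 * np.exp(np.asarray(eta, dtype=float)))


def covariates_from_row(row: pd.Series) -> PatientCovariates:
    """Build :class:`PatientCovariates` from a CSV row with canonical columns."""
    return PatientCovariates(
        age=float(row["age"]),
        vascular_invasion=bool(int(row["vascular_invasion"])),
        ecog=int(row["ecog"]),
        afp=float(row["afp"]),
        albumin=float(row["albumin"]),
        creatinine=float(row["creatinine"]),
        ast=float(row["ast"]),
        ehs=bool(int(row["ehs"])),
        aetiology=str(row["aetiology"]),
    )


def predict_batch(df: pd.DataFrame, model: ProsashModel,
                  times: Iterable[float] = (3, 6, 12, 18, 24),
                  horizon: float = 31.28) -> pd.DataFrame:
    """Per-row eta, risk category, S(t) at requested months, predicted median.

    Raises ``ValueError`` naming the row and field on invalid input.
    """
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    times = list(times)
    records = []
    for idx, row in df.iterrows():
        try:
            cov = covariates_from_row(row)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        eta = linear_predictor(cov, model)
        rec = {"eta": eta, "risk_category": risk_category(eta, model.cutoffs)}
        for t in times:
            rec[f"S_{t:g}m"] = survival_curve(cov, model, [t]).survival[0]
        med = predicted_median_survival(cov, model, horizon=horizon)
        rec["predicted_median_months"] = np.nan if med == NOT_REACHED else med
        records.append(rec)
    out = pd.DataFrame.from_records(records, index=df.index)
    return out
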