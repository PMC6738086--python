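"""Maximum-likelihood fitting of flexible parametric survival models.

The model class is the Royston–Parmar spline model on the log cumulative
hazard scale: with ``x = log t``,

    log H(t | x_i) = s(x; gamma) + x_i' beta,

where ``s`` is a restricted cubic spline.  With no internal knots (one spline
degree of freedom) this is exactly a Weibull model; each extra knot buys the
baseline more flexibility.  The hazard is

    h(t) = s'(x) / t * exp(s(x) + x_i' beta),

so the log likelihood over right-censored data ``(t_i, d_i)`` is

    sum_i d_i [log s'(x_i) - log t_i + s(x_i) + eta_i] - exp(s(x_i) + eta_i).

``s'`` must be positive at every event time for the hazard to be valid; the
optimiser treats violations as -inf likelihood (soft rejection) rather than
imposing constraints.

Alongside the fitter this module provides the model-building machinery used
to develop prognostic models of this kind: spline degrees-of-freedom
selection and backward covariate elimination by likelihood-ratio testing,
time-dependent-effect tests, and Martingale-residual functional-form checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_core import ProsashModel, RestrictedCubicSplineLogTime, RiskCutoffs

__all__ = [
    "FitError",
    "FittedFlexParModel",
    "FlexParSpec",
    "backward_select",
    "expand_terms",
    "fit",
    "functional_form_check",
    "hazard_ratios",
    "log_likelihood",
    "lr_test",
    "martingale_residuals",
    "place_knots",
    "prosash_design_frame",
    "select_df",
    "test_td_effect",
    "validate_survival_data",
]


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (degenerate data, non-convergence)."""


def validate_survival_data(df: pd.DataFrame,
                           covariates: Sequence[str] = ()) -> None:
    """Check the (time, event, covariates) invariants for fitting."""
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival data needs a '{col}' column")
    if not np.all(df["time"].to_numpy() > 0):
        raise ValueError("all survival times must be strictly positive")
    if not set(np.unique(df["event"])) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    if int(df["event"].sum()) < 1:
        raise FitError("cannot fit a survival model to data with zero events")
    cols = ["time", "event", *covariates]
    if df[cols].isna().any().any():
        raise ValueError("missing values present; apply complete-case filtering "
                         "before fitting")


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

def expand_terms(df: pd.DataFrame, covariates: Sequence[str]
                 ) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Expand covariate terms into a numeric design matrix.

    Categorical / object columns are dummy-coded against the first level
    (category order for Categorical dtype, order of first appearance
    otherwise); each source term maps to its block of design columns so
    selection procedures can drop multi-level factors whole.

    Returns (matrix, column names, term -> column-name block).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: dict[str, list[str]] = {}
    for term in covariates:
        if term not in df.columns:
            raise ValueError(f"covariate '{term}' not in data")
        s = df[term]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            if isinstance(s.dtype, pd.CategoricalDtype):
                levels = list(s.cat.categories)
            else:
                levels = list(pd.unique(s))
            block = []
            for lev in levels[1:]:
                name = f"{term}[{lev}]"
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(name)
                block.append(name)
            blocks[term] = block
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
            blocks[term] = [term]
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, blocks


def prosash_design_frame(df: pd.DataFrame, age_center: float = 60.0
                         ) -> pd.DataFrame:
    """Derive the canonical PROSASH model terms from raw covariate columns.

    Produces ``age_centered``, natural-log transforms of AFP / creatinine /
    AST, the age-by-vascular-invasion interaction, and keeps ``aetiology`` as
    an ordered categorical with HCV as reference.  ``time`` / ``event``
    columns are carried through when present.
    """
    out = pd.DataFrame(index=df.index)
    for col in ("time", "event"):
        if col in df.columns:
            out[col] = df[col]
    out["vascular_invasion"] = df["vascular_invasion"].astype(float)
    out["age_centered"] = df["age"].astype(float) - age_center
    out["age_x_vi"] = out["age_centered"] * out["vascular_invasion"]
    out["ecog1"] = df["ecog"].astype(float)
    out["ln_afp"] = np.log(df["afp"].astype(float))
    out["albumin"] = df["albumin"].astype(float)
    out["ln_creatinine"] = np.log(df["creatinine"].astype(float))
    out["ln_ast"] = np.log(df["ast"].astype(float))
    out["ehs"] = df["ehs"].astype(float)
    out["aetiology"] = pd.Categorical(df["aetiology"],
                                      categories=["HCV", "HBV", "other"])
    return out


PROSASH_TERMS = ["vascular_invasion", "age_centered", "age_x_vi", "ecog1",
                 "ln_afp", "albumin", "ln_creatinine", "ln_ast", "ehs",
                 "aetiology"]

# design-column -> published-coefficient naming
_PUBLISHED_NAMES = {"aetiology[HBV]": "hbv", "aetiology[other]": "other_aetiology"}


# ---------------------------------------------------------------------------
# knots and likelihood
# ---------------------------------------------------------------------------

def place_knots(times: np.ndarray, events: np.ndarray, df: int
                ) -> RestrictedCubicSplineLogTime:
    """Knot positions for a ``df``-degree spline baseline.

    Boundary knots sit at the min and max of the log *event* times; the
    ``df - 1`` internal knots at equally spaced centiles of the log event
    times (df=2: the median; df=3: the 33rd/67th centiles).  Returns a spline
    with placeholder coefficients (slope one), to be estimated.
    """
    if df < 1:
        raise ValueError("spline degrees of freedom must be >= 1")
    log_ev = np.log(np.asarray(times, dtype=float)[np.asarray(events) == 1])
    if len(np.unique(log_ev)) < df + 1:
        raise FitError(f"need at least {df + 1} distinct event times for df={df}")
    k_min, k_max = float(log_ev.min()), float(log_ev.max())
    if df == 1:
        internal: tuple[float, ...] = ()
    else:
        qs = np.linspace(0, 100, df + 1)[1:-1]
        internal = tuple(float(v) for v in np.percentile(log_ev, qs))
    gamma = (0.0, 1.0) + (0.0,) * len(internal)
    return RestrictedCubicSplineLogTime((k_min, k_max), internal, gamma)


@dataclass
class FlexParSpec:
    """What to fit: spline flexibility, covariates, time-dependent terms."""

    df: int = 2
    covariates: Sequence[str] = ()
    td_covariates: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        extra = set(self.td_covariates) - set(self.covariates)
        if extra:
            raise ValueError(f"time-dependent terms not among covariates: {extra}")


class _Likelihood:
    """Precomputed design for the spline log-cumulative-hazard likelihood.

    Parameter vector theta = (gamma_0..gamma_df, beta..., td-coefs...).
    ``V`` holds the value of each term at the subject's own log time, ``D``
    its derivative with respect to log time (zero for proportional covariate
    columns, the spline-basis derivative for gamma and TD columns).
    """

    def __init__(self, times, events, X, x_names,
                 spline: RestrictedCubicSplineLogTime,
                 td_cols: Mapping[str, np.ndarray] | None = None):
        t = np.asarray(times, dtype=float)
        self.d = np.asarray(events, dtype=float)
        x = np.log(t)
        self.log_t = x
        B = spline.basis(x)          # n x (df+1)
        dB = spline.basis_deriv(x)
        V = [B]
        D = [dB]
        names = [f"gamma{k}" for k in range(B.shape[1])]
        if X.shape[1]:
            V.append(np.asarray(X, dtype=float))
            D.append(np.zeros_like(X, dtype=float))
            names.extend(x_names)
        for cname, cvals in (td_cols or {}).items():
            c = np.asarray(cvals, dtype=float)[:, None]
            V.append(c * B[:, 1:])       # interactions with non-constant basis
            D.append(c * dB[:, 1:])
            names.extend(f"{cname}:t{k}" for k in range(1, B.shape[1]))
        self.V = np.hstack(V)
        self.D = np.hstack(D)
        self.names = names
        self.n_params = self.V.shape[1]
        self._const = -float(self.d @ x)   # -sum_i d_i log t_i

    def loglik(self, theta: np.ndarray) -> float:
        sprime = self.D @ theta
        ev = self.d == 1
        if np.any(sprime[ev] <= 0):
            return -np.inf
        logH = self.V @ theta
        with np.errstate(over="ignore"):
            H = np.exp(logH)
        if not np.all(np.isfinite(H)):
            return -np.inf
        return float(self.d[ev] @ (np.log(sprime[ev]) + logH[ev])
                     + self._const - H.sum())

    def grad(self, theta: np.ndarray) -> np.ndarray:
        sprime = self.D @ theta
        logH = self.V @ theta
        H = np.exp(logH)
        ev = self.d == 1
        g = (self.D[ev] / sprime[ev, None]).sum(axis=0)
        g += self.V[ev].sum(axis=0)
        g -= H @ self.V
        return g

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        sprime = self.D @ theta
        H = np.exp(self.V @ theta)
        ev = self.d == 1
        Dev = self.D[ev] / sprime[ev, None]
        return -(Dev.T @ Dev) - (self.V * H[:, None]).T @ self.V


def log_likelihood(gamma: Sequence[float], beta: Sequence[float],
                   data: pd.DataFrame, spline: RestrictedCubicSplineLogTime,
                   covariates: Sequence[str] = ()) -> float:
    """Log likelihood at given spline/covariate coefficients.

    Returns ``-inf`` (not an exception) when the fitted log cumulative hazard
    is decreasing at an event time, so optimisers can retreat.
    """
    X, names, _ = expand_terms(data, covariates)
    lik = _Likelihood(data["time"].to_numpy(), data["event"].to_numpy(),
                      X, names, spline)
    theta = np.concatenate([np.asarray(gamma, float), np.asarray(beta, float)])
    return lik.loglik(theta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedFlexParModel:
    """A fitted spline survival model with its covariance and fit record."""

    spline: RestrictedCubicSplineLogTime
    beta: dict[str, float]
    param_names: list[str]
    params: np.ndarray
    covariance: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_iter: int
    grad_norm: float
    spec: FlexParSpec
    term_blocks: dict[str, list[str]] = field(default_factory=dict)
    removal_order: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        """eta for each row of ``data`` under the proportional part of the fit."""
        X, names, _ = expand_terms(data, self.spec.covariates)
        b = np.array([self.beta[n] for n in names])
        return X @ b

    def cumulative_hazard(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted H(t_i) at each subject's own observed time."""
        x = np.log(data["time"].to_numpy(dtype=float))
        logH = self.spline(x) + self.linear_predictor(data)
        if self.spec.td_covariates:
            B = self.spline.basis(x)
            for cname in self.spec.td_covariates:
                c = data[cname].to_numpy(dtype=float)
                for k in range(1, B.shape[1]):
                    logH += self.beta[f"{cname}:t{k}"] * c * B[:, k]
        return np.exp(logH)

    def to_prosash_model(self, cutoffs: Sequence[float],
                         version: str = "refit",
                         age_center: float = 60.0) -> ProsashModel:
        """Package the fit in the frozen-model JSON schema.

        Only valid for proportional-hazards fits on the canonical PROSASH
        design columns; dummy columns are renamed to the published scheme.
        """
        if self.spec.td_covariates:
            raise ValueError("cannot freeze a model with time-dependent effects")
        coeffs = {_PUBLISHED_NAMES.get(k, k): v for k, v in self.beta.items()}
        return ProsashModel(
            coefficients=coeffs,
            spline=self.spline,
            cutoffs=RiskCutoffs(tuple(cutoffs)),
            age_center=age_center,
            version=version,
        )

    def fit_report(self) -> dict:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "n_params": self.n_params,
            "iterations": self.n_iter,
            "grad_norm": self.grad_norm,
            "removal_order": list(self.removal_order),
            "params": dict(zip(self.param_names, self.params.tolist())),
        }


def _init_gamma(times, events, spline: RestrictedCubicSplineLogTime) -> np.ndarray:
    """Seed gamma by regressing log(-log KM) on the spline basis at event times."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(times, events)
    ev_times = np.unique(np.asarray(times)[np.asarray(events) == 1])
    S = km.survival_function_at_times(ev_times).to_numpy()
    keep = (S > 1e-8) & (S < 1 - 1e-8)
    x = np.log(ev_times[keep])
    y = np.log(-np.log(S[keep]))
    B = spline.basis(x)
    if len(y) >= B.shape[1]:
        g, *_ = np.linalg.lstsq(B, y, rcond=None)
        # ensure a strictly increasing start for the optimiser
        if np.all(spline.basis_deriv(x) @ g > 0):
            return g
    g = np.zeros(B.shape[1])
    g[0], g[1] = (np.median(y) - np.median(x)) if len(y) else -1.0, 1.0
    return g


def fit(data: pd.DataFrame, spec: FlexParSpec) -> FittedFlexParModel:
    """Fit by maximum likelihood (quasi-Newton with analytic gradient).

    The covariance is the inverse observed information at the optimum.
    Raises :class:`FitError` with the gradient norm on non-convergence.
    """
    validate_survival_data(data, spec.covariates)
    t = data["time"].to_numpy(dtype=float)
    d = data["event"].to_numpy()
    spline0 = place_knots(t, d, spec.df)
    X, x_names, blocks = expand_terms(data, spec.covariates)
    td_cols = {}
    for cname in spec.td_covariates:
        td_cols[cname] = data[cname].to_numpy(dtype=float)
    lik = _Likelihood(t, d, X, x_names, spline0, td_cols)

    theta0 = np.zeros(lik.n_params)
    g0 = _init_gamma(t, d, spline0)
    theta0[: len(g0)] = g0

    def nll(th):
        v = lik.loglik(th)
        return 1e12 if not np.isfinite(v) else -v

    def ngrad(th):
        if not np.isfinite(lik.loglik(th)):
            return np.zeros_like(th)  # inside the penalty plateau
        return -lik.grad(th)

    res = optimize.minimize(nll, theta0, jac=ngrad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    theta = res.x
    n_iter = int(res.nit)
    # Newton polish with the analytic Hessian
    for _ in range(50):
        g = lik.grad(theta)
        if np.max(np.abs(g)) < 1e-6:
            break
        Hm = lik.hessian(theta)
        try:
            step = np.linalg.solve(Hm, -g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        base = lik.loglik(theta)
        while scale > 1e-6 and lik.loglik(theta + scale * step) < base:
            scale *= 0.5
        if scale <= 1e-6:
            break
        theta = theta + scale * step
        n_iter += 1
    grad_norm = float(np.max(np.abs(lik.grad(theta))))
    ll = lik.loglik(theta)
    if not np.isfinite(ll) or grad_norm > 1e-4:
        raise FitError(f"optimiser did not converge: |grad|_inf={grad_norm:.3g} "
                       f"after {n_iter} iterations")

    info = -lik.hessian(theta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("observed information is singular") from exc
    cov = (cov + cov.T) / 2.0

    n_gamma = spec.df + 1
    spline = RestrictedCubicSplineLogTime(
        spline0.boundary_knots, spline0.internal_knots,
        tuple(float(v) for v in theta[:n_gamma]))
    beta = dict(zip(lik.names[n_gamma:], (float(v) for v in theta[n_gamma:])))
    return FittedFlexParModel(
        spline=spline, beta=beta, param_names=lik.names, params=theta,
        covariance=cov, loglik=float(ll), n=len(t), n_events=int(d.sum()),
        n_iter=n_iter, grad_norm=grad_norm, spec=spec, term_blocks=blocks)


# ---------------------------------------------------------------------------
# model building
# ---------------------------------------------------------------------------

def lr_test(nested: FittedFlexParModel, full: FittedFlexParModel) -> float:
    """Likelihood-ratio p-value of the nested model against the full one."""
    k = full.n_params - nested.n_params
    if k < 0 or full.n != nested.n:
        raise ValueError("models are not nested on the same data")
    if k == 0:
        return 1.0
    lr = max(0.0, 2.0 * (full.loglik - nested.loglik))
    return float(stats.chi2.sf(lr, k))


def select_df(data: pd.DataFrame, candidate_dfs: Sequence[int],
              covariates: Sequence[str] = (), alpha: float = 0.05) -> int:
    """Smallest spline df not rejected against the next larger candidate.

    Sequential likelihood-ratio comparison at level ``alpha``; ties break
    toward the smaller df (parsimony).
    """
    cands = sorted(set(candidate_dfs))
    if not cands:
        raise ValueError("need at least one candidate df")
    if len(cands) == 1:
        return cands[0]
    fits = {k: fit(data, FlexParSpec(df=k, covariates=covariates))
            for k in cands}
    for small, big in zip(cands, cands[1:]):
        if lr_test(fits[small], fits[big]) > alpha:
            return small
    return cands[-1]


def backward_select(data: pd.DataFrame, covariates: Sequence[str],
                    alpha: float = 0.05, df: int = 2) -> FittedFlexParModel:
    """Stepwise backward elimination by likelihood-ratio p-values.

    Removes one term per iteration — the one with the largest p-value above
    ``alpha`` — refitting each time; multi-level factors leave as blocks.
    Deterministic given the input column order.  The fitted model records the
    removal order.
    """
    current = list(covariates)
    removed: list[str] = []
    model = fit(data, FlexParSpec(df=df, covariates=current))
    while current:
        pvals = {}
        for term in current:
            reduced = fit(data, FlexParSpec(
                df=df, covariates=[c for c in current if c != term]))
            pvals[term] = lr_test(reduced, model)
        worst = max(current, key=lambda c: pvals[c])  # first-listed wins ties
        if pvals[worst] <= alpha:
            break
        current.remove(worst)
        removed.append(worst)
        model = fit(data, FlexParSpec(df=df, covariates=current))
    model.removal_order = removed
    return model


def test_td_effect(model: FittedFlexParModel, data: pd.DataFrame,
                   covariate: str) -> float:
    """LR test for a time-dependent effect of one model covariate.

    Augments the fit with interactions between the covariate and the
    non-constant spline basis functions and compares against the
    proportional-hazards fit.
    """
    if covariate not in model.spec.covariates:
        raise ValueError(f"'{covariate}' is not in the fitted model")
    if covariate in model.term_blocks and len(model.term_blocks[covariate]) > 1:
        raise NotImplementedError("TD tests for multi-level factors are not "
                                  "supported; test the dummy columns instead")
    aug = fit(data, FlexParSpec(df=model.spec.df,
                                covariates=model.spec.covariates,
                                td_covariates=[covariate]))
    return lr_test(model, aug)


def martingale_residuals(model: FittedFlexParModel,
                         data: pd.DataFrame) -> np.ndarray:
    """``r_i = d_i - H_hat(t_i)``; sums to ~0 at the MLE for the null model."""
    return data["event"].to_numpy(dtype=float) - model.cumulative_hazard(data)


def functional_form_check(residuals: np.ndarray, covariate_values: np.ndarray
                          ) -> tuple[float, bool]:
    """Least-squares slope of residuals on a covariate, and a misfit flag.

    A slope more than two standard errors from zero flags a mis-specified
    functional form for that covariate.
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    if len(r) != len(x):
        raise ValueError("residuals and covariate must have equal length")
    if len(r) < 3 or np.ptp(x) == 0.0:
        raise ValueError("need >= 3 observations and a non-constant covariate")
    res = stats.linregress(x, r)
    flag = bool(res.stderr > 0 and abs(res.slope) / res.stderr > 2.0)
    return float(res.slope), flag


def hazard_ratios(model: FittedFlexParModel) -> pd.DataFrame:
    """exp(beta) with Wald 95% CIs and two-sided normal p-values per term."""
    rows = []
    n_gamma = model.spec.df + 1
    for i, name in enumerate(model.param_names):
        if i < n_gamma:
            continue
        b = model.params[i]
        se = math.sqrt(model.covariance[i, i])
        z = b / se if se > 0 else np.inf
        rows.append({
            "term": name,
            "coef": b,
            "se": se,
            "hr": math.exp(b),
            "hr_lower": math.exp(b - 1.959963984540054 * se),
            "hr_upper": math.exp(b + 1.959963984540054 * se),
            "p": 2.0 * stats.norm.sf(abs(z)),
        })
    return pd.DataFrame(rows).set_index("term")
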