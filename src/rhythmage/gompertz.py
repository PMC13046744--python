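"""Gompertz proportional-hazards models and the rhythm-based biological age.

Biological age (BA) is defined by equating the predicted cumulative mortality
hazard at a fixed horizon (default 5 years) under a Gompertz PH model with
rest-activity rhythm covariates (MESOR, amplitude, acrophase) plus
chronological age, to the hazard of an age-only Gompertz model, and solving
for age.  Age acceleration AA = BA - CA; AA > 0 is "accelerated".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "GompertzPH",
    "gompertz_loglik",
    "fit_gompertz_ph",
    "cosinor_age",
    "estimate_cosinor_age",
    "stratify_age_acceleration",
]

_A_EPS = 1e-8  # |a| below this uses the exponential-limit branch


def _cumhaz_base(a: float, t: np.ndarray) -> np.ndarray:
    """(e^{a t} - 1)/a, with the a -> 0 limit t."""
    t = np.asarray(t, dtype=float)
    if abs(a) < _A_EPS:
        return t * (1.0 + a * t / 2.0)
    return np.expm1(a * t) / a


@dataclass
class GompertzPH:
    """h(t | x) = b * exp(a t) * exp(x' beta)."""

    a: float
    ln_b: float
    coeffs: np.ndarray
    covariate_names: List[str]
    horizon: float = 5.0
    sex: str = "all"
    converged: bool = True
    loglik: float = np.nan

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != len(self.covariate_names):
            raise ValueError("coefficient vector does not match covariate names")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def b(self) -> float:
        return float(np.exp(self.ln_b))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coeffs

    def cumulative_hazard(self, t, X) -> np.ndarray:
        eta = self.linear_predictor(X)
        return self.b * _cumhaz_base(self.a, t) * np.exp(eta)

    def risk(self, t, X) -> np.ndarray:
        """P(T <= t | x)."""
        return 1.0 - np.exp(-self.cumulative_hazard(t, X))

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "ln_b": self.ln_b,
            "coeffs": dict(zip(self.covariate_names, self.coeffs.tolist())),
            "horizon": self.horizon,
            "sex": self.sex,
        }


def gompertz_loglik(
    theta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Censored log-likelihood at theta = (ln_b, a, beta...).

    l = sum_i d_i (ln b + a t_i + eta_i) - sum_i (b/a)(e^{a t_i} - 1) e^{eta_i}
    """
    ln_b, a = theta[0], theta[1]
    beta = theta[2:]
    eta = X @ beta
    b = np.exp(ln_b)
    base = _cumhaz_base(a, time)
    return float(
        (event * (ln_b + a * time + eta)).sum() - (b * base * np.exp(eta)).sum()
    )


def _neg_loglik_grad(theta, X, time, event, with_hess=False):
    ln_b, a = theta[0], theta[1]
    beta = theta[2:]
    eta = X @ beta
    b = np.exp(ln_b)
    if abs(a) < _A_EPS:
        base = time * (1.0 + a * time / 2.0)
        dbase = time**2 / 2.0 + a * time**3 / 3.0
        d2base = time**3 / 3.0
    else:
        e_at = np.exp(a * time)
        base = (e_at - 1.0) / a
        dbase = (time * e_at - base) / a
        d2base = (time**2 * e_at - 2.0 * dbase) / a
    w = b * base * np.exp(eta)
    v = b * np.exp(eta) * dbase
    ll = (event * (ln_b + a * time + eta)).sum() - w.sum()
    g_lnb = event.sum() - w.sum()
    g_a = (event * time).sum() - v.sum()
    g_beta = X.T @ (event - w)
    grad = np.concatenate([[g_lnb, g_a], g_beta])
    if not with_hess:
        return -ll, -grad
    p = X.shape[1]
    H = np.zeros((p + 2, p + 2))
    H[0, 0] = w.sum()
    H[0, 1] = H[1, 0] = v.sum()
    H[1, 1] = (b * np.exp(eta) * d2base).sum()
    H[0, 2:] = H[2:, 0] = X.T @ w
    H[1, 2:] = H[2:, 1] = X.T @ v
    H[2:, 2:] = X.T @ (w[:, None] * X)
    return -ll, -grad, H


def fit_gompertz_ph(
    covariates: pd.DataFrame | np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = 5.0,
    sex: str = "all",
    fix_a: Optional[float] = None,
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> GompertzPH:
    """Maximum-likelihood Gompertz PH fit, parameterised as (ln b, a, beta).

    ``fix_a`` pins the shape (fix_a=0 gives the exponential model, and is how
    a shape shared across two fits can be imposed).
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0.0, 1.0]).all():
        raise ValueError("event must be 0/1")
    if event.sum() < 1:
        raise ValueError("no events: Gompertz PH model is not estimable")

    d = event.sum()
    theta0 = np.concatenate([[np.log(d / time.sum()), 0.05], np.zeros(X.shape[1])])

    free = np.ones(theta0.size, dtype=bool)
    if fix_a is not None:
        theta0[1] = fix_a
        free[1] = False

    # BFGS to the neighbourhood, then Newton with the analytic Hessian
    def fun(th_free):
        full = theta0.copy()
        full[free] = th_free
        nll, g = _neg_loglik_grad(full, X, time, event)
        return nll, g[free]

    res = minimize(fun, theta0[free], jac=True, method="BFGS",
                   options={"gtol": 1e-5, "maxiter": max_iter})
    theta = theta0.copy()
    theta[free] = res.x

    nll, g, H = _neg_loglik_grad(theta, X, time, event, with_hess=True)
    for _ in range(50):
        if np.abs(g[free]).max() < gtol:
            break
        Hf = H[np.ix_(free, free)]
        try:
            step = np.linalg.solve(Hf, g[free])
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            trial = theta.copy()
            trial[free] = theta[free] - scale * step
            nll_t, g_t, H_t = _neg_loglik_grad(trial, X, time, event, with_hess=True)
            if np.isfinite(nll_t) and nll_t <= nll + 1e-12:
                theta, nll, g, H = trial, nll_t, g_t, H_t
                break
            scale /= 2.0
        else:
            break
    gnorm = np.abs(g[free]).max() if free.any() else 0.0

    if gnorm > 1e-4:
        raise RuntimeError(
            f"Gompertz PH fit did not converge: max|grad| = {gnorm:.3g}"
        )
    return GompertzPH(
        a=float(theta[1]), ln_b=float(theta[0]), coeffs=theta[2:],
        covariate_names=names, horizon=horizon, sex=sex,
        converged=bool(gnorm <= gtol * 10),
        loglik=-float(nll),
    )


def _ln_base(a: float, t: float) -> float:
    return float(np.log(_cumhaz_base(a, np.array([t]))[0]))


def cosinor_age(
    full: GompertzPH,
    age_only: GompertzPH,
    covariates: pd.DataFrame,
    age_col: str = "age",
) -> pd.DataFrame:
    """Solve H_full(t*; subject) = H_age_only(t*; BA) analytically for BA.

    BA = [ln b_f + ln((e^{a_f t*}-1)/a_f) + eta_full
          - ln b_o - ln((e^{a_o t*}-1)/a_o)] / gamma_age
    where gamma_age is the age coefficient of the age-only model.
    """
    if full.horizon != age_only.horizon:
        raise ValueError("models must share the risk horizon")
    if age_only.covariate_names != [age_col]:
        raise ValueError("age-only model must have the single covariate "
                         f"'{age_col}'")
    gamma = float(age_only.coeffs[0])
    if gamma <= 0:
        raise ValueError("age coefficient of the age-only model must be positive")
    t = full.horizon
    X = covariates[full.covariate_names].to_numpy(dtype=float)
    eta_full = full.linear_predictor(X)
    const = (
        full.ln_b + _ln_base(full.a, t) - age_only.ln_b - _ln_base(age_only.a, t)
    )
    ba = (const + eta_full) / gamma
    ca = covariates[age_col].to_numpy(dtype=float)
    aa = ba - ca
    out = pd.DataFrame({"ba": ba, "ca": ca, "aa": aa, "accelerated": aa > 0})
    if "subject_id" in covariates.columns:
        out.insert(0, "subject_id", covariates["subject_id"].to_numpy())
    return out


def estimate_cosinor_age(
    data: pd.DataFrame,
    rhythm_cols: Sequence[str] = ("mesor", "cosinor_amplitude", "acrophase"),
    age_col: str = "age",
    sex_col: str = "male",
    time_col: str = "time",
    event_col: str = "event",
    horizon: float = 5.0,
    shared_shape: bool = False,
) -> tuple[pd.DataFrame, Dict[str, Dict[str, GompertzPH]]]:
    """Sex-specific CosinorAge: fit full and age-only Gompertz models per sex,
    then solve for BA for every subject.  Returns (results, models)."""
    results = []
    models: Dict[str, Dict[str, GompertzPH]] = {}
    for sex_val, label in [(1, "male"), (0, "female")]:
        sub = data[data[sex_col] == sex_val]
        if len(sub) == 0:
            continue
        cols = list(rhythm_cols) + [age_col]
        full = fit_gompertz_ph(sub[cols], sub[time_col], sub[event_col],
                               horizon=horizon, sex=label)
        fix = full.a if shared_shape else None
        only = fit_gompertz_ph(sub[[age_col]], sub[time_col], sub[event_col],
                               horizon=horizon, sex=label, fix_a=fix)
        models[label] = {"full": full, "age_only": only}
        results.append(cosinor_age(full, only, sub, age_col=age_col))
    res = pd.concat(results, ignore_index=True)
    return res, models


_AA_BINS = [-np.inf, -5.0, -3.0, 0.0, 3.0, 5.0, np.inf]
_AA_LABELS = ["AA<=-5", "(-5,-3]", "(-3,0]", "(0,3]", "(3,5]", ">5"]


def stratify_age_acceleration(
    aa: np.ndarray | pd.Series,
    features: Optional[pd.DataFrame] = None,
    by: Optional[str] = None,
    value_cols: Optional[Sequence[str]] = None,
) -> pd.Series | pd.DataFrame:
    """Right-closed age-acceleration strata; optionally per-stratum (and
    per-phenotype) medians of chosen features -- the tabular analogue of the
    stratified activity heatmaps."""
    aa = pd.Series(np.asarray(aa, dtype=float))
    if not np.isfinite(aa).all():
        raise ValueError("AA values must be finite")
    labels = pd.cut(aa, bins=_AA_BINS, labels=_AA_LABELS, right=True)
    if features is None:
        return labels
    df = features.copy()
    df["aa_stratum"] = labels.to_numpy()
    group = ["aa_stratum"] + ([by] if by else [])
    cols = list(value_cols) if value_cols else df.select_dtypes("number").columns.tolist()
    out = df.groupby(group, observed=False)[cols].median()
    return out.reset_index()
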