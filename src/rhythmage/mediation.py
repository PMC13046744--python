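"""Counterfactual natural-effects mediation for survival outcomes.

Weighting-based estimator: a Gaussian model for the mediator given exposure
and covariates supplies density-ratio weights on a dataset expanded with a
hypothetical exposure level x*; a weighted Cox proportional-hazards fit on
(x, x*) then yields the natural direct effect (NDE, coefficient of x) and the
natural indirect effect (NIE, coefficient of x*) on the hazard-ratio scale,
with TE = NDE x NIE by construction.  Percentile bootstrap CIs resample
subjects.  Proportion mediated = log(NIE HR) / log(TE HR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._cox import cox_fit

__all__ = [
    "MediatorModel",
    "MediationEstimate",
    "fit_mediator_model",
    "natural_effects_cox",
    "proportion_mediated",
    "bootstrap_ci",
    "mediate_with_ci",
    "sex_stratified_mediation",
]


@dataclass
class MediatorModel:
    """Gaussian linear model M | X, C used for density-ratio weights."""

    coef: np.ndarray          # intercept, exposure, covariates...
    resid_sd: float
    columns: List[str]

    def mean(self, x: np.ndarray, C: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(len(x)), x, C])
        return design @ self.coef

    def density(self, m: np.ndarray, x: np.ndarray, C: np.ndarray) -> np.ndarray:
        return norm.pdf(m, loc=self.mean(x, C), scale=self.resid_sd)


@dataclass
class MediationEstimate:
    exposure: str
    te_hr: float
    nde_hr: float
    nie_hr: float
    proportion_mediated: float
    n: int
    n_boot: int = 0
    ci: Dict[str, tuple] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "exposure": self.exposure,
            "te_hr": self.te_hr,
            "nde_hr": self.nde_hr,
            "nie_hr": self.nie_hr,
            "proportion_mediated": self.proportion_mediated,
            "n": self.n,
            "n_boot": self.n_boot,
        }
        for k, (lo, hi) in self.ci.items():
            row[f"{k}_lo"], row[f"{k}_hi"] = lo, hi
        return row


def fit_mediator_model(
    mediator: np.ndarray, exposure: np.ndarray, covariates: pd.DataFrame
) -> MediatorModel:
    m = np.asarray(mediator, dtype=float)
    x = np.asarray(exposure, dtype=float)
    C = covariates.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(x)), x, C])
    coef, *_ = np.linalg.lstsq(design, m, rcond=None)
    resid = m - design @ coef
    dof = max(len(m) - design.shape[1], 1)
    sd = float(np.sqrt((resid**2).sum() / dof))
    if sd <= 1e-8 * max(float(np.std(m)), 1e-12):
        raise ValueError("zero residual variance in mediator model")
    return MediatorModel(coef=coef, resid_sd=sd,
                         columns=["intercept", "exposure", *covariates.columns])


def natural_effects_cox(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
    backend: str = "fast",
    truncate_weights: bool = False,
) -> MediationEstimate:
    """Point estimates of TE/NDE/NIE hazard ratios (see module docstring)."""
    x = data[exposure].to_numpy(dtype=float)
    if not np.isin(x, [0.0, 1.0]).all():
        raise ValueError("exposure must be binary 0/1")
    for level in (0, 1):
        if data.loc[x == level, event_col].sum() < 1:
            raise ValueError(f"no events in exposure arm {level}")

    C = data[list(covariates)]
    med = fit_mediator_model(data[mediator].to_numpy(), x, C)

    # expand with hypothetical exposure x*
    n = len(data)
    rep = pd.concat([data.reset_index(drop=True)] * 2, ignore_index=True)
    x_star = np.r_[np.zeros(n), np.ones(n)]
    x_obs = np.r_[x, x]
    m = rep[mediator].to_numpy(dtype=float)
    Cmat = rep[list(covariates)].to_numpy(dtype=float)
    w = med.density(m, x_star, Cmat) / med.density(m, x_obs, Cmat)
    if truncate_weights:
        lo, hi = np.percentile(w, [1, 99])
        w = np.clip(w, lo, hi)
    elif w.max() / max(w.min(), 1e-300) > 1e3:
        warnings.warn("extreme mediation weights (max/min > 1e3); consider "
                      "truncate_weights=True")

    X = np.column_stack([x_obs, x_star, Cmat])
    t = rep[time_col].to_numpy(dtype=float)
    e = rep[event_col].to_numpy(dtype=float)
    if backend == "fast":
        beta = cox_fit(X, t, e, weights=w)
    elif backend == "lifelines":
        from lifelines import CoxPHFitter

        df = pd.DataFrame(X, columns=["x", "x_star", *covariates])
        df["time"], df["event"], df["w"] = t, e, w
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", weights_col="w",
                    robust=False)
        beta = cph.params_.to_numpy()
    else:
        raise ValueError(f"unknown backend '{backend}'")

    nde = float(np.exp(beta[0]))
    nie = float(np.exp(beta[1]))
    te = nde * nie  # log TE = log NDE + log NIE by construction
    return MediationEstimate(
        exposure=exposure, te_hr=te, nde_hr=nde, nie_hr=nie,
        proportion_mediated=proportion_mediated(nie, te), n=n,
    )


def proportion_mediated(nie_hr: float, te_hr: float) -> float:
    """ln(NIE HR) / ln(TE HR); undefined (nan) when TE HR = 1."""
    if te_hr <= 0 or nie_hr <= 0:
        raise ValueError("hazard ratios must be positive")
    if te_hr == 1.0:
        return np.nan
    return float(np.log(nie_hr) / np.log(te_hr))


def bootstrap_ci(
    estimator: Callable[[pd.DataFrame], Dict[str, float]],
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_fail_frac: float = 0.10,
):
    """Percentile bootstrap over subject resamples.

    ``estimator`` maps a resampled cohort to a dict of statistics; failed
    replicates are dropped (error if more than 10% fail).  Returns
    (ci_dict, n_failed).
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    stats: Dict[str, list] = {}
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            est = estimator(sample)
        except Exception:
            failed += 1
            continue
        for k, v in est.items():
            stats.setdefault(k, []).append(v)
    if failed > max_fail_frac * n_boot:
        raise RuntimeError(f"{failed}/{n_boot} bootstrap replicates failed")
    ci = {
        k: tuple(np.percentile(v, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
        for k, v in stats.items()
    }
    return ci, failed


def mediate_with_ci(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    backend: str = "fast",
) -> MediationEstimate:
    """Point estimates plus percentile bootstrap CIs for one exposure."""
    point = natural_effects_cox(data, exposure, mediator, covariates,
                                backend=backend)

    def est(sample: pd.DataFrame) -> Dict[str, float]:
        e = natural_effects_cox(sample, exposure, mediator, covariates,
                                backend=backend)
        return {"te_hr": e.te_hr, "nde_hr": e.nde_hr, "nie_hr": e.nie_hr,
                "log_nde": np.log(e.nde_hr), "log_nie": np.log(e.nie_hr)}

    ci, _ = bootstrap_ci(est, data, n_boot=n_boot, seed=seed)
    point.ci = {k: ci[k] for k in ("te_hr", "nde_hr", "nie_hr")}
    point.n_boot = n_boot
    return point


DEFAULT_MEDIATION_COVARIATES = ["age", "tdi", "bmi_class", "employed", "shift_work"]


def sex_stratified_mediation(
    cohort: pd.DataFrame,
    exposures: Sequence[str] = ("irregular", "insufficient_mvpa", "low_amplitude"),
    mediator: str = "sii_z",
    covariates: Sequence[str] = tuple(DEFAULT_MEDIATION_COVARIATES),
    sex_col: str = "male",
    n_boot: int = 200,
    seed: int = 0,
    backend: str = "fast",
) -> pd.DataFrame:
    """TE/NDE/NIE HRs with CIs and proportion mediated, per sex x exposure."""
    rows = []
    for sex_val, label in [(1, "male"), (0, "female")]:
        sub = cohort[cohort[sex_col] == sex_val].reset_index(drop=True)
        if len(sub) == 0:
            continue
        for exp in exposures:
            if sub.loc[sub[exp] == 1, "event"].sum() < 5:
                warnings.warn(f"{label}/{exp}: fewer than 5 events in the "
                              "exposed stratum; estimates unstable")
            est = mediate_with_ci(sub, exp, mediator, covariates,
                                  n_boot=n_boot, seed=seed, backend=backend)
            row = est.as_row()
            row["sex"] = label
            rows.append(row)
    return pd.DataFrame(rows)
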