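"""Association of wearable features with systemic inflammation (SII).

Quartile construction with the high-amplitude/good-regularity quartile as the
reference, z-scored SII as the outcome of Gaussian identity-link GLMs (main
effects, quartile trends, sex-stratified MVPA contrasts, pairwise binary
interactions), Benjamini-Hochberg FDR control, and the shift-work /
sleep-disturbance sensitivity filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GLMResult",
    "zscore",
    "quartile_groups",
    "fit_sii_glm",
    "fit_interaction_glm",
    "bh_fdr",
    "sensitivity_filter",
]


@dataclass
class GLMResult:
    terms: List[str]
    beta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int
    p_adj: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )
        if self.p_adj is not None:
            df["p_adj"] = self.p_adj
        df["n"] = self.n
        return df


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample SD 1."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot z-score")
    return (x - x.mean()) / sd


def quartile_groups(
    feature: np.ndarray, direction: str = "low_is_q1"
) -> Tuple[np.ndarray, np.ndarray]:
    """Quartile labels Q1..Q4 plus the numeric trend code.

    Q4 is the favourable extreme (reference); the trend code runs 0 (Q4) to
    3 (Q1) so a positive regression coefficient means "per-quartile move
    toward the unfavourable extreme raises SII".  ``direction='low_is_q1'``
    puts low feature values in Q1 (amplitude, IS); 'high_is_q1' reverses.
    Sample-quartile cuts use linear-interpolation percentiles; ties go to the
    lower group.
    """
    x = np.asarray(feature, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 observations for quartiles")
    if direction not in ("low_is_q1", "high_is_q1"):
        raise ValueError("direction must be 'low_is_q1' or 'high_is_q1'")
    cuts = np.percentile(x, [25, 50, 75])
    # rank from low values: 0..3; ties at a cut go to the lower group
    rank = np.searchsorted(cuts, x, side="left")
    q_from_low = rank if direction == "low_is_q1" else 3 - rank
    # q_from_low = 0 is the unfavourable extreme -> Q1
    labels = np.array([f"Q{r + 1}" for r in q_from_low])
    trend = 3 - q_from_low  # 0 at Q4 (reference) ... 3 at Q1
    for q in range(4):
        if not (q_from_low == q).any():
            raise ValueError(f"quartile cut Q{q + 1} is empty (massive ties)")
    return labels, trend.astype(int)


def _design(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Design matrix with categorical expansion against first-level reference."""
    X = pd.DataFrame(index=df.index)
    for c in cols:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[c] = col.astype(float)
    return X


def _ols_result(y: np.ndarray, X: pd.DataFrame, keep: Sequence[str]) -> GLMResult:
    # constant adjustment columns (e.g. a comorbidity absent from a stratum)
    # carry no information and are dropped silently
    const_cols = [c for c in X.columns if X[c].nunique() <= 1 and c not in keep]
    X = X.drop(columns=const_cols)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy(dtype=float))
    if rank < Xc.shape[1]:
        corr = Xc.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear terms: {worst}")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    idx = [t for t in keep if t in fit.params.index]
    return GLMResult(
        terms=idx,
        beta=fit.params[idx].to_numpy(),
        ci_low=ci.loc[idx, 0].to_numpy(),
        ci_high=ci.loc[idx, 1].to_numpy(),
        p=fit.pvalues[idx].to_numpy(),
        n=int(fit.nobs),
    )


def fit_sii_glm(
    data: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str],
    extra_adjustments: Sequence[str] = (),
    outcome: str = "sii_z",
    quartiles: bool = False,
    direction: str = "low_is_q1",
    sex_stratum: Optional[int] = None,
    sex_col: str = "male",
) -> GLMResult:
    """Gaussian identity-link GLM of z-scored SII on an exposure.

    ``quartiles=True`` fits both the Q1..Q3-vs-Q4 contrasts and (separately
    callable via trend_glm) the numeric trend.  ``sex_stratum`` restricts to
    one sex (the MVPA rows).  Complete cases only.
    """
    cols = [outcome, exposure, *covariates, *extra_adjustments]
    if sex_stratum is not None:
        data = data[data[sex_col] == sex_stratum]
    df = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    adj = list(dict.fromkeys([*covariates, *extra_adjustments]))

    if quartiles:
        labels, _ = quartile_groups(df[exposure].to_numpy(), direction)
        dummies = pd.get_dummies(
            pd.Categorical(labels, categories=["Q4", "Q3", "Q2", "Q1"]),
            prefix=exposure, dtype=float,
        ).drop(columns=f"{exposure}_Q4")
        X = pd.concat([dummies.set_index(df.index), _design(df, adj)], axis=1)
        keep = list(dummies.columns)
    else:
        X = pd.concat(
            [df[[exposure]].astype(float), _design(df, adj)], axis=1
        )
        keep = [exposure]
    return _ols_result(df[outcome].to_numpy(dtype=float), X, keep)


def trend_glm(
    data: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str],
    extra_adjustments: Sequence[str] = (),
    outcome: str = "sii_z",
    direction: str = "low_is_q1",
) -> GLMResult:
    """Numeric quartile-trend GLM (0 = Q4 reference ... 3 = Q1)."""
    cols = [outcome, exposure, *covariates, *extra_adjustments]
    df = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    _, trend = quartile_groups(df[exposure].to_numpy(), direction)
    df = df.assign(**{f"{exposure}_trend": trend})
    adj = list(dict.fromkeys([*covariates, *extra_adjustments]))
    X = pd.concat([df[[f"{exposure}_trend"]], _design(df, adj)], axis=1)
    return _ols_result(df[outcome].to_numpy(dtype=float), X, [f"{exposure}_trend"])


def fit_interaction_glm(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    covariates: Sequence[str],
    outcome: str = "sii_z",
) -> GLMResult:
    """Joint 4-level factor of two binary exposures; reference = both 0
    (the doubly favourable cell).  Returns the three cell contrasts."""
    df = data.dropna(subset=[outcome, factor_a, factor_b,
                             *[c for c in covariates if c in data.columns]]).copy()
    a = df[factor_a].to_numpy(dtype=int)
    b = df[factor_b].to_numpy(dtype=int)
    if not set(np.unique(a)) <= {0, 1} or not set(np.unique(b)) <= {0, 1}:
        raise ValueError("both factors must be binary 0/1")
    cells = {
        f"{factor_a}_only": ((a == 1) & (b == 0)).astype(float),
        f"{factor_b}_only": ((a == 0) & (b == 1)).astype(float),
        "both": ((a == 1) & (b == 1)).astype(float),
    }
    nonconst = {k: v for k, v in cells.items() if v.any()}
    if ((a == 0) & (b == 0)).sum() == 0:
        raise ValueError("empty reference cell")
    X = pd.concat(
        [pd.DataFrame(nonconst, index=df.index), _design(df, covariates)], axis=1
    )
    return _ols_result(df[outcome].to_numpy(dtype=float), X, list(nonconst))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sensitivity_filter(
    cohort: pd.DataFrame,
    exclude_shift_work: bool = False,
    exclude_sleep_disturbance: bool = False,
    shift_col: str = "shift_work",
    sleep_col: str = "sleep_disturbance",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Remove flagged rows; reports n removed per criterion."""
    report = {"input": len(cohort)}
    out = cohort
    if exclude_shift_work:
        n0 = len(out)
        out = out[out[shift_col] == 0]
        report["removed_shift_work"] = n0 - len(out)
    if exclude_sleep_disturbance:
        n0 = len(out)
        out = out[out[sleep_col] == 0]
        report["removed_sleep_disturbance"] = n0 - len(out)
    report["output"] = len(out)
    if len(out) == 0:
        warnings.warn("sensitivity filter removed every subject")
    return out.reset_index(drop=True), report
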