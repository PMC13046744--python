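"""Accelerated-aging classification with MRMR selection and Shapley attribution.

Feature selection: a greedy Spearman-correlation prune (collapse clusters with
|rho| above a threshold to the member most relevant to the label) followed by
MRMR ranking under the mutual-information-difference (MID) criterion, with
mutual information estimated by equal-frequency binning.  Models: logistic
regression, random forest, SVC, decision tree and XGBoost via their standard
implementations, evaluated on a stratified 65/15/20 train/validation/test
split with AUC, accuracy and the Matthews correlation coefficient.  Shapley
attributions are computed in-house: exact coalition enumeration for <= 12
features and a permutation-sampling estimator otherwise, marginalising
out-of-coalition features over a background sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "SelectionResult",
    "EvalReport",
    "ShapleyAttribution",
    "mutual_information",
    "spearman_prune",
    "mrmr_select",
    "split_train_val_test",
    "train_and_evaluate",
    "mcc_from_counts",
    "shapley_attributions",
]


# ---------------------------------------------------------------------------
# mutual information and selection


def _quantile_bins(x: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-frequency discretisation; constant columns give one bin."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in MI (nats) between quantile-binned x and discrete/binned y."""
    bx = _quantile_bins(x, n_bins)
    by = _quantile_bins(np.asarray(y, dtype=float), n_bins)
    joint = pd.crosstab(bx, by).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px @ py))
    return float(np.nansum(terms))


@dataclass
class SelectionResult:
    retained: List[str]
    ranking: List[str]
    relevance: Dict[str, float]
    redundancy: Dict[str, float] = field(default_factory=dict)


def spearman_prune(
    features: pd.DataFrame, label: np.ndarray, threshold: float = 0.7,
    n_bins: int = 8,
) -> List[str]:
    """Greedy correlation prune.

    While any retained pair has |Spearman rho| > threshold, take the
    highest-|rho| pair and drop the member with lower mutual information with
    the label; ties broken by column-name order (earlier name kept).
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    rel = {c: mutual_information(features[c].to_numpy(), label, n_bins) for c in cols}
    rho = pd.DataFrame(
        np.abs(spearmanr(features.to_numpy()).statistic if len(cols) > 2
               else np.array([[1.0, abs(spearmanr(features.iloc[:, 0],
                                                  features.iloc[:, 1]).statistic)],
                              [abs(spearmanr(features.iloc[:, 0],
                                             features.iloc[:, 1]).statistic), 1.0]])),
        index=cols, columns=cols,
    )
    retained = list(cols)
    while True:
        best = None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = rho.loc[a, b]
                if r > threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        if rel[a] > rel[b]:
            drop = b
        elif rel[b] > rel[a]:
            drop = a
        else:
            drop = max(a, b)  # keep the earlier name
        retained.remove(drop)
    return retained


def mrmr_select(
    features: pd.DataFrame, label: np.ndarray, k: int, n_bins: int = 8
) -> SelectionResult:
    """Greedy MRMR ranking under the MID criterion.

    At each step the next feature maximises I(f; y) - mean_{s in S} I(f; s);
    deterministic tie-break by name.
    """
    cols = list(features.columns)
    if k > len(cols):
        raise ValueError("k exceeds the number of features")
    X = {c: features[c].to_numpy() for c in cols}
    y = np.asarray(label)
    rel = {c: mutual_information(X[c], y, n_bins) for c in cols}
    pair_mi: Dict[Tuple[str, str], float] = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_information(X[key[0]], X[key[1]], n_bins)
        return pair_mi[key]

    selected: List[str] = []
    redundancy: Dict[str, float] = {}
    remaining = sorted(cols)
    while len(selected) < k:
        scores = []
        for c in remaining:
            red = (np.mean([mi_pair(c, s) for s in selected]) if selected else 0.0)
            scores.append((rel[c] - red, c, red))
        scores.sort(key=lambda t: (-t[0], t[1]))
        _, chosen, red = scores[0]
        selected.append(chosen)
        redundancy[chosen] = red
        remaining.remove(chosen)
    return SelectionResult(retained=cols, ranking=selected, relevance=rel,
                           redundancy=redundancy)


# ---------------------------------------------------------------------------
# split / train / evaluate


def split_train_val_test(
    labels: np.ndarray,
    fractions: Tuple[float, float, float] = (0.65, 0.15, 0.20),
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label-stratified, disjoint, exhaustive index split."""
    from sklearn.model_selection import train_test_split

    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(labels)
    idx = np.arange(y.size)
    rest, test = train_test_split(
        idx, test_size=fractions[2], random_state=seed, stratify=y
    )
    val_frac = fractions[1] / (fractions[0] + fractions[1])
    train, val = train_test_split(
        rest, test_size=val_frac, random_state=seed, stratify=y[rest]
    )
    for part in (train, val, test):
        if len(np.unique(y[part])) < 2:
            import warnings

            warnings.warn("a split contains a single class")
    return np.sort(train), np.sort(val), np.sort(test)


def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    num = tp * tn - fp * fn
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return float(num / den) if den > 0 else 0.0


def _make_model(family: str, params: dict, seed: int):
    if family == "lr":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, **params)
    if family == "svc":
        from sklearn.svm import SVC

        return SVC(probability=True, random_state=seed, **params)
    if family == "dt":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            verbosity=0, **params,
        )
    raise ValueError(f"unknown model family '{family}'")


DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "lr": {"C": [0.1, 1.0, 10.0]},
    "rf": {"n_estimators": [200], "max_depth": [None, 8]},
    "svc": {"C": [1.0, 10.0]},
    "dt": {"max_depth": [4, 8, None]},
    "xgb": {"n_estimators": [200], "max_depth": [3, 5], "learning_rate": [0.1]},
}


@dataclass
class EvalReport:
    model_family: str
    auc: float
    accuracy: float
    mcc: float
    best_params: dict
    split_sizes: Tuple[int, int, int]
    model: object = None


def train_and_evaluate(
    features: pd.DataFrame,
    labels: np.ndarray,
    model_family: str = "xgb",
    hyper_grid: Optional[Dict[str, list]] = None,
    seed: int = 0,
    fractions: Tuple[float, float, float] = (0.65, 0.15, 0.20),
) -> EvalReport:
    """Grid search on the validation split, retrain on train+validation,
    report AUC / accuracy / MCC on the untouched test split."""
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    X = features.to_numpy(dtype=float)
    tr, va, te = split_train_val_test(y, fractions, seed)
    grid = hyper_grid if hyper_grid is not None else DEFAULT_GRIDS[model_family]

    keys = list(grid)
    best_auc, best_params = -np.inf, {}
    for combo in product(*[grid[k] for k in keys]):
        params = dict(zip(keys, combo))
        model = _make_model(model_family, params, seed)
        model.fit(X[tr], y[tr])
        auc = roc_auc_score(y[va], model.predict_proba(X[va])[:, 1])
        if auc > best_auc:
            best_auc, best_params = auc, params

    model = _make_model(model_family, best_params, seed)
    trval = np.sort(np.concatenate([tr, va]))
    model.fit(X[trval], y[trval])
    proba = model.predict_proba(X[te])[:, 1]
    pred = (proba >= 0.5).astype(int)
    tp = int(((pred == 1) & (y[te] == 1)).sum())
    fp = int(((pred == 1) & (y[te] == 0)).sum())
    fn = int(((pred == 0) & (y[te] == 1)).sum())
    tn = int(((pred == 0) & (y[te] == 0)).sum())
    return EvalReport(
        model_family=model_family,
        auc=float(roc_auc_score(y[te], proba)),
        accuracy=float((pred == y[te]).mean()),
        mcc=mcc_from_counts(tp, fp, fn, tn),
        best_params=best_params,
        split_sizes=(len(tr), len(va), len(te)),
        model=model,
    )


# ---------------------------------------------------------------------------
# Shapley attribution


@dataclass
class ShapleyAttribution:
    values: np.ndarray         # instances x features
    base_value: float
    feature_names: List[str]
    se: Optional[np.ndarray] = None   # Monte-Carlo SE (sampling mode only)

    def global_ranking(self) -> pd.DataFrame:
        mean_abs = np.abs(self.values).mean(axis=0)
        df = pd.DataFrame({"feature": self.feature_names, "mean_abs": mean_abs})
        return df.sort_values("mean_abs", ascending=False).reset_index(drop=True)

    def direction(self, instances: np.ndarray) -> pd.Series:
        """Sign of the correlation between feature value and attribution."""
        signs = {}
        for j, name in enumerate(self.feature_names):
            v = self.values[:, j]
            x = instances[:, j]
            if v.std() == 0 or x.std() == 0:
                signs[name] = 0.0
            else:
                signs[name] = float(np.sign(np.corrcoef(x, v)[0, 1]))
        return pd.Series(signs)


def _coalition_value(predict, instances, background, mask) -> np.ndarray:
    """E_b[f(x_S, B_{~S})] per instance for coalition mask S."""
    n_i = instances.shape[0]
    n_b = background.shape[0]
    hybrid = np.repeat(background[None, :, :], n_i, axis=0)  # (n_i, n_b, p)
    hybrid[:, :, mask] = instances[:, None, mask]
    preds = predict(hybrid.reshape(n_i * n_b, -1))
    return preds.reshape(n_i, n_b).mean(axis=1)


def shapley_attributions(
    model_predict: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    instances: np.ndarray,
    mode: str = "exact",
    n_permutations: int = 100,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> ShapleyAttribution:
    """Shapley values of the value function v(S) = E_background f(x_S, B).

    Exact mode enumerates all coalitions (requires <= 12 features); sampling
    mode is the seeded permutation estimator.  Efficiency (sum of
    attributions = f(x) - E_background f) holds exactly in exact mode.
    """
    background = np.asarray(background, dtype=float)
    instances = np.asarray(instances, dtype=float)
    if background.size == 0:
        raise ValueError("empty background")
    n_i, p = instances.shape
    names = list(feature_names) if feature_names else [f"f{j}" for j in range(p)]

    base = float(model_predict(background).mean())

    if mode == "exact":
        if p > 12:
            raise ValueError("exact mode supports at most 12 features")
        from math import factorial

        vals = np.zeros((2**p, n_i))
        for s in range(2**p):
            mask = np.array([(s >> j) & 1 for j in range(p)], dtype=bool)
            vals[s] = _coalition_value(model_predict, instances, background, mask)
        phi = np.zeros((n_i, p))
        fact = [factorial(i) for i in range(p + 1)]
        for s in range(2**p):
            size = bin(s).count("1")
            w = fact[size] * fact[p - size - 1] / fact[p]
            for j in range(p):
                if not (s >> j) & 1:
                    phi[:, j] += w * (vals[s | (1 << j)] - vals[s])
        return ShapleyAttribution(values=phi, base_value=base, feature_names=names)

    if mode != "sampling":
        raise ValueError("mode must be 'exact' or 'sampling'")
    rng = np.random.default_rng(seed)
    phi = np.zeros((n_i, p))
    phi_sq = np.zeros((n_i, p))
    n_b = background.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        hybrid = np.repeat(background[None, :, :], n_i, axis=0)
        prev = model_predict(hybrid.reshape(n_i * n_b, -1)).reshape(n_i, n_b).mean(1)
        for j in perm:
            hybrid[:, :, j] = instances[:, None, j]
            cur = model_predict(hybrid.reshape(n_i * n_b, -1)).reshape(n_i, n_b).mean(1)
            phi[:, j] += cur - prev
            phi_sq[:, j] += (cur - prev) ** 2
            prev = cur
    phi /= n_permutations
    var = np.maximum(phi_sq / n_permutations - phi**2, 0.0)
    se = np.sqrt(var / n_permutations)
    return ShapleyAttribution(values=phi, base_value=base, feature_names=names,
                              se=se)
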