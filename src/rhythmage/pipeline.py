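"""End-to-end orchestration: simulate -> features -> cosinorage -> ml ->
assoc -> mediate -> report.

Each stage writes CSV/JSON artifacts plus a manifest entry (parameters, input
and output hashes, duration); a rerun with the same config and seed
reproduces identical artifact hashes.  Minute-level traces are regenerated
deterministically from the config seed rather than written to disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time as _time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from . import gompertz as gz
from . import inflammation as infl
from . import mediation as med
from . import ml as ml_mod
from . import synth

__all__ = ["RunConfig", "run_pipeline", "report"]

log = logging.getLogger("rhythmage")

STAGES = ["simulate", "features", "cosinorage", "ml", "assoc", "mediate", "report"]

_DEPS = {
    "simulate": [],
    "features": ["simulate"],
    "cosinorage": ["features", "simulate"],
    "ml": ["features", "cosinorage"],
    "assoc": ["features", "simulate"],
    "mediate": ["features", "simulate"],
    "report": ["features", "simulate", "cosinorage", "ml", "assoc", "mediate"],
}

_STAGE_OUTPUTS = {
    "simulate": ["truth.csv", "covariates.csv", "blood.csv", "survival.csv"],
    "features": ["features.csv", "flow.json"],
    "cosinorage": ["aging.csv", "models.json"],
    "ml": ["selection.json", "metrics.json", "attributions.csv", "split.csv"],
    "assoc": ["assoc_main.csv", "assoc_interactions.csv", "sensitivity_report.txt"],
    "mediate": ["mediation.csv"],
    "report": ["table1.csv", "strata_mvpa.csv", "strata_is.csv"],
}


@dataclass
class RunConfig:
    n_subjects: int = 2000
    days: int = 7
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    model_family: str = "xgb"
    k_features: int = 25
    n_boot: int = 200
    mvpa_cut: float = 100.0
    sed_cut: float = 40.0
    min_wear_hours: float = 72.0
    log_level: str = "INFO"
    shap_instances: int = 200
    shap_background: int = 100
    shap_permutations: int = 20

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        self.stages = [s for s in STAGES if s in self.stages]  # dependency order
        if self.n_subjects < 1 or self.days < 1:
            raise ValueError("n_subjects and days must be >= 1")


def _sha(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        os.makedirs(cfg.outdir, exist_ok=True)
        self.manifest: List[dict] = []
        self.memory: Dict[str, object] = {}

    def path(self, name: str) -> str:
        return os.path.join(self.cfg.outdir, name)

    def need(self, name: str, producer: str) -> pd.DataFrame:
        p = self.path(name)
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"missing upstream artifact '{name}' (stage '{producer}')"
            )
        return pd.read_csv(p)

    def record(self, stage: str, t0: float, inputs: Sequence[str]) -> None:
        entry = {
            "stage": stage,
            "params": {"seed": self.cfg.seed, "n_subjects": self.cfg.n_subjects},
            "inputs": {n: _sha(self.path(n)) for n in inputs
                       if os.path.exists(self.path(n))},
            "outputs": {n: _sha(self.path(n)) for n in _STAGE_OUTPUTS[stage]
                        if os.path.exists(self.path(n))},
            "duration_s": round(_time.time() - t0, 3),
        }
        self.manifest.append(entry)


def run_pipeline(config: RunConfig) -> str:
    """Run the requested stages; returns the artifact directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    run = _Run(config)

    for stage in config.stages:
        t0 = _time.time()
        log.info("stage %s: start", stage)
        globals()[f"_stage_{stage}"](run)
        run.record(stage, t0, inputs=[
            out for dep in _DEPS[stage] for out in _STAGE_OUTPUTS[dep]
        ])
        log.info("stage %s: done in %.1fs", stage, _time.time() - t0)

    with open(run.path("manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=1)
    return config.outdir


def _stage_simulate(run: _Run) -> None:
    cfg = run.cfg
    gcfg = synth.default_config(cfg.n_subjects, seed=cfg.seed, days=cfg.days)
    bundle = synth.generate_cohort(gcfg, with_traces=True)
    run.memory["bundle"] = bundle
    run.memory["gcfg"] = gcfg
    for name, tab in [("truth", bundle.truth), ("covariates", bundle.covariates),
                      ("blood", bundle.blood), ("survival", bundle.survival)]:
        _write_csv(tab, run.path(f"{name}.csv"))
    log.info("simulate: n in %d / out %d", cfg.n_subjects, len(bundle.truth))


def _get_bundle(run: _Run) -> synth.CohortBundle:
    if "bundle" not in run.memory:
        run.need("truth.csv", "simulate")  # raises with the stage name
        gcfg = synth.default_config(run.cfg.n_subjects, seed=run.cfg.seed,
                                    days=run.cfg.days)
        run.memory["bundle"] = synth.generate_cohort(gcfg, with_traces=True)
    return run.memory["bundle"]


def _stage_features(run: _Run) -> None:
    bundle = _get_bundle(run)
    feats, flow = ft.extract_features(
        bundle.series,
        mvpa_cut=run.cfg.mvpa_cut,
        sed_cut=run.cfg.sed_cut,
        min_wear_hours=run.cfg.min_wear_hours,
    )
    _write_csv(feats, run.path("features.csv"))
    with open(run.path("flow.json"), "w") as fh:
        json.dump(flow, fh, indent=1)
    log.info("features: %s", flow)


def _merged(run: _Run) -> pd.DataFrame:
    feats = run.need("features.csv", "features")
    cov = run.need("covariates.csv", "simulate")
    blood = run.need("blood.csv", "simulate")
    surv = run.need("survival.csv", "simulate")
    df = feats.merge(cov, on="subject_id").merge(blood, on="subject_id")
    df = df.merge(surv, on="subject_id")
    df["sii_z"] = infl.zscore(df["sii"].to_numpy())
    return df


def _stage_cosinorage(run: _Run) -> None:
    df = _merged(run).dropna(subset=["mesor", "cosinor_amplitude", "acrophase"])
    res, models = gz.estimate_cosinor_age(df)
    _write_csv(res, run.path("aging.csv"))
    dump = {sex: {k: m.to_dict() for k, m in pair.items()}
            for sex, pair in models.items()}
    with open(run.path("models.json"), "w") as fh:
        json.dump(dump, fh, indent=1)
    frac = res["accelerated"].mean()
    log.info("cosinorage: %d subjects, %.1f%% accelerated", len(res), 100 * frac)


_ID_COLS = {"subject_id"}
# mesor feeds the biological-age model but is not part of the ML feature
# vector (and is nearly collinear with amplitude in this generator)
_ML_EXCLUDED = {"subject_id", "mesor"}


def _stage_ml(run: _Run) -> None:
    cfg = run.cfg
    feats = run.need("features.csv", "features")
    aging = run.need("aging.csv", "cosinorage")
    df = feats.merge(aging[["subject_id", "accelerated"]], on="subject_id").dropna()
    y = df["accelerated"].astype(int).to_numpy()
    cols = [c for c in feats.columns
            if c not in _ML_EXCLUDED and pd.api.types.is_numeric_dtype(feats[c])]
    X = df[cols]
    X = (X - X.mean()) / X.std(ddof=1)
    X = X.dropna(axis=1)  # constant columns

    retained = ml_mod.spearman_prune(X, y, threshold=0.7)
    k = min(cfg.k_features, len(retained))
    sel = ml_mod.mrmr_select(X[retained], y, k=k)
    chosen = sel.ranking
    report = ml_mod.train_and_evaluate(X[chosen], y, cfg.model_family, seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    Xm = X[chosen].to_numpy()
    bg = Xm[rng.choice(len(Xm), min(cfg.shap_background, len(Xm)), replace=False)]
    inst_idx = rng.choice(len(Xm), min(cfg.shap_instances, len(Xm)), replace=False)
    inst = Xm[inst_idx]
    model = report.model
    attr = ml_mod.shapley_attributions(
        lambda Z: model.predict_proba(Z)[:, 1], bg, inst,
        mode="sampling", n_permutations=cfg.shap_permutations, seed=cfg.seed,
        feature_names=chosen,
    )
    with open(run.path("selection.json"), "w") as fh:
        json.dump({"retained": retained, "ranking": chosen,
                   "relevance": sel.relevance}, fh, indent=1)
    with open(run.path("metrics.json"), "w") as fh:
        json.dump({"model_family": report.model_family, "auc": report.auc,
                   "accuracy": report.accuracy, "mcc": report.mcc,
                   "split_sizes": report.split_sizes,
                   "best_params": report.best_params}, fh, indent=1)
    adf = pd.DataFrame(attr.values, columns=chosen)
    adf.insert(0, "subject_id", df["subject_id"].to_numpy()[inst_idx])
    _write_csv(adf, run.path("attributions.csv"))

    tr, va, te = ml_mod.split_train_val_test(y, seed=cfg.seed)
    split = np.full(len(y), "trainval", dtype=object)
    split[te] = "test"
    _write_csv(pd.DataFrame({"subject_id": df["subject_id"], "split": split}),
               run.path("split.csv"))
    log.info("ml: %s auc=%.3f mcc=%.3f", cfg.model_family, report.auc, report.mcc)


MAIN_EFFECT_COVARIATES = [
    "age", "male", "white", "tdi", "bmi_class", "employed", "shift_work",
    "smoking", "alcohol", "sleep_duration", "hypertension", "diabetes",
    "cvd", "cancer", "neuro", "resp",
]
INTERACTION_COVARIATES = ["age", "male", "white", "tdi", "bmi_class",
                          "employed", "shift_work"]


def _stage_assoc(run: _Run) -> None:
    df = _merged(run).dropna(subset=["relative_amplitude", "interdaily_stability",
                                     "mvpa_h_day", "sii_z"])
    rows = []

    def add(result: infl.GLMResult, label: str) -> None:
        frame = result.to_frame()
        frame.insert(0, "block", label)
        rows.append(frame)

    add(infl.trend_glm(df, "relative_amplitude", MAIN_EFFECT_COVARIATES,
                       extra_adjustments=["mvpa_h_day"]), "ra_trend")
    add(infl.fit_sii_glm(df, "relative_amplitude", MAIN_EFFECT_COVARIATES,
                         extra_adjustments=["mvpa_h_day"], quartiles=True),
        "ra_quartiles")
    add(infl.trend_glm(df, "interdaily_stability", MAIN_EFFECT_COVARIATES,
                       extra_adjustments=["mvpa_h_day"]), "is_trend")
    add(infl.fit_sii_glm(df, "interdaily_stability", MAIN_EFFECT_COVARIATES,
                         extra_adjustments=["mvpa_h_day"], quartiles=True),
        "is_quartiles")
    covs_no_sex = [c for c in MAIN_EFFECT_COVARIATES if c != "male"]
    for sex, lab in [(1, "male"), (0, "female")]:
        add(infl.fit_sii_glm(df, "insufficient_mvpa", covs_no_sex,
                             extra_adjustments=["interdaily_stability"],
                             sex_stratum=sex), f"mvpa_{lab}")
    main = pd.concat(rows, ignore_index=True)
    main["p_adj"] = infl.bh_fdr(main["p"].to_numpy())

    # binary exposures for the interaction models
    ra_q1 = (infl.quartile_groups(df["relative_amplitude"].to_numpy())[0] == "Q1")
    is_q1 = (infl.quartile_groups(df["interdaily_stability"].to_numpy())[0] == "Q1")
    dfi = df.assign(low_amplitude=ra_q1.astype(int), irregular=is_q1.astype(int))
    inter_rows = []
    for a, b, lab in [("low_amplitude", "irregular", "amplitude_x_regularity"),
                      ("insufficient_mvpa", "irregular", "mvpa_x_regularity"),
                      ("low_amplitude", "insufficient_mvpa", "amplitude_x_mvpa")]:
        r = infl.fit_interaction_glm(dfi, a, b, INTERACTION_COVARIATES)
        frame = r.to_frame()
        frame.insert(0, "block", lab)
        inter_rows.append(frame)
    inter = pd.concat(inter_rows, ignore_index=True)

    _write_csv(main, run.path("assoc_main.csv"))
    _write_csv(inter, run.path("assoc_interactions.csv"))

    filtered, rep = infl.sensitivity_filter(df, exclude_shift_work=True,
                                            exclude_sleep_disturbance=True)
    with open(run.path("sensitivity_report.txt"), "w") as fh:
        for k, v in rep.items():
            fh.write(f"{k}: {v}\n")
    log.info("assoc: %d main-effect rows, sensitivity %s", len(main), rep)


def _stage_mediate(run: _Run) -> None:
    df = _merged(run).dropna(subset=["cosinor_amplitude", "interdaily_stability",
                                     "mvpa_h_day", "sii_z", "time", "event"])
    amp_q1 = (infl.quartile_groups(df["cosinor_amplitude"].to_numpy())[0] == "Q1")
    is_q1 = (infl.quartile_groups(df["interdaily_stability"].to_numpy())[0] == "Q1")
    dfm = df.assign(low_amplitude=amp_q1.astype(int), irregular=is_q1.astype(int))
    table = med.sex_stratified_mediation(dfm, n_boot=run.cfg.n_boot,
                                         seed=run.cfg.seed)
    _write_csv(table, run.path("mediation.csv"))
    log.info("mediate: %d rows", len(table))


# ---------------------------------------------------------------------------
# report


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.2f} [{q1:.2f}, {q3:.2f}]"


def report(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    split: pd.DataFrame,
    aging: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """Descriptive summary tables.

    Continuous variables: median [IQR] per split group with Wilcoxon
    rank-sum p-values; categorical variables: N (%) with chi-square (no
    continuity correction).  With aging results, adds per-stratum median
    tables (MVPA by rhythm-regularity phenotype and IS by MVPA phenotype).
    """
    from scipy.stats import chi2_contingency, ranksums

    df = features.merge(covariates, on="subject_id").merge(split, on="subject_id")
    groups = df["split"].unique()
    if len(groups) != 2:
        raise ValueError("report expects exactly two split groups")
    g0 = df[df["split"] == groups[0]]
    g1 = df[df["split"] == groups[1]]

    cat_cols = [c for c in ("male", "white", "bmi_class", "employed", "shift_work",
                            "smoking", "alcohol", "insufficient_mvpa")
                if c in df.columns]
    num_cols = [c for c in df.select_dtypes("number").columns
                if c not in cat_cols and c != "subject_id"]
    rows = []
    for c in num_cols:
        a, b = g0[c].dropna(), g1[c].dropna()
        if a.std() == 0 and b.std() == 0:
            p = 1.0
        else:
            p = float(ranksums(a, b).pvalue)
        rows.append({"variable": c, groups[0]: _median_iqr(a),
                     groups[1]: _median_iqr(b), "p": p, "type": "continuous"})
    for c in cat_cols:
        tab = pd.crosstab(df[c], df["split"])
        if tab.shape[0] < 2:
            p = 1.0
        else:
            p = float(chi2_contingency(tab.to_numpy(), correction=False)[1])
        n0 = g0[c].value_counts().to_dict()
        n1 = g1[c].value_counts().to_dict()
        rows.append({"variable": c,
                     groups[0]: "; ".join(f"{k}: {v} ({100 * v / len(g0):.1f}%)"
                                          for k, v in sorted(n0.items())),
                     groups[1]: "; ".join(f"{k}: {v} ({100 * v / len(g1):.1f}%)"
                                          for k, v in sorted(n1.items())),
                     "p": p, "type": "categorical"})
    out = {"table1": pd.DataFrame(rows)}

    if aging is not None:
        merged = df.merge(aging[["subject_id", "aa"]], on="subject_id")
        is_med = merged["interdaily_stability"].median()
        merged["rhythm_phenotype"] = np.where(
            merged["interdaily_stability"] >= is_med, "regular", "irregular")
        mvpa_med = merged["mvpa_h_day"].median()
        merged["mvpa_phenotype"] = np.where(
            merged["mvpa_h_day"] >= mvpa_med, "high", "low")
        out["strata_mvpa"] = gz.stratify_age_acceleration(
            merged["aa"].to_numpy(), merged, by="rhythm_phenotype",
            value_cols=["mvpa_h_day"])
        out["strata_is"] = gz.stratify_age_acceleration(
            merged["aa"].to_numpy(), merged, by="mvpa_phenotype",
            value_cols=["interdaily_stability"])
    return out


def _stage_report(run: _Run) -> None:
    feats = run.need("features.csv", "features")
    cov = run.need("covariates.csv", "simulate")
    split = run.need("split.csv", "ml")
    aging = run.need("aging.csv", "cosinorage")
    tables = report(feats, cov, split, aging)
    _write_csv(tables["table1"], run.path("table1.csv"))
    _write_csv(tables["strata_mvpa"], run.path("strata_mvpa.csv"))
    _write_csv(tables["strata_is"], run.path("strata_is.csv"))
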