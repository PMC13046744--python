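"""Synthetic cohort generator: activity traces, covariates, SII and survival.

The generator emits minute-level ENMO traces with a cosinor backbone
(Y(t) = M + A cos(2pi (t - phi)/24) + e(t)), subject-level parameter
heterogeneity, day-to-day variability, an SII mediator driven linearly by
behavioural features, and Gompertz proportional-hazards survival with
administrative censoring.  Every quantity has a recorded ground truth so the
downstream estimators (cosinor fit, GLM, Gompertz MLE, mediation) can be
tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .features import EpochSeries

__all__ = [
    "SubjectParams",
    "GompertzTruth",
    "GeneratorConfig",
    "CohortBundle",
    "simulate_activity_series",
    "simulate_raw_triaxial",
    "simulate_sii",
    "simulate_survival",
    "generate_subject_truth",
    "generate_cohort",
    "default_config",
    "null_mediation_config",
    "full_mediation_config",
]

MINUTES_PER_DAY = 1440


@dataclass
class SubjectParams:
    """Ground-truth rhythm parameters of one subject."""

    subject_id: str = "S0"
    mesor: float = 45.0          # mg
    amplitude: float = 43.0      # mg
    acrophase_h: float = 14.0    # clock hour of the fitted maximum
    day_cv: float = 0.0          # CV of the lognormal day multiplier on amplitude
    low_day_prob: float = 0.0    # probability of a whole-day "rest day"
    low_day_mult: float = 0.25   # whole-profile multiplier on rest days
    acrophase_day_sd: float = 0.0   # h, Gaussian day-to-day jitter of the peak
    noise_sd: float = 0.0        # mg, additive truncated-Gaussian epoch noise
    mult_sigma: float = 0.0      # sigma of mean-preserving lognormal epoch noise
    noise_ar: float = 0.0        # AR(1) coefficient of the epoch noise
    bout_rate: float = 0.0       # expected MVPA bouts per day (off by default)
    bout_mg: float = 200.0       # added intensity during a bout
    bout_len_min: int = 20
    night_depth: float = 0.0     # 0..1 extra suppression opposite the acrophase
    fragmented: bool = False     # fragmented-rhythm phenotype


@dataclass
class GompertzTruth:
    """True hazard h(t) = b * exp(a t) * exp(eta), eta = sum(beta_k * x_k)."""

    a: float = 0.09              # 1/year shape
    b: float = 2.2e-3            # 1/year baseline rate
    beta: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("Gompertz rate b must be positive")


@dataclass
class GeneratorConfig:
    n_subjects: int = 1000
    days: int = 7
    epoch_s: int = 60
    # population distributions of the rhythm parameters
    mesor_dist: tuple = (22.0, 10.0)            # Normal, mg
    amplitude_dist: tuple = (4.15, 0.37)        # Lognormal (mu, sigma)
    acrophase_dist: tuple = (13.9, 1.1)         # Normal, clock h
    day_cv: float = 0.65                        # amplitude day-multiplier CV
    low_day_prob: float = 0.20                  # whole-day rest-day probability
    low_day_mult: float = 0.25
    acrophase_day_sd: float = 1.3               # h
    noise_sd: float = 4.0                       # mg additive
    mult_sigma: float = 0.32                    # lognormal epoch-noise sigma
    noise_ar: float = 0.6                       # AR(1) noise correlation
    frag_prob: float = 0.10
    bout_rate_dist: tuple = (0.5, 0.9)          # Normal truncated at 0, bouts/day
    night_depth: float = 0.8
    # SII mediator model: SII = intercept + sum(coeff * term) + N(0, noise)
    sii_intercept: float = 560.0
    sii_coeffs: Dict[str, float] = field(
        default_factory=lambda: {
            "amplitude": -1.0,           # per mg
            "fragmented": 30.0,
            "mvpa_true*male": -45.0,     # per h/day, males only
            "age_c": 1.0,                # per year over 58
        }
    )
    sii_noise_sd: float = 150.0
    # survival truth
    gompertz_truth: GompertzTruth = field(
        default_factory=lambda: GompertzTruth(
            a=0.09,
            b=2.2e-3,
            beta={
                "age_c": 0.085,
                "male": 0.35,
                "amplitude_c": -0.012,   # per mg of true cosinor amplitude
                "fragmented": 0.25,
                "insufficient_mvpa": 0.25,
                "sii_z*male": 0.30,
                "sii_z": 0.05,
            },
        )
    )
    censor_years: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if 3600 % self.epoch_s != 0:
            raise ValueError("epoch_s must divide 3600")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.frag_prob <= 1.0:
            raise ValueError("frag_prob must be in [0, 1]")
        if np.exp(self.amplitude_dist[0]) <= 0:
            raise ValueError("amplitude location must be positive")


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, keyed by subject_id."""

    series: Dict[str, EpochSeries]
    covariates: pd.DataFrame
    blood: pd.DataFrame          # sii, platelets, neutrophils, lymphocytes
    survival: pd.DataFrame       # time (years), event (0/1)
    truth: pd.DataFrame          # per-subject generative parameters

    def __post_init__(self) -> None:
        ids = set(self.truth["subject_id"])
        for name, tab in [
            ("covariates", self.covariates),
            ("blood", self.blood),
            ("survival", self.survival),
        ]:
            if set(tab["subject_id"]) != ids:
                raise ValueError(f"{name} table does not share the subject-id key set")
        if (self.survival["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.survival["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per subject, derived from (seed, subject index): cohorts are
    # reproducible under subsetting
    return np.random.default_rng([seed, index])


def simulate_activity_series(
    params: SubjectParams,
    days: int = 7,
    epoch_s: int = 60,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> EpochSeries:
    """Minute-level ENMO trace from a daily-perturbed cosinor mean plus noise.

    Values are truncated at zero (ENMO is non-negative).  Deterministic given
    the seed.  MVPA bouts and the nightly low-activity window are controlled
    by ``bout_rate`` and ``night_depth`` and are off by default.
    """
    if params.amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if days < 1:
        raise ValueError("days must be >= 1")
    if 3600 % epoch_s != 0:
        raise ValueError("epoch_s must divide 3600")
    if rng is None:
        rng = np.random.default_rng(seed)

    per_day = 86400 // epoch_s
    t_day = (np.arange(per_day) + 0.5) * epoch_s / 3600.0  # clock hours, bin centres

    amp = params.amplitude * (0.3 if params.fragmented else 1.0)
    # lognormal amplitude multiplier with unit mean and CV = day_cv
    if params.day_cv > 0:
        sig2 = np.log1p(params.day_cv**2)
        mult = rng.lognormal(-sig2 / 2.0, np.sqrt(sig2), size=days)
    else:
        mult = np.ones(days)
    # occasional whole-day low-activity ("rest") days
    day_mult = np.where(rng.random(days) < params.low_day_prob,
                        params.low_day_mult, 1.0)
    phase = params.acrophase_h + (
        rng.normal(0.0, params.acrophase_day_sd, size=days)
        if params.acrophase_day_sd > 0
        else np.zeros(days)
    )

    mean = day_mult[:, None] * (
        params.mesor
        + (amp * mult)[:, None]
        * np.cos(2 * np.pi * (t_day[None, :] - phase[:, None]) / 24.0)
    )

    if params.night_depth > 0:
        night_centre = (params.acrophase_h + 12.0) % 24.0
        dist = np.abs((t_day - night_centre + 12.0) % 24.0 - 12.0)
        night = dist <= 4.0
        mean[:, night] *= 1.0 - params.night_depth

    if params.bout_rate > 0:
        n_len = max(1, int(round(params.bout_len_min * 60 / epoch_s)))
        for d in range(days):
            for _ in range(rng.poisson(params.bout_rate * day_mult[d])):
                centre = (params.acrophase_h + rng.normal(0.0, 3.0)) % 24.0
                start = int(centre * 3600 / epoch_s) % per_day
                stop = min(per_day, start + n_len)
                mean[d, start:stop] += params.bout_mg * rng.uniform(0.6, 1.4)

    y = np.maximum(mean, 0.0)
    if params.mult_sigma > 0 or params.noise_sd > 0:
        eps = rng.normal(0.0, 1.0, size=mean.size)
        if params.noise_ar > 0:
            from scipy.signal import lfilter

            rho = params.noise_ar
            eps = lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], eps)
        eps = eps.reshape(mean.shape)
        if params.mult_sigma > 0:
            # mean-preserving lognormal minute-level burstiness
            y = y * np.exp(params.mult_sigma * eps - params.mult_sigma**2 / 2.0)
            if params.noise_sd > 0:
                y = y + rng.normal(0.0, params.noise_sd, size=mean.shape)
        else:
            y = y + params.noise_sd * eps
    y = np.maximum(y, 0.0)

    if params.fragmented:
        # shuffle 30% of hourly blocks within each day
        eph = 3600 // epoch_s
        hours = 24
        for d in range(days):
            blocks = y[d].reshape(hours, eph)
            k = int(round(0.3 * hours))
            idx = rng.choice(hours, size=k, replace=False)
            blocks[np.sort(idx)] = blocks[rng.permutation(idx)]
            y[d] = blocks.reshape(-1)

    enmo = y.reshape(-1)
    return EpochSeries(
        subject_id=params.subject_id,
        start_time=pd.Timestamp("2015-01-05 00:00:00"),
        epoch_s=epoch_s,
        enmo=enmo,
        wear=np.ones(enmo.size, dtype=bool),
    )


def simulate_raw_triaxial(
    series: EpochSeries, sample_rate_hz: float = 30.0, seed: int = 0
) -> pd.DataFrame:
    """Tri-axial g-unit signal whose per-minute ENMO equals the input series.

    Each sample has vector magnitude 1 g + epoch ENMO with a random
    orientation, so max(0, |v| - 1) averaged per epoch recovers the input
    exactly (to rounding).
    """
    if sample_rate_hz < 1:
        raise ValueError("sample_rate_hz must be >= 1")
    if series.enmo.size == 0:
        raise ValueError("empty series")
    rng = np.random.default_rng(seed)
    n_per = int(round(sample_rate_hz * series.epoch_s))
    mags = 1.0 + np.repeat(series.enmo, n_per) / 1000.0
    n = mags.size
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    xyz = v * mags[:, None]
    t = np.arange(n) / sample_rate_hz
    return pd.DataFrame({"t_s": t, "x_g": xyz[:, 0], "y_g": xyz[:, 1], "z_g": xyz[:, 2]})


def _resolve_terms(df: pd.DataFrame, coeffs: Dict[str, float]) -> np.ndarray:
    """Linear predictor from coefficient dict; 'a*b' keys are products."""
    lp = np.zeros(len(df))
    for key, c in coeffs.items():
        cols = key.split("*")
        x = np.ones(len(df))
        for col in cols:
            if col not in df.columns:
                raise KeyError(f"coefficient term '{col}' not found in columns")
            x = x * df[col].to_numpy(dtype=float)
        lp += c * x
    return lp


def simulate_sii(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    sii_coeffs: Dict[str, float],
    noise_sd: float,
    seed: int = 0,
    intercept: float = 560.0,
) -> pd.DataFrame:
    """SII = linear predictor + Gaussian noise, floored at a small positive value.

    Emits platelet/neutrophil/lymphocyte counts that satisfy
    SII = platelets * neutrophils / lymphocytes exactly.
    """
    rng = np.random.default_rng(seed)
    df = pd.concat(
        [features.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1
    )
    df = df.loc[:, ~df.columns.duplicated()]
    lp = intercept + _resolve_terms(df, sii_coeffs)
    sii = lp + (rng.normal(0.0, noise_sd, len(df)) if noise_sd > 0 else 0.0)
    sii = np.maximum(sii, 10.0)
    lymph = rng.lognormal(np.log(2.0), 0.20, len(df))
    neut = rng.lognormal(np.log(4.0), 0.25, len(df))
    plate = sii * lymph / neut
    out = pd.DataFrame(
        {
            "sii": sii,
            "platelets": plate,
            "neutrophils": neut,
            "lymphocytes": lymph,
        }
    )
    if "subject_id" in df.columns:
        out.insert(0, "subject_id", df["subject_id"].to_numpy())
    return out


def gompertz_survival(t: np.ndarray, a: float, b: float, eta: np.ndarray | float = 0.0):
    """Closed-form S(t) = exp(-(b/a)(e^{at}-1) e^{eta}); exponential limit at a=0."""
    t = np.asarray(t, dtype=float)
    if abs(a) < 1e-12:
        cum = b * t
    else:
        cum = (b / a) * np.expm1(a * t)
    return np.exp(-cum * np.exp(eta))


def simulate_survival(
    linear_predictor: np.ndarray,
    gompertz_truth: GompertzTruth,
    censor_years: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Inverse-CDF event times for the Gompertz PH model, censored administratively."""
    if gompertz_truth.b <= 0:
        raise ValueError("Gompertz rate b must be positive")
    rng = np.random.default_rng(seed)
    eta = np.asarray(linear_predictor, dtype=float)
    e = rng.exponential(1.0, size=eta.size)  # -ln U
    a, b = gompertz_truth.a, gompertz_truth.b
    scaled = e * np.exp(-eta) / b
    if abs(a) < 1e-12:
        t = scaled
    else:
        arg = 1.0 + a * scaled
        with np.errstate(invalid="ignore"):
            t = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / a, np.inf)
    event = (t <= censor_years).astype(int)
    time = np.minimum(t, censor_years)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time": time, "event": event})


# ---------------------------------------------------------------------------
# cohort assembly


def _expected_mvpa_hours(
    mesor, amplitude, acrophase, mult_sigma, bout_rate, bout_len_min, night_depth,
    fragmented, mvpa_cut=100.0,
):
    """Expected daily hours above the MVPA cut under the generative model.

    Uses the lognormal exceedance probability of the mean profile on a
    regular day (day multipliers at their typical value); bout time is added
    directly.
    """
    from scipy.stats import norm

    t = (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0
    amp = np.asarray(amplitude) * np.where(fragmented, 0.3, 1.0)
    mean = np.asarray(mesor)[:, None] + amp[:, None] * np.cos(
        2 * np.pi * (t[None, :] - np.asarray(acrophase)[:, None]) / 24.0
    )
    centre = (np.asarray(acrophase) + 12.0) % 24.0
    dist = np.abs((t[None, :] - centre[:, None] + 12.0) % 24.0 - 12.0)
    mean = np.where(dist <= 4.0, mean * (1.0 - night_depth), mean)
    mean = np.maximum(mean, 0.0)
    if mult_sigma > 0:
        with np.errstate(divide="ignore"):
            z = (np.log(mvpa_cut / np.maximum(mean, 1e-9)) + mult_sigma**2 / 2.0)
        p = norm.sf(z / mult_sigma)
        p[mean <= 1e-9] = 0.0
    else:
        p = (mean > mvpa_cut).astype(float)
    hours = p.sum(axis=1) / 60.0
    hours = hours + np.asarray(bout_rate) * bout_len_min / 60.0
    return hours


def _cat3(u: float, c1: float, c2: float) -> int:
    return 0 if u < c1 else (1 if u < c2 else 2)


def generate_subject_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Per-subject ground-truth parameters plus covariates (no traces).

    Every subject's parameter draws come from a stream derived from
    (seed, subject index), so the first k subjects of a cohort are identical
    for any cohort size.
    """
    n = config.n_subjects
    rows = []
    for i in range(n):
        r = _subject_rng(config.seed, i + 2**20)
        rows.append((
            f"S{i:05d}",
            max(r.normal(*config.mesor_dist), 5.0),
            r.lognormal(config.amplitude_dist[0], config.amplitude_dist[1]),
            r.normal(*config.acrophase_dist) % 24.0,
            int(r.random() < config.frag_prob),
            max(r.normal(*config.bout_rate_dist), 0.0),
            float(np.clip(r.normal(57.0, 8.0), 40.0, 70.0)),
            int(r.random() < 0.40),          # male
            int(r.random() < 0.978),         # white
            r.normal(-2.2, 2.6),             # tdi
            _cat3(r.random(), 0.413, 0.825),  # bmi class
            int(r.random() < 0.61),          # employed
            int(r.random() < 0.072),         # shift work
            _cat3(r.random(), 0.583, 0.938),  # smoking
            _cat3(r.random(), 0.053, 0.504),  # alcohol
            int(r.random() < 0.234),         # hypertension
            int(r.random() < 0.034),         # diabetes
            int(r.random() < 0.003),         # cvd
            int(r.random() < 0.149),         # cancer
            int(r.random() < 0.002),         # neuro
            int(r.random() < 0.013),         # resp
            int(r.random() < 0.28),          # sleep disturbance
        ))
    df = pd.DataFrame(rows, columns=[
        "subject_id", "mesor", "amplitude", "acrophase", "fragmented",
        "bout_rate", "age", "male", "white", "tdi", "bmi_class", "employed",
        "shift_work", "smoking", "alcohol", "hypertension", "diabetes", "cvd",
        "cancer", "neuro", "resp", "sleep_disturbance",
    ])
    df.insert(7, "age_c", df["age"] - 58.0)
    df["mvpa_true"] = _expected_mvpa_hours(
        df["mesor"].to_numpy(), df["amplitude"].to_numpy(),
        df["acrophase"].to_numpy(), config.mult_sigma,
        df["bout_rate"].to_numpy(), 20, config.night_depth,
        df["fragmented"].to_numpy().astype(bool),
    )
    q1 = np.quantile(df["amplitude"], 0.25)
    df["low_amplitude"] = (df["amplitude"] <= q1).astype(int)
    df["amplitude_c"] = df["amplitude"] - df["amplitude"].mean()
    df["insufficient_mvpa"] = (df["mvpa_true"] * 7 * 60 < 150).astype(int)
    return df


def generate_cohort(config: GeneratorConfig, with_traces: bool = True) -> CohortBundle:
    """Full cohort bundle; with_traces=False skips minute-level series."""
    truth = generate_subject_truth(config)
    n = config.n_subjects

    blood = simulate_sii(
        truth,
        truth[["subject_id"]],
        config.sii_coeffs,
        config.sii_noise_sd,
        seed=int(np.random.default_rng([config.seed, 3]).integers(2**31)),
        intercept=config.sii_intercept,
    )
    design = truth.copy()
    s = blood["sii"].to_numpy()
    design["sii_z"] = (s - s.mean()) / s.std(ddof=1)
    eta = _resolve_terms(design, config.gompertz_truth.beta)
    survival = simulate_survival(
        eta,
        config.gompertz_truth,
        config.censor_years,
        seed=int(np.random.default_rng([config.seed, 4]).integers(2**31)),
    )
    survival.insert(0, "subject_id", truth["subject_id"].to_numpy())
    truth = truth.assign(eta_true=eta)

    series: Dict[str, EpochSeries] = {}
    if with_traces:
        for i, row in enumerate(truth.itertuples(index=False)):
            params = SubjectParams(
                subject_id=row.subject_id,
                mesor=row.mesor,
                amplitude=row.amplitude,
                acrophase_h=row.acrophase,
                day_cv=config.day_cv,
                low_day_prob=config.low_day_prob,
                low_day_mult=config.low_day_mult,
                acrophase_day_sd=config.acrophase_day_sd,
                noise_sd=config.noise_sd,
                mult_sigma=config.mult_sigma,
                noise_ar=config.noise_ar,
                bout_rate=row.bout_rate,
                night_depth=config.night_depth,
                fragmented=bool(row.fragmented),
            )
            series[row.subject_id] = simulate_activity_series(
                params,
                days=config.days,
                epoch_s=config.epoch_s,
                rng=_subject_rng(config.seed, i),
            )

    covar_cols = [
        "subject_id", "age", "age_c", "male", "white", "tdi", "bmi_class",
        "employed", "shift_work", "smoking", "alcohol", "hypertension",
        "diabetes", "cvd", "cancer", "neuro", "resp", "sleep_disturbance",
    ]
    return CohortBundle(
        series=series,
        covariates=truth[covar_cols].copy(),
        blood=blood,
        survival=survival,
        truth=truth,
    )


def default_config(n_subjects: int = 2000, seed: int = 0, **kw) -> GeneratorConfig:
    return GeneratorConfig(n_subjects=n_subjects, seed=seed, **kw)


def null_mediation_config(n_subjects: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Exposure acts on the hazard only directly; the mediator carries nothing."""
    cfg = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    cfg.sii_coeffs = {"age_c": 1.0}  # SII independent of rhythm features
    cfg.gompertz_truth = GompertzTruth(
        a=0.09, b=4.0e-3,
        beta={"age_c": 0.08, "low_amplitude": np.log(1.8), "sii_z": 0.30},
    )
    return cfg


def full_mediation_config(n_subjects: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Exposure acts on the hazard only through the mediator."""
    cfg = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    cfg.sii_coeffs = {"low_amplitude": 160.0, "age_c": 1.0}  # ~ +1 SD shift
    cfg.sii_noise_sd = 150.0
    cfg.gompertz_truth = GompertzTruth(
        a=0.09, b=4.0e-3, beta={"age_c": 0.08, "sii_z": 0.55},
    )
    return cfg


def write_cohort_csvs(bundle: CohortBundle, outdir) -> Dict[str, str]:
    """Write the bundle to plain CSV files; returns {name: path}."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    rows = []
    for sid, es in bundle.series.items():
        ts = pd.date_range(es.start_time, periods=es.enmo.size, freq=f"{es.epoch_s}s")
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                    "enmo_mg": es.enmo,
                    "wear": es.wear.astype(int),
                }
            )
        )
    if rows:
        epochs = pd.concat(rows, ignore_index=True)
        p = os.path.join(outdir, "epochs.csv")
        epochs.to_csv(p, index=False)
        paths["epochs"] = p
    for name, tab in [
        ("covariates", bundle.covariates),
        ("blood", bundle.blood),
        ("survival", bundle.survival),
        ("truth", bundle.truth),
    ]:
        p = os.path.join(outdir, f"{name}.csv")
        tab.to_csv(p, index=False)
        paths[name] = p
    return paths
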