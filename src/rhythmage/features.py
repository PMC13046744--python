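"""Rest-activity rhythm features from minute-level wrist accelerometry.

Implements the feature families used throughout the analysis: single-component
cosinor (MESOR, amplitude, acrophase, up-mesor, pseudo-F, optional period
search), nonparametric circadian metrics (IS, IV, M10/L5, relative amplitude),
physical-activity intensity features (MVPA, sedentary time, intensity
gradient), detrended fluctuation analysis, functional PCA of average 24-h
profiles, a simplified sleep detector, day-level coefficients of variation,
wear-time quality control, and the IS/IV regularity screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "CosinorFit",
    "NonparamMetrics",
    "enmo_from_raw",
    "qc_wear",
    "fit_cosinor",
    "daily_cosinor_cv",
    "nonparametric_metrics",
    "intensity_features",
    "dfa_exponents",
    "fpca_profiles",
    "sleep_metrics",
    "regularity_screen",
    "extract_features",
]


@dataclass
class EpochSeries:
    """One subject's epoch-level ENMO trace with wear annotations."""

    subject_id: str
    start_time: pd.Timestamp
    epoch_s: int
    enmo: np.ndarray  # mg, one value per epoch
    wear: np.ndarray  # bool, one flag per epoch

    def __post_init__(self) -> None:
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.enmo.size != self.wear.size:
            raise ValueError("enmo and wear must have equal length")
        if (self.enmo < 0).any():
            raise ValueError("ENMO must be non-negative")

    @property
    def per_day(self) -> int:
        return 86400 // self.epoch_s

    @property
    def n_days(self) -> int:
        return self.enmo.size // self.per_day

    @property
    def hours(self) -> np.ndarray:
        """Hours since series start (bin centres)."""
        return (np.arange(self.enmo.size) + 0.5) * self.epoch_s / 3600.0


@dataclass
class CosinorFit:
    mesor: float        # mg
    amplitude: float    # mg
    acrophase: float    # clock hour of the fitted maximum, [0, 24); nan if undefined
    period: float       # h
    pseudo_f: float
    up_mesor: float     # clock hour of the upward MESOR crossing
    rss: float          # mg^2
    acrophase_defined: bool = True


@dataclass
class NonparamMetrics:
    is_: float
    iv: float
    ra: float
    m10: float
    l5: float
    m10_onset: float
    l5_onset: float
    defined: bool = True


# ---------------------------------------------------------------------------
# ENMO and QC


def enmo_from_raw(raw: pd.DataFrame, epoch_s: int = 60) -> EpochSeries:
    """Epoch-average ENMO (mg) from raw tri-axial g-unit samples.

    Per sample: max(0, sqrt(x^2 + y^2 + z^2) - 1), then averaged within each
    epoch.  Columns: t_s, x_g, y_g, z_g.
    """
    if len(raw) == 0:
        raise ValueError("empty raw signal")
    t = raw["t_s"].to_numpy(dtype=float)
    mag = np.sqrt(
        raw["x_g"].to_numpy() ** 2 + raw["y_g"].to_numpy() ** 2 + raw["z_g"].to_numpy() ** 2
    )
    enmo_mg = np.maximum(mag - 1.0, 0.0) * 1000.0
    idx = (t // epoch_s).astype(int)
    n_epochs = idx[-1] + 1
    sums = np.bincount(idx, weights=enmo_mg, minlength=n_epochs)
    counts = np.bincount(idx, minlength=n_epochs)
    enmo = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return EpochSeries(
        subject_id="raw",
        start_time=pd.Timestamp("2015-01-05"),
        epoch_s=epoch_s,
        enmo=enmo,
        wear=counts > 0,
    )


def qc_wear(series: EpochSeries, min_hours: float = 72.0) -> Tuple[bool, str]:
    """Wear-time QC: fail on < min_hours total wear, or on any empty
    hour-of-day bin across the whole recording."""
    wear_h = series.wear.sum() * series.epoch_s / 3600.0
    if wear_h < min_hours:
        return False, f"insufficient wear time ({wear_h:.1f} h < {min_hours} h)"
    hour_of_day = (np.arange(series.enmo.size) * series.epoch_s // 3600) % 24
    covered = np.zeros(24, dtype=bool)
    np.logical_or.at(covered, hour_of_day, series.wear)
    if not covered.all():
        missing = np.where(~covered)[0]
        return False, f"no wear data in hour-of-day bin(s) {missing.tolist()}"
    return True, "pass"


# ---------------------------------------------------------------------------
# cosinor


def _cosinor_ols(t_h: np.ndarray, y: np.ndarray, period: float):
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t_h), np.cos(w * t_h), np.sin(w * t_h)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss


def fit_cosinor(
    series: EpochSeries,
    period: float = 24.0,
    period_search: bool = False,
    period_bounds: Tuple[float, float] = (23.0, 25.0),
    min_days: int = 2,
) -> CosinorFit:
    """Least-squares single-component cosinor fit.

    The nonlinear cosine fit is linearised on {1, cos wt, sin wt}; amplitude
    and acrophase follow from the two linear coefficients.  When
    period_search is set, the period minimising the RSS on a grid over
    period_bounds (refined by golden-section) is used.
    """
    mask = series.wear
    if mask.sum() < min_days * series.per_day:
        raise ValueError("insufficient data: need at least "
                         f"{min_days} full days of wear epochs")
    t = series.hours[mask]
    y = series.enmo[mask]

    if period_search:
        from scipy.optimize import minimize_scalar

        grid = np.arange(period_bounds[0], period_bounds[1] + 1e-9, 0.05)
        rss_grid = np.array([_cosinor_ols(t, y, p)[1] for p in grid])
        p0 = grid[np.argmin(rss_grid)]
        lo = max(period_bounds[0], p0 - 0.05)
        hi = min(period_bounds[1], p0 + 0.05)
        res = minimize_scalar(
            lambda p: _cosinor_ols(t, y, p)[1], bounds=(lo, hi), method="bounded"
        )
        period = float(res.x)

    beta, rss = _cosinor_ols(t, y, period)
    mesor, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    n = y.size
    tss = float(((y - y.mean()) ** 2).sum())
    mss = max(tss - rss, 0.0)
    pseudo_f = (mss / 2.0) / (rss / (n - 3)) if rss > 0 else np.inf

    if amplitude < 1e-12:
        return CosinorFit(
            mesor=float(mesor), amplitude=0.0, acrophase=np.nan, period=period,
            pseudo_f=0.0 if rss > 0 else 0.0, up_mesor=np.nan, rss=rss,
            acrophase_defined=False,
        )
    # Y = M + A cos(w t - psi); peak at w t = psi
    psi = np.arctan2(bs, bc)
    t_peak = (psi / (2 * np.pi)) * period
    # clock time of the maximum relative to the series start (midnight)
    acrophase = float(t_peak % 24.0)
    up_mesor = float((acrophase - period / 4.0) % 24.0)
    return CosinorFit(
        mesor=float(mesor), amplitude=amplitude, acrophase=acrophase,
        period=float(period), pseudo_f=float(pseudo_f), up_mesor=up_mesor, rss=rss,
    )


def _cv_percent(values: np.ndarray) -> float:
    # population SD (the CV of the day-level estimates themselves)
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m == 0:
        return np.nan
    return float(values.std() / m * 100.0)


def _circular_cv_percent(hours: np.ndarray) -> float:
    """CV of a clock-hour quantity: SD of unwrapped hours over the mean clock value."""
    rad = np.asarray(hours, dtype=float) / 24.0 * 2 * np.pi
    unwrapped = np.unwrap(rad) / (2 * np.pi) * 24.0
    mean_clock = unwrapped.mean() % 24.0
    if mean_clock == 0:
        return np.nan
    return float(unwrapped.std() / mean_clock * 100.0)


def _valid_days(series: EpochSeries, min_wear_h: float = 20.0) -> np.ndarray:
    per_day = series.per_day
    n_days = series.n_days
    wear = series.wear[: n_days * per_day].reshape(n_days, per_day)
    return wear.sum(axis=1) * series.epoch_s / 3600.0 >= min_wear_h


def daily_cosinor_cv(series: EpochSeries, min_valid_days: int = 3) -> Dict[str, float]:
    """Coefficients of variation (%) of day-level cosinor parameters.

    Each valid day (>= 20 h wear) is fitted separately at a fixed 24-h period;
    CV = sample SD / mean.  Circular parameters (acrophase, up-mesor) use the
    SD of unwrapped hours over the mean clock value.
    """
    per_day = series.per_day
    valid = _valid_days(series)
    fits = []
    for d in np.where(valid)[0]:
        sl = slice(d * per_day, (d + 1) * per_day)
        day = EpochSeries(series.subject_id, series.start_time, series.epoch_s,
                          series.enmo[sl], series.wear[sl])
        fit = fit_cosinor(day, period=24.0, min_days=1)
        fits.append(fit)
    if len(fits) < min_valid_days:
        import warnings

        warnings.warn("fewer than 3 valid days; daily CVs undefined")
        return {k: np.nan for k in
                ("amplitude_cv", "mesor_cv", "acrophase_cv", "up_mesor_cv")}
    amps = np.array([f.amplitude for f in fits])
    mesors = np.array([f.mesor for f in fits])
    acros = np.array([f.acrophase for f in fits])
    ups = np.array([f.up_mesor for f in fits])
    ok = ~np.isnan(acros)
    return {
        "amplitude_cv": _cv_percent(amps),
        "mesor_cv": _cv_percent(mesors),
        "acrophase_cv": _circular_cv_percent(acros[ok]) if ok.sum() >= 2 else np.nan,
        "up_mesor_cv": _circular_cv_percent(ups[ok]) if ok.sum() >= 2 else np.nan,
    }


# ---------------------------------------------------------------------------
# nonparametric circadian metrics


def _hourly_series(series: EpochSeries) -> np.ndarray:
    eph = 3600 // series.epoch_s
    n_hours = series.enmo.size // eph
    x = series.enmo[: n_hours * eph].reshape(n_hours, eph)
    w = series.wear[: n_hours * eph].reshape(n_hours, eph)
    with np.errstate(invalid="ignore"):
        vals = np.where(w.any(axis=1), (x * w).sum(axis=1) / np.maximum(w.sum(axis=1), 1),
                        np.nan)
    return vals


def average_profile(series: EpochSeries) -> np.ndarray:
    """Average 24-h profile at epoch resolution (wear epochs only)."""
    per_day = series.per_day
    n = (series.enmo.size // per_day) * per_day
    x = series.enmo[:n].reshape(-1, per_day)
    w = series.wear[:n].reshape(-1, per_day)
    sums = (x * w).sum(axis=0)
    counts = w.sum(axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _rolling_circular_mean(profile: np.ndarray, width: int) -> np.ndarray:
    ext = np.concatenate([profile, profile[: width - 1]])
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return (c[width:] - c[:-width]) / width


def nonparametric_metrics(series: EpochSeries) -> NonparamMetrics:
    """IS, IV (hourly binning, p = 24) and M10/L5/relative amplitude
    (rolling windows on the average 24-h profile)."""
    hourly = _hourly_series(series)
    hourly = hourly[~np.isnan(hourly)]
    n = hourly.size
    if n < 72:
        raise ValueError("need at least 3 full days for nonparametric metrics")
    xbar = hourly.mean()
    denom = ((hourly - xbar) ** 2).sum()
    if denom == 0:
        return NonparamMetrics(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, defined=False)
    p = 24
    hod = np.arange(n) % p
    hmeans = np.array([hourly[hod == h].mean() for h in range(p)])
    is_ = float(n * ((hmeans - xbar) ** 2).sum() / (p * denom))
    iv = float(n * (np.diff(hourly) ** 2).sum() / ((n - 1) * denom))

    prof = average_profile(series)
    per_hour = series.per_day // 24
    m10_roll = _rolling_circular_mean(prof, 10 * per_hour)
    l5_roll = _rolling_circular_mean(prof, 5 * per_hour)
    i10 = int(np.argmax(m10_roll))
    i5 = int(np.argmin(l5_roll))
    m10 = float(m10_roll[i10])
    l5 = float(l5_roll[i5])
    ra = float((m10 - l5) / (m10 + l5)) if (m10 + l5) > 0 else np.nan
    return NonparamMetrics(
        is_=is_, iv=iv, ra=ra, m10=m10, l5=l5,
        m10_onset=i10 * series.epoch_s / 3600.0,
        l5_onset=i5 * series.epoch_s / 3600.0,
    )


def daily_relative_amplitude(series: EpochSeries) -> np.ndarray:
    """Per-day relative amplitude from each day's own 24-h profile."""
    per_day = series.per_day
    per_hour = per_day // 24
    out = []
    for d in np.where(_valid_days(series))[0]:
        prof = series.enmo[d * per_day : (d + 1) * per_day]
        m10 = _rolling_circular_mean(prof, 10 * per_hour).max()
        l5 = _rolling_circular_mean(prof, 5 * per_hour).min()
        out.append((m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else np.nan)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# intensity features


def intensity_features(
    series: EpochSeries,
    mvpa_cut: float = 100.0,
    sed_cut: float = 40.0,
    bin_width: float = 25.0,
    bin_max: float = 4000.0,
) -> Dict[str, float]:
    """MVPA and sedentary hours/day, weekly-MVPA insufficiency flag,
    day-level CVs, and the intensity gradient.

    MVPA: mean daily hours with ENMO > mvpa_cut; sedentary: mean daily hours
    with ENMO < sed_cut during wear.  Insufficient if weekly MVPA < 150 min.
    Intensity gradient: OLS slope of ln(minutes in bin) on ln(bin midpoint)
    over 25-mg bins, zero bins dropped.
    """
    if series.wear.sum() == 0:
        raise ValueError("no wear epochs")
    per_day = series.per_day
    valid = _valid_days(series)
    if not valid.any():
        raise ValueError("no valid days")
    n = series.n_days * per_day
    x = series.enmo[:n].reshape(-1, per_day)[valid]
    w = series.wear[:n].reshape(-1, per_day)[valid]
    h_per_epoch = series.epoch_s / 3600.0

    mvpa_daily = ((x > mvpa_cut) & w).sum(axis=1) * h_per_epoch
    sed_daily = ((x < sed_cut) & w).sum(axis=1) * h_per_epoch
    mvpa = float(mvpa_daily.mean())
    sed = float(sed_daily.mean())
    weekly_min = mvpa * 7 * 60.0
    insufficient = bool(weekly_min < 150.0)  # "150 min or more" is sufficient

    vals = x[w]
    edges = np.arange(0.0, bin_max + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    minutes = counts[keep] * series.epoch_s / 60.0
    if keep.sum() >= 2:
        slope = float(np.polyfit(np.log(mids[keep]), np.log(minutes), 1)[0])
    else:
        slope = np.nan
    return {
        "mvpa_h_day": mvpa,
        "sedentary_h_day": sed,
        "insufficient_mvpa": insufficient,
        "mvpa_cv": _cv_percent(mvpa_daily) if len(mvpa_daily) >= 3 else np.nan,
        "sedentary_cv": _cv_percent(sed_daily) if len(sed_daily) >= 3 else np.nan,
        "intensity_gradient": slope,
    }


# ---------------------------------------------------------------------------
# detrended fluctuation analysis


def _dfa_fluctuations(profile: np.ndarray, sizes: Iterable[int]) -> np.ndarray:
    out = []
    for s in sizes:
        n_seg = profile.size // s
        segs = profile[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s, dtype=float)
        X = np.column_stack([np.ones(s), t])
        # residual projector applied to every segment at once
        coef, *_ = np.linalg.lstsq(X, segs.T, rcond=None)
        resid = segs.T - X @ coef
        out.append(np.sqrt((resid**2).mean()))
    return np.asarray(out)


def dfa_exponents(
    series: EpochSeries,
    short_max_h: float = 2.0,
    long_max_h: float = 27.0,
) -> Tuple[float, float]:
    """DFA scaling exponents over short (< 2 h) and long (> 2 h) scales.

    Cumulative sum of the mean-centred minute series, log-spaced window sizes,
    first-order detrending per window; alpha = slope of log F(n) vs log n.
    """
    y = series.enmo[series.wear]
    if y.size < 3 * series.per_day:
        raise ValueError("need at least 3 days of epochs for DFA")
    if y.std() == 0:
        return np.nan, np.nan
    profile = np.cumsum(y - y.mean())
    eph = 3600 // series.epoch_s  # epochs per hour
    short_sizes = np.unique(
        np.round(np.geomspace(4, short_max_h * eph, 10)).astype(int)
    )
    long_sizes = np.unique(
        np.round(np.geomspace(short_max_h * eph, min(long_max_h * eph, y.size // 4), 10)
                 ).astype(int)
    )
    f_short = _dfa_fluctuations(profile, short_sizes)
    f_long = _dfa_fluctuations(profile, long_sizes)
    a1 = float(np.polyfit(np.log(short_sizes), np.log(f_short), 1)[0])
    a2 = float(np.polyfit(np.log(long_sizes), np.log(f_long), 1)[0])
    return a1, a2


# ---------------------------------------------------------------------------
# functional PCA of average 24-h profiles


def fpca_profiles(profiles: np.ndarray, n_components: int = 4):
    """PCA of subjects x 1440 average 24-h profiles.

    Column-centred eigendecomposition; each component's largest-magnitude
    loading is made positive for reproducibility.  Returns (scores,
    components, explained_variance_ratio).
    """
    profiles = np.asarray(profiles, dtype=float)
    n, m = profiles.shape
    if n < n_components + 1:
        raise ValueError("need more subjects than components")
    centred = profiles - profiles.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    comps = vt[:n_components]
    scores = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    var = s**2
    scale = max(float((profiles**2).sum()), 1.0)
    if var.sum() > 1e-18 * scale:
        evr = var[:n_components] / var.sum()
    else:  # numerically zero between-subject variance
        evr = np.zeros(n_components)
    return scores, comps, evr


# ---------------------------------------------------------------------------
# sleep


def sleep_metrics(
    series: EpochSeries,
    rest_threshold: float = 10.0,
    smooth_min: int = 5,
    max_interruption_min: int = 20,
) -> Dict[str, float]:
    """Simplified sleep detector on noon-to-noon windows.

    Main sleep = longest run of epochs whose 5-min rolling ENMO is below the
    rest threshold, allowing interruptions of up to 20 min.  Onset is
    reported as hours since the previous midnight, so post-midnight onsets
    exceed 24.  Efficiency = fraction of the window below threshold.
    Irregular-sleep flag when the SD of nightly duration exceeds 90 min.
    """
    per_day = series.per_day
    eph = 3600 // series.epoch_s
    noon = 12 * eph
    n_windows = (series.enmo.size - noon) // per_day
    if n_windows < 3:
        raise ValueError("need at least 3 noon-to-noon windows")

    k = max(1, smooth_min * 60 // series.epoch_s)
    kernel = np.ones(k) / k
    smooth = np.convolve(series.enmo, kernel, mode="same")
    below = smooth < rest_threshold
    gap_max = max_interruption_min * 60 // series.epoch_s

    onsets, durations, effs = [], [], []
    for wdx in range(n_windows):
        a = noon + wdx * per_day
        b = a + per_day
        win = below[a:b]
        runs = _runs(win)
        if not runs:
            continue
        merged = _merge_runs(runs, gap_max)
        s0, s1 = max(merged, key=lambda r: r[1] - r[0])
        length_h = (s1 - s0) * series.epoch_s / 3600.0
        if length_h < 1.0:
            continue
        # hours since the midnight preceding this window's noon
        onset_h = (a + s0) * series.epoch_s / 3600.0 - wdx * 24.0
        eff = win[s0:s1].mean()
        onsets.append(onset_h)
        durations.append(length_h)
        effs.append(eff)

    if len(durations) <= n_windows / 2:
        return {k: np.nan for k in
                ("sleep_onset", "sleep_duration", "sleep_efficiency",
                 "sleep_duration_cv", "irregular_sleep")}
    durations = np.asarray(durations)
    sd_min = durations.std() * 60.0 if durations.size >= 2 else 0.0
    return {
        "sleep_onset": float(np.mean(onsets)),
        "sleep_duration": float(durations.mean()),
        "sleep_efficiency": float(np.mean(effs)),
        "sleep_duration_cv": _cv_percent(durations) if durations.size >= 3 else np.nan,
        "irregular_sleep": bool(sd_min > 90.0),
    }


def _runs(mask: np.ndarray):
    """(start, stop) pairs of True runs."""
    m = np.asarray(mask, dtype=bool)
    d = np.diff(m.astype(int))
    starts = np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0] + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        stops = np.r_[stops, m.size]
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs, gap_max: int):
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap_max:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


# ---------------------------------------------------------------------------
# cohort-level operations


def regularity_screen(
    metrics: pd.DataFrame,
    is_col: str = "interdaily_stability",
    iv_col: str = "intradaily_variability",
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> pd.Series:
    """Inclusion mask: IS >= its 5th percentile AND IV <= its 95th percentile
    (linear-interpolation percentiles).  Skipped with a warning for n < 20."""
    if len(metrics) < 20:
        import warnings

        warnings.warn("fewer than 20 subjects; regularity screen skipped")
        return pd.Series(True, index=metrics.index)
    is_lo = np.percentile(metrics[is_col], lower_pct)
    iv_hi = np.percentile(metrics[iv_col], upper_pct)
    return (metrics[is_col] >= is_lo) & (metrics[iv_col] <= iv_hi)


def extract_subject_features(
    series: EpochSeries,
    mvpa_cut: float = 100.0,
    sed_cut: float = 40.0,
    period_search: bool = False,
) -> Dict[str, float]:
    """All per-subject features (fPCA scores are appended cohort-wide)."""
    fit = fit_cosinor(series, period_search=period_search)
    cvs = daily_cosinor_cv(series)
    npm = nonparametric_metrics(series)
    inten = intensity_features(series, mvpa_cut=mvpa_cut, sed_cut=sed_cut)
    a1, a2 = dfa_exponents(series)
    sleep = sleep_metrics(series)
    ra_daily = daily_relative_amplitude(series)
    out = {
        "subject_id": series.subject_id,
        "mesor": fit.mesor,
        "cosinor_amplitude": fit.amplitude,
        "cosinor_amplitude_cv": cvs["amplitude_cv"],
        "acrophase": fit.acrophase,
        "acrophase_cv": cvs["acrophase_cv"],
        "up_mesor": fit.up_mesor,
        "up_mesor_cv": cvs["up_mesor_cv"],
        "pseudo_f": fit.pseudo_f,
        "interdaily_stability": npm.is_,
        "intradaily_variability": npm.iv,
        "relative_amplitude": npm.ra,
        "relative_amplitude_cv": _cv_percent(ra_daily[~np.isnan(ra_daily)])
        if np.isfinite(ra_daily).sum() >= 3 else np.nan,
        "dfa1": a1,
        "dfa2": a2,
    }
    out.update(inten)
    out.update(sleep)
    out["insufficient_mvpa"] = int(out["insufficient_mvpa"])
    if isinstance(out["irregular_sleep"], (bool, np.bool_)):
        out["irregular_sleep"] = int(out["irregular_sleep"])
    return out


def extract_features(
    series_map: Dict[str, EpochSeries],
    mvpa_cut: float = 100.0,
    sed_cut: float = 40.0,
    min_wear_hours: float = 72.0,
    period_search: bool = False,
    apply_regularity_screen: bool = True,
    n_fpca: int = 4,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Cohort feature table with QC, regularity screen and fPCA scores.

    Returns (features, flow) where flow counts subjects in/out at each
    exclusion step.
    """
    flow = {"input": len(series_map)}
    rows, profiles, ids = [], [], []
    for sid, es in series_map.items():
        ok, _ = qc_wear(es, min_hours=min_wear_hours)
        if not ok:
            continue
        rows.append(extract_subject_features(es, mvpa_cut, sed_cut, period_search))
        profiles.append(average_profile(es))
        ids.append(sid)
    flow["pass_wear_qc"] = len(rows)
    feats = pd.DataFrame(rows)
    profiles = np.asarray(profiles)

    if apply_regularity_screen and len(feats) >= 20:
        mask = regularity_screen(feats).to_numpy()
        feats = feats[mask].reset_index(drop=True)
        profiles = profiles[mask]
    flow["pass_regularity_screen"] = len(feats)

    if len(feats) > n_fpca:
        scores, _, _ = fpca_profiles(profiles, n_components=n_fpca)
        # fPC1 tracks overall amplitude and is excluded downstream
        for k in range(1, n_fpca):
            feats[f"fpc{k + 1}"] = scores[:, k]
    flow["complete_features"] = int(feats.dropna().shape[0])
    return feats, flow
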