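"""Feature-extraction unit tests: ENMO, QC, cosinor, nonparametric metrics,
intensity, DFA, fPCA, sleep, regularity screen and invariances."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rhythmage import synth
from rhythmage.features import (
    EpochSeries,
    daily_cosinor_cv,
    dfa_exponents,
    enmo_from_raw,
    fit_cosinor,
    fpca_profiles,
    intensity_features,
    nonparametric_metrics,
    qc_wear,
    regularity_screen,
    sleep_metrics,
)
from tests.conftest import make_series


def cosine_series(mesor, amplitude, peak_h, days=7, epoch_s=60, noise_sd=0.0,
                  seed=0):
    per = 86400 // epoch_s
    t = (np.arange(per * days) + 0.5) * epoch_s / 3600.0
    y = mesor + amplitude * np.cos(2 * np.pi * (t - peak_h) / 24.0)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
    return make_series(np.maximum(y, 0.0), epoch_s=epoch_s)


class TestEnmoFromRaw:
    @pytest.mark.parametrize("z,expected", [(1.0, 0.0), (1.2, 200.0), (0.8, 0.0)])
    def test_constant_orientation(self, z, expected):
        n = 600
        raw = pd.DataFrame({"t_s": np.arange(n) / 5.0, "x_g": 0.0, "y_g": 0.0,
                            "z_g": z})
        es = enmo_from_raw(raw, epoch_s=60)
        assert np.allclose(es.enmo, expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            enmo_from_raw(pd.DataFrame(columns=["t_s", "x_g", "y_g", "z_g"]))


class TestWearQC:
    def test_sixty_hours_fails(self):
        n = 7 * 1440
        wear = np.zeros(n, dtype=bool)
        wear[: 60 * 60] = True  # 60 h
        ok, why = qc_wear(make_series(np.ones(n), wear=wear))
        assert not ok and "insufficient wear" in why

    def test_full_week_passes(self):
        ok, why = qc_wear(make_series(np.ones(7 * 1440)))
        assert ok

    def test_missing_hour_of_day_fails_coverage_rule(self):
        n = 7 * 1440
        wear = np.ones(n, dtype=bool)
        hod = (np.arange(n) // 60) % 24
        wear[hod == 3] = False  # 03:00-04:00 never worn, still > 72 h total
        ok, why = qc_wear(make_series(np.ones(n), wear=wear))
        assert not ok and "hour-of-day" in why


class TestCosinor:
    def test_exact_recovery_noise_free(self):
        fit = fit_cosinor(cosine_series(50, 20, 14))
        assert fit.mesor == pytest.approx(50, abs=1e-6)
        assert fit.amplitude == pytest.approx(20, abs=1e-6)
        assert fit.acrophase == pytest.approx(14.0, abs=1e-6)
        assert fit.up_mesor == pytest.approx(8.0, abs=1e-6)

    def test_constant_series_flags_undefined_acrophase(self):
        fit = fit_cosinor(make_series(np.full(7 * 1440, 50.0)))
        assert fit.mesor == pytest.approx(50.0)
        assert fit.amplitude == 0.0
        assert fit.pseudo_f == 0.0
        assert not fit.acrophase_defined and np.isnan(fit.acrophase)

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError):
            fit_cosinor(make_series(np.ones(1440)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_phase_grid_oracle_on_noisy_series(self, seed):
        rng = np.random.default_rng(seed)
        truth_a = rng.uniform(20, 50)
        truth_p = rng.uniform(0, 24)
        es = cosine_series(60, truth_a, truth_p, noise_sd=25, seed=seed + 100)
        fit = fit_cosinor(es)
        # oracle: scan acrophase at 0.01 h resolution, profile out (M, A)
        t = es.hours
        y = es.enmo
        best = (np.inf, None, None)
        for phi in np.arange(0, 24, 0.01):
            X = np.column_stack([np.ones_like(t),
                                 np.cos(2 * np.pi * (t - phi) / 24.0)])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(res[0]) if res.size else np.inf
            if beta[1] >= 0 and sse < best[0]:
                best = (sse, beta, phi)
        _, beta_o, phi_o = best
        assert fit.amplitude == pytest.approx(beta_o[1], abs=0.02)
        assert abs((fit.acrophase - phi_o + 12) % 24 - 12) <= 0.011

    def test_period_search_finds_shifted_period(self):
        per = 1440
        t = (np.arange(per * 7) + 0.5) / 60.0
        y = 50 + 20 * np.cos(2 * np.pi * t / 24.6)
        fit = fit_cosinor(make_series(y), period_search=True)
        assert fit.period == pytest.approx(24.6, abs=0.01)


class TestDailyCV:
    def test_identical_days_give_zero_cv(self):
        cv = daily_cosinor_cv(cosine_series(50, 20, 14))
        assert cv["amplitude_cv"] == pytest.approx(0.0, abs=1e-8)

    def test_known_day_amplitudes(self):
        # day amplitudes 40, 50, 60 -> CV = sample SD / mean = 16.33%
        per = 1440
        t = (np.arange(per) + 0.5) / 60.0
        days = [70 + a * np.cos(2 * np.pi * (t - 14) / 24.0) for a in (40, 50, 60)]
        es = make_series(np.concatenate(days))
        cv = daily_cosinor_cv(es)
        expect = np.std([40, 50, 60]) / 50 * 100
        assert cv["amplitude_cv"] == pytest.approx(expect, abs=1e-6)
        assert expect == pytest.approx(16.33, abs=0.005)

    def test_too_few_days_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            cv = daily_cosinor_cv(cosine_series(50, 20, 14, days=2))
        assert np.isnan(cv["amplitude_cv"])


class TestNonparametric:
    def test_perfectly_periodic_series_has_unit_is(self):
        npm = nonparametric_metrics(cosine_series(50, 20, 14))
        assert npm.is_ == pytest.approx(1.0, abs=1e-9)

    def test_hourly_cosine_iv_closed_form(self):
        t = np.arange(7 * 24, dtype=float)
        y = 50 + 20 * np.cos(2 * np.pi * t / 24.0)
        npm = nonparametric_metrics(make_series(y, epoch_s=3600))
        assert npm.iv == pytest.approx(2 * (1 - np.cos(2 * np.pi / 24)), rel=0.02)
        assert npm.iv == pytest.approx(0.0681, abs=0.002)

    def test_white_noise_iv_near_two(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 10, 168)
        npm = nonparametric_metrics(make_series(np.maximum(y, 0), epoch_s=3600))
        assert abs(npm.iv - 2.0) < 0.15

    def test_is_in_unit_interval_and_ra_identity(self, traced_cohort):
        sid = list(traced_cohort.series)[0]
        npm = nonparametric_metrics(traced_cohort.series[sid])
        assert 0.0 <= npm.is_ <= 1.0
        assert npm.ra == pytest.approx((npm.m10 - npm.l5) / (npm.m10 + npm.l5))
        assert 0.0 <= npm.ra <= 1.0

    def test_zero_variance_flagged(self):
        npm = nonparametric_metrics(make_series(np.full(7 * 1440, 5.0)))
        assert not npm.defined


class TestIntensity:
    def test_constant_150mg_is_all_mvpa(self):
        out = intensity_features(make_series(np.full(7 * 1440, 150.0)))
        assert out["mvpa_h_day"] == pytest.approx(24.0)
        assert out["sedentary_h_day"] == 0.0
        assert not out["insufficient_mvpa"]

    @pytest.mark.parametrize("weekly_min,insufficient", [(140, True), (150, False)])
    def test_weekly_mvpa_boundary_inclusive(self, weekly_min, insufficient):
        # exactly weekly_min minutes above the cut across 7 days
        per_day = weekly_min / 7.0
        day = np.full(1440, 10.0)
        n_whole = int(per_day)
        day[:n_whole] = 150.0
        days = np.tile(day, 7)
        extra = int(round((per_day - n_whole) * 7))
        if extra:
            days[1440 * np.arange(extra) + n_whole] = 150.0
        out = intensity_features(make_series(days))
        assert out["insufficient_mvpa"] == insufficient

    def test_intensity_gradient_matches_independent_regression(self):
        rng = np.random.default_rng(1)
        y = rng.pareto(1.5, 7 * 1440) * 20.0
        es = make_series(np.minimum(y, 3999.0))
        out = intensity_features(es)
        edges = np.arange(0, 4025, 25.0)
        counts, _ = np.histogram(es.enmo, bins=edges)
        mids = (edges[:-1] + edges[1:]) / 2
        keep = counts > 0
        import statsmodels.api as sm

        ols = sm.OLS(np.log(counts[keep] * 1.0),
                     sm.add_constant(np.log(mids[keep]))).fit()
        assert out["intensity_gradient"] == pytest.approx(ols.params[1], abs=1e-8)

    def test_no_wear_raises(self):
        with pytest.raises(ValueError):
            intensity_features(make_series(np.ones(1440),
                                           wear=np.zeros(1440, bool)))


class TestDFA:
    def test_white_noise_exponent_half(self):
        rng = np.random.default_rng(3)
        es = make_series(np.abs(rng.normal(50, 10, 7 * 1440)))
        a1, _ = dfa_exponents(es)
        assert a1 == pytest.approx(0.5, abs=0.05)

    def test_random_walk_exponent_three_halves(self):
        rng = np.random.default_rng(4)
        w = np.cumsum(rng.normal(0, 1, 7 * 1440))
        es = make_series(w - w.min() + 1)
        a1, a2 = dfa_exponents(es)
        assert a1 == pytest.approx(1.5, abs=0.1)
        assert a2 == pytest.approx(1.5, abs=0.15)

    def test_constant_series_undefined(self):
        a1, a2 = dfa_exponents(make_series(np.full(7 * 1440, 3.0)))
        assert np.isnan(a1) and np.isnan(a2)


class TestFPCA:
    def test_identical_profiles_give_zero_scores(self):
        profiles = np.tile(np.sin(np.linspace(0, 2 * np.pi, 1440)), (10, 1))
        scores, comps, evr = fpca_profiles(profiles)
        assert np.allclose(scores, 0.0, atol=1e-9)
        assert np.allclose(evr, 0.0, atol=1e-9)

    def test_rank_one_structure_recovered(self):
        rng = np.random.default_rng(5)
        shape = np.sin(np.linspace(0, 2 * np.pi, 200))
        load = rng.normal(size=30)
        profiles = np.outer(load, shape)
        scores, comps, evr = fpca_profiles(profiles, n_components=2)
        corr = np.corrcoef(comps[0], shape)[0, 1]
        assert abs(corr) > 0.9999
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal_and_sign_convention(self):
        rng = np.random.default_rng(6)
        profiles = rng.normal(size=(40, 300))
        scores, comps, _ = fpca_profiles(profiles, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        for k in range(4):
            assert comps[k, np.argmax(np.abs(comps[k]))] > 0

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            fpca_profiles(np.ones((3, 100)), n_components=4)


def _sleep_series(active_mg=60.0, nights=None):
    """7-day series, zero activity 23:00-07:00 each night unless overridden."""
    day = np.full(1440, active_mg)
    days = np.tile(day, 7).reshape(7, 1440)
    for d in range(7):
        days[d, 23 * 60 :] = 0.0
        if d + 1 < 7:
            days[d + 1, : 7 * 60] = 0.0
    return days


class TestSleep:
    def test_constructed_window_exact_with_unsmoothed_detector(self):
        es = make_series(_sleep_series().reshape(-1))
        out = sleep_metrics(es, smooth_min=1)
        assert out["sleep_onset"] == pytest.approx(23.0, abs=0.02)
        assert out["sleep_duration"] == pytest.approx(8.0, abs=0.04)
        assert out["sleep_efficiency"] == pytest.approx(1.0)
        assert not out["irregular_sleep"]

    def test_default_smoothing_shifts_onset_by_at_most_window(self):
        es = make_series(_sleep_series().reshape(-1))
        out = sleep_metrics(es)
        assert out["sleep_onset"] == pytest.approx(23.0, abs=0.1)

    def test_interrupted_window_efficiency(self):
        days = _sleep_series()
        # two 15-min activity blocks inside every night (<= 20 min each,
        # bridged by the interruption tolerance): 30 min awake of 8 h
        for d in range(6):
            days[d + 1, 60:75] = 80.0
            days[d + 1, 180:195] = 80.0
        es = make_series(days.reshape(-1))
        out = sleep_metrics(es, smooth_min=1)
        assert out["sleep_duration"] == pytest.approx(8.0, abs=0.05)
        assert out["sleep_efficiency"] == pytest.approx(7.5 / 8.0, abs=0.01)

    def test_irregular_sleep_flag_above_90min_sd(self):
        days = _sleep_series()
        # night lengths alternate 6 h and 10 h -> SD > 90 min
        for d in range(6):
            if d % 2 == 0:
                days[d + 1, : 9 * 60] = 0.0   # extend to 10 h
            else:
                days[d + 1, 5 * 60 : 7 * 60] = 80.0  # shorten to 6 h
        out = sleep_metrics(make_series(days.reshape(-1)), smooth_min=1)
        assert out["irregular_sleep"]


class TestRegularityScreen:
    def test_identical_metrics_retain_all(self):
        df = pd.DataFrame({"interdaily_stability": np.full(50, 0.5),
                           "intradaily_variability": np.full(50, 1.0)})
        assert regularity_screen(df).all()

    def test_known_ranks_excluded(self):
        rng = np.random.default_rng(0)
        is_vals = rng.permutation(100) / 100.0
        iv_vals = rng.permutation(100) / 50.0
        df = pd.DataFrame({"interdaily_stability": is_vals,
                           "intradaily_variability": iv_vals})
        mask = regularity_screen(df)
        dropped = set(np.where(~mask)[0])
        expect = set(np.argsort(is_vals)[:5]) | set(np.argsort(iv_vals)[-5:])
        assert dropped == expect

    def test_small_sample_skipped_with_warning(self):
        df = pd.DataFrame({"interdaily_stability": [0.1, 0.9],
                           "intradaily_variability": [2.0, 0.5]})
        with pytest.warns(UserWarning):
            mask = regularity_screen(df)
        assert mask.all()

    def test_fragmented_phenotype_excluded_more_often(self):
        cfg = synth.default_config(120, seed=21)
        cfg.frag_prob = 0.3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = synth.generate_cohort(cfg)
        rows = []
        for sid, es in bundle.series.items():
            npm = nonparametric_metrics(es)
            rows.append({"subject_id": sid, "interdaily_stability": npm.is_,
                         "intradaily_variability": npm.iv})
        df = pd.DataFrame(rows).merge(
            bundle.truth[["subject_id", "fragmented"]], on="subject_id")
        mask = regularity_screen(df)
        excl = ~mask.to_numpy()
        frag = df["fragmented"].to_numpy().astype(bool)
        assert excl[frag].mean() > excl[~frag].mean()


class TestInvariances:
    def _features(self, es):
        fit = fit_cosinor(es)
        npm = nonparametric_metrics(es)
        a1, a2 = dfa_exponents(es)
        return fit, npm, (a1, a2)

    def test_whole_day_shift_leaves_features_unchanged(self):
        es = cosine_series(50, 25, 13, noise_sd=15, seed=2)
        rolled = make_series(np.roll(es.enmo, 1440))
        f0, n0, d0 = self._features(es)
        f1, n1, d1 = self._features(rolled)
        assert f1.amplitude == pytest.approx(f0.amplitude, rel=1e-9)
        assert f1.acrophase == pytest.approx(f0.acrophase, abs=1e-9)
        assert n1.is_ == pytest.approx(n0.is_, rel=1e-9)
        assert n1.ra == pytest.approx(n0.ra, rel=1e-9)

    @pytest.mark.parametrize("delta_h", [3, 7])
    def test_time_shift_moves_acrophase(self, delta_h):
        es = cosine_series(50, 25, 13, noise_sd=10, seed=3)
        rolled = make_series(np.roll(es.enmo, delta_h * 60))
        f0 = fit_cosinor(es)
        f1 = fit_cosinor(rolled)
        shift = (f1.acrophase - f0.acrophase) % 24
        assert shift == pytest.approx(delta_h, abs=0.05)

    def test_scale_equivariance(self):
        es = cosine_series(50, 25, 13, noise_sd=15, seed=4)
        scaled = make_series(3.0 * es.enmo)
        f0, n0, d0 = self._features(es)
        f1, n1, d1 = self._features(scaled)
        assert f1.mesor == pytest.approx(3 * f0.mesor, rel=1e-9)
        assert f1.amplitude == pytest.approx(3 * f0.amplitude, rel=1e-9)
        assert n1.m10 == pytest.approx(3 * n0.m10, rel=1e-9)
        assert n1.is_ == pytest.approx(n0.is_, rel=1e-9)
        assert n1.iv == pytest.approx(n0.iv, rel=1e-9)
        assert n1.ra == pytest.approx(n0.ra, rel=1e-9)
        assert d1[0] == pytest.approx(d0[0], rel=1e-9)
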