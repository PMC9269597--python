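"""HRV feature catalog: time-domain, three spectral estimators, non-linear."""

import numpy as np
import pytest

from facehrv.hrv import (
    NONLINEAR_NAMES,
    TIME_DOMAIN_NAMES,
    FreqBands,
    band_features,
    dfa,
    extract_all_features,
    nonlinear_features,
    poincare_features,
    psd_estimate,
    resample_nni,
    sample_entropy,
    time_domain_features,
)
from facehrv.pulse import NNISeries
from facehrv.synthetic import generate_rr_series


def _series(nni_ms, t0=0.0):
    nni_ms = np.asarray(nni_ms, dtype=float)
    beat_times = t0 + np.concatenate(([0.0], np.cumsum(nni_ms / 1000.0)))
    return NNISeries(nni=nni_ms, nni_times=beat_times[1:], beat_times=beat_times)


def _modulated_series(duration=600.0, hr=60.0, lf=0.0, hf=0.05, hf_freq=0.25,
                      jitter=0.0, seed=1):
    truth = generate_rr_series(duration, hr, lf_amp=lf, lf_freq_hz=0.1,
                               hf_amp=hf, hf_freq_hz=hf_freq,
                               jitter_sd_ms=jitter, seed=seed)
    return _series(truth.nni, t0=truth.beat_times[0])


class TestTimeDomain:
    def test_constant_series(self):
        fs = time_domain_features(_series([1000.0] * 61))
        assert fs["nni_mean"] == 1000.0
        assert fs["sdnn"] == 0.0
        assert fs["rmssd"] == 0.0
        assert fs["nn50"] == 0 and fs["pnn50"] == 0.0
        assert fs["hr_mean"] == pytest.approx(60.0)

    def test_hand_evaluated_formulas(self):
        fs = time_domain_features(_series([1000.0, 950.0, 1050.0]))
        # diffs are -50 and +100
        assert fs["rmssd"] == pytest.approx(np.sqrt((50**2 + 100**2) / 2), abs=1e-4)
        assert fs["rmssd"] == pytest.approx(79.0569, abs=1e-3)
        assert fs["nn50"] == 1
        assert fs["pnn50"] == pytest.approx(50.0)
        assert fs["sdnn"] == pytest.approx(np.std([1000, 950, 1050], ddof=1))
        assert fs["nni_diff_mean"] == pytest.approx(75.0)

    def test_catalog_is_fifteen_fixed_names(self, long_nni):
        fs = time_domain_features(long_nni)
        assert tuple(fs.features) == TIME_DOMAIN_NAMES
        assert len(fs) == 15
        assert all(t == "time" for t in fs.method_tags.values())

    def test_strict_nnxx_thresholds(self):
        # a difference of exactly 50 ms must NOT count ("more than 50 ms")
        fs = time_domain_features(_series([1000.0, 1050.0, 1000.0]))
        assert fs["nn50"] == 0
        assert fs["nn20"] == 2

    def test_scale_invariance_of_dispersion(self, long_nni):
        fs1 = time_domain_features(long_nni)
        scaled = _series(long_nni.nni * 2.0)
        fs2 = time_domain_features(scaled)
        for name in ("nni_mean", "sdnn", "rmssd", "sdsd"):
            assert fs2[name] == pytest.approx(2.0 * fs1[name], rel=1e-9)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features(_series([1000.0]))


class TestResample:
    def test_constant_series_resamples_constant(self):
        sig = resample_nni(_series([800.0] * 50), fs_interp=4.0)
        np.testing.assert_allclose(sig.values, 800.0, rtol=1e-9)
        assert sig.fs == 4.0

    def test_modulation_frequency_survives(self):
        sig = resample_nni(_modulated_series(hf=0.05, hf_freq=0.1), fs_interp=4.0)
        from scipy.signal import periodogram

        freqs, power = periodogram(sig.values - sig.values.mean(), fs=4.0)
        assert freqs[np.argmax(power)] == pytest.approx(0.1, abs=0.01)

    def test_linear_fallback_warns(self):
        with pytest.warns(UserWarning, match="linear"):
            resample_nni(_series([1000.0, 900.0, 1000.0]), fs_interp=4.0)


class TestPSD:
    @pytest.mark.parametrize("method", ["welch", "ar", "lomb"])
    def test_single_tone_peak_recovery(self, method):
        series = _modulated_series(hf=0.05, hf_freq=0.25)
        psd = psd_estimate(series, method=method)
        f_peak = psd.freqs[np.argmax(psd.power)]
        df = np.median(np.diff(psd.freqs))
        assert abs(f_peak - 0.25) <= max(df, 0.01) + 1e-9

    def test_welch_total_power_parseval(self):
        series = _modulated_series(hf=0.0, jitter=20.0, seed=5)
        tach = resample_nni(series, fs_interp=4.0)
        psd = psd_estimate(series, method="welch", f_max=2.0)
        total = np.trapezoid(psd.power, psd.freqs)
        var = np.var(tach.values)
        assert total == pytest.approx(var, rel=0.10)

    def test_ar_recovers_ar2_spectral_peak(self):
        # simulate an AR(2) tachogram with a known resonance; the tachogram
        # is sampled once per beat (~1 s spacing), so the pole phase is
        # 2 pi f0 * 1 s
        rho, f0 = 0.95, 0.25
        a1 = 2 * rho * np.cos(2 * np.pi * f0 * 1.0)
        a2 = -rho**2
        rng = np.random.default_rng(7)
        x = np.zeros(2400)
        for i in range(2, x.size):
            x[i] = a1 * x[i - 1] + a2 * x[i - 2] + rng.normal()
        nni = 1000.0 + 10.0 * x / x.std()
        series = _series(nni)
        # bypass IPFM: feed the AR tachogram directly through the Burg path
        psd = psd_estimate(series, method="ar", ar_order=2, fs_interp=4.0)
        f_peak = psd.freqs[np.argmax(psd.power)]
        assert f_peak == pytest.approx(f0, rel=0.10)

    def test_unknown_method_rejected(self, long_nni):
        with pytest.raises(ValueError, match="unknown"):
            psd_estimate(long_nni, method="music")

    def test_short_series_rejected_for_welch(self):
        with pytest.raises(ValueError, match="Welch"):
            psd_estimate(_series([1000.0, 900.0, 1000.0, 950.0] * 5), method="welch")


class TestBandFeatures:
    def test_twelve_per_method_and_rel_sum(self, long_nni):
        for method in ("welch", "ar", "lomb"):
            fs = psd_estimate(long_nni, method=method)
            feats = band_features(fs)
            assert len(feats) == 12
            rel = sum(feats[f"{method}_{b}_rel"] for b in ("vlf", "lf", "hf"))
            assert rel == pytest.approx(1.0, abs=1e-6)

    def test_hf_tone_concentrates_power(self):
        series = _modulated_series(hf=0.05, hf_freq=0.25)
        feats = band_features(psd_estimate(series, method="welch"))
        assert feats["welch_hf_rel"] > 0.8
        assert feats["welch_hf_peak_hz"] == pytest.approx(0.25, abs=0.01)

    def test_band_not_on_grid_flagged_missing(self):
        from facehrv.hrv import PSDEstimate

        psd = PSDEstimate(freqs=np.linspace(0.1, 0.4, 50),
                          power=np.ones(50), method="welch")
        feats = band_features(psd)
        assert feats["welch_vlf_abs_ms2"] is None
        assert feats["welch_vlf_peak_hz"] is None

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            FreqBands(vlf=(0.0, 0.05), lf=(0.04, 0.15))


class TestPoincare:
    def test_constant_series_degenerate(self):
        fs = poincare_features(_series([1000.0] * 10))
        assert fs["sd1"] == 0.0 and fs["sd2"] == 0.0
        assert fs["ellipse_area"] == 0.0
        assert fs["sd_ratio"] is None

    def test_alternating_series_sd1(self):
        nni = np.concatenate([np.tile([900.0, 1100.0], 30), [900.0]])
        fs = poincare_features(_series(nni))
        sdsd = np.std(np.diff(nni), ddof=1)
        assert fs["sd1"] == pytest.approx(sdsd / np.sqrt(2), rel=1e-9)
        # SDSD ~ 200 ms -> SD1 ~ 200/sqrt(2) = 141.42 ms (exact under the
        # population SD; 1% covers the sample-SD correction)
        assert fs["sd1"] == pytest.approx(141.42, rel=0.01)

    def test_sd1_equals_rotated_coordinate_sd(self, long_nni):
        # oracle: SD of the scatter coordinate perpendicular to the identity line
        x, y = long_nni.nni[:-1], long_nni.nni[1:]
        perp = (x - y) / np.sqrt(2)
        fs = poincare_features(long_nni)
        assert fs["sd1"] == pytest.approx(np.std(perp, ddof=1), rel=1e-9)

    def test_ratio_pair_consistency(self, long_nni):
        fs = poincare_features(long_nni)
        assert fs["csi"] == pytest.approx(1.0 / fs["sd_ratio"], rel=1e-9)
        assert fs["sd2_sd1_ratio"] == fs["csi"]
        assert fs["ellipse_area"] == pytest.approx(np.pi * fs["sd1"] * fs["sd2"])


class TestSampleEntropy:
    def test_periodic_series_near_zero(self):
        nni = np.tile([900.0, 1000.0, 1100.0], 40)
        se = sample_entropy(_series(nni), m=2, r=0.2)
        assert se == pytest.approx(0.0, abs=0.05)

    def test_matches_naive_double_loop(self, rng):
        x = 1000.0 + 30.0 * rng.standard_normal(200)
        se = sample_entropy(_series(x), m=2, r=0.2)

        # independent O(N^2) counting oracle
        tol = 0.2 * np.std(x)
        n, m = x.size, 2
        A = B = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(m)) < tol:
                    B += 1
                    if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < tol:
                        A += 1
        assert se == pytest.approx(-np.log(A / B), rel=1e-12)

    def test_shuffling_does_not_decrease_entropy(self, rng):
        series = _modulated_series(duration=300.0, hf=0.05, jitter=2.0, seed=3)
        se_orig = sample_entropy(series)
        shuffled = rng.permutation(series.nni)
        se_shuf = sample_entropy(_series(shuffled))
        assert se_shuf >= se_orig


class TestDFA:
    def test_white_noise_alpha_half(self, rng):
        nni = 1000.0 + 30.0 * rng.standard_normal(3000)
        a1, a2, overall = dfa(nni if isinstance(nni, np.ndarray) else nni)
        assert a1 == pytest.approx(0.5, abs=0.1)
        assert a2 == pytest.approx(0.5, abs=0.1)

    def test_random_walk_alpha_three_halves(self, rng):
        steps = rng.standard_normal(3000)
        nni = 1000.0 + np.cumsum(steps)
        a1, a2, overall = dfa(nni)
        assert overall == pytest.approx(1.5, abs=0.1)

    def test_fluctuation_monotone_in_scale(self, rng):
        from facehrv.hrv import dfa_fluctuation

        x = 1000.0 + 30.0 * rng.standard_normal(1000)
        profile = np.cumsum(x - x.mean())
        values = [dfa_fluctuation(profile, n) for n in (4, 8, 16, 32, 64)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            dfa(np.full(20, 1000.0))


class TestFullCatalog:
    def test_family_sizes(self, long_nni):
        fs = extract_all_features(long_nni)
        assert len(fs.names("time")) == 15
        freq = [n for n, t in fs.method_tags.items() if t.startswith("freq_")]
        assert len(freq) == 36
        for method in ("welch", "ar", "lomb"):
            assert len(fs.names(f"freq_{method}")) == 12
        assert len(fs.names("nonlinear")) == 12
        assert len(fs) == 63

    def test_nonlinear_catalog_names(self, long_nni):
        fs = nonlinear_features(long_nni)
        assert tuple(fs.features) == NONLINEAR_NAMES

    def test_every_value_finite_or_missing(self, long_nni):
        fs = extract_all_features(long_nni)
        for name, value in fs.features.items():
            assert value is None or np.isfinite(value), name

    def test_estimators_agree_on_lf_hf_ratio(self):
        """LF:HF power generated 1:2 -> estimated hf_rel/lf_rel in [1.5, 2.7]."""
        # equal-amplitude check: hf_amp/lf_amp = sqrt(2) gives power ratio 2
        # mild broadband jitter keeps the spectrum off the all-pole
        # estimator's degenerate pure-line case
        truth = generate_rr_series(600.0, 70.0, lf_amp=0.02, lf_freq_hz=0.1,
                                   hf_amp=0.02 * np.sqrt(2), hf_freq_hz=0.25,
                                   jitter_sd_ms=3.0, seed=13)
        series = _series(truth.nni, t0=truth.beat_times[0])
        for method in ("welch", "ar", "lomb"):
            feats = band_features(psd_estimate(series, method=method))
            ratio = feats[f"{method}_hf_rel"] / feats[f"{method}_lf_rel"]
            assert 1.5 <= ratio <= 2.7, method

    def test_constant_series_dispersion_zero_or_missing(self):
        fs = extract_all_features(_series([1000.0] * 400))
        assert fs["nni_mean"] == 1000.0
        assert fs["sdnn"] == 0.0
        assert fs["sampen"] is None
        assert fs["sd_ratio"] is None
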