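"""Step-response metrics: amplitude, Hill fit, QI, latency, bias, transience."""

import warnings

import numpy as np
import pytest

import chirpcode as cc
from chirpcode.metrics import (
    bias_index,
    classify_response,
    fit_hill,
    latency_to_onset,
    match_firing_rate,
    quality_index,
    response_amplitude,
    transience_index,
)
from chirpcode.preprocess import PSTHMatrix, bin_psth


def psth_from_rate(rate_per_bin, bin_s, t0=0.0, n_trials=4):
    """Deterministic PSTH whose every trial holds rate*bin_s expected counts."""
    counts = np.tile(np.asarray(rate_per_bin, float)[:, None] * bin_s, (1, n_trials))
    return PSTHMatrix(counts, bin_s, t0)


class TestResponseAmplitude:
    def test_constant_rate_gives_zero(self):
        psth = psth_from_rate(np.full(320, 5.0), 0.025, t0=-2.0)
        assert response_amplitude(psth) == pytest.approx(0.0)

    def test_baseline_subtraction(self):
        rate = np.full(320, 2.0)
        rate[84] = 47.0  # t = 0.1 s given t0 = -2
        psth = psth_from_rate(rate, 0.025, t0=-2.0)
        assert response_amplitude(psth) == pytest.approx(45.0)

    def test_off_response_captured_after_offset(self):
        rate = np.full(320, 1.0)
        rate[208] = 30.0  # t = 3.2 s
        psth = psth_from_rate(rate, 0.025, t0=-2.0)
        assert response_amplitude(psth) == pytest.approx(29.0)

    def test_missing_baseline_window_rejected(self):
        psth = psth_from_rate(np.full(240, 5.0), 0.025, t0=0.0)
        with pytest.raises(ValueError, match="baseline"):
            response_amplitude(psth)


class TestFitHill:
    def test_exact_recovery_on_clean_curve(self):
        x = np.array([13.0, 14.0, 15.0, 15.5, 16.0, 17.0])
        y = 3.0 + (40.0 - 3.0) / (1.0 + 10.0 ** (1.2 * (15.4 - x)))
        fit = fit_hill(y, x)
        assert fit.ec50_log == pytest.approx(15.4, abs=1e-4)
        assert fit.slope == pytest.approx(1.2, abs=1e-3)
        assert fit.top == pytest.approx(40.0, abs=1e-3)
        assert fit.r2 > 0.999

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, np.nan, 2.0, 3.0], [13, 14, 15, 16])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, 2.0, 3.0], [13, 14, 15])

    def test_flat_data_low_r2(self):
        fit = fit_hill([5.0, 5.0, 5.0, 5.0, 5.0], [13, 14, 15, 16, 17])
        assert fit.r2 <= 0.5


def brute_force_qi(counts):
    """Two-loop population-variance oracle for the quality index."""
    n_bins, n_trials = counts.shape
    mean_per_bin = [sum(counts[b]) / n_trials for b in range(n_bins)]
    mu = sum(mean_per_bin) / n_bins
    num = sum((m - mu) ** 2 for m in mean_per_bin) / n_bins
    dens = []
    for r in range(n_trials):
        col = counts[:, r]
        m = sum(col) / n_bins
        dens.append(sum((v - m) ** 2 for v in col) / n_bins)
    den = sum(dens) / n_trials
    return num / den if den > 0 else 0.0


class TestQualityIndex:
    def test_identical_trials_give_one(self):
        trial = np.array([0, 3, 1, 4, 2, 5], dtype=float)
        psth = PSTHMatrix(np.tile(trial[:, None], (1, 6)), 0.2, 0.0)
        assert quality_index(psth) == pytest.approx(1.0)

    def test_white_noise_scales_as_inverse_trials(self):
        rng = np.random.default_rng(0)
        for n_trials in (5, 20):
            qis = [
                quality_index(
                    PSTHMatrix(rng.normal(size=(400, n_trials)) + 10, 0.2, 0.0)
                )
                for _ in range(30)
            ]
            assert np.mean(qis) == pytest.approx(1.0 / n_trials, rel=0.2)

    def test_all_constant_trials_define_zero(self):
        psth = PSTHMatrix(np.full((10, 4), 3.0), 0.2, 0.0)
        assert quality_index(psth) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.poisson(2.0, size=(rng.integers(3, 20), rng.integers(2, 8)))
            psth = PSTHMatrix(counts, 0.2, 0.0)
            assert quality_index(psth) == pytest.approx(
                brute_force_qi(counts), abs=1e-12
            )

    def test_increases_with_reliability(self, stim):
        """QI tracks the generative trial-to-trial reliability monotonically."""
        from chirpcode.synthetic import UnitGroundTruth, rate_model, sample_spikes
        from scipy.stats import spearmanr

        gt = UnitGroundTruth(polarity_weights=(1.0, 0.0), baseline_rate=2.0, gain=40.0)
        rate = rate_model(gt, stim)
        rels = np.linspace(0.0, 1.0, 12)
        qis = []
        for k, rel in enumerate(rels):
            trials = sample_spikes(rate, stim, 10, rel, seed=500 + k)
            qis.append(quality_index(bin_psth(trials, 0.2, (0.0, 30.0))))
        rho, _ = spearmanr(rels, qis)
        assert rho > 0.9


class TestMatchFiringRate:
    def test_identical_groups_fully_paired(self):
        rates = np.linspace(1, 20, 15)
        ia, ib = match_firing_rate(rates, rates, seed=0)
        assert ia.size == 15
        np.testing.assert_allclose(rates[ia], rates[ib])

    def test_disjoint_ranges_empty_with_warning(self):
        with pytest.warns(UserWarning, match="caliper"):
            ia, ib = match_firing_rate([1.0, 2.0], [100.0, 200.0], seed=0)
        assert ia.size == 0

    def test_matching_reduces_ks_distance(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 200)
        b = rng.normal(13, 2, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ia, ib = match_firing_rate(a, b, seed=1)
        assert ia.size > 20
        assert ks_2samp(a[ia], b[ib]).statistic < ks_2samp(a, b).statistic


class TestLatency:
    def test_clean_step_recovered(self):
        rate = np.zeros(600)  # 1 ms bins over [-0.3, 0.3)
        rate[330:] = 80.0  # step at +30 ms
        psth = psth_from_rate(rate, 0.001, t0=-0.3)
        lat = latency_to_onset(psth)
        assert lat is not None
        assert lat == pytest.approx(0.030, abs=0.010)  # within boxcar width

    def test_flat_unit_undefined(self):
        psth = psth_from_rate(np.full(600, 4.0), 0.001, t0=-0.3)
        assert latency_to_onset(psth) is None

    def test_preset_latency_ordering(self, stim):
        """Slower ON-BC-like units vs faster RGC-like units, correct direction."""
        from chirpcode.synthetic import UnitGroundTruth, rate_model, sample_spikes

        def median_latency(lat_true, seed0):
            vals = []
            for k in range(12):
                gt = UnitGroundTruth(
                    polarity_weights=(1.0, 0.0),
                    latency_s=lat_true,
                    baseline_rate=5.0,
                    gain=70.0,
                    transience_tau_s=0.4,
                )
                trials = sample_spikes(rate_model(gt, stim), stim, 10, 0.8, seed0 + k)
                psth = bin_psth(trials, 0.001, (0.0, 30.0))
                lat = latency_to_onset(psth, baseline_window=(29.7, 30.0))
                if lat is not None:
                    vals.append(lat)
            return np.median(vals)

        assert median_latency(0.043, 900) > median_latency(0.030, 950)


class TestBiasAndTransience:
    def test_bias_extremes_and_ratio(self):
        only_on = [np.array([0.1, 0.2, 0.3])]
        assert bias_index(only_on) == 1.0
        balanced = [np.array([0.1, 0.2, 3.1, 3.2])]
        assert bias_index(balanced) == 0.0
        skewed = [np.array([0.1, 0.2, 0.3] + [3.1 + 0.01 * k for k in range(9)])]
        assert bias_index(skewed) == pytest.approx(-0.5)

    def test_bias_empty_defined_zero(self):
        assert bias_index([np.empty(0)]) == 0.0

    def test_transience_sustained_is_one(self):
        rate = np.zeros(240)
        rate[:40] = 20.0  # constant over the 1 s ON window, zero elsewhere
        psth = psth_from_rate(rate, 0.025, t0=0.0)
        assert transience_index(psth, bias=1.0) == pytest.approx(1.0)

    def test_transience_single_bin(self):
        rate = np.zeros(240)
        rate[0] = 20.0
        psth = psth_from_rate(rate, 0.025, t0=0.0)
        assert transience_index(psth, bias=1.0) == pytest.approx(1.0 / 40.0)

    def test_off_bias_anchors_at_offset(self):
        rate = np.zeros(240)
        rate[120:160] = 10.0  # 1 s after offset (t in [3, 4))
        psth = psth_from_rate(rate, 0.025, t0=0.0)
        assert transience_index(psth, bias=-0.5) == pytest.approx(1.0)
        # same response read as ON would be 0 (nothing after onset)
        assert transience_index(psth, bias=0.5) == pytest.approx(0.0)

    def test_no_step_response_undefined(self):
        psth = psth_from_rate(np.zeros(240), 0.025, t0=0.0)
        assert transience_index(psth, bias=0.5) is None

    def test_bias_time_rescaling_invariance(self):
        """Uniformly rescaling spikes and windows leaves the index unchanged."""
        trials = [np.array([0.1, 0.4, 3.2]), np.array([0.2, 3.1, 3.4])]
        scaled = [t * 2.0 for t in trials]
        assert bias_index(trials) == bias_index(
            scaled, onset_s=0.0, offset_s=6.0, window_s=1.0
        )


class TestClassification:
    @pytest.mark.parametrize(
        "bias,transience,expected",
        [
            (0.81, 0.36, "ON_transient"),
            (0.81, 0.62, "ON_sustained"),
            (-0.9, 0.5, "OFF"),
            (0.0, 0.5, "ON_OFF"),
            (-0.33, 0.5, "ON_OFF"),
            (0.34, None, None),
        ],
    )
    def test_rule_application(self, bias, transience, expected):
        assert classify_response(bias, transience) == expected
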