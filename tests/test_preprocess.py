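"""PSTH binning, exclusion rules, light-responsiveness shuffle test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chirpcode as cc
from chirpcode.preprocess import (
    bin_psth,
    exclusion_filter,
    lr_shuffle_test,
    mean_intertrial_correlation,
)


def brute_force_bin(trials, bin_s, window):
    """Per-spike loop oracle for bin_psth."""
    a, b = window
    n_bins = int(np.ceil((b - a) / bin_s - 1e-9))
    counts = np.zeros((n_bins, len(trials)), dtype=int)
    for j, spikes in enumerate(trials):
        for t in spikes:
            if a <= t < b:
                k = int((t - a) / bin_s)
                counts[min(k, n_bins - 1), j] += 1
    return counts


class TestBinPsth:
    def test_direct_counting(self):
        psth = bin_psth([np.array([0.010, 0.012, 0.030])], 0.025, (0.0, 0.075))
        np.testing.assert_array_equal(psth.counts[:, 0], [2, 1, 0])

    def test_conservation(self, on_sustained_trials):
        psth = bin_psth(on_sustained_trials, 0.025, (0.0, 30.0))
        total = sum(len(t) for t in on_sustained_trials)
        assert psth.counts.sum() == total

    def test_full_chirp_bin_count(self, on_sustained_trials):
        assert bin_psth(on_sustained_trials, 0.025, (0.0, 30.0)).n_bins == 1200

    def test_window_end_excluded(self):
        psth = bin_psth([np.array([0.074999, 0.075])], 0.025, (0.0, 0.075))
        assert psth.counts.sum() == 1

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            bin_psth([np.array([1.0])], 0.025, (2.0, 2.0))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        spikes=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), max_size=50
        ),
        bin_ms=st.sampled_from([1, 25, 50, 200]),
    )
    def test_matches_brute_force(self, spikes, bin_ms):
        trials = [np.sort(np.asarray(spikes))]
        psth = bin_psth(trials, bin_ms / 1000.0, (0.0, 1.0))
        np.testing.assert_array_equal(
            psth.counts, brute_force_bin(trials, bin_ms / 1000.0, (0.0, 1.0))
        )

    def test_rate_view(self):
        psth = bin_psth([np.array([0.01])], 0.025, (0.0, 0.05))
        assert psth.rate_view[0, 0] == pytest.approx(40.0)


class TestExclusionFilter:
    def _psth_with(self, n_active_trials, n_trials=10, dense=True):
        rng = np.random.default_rng(0)
        trials = []
        for k in range(n_trials):
            if k < n_active_trials:
                n = 400 if dense else 3
                trials.append(np.sort(rng.uniform(0, 30, n)))
            else:
                trials.append(np.empty(0))
        return bin_psth(trials, 0.025, (0.0, 30.0))

    def test_too_few_active_trials_dropped(self):
        dec = exclusion_filter(self._psth_with(7))
        assert not dec.keep and "trials" in dec.reasons

    def test_active_unit_kept(self):
        # ~131 occupied summed bins out of 1200 (>10%), 10 active trials
        rng = np.random.default_rng(1)
        occupied = rng.choice(1200, 131, replace=False) * 0.025 + 0.001
        trials = [occupied + 0.0001 * k for k in range(10)]
        psth = bin_psth(trials, 0.025, (0.0, 30.0))
        dec = exclusion_filter(psth)
        assert dec.keep and dec.frac_active_bins > 0.10

    def test_silent_unit_dropped_both(self):
        psth = bin_psth([np.empty(0)] * 10, 0.025, (0.0, 30.0))
        dec = exclusion_filter(psth)
        assert dec.reasons == ("bins", "trials")

    def test_matches_brute_force(self, small_grm6):
        for unit in small_grm6.units[:10]:
            psth = bin_psth(unit.trials, 0.025, (0.0, 30.0))
            dec = exclusion_filter(psth)
            summed = psth.counts.sum(axis=1)
            frac = sum(1 for v in summed if v > 0) / len(summed)
            ntr = sum(1 for j in range(psth.n_trials) if psth.counts[:, j].sum() > 0)
            assert dec.keep == (frac >= 0.10 and ntr >= 8)


def brute_force_mean_corr(counts):
    """Explicit pairwise np.corrcoef oracle; constant vectors -> 0."""
    x = counts.T.astype(float)
    vals = []
    for i in range(x.shape[0]):
        for j in range(i + 1, x.shape[0]):
            if x[i].std() == 0 or x[j].std() == 0:
                vals.append(0.0)
            else:
                vals.append(float(np.corrcoef(x[i], x[j])[0, 1]))
    return float(np.mean(vals))


class TestLRShuffleTest:
    def test_identical_trials_maximally_significant(self):
        trial = np.array([0.1, 0.5, 0.52, 1.4, 2.0])
        psth = bin_psth([trial] * 8, 0.025, (0.0, 3.0))
        res = lr_shuffle_test(psth, n_shuffles=10_000, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 10_001)
        assert res.is_lr

    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.0, size=(80, 6))
        counts[:, 2] = 0  # one silent trial: correlation convention = 0
        psth = cc.PSTHMatrix(counts, 0.025, 0.0)
        res = lr_shuffle_test(psth, n_shuffles=10, seed=0)
        assert res.statistic == pytest.approx(brute_force_mean_corr(counts), abs=1e-12)

    def test_null_matches_shifted_brute_force(self):
        """The FFT-assembled null equals recomputing after explicit rolls."""
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, size=(40, 4))
        psth = cc.PSTHMatrix(counts, 0.025, 0.0)
        seed = 11
        res = lr_shuffle_test(psth, n_shuffles=5, seed=seed)
        shifts = np.random.default_rng(seed).integers(0, 40, size=(5, 4))
        null = []
        for s in shifts:
            rolled = np.stack(
                [np.roll(counts[:, j], -int(s[j])) for j in range(4)], axis=1
            )
            null.append(brute_force_mean_corr(rolled))
        worse = sum(1 for v in null if v >= res.statistic - 1e-12)
        assert res.p_value == pytest.approx((1 + worse) / 6)

    def test_invariant_to_trial_relabeling_and_offset(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(60, 5))
        base = lr_shuffle_test(cc.PSTHMatrix(counts, 0.025, 0.0), 200, seed=1)
        perm = lr_shuffle_test(
            cc.PSTHMatrix(counts[:, [4, 2, 0, 1, 3]], 0.025, 0.0), 200, seed=1
        )
        shifted = lr_shuffle_test(cc.PSTHMatrix(counts + 7, 0.025, 0.0), 200, seed=1)
        assert base.statistic == pytest.approx(perm.statistic, abs=1e-12)
        assert base.statistic == pytest.approx(shifted.statistic, abs=1e-12)

    def test_responsive_unit_detected(self, on_sustained_trials):
        psth = bin_psth(on_sustained_trials, 0.025, (0.0, 30.0))
        assert lr_shuffle_test(psth, 10_000, seed=2).is_lr

    def test_null_pvalues_superuniform(self, stim):
        """Homogeneous-Poisson units: rejection at alpha=0.05 stays near 5%."""
        from chirpcode.synthetic import sample_spikes

        rate = np.full(stim.waveform.size, 8.0)
        rejections = 0
        n_units = 120
        for k in range(n_units):
            trials = sample_spikes(rate, stim, 8, 1.0, seed=1000 + k)
            psth = bin_psth(trials, 0.025, (0.0, 30.0))
            res = lr_shuffle_test(psth, n_shuffles=400, seed=k)
            rejections += res.p_value < 0.05
        assert rejections / n_units < 0.11

    def test_trial_vs_mean_statistic_variant(self):
        """Alternative statistic: each trial against the mean of the others."""
        rng = np.random.default_rng(6)
        trial = rng.poisson(3.0, size=80).astype(float)
        psth = cc.PSTHMatrix(np.tile(trial[:, None], (1, 6)), 0.025, 0.0)
        res = lr_shuffle_test(psth, 200, seed=0, statistic="trial_vs_mean")
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 201.0)
        noise = cc.PSTHMatrix(rng.poisson(3.0, size=(80, 6)), 0.025, 0.0)
        rn = lr_shuffle_test(noise, 200, seed=0, statistic="trial_vs_mean")
        assert rn.p_value > 1.0 / 201.0
        with pytest.raises(ValueError, match="statistic"):
            lr_shuffle_test(noise, 10, 0, statistic="bogus")

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            lr_shuffle_test(cc.PSTHMatrix(np.ones((10, 1)), 0.025, 0.0), 10, 0)


def test_restrict_subwindow(on_sustained_trials):
    psth = bin_psth(on_sustained_trials, 0.025, (0.0, 30.0))
    sub = psth.restrict((1.0, 2.0))
    assert sub.n_bins == 40
    assert sub.window == (1.0, 2.0)
    with pytest.raises(ValueError):
        psth.restrict((29.0, 31.0))
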