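"""Smoothing/averaging, normalization, centering, epoch extraction, ANOVA."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import prepmove as pm
import prepmove.preprocess as pp
from conftest import make_tensor, single_spike_trialset


class TestSmoothAndAverage:
    def test_single_spike_has_analytic_kernel_peak(self):
        ts = single_spike_trialset([400.0])
        tens = pp.smooth_and_average(ts, 20.0, pp.TARGET, (300.0, 500.0))
        peak = 1000.0 / (20.0 * np.sqrt(2 * np.pi))  # ~19.95 spikes/s
        i = np.argmin(np.abs(tens.time - 400.0))
        assert tens.rates[0, 0, i] == pytest.approx(peak, rel=1e-3)

    def test_empty_spike_trains_give_zero_tensor(self):
        ts = single_spike_trialset([])
        tens = pp.smooth_and_average(ts, 20.0, pp.TARGET, (0.0, 400.0))
        assert np.all(tens.rates == 0.0)

    def test_homogeneous_poisson_average_matches_count_rate(self):
        """500 Poisson trials at 30 spikes/s -> time-averaged rate 30 ± 1."""
        rng = np.random.default_rng(0)
        n_trials, dur = 500, 700.0
        rows, spikes = [], {}
        for tid in range(n_trials):
            n = rng.poisson(30.0 * dur / 1000.0)
            spikes[tid] = [np.sort(rng.uniform(0, dur, n))]
            rows.append(dict(trial_id=tid, context="c", direction_deg=0.0,
                             target_on_ms=100.0, go_cue_ms=100.0,
                             move_on_ms=400.0, trial_end_ms=dur))
        ts = pm.TrialSet(trials=pd.DataFrame(rows), spikes=spikes, rates=None,
                         kinematics={}, emg={}, time_step=1.0, kin_dt=1.0,
                         n_neurons=1)
        tens = pp.smooth_and_average(ts, 20.0, pp.TARGET, (0.0, 500.0))
        assert tens.rates.mean() == pytest.approx(30.0, abs=1.0)

    def test_smoothing_conserves_spike_mass(self):
        """Time-integral of the smoothed rate equals the spike count."""
        ts = single_spike_trialset([300.0, 420.0, 421.5])
        tens = pp.smooth_and_average(ts, 20.0, pp.TARGET, (100.0, 600.0))
        integral = tens.rates[0, 0].sum() * 1.0 / 1000.0  # spikes
        assert integral == pytest.approx(3.0, rel=1e-6)

    def test_missing_condition_raises(self, auto_only_dataset):
        ts, _ = auto_only_dataset
        with pytest.raises(pm.MissingConditionError):
            pp.smooth_and_average(ts, 20.0, pp.MOVE, (-100.0, 100.0),
                                  contexts=["no-such-context"])


class TestSoftNormalize:
    def test_documented_factor_arithmetic(self):
        rates = np.zeros((1, 2, 3))
        rates[0, 0] = [0.0, 15.0, 10.0]
        tens = make_tensor(rates)
        out, factors = pm.soft_normalize(tens)
        assert factors[0] == pytest.approx(20.0)
        assert out.rates[0, 0, 2] == pytest.approx(0.5)

    def test_silent_neuron_gets_constant_factor(self):
        out, factors = pm.soft_normalize(make_tensor(np.zeros((2, 2, 4))))
        np.testing.assert_allclose(factors, 5.0)
        assert np.all(out.rates == 0.0)

    def test_round_trip_and_range_bound(self):
        rng = np.random.default_rng(3)
        tens = make_tensor(rng.gamma(2.0, 10.0, (6, 4, 20)))
        out, factors = pm.soft_normalize(tens)
        np.testing.assert_allclose(
            out.rates * factors[:, None, None], tens.rates, atol=1e-12
        )
        rng_norm = out.rates.max(axis=(1, 2)) - out.rates.min(axis=(1, 2))
        assert np.all(rng_norm < 1.0)


class TestMeanCenter:
    def test_two_condition_arithmetic(self):
        rates = np.zeros((1, 2, 1))
        rates[0, :, 0] = [4.0, 6.0]
        out, mean = pm.mean_center(make_tensor(rates))
        np.testing.assert_allclose(out.rates[0, :, 0], [-1.0, 1.0])
        assert mean[0, 0] == pytest.approx(5.0)

    def test_centering_is_idempotent_and_exact(self):
        rng = np.random.default_rng(5)
        tens = make_tensor(rng.normal(10, 3, (5, 6, 30)))
        once, _ = pm.mean_center(tens)
        twice, _ = pm.mean_center(once)
        assert np.abs(once.rates.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(once.rates, twice.rates, atol=1e-12)

    def test_single_condition_is_degenerate(self):
        with pytest.raises(ValueError):
            pm.mean_center(make_tensor(np.ones((2, 1, 5))))


class TestConcatenateAndEpochs:
    def test_constant_tensors_join_without_discontinuity(self):
        left = make_tensor(np.full((2, 3, 400), 10.0), lock=pp.TARGET, t0=-50.0)
        right = make_tensor(np.full((2, 3, 80), 10.0), lock=pp.MOVE, t0=-40.0)
        cat = pm.concatenate_alignments(left, right, separation=300.0)
        assert np.all(cat.rates == 10.0)
        assert np.abs(np.diff(cat.rates, axis=2)).max() == 0.0
        # target-locked part is trimmed where the movement-locked part begins
        assert cat.junction_index == cat.time.size - 80
        assert np.all(np.diff(cat.time) > 0)

    def test_default_windows_give_documented_lengths(self):
        """-200..450 target-locked plus -350..400 movement-locked at 1 ms."""
        left = make_tensor(np.zeros((1, 2, 651)), lock=pp.TARGET, t0=-200.0)
        right = make_tensor(np.zeros((1, 2, 751)), lock=pp.MOVE, t0=-350.0)
        cat = pm.concatenate_alignments(left, right, separation=900.0)
        assert left.time.size == 651 and right.time.size == 751
        assert cat.time.size == 651 + 751
        assert cat.junction_index == 651

    def test_full_overlap_is_rejected(self):
        left = make_tensor(np.zeros((1, 2, 50)), lock=pp.TARGET, t0=0.0)
        right = make_tensor(np.zeros((1, 2, 300)), lock=pp.MOVE, t0=-350.0)
        with pytest.raises(ValueError):
            pm.concatenate_alignments(left, right, separation=100.0)

    def test_junction_discontinuity_small_at_true_separation(self, small_dataset):
        """Using the median separation keeps the junction step near the noise
        level; forcing a wrong separation inflates it."""
        ts, _ = small_dataset
        left = pp.smooth_and_average(ts, 20.0, pp.TARGET, (-200, 450), [pm.CUE])
        right = pp.smooth_and_average(ts, 20.0, pp.MOVE, (-350, 400), [pm.CUE])
        sep = pp.median_separation(ts, pm.CUE)

        def jump(s):
            cat = pm.concatenate_alignments(left, right, s)
            j = cat.junction_index
            return np.abs(cat.rates[:, :, j] - cat.rates[:, :, j - 1]).mean()

        assert jump(sep) < jump(sep + 250.0)

    def test_epoch_extraction_shapes_and_identity(self):
        rng = np.random.default_rng(1)
        rates = rng.normal(size=(3, 4, 900))
        tens = make_tensor(rates, lock=pp.TARGET, t0=-200.0)
        P = pm.extract_epoch(tens, pp.DELAY_EPOCH)
        assert P.shape == (3, 4 * 450)  # 450 ms delay epoch per condition
        move_tensor = make_tensor(rates[:, :, :751], lock=pp.MOVE, t0=-350.0)
        M = pm.extract_epoch(move_tensor, pp.MOVE_EPOCH)
        assert M.shape == (3, 4 * 300)  # 300 ms movement epoch
        full = pp.EpochDefinition(pp.TARGET, -200.0, 700.0)
        np.testing.assert_array_equal(
            pm.extract_epoch(tens, full), rates.reshape(3, -1)
        )

    def test_epoch_outside_bounds_raises(self):
        tens = make_tensor(np.zeros((2, 2, 100)), lock=pp.TARGET, t0=0.0)
        with pytest.raises(ValueError):
            pm.extract_epoch(tens, pp.EpochDefinition(pp.TARGET, 50.0, 500.0))


def _poisson_trialset(rng, n_neurons, rates_by_dir, trials_per_dir, dur=600.0):
    rows, spikes = [], {}
    tid = 0
    for direc, rate in rates_by_dir.items():
        for _ in range(trials_per_dir):
            trains = []
            for n in range(n_neurons):
                k = rng.poisson(rate * dur / 1000.0)
                trains.append(np.sort(rng.uniform(0, dur, k)))
            spikes[tid] = trains
            rows.append(dict(trial_id=tid, context="c", direction_deg=direc,
                             target_on_ms=0.0, go_cue_ms=0.0, move_on_ms=200.0,
                             trial_end_ms=dur))
            tid += 1
    return pm.TrialSet(trials=pd.DataFrame(rows), spikes=spikes, rates=None,
                       kinematics={}, emg={}, time_step=1.0, kin_dt=1.0,
                       n_neurons=n_neurons)


class TestTuningAnova:
    def test_type_one_error_rate_is_nominal(self):
        """Direction-independent Poisson neurons are rejected at ~alpha.

        1000 independent untuned neurons stand in for 1000 simulated
        populations; each neuron's ANOVA is an independent replicate.
        """
        rng = np.random.default_rng(8)
        ts = _poisson_trialset(rng, 1000, {d: 20.0 for d in range(0, 360, 45)}, 10)
        p = pm.tuning_anova(ts, pp.EpochDefinition(pp.TARGET, 0.0, 600.0))
        rate = np.mean(p < 0.05)
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_strong_tuning_is_detected(self):
        rng = np.random.default_rng(9)
        rates = {d: 10.0 + 40.0 * (1 + np.cos(np.deg2rad(d))) for d in
                 range(0, 360, 45)}
        ts = _poisson_trialset(rng, 1, rates, 30)
        p = pm.tuning_anova(ts, pp.EpochDefinition(pp.TARGET, 0.0, 600.0))
        assert p[0] < 1e-6

    def test_degenerate_identical_trials_yield_nan(self):
        rng = np.random.default_rng(10)
        ts = _poisson_trialset(rng, 1, {0.0: 0.0, 90.0: 0.0}, 3)
        p = pm.tuning_anova(ts, pp.EpochDefinition(pp.TARGET, 0.0, 600.0))
        assert np.isnan(p[0])

    def test_underpopulated_direction_raises(self):
        rng = np.random.default_rng(11)
        ts = _poisson_trialset(rng, 1, {0.0: 10.0, 90.0: 10.0}, 1)
        with pytest.raises(ValueError):
            pm.tuning_anova(ts, pp.EpochDefinition(pp.TARGET, 0.0, 600.0))
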