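"""Shared fixtures: small synthetic datasets built once per session."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import prepmove as pm


@pytest.fixture(scope="session")
def small_spec():
    """Three-context spec scaled down for fast unit tests."""
    return pm.SyntheticSpec(n_neurons=30, trials_per_condition=8, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return pm.generate_dataset(small_spec)


@pytest.fixture(scope="session")
def auto_only_spec():
    """Single quasi-automatic context: short trials, cheap to generate."""
    ctx = pm.default_contexts()[2]
    return pm.SyntheticSpec(
        n_neurons=24, trials_per_condition=10, contexts=(ctx,), seed=7
    )


@pytest.fixture(scope="session")
def auto_only_dataset(auto_only_spec):
    return pm.generate_dataset(auto_only_spec)


def make_tensor(rates, dt=1.0, lock="movement_onset", t0=0.0, contexts=None):
    """Wrap a (N, C, T) array as a RateTensor with a simple aligned axis."""
    rates = np.asarray(rates, dtype=float)
    n_t = rates.shape[2]
    time = t0 + np.arange(n_t) * dt
    if contexts is None:
        conds = [("ctx", 45.0 * i) for i in range(rates.shape[1])]
    else:
        conds = contexts
    return pm.RateTensor(
        rates=rates,
        time=time,
        lock=np.full(n_t, lock, dtype=object),
        rel_time=time.copy(),
        conditions=conds,
    )


def single_spike_trialset(spike_times, trial_end=1000.0, n_neurons=1):
    """One-trial TrialSet with given spike times for neuron 0."""
    trials = pd.DataFrame(
        [dict(trial_id=0, context="ctx", direction_deg=0.0, target_on_ms=0.0,
              go_cue_ms=0.0, move_on_ms=500.0, trial_end_ms=trial_end)]
    )
    spikes = {0: [np.asarray(spike_times, dtype=float)]
              + [np.empty(0)] * (n_neurons - 1)}
    T = int(trial_end)
    return pm.TrialSet(
        trials=trials, spikes=spikes, rates=None,
        kinematics={0: np.zeros((T, 2))}, emg={0: np.zeros((1, T))},
        time_step=1.0, kin_dt=1.0, n_neurons=n_neurons,
    )
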