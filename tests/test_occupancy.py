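"""Projections, occupancy, latencies, bootstrap, and similarity statistics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

import prepmove as pm
import prepmove.occupancy_stats as occ
import prepmove.preprocess as pp
from conftest import make_tensor


def _orthopair(rng, n, d1, d2):
    Q, _ = np.linalg.qr(rng.standard_normal((n, d1 + d2)))
    return Q[:, :d1], Q[:, d1:]


class TestProjectAndReconstruct:
    def test_orthonormal_inversion_recovers_latents(self):
        rng = np.random.default_rng(0)
        W, _ = np.linalg.qr(rng.standard_normal((10, 3)))
        z = rng.normal(size=(3, 4, 20))
        tens = make_tensor(np.einsum("nk,kct->nct", W, z))
        proj = pm.project(tens, W)
        np.testing.assert_allclose(proj.latents, z, atol=1e-10)

    def test_zero_tensor_gives_zero_latents(self):
        tens = make_tensor(np.zeros((6, 2, 10)))
        proj = pm.project(tens, np.eye(6)[:, :2])
        assert np.all(proj.latents == 0.0)

    def test_energy_split_is_pythagorean(self):
        rng = np.random.default_rng(1)
        Wp, Wm = _orthopair(rng, 12, 3, 3)
        rates = rng.normal(size=(12, 4, 15))
        tens = make_tensor(rates)
        ep = np.sum(pm.project(tens, Wp).latents ** 2, axis=0)
        em = np.sum(pm.project(tens, Wm).latents ** 2, axis=0)
        tot = np.sum(rates**2, axis=0)
        assert np.all(ep + em <= tot + 1e-10)
        # equality iff the data lie in the joint span
        inside = np.einsum("nk,kct->nct", Wp, pm.project(tens, Wp).latents) + \
            np.einsum("nk,kct->nct", Wm, pm.project(tens, Wm).latents)
        tens2 = make_tensor(inside)
        ep2 = np.sum(pm.project(tens2, Wp).latents ** 2, axis=0)
        em2 = np.sum(pm.project(tens2, Wm).latents ** 2, axis=0)
        np.testing.assert_allclose(ep2 + em2, np.sum(inside**2, axis=0),
                                   atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        tens = make_tensor(np.zeros((5, 2, 4)))
        with pytest.raises(ValueError):
            pm.project(tens, np.eye(4))

    def test_reconstruction_r2_extremes(self):
        rng = np.random.default_rng(2)
        Wp, Wm = _orthopair(rng, 10, 2, 2)
        pair = pm.SubspacePair(W_prep=Wp, W_move=Wm, objective_value=1.0,
                               captured={}, optimizer_report={})
        z = rng.normal(size=(2, 3, 30))
        inside = np.einsum("nk,kct->nct", Wp, z)
        ps = pm.reconstruct(make_tensor(inside), pair)
        np.testing.assert_allclose(ps.r2, 1.0, atol=1e-10)
        # data orthogonal to both subspaces
        basis = np.hstack([Wp, Wm])
        raw = rng.normal(size=(10, 3, 30))
        outside = raw - np.einsum(
            "nk,kct->nct", basis, np.einsum("nk,nct->kct", basis, raw)
        )
        ps2 = pm.reconstruct(make_tensor(outside), pair)
        assert np.nanmax(ps2.r2) < 1e-10

    def test_full_reconstruction_requires_mean(self):
        rng = np.random.default_rng(3)
        Wp, Wm = _orthopair(rng, 6, 2, 2)
        pair = pm.SubspacePair(W_prep=Wp, W_move=Wm, objective_value=1.0,
                               captured={}, optimizer_report={})
        with pytest.raises(ValueError):
            pm.reconstruct(make_tensor(np.zeros((6, 2, 5))), pair, full=True)


class TestOccupancy:
    def test_condition_identical_latents_have_zero_occupancy(self):
        tens = make_tensor(np.tile(np.random.default_rng(0).normal(
            size=(4, 1, 10)), (1, 3, 1)))
        tr = pm.occupancy(pm.project(tens, np.eye(4)[:, :2]))
        np.testing.assert_allclose(tr.values, 0.0, atol=1e-12)

    def test_hand_computed_variance(self):
        vals = np.linspace(-1.0, 1.0, 8)
        lat = vals[None, :, None] * np.ones((1, 8, 1))
        proj = occ.ProjectionSet(latents=lat, time=np.array([0.0]),
                                 rel_time=np.array([0.0]),
                                 lock=np.array(["movement_onset"]),
                                 conditions=[("c", d) for d in range(8)])
        tr = pm.occupancy(proj)
        assert tr.values[0] == pytest.approx(np.var(vals, ddof=1))

    def test_latent_and_reconstruction_routes_agree(self):
        """Occupancy from latents equals summed per-neuron pattern variance."""
        rng = np.random.default_rng(4)
        Wp, _ = _orthopair(rng, 15, 4, 4)
        tens = make_tensor(rng.normal(size=(15, 6, 25)))
        proj = pm.project(tens, Wp)
        route_a = pm.occupancy(proj).values
        patterns = np.einsum("nk,kct->nct", Wp, proj.latents)
        route_b = patterns.var(axis=1, ddof=1).sum(axis=0)
        np.testing.assert_allclose(route_a, route_b, atol=1e-10)

    def test_single_condition_rejected(self):
        tens = make_tensor(np.zeros((4, 1, 5)))
        with pytest.raises(ValueError):
            pm.occupancy(pm.project(tens, np.eye(4)[:, :1]))

    def test_reference_normalization(self):
        rng = np.random.default_rng(5)
        tens = make_tensor(rng.normal(size=(4, 3, 12)))
        tr = pm.occupancy(pm.project(tens, np.eye(4)[:, :2]))
        ref = pm.occupancy(pm.project(tens, np.eye(4)[:, 2:]))
        normed = tr.normalized(ref)
        np.testing.assert_allclose(
            normed.values, tr.values / ref.values.max(), atol=1e-12
        )


class TestBootstrap:
    def test_identical_neurons_give_zero_envelope(self):
        row = np.random.default_rng(6).normal(size=(1, 4, 60))
        tens = make_tensor(np.tile(row, (8, 1, 1)), lock=pp.MOVE, t0=-30.0)
        delay = pp.EpochDefinition(pp.MOVE, -30.0, -10.0)
        move = pp.EpochDefinition(pp.MOVE, 0.0, 25.0)
        out = pm.bootstrap_occupancy(tens, delay, move, d_prep=1, d_move=1,
                                     n_boot=4, seed=0, n_restarts=1)
        assert np.abs(out.prep.boot_sd).max() < 1e-9
        assert np.abs(out.move.boot_sd).max() < 1e-9

    def test_seeded_determinism(self, auto_only_dataset):
        ts, _ = auto_only_dataset
        tens = pp.smooth_and_average(ts, 20.0, pp.MOVE, (-250.0, 150.0))
        tens, _ = pp.mean_center(pm.soft_normalize(tens)[0])
        delay = pp.EpochDefinition(pp.MOVE, -190.0, -150.0)
        move = pp.EpochDefinition(pp.MOVE, -50.0, 150.0)
        kw = dict(d_prep=2, d_move=2, n_boot=5, seed=3, n_restarts=1)
        a = pm.bootstrap_occupancy(tens, delay, move, **kw)
        b = pm.bootstrap_occupancy(tens, delay, move, **kw)
        np.testing.assert_array_equal(a.prep.boot_sd, b.prep.boot_sd)
        np.testing.assert_array_equal(a.prep.values, b.prep.values)


class TestBootstrapPvalue:
    def test_fully_separated_distributions_hit_floor(self):
        p = pm.bootstrap_pvalue(np.arange(10, 20), np.arange(10), "greater")
        assert p == pytest.approx(1.0 / 100)

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        p = pm.bootstrap_pvalue(x, x.copy() + rng.normal(0, 1e-12, 500))
        assert p == pytest.approx(0.5, abs=0.05)

    def test_shifted_normals_match_closed_form(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.5, 1.0, 800)
        b = rng.normal(0.0, 1.0, 800)
        p = pm.bootstrap_pvalue(a, b, "greater")
        analytic = norm.cdf(-0.5 / np.sqrt(2.0))  # P(A <= B)
        assert p == pytest.approx(analytic, abs=0.05)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            pm.bootstrap_pvalue([], [1.0])


class TestThresholdLatency:
    def test_linear_ramp_analytic(self):
        t = np.arange(0.0, 101.0)
        assert pm.threshold_latency(t / 100.0, t, frac=0.1) == pytest.approx(10.0)

    def test_latency_monotone_in_fraction(self):
        rng = np.random.default_rng(9)
        v = np.cumsum(np.abs(rng.normal(size=200)))
        t = np.arange(200.0)
        lats = [pm.threshold_latency(v, t, frac=f)
                for f in [0.05, 0.1, 0.3, 0.5, 0.9]]
        assert all(a <= b + 1e-12 for a, b in zip(lats, lats[1:]))

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            pm.threshold_latency(np.zeros(10), np.arange(10.0))


class TestEmgLatency:
    def test_single_muscle_is_its_own_crossing(self):
        t = np.arange(0.0, 200.0)
        conds = np.stack([np.clip(t - 100.0 - 5 * k, 0, None) for k in range(4)])
        emg = conds[None, :, :]  # one muscle
        lat, w = pm.emg_latency(emg, t, frac=0.1)
        assert abs(abs(w[0]) - 1.0) < 1e-9
        tr = conds.var(axis=0, ddof=1)
        assert lat == pytest.approx(pm.threshold_latency(tr, t, frac=0.1))

    def test_gain_differences_are_normalized_away(self):
        t = np.arange(0.0, 200.0)
        conds = np.stack([np.clip(t - 100.0 - 5 * k, 0, None) for k in range(4)])
        one = conds[None]
        two = np.stack([conds, 7.5 * conds])
        lat1, _ = pm.emg_latency(one, t)
        lat2, _ = pm.emg_latency(two, t)
        assert lat1 == pytest.approx(lat2, abs=1e-9)

    def test_silent_set_rejected(self):
        with pytest.raises(ValueError):
            pm.emg_latency(np.zeros((2, 3, 10)), np.arange(10.0))


class TestSimilarity:
    def _proj(self, latents, t0=0.0):
        d, c, T = latents.shape
        time = t0 + np.arange(T)
        return occ.ProjectionSet(latents=latents, time=time, rel_time=time,
                                 lock=np.full(T, "movement_onset", dtype=object),
                                 conditions=[("x", 45.0 * i) for i in range(c)])

    def test_state_correlation_extremes(self):
        rng = np.random.default_rng(10)
        a = self._proj(rng.normal(size=(3, 8, 10)))
        same = pm.cross_context_state_similarity(a, a, at_time=5.0)
        flipped = pm.cross_context_state_similarity(
            a, self._proj(-a.latents), at_time=5.0
        )
        assert same == pytest.approx(1.0)
        assert flipped == pytest.approx(-1.0)

    def test_covariance_timecourse_bilinearity_and_shuffle_null(self):
        rng = np.random.default_rng(11)
        a = self._proj(rng.normal(size=(4, 8, 30)))
        b = self._proj(2.0 * a.latents)
        c11 = pm.cross_context_covariance_timecourse(a, a).values
        c12 = pm.cross_context_covariance_timecourse(a, b).values
        np.testing.assert_allclose(c12, 2.0 * c11, atol=1e-12)
        perm = rng.permutation(8)
        shuf = self._proj(a.latents[:, perm, :])
        c_sh = pm.cross_context_covariance_timecourse(a, shuf).values
        assert np.abs(c_sh).mean() < 0.3 * np.abs(c11).mean()

    def test_tuning_slope_identity_zero_and_known_gain(self):
        rng = np.random.default_rng(12)
        ref = rng.normal(size=(40, 8))
        m, se, _ = pm.tuning_slope(ref, ref)
        assert m == pytest.approx(1.0, abs=1e-12) and se < 1e-12
        m0, _, _ = pm.tuning_slope(np.zeros_like(ref), ref)
        assert m0 == pytest.approx(0.0, abs=1e-12)
        means = []
        for seed in range(30):
            r = np.random.default_rng(100 + seed)
            ref_s = r.normal(size=(40, 8))
            noisy = 1.2 * ref_s + r.normal(0, 0.2, ref_s.shape)
            means.append(pm.tuning_slope(noisy, ref_s)[0])
        assert np.mean(means) == pytest.approx(1.2, abs=0.03)

    def test_tuning_slope_excludes_flat_reference_neurons(self):
        rng = np.random.default_rng(13)
        ref = rng.normal(size=(5, 8))
        ref[2] = 1.0  # zero variance
        m, se, slopes = pm.tuning_slope(ref, ref)
        assert np.isnan(slopes[2])
        assert m == pytest.approx(1.0)

    def test_pattern_correlation_extremes(self):
        rng = np.random.default_rng(14)
        rates = rng.normal(size=(6, 4, 100))
        ta = make_tensor(rates, lock=pp.MOVE, t0=-50.0)
        tb = make_tensor(rates.copy(), lock=pp.MOVE, t0=-50.0)
        window = pp.EpochDefinition(pp.MOVE, -50.0, 50.0)
        r, med = pm.pattern_correlation(ta, tb, window)
        np.testing.assert_allclose(r, 1.0)
        noise = make_tensor(rng.normal(size=(6, 4, 100)), lock=pp.MOVE, t0=-50.0)
        _, med0 = pm.pattern_correlation(ta, noise, window)
        assert abs(med0) < 0.15


class TestRtSplit:
    def test_random_split_is_exchangeable_and_rt_split_shifts_cue(self, small_dataset):
        ts, _ = small_dataset
        tens = pp.smooth_and_average(ts, 20.0, pp.MOVE, (-300.0, 300.0), [pm.CUE])
        factors = pm.pooled_soft_factors([tens])
        tn, _ = pp.mean_center(replace(tens, rates=tens.rates / factors[:, None, None]))
        pair = pm.optimize_subspaces(
            pm.epoch_covariance(pm.extract_epoch(
                tn, pp.EpochDefinition(pp.MOVE, -300.0, -150.0))),
            pm.epoch_covariance(pm.extract_epoch(
                tn, pp.EpochDefinition(pp.MOVE, -50.0, 250.0))),
            2, 2, n_restarts=2, seed=0,
        )
        # random (non-RT) labels: halves agree closely
        rng = np.random.default_rng(0)
        ids = ts.trials[ts.trials["context"] == pm.CUE]["trial_id"].to_numpy()
        labels = {int(t): bool(v) for t, v in
                  zip(ids, rng.permutation(ids.size) < ids.size // 2)}
        out = pm.rt_split_analysis(ts, pair, factors, window=(-300.0, 300.0),
                                   contexts=[pm.CUE], split_labels=labels)
        short, long_ = out[pm.CUE]["short"], out[pm.CUE]["long"]
        denom = max(short.values.max(), long_.values.max())
        assert np.abs(short.values - long_.values).max() / denom < 0.5
        # true RT split: cue prep envelope is target-locked, so long-RT
        # trials carry the plateau further back in movement-locked time
        out_rt = pm.rt_split_analysis(ts, pair, factors, window=(-300.0, 300.0),
                                      contexts=[pm.CUE])
        lat_s = pm.threshold_latency(out_rt[pm.CUE]["short"])
        lat_l = pm.threshold_latency(out_rt[pm.CUE]["long"])
        assert lat_l <= lat_s

    def test_empty_half_rejected(self, small_dataset):
        ts, _ = small_dataset
        pair = pm.SubspacePair(W_prep=np.eye(ts.n_neurons)[:, :2],
                               W_move=np.eye(ts.n_neurons)[:, 2:4],
                               objective_value=0.5, captured={},
                               optimizer_report={})
        ids = ts.trials["trial_id"]
        labels = {int(t): True for t in ids}
        with pytest.raises(pm.MissingConditionError):
            pm.rt_split_analysis(ts, pair, np.ones(ts.n_neurons),
                                 contexts=[pm.CUE], split_labels=labels)
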