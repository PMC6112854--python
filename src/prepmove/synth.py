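"""Synthetic multi-context motor-cortical population generator.

Emulates delayed-reach experiments in which the same set of radial reaches is
initiated under three behavioral contexts:

* ``cue-initiated`` — an instructed-delay task: the target appears, a variable
  delay follows, and a go cue releases the reach.  Preparatory activity rises
  after target onset and is sustained through the delay.
* ``self-initiated`` — the animal chooses when to move; preparatory activity
  develops in a stereotyped fashion a few hundred milliseconds before
  movement onset.
* ``quasi-automatic`` — a zero-delay interception reach with very short
  reaction times; preparation is compressed into a few tens of milliseconds.

Single-neuron firing rates are driven by low-dimensional latent time courses
living in two mutually orthogonal ground-truth subspaces (a "preparatory" and
a "movement" subspace).  Movement latents form a rotating pair, shared across
contexts up to a gain, gated on shortly before movement onset.  Spiking is
Poisson (or Gaussian rate noise), kinematics are minimum-jerk reaches, and
EMG is a lagged rectified mixture of the movement latents — so every
downstream analysis stage has a testable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

CUE = "cue-initiated"
SELF = "self-initiated"
AUTO = "quasi-automatic"

#: fraction of reach duration between minimum-jerk launch and the moment the
#: speed profile crosses 1% of its peak.  Movement onset is defined
#: operationally as that threshold crossing, so the launch is placed
#: TAU_ONSET * reach_duration before the nominal movement onset.
TAU_ONSET = 0.5 * (1.0 - np.sqrt(1.0 - 0.1))  # ~0.025658


@dataclass(frozen=True)
class ContextSpec:
    """Per-context timing and latent-envelope parameters.

    ``prep_lag`` controls when preparatory latents switch on.  If set, their
    onset is movement-locked at (movement gate − prep_lag), which makes the
    designed preparatory-over-movement lead exactly ``prep_lag`` in that
    context.  If ``None`` the envelope is target-locked (the instructed-delay
    plateau shape).
    """

    name: str
    delay_range: tuple[float, float]  # ms, uniform; (0, 0) = no delay
    rt_mean: float  # ms
    rt_sd: float  # ms
    prep_lag: Optional[float]  # ms, or None for target-locked onset
    envelope: str  # "plateau" | "ramp" | "transient"
    prep_gain: float = 1.0
    move_gain_scale: float = 1.0


def default_contexts() -> tuple[ContextSpec, ...]:
    """The three study contexts with documented default RT distributions."""
    return (
        ContextSpec(CUE, (0.0, 1000.0), 253.0, 50.0, None, "plateau"),
        ContextSpec(SELF, (0.0, 0.0), 935.0, 132.0, 250.0, "ramp"),
        ContextSpec(AUTO, (0.0, 0.0), 205.0, 32.0, 40.0, "transient"),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic experiment."""

    n_neurons: int = 120
    n_directions: int = 8
    contexts: tuple[ContextSpec, ...] = field(default_factory=default_contexts)
    d_prep_true: int = 2
    d_move_true: int = 2
    time_step: float = 1.0  # ms rate/EMG grid
    rotation_freq: float = 2.0  # Hz, movement-latent rotation
    baseline_rate: float = 30.0  # spikes/s
    gain: float = 60.0  # spikes/s per unit latent loading
    move_amp: float = 1.5  # movement latents stronger than preparatory
    noise_model: str = "poisson"  # or "gaussian"
    noise_sd: float = 1.0  # spikes/s, gaussian model only
    trials_per_condition: int = 40
    pre_target: float = 300.0  # ms recorded before target onset
    post_move: float = 400.0  # ms recorded after movement onset
    move_gate: float = 150.0  # movement latents zero before move - gate
    rise_ms: float = 15.0  # half-cosine envelope rise time
    ramp_start_level: float = 0.85  # self-initiated envelope level at onset
    n_muscles: int = 8
    emg_lag: float = 20.0  # ms EMG lags movement latents
    emg_noise_sd: float = 0.02
    reach_distance: float = 130.0  # mm
    reach_duration: float = 350.0  # ms
    kin_dt: float = 1.0  # ms kinematic sample interval
    #: True: row-balanced loadings whose subspaces stay orthogonal after
    #: soft normalization (clean subspace recovery).  False: plain Gaussian
    #: QR loadings — neurons are then an approximately iid sample, the
    #: regime in which neuron-resampling bootstrap theory applies.
    balanced_loadings: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.d_prep_true + self.d_move_true > self.n_neurons:
            raise ValueError(
                "d_prep_true + d_move_true must not exceed n_neurons "
                f"({self.d_prep_true}+{self.d_move_true} > {self.n_neurons})"
            )
        for name, val in [
            ("time_step", self.time_step),
            ("kin_dt", self.kin_dt),
            ("reach_duration", self.reach_duration),
            ("pre_target", self.pre_target),
            ("post_move", self.post_move),
            ("rise_ms", self.rise_ms),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not self.contexts:
            raise ValueError("context list must be nonempty")
        for ctx in self.contexts:
            if ctx.rt_sd < 0:
                raise ValueError("rt_sd must be >= 0")
            if ctx.rt_mean <= 0:
                raise ValueError("rt_mean must be positive")
            if ctx.delay_range[1] < ctx.delay_range[0] or ctx.delay_range[0] < 0:
                raise ValueError(f"invalid delay_range {ctx.delay_range}")
            if ctx.envelope not in ("plateau", "ramp", "transient"):
                raise ValueError(f"unknown envelope {ctx.envelope!r}")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def context(self, name: str) -> ContextSpec:
        for ctx in self.contexts:
            if ctx.name == name:
                return ctx
        raise KeyError(f"unknown context label {name!r}")


@dataclass
class GroundTruth:
    """The simulator's true subspaces and canonical latent time courses.

    Latents are stored on a movement-locked time axis (``latent_time``, ms
    relative to movement onset) at the median trial timing of each context;
    per-trial latents are regenerated from the same envelope functions.
    """

    W_prep_true: np.ndarray  # (n_neurons, d_prep_true), orthonormal
    W_move_true: np.ndarray  # (n_neurons, d_move_true), orthonormal
    prep_latents: dict[str, np.ndarray]  # context -> (d, n_dir, T)
    move_latents: dict[str, np.ndarray]
    latent_time: np.ndarray  # ms relative to movement onset
    direction_tuning_prep: np.ndarray  # (d_prep_true, n_directions)
    direction_tuning_move: np.ndarray
    emg_mixing: np.ndarray  # (n_muscles, d_move_true)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("W_prep_true", data=self.W_prep_true)
            f.create_dataset("W_move_true", data=self.W_move_true)
            f.create_dataset("latent_time", data=self.latent_time)
            f.create_dataset("direction_tuning_prep", data=self.direction_tuning_prep)
            f.create_dataset("direction_tuning_move", data=self.direction_tuning_move)
            f.create_dataset("emg_mixing", data=self.emg_mixing)
            for grp_name, latents in [
                ("prep_latents", self.prep_latents),
                ("move_latents", self.move_latents),
            ]:
                grp = f.create_group(grp_name)
                for ctx, arr in latents.items():
                    grp.create_dataset(ctx, data=arr)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with h5py.File(path, "r") as f:
            return cls(
                W_prep_true=f["W_prep_true"][()],
                W_move_true=f["W_move_true"][()],
                prep_latents={k: v[()] for k, v in f["prep_latents"].items()},
                move_latents={k: v[()] for k, v in f["move_latents"].items()},
                latent_time=f["latent_time"][()],
                direction_tuning_prep=f["direction_tuning_prep"][()],
                direction_tuning_move=f["direction_tuning_move"][()],
                emg_mixing=f["emg_mixing"][()],
            )


@dataclass
class TrialSet:
    """Raw per-trial observables: spikes (or rates), kinematics, EMG, events.

    ``trials`` columns: trial_id, context, direction_deg, target_on_ms,
    go_cue_ms, move_on_ms, trial_end_ms.  All times are relative to trial
    start and snapped to the rate grid.
    """

    trials: pd.DataFrame
    spikes: dict[int, list[np.ndarray]]  # trial_id -> per-neuron spike times, ms
    rates: Optional[dict[int, np.ndarray]]  # gaussian model: (n_neurons, T)
    kinematics: dict[int, np.ndarray]  # trial_id -> (T_kin, 2) positions, mm
    emg: dict[int, np.ndarray]  # trial_id -> (n_muscles, T)
    time_step: float
    kin_dt: float
    n_neurons: int

    @property
    def contexts(self) -> list[str]:
        return list(dict.fromkeys(self.trials["context"]))

    @property
    def directions(self) -> np.ndarray:
        return np.unique(self.trials["direction_deg"].to_numpy())

    def trial_times(self, trial_id: int) -> np.ndarray:
        """Bin-center time grid of the rate/EMG traces of one trial."""
        end = float(self.trials.set_index("trial_id").loc[trial_id, "trial_end_ms"])
        n = int(round(end / self.time_step))
        return (np.arange(n) + 0.5) * self.time_step


# ---------------------------------------------------------------------------
# latent envelopes


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Half-cosine rise from 0 at x=0 to 1 at x=1."""
    y = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * y))


def _prep_envelope(
    t: np.ndarray, target_on: float, move_on: float, ctx: ContextSpec, spec: SyntheticSpec
) -> np.ndarray:
    """Preparatory latent envelope for one trial, on trial time ``t`` (ms)."""
    gate = move_on - spec.move_gate
    if ctx.prep_lag is None:
        onset = target_on
    else:
        onset = max(gate - ctx.prep_lag, target_on)
    rise = _smoothstep((t - onset) / spec.rise_ms)
    u = t - move_on
    # collapse: full strength until 70 ms before movement onset, gone by +20
    fall = 1.0 - _smoothstep((u + 70.0) / 90.0)
    if ctx.envelope == "plateau":
        s = np.maximum(t - onset - spec.rise_ms, 0.0)
        base = 1.0 + 0.3 * np.exp(-s / 80.0)  # post-target peak settling to plateau
    elif ctx.envelope == "ramp":
        span = max((move_on - 70.0) - (onset + spec.rise_ms), 1.0)
        frac = np.clip((t - onset - spec.rise_ms) / span, 0.0, 1.0)
        base = spec.ramp_start_level + (1.2 - spec.ramp_start_level) * frac
    elif ctx.envelope == "transient":
        base = np.full_like(t, 1.3)
    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown envelope {ctx.envelope!r}")
    return ctx.prep_gain * rise * base * fall


def _move_envelope(t: np.ndarray, move_on: float, spec: SyntheticSpec) -> np.ndarray:
    """Movement latent gating envelope; zero before move_on − move_gate."""
    u = t - move_on
    rise = _smoothstep((u + spec.move_gate) / spec.rise_ms)
    bump = 1.0 + 0.2 * np.exp(-(((u - 50.0) / 60.0) ** 2))  # peak just after onset
    # taper late in the movement
    fall = 1.0 - 0.8 * _smoothstep((u - 300.0) / 100.0)
    return rise * bump * fall


def _trial_latents(
    t: np.ndarray,
    target_on: float,
    move_on: float,
    dir_idx: int,
    ctx: ContextSpec,
    spec: SyntheticSpec,
    tuning_prep: np.ndarray,
    tuning_move: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent time courses (d, T) for one trial."""
    env_p = _prep_envelope(t, target_on, move_on, ctx, spec)
    z_prep = tuning_prep[:, dir_idx][:, None] * env_p[None, :]

    env_m = _move_envelope(t, move_on, spec)
    u = t - move_on
    phase = 2.0 * np.pi * spec.rotation_freq / 1000.0 * (u + spec.move_gate)
    c, s = np.cos(phase), np.sin(phase)
    z_move = np.zeros((spec.d_move_true, t.size))
    a, b = tuning_move[0, dir_idx], tuning_move[1, dir_idx]
    z_move[0] = c * a - s * b
    z_move[1] = s * a + c * b
    for k in range(2, spec.d_move_true):
        z_move[k] = tuning_move[k, dir_idx]
    z_move *= spec.move_amp * ctx.move_gain_scale * env_m[None, :]
    return z_prep, z_move


def _balanced_orthonormal(
    rng: np.random.Generator, n: int, d: int, col_weights: np.ndarray,
    n_iter: int = 60,
) -> np.ndarray:
    """Random orthonormal n x d frame with near-equal weighted row norms.

    Starting from the Q factor of a Gaussian matrix, rows are iteratively
    rescaled toward equal weighted norm and the columns re-orthonormalized by
    symmetric (Loewdin) orthogonalization, which perturbs the frame minimally.
    Row balancing keeps every neuron's modulation range comparable, so the
    soft-normalization step downstream rescales neurons nearly uniformly and
    the mutual orthogonality of the ground-truth subspaces survives into the
    analysis space.  Columns are exactly orthonormal on return.
    """
    Q, _ = np.linalg.qr(rng.standard_normal((n, d)))
    blocks = [np.flatnonzero(col_weights == w) for w in np.unique(col_weights)]
    for _ in range(n_iter):
        for idx in blocks:
            r = np.maximum(np.linalg.norm(Q[:, idx], axis=1), 1e-12)
            Q[:, idx] *= (np.sqrt(np.mean(r**2)) / r)[:, None]
        evals, evecs = np.linalg.eigh(Q.T @ Q)
        Q = Q @ (evecs / np.sqrt(evals)) @ evecs.T
    return Q


def _draw_structure(spec: SyntheticSpec, rng: np.random.Generator):
    """Ground-truth bases, direction tuning, and EMG mixing (seed-determined)."""
    d = spec.d_prep_true + spec.d_move_true
    if spec.balanced_loadings:
        col_w = np.concatenate(
            [np.ones(spec.d_prep_true), np.full(spec.d_move_true, spec.move_amp)]
        )
        Q = _balanced_orthonormal(rng, spec.n_neurons, d, col_w)
    else:
        Q, _ = np.linalg.qr(rng.standard_normal((spec.n_neurons, d)))
    W_prep = Q[:, : spec.d_prep_true]
    W_move = Q[:, spec.d_prep_true :]

    theta = np.deg2rad(np.arange(spec.n_directions) * 360.0 / spec.n_directions)

    def tuning(d_true: int) -> np.ndarray:
        U = np.zeros((d_true, spec.n_directions))
        U[0] = np.cos(theta)
        if d_true > 1:
            U[1] = np.sin(theta)
        for k in range(2, d_true):
            # fixed random mixture of second-harmonic tuning, lower amplitude
            w = rng.standard_normal(2)
            w /= np.linalg.norm(w)
            U[k] = 0.4 * (w[0] * np.cos(2 * theta) + w[1] * np.sin(2 * theta))
        return U

    U_prep = tuning(spec.d_prep_true)
    U_move = tuning(spec.d_move_true)
    emg_mix = np.abs(rng.standard_normal((spec.n_muscles, spec.d_move_true)))
    emg_mix *= rng.choice([-1.0, 1.0], size=emg_mix.shape)
    return W_prep, W_move, U_prep, U_move, emg_mix


def _canonical_latents(spec: SyntheticSpec, U_prep, U_move):
    """Median-timing latents per context on a movement-locked grid."""
    dt = spec.time_step
    latent_time = np.arange(-600.0, spec.post_move + dt, dt)
    prep_latents: dict[str, np.ndarray] = {}
    move_latents: dict[str, np.ndarray] = {}
    for ctx in spec.contexts:
        delay = 0.5 * (ctx.delay_range[0] + ctx.delay_range[1])
        move_on = 0.0  # movement-locked axis
        target_on = -(delay + ctx.rt_mean)
        zp = np.zeros((spec.d_prep_true, spec.n_directions, latent_time.size))
        zm = np.zeros((spec.d_move_true, spec.n_directions, latent_time.size))
        for j in range(spec.n_directions):
            zp[:, j], zm[:, j] = _trial_latents(
                latent_time, target_on, move_on, j, ctx, spec, U_prep, U_move
            )
        prep_latents[ctx.name] = zp
        move_latents[ctx.name] = zm
    return latent_time, prep_latents, move_latents


def _predicted_factors(spec, W_prep, W_move, prep_latents, move_latents,
                       kernel_sd: float = 20.0) -> np.ndarray:
    """Predicted soft-normalization factors from noise-free canonical rates."""
    from scipy.ndimage import gaussian_filter1d

    hi = np.full(spec.n_neurons, -np.inf)
    lo = np.full(spec.n_neurons, np.inf)
    for ctx in spec.contexts:
        zp = prep_latents[ctx.name]
        zm = move_latents[ctx.name]
        rate = spec.baseline_rate + spec.gain * (
            np.einsum("nk,kjt->njt", W_prep, zp)
            + np.einsum("nk,kjt->njt", W_move, zm)
        )
        np.clip(rate, 0.0, None, out=rate)
        rate = gaussian_filter1d(rate, kernel_sd / spec.time_step, axis=2,
                                 mode="nearest", truncate=4.0)
        hi = np.maximum(hi, rate.max(axis=(1, 2)))
        lo = np.minimum(lo, rate.min(axis=(1, 2)))
    return (hi - lo) + 5.0


def design_latents(spec: SyntheticSpec) -> GroundTruth:
    """Ground-truth bases and canonical (median-timing) latent time courses.

    The canonical latents are evaluated on a movement-locked grid using each
    context's median delay and median RT, one column per reach direction.

    The planted bases are mutually orthogonal both in firing-rate space and,
    to good approximation, after per-neuron soft normalization: the movement
    basis is projected out of span(W_prep, D^-2 W_prep), with D the
    normalization factors predicted from the noise-free canonical rates
    (iterated to self-consistency).  Without this, the diagonal rescaling
    would tilt the two planted subspaces several degrees away from
    orthogonality in the space where the analysis operates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    W_prep, W_move, U_prep, U_move, emg_mix = _draw_structure(spec, rng)

    if spec.balanced_loadings and (
        spec.n_neurons >= 2 * spec.d_prep_true + spec.d_move_true + 1
    ):
        for _ in range(3):
            _, zp_c, zm_c = _canonical_latents(spec, U_prep, U_move)
            D = _predicted_factors(spec, W_prep, W_move, zp_c, zm_c)
            S = np.hstack([W_prep, W_prep / (D**2)[:, None]])
            Qs, _ = np.linalg.qr(S)
            W_move = W_move - Qs @ (Qs.T @ W_move)
            Q, R = np.linalg.qr(W_move)
            sgn = np.sign(np.diag(R))
            sgn[sgn == 0] = 1.0
            W_move = Q * sgn

    latent_time, prep_latents, move_latents = _canonical_latents(spec, U_prep, U_move)
    return GroundTruth(
        W_prep_true=W_prep,
        W_move_true=W_move,
        prep_latents=prep_latents,
        move_latents=move_latents,
        latent_time=latent_time,
        direction_tuning_prep=U_prep,
        direction_tuning_move=U_move,
        emg_mixing=emg_mix,
    )


def _truncnorm_rt(ctx: ContextSpec, spec: SyntheticSpec, rng: np.random.Generator, n: int):
    """Truncated-normal RTs with a causality floor.

    The floor guarantees that movement-locked latent onsets
    (movement gate − prep_lag) never precede target onset.
    """
    lo = ctx.rt_mean - 2.5 * ctx.rt_sd
    hi = ctx.rt_mean + 2.5 * ctx.rt_sd
    floor = spec.move_gate + (ctx.prep_lag or 0.0) + 2.0 * spec.time_step
    lo = max(lo, floor if ctx.prep_lag is not None else spec.move_gate + 1.0)
    hi = max(hi, lo + spec.time_step)
    if ctx.rt_sd == 0:
        return np.full(n, max(ctx.rt_mean, lo))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.normal(ctx.rt_mean, ctx.rt_sd, size=2 * (n - filled) + 8)
        keep = draws[(draws >= lo) & (draws <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_dataset(
    spec: SyntheticSpec,
    loadings: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[TrialSet, GroundTruth]:
    """Simulate a full multi-context dataset with known ground truth.

    Per-trial firing rate of neuron *n*:
    ``rate_n(t) = max(0, baseline + gain * (W_prep z_prep(t) + W_move z_move(t))_n)``
    with spikes drawn per ``spec.noise_model``.  Identical ``spec`` (including
    seed) yields an identical dataset.

    ``loadings`` replaces the drawn (W_prep, W_move) pair, e.g. with rows
    subsampled from a large master pool for neuron-sampling studies where
    the population must be an iid draw; the orthonormality guarantees then
    rest with the caller.
    """
    spec.validate()
    truth = design_latents(spec)
    if loadings is not None:
        Wp, Wm = loadings
        if Wp.shape != (spec.n_neurons, spec.d_prep_true) or Wm.shape != (
            spec.n_neurons, spec.d_move_true,
        ):
            raise ValueError("loadings shapes do not match the spec")
        truth.W_prep_true = np.asarray(Wp, dtype=float)
        truth.W_move_true = np.asarray(Wm, dtype=float)
    rng = np.random.default_rng(spec.seed)
    # re-draw the structure with the same rng stream so the trial-level draws
    # below are aligned with design_latents' seed usage
    _draw_structure(spec, rng)

    dt = spec.time_step
    rows = []
    spikes: dict[int, list[np.ndarray]] = {}
    rates: dict[int, np.ndarray] = {}
    kinematics: dict[int, np.ndarray] = {}
    emg: dict[int, np.ndarray] = {}
    directions = np.arange(spec.n_directions) * 360.0 / spec.n_directions

    trial_id = 0
    for ctx in spec.contexts:
        n_cond_trials = spec.trials_per_condition
        for j, direc in enumerate(directions):
            delays = rng.uniform(*ctx.delay_range, size=n_cond_trials)
            rts = _truncnorm_rt(ctx, spec, rng, n_cond_trials)
            for i in range(n_cond_trials):
                target_on = _snap(spec.pre_target, dt)
                go_cue = _snap(target_on + delays[i], dt)
                move_on = _snap(go_cue + rts[i], dt)
                trial_end = _snap(move_on + spec.post_move, dt)
                n_t = int(round(trial_end / dt))
                t = (np.arange(n_t) + 0.5) * dt

                zp, zm = _trial_latents(
                    t, target_on, move_on, j, ctx, spec,
                    truth.direction_tuning_prep, truth.direction_tuning_move,
                )
                rate = spec.baseline_rate + spec.gain * (
                    truth.W_prep_true @ zp + truth.W_move_true @ zm
                )
                np.clip(rate, 0.0, None, out=rate)

                if spec.noise_model == "poisson":
                    counts = rng.poisson(rate * dt / 1000.0)
                    spikes[trial_id] = [
                        np.repeat(t, counts[n]) for n in range(spec.n_neurons)
                    ]
                else:
                    noisy = rate + rng.normal(0.0, spec.noise_sd, size=rate.shape)
                    rates[trial_id] = np.clip(noisy, 0.0, None)
                    spikes[trial_id] = [np.empty(0) for _ in range(spec.n_neurons)]

                kinematics[trial_id] = _reach_kinematics(
                    trial_end, move_on, np.deg2rad(direc), spec
                )
                emg[trial_id] = _trial_emg(t, move_on, j, ctx, spec, truth, rng)

                rows.append(
                    dict(
                        trial_id=trial_id,
                        context=ctx.name,
                        direction_deg=direc,
                        target_on_ms=target_on,
                        go_cue_ms=go_cue,
                        move_on_ms=move_on,
                        trial_end_ms=trial_end,
                    )
                )
                trial_id += 1

    trials = pd.DataFrame(rows)
    ts = TrialSet(
        trials=trials,
        spikes=spikes,
        rates=rates if spec.noise_model == "gaussian" else None,
        kinematics=kinematics,
        emg=emg,
        time_step=dt,
        kin_dt=spec.kin_dt,
        n_neurons=spec.n_neurons,
    )
    return ts, truth


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _reach_kinematics(
    trial_end: float, move_on: float, theta: float, spec: SyntheticSpec
) -> np.ndarray:
    """Minimum-jerk 2-D reach; speed crosses 1% of peak at ``move_on``."""
    t = np.arange(0.0, trial_end, spec.kin_dt)
    launch = move_on - TAU_ONSET * spec.reach_duration
    tau = np.clip((t - launch) / spec.reach_duration, 0.0, 1.0)
    profile = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    pos = spec.reach_distance * profile[:, None] * np.array([np.cos(theta), np.sin(theta)])
    return pos


def _trial_emg(
    t: np.ndarray,
    move_on: float,
    dir_idx: int,
    ctx: ContextSpec,
    spec: SyntheticSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rectified, lagged mixture of the movement latents, plus noise."""
    _, zm = _trial_latents(
        t - spec.emg_lag, spec.pre_target, move_on, dir_idx, ctx, spec,
        truth.direction_tuning_prep, truth.direction_tuning_move,
    )
    sig = truth.emg_mixing @ zm
    sig += rng.normal(0.0, spec.emg_noise_sd, size=sig.shape)
    return np.clip(sig, 0.0, None)


# ---------------------------------------------------------------------------
# delimited-text round trip


def write_trialset(ts: TrialSet, outdir: str | Path) -> None:
    """Write a TrialSet to TSV files (spikes, trials, kinematics, emg)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts.trials.to_csv(outdir / "trials.tsv", sep="\t", index=False)

    spike_rows = []
    for tid, trains in ts.spikes.items():
        for n, st in enumerate(trains):
            for s in st:
                spike_rows.append((tid, n, s))
    pd.DataFrame(
        spike_rows, columns=["trial_id", "neuron_id", "spike_time_ms"]
    ).to_csv(outdir / "spikes.tsv", sep="\t", index=False)

    kin_rows = []
    for tid, pos in ts.kinematics.items():
        times = np.arange(pos.shape[0]) * ts.kin_dt
        for t_ms, (x, y) in zip(times, pos):
            kin_rows.append((tid, t_ms, x, y))
    pd.DataFrame(kin_rows, columns=["trial_id", "time_ms", "x_mm", "y_mm"]).to_csv(
        outdir / "kinematics.tsv", sep="\t", index=False
    )

    emg_rows = []
    for tid, sig in ts.emg.items():
        times = (np.arange(sig.shape[1]) + 0.5) * ts.time_step
        for m in range(sig.shape[0]):
            for t_ms, v in zip(times, sig[m]):
                emg_rows.append((tid, m, t_ms, v))
    pd.DataFrame(emg_rows, columns=["trial_id", "muscle_id", "time_ms", "value"]).to_csv(
        outdir / "emg.tsv", sep="\t", index=False
    )


def load_trialset(indir: str | Path, n_neurons: int | None = None,
                  time_step: float = 1.0) -> TrialSet:
    """Load a TrialSet previously written with :func:`write_trialset`."""
    indir = Path(indir)
    trials = pd.read_csv(indir / "trials.tsv", sep="\t")
    sp = pd.read_csv(indir / "spikes.tsv", sep="\t")
    if n_neurons is None:
        n_neurons = int(sp["neuron_id"].max()) + 1 if len(sp) else 0
    spikes: dict[int, list[np.ndarray]] = {}
    grouped = sp.groupby(["trial_id", "neuron_id"])["spike_time_ms"]
    by_trial: dict[int, dict[int, np.ndarray]] = {}
    for (tid, nid), vals in grouped:
        by_trial.setdefault(int(tid), {})[int(nid)] = vals.to_numpy()
    for tid in trials["trial_id"]:
        per = by_trial.get(int(tid), {})
        spikes[int(tid)] = [per.get(n, np.empty(0)) for n in range(n_neurons)]

    kin = pd.read_csv(indir / "kinematics.tsv", sep="\t")
    kinematics = {}
    kin_dt = 1.0
    for tid, grp in kin.groupby("trial_id"):
        grp = grp.sort_values("time_ms")
        kinematics[int(tid)] = grp[["x_mm", "y_mm"]].to_numpy()
        if len(grp) > 1:
            kin_dt = float(np.diff(grp["time_ms"].to_numpy()[:2])[0])

    emg_df = pd.read_csv(indir / "emg.tsv", sep="\t")
    emg = {}
    for tid, grp in emg_df.groupby("trial_id"):
        mat = grp.pivot_table(index="muscle_id", columns="time_ms", values="value")
        emg[int(tid)] = mat.to_numpy()

    return TrialSet(
        trials=trials,
        spikes=spikes,
        rates=None,
        kinematics=kinematics,
        emg=emg,
        time_step=time_step,
        kin_dt=kin_dt,
        n_neurons=n_neurons,
    )
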