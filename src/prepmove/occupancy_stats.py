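"""Projections, reconstructions, occupancy, latencies, and cross-context
similarity statistics.

"Occupancy" of a subspace at time t is the summed across-condition variance
of the projections onto that subspace's dimensions — the strength of
direction selectivity expressed in the subspace.  Because bases are
orthonormal, occupancy computed from the latents equals the sum over neurons
of the variance of their reconstructed patterns (a dual-route identity used
as a self-check).  Sampling uncertainty is estimated by redrawing neurons
with replacement and re-running the full subspace identification for each
surrogate population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .preprocess import (
    EpochDefinition,
    MissingConditionError,
    RateTensor,
    extract_epoch,
    mean_center,
    smooth_and_average,
)
from .subspaces import CovarianceMatrix, SubspacePair, epoch_covariance, optimize_subspaces


@dataclass
class ProjectionSet:
    """Latent time courses x_k(t, theta): (d, n_conditions, n_times)."""

    latents: np.ndarray
    time: np.ndarray
    rel_time: np.ndarray
    lock: np.ndarray
    conditions: list
    label: str = ""

    @property
    def d(self) -> int:
        return self.latents.shape[0]

    def select_context(self, context: str) -> "ProjectionSet":
        idx = [i for i, (c, _) in enumerate(self.conditions) if c == context]
        if not idx:
            raise MissingConditionError(f"no conditions for context {context!r}")
        return replace(self, latents=self.latents[:, idx],
                       conditions=[self.conditions[i] for i in idx])

    def at_time(self, t: float) -> np.ndarray:
        """(d, n_conditions) state at the sample nearest to display time t."""
        i = int(np.argmin(np.abs(self.time - t)))
        return self.latents[:, :, i]


@dataclass
class OccupancyTrace:
    """Across-condition variance in a subspace per time, with bootstrap SD."""

    values: np.ndarray
    time: np.ndarray
    boot_sd: Optional[np.ndarray] = None
    boot_samples: Optional[np.ndarray] = None  # (n_boot, n_times)
    reference_label: str = ""

    def normalized(self, reference: "OccupancyTrace | float") -> "OccupancyTrace":
        """Rescale by the peak of a reference trace (Fig-8-style display)."""
        ref_max = reference if np.isscalar(reference) else float(np.max(reference.values))
        if ref_max <= 0:
            raise ValueError("reference peak must be positive")
        return OccupancyTrace(
            values=self.values / ref_max,
            time=self.time,
            boot_sd=None if self.boot_sd is None else self.boot_sd / ref_max,
            boot_samples=None if self.boot_samples is None
            else self.boot_samples / ref_max,
            reference_label="normalized",
        )


@dataclass
class PatternSet:
    """Per-neuron preparatory/movement patterns and the across-condition mean.

    prep + move + mean term = full reconstruction.
    """

    prep_patterns: np.ndarray  # (N, C, T)
    move_patterns: np.ndarray
    mean_term: Optional[np.ndarray]  # (N, T) or None
    r2: np.ndarray  # per-neuron reconstruction R^2 (tuned part)


def project(tensor: RateTensor, W: np.ndarray, label: str = "") -> ProjectionSet:
    """Project population activity onto a basis: latents = W' r(t, theta).

    The tensor is expected to be soft-normalized and mean-centered; the
    projection itself is simply a weighted sum of single-neuron responses.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != tensor.n_neurons:
        raise ValueError(
            f"basis has {W.shape[0]} rows but tensor has {tensor.n_neurons} neurons"
        )
    latents = np.einsum("nk,nct->kct", W, tensor.rates)
    return ProjectionSet(
        latents=latents,
        time=tensor.time.copy(),
        rel_time=tensor.rel_time.copy(),
        lock=tensor.lock.copy(),
        conditions=list(tensor.conditions),
        label=label,
    )


def reconstruct(
    tensor: RateTensor,
    pair: SubspacePair,
    mean_term: Optional[np.ndarray] = None,
    full: bool = False,
) -> PatternSet:
    """Reconstruct per-neuron responses from the two subspace projections.

    Each neuron's preparatory pattern is the weighted sum of the preparatory
    projections; analogously for the movement pattern.  With ``full=True``
    the across-condition mean term must be supplied and R^2 is reported for
    prep + move + mean against ``tensor.rates + mean``; otherwise R^2 is for
    the tuned (mean-centered) part.
    """
    if full and mean_term is None:
        raise ValueError("full reconstruction requires the across-condition mean term")
    xp = np.einsum("nk,nct->kct", pair.W_prep, tensor.rates)
    xm = np.einsum("nk,nct->kct", pair.W_move, tensor.rates)
    prep_pat = np.einsum("nk,kct->nct", pair.W_prep, xp)
    move_pat = np.einsum("nk,kct->nct", pair.W_move, xm)
    recon = prep_pat + move_pat
    target = tensor.rates
    if full:
        recon = recon + mean_term[:, None, :]
        target = tensor.rates + mean_term[:, None, :]
    resid = target - recon
    mu = target.mean(axis=(1, 2), keepdims=True)
    ss_tot = np.sum((target - mu) ** 2, axis=(1, 2))
    ss_res = np.sum(resid**2, axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    return PatternSet(prep_patterns=prep_pat, move_patterns=move_pat,
                      mean_term=mean_term, r2=r2)


def occupancy(
    proj: ProjectionSet, reference: "OccupancyTrace | float | None" = None
) -> OccupancyTrace:
    """Sum over dimensions of the across-condition variance, per time.

    Uses the unbiased (n-1) denominator.  With a ``reference``, values are
    divided by the reference trace's peak (e.g. normalize every context by
    the cue-initiated peak).
    """
    if proj.latents.shape[1] < 2:
        raise ValueError("occupancy requires >= 2 conditions")
    vals = proj.latents.var(axis=1, ddof=1).sum(axis=0)
    trace = OccupancyTrace(values=vals, time=proj.time.copy())
    if reference is not None:
        trace = trace.normalized(reference)
    return trace


@dataclass
class BootstrapOccupancy:
    """Occupancy traces with neuron-bootstrap envelopes and diagnostics."""

    prep: OccupancyTrace
    move: OccupancyTrace
    pair: SubspacePair
    n_redrawn: int = 0


def bootstrap_occupancy(
    tensor: RateTensor,
    delay_epoch: EpochDefinition,
    move_epoch: EpochDefinition,
    d_prep: int = 12,
    d_move: int = 12,
    n_boot: int = 1000,
    seed: int = 0,
    fit_delay: Optional[RateTensor] = None,
    fit_move: Optional[RateTensor] = None,
    n_restarts: int = 5,
    boot_restarts: int = 1,
    boot_max_iter: int = 2000,
    boot_tol: float = 1e-9,
    keep_samples: bool = False,
) -> BootstrapOccupancy:
    """Occupancy with a bootstrap envelope over neuron resampling.

    Subspaces are identified from the delay epoch of ``fit_delay`` and the
    movement epoch of ``fit_move`` (both default to ``tensor``; pass the
    cue-initiated target-locked / movement-locked tensors to identify
    dimensions from one context and measure occupancy in another).

    Each of ``n_boot`` surrogate populations redraws neurons with
    replacement — the same redraw applied to the fit tensors and to the
    occupancy tensor — and re-runs the central analysis: covariances,
    subspace optimization, projection, occupancy (occupancy is invariant to
    the rotational indeterminacy of a redrawn basis within its subspace, so
    no alignment step is needed).  The per-time SD of the resulting sampling
    distribution is the standard error envelope.  Resamples whose redraw
    leaves fewer distinct neurons than the requested total dimensionality
    are redrawn (counted in ``n_redrawn``).  Deterministic given seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    fit_delay = tensor if fit_delay is None else fit_delay
    fit_move = tensor if fit_move is None else fit_move
    P_full = extract_epoch(fit_delay, delay_epoch)
    M_full = extract_epoch(fit_move, move_epoch)

    def fit_pair(P, M, n_rs: int, sd: int, max_iter: int, tol: float):
        return optimize_subspaces(
            epoch_covariance(P, "prep"), epoch_covariance(M, "move"),
            d_prep, d_move, n_restarts=n_rs, seed=sd,
            max_iter=max_iter, tol=tol,
        )

    pair = fit_pair(P_full, M_full, n_restarts, seed, 5000, 1e-10)
    prep = occupancy(project(tensor, pair.W_prep, "prep"))
    move = occupancy(project(tensor, pair.W_move, "move"))

    rng = np.random.default_rng(seed)
    N = tensor.n_neurons
    n_t = prep.values.size
    boot_p = np.empty((n_boot, n_t))
    boot_m = np.empty((n_boot, n_t))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, N, size=N)
        if np.unique(idx).size < d_prep + d_move:
            n_redrawn += 1
            continue
        sub = replace(tensor, rates=tensor.rates[idx])
        pair_b = fit_pair(P_full[idx], M_full[idx], boot_restarts,
                          seed + 1 + b, boot_max_iter, boot_tol)
        boot_p[b] = occupancy(project(sub, pair_b.W_prep)).values
        boot_m[b] = occupancy(project(sub, pair_b.W_move)).values
        b += 1

    prep.boot_sd = boot_p.std(axis=0, ddof=1)
    move.boot_sd = boot_m.std(axis=0, ddof=1)
    if keep_samples:
        prep.boot_samples = boot_p
        move.boot_samples = boot_m
    return BootstrapOccupancy(prep=prep, move=move, pair=pair, n_redrawn=n_redrawn)


def bootstrap_pvalue(dist_a, dist_b, tail: str = "greater") -> float:
    """One-tailed bootstrap p-value from two sampling distributions.

    ``tail="greater"`` tests the hypothesis that A exceeds B: p is the
    fraction of redrawn comparisons violating that direction (if 95% of
    comparisons favor A, p = 0.05).  Floored at 1/n_pairs.
    """
    a = np.asarray(dist_a, dtype=float).ravel()
    b = np.asarray(dist_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty distribution")
    if tail == "greater":
        viol = np.mean(a[:, None] <= b[None, :])
    elif tail == "less":
        viol = np.mean(a[:, None] >= b[None, :])
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    floor = 1.0 / (a.size * b.size)
    return float(max(viol, floor))


def threshold_latency(values, time=None, frac: float = 0.10) -> float:
    """Earliest time a trace reaches ``frac`` of its peak (ms).

    Accepts an :class:`OccupancyTrace` or a values array plus time axis.
    Linear interpolation between samples; a trace without a positive peak
    raises.
    """
    if isinstance(values, OccupancyTrace):
        time = values.time
        values = values.values
    v = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    peak = v.max()
    if peak <= 0:
        raise ValueError("trace has no positive peak")
    thresh = frac * peak
    i_pk = int(np.argmax(v))
    above = np.flatnonzero(v[: i_pk + 1] >= thresh)
    i = above[0]
    if i == 0 or v[i] <= thresh:
        return float(t[i])
    lo, hi = v[i - 1], v[i]
    return float(t[i - 1] + (t[i] - t[i - 1]) * (thresh - lo) / (hi - lo))


def average_emg(
    trialset,
    kernel_sd: float = 10.0,
    alignment_event: str = "movement_onset",
    window: tuple[float, float] = (-350.0, 400.0),
    context: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smoothed, trial-averaged EMG: (n_muscles, n_conditions, n_times).

    Conditions are reach directions within the selected context.  Returns
    (emg, time axis relative to the alignment event).
    """
    from .preprocess import _EVENT_COL

    event_col = _EVENT_COL[alignment_event]
    dt = trialset.time_step
    start, end = window
    n_t = int(round((end - start) / dt)) + 1
    rel = start + np.arange(n_t) * dt
    trials = trialset.trials
    if context is not None:
        trials = trials[trials["context"] == context]
    if len(trials) == 0:
        raise MissingConditionError(f"no trials for context {context!r}")
    n_mus = next(iter(trialset.emg.values())).shape[0]
    dirs = np.sort(trials["direction_deg"].unique())
    pad = int(np.ceil(4.0 * kernel_sd / dt)) + 1
    out = np.zeros((n_mus, dirs.size, n_t))
    for ci, direc in enumerate(dirs):
        sel = trials[trials["direction_deg"] == direc]
        acc = np.zeros((n_mus, n_t + 2 * pad))
        for _, row in sel.iterrows():
            sig = trialset.emg[int(row["trial_id"])]
            idx = np.floor((float(row[event_col]) + rel) / dt).astype(int)
            pidx = np.concatenate(
                [idx[0] - np.arange(pad, 0, -1), idx, idx[-1] + np.arange(1, pad + 1)]
            )
            pidx = np.clip(pidx, 0, sig.shape[1] - 1)
            acc += sig[:, pidx]
        acc /= len(sel)
        sm = gaussian_filter1d(acc, kernel_sd / dt, axis=1, mode="reflect", truncate=4.0)
        out[:, ci, :] = sm[:, pad : pad + n_t]
    return out, rel


def emg_latency(
    emg: np.ndarray, time: np.ndarray, frac: float = 0.10, pooling: str = "variance"
) -> tuple[float, np.ndarray]:
    """Latency of EMG onset via the first principal component.

    Muscles are range-normalized (a critical step so every muscle
    contributes), PCA is run over (condition, time) samples, each
    condition's EMG is projected onto PC1, and the threshold latency of the
    pooled projection trace is returned together with the PC1 weights.

    ``pooling="variance"`` (default) uses the across-condition variance of
    the PC1 projection — the same selectivity-strength statistic as subspace
    occupancy, which keeps the two latencies commensurate when measuring the
    neural lead over muscle activity.  ``pooling="mean"`` uses the
    across-condition mean activity instead.
    """
    emg = np.asarray(emg, dtype=float)
    if emg.ndim != 3 or emg.shape[0] < 1:
        raise ValueError("need (n_muscles, n_conditions, n_times) EMG")
    rng_ = emg.max(axis=(1, 2)) - emg.min(axis=(1, 2))
    if np.all(rng_ <= 0):
        raise ValueError("silent EMG set")
    norm = emg / np.where(rng_ > 0, rng_, 1.0)[:, None, None]
    X = norm.reshape(norm.shape[0], -1)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, _, _ = np.linalg.svd(Xc, full_matrices=False)
    w = U[:, 0]
    proj = np.einsum("m,mct->ct", w, norm)
    if pooling == "variance":
        if proj.shape[0] < 2:
            trace = (proj - proj.mean(axis=1, keepdims=True))[0] ** 2
        else:
            trace = proj.var(axis=0, ddof=1)
    elif pooling == "mean":
        trace = proj.mean(axis=0)
        if trace[np.argmax(np.abs(trace))] < 0:
            w = -w
            trace = -trace
        trace = trace - trace.min()
    else:
        raise ValueError("pooling must be 'variance' or 'mean'")
    return threshold_latency(trace, time, frac=frac), w


def cross_context_state_similarity(
    proj_a: ProjectionSet,
    proj_b: ProjectionSet,
    at_time: float,
    n_dims: Optional[int] = None,
) -> float:
    """Pearson correlation of subspace states across contexts.

    States (one per reach direction, taken at ``at_time`` — e.g. 55 ms
    before movement onset on a movement-locked axis) are flattened over
    (direction x dimension) and correlated.
    """
    if len(proj_a.conditions) < 2 or len(proj_b.conditions) < 2:
        raise ValueError("need >= 2 directions")
    dirs_a = [d for _, d in proj_a.conditions]
    dirs_b = [d for _, d in proj_b.conditions]
    if dirs_a != dirs_b:
        raise ValueError("contexts must share the same reach directions")
    a = proj_a.at_time(at_time)
    b = proj_b.at_time(at_time)
    if n_dims is not None:
        a, b = a[:n_dims], b[:n_dims]
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def cross_context_covariance_timecourse(
    proj_a: ProjectionSet, proj_b: ProjectionSet
) -> OccupancyTrace:
    """Covariance between two contexts' subspace patterns, per time.

    At each time the (direction x dimension) state vectors of the two
    contexts are compared by their mean-removed inner product divided by
    (count - 1).  High when patterns are both strong and similar; the
    vertical scale is arbitrary.
    """
    if proj_a.latents.shape != proj_b.latents.shape or not np.allclose(
        proj_a.time, proj_b.time
    ):
        raise ValueError("projections must share shape and time axis")
    d, C, T = proj_a.latents.shape
    a = proj_a.latents.reshape(d * C, T)
    b = proj_b.latents.reshape(d * C, T)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    vals = np.sum(a * b, axis=0) / (d * C - 1)
    return OccupancyTrace(values=vals, time=proj_a.time.copy(),
                          reference_label="covariance")


def tuning_slope(
    patterns_a: np.ndarray, patterns_ref: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Per-neuron regression of one context's direction tuning on another's.

    ``patterns_a`` and ``patterns_ref`` are (n_neurons, n_directions) pattern
    values at a chosen time (e.g. the preparatory pattern 100 ms before
    movement onset).  For each neuron an OLS line (with intercept) of A
    versus reference is fit; identical tuning across contexts yields slope 1.
    Neurons whose reference tuning has zero variance are excluded.
    Returns (mean slope, SE of the mean, per-neuron slopes with NaN for
    excluded neurons).
    """
    A = np.asarray(patterns_a, dtype=float)
    R = np.asarray(patterns_ref, dtype=float)
    if A.shape != R.shape:
        raise ValueError("pattern sets must cover identical neurons/directions")
    Rc = R - R.mean(axis=1, keepdims=True)
    Ac = A - A.mean(axis=1, keepdims=True)
    var = np.sum(Rc**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = np.where(var > 0, np.sum(Ac * Rc, axis=1) / var, np.nan)
    ok = np.isfinite(slopes)
    if not np.any(ok):
        raise ValueError("no neuron has reference tuning variance")
    mean = float(np.mean(slopes[ok]))
    se = float(np.std(slopes[ok], ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else 0.0
    return mean, se, slopes


def pattern_correlation(
    tensor_a: RateTensor, tensor_b: RateTensor, epoch: EpochDefinition
) -> tuple[np.ndarray, float]:
    """Per-neuron Pearson correlation of response blocks between contexts.

    Each neuron's (condition x time) block within the epoch window is
    flattened and correlated between the two tensors; the median across
    neurons is reported.  Zero-variance blocks yield NaN (flagged neurons)
    and are excluded from the median.
    """
    if tensor_a.n_neurons != tensor_b.n_neurons:
        raise ValueError("tensors must share neurons")
    ia = tensor_a.epoch_sample_index(epoch)
    ib = tensor_b.epoch_sample_index(epoch)
    if ia.size == 0 or ia.size != ib.size:
        raise ValueError("epoch window invalid for these tensors")
    A = tensor_a.rates[:, :, ia].reshape(tensor_a.n_neurons, -1)
    B = tensor_b.rates[:, :, ib].reshape(tensor_b.n_neurons, -1)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((na > 0) & (nb > 0), np.sum(A * B, axis=1) / (na * nb), np.nan)
    return r, float(np.nanmedian(r))


def rt_split_analysis(
    trialset,
    pair: SubspacePair,
    soft_factors: np.ndarray,
    kernel_sd: float = 20.0,
    window: tuple[float, float] = (-350.0, 400.0),
    contexts: Optional[list[str]] = None,
    split_labels: Optional[dict[int, bool]] = None,
) -> dict:
    """Occupancy per RT half, projected onto fixed (full-data) subspaces.

    Trials of each context are divided at the median RT (movement onset −
    go cue), or by explicit ``split_labels`` (trial_id -> True for the
    "short" group) for permutation controls.  Per half, movement-locked
    trial averages are recomputed, normalized with the *full-data* soft
    factors, mean-centered, and projected onto the already-identified
    preparatory subspace.  Returns, per context, occupancy traces for both
    halves plus the median go-cue time relative to movement onset (for the
    display alignment in which one context's target onset is aligned to
    another's go cue).
    """
    trials = trialset.trials
    if contexts is None:
        contexts = list(dict.fromkeys(trials["context"]))
    out = {}
    for ctx in contexts:
        sel = trials[trials["context"] == ctx]
        rt = (sel["move_on_ms"] - sel["go_cue_ms"]).to_numpy()
        if split_labels is None:
            med = np.median(rt)
            short_ids = sel["trial_id"].to_numpy()[rt <= med]
            long_ids = sel["trial_id"].to_numpy()[rt > med]
        else:
            lab = sel["trial_id"].map(split_labels).to_numpy(dtype=bool)
            short_ids = sel["trial_id"].to_numpy()[lab]
            long_ids = sel["trial_id"].to_numpy()[~lab]
        halves = {}
        for name, ids in [("short", short_ids), ("long", long_ids)]:
            if ids.size == 0:
                raise MissingConditionError(f"empty {name}-RT half for {ctx!r}")
            tens = smooth_and_average(
                trialset, kernel_sd=kernel_sd, alignment_event="movement_onset",
                window=window, contexts=[ctx], trial_ids=ids,
            )
            tens = replace(tens, rates=tens.rates / soft_factors[:, None, None])
            tens, _ = mean_center(tens)
            halves[name] = occupancy(project(tens, pair.W_prep, "prep"))
            halves[f"{name}_median_move_on"] = float(
                np.median(
                    trials.set_index("trial_id").loc[ids, "move_on_ms"]
                    - trials.set_index("trial_id").loc[ids, "go_cue_ms"]
                )
            )
        out[ctx] = halves
    return out


def neuron_bootstrap_ci(
    stat_fn, n_neurons: int, n_boot: int = 1000, seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, np.ndarray]:
    """Percentile CI of a statistic under neuron resampling.

    ``stat_fn(idx)`` must evaluate the statistic on the neuron index array
    ``idx`` (with repeats).  Returns (lo, hi, samples).
    """
    rng = np.random.default_rng(seed)
    samples = np.array(
        [stat_fn(rng.integers(0, n_neurons, n_neurons)) for _ in range(n_boot)]
    )
    lo, hi = np.quantile(samples, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi), samples
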