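"""Trial-averaged rate tensors: smoothing, alignment, normalization.

The analysis operates on trial-averaged, time-resolved firing rates indexed
neuron x condition x time (a condition is one reach direction within one
initiation context).  Spike trains are smoothed with a Gaussian kernel
(20 ms SD for most analyses, 10 ms for latency analyses), averaged across
trials aligned to a named event, optionally concatenated across alignments,
soft-normalized per neuron (factor = firing-rate range + 5) and mean-centered
across conditions at each time so that downstream dimensionality reduction
targets condition-tuned structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .synth import TrialSet

TARGET = "target_onset"
MOVE = "movement_onset"
_EVENT_COL = {TARGET: "target_on_ms", MOVE: "move_on_ms"}


class MissingConditionError(ValueError):
    """A requested (context, direction) condition has no analyzable trials."""


@dataclass(frozen=True)
class EpochDefinition:
    """A named analysis epoch relative to an alignment event.

    Defaults in the pipeline: a 450 ms delay epoch beginning 50 ms after
    target onset, and a 300 ms movement epoch beginning 50 ms before
    movement onset.
    """

    alignment_event: str  # TARGET or MOVE
    start_offset: float  # ms
    end_offset: float  # ms

    def __post_init__(self):
        if self.alignment_event not in (TARGET, MOVE):
            raise ValueError(f"unknown alignment event {self.alignment_event!r}")
        if self.end_offset <= self.start_offset:
            raise ValueError("end_offset must exceed start_offset")


DELAY_EPOCH = EpochDefinition(TARGET, 50.0, 500.0)
MOVE_EPOCH = EpochDefinition(MOVE, -50.0, 250.0)


@dataclass
class RateTensor:
    """Trial-averaged rates (n_neurons, n_conditions, n_times) with alignment
    annotations.

    ``time`` is a strictly increasing display axis; ``lock`` and ``rel_time``
    record, per sample, which event the sample is locked to and the time
    relative to that event.  ``junction_index`` marks the first sample of the
    movement-locked segment after concatenation (None if single-alignment).
    """

    rates: np.ndarray
    time: np.ndarray
    lock: np.ndarray  # (n_times,) of str
    rel_time: np.ndarray  # (n_times,)
    conditions: list[tuple[str, float]]  # (context, direction_deg)
    junction_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.rates.shape[1]

    def condition_contexts(self) -> np.ndarray:
        return np.array([c for c, _ in self.conditions])

    def select_context(self, context: str) -> "RateTensor":
        idx = [i for i, (c, _) in enumerate(self.conditions) if c == context]
        if not idx:
            raise MissingConditionError(f"no conditions for context {context!r}")
        return replace(
            self,
            rates=self.rates[:, idx],
            conditions=[self.conditions[i] for i in idx],
        )

    def epoch_sample_index(self, epoch: EpochDefinition) -> np.ndarray:
        """Sample indices whose lock matches the epoch, half-open window."""
        mask = (
            (self.lock == epoch.alignment_event)
            & (self.rel_time >= epoch.start_offset - 1e-9)
            & (self.rel_time < epoch.end_offset - 1e-9)
        )
        return np.flatnonzero(mask)


def smooth_and_average(
    trialset: TrialSet,
    kernel_sd: float = 20.0,
    alignment_event: str = TARGET,
    window: tuple[float, float] = (-200.0, 450.0),
    contexts: list[str] | None = None,
    trial_ids: np.ndarray | None = None,
) -> RateTensor:
    """Kernel-smoothed, trial-averaged firing rates aligned to an event.

    Rates are in spikes/s, sampled at the trialset's grid step on
    ``window[0] .. window[1]`` inclusive (integer-sample grid).  Smoothing
    uses a Gaussian kernel truncated at ±4 SD, unit mass, computed on a
    padded window so edge samples are unbiased.  A condition with zero
    usable trials raises :class:`MissingConditionError`.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    event_col = _EVENT_COL[alignment_event]
    dt = trialset.time_step
    start, end = window
    n_t = int(round((end - start) / dt)) + 1
    rel = start + np.arange(n_t) * dt

    pad = int(np.ceil(4.0 * kernel_sd / dt)) + 1
    n_pad = n_t + 2 * pad
    sigma_bins = kernel_sd / dt

    trials = trialset.trials
    if contexts is not None:
        trials = trials[trials["context"].isin(contexts)]
    if trial_ids is not None:
        trials = trials[trials["trial_id"].isin(np.asarray(trial_ids))]

    if len(trials) == 0:
        raise MissingConditionError("no trials match the requested selection")
    # condition order: trialset context order, directions ascending
    ctx_order = {c: i for i, c in enumerate(dict.fromkeys(trials["context"]))}
    cond_keys = sorted(
        set(zip(trials["context"], trials["direction_deg"])),
        key=lambda k: (ctx_order[k[0]], k[1]),
    )

    N = trialset.n_neurons
    out = np.zeros((N, len(cond_keys), n_t))
    use_rates = trialset.rates is not None

    for ci, (ctx, direc) in enumerate(cond_keys):
        sel = trials[(trials["context"] == ctx) & (trials["direction_deg"] == direc)]
        if len(sel) == 0:
            raise MissingConditionError(f"no trials for condition {(ctx, direc)}")
        acc = np.zeros((N, n_pad))
        for _, row in sel.iterrows():
            tid = int(row["trial_id"])
            event = float(row[event_col])
            if use_rates:
                r = trialset.rates[tid]
                idx = np.floor((event + rel) / dt).astype(int)
                pad_idx = np.concatenate(
                    [idx[0] - np.arange(pad, 0, -1), idx, idx[-1] + np.arange(1, pad + 1)]
                )
                pad_idx = np.clip(pad_idx, 0, r.shape[1] - 1)
                acc += r[:, pad_idx]
            else:
                pad_start = event + start - pad * dt
                counts = np.zeros((N, n_pad))
                for n, st in enumerate(trialset.spikes[tid]):
                    if st.size == 0:
                        continue
                    b = np.floor((st - pad_start) / dt + 0.5).astype(int)
                    b = b[(b >= 0) & (b < n_pad)]
                    np.add.at(counts[n], b, 1)
                acc += counts * (1000.0 / dt)
        acc /= len(sel)
        sm = gaussian_filter1d(acc, sigma_bins, axis=1, mode="reflect", truncate=4.0)
        out[:, ci, :] = sm[:, pad : pad + n_t]

    return RateTensor(
        rates=out,
        time=rel.copy(),
        lock=np.full(n_t, alignment_event, dtype=object),
        rel_time=rel.copy(),
        conditions=list(cond_keys),
        meta={"kernel_sd": kernel_sd, "alignment_event": alignment_event},
    )


def median_separation(trialset: TrialSet, context: str) -> float:
    """Median target-onset → movement-onset interval for one context (ms)."""
    sel = trialset.trials[trialset.trials["context"] == context]
    if len(sel) == 0:
        raise MissingConditionError(f"no trials for context {context!r}")
    return float(np.median(sel["move_on_ms"] - sel["target_on_ms"]))


def concatenate_alignments(
    target_locked: RateTensor, move_locked: RateTensor, separation: float
) -> RateTensor:
    """Join a target-locked and a movement-locked tensor at a junction.

    ``separation`` is the target→movement interval at which the two segments
    are laid out (typically the context's median, so the separation is close
    to typical behavior).  The target-locked segment is trimmed where it
    would overlap the start of the movement-locked segment; if nothing of it
    survives, the windows cannot both be honored and a ValueError is raised.
    The output time axis is relative to target onset.
    """
    if target_locked.conditions != move_locked.conditions:
        raise ValueError("tensors must share conditions")
    if target_locked.n_neurons != move_locked.n_neurons:
        raise ValueError("tensors must share neurons")
    right_abs = separation + move_locked.rel_time
    keep_left = target_locked.rel_time < right_abs[0] - 1e-9
    if not np.any(keep_left):
        raise ValueError(
            "movement-locked window fully overlaps the target-locked window; "
            "cannot honor both"
        )
    rates = np.concatenate(
        [target_locked.rates[:, :, keep_left], move_locked.rates], axis=2
    )
    time = np.concatenate([target_locked.rel_time[keep_left], right_abs])
    lock = np.concatenate([target_locked.lock[keep_left], move_locked.lock])
    rel = np.concatenate([target_locked.rel_time[keep_left], move_locked.rel_time])
    return RateTensor(
        rates=rates,
        time=time,
        lock=lock,
        rel_time=rel,
        conditions=list(target_locked.conditions),
        junction_index=int(keep_left.sum()),
        meta={**target_locked.meta, "separation": separation},
    )


def soft_normalize(
    tensor: RateTensor, constant: float = 5.0
) -> tuple[RateTensor, np.ndarray]:
    """Per-neuron soft normalization: divide by (firing-rate range + constant).

    The range is pooled over every condition and time in the tensor, so one
    factor serves the whole analysis.  Silent neurons get factor ``constant``.
    Returns the normalized tensor and the factors (for inversion).
    """
    rng = tensor.rates.max(axis=(1, 2)) - tensor.rates.min(axis=(1, 2))
    factors = rng + constant
    return replace(tensor, rates=tensor.rates / factors[:, None, None]), factors


def mean_center(tensor: RateTensor) -> tuple[RateTensor, np.ndarray]:
    """Remove each neuron's across-condition mean at every time point.

    Returns the centered tensor and the removed mean (n_neurons, n_times),
    needed for full reconstruction.  Centering is idempotent; with a single
    condition it is degenerate and raises.
    """
    if tensor.n_conditions < 2:
        raise ValueError("mean centering requires >= 2 conditions")
    mean = tensor.rates.mean(axis=1)
    return replace(tensor, rates=tensor.rates - mean[:, None, :]), mean


def extract_epoch(tensor: RateTensor, epoch: EpochDefinition) -> np.ndarray:
    """Epoch data matrix, (n_neurons, n_conditions * n_epoch_times).

    Columns are ordered condition-major then time — the P or M matrix of the
    subspace optimization.  The epoch must lie inside the tensor's annotated
    alignment segment.
    """
    idx = tensor.epoch_sample_index(epoch)
    n_expect = int(round((epoch.end_offset - epoch.start_offset) /
                         np.min(np.diff(tensor.time))))
    if idx.size == 0 or idx.size < n_expect:
        raise ValueError(
            f"epoch {epoch} not fully contained in tensor alignment segments"
        )
    sub = tensor.rates[:, :, idx]
    return sub.reshape(tensor.n_neurons, -1)


def tuning_anova(
    trialset: TrialSet,
    epoch: EpochDefinition,
    context: str | None = None,
) -> np.ndarray:
    """One-way fixed-effects ANOVA of epoch-mean rate across reach directions.

    Uses per-trial epoch-mean rates (spike count / duration, or mean of the
    rate samples for rate-based trialsets).  Returns a p-value per neuron;
    degenerate inputs (zero variance everywhere) yield NaN.  Any direction
    with fewer than 2 trials raises.
    """
    trials = trialset.trials
    if context is not None:
        trials = trials[trials["context"] == context]
    event_col = _EVENT_COL[epoch.alignment_event]
    dt = trialset.time_step
    dur_s = (epoch.end_offset - epoch.start_offset) / 1000.0
    groups: dict[float, list[np.ndarray]] = {}
    for _, row in trials.iterrows():
        tid = int(row["trial_id"])
        ev = float(row[event_col])
        lo, hi = ev + epoch.start_offset, ev + epoch.end_offset
        if trialset.rates is not None:
            r = trialset.rates[tid]
            i0 = max(int(np.floor(lo / dt)), 0)
            i1 = min(int(np.floor(hi / dt)), r.shape[1])
            vals = r[:, i0:i1].mean(axis=1)
        else:
            vals = np.array(
                [
                    np.count_nonzero((st >= lo) & (st < hi)) / dur_s
                    for st in trialset.spikes[tid]
                ]
            )
        groups.setdefault(float(row["direction_deg"]), []).append(vals)
    for direc, lst in groups.items():
        if len(lst) < 2:
            raise ValueError(f"direction {direc} has fewer than 2 trials")
    stacked = {d: np.stack(lst) for d, lst in groups.items()}  # (n_trials, N)
    N = next(iter(stacked.values())).shape[1]
    pvals = np.empty(N)
    with np.errstate(invalid="ignore", divide="ignore"):
        for n in range(N):
            samples = [arr[:, n] for arr in stacked.values()]
            pvals[n] = stats.f_oneway(*samples).pvalue
    return pvals
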