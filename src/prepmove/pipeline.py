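"""End-to-end orchestration: simulate -> RT -> preprocess -> subspaces ->
occupancy/latency/similarity, with a declarative config and a manifest.

The pipeline mirrors the analysis order of a delayed-reach population study:
subspaces are identified from the cue-initiated context only (delay epoch vs
movement epoch), then every context's activity is projected onto those fixed
dimensions.  All randomness flows from the config seeds, so a manifest (the
config hash plus seeds and versions) is sufficient to reproduce outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior, occupancy_stats as occ, preprocess as pp, subspaces as ss
from .synth import CUE, ContextSpec, SyntheticSpec, default_contexts, generate_dataset

log = logging.getLogger("prepmove")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration with the study's default values."""

    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    kernel_sd_main: float = 20.0  # ms, all standard analyses
    kernel_sd_latency: float = 10.0  # ms, latency analyses only
    delay_epoch: tuple[float, float] = (50.0, 500.0)  # re target onset
    move_epoch: tuple[float, float] = (-50.0, 250.0)  # re movement onset
    target_window: tuple[float, float] = (-200.0, 450.0)  # concatenated display
    fit_target_window: tuple[float, float] = (-200.0, 500.0)  # covers delay epoch
    move_window: tuple[float, float] = (-350.0, 400.0)
    d_prep: int = 12
    d_move: int = 12
    n_restarts: int = 10
    n_boot: int = 1000
    seed: int = 0
    fit_context: str = CUE
    final_state_time: float = -55.0  # ms re movement onset
    slope_time: float = -100.0
    latency_frac: float = 0.10

    def validate(self) -> None:
        self.spec.validate()
        if self.d_prep + self.d_move > self.spec.n_neurons:
            raise ValueError("d_prep + d_move exceeds n_neurons")
        if not any(c.name == self.fit_context for c in self.spec.contexts):
            raise ValueError(f"fit_context {self.fit_context!r} not in context list")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"]["contexts"] = [asdict(c) for c in self.spec.contexts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sd = dict(d.pop("spec", {}))
        ctxs = sd.pop("contexts", None)
        if ctxs is not None:
            sd["contexts"] = tuple(
                ContextSpec(**{**c, "delay_range": tuple(c["delay_range"])})
                for c in ctxs
            )
        spec = SyntheticSpec(**sd) if sd else SyntheticSpec()
        for k in ("delay_epoch", "move_epoch", "target_window", "move_window"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(spec=spec, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), f)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name, t0, **scalars):
    log.info("stage=%s duration=%.2fs %s", name, _time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in scalars.items()))


def pooled_soft_factors(tensors, constant: float = 5.0) -> np.ndarray:
    """Soft-normalization factors from the range pooled over several tensors."""
    hi = np.max([t.rates.max(axis=(1, 2)) for t in tensors], axis=0)
    lo = np.min([t.rates.min(axis=(1, 2)) for t in tensors], axis=0)
    return (hi - lo) + constant


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 n_boot: Optional[int] = None) -> dict:
    """Run the full analysis; returns a results dict and optionally writes
    the TSV/manifest bundle to ``outdir``.

    ``n_boot`` overrides the config's bootstrap count (useful for quick
    runs).  Identical config + seed produces identical results.
    """
    config.validate()
    nb = config.n_boot if n_boot is None else n_boot
    results: dict = {"config": config.to_dict()}
    t0 = _time.perf_counter()

    trialset, truth = generate_dataset(config.spec)
    _stage("simulate", t0, n_trials=len(trialset.trials))

    # --- behavioral RT estimation from kinematics -------------------------
    t0 = _time.perf_counter()
    kin_trials = [
        behavior.KinematicTrial(
            position=trialset.kinematics[int(r.trial_id)],
            sample_interval=trialset.kin_dt,
            trial_id=int(r.trial_id),
            condition=f"{r.context}/{r.direction_deg:g}",
            go_cue=float(r.go_cue_ms),
        )
        for r in trialset.trials.itertuples()
    ]
    rt_table = behavior.estimate_movement_onset(kin_trials)
    results["rt_table"] = rt_table
    _stage("rt", t0, analyzable=int(rt_table["analyzable"].sum()))

    # --- preprocessing: aligned averages + concatenated tensors -----------
    t0 = _time.perf_counter()
    contexts = [c.name for c in config.spec.contexts]
    raw_cat, raw_fit_left, raw_right = {}, {}, {}
    for ctx in contexts:
        left = pp.smooth_and_average(
            trialset, config.kernel_sd_main, pp.TARGET, config.target_window, [ctx]
        )
        right = pp.smooth_and_average(
            trialset, config.kernel_sd_main, pp.MOVE, config.move_window, [ctx]
        )
        raw_fit_left[ctx] = pp.smooth_and_average(
            trialset, config.kernel_sd_main, pp.TARGET, config.fit_target_window, [ctx]
        )
        raw_right[ctx] = right
        sep = pp.median_separation(trialset, ctx)
        raw_cat[ctx] = pp.concatenate_alignments(left, right, sep)
    factors = pooled_soft_factors(list(raw_cat.values()))

    def norm_center(t):
        out = replace(t, rates=t.rates / factors[:, None, None])
        out, mu = pp.mean_center(out)
        return out, mu

    tensors, means = {}, {}
    fit_left, move_locked = {}, {}
    for ctx in contexts:
        tensors[ctx], means[ctx] = norm_center(raw_cat[ctx])
        fit_left[ctx], _ = norm_center(raw_fit_left[ctx])
        move_locked[ctx], _ = norm_center(raw_right[ctx])
    results["soft_factors"] = factors
    _stage("preprocess", t0)

    # --- subspace identification on the fit context -----------------------
    t0 = _time.perf_counter()
    delay = pp.EpochDefinition(pp.TARGET, *config.delay_epoch)
    move_ep = pp.EpochDefinition(pp.MOVE, *config.move_epoch)
    C_prep = ss.epoch_covariance(
        pp.extract_epoch(fit_left[config.fit_context], delay), "prep"
    )
    C_move = ss.epoch_covariance(
        pp.extract_epoch(move_locked[config.fit_context], move_ep), "move"
    )
    pair = ss.optimize_subspaces(
        C_prep, C_move, config.d_prep, config.d_move,
        n_restarts=config.n_restarts, seed=config.seed,
    )
    pair.check()
    results["pair"] = pair
    _stage("subspaces", t0, objective=round(pair.objective_value, 6))

    # --- occupancy with bootstrap envelopes -------------------------------
    t0 = _time.perf_counter()
    boot = {}
    for ctx in contexts:
        boot[ctx] = occ.bootstrap_occupancy(
            tensors[ctx], delay, move_ep, config.d_prep, config.d_move,
            n_boot=nb, seed=config.seed, n_restarts=config.n_restarts,
            fit_delay=fit_left[config.fit_context],
            fit_move=move_locked[config.fit_context],
        )
    ref_prep = float(boot[config.fit_context].prep.values.max())
    ref_move = float(boot[config.fit_context].move.values.max())
    results["occupancy"] = boot
    results["occupancy_reference"] = {"prep": ref_prep, "move": ref_move}
    _stage("occupancy", t0, n_boot=nb)

    # --- latency analyses (10 ms kernel, movement-locked) -----------------
    # dimensions are recomputed once from the fit context's 10 ms-kernel
    # data, then every context's occupancy is measured on those dimensions
    t0 = _time.perf_counter()
    lat_fit_left, _ = norm_center(pp.smooth_and_average(
        trialset, config.kernel_sd_latency, pp.TARGET,
        config.fit_target_window, [config.fit_context],
    ))
    lat_move = {}
    for ctx in contexts:
        tens = pp.smooth_and_average(
            trialset, config.kernel_sd_latency, pp.MOVE, config.move_window, [ctx]
        )
        lat_move[ctx], _ = norm_center(tens)
    pair_lat = ss.optimize_subspaces(
        ss.epoch_covariance(pp.extract_epoch(lat_fit_left, delay), "prep"),
        ss.epoch_covariance(
            pp.extract_epoch(lat_move[config.fit_context], move_ep), "move"
        ),
        config.d_prep, config.d_move,
        n_restarts=config.n_restarts, seed=config.seed,
    )
    latencies = []
    for ctx in contexts:
        tens = lat_move[ctx]
        prep_tr = occ.occupancy(occ.project(tens, pair_lat.W_prep))
        move_tr = occ.occupancy(occ.project(tens, pair_lat.W_move))
        lat_p = occ.threshold_latency(prep_tr, frac=config.latency_frac)
        lat_m = occ.threshold_latency(move_tr, frac=config.latency_frac)
        emg_avg, emg_t = occ.average_emg(
            trialset, config.kernel_sd_latency, pp.MOVE, config.move_window, ctx
        )
        lat_emg, _ = occ.emg_latency(emg_avg, emg_t, frac=config.latency_frac)
        latencies.append(
            dict(context=ctx, prep_latency_ms=lat_p, move_latency_ms=lat_m,
                 emg_latency_ms=lat_emg,
                 prep_lead_ms=lat_m - lat_p, neural_emg_lead_ms=lat_emg - lat_m)
        )
    results["latencies"] = pd.DataFrame(latencies)
    _stage("latency", t0)

    # --- cross-context similarity ----------------------------------------
    t0 = _time.perf_counter()
    proj_prep = {c: occ.project(move_locked[c], pair.W_prep, "prep") for c in contexts}
    sim_rows = []
    cov_traces = {}
    for a in contexts:
        for b in contexts:
            if a >= b:
                continue
            r = occ.cross_context_state_similarity(
                proj_prep[a], proj_prep[b], config.final_state_time
            )
            sim_rows.append(dict(context_a=a, context_b=b, state_correlation=r))
            cov_traces[(a, b)] = occ.cross_context_covariance_timecourse(
                proj_prep[a], proj_prep[b]
            )
    move_win = pp.EpochDefinition(pp.MOVE, -50.0, 250.0)
    pat = {
        c: occ.reconstruct(move_locked[c], pair).prep_patterns for c in contexts
    }
    slope_rows = []
    ref_ctx = config.fit_context
    i_slope = int(np.argmin(np.abs(move_locked[ref_ctx].time - config.slope_time)))
    for c in contexts:
        if c == ref_ctx:
            continue
        m, se, _ = occ.tuning_slope(pat[c][:, :, i_slope], pat[ref_ctx][:, :, i_slope])
        slope_rows.append(dict(context=c, reference=ref_ctx, slope=m, se=se))
    corr_rows = []
    for c in contexts:
        if c == ref_ctx:
            continue
        _, med = occ.pattern_correlation(move_locked[c], move_locked[ref_ctx], move_win)
        corr_rows.append(dict(context=c, reference=ref_ctx,
                              median_pattern_correlation=med))
    results["similarity"] = pd.DataFrame(sim_rows)
    results["covariance_traces"] = cov_traces
    results["slopes"] = pd.DataFrame(slope_rows)
    results["pattern_correlations"] = pd.DataFrame(corr_rows)
    _stage("similarity", t0)

    if outdir is not None:
        _write_bundle(results, config, Path(outdir))
    return results


def _write_bundle(results: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["rt_table"].to_csv(outdir / "rt_table.tsv", sep="\t", index=False)
    for ctx, b in results["occupancy"].items():
        ref = results["occupancy_reference"]
        df = pd.DataFrame(
            dict(
                time_ms=b.prep.time,
                prep_occupancy=b.prep.values / ref["prep"],
                prep_boot_sd=b.prep.boot_sd / ref["prep"],
                move_occupancy=b.move.values / ref["move"],
                move_boot_sd=b.move.boot_sd / ref["move"],
            )
        )
        safe = ctx.replace("/", "_").replace(" ", "_")
        df.to_csv(outdir / f"occupancy_{safe}.tsv", sep="\t", index=False)
    results["latencies"].to_csv(outdir / "latencies.tsv", sep="\t", index=False)
    results["similarity"].to_csv(outdir / "similarity.tsv", sep="\t", index=False)
    results["slopes"].to_csv(outdir / "slopes.tsv", sep="\t", index=False)
    results["pair"].save(outdir / "subspaces.h5")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "objective": results["pair"].objective_value,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=float)
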