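# Methods

This note documents the models and estimators implemented in `prepmove`, the
synthetic-data generator that stands in for monkey recordings, the default
parameters, and the design decisions taken where the methodology was
genuinely open.  Nothing here reports an empirical claim that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Data model and preprocessing

Analyses operate on trial-averaged, time-resolved firing rates indexed
neuron × condition × time, where a *condition* is one reach direction within
one initiation context.  Spike trains are binned at 1 ms, convolved with a
unit-mass Gaussian kernel (SD 20 ms for standard analyses, 10 ms for latency
analyses, truncated at ±4 SD; the padding window uses real data so edge
samples are unbiased), and averaged across trials aligned to target onset or
movement onset.  Target-locked and movement-locked segments can be
concatenated into a single tensor; the junction is placed at the context's
median target→movement separation, and the target-locked segment is trimmed
where it would overlap the movement-locked one.  Covariance matrices for
subspace identification are always extracted from the un-concatenated
aligned averages (delay epoch: 50–500 ms after target onset; movement epoch:
−50–250 ms around movement onset), so the junction never touches them.

Two normalizations precede dimensionality reduction:

- **Soft normalization**: each neuron is divided by (firing-rate range + 5),
  the range pooled over all contexts/conditions/times, so one factor per
  neuron serves the whole analysis and high-rate neurons do not dominate.
- **Mean centering**: at each time, each neuron's mean across conditions is
  removed (and kept, for full reconstructions), so analyses target
  condition-tuned structure.

## 2. Subspace identification

Preparatory and movement subspaces jointly maximize

½ [ Tr(Wₚᵀ Cₚ Wₚ) / Σᵢ≤dₚ σₚ(i) + Tr(Wₘᵀ Cₘ Wₘ) / Σᵢ≤dₘ σₘ(i) ],

subject to WₚᵀWₘ = 0 and orthonormal blocks.  The normalizers use the top-d
singular values of each covariance; this bounds each term by 1 (so the
objective lives in [0, 1]) and makes the objective insensitive to the
relative strength and dimensionality of the two epochs.  Defaults
d_prep = d_move = 12, configurable.

The optimizer is gradient ascent on the Stiefel manifold of the joined
N×(dₚ+dₘ) orthonormal matrix: Euclidean gradient `[CₚWₚ/sₚ, CₘWₘ/sₘ]`,
projection to the tangent space, QR retraction, backtracking line search
(growth 1.3, halving on failure), convergence when the relative objective
increase falls below 1e−10 or after 5000 iterations.  The first start is the
per-epoch PCA solution made jointly feasible by QR orthogonalization (its
objective is a reported lower bound the final answer can never fall below);
remaining restarts (default 10 in the pipeline) are seeded random
orthonormal matrices.  A 0.001-rad grid-search oracle over the one-parameter
family of feasible 2×2 pairs serves as an independent correctness check.

Within each recovered subspace the basis is rotated so projected variance is
diagonal and descending, with the largest-magnitude element of each column
made positive (deterministic across platforms).  For visualizing rotational
structure, a least-squares skew-symmetric linear dynamics fit
(min ‖Ẋ − MX‖, M = −Mᵀ, solved in closed form via a Sylvester equation
inside the data's row space) supplies the plane of the fastest conjugate
eigenvalue pair.  This is a deliberate simplification of full
rotation-discovery methods: it fits one linear skew field to all conditions
and reports one plane.

## 3. Occupancy, bootstrap, latencies

**Occupancy** of a subspace at time t is Σₖ var_θ(xₖ(t, θ)) — the summed
across-condition variance of the projections, with the unbiased (n−1)
denominator throughout.  Because bases are orthonormal this equals the
summed per-neuron variance of the reconstructed patterns; the identity is
asserted to 1e−10 in the tests (dual-route check).

**Bootstrap envelopes** redraw neurons with replacement and re-run the full
identification (covariances → optimization → projection → occupancy) per
surrogate population; the per-time SD of the resulting sampling distribution
is the standard-error envelope, and one-tailed p-values come from paired
comparisons of two sampling distributions (floored at 1/n_pairs).  Occupancy
is invariant to the rotational indeterminacy of a redrawn basis within its
subspace, so no alignment step is needed.  Resamples with fewer distinct
neurons than the requested dimensionality are redrawn and counted.  The
bootstrap's premise is that neurons are an (approximately) iid sample; see
§4 on when the generator satisfies this.

**Latencies** are the earliest time a trace reaches 10% of its peak (linear
interpolation between samples), computed on movement-locked tensors smoothed
with the 10 ms kernel.  For the neural-vs-EMG comparison, EMG is
range-normalized per muscle, PCA is run over (condition, time) samples, and
the latency is taken on the *across-condition variance* of the PC1
projection — the same selectivity-strength statistic as occupancy, which
keeps the two latencies commensurate (with mean pooling, the 10% crossing
sits at a different point of the kernel-smeared rise and a designed lead is
mis-estimated by roughly the kernel width).  For timing comparisons the
dimensions are identified once, from the cue-initiated context, and all
contexts are projected onto those fixed dimensions.

**Cross-context statistics**: final preparatory states (default 55 ms before
movement onset) are flattened over (direction × dimension) and Pearson-
correlated between contexts; per-neuron tuning slopes come from OLS (with
intercept) of one context's pattern values on another's at a fixed time
(default −100 ms), excluding zero-variance reference neurons; per-neuron
pattern correlations use (condition × time) blocks in a stated window; the
covariance time course is the mean-removed inner product across
(direction × dimension) pairs divided by (count − 1) — its vertical scale is
arbitrary, only its timing is interpreted.  RT-split analyses recompute
trial averages per RT half and project onto the *fixed* full-data subspaces.

## 4. The synthetic generator

The generator emulates the three initiation contexts with scripted
low-dimensional latents — it is a measurement model, not a recurrent
network; latents are designed, not emergent.

- **Geometry.** Ground-truth bases W_prep (d=2) ⊥ W_move (d=2) drive rates
  `r = max(0, baseline + gain·(W_prep z_prep + W_move z_move))` with
  baseline 30 spikes/s and gain 60 (per-neuron modulations of roughly
  ±7–15 spikes/s; rectification is rare).  Loadings are drawn as a
  row-balanced random orthonormal frame (iterated Löwdin orthogonalization),
  and W_move is additionally projected out of span(W_prep, D⁻²W_prep),
  where D is the predicted soft-normalization diagonal, iterated to
  self-consistency.  This makes the planted pair orthogonal both in rate
  space (exactly) and in the soft-normalized analysis space (~0.5°).
  Without the correction the diagonal rescaling tilts the planted subspaces
  several degrees from orthogonality in the space where the analysis
  operates, and no orthogonality-constrained method could recover them
  cleanly.  `balanced_loadings=False` switches to a plain Gaussian-QR draw.
  For *neuron-sampling* studies (e.g. bootstrap-coverage checks) even that
  is not enough: any per-population orthonormalization enforces
  Σₙwₙwₙᵀ = I exactly, which suppresses across-population variance and makes
  neurons non-iid, so the bootstrap over-covers.  Those studies subsample
  each population's rows iid with replacement from one large master pool via
  the `loadings` override of `generate_dataset`.
- **Condition tuning.** First two latent dimensions ∝ (cos θ, sin θ) of
  reach direction; any higher planted dimensions are fixed random mixtures
  of second-harmonic tuning at lower amplitude.
- **Preparatory envelopes.** Cue-initiated: target-locked half-cosine rise
  (15 ms) to a post-target peak (1.3) decaying (τ = 80 ms) to a sustained
  plateau (1.0).  Self-initiated: movement-locked onset followed by a ramp
  that grows toward a 1.2 peak 70 ms before movement onset.
  Quasi-automatic: rapid movement-locked transient (1.3).  All envelopes
  collapse to ~0 between −70 and +20 ms around movement onset, so the final
  preparatory state (−55 ms) is still strong while occupancy is near
  baseline by shortly after movement begins.
- **prep_lag (per context).** When set, the preparatory envelope onset is
  movement-locked at (movement gate − prep_lag), making the designed
  preparatory-over-movement lead equal to prep_lag and recoverable by the
  10%-of-peak estimator; when `None` (the cue-initiated default) the onset
  is target-locked, giving the instructed-delay plateau.  A design
  constraint on the shapes: every context's rise must reach a comparable
  fraction of its eventual peak (rise tops at 1.3, 1.3·0.85 ≈ 1.1 and 1.3 of
  peaks 1.3, 1.2, 1.3), so the fraction-of-peak threshold crosses at an
  equivalent point of each smoothed rise; an earlier draft with a low ramp
  start (0.6) put the self-initiated crossing at 0.63 of its rise top and
  the kernel smear shifted the estimated onset ~8 ms late.
- **Movement latents.** A rotating pair (default 2 Hz) gated on 150 ms
  before movement onset, identical across contexts up to a gain
  (`move_amp` = 1.5 × the preparatory scale, as movement activity is the
  stronger of the two), with a modest post-onset peak and a late taper.
- **Trial timing.** Target onset at 300 ms; cue-initiated delays uniform on
  0–1000 ms; RTs truncated-normal per context (means/SDs 253/50, 935/132,
  205/32 ms as documentation defaults), truncated at ±2.5 SD with a
  causality floor RT ≥ gate + prep_lag + 2 ms so movement-locked latent
  onsets never precede target onset (binds mildly for the quasi-automatic
  context).  All event times snap to the 1 ms grid.
- **Spiking.** Poisson counts per 1 ms bin (or Gaussian rate noise with
  `noise_sd`, in which case trial rate traces are carried instead of
  spikes).  Default 40 trials per condition.
- **Kinematics.** Minimum-jerk 130 mm reaches of 350 ms.  Movement onset is
  defined *operationally* as the 1%-of-peak crossing of the speed profile —
  the same convention the estimator uses — so the minimum-jerk launch is
  placed ~2.6% of the reach duration before the nominal onset.
- **EMG.** Eight muscles, each a rectified fixed random mixture of the
  movement latents delayed by `emg_lag` (20 ms) plus a small noise floor.
  Because the movement latents are shared across contexts, EMG patterns
  correlate ≥ 0.95 across contexts by construction.

What passing tests on these data do **not** show: robustness to
non-Poisson spiking statistics, non-stationary baselines, electrode drift,
correlated noise across neurons, emergent (rather than scripted) dynamics,
or single-trial variability structure beyond independent noise — real
recordings can violate all of these.

## 5. Reaction-time estimation

Per trial, the moment of peak acceleration (t_peakAcc) is located on a
heavily smoothed speed trace (zero-phase Gaussian, SD 12 ms); any systematic
shift this introduces is common to all trials of a condition and cancels
exactly through the correction term, while the smoothing suppresses
trial-to-trial jitter of the peak.  Trials are aligned on t_peakAcc and
their lightly smoothed (SD 3 ms) speeds averaged over the region all trials
cover.  The interval t_corr from the threshold crossing of that average back
to the alignment point is measured once per condition, and each trial's
onset is t_peakAcc − t_corr.  The threshold is the stated fraction (default
1%) of the average's peak, referenced to its pre-peak baseline floor
(speed is a magnitude, so measurement noise leaves a positive floor that
does not average away), and the crossing is taken as the *last* upward
crossing before the peak so floor-noise excursions far from the movement are
skipped.  On clean traces both refinements are no-ops.  Trials with flat
speed, or conditions whose average never exceeds threshold, are flagged
unanalyzable rather than raising.  Circular dispersion of reach directions
uses √(−2 ln R̄), returning ∞ below machine resolution of R̄.

## 6. Problem sizes and tolerances used in the tests

Unit tests run on 24–40-neuron populations with 6–10 trials per condition.
The acceptance-style checks use: 50 random optimizer problems with N up to
150; 200 2×2 oracle comparisons at 1e−4; recovery at N=120 (high SNR:
Gaussian rate noise, SD 0.5 spikes/s, 20 trials); timing grammar at N=120
with 30 trials and prep_lag=40 ms in all contexts; bootstrap coverage on 100
populations of 30 neurons (one context, n_boot=200, subsampled from a
2000-neuron master pool) with the expected occupancy estimated from 80
noise-free populations; similarity statistics over 100 seeds at N=50.
Exact linear-algebra identities are asserted at 1e−8–1e−12; stochastic
checks at tolerances stated in the individual tests.

## 7. Known limitations

- The skew-symmetric plane fit assumes one global linear rotational field;
  data with multiple frequency components in overlapping dimensions will
  yield a compromise plane.
- The optimizer guarantees a feasible local maximum (never below the PCA
  start), not a global one; the restart count is the only defense, though
  the 2×2 oracle and recovery tests show the default is adequate.
- Occupancy mixes signal and noise variance additively; no noise-floor
  subtraction is performed, matching the conventions of the field.
- OLS tuning slopes attenuate toward zero when the *reference* patterns are
  noisy (classical errors-in-variables); slope checks in the tests use
  high-SNR constructions where the attenuation is negligible.
- With few trials and strong rectification the Poisson generator's
  trial-averaged rates are slightly nonlinear in the latents; gain-recovery
  analyses should use the Gaussian noise model or high baselines.
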