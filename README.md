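# prepmove

Orthogonal preparatory/movement subspace analysis of motor-cortical
population activity, together with a fully specified synthetic multi-context
population generator so that every analysis stage can be validated against a
known ground truth.

## The scientific problem

During delayed reaching, motor cortex is active long before the arm moves.
A productive way to reconcile preparatory activity with the absence of
movement is geometric: delay-period activity and movement-period activity
occupy *mutually orthogonal subspaces* of the population state space, so
preparatory activity can grow without driving muscles.  This package
implements the population-level machinery behind that account, for
experiments in which the same set of radial reaches is initiated in three
different ways: after an instructed delay (**cue-initiated**), at the
animal's own pace (**self-initiated**), or by immediate target interception
with very short reaction times (**quasi-automatic**).

It is a library for computational/systems neuroscientists who want to

- estimate movement onset and reaction times from hand kinematics
  (peak-acceleration alignment with a low speed threshold),
- build trial-averaged, soft-normalized, mean-centered rate tensors from
  spike tables,
- identify preparatory and movement subspaces by constrained
  trace-maximization,
- quantify subspace **occupancy** over time with neuron-bootstrap
  uncertainty, event latencies (10%-of-peak), and cross-context similarity
  statistics,
- and generate synthetic multi-context populations (Poisson spikes,
  minimum-jerk kinematics, EMG) with planted orthogonal structure.

## The core method

Let `P ∈ R^{N×CT}` hold delay-epoch responses and `M ∈ R^{N×CT}`
movement-epoch responses (N neurons, C reach directions, T epoch samples;
responses soft-normalized and mean-centered across conditions).  With
`C_prep = cov(P)`, `C_move = cov(M)` and `σ(i)` their singular values, the
method finds

```
maximize   1/2 [ Tr(W_prep' C_prep W_prep) / Σ_{i≤d_prep} σ_prep(i)
               + Tr(W_move' C_move W_move) / Σ_{i≤d_move} σ_move(i) ]
subject to W_prep' W_move = 0,  W_prep' W_prep = I,  W_move' W_move = I
```

solved by Riemannian gradient ascent on the Stiefel manifold of the joined
`N×(d_prep+d_move)` orthonormal matrix (cross-orthogonality is then
automatic), with a PCA-based feasible initialization, seeded restarts, and
an exhaustive grid-search oracle for 2×2 problems.  Occupancy of a subspace
at time t is `Σ_k var_θ(x_k(t,θ))`, the summed across-condition variance of
the projections — equivalently the summed variance of each neuron's
reconstructed pattern.  Uncertainty comes from redrawing neurons with
replacement and re-running the entire identification per surrogate
population.

## Worked example

`examples/03_identify_subspaces.py` simulates 120 neurons under the
cue-initiated context (high SNR), runs the full preprocessing chain, and
identifies 12+12 dimensions:

```
objective value: 0.9645 (1 = each basis captures as much as an unconstrained top-d basis could)
W_prep captures 96.0% of delay-epoch but only 3.1% of movement-epoch tuned variance
W_move captures 96.9% of movement-epoch but only 4.0% of delay-epoch tuned variance
largest principal angle to the planted preparatory plane: 1.79 deg
```

The variance split is the signature of the method: preparatory dimensions
carry delay-period direction selectivity and almost none of the
movement-epoch selectivity, and the recovered subspace is within two degrees
of the planted one.  `examples/04_occupancy_and_latency.py` adds the timing
grammar (occupancy onsets via the 10%-of-peak rule):

```
designed: preparatory lead 40 ms; EMG lags movement latents by 20 ms
  cue-initiated    prep onset  -189.7 ms, move onset  -145.2 ms (lead 44.5 ms), EMG onset  -126.3 ms; peak boot SE 7% of peak occupancy
  self-initiated   prep onset  -187.6 ms, move onset  -144.5 ms (lead 43.1 ms), EMG onset  -126.3 ms; peak boot SE 12% of peak occupancy
  quasi-automatic  prep onset  -186.9 ms, move onset  -146.2 ms (lead 40.7 ms), EMG onset  -126.3 ms; peak boot SE 10% of peak occupancy
```

Preparatory occupancy rises a few tens of milliseconds before movement
occupancy in every context, which in turn rises ~20 ms before the muscles —
the designed ordering, recovered by the estimators.  The other examples
cover simulation, reaction-time estimation, and cross-context similarity.

A thin CLI wraps the pipeline: `prepmove simulate --out DIR --seed 1` writes
a synthetic dataset as TSV files; `prepmove run --out DIR --seed 1` runs the
full analysis and writes occupancy/latency/similarity tables plus a
reproducibility manifest.

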