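# Methods

## Inference engine

Both paradigms reduce to chains, where sum-product message passing is
exact and equal to forward–backward. Messages are normalized at every
timestep and the log normalizers accumulated, so the log evidence is
recovered without underflow for chains far longer than the T ≤ 80 used
here (tested to T = 5000). Emissions are callbacks evaluated per (state,
observation): discrete tables and continuous densities are treated
identically, and a missing observation contributes a constant factor 1
(used to pad trial timelines). An observation to which every state
assigns zero likelihood raises an error naming the timestep rather than
silently renormalizing.

A brute-force oracle (`enumerate_oracle`) sums over all state paths
explicitly and refuses instances above 10^6 paths; the engine is tested
against it to 1e-10 on randomized chains, and the speed-optimized scalar
smoothers used inside the fitting loops are tested against the generic
engine to 1e-12.

## Tactile paradigm (three-cause model)

A trial is a length-50 chain, 10 ms per step. The observation series is 0
at baseline, the probe frequency over the (inclusive, 1-based) probe
window 10–15, and the object frequency from contact onset 25 to the end.
Physical 40/240 Hz stimuli are mapped onto model units {low: 30, high:
70}; the mapping is configuration, not a constant, because the original
description leaves the unit correspondence ambiguous. The movement-policy
frequency equals the object frequency.

Likelihood assumptions: *none* → truncated normal at 0 with fixed width
σ₀ = 5 (configuration, not a free parameter, keeping the free-parameter
count at seven); *external* → uniform 1/100; *internal* → truncated
normal at the policy frequency with free width σ (motor + sensory noise).
All truncations are renormalized over [0, 100].

Free parameters: six transition logits and σ. Each transition row is the
softmax of `[l₁, l₂, 0]` — the *none* column is the anchor recovered by
normalization — which is row-stochastic at every point of the bounded
(−3, 3) logit box; per-entry sigmoids would not guarantee this. The prior
over causes at t = 1 is fixed uniform (it does not influence detection
behavior enough to be identifiable). σ is optimized as log σ (bounds
1–100 in natural units, starts in [5, 40]) to keep it positive.

The detection probability is the **mean** posterior P(C = external) over
the probe window (the maximum would be a defensible alternative; the mean
is smoother for optimization). The fitting cost sums Bernoulli KL terms
over the four movement trial types and adds the endpoint penalty
λ·[−log P(M₅ = none) − log P(M₄₀ = internal)] averaged over the two
congruent trial types, with λ = 1 (the constraints are stated without a
weight; λ = 1 puts them on the same nats scale as the KL terms).
Probabilities inside logs are clipped at 1e-12. Fitting is multi-start
Powell (tolerance 1e-12, bounded, starts jittered uniformly in the
bounds, function-evaluation cap 4000 per restart); the default is 10
restarts, reduced to 3 in the recovery harnesses.

Default simulation parameters are task-inspired and anchored to published
fitted group means where available: sticky internal transitions
(P(int|int) = 0.68), unlikely exits from *none* (P(int|none) = 0.26,
P(ext|none) = 0.17), σ = 20.61. With these defaults the attenuation
asymmetry (congruent probes absorbed internally, incongruent probes
detected externally) holds for every σ in [5, 40].

## Delay paradigm (common vs. separate causes)

A trial is a pair of binary streams over an 80-step chain, one
deci-second (≈ 41.7 ms of experimental delay per shift step, mapping the
six delays 0–417 ms onto shifts {0, 2, 4, 6, 8, 10}; the mapping is
configurable). The proprioceptive stream is the movement step pattern
(neutral 0 → right 1 at step 20 → neutral at step 50 — invented
scaffolding, configurable, placed so no shift truncates the pattern); the
visual stream is the identical pattern delayed by the shift.

Eight free probabilities (stored as logits): common-chain prior and
transition rows, the emission table shared by both structures and both
channels, and the separate-chain prior and transitions (shared by the
visual and proprioceptive chains). The structure prior P(W = common) is
fixed at 0.5, and the delay-detection probability is the posterior
P(W = separate | streams) = σ(log E_SC − log E_CC) rather than a hard
argmax, so the cost is well defined on probabilities.

**Label switching.** Jointly complementing the hidden-state labels of all
chains (priors complemented, transition rows exchanged and complemented,
emission-table rows exchanged) leaves both structures' evidences exactly
invariant, so fitted optima come in symmetric pairs. Fits are
canonicalized to `c_lik_00 ≥ c_lik_10` (state 0 preferentially emits
observation 0, matching the neutral-position reading); without this,
parameter-recovery statistics are corrupted by mode flips.

Fitting is per participant and per agency condition (active/passive
separately): Powell at tolerance 1e-8, starts uniform in (−1, 1) on the
logit scale, hard bounds (−5, 5) to keep probabilities off exact 0/1, 10
restarts by default. Psychometric summaries fit the two-parameter
logistic ψ(d) = 1/(1 + e^{−slope·(d − threshold)}) by least squares
(slope optimized on the log scale to keep it positive, three slope
initializations); flat or non-identifiable data return a flagged
degenerate fit instead of raising.

Default simulation parameters are a plausible sticky-chain regime:
reliable emissions (0.9/0.1), sticky common chain (0.95), less persistent
separate chains (0.85), prior 0.9 on the neutral state. The published
group-mean fitted parameters (transitions near 0.5) cannot produce the
delay-crossover pattern in forward simulation — with near-uniform
transitions the separate-cause structure pays roughly twice a large path
cost that emission mismatch never overcomes — so the simulation defaults
are the package's own choice, selected once for qualitative agreement
with the reported crossover behavior. Intuition for the crossover: at
zero delay the separate-cause structure pays the movement path cost
twice; with increasing shift the single common chain accrues emission
mismatch ∝ shift × log-odds of the emission reliability, and the
crossover sits where the two costs balance.

## Model evidence and comparison

The likelihood entering the evidence is the Bernoulli likelihood of the
per-cell detection counts under the model's predicted probabilities (the
fitting cost is a KL reformulation of the same match and is used only for
fitting). Priors on free parameters are independent standard normals on
the logit scale — the evidence requires a proper prior and none is
published; results should be read alongside this prior specification.

`laplace_evidence` re-polishes the supplied optimum with L-BFGS-B,
evaluates the Hessian of the negative log posterior by central finite
differences (step 1e-4, accurate to O(step²)), and repairs non-positive-
definite Hessians with iteratively doubled diagonal jitter from 1e-6 (at
most 10 doublings, flagged in the result) — boundary optima are a real
possibility with bounded logits. Irreparable curvature raises with the
flat eigendirections named. A zero-parameter model degenerates to
LAP = log-likelihood exactly. Accuracy is tested against dense quadrature
on 1-D Bernoulli-rate and Gaussian models (≤ 0.1 nats) and against the
conjugate Gaussian–Gaussian closed form (≤ 1e-6).

Baselines: *bias* — one free response rate per participant (per agency
condition in the delay paradigm); *uniform* — fixed rate 1/3, zero
parameters; *forced fusion / separation* — structure pinned to
always-common / always-separate, making the detection probability the
clipped structure posterior (1e-12 or 1 − 1e-12), constant across delays.
With the structure pinned, the chain parameters no longer enter the
response likelihood, so these models are evaluated with zero effective
dimensions (any free direction would be exactly flat in the Hessian).

Group-level comparison sums per-participant ΔLAP; exp(Σ ΔLAP) is the
group evidence ratio, reported with the mean ± standard error of the
per-participant differences.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
assumes: per condition cell, the generative model's detection probability
at known ground truth, and a binomial detection count. It does **not**
emulate lapses, attention drift, session effects, learning, response
times or any within-trial dynamics — a green recovery test establishes
that the fitting machinery inverts the model on data from the model, not
that the model describes human behavior.

Ground-truth ranges default to neighborhoods of the published fitted
regimes: tactile transitions in ±0.75-logit boxes around the
sticky-internal means with σ uniform in [10, 35]; delay-paradigm
probabilities around the sticky-chain simulation defaults. Per-cell trial
counts default to 100 (tactile) and 24 (delay) — configuration values,
since the original per-cell counts are not all published; the recovery
studies use 200 and 600 trials per condition. Cohorts regenerate
bit-identically from their seed (PCG64; generator and numpy version
recorded in the provenance sidecar).

Recovery findings at these scales: σ recovers well (correlation ≈ 0.74
at 30 participants × 200 trials) while individual transition
probabilities recover poorly — four detection rates underdetermine seven
parameters, and condition structure drives which parameters are
identifiable. In the delay paradigm the shared emission probabilities
recover within 0.15 absolute error in ≥ 80% of replicates at 600
trials/condition once label switching is canonicalized.

## Known limitations

- The tactile model ignores movement-speed variability, the baseline
  (no-movement) block, and reaction times; the delay model ignores the
  hand-identity manipulation and continuous lever trajectories.
- With four data cells per tactile participant, only σ and coarse
  transition structure are identifiable; fitted transition matrices
  should not be interpreted parameter-by-parameter.
- Multi-start Powell with few restarts can miss the global basin on the
  delay model's rugged cost surface (saturated cells create near-flat
  plateaus); the recovery harnesses use 5 restarts as a floor.
- The Laplace approximation is a local Gaussian approximation; with
  counts this small it is accurate to ~0.05 nats on 1-D models but has no
  global guarantee for the 7- and 8-parameter models.
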