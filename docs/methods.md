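# Methods

## Model

Head yaw angular velocity is the single latent state. Positive velocity
denotes a leftward (counter-clockwise from above) turn; this convention
is arbitrary and recorded as the constant `LEFTWARD_POSITIVE`.

**Process model (the agent's "laws of physics").** A damped random walk
with an optional pull toward the knowledge signal:

μ_k = (1 − b·S)·a·Ω_{k−1} + b·S·u_k,  Ω_k ~ N(μ_k, σ_q²).

The knowledge signal enters the prediction *mean* as a convex
combination rather than as an additive control input. This choice keeps
the model conditionally linear-Gaussian given (u, S), so the exact
Kalman recursion is available as an oracle, and it gives the knowledge
weight `b` a direct interpretation: b = 0 ignores predictions of the
movement, b = 1 relies on them entirely.

**Sensor model.** The agent assumes y_k ~ N(Ω_k, σ_v²). The *world*
generates observations differently per condition: healthy sensors emit
the true velocity plus N(0, sensor_noise_sd²); deafferented (BVP)
sensors emit N(0, bvp_noise_sd²) independent of head motion. The two
sides are deliberately decoupled — interventions edit beliefs (σ_v,
σ_q, b) and never the world.

**Knowledge signal.** u_k = gain · Ω_true(t_k − delay) + N(0, σ_u²)
when the movement is self-initiated, identically zero when passive.
It is expressed on the velocity level (not acceleration or motor
torque) for linearity; the default delay is 0 and the default gain 1
(a faithful efference copy with a small noise floor).

**Inference.** Bootstrap particle filter: particles drawn from the
initial belief, weighted by the first observation, then repeatedly
propagated through the dynamic prior and reweighted by the Gaussian
likelihood. Weights live in log space and are normalized by
log-sum-exp; systematic resampling triggers when ESS = 1/Σw² falls
below 0.5·N. Posterior mean and sd (the weighted, biased estimator) are
recorded before resampling. The exact filter runs the matching Kalman
recursion with prediction variance (a·(1 − b·S))²·P + σ_q²; it accepts
σ_v = 0 (posterior collapses onto the observation), which the particle
filter cannot represent. The imagery mode iterates prediction only —
mean follows the knowledge-pulled recursion, variance grows toward its
stationary value — modelling imagined self-motion as the generative
model run off-line.

## Default parameters

| parameter | value | meaning / rationale |
|---|---|---|
| dt | 0.01 s | resolves the 1-s movement with 100 samples |
| total_time | 2.0 s | movement (0.5–1.5 s) plus margins |
| amplitude | 60 deg/s | a brisk, natural head turn |
| shape | raised cosine (sin²) bell | smooth, zero-endpoint velocity profile of a discrete head turn |
| sensor_noise_sd (healthy world) | 10 deg/s | noisy but clearly informative canal signal |
| bvp_noise_sd (BVP world) | 3 deg/s | spontaneous neuronal noise of the deafferented signal; see below |
| a (decay) | 0.995 /step | ~2-s damping time constant |
| σ_q | 6 deg/s per step | wide dynamic prior: without knowledge, the agent leans on its sensors |
| b (knowledge weight) | 0.8 | strong but imperfect reliance on predicted motion |
| assumed σ_v | 10 deg/s | matches the healthy sensor — a well-calibrated healthy agent |
| initial belief | N(0, 1²) deg/s | stationary head at trial start |
| knowledge gain / noise / delay | 1.0 / 1 deg/s / 0 s | faithful efference copy with a small noise floor |
| conventional inflation | ×10 | strong sensory down-weighting after rehabilitation |
| cognitive sharpening / new b | ×3 / 0.95 | more confident and more trusted predictions after training |
| n_particles | 5000 (50,000 for oracle checks) | Monte Carlo error ≪ metric differences |
| replicates | 20 seeds | stable seed-means for paired comparisons |

The untreated BVP agent keeps the healthy internal model. This
mis-specification is a modelling commitment, not an oversight: a patient
who *knew* the sensor was pure noise would ignore it, but the observed
attenuation of self-motion percepts requires the posterior to be partly
drawn toward the (zero-mean) data.

On `bvp_noise_sd`: the wandering of the passive BVP posterior scales
with the Kalman gain times the world noise. With the wide default prior
(σ_q = 6) and matched assumed sensor noise, a world noise as large as
the healthy transduction noise (10 deg/s) would make the passive BVP
estimate wander by a noticeable fraction of the movement amplitude,
contradicting the defining phenomenon that the passive patient
perceives no motion. We therefore model the deafferented signal's
spontaneous discharge noise as smaller (3 deg/s) than healthy
transduction noise. This is physiologically defensible — the
deafferented central signal lacks the transduced stimulus variability —
and it leaves the active-condition results untouched (the filter gain
depends on the *assumed* noise, not the actual one).

## Metrics

- **displacement gain** (headline): ∫ posterior mean dt / ∫ truth dt.
  Robust to jitter at the peak; a value below 1 is the perceptual
  analogue of a reduced vestibulo-ocular-reflex gain (an analogy — no
  oculomotor dynamics are simulated).
- **peak gain**: posterior mean at the time of the true speed peak,
  normalized by the true peak.
- **response lag**: argmax over non-negative lags (≤ 0.3 s) of the
  cross-correlation with the truth, refined by parabolic interpolation
  around the discrete argmax. Negative lags are excluded because the
  causal filter cannot systematically lead the stimulus; a flat trace
  returns 0 with a warning.
- **mean uncertainty**: average posterior sd over the movement window.
- **zero-motion score**: max |posterior mean| / true peak; ≈ 0 when no
  motion is perceived.

## What the synthetic world does and does not emulate

The generator produces a single deterministic yaw-velocity bell, white
Gaussian sensor noise, and a velocity-level knowledge signal. It omits
canal transfer-function dynamics (high-pass filtering, cupula time
constants), 3D rotations, otolith/translation channels, explicit
visual-proprioceptive fusion, covert saccades, and any learning across
trials. Passing tests therefore demonstrate the internal consistency of
the inference account — tracking, lag reduction by self-initiation,
zero percept in passive sensor loss, attenuated percept in active
movement, and ordered improvement under the two intervention
mechanisms — not quantitative agreement with patient data, of which
none is used.

## Numerical choices

- Log-space weights with log-sum-exp normalization; weight sums are
  checked to 1e-12.
- Systematic resampling guarantees offspring counts within 1 of N·w_i;
  the top of the cumulative weight profile is clamped to exactly 1 to
  guard against floating-point shortfall.
- The posterior sd uses the weighted (biased, 1/N-normalized)
  estimator.
- Degenerate inputs fail loudly: zero assumed sensor noise has no
  density (the exact filter handles that limit), zero-truth metrics are
  rejected where the normalizer vanishes.
- Seeding: each (condition, replicate) derives a 31-bit seed from a
  SHA-256 hash of (master_seed, label, replicate); observation,
  knowledge, and filter streams are independent `SeedSequence` children
  of it. Outputs are byte-reproducible across runs and platforms.

## Experiment suites and their property checks

The four-condition suite checks, on 20-seed means: healthy passive
displacement gain in [0.8, 1.1]; active lag < passive lag (healthy);
passive BVP median zero-motion score < 0.1; active BVP displacement
gain strictly in (0, 1) with the correct direction in ≥ 90% of
replicates. The rehabilitation suite checks strictly increasing
displacement gain (untreated < conventional < conventional+cognitive,
matched seeds) and lower posterior uncertainty under cognitive
training. Sweeps over sensor-noise inflation {1, 3, 10, 30} and prior
sharpening {1, 2, 4, 8} check non-decreasing seed-mean gain (Spearman
sign +1). All thresholds are design choices of this package; the
phenomena themselves are qualitative.

Problem sizes (201 time steps, 5000 particles, 20 replicates, 50,000
particles for oracle comparisons) keep the full study at about half a
minute on one CPU while leaving Monte Carlo error an order of magnitude
below every asserted difference.

## Known limitations

- The knowledge switch S is fixed per condition, never inferred; no
  smoothing, no parameter learning, no adaptation across sessions.
- One degree of freedom (yaw velocity); no position/displacement state.
- The intervention magnitudes are illustrative dose levels, not fitted
  to any rehabilitation outcome data.
- With a near-uninformative likelihood (large inflation) the particle
  filter rarely resamples and its ESS stays near N, so the sd estimate
  inherits the prediction-chain variance; the exact filter should be
  preferred for variance-sensitive analyses in that regime.
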