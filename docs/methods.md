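# Methods

## Coordinate frame and per-trial model

Directions are angles in degrees relative to the reach target, with the
direction that counters the imposed rotation positive. On a perturbed
trial the cursor direction is `x_v = hand − r`. This frame makes the
sensory-prediction error on a free-aiming trial equal `x^i − r` as an
identity (cursor minus aim = implicit state minus rotation), and the
re-aiming performance error coincide with SPE whenever the re-aiming
reference equals the participant's own aim.

Hand localization is inverse-variance cue fusion of the motor prediction
(`σ_u = 5.05°`), proprioception (`σ_p = 11.12°`) and vision. The sensory
uncertainties and the visual intercept `b = 1.853°` are fixed at
error-clamp estimates and treated as paradigm-independent constants; the
visual-uncertainty slope `k` stays free because fixation behavior (and
hence the effective eccentricity cost) differs between paradigms. The
default rates (`A_e = 0.75`, `B_e = 0.513`, `A_i = 0.98`, `B_i = 0.151`,
`k = 0.204`) are one plausible parameter set consistent with published
estimates for this paradigm family; they are the generator defaults, not
fitted claims.

Per-trial regimes:

* **Free aiming** — aim = explicit state; explicit state updated by
  performance error; implicit state by the model-kind's error.
* **Instructed re-aiming** — the explicit state is clamped to the
  instructed direction and its performance-error update is suppressed.
  The PE model's implicit error is scored against the *original* target by
  default (which nullifies PE at re-aiming onset); a per-trial `pe_reaim`
  switch scores it against the re-aiming target instead, the alternative
  performance-error account in which that error is equivalent to SPE. The
  late-re-aiming design (`exp5`) sets the switch in its re-aiming phase,
  which is what makes the PE model predict renewed implicit growth there.
* **No feedback** (exclusion, null, washout, proprioception tests) — both
  states decay by their retention rates with the error term dropped; this
  is the standard state-space treatment of unreinforced trials. We decay
  the explicit state on passive proprioception-test trials too; nothing
  observable depends on that choice in these designs.

Angles are plain reals (no wraparound): all designs stay far from ±180°.
Eccentricity uses the absolute value |x_v − x_u|. The exponential and
power-law visual-uncertainty variants are parameterized as
`b·exp(c·ecc)` and `b + k·ecc^γ`; both reduce to `b` at zero eccentricity,
which pins the zero-rotation limit to the same weights as the linear form.

## Synthetic-data generator

The generator emulates the six designs plus a generic
report-every-trial blocked design (`bond2015`, whose exact trial counts
are not published; we use 8 baseline, 80 reported adaptation trials and a
16-trial exclusion washout). Schedules follow the printed layouts: blocked
35/75/20 with exclusions at adaptation trials 50–65 and proprioception
tests at 15–35 (`exp1`); four 40-trial blocks stepping 15→30→45→60° vs.
160 one-step trials at 60° (`exp2`); 99 signed random rotations
(0, ±4, ±8, ±16, ±32, ±64°, nine each — exactly zero mean) alternating
with 99 no-feedback null trials after a 30-trial interleaved baseline
(`exp3`; the pseudo-random order is a fixed, seed-frozen permutation
shared by all participants, since the original order is not printed); 120
instructed re-aiming trials at a 45° or 90° offset after a 40-trial
baseline (`exp4`; the baseline length is unstated, 40 is our choice); the
60 + 40 + 15-cycle late-re-aiming design with aiming reports at cycles
5/19/33/47, exclusions at 6/20/34/48 and re-aiming-phase exclusions at
1/11/21 (`exp5`; the re-aiming reference is each run's explicit state at
the last aiming report); and the probe design 20/44/20 with a probe every
fourth trial, the first eight adaptation trials unprobed (`exp6`).

Latent states evolve deterministically; Gaussian noise is added only to
executed and reported quantities (motor σ = 4° by default — a typical
baseline reach dispersion, as the source magnitude is unpublished — and
report σ = 2°). Consequences: a condition's mean equals the deterministic
trajectory, the mean's standard error shrinks as 1/√n, and every
extracted measure has an exact latent oracle. Real data differ — noise
feeds back into the learned states, participants differ in parameters,
and aiming is discretized — so passing tests certify the pipeline's
internal consistency and discriminability under these idealized
conditions, not behavioral realism. Multi-target designs are collapsed to
a single target-relative frame (the models contain no generalization
term); proprioception-test passive locations (±5°, ±15°) are bookkeeping
that cancels in the bias average. Movement-time exclusion filters are out
of generator scope; the direction-window filter (−20° to 120°) is
provided for ingesting real tables.

## Fitting

The objective is unweighted SSE of the noise-free model means against the
observed condition means, pooled over conditions fit simultaneously and
over the selected channels: `total` (hand on feedback trials), `implicit`
(hand on aim-at-target no-feedback trials) and `explicit` (reported aim);
per-channel weights are exposed. `clamp_explicit` treats an observed
explicit series as known data, replacing the modeled explicit state.
Optimization is L-BFGS-B within box bounds from seeded Latin-hypercube
multi-starts (20 by default; 3–5 in the bulk recovery/confusion studies,
where the search space is the drawing range), with ftol 1e-8. The rate
ordering A_e < A_i, B_e > B_i is enforced by reparameterization
(A_e = A_i·u, B_i = B_e·v, u,v ∈ [0,1)) when both members of a pair are
free, and by bound restriction otherwise — no penalty terms. Boundary
solutions are flagged, not rejected. The single-trial design optionally
bounds A_i ≥ 0.7.

## Evaluation

R² is computed about the grand mean of the fitted observations; RMSE is
√(SSE/n). AIC and BIC use the Gaussian concentrated log-likelihood,
`n·ln(SSE/n) + 2p` and `n·ln(SSE/n) + p·ln(n)`: the formulas are not
printed in the literature this implements, but this is the standard
choice for comparing least-squares state-space fits on identical data.
Concordance is Lin's coefficient with population (1/n) moments. The
participant bootstrap resamples participants with replacement (the
conventional 5000 resamples by default; tests use far fewer), rebuilds
the condition means and refits from a warm start at the point estimate.

Parameter recovery draws true values uniformly in realistic ranges
bracketing published estimates (k ∈ [0.10, 0.30], A_i ∈ [0.90, 0.995],
B_i ∈ [0.08, 0.25]), simulates group datasets with motor noise, refits
within the same ranges, and reports per-parameter CCC. On the blocked
design the recovered set is (k, A_i, B_i) with the explicit parameters
fixed at their generating values — the implicit pathway is the scientific
target there, and the design's recovery claim concerns those three; the
five-parameter fit remains available through `FitSpec`. The confusion
analysis simulates from each generative model, fits all candidates
(PPE with k free; PE/SPE without), and selects by minimum BIC, breaking
exact ties toward fewer parameters and counting them. Study sizes are
100 recovery simulations and 50 per confusion row, desk-scale choices
that keep each study in the ~1–2 minute range.

## Known limitations

* Fitting targets noise-free model means; there is no likelihood for the
  stochastic generator and no posterior inference.
* Observation-only noise understates parameter uncertainty relative to
  process-noise generators; recovery CCCs are accordingly optimistic
  upper bounds on what identical designs achieve with real data.
* The `bond2015` layout is an emulation, not the original protocol.
* Within-movement kinematics, reaction times, gaze, and generalization
  across targets are out of scope.
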