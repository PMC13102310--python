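# vmradapt

Trial-by-trial error models of visuomotor rotation (VMR) adaptation.

When people reach with a cursor whose direction is rotated relative to
their hand, they adapt through two dissociable processes: **explicit**
learning (deliberate re-aiming away from the target) and **implicit**
learning (subconscious recalibration). What error signal drives the
implicit part is contested. This package implements, as one state-space
framework, the three competing accounts —

* **PE** (performance error): cursor direction minus target direction;
* **SPE** (sensory prediction error): cursor direction minus the
  predicted/aiming direction;
* **PPE** (perceptual prediction error): the *Bayesian perceived hand
  direction* minus the predicted/aiming direction —

together with simulators of the standard VMR experiment designs,
constrained least-squares fitting, and the model-validation machinery
(participant bootstrap, parameter recovery scored by Lin's concordance
correlation coefficient, and BIC confusion matrices). It is aimed at
computational sensorimotor-learning researchers who want a tested,
reusable pipeline for simulating these designs and stress-testing
model-comparison claims.

## The model

All directions are in degrees relative to the target, positive countering
the rotation `r`, so the cursor moves at `x_v = x - r` where
`x = x^e + x^i` is the hand. Perceived hand direction fuses the motor
prediction `x_u` (the aiming direction), the proprioceptive cue
`x_p` (the actual hand), and the visual cue `x_v` by reliability:

    x̂_hand = Σᵢ Wᵢ xᵢ,   Wᵢ = (1/σᵢ²) / Σⱼ (1/σⱼ²),   i,j ∈ {u, p, v}

with fixed σ_u = 5.05°, σ_p = 11.12°, and a visual uncertainty that grows
with the cursor's eccentricity from the aiming direction,
σ_v = k·|x_v − x_u| + b (b = 1.853°; exponential and power-law forms are
also available). Learning is a per-trial state-space recursion:

    x^e_{t+1} = A_e x^e_t − B_e · e_PE          (explicit, all models)
    x^i_{t+1} = A_i x^i_t − B_i · e_model       (implicit)

where `e_model` is `e_PE = x − r` (PE model), `e_SPE = x_v − x_u` (SPE
model), or `e_PPE = x̂_hand − x_u` (PPE model); a two-implicit-state
variant drives a fast component with PE and a slow one with SPE. Because
large rotations make the cursor eccentric and hence visually unreliable,
`e_PPE` is nonmonotone in rotation size — the property that separates the
PPE account from the other two on blocked, stepwise, random single-trial,
and instructed re-aiming designs.

## Worked example

```sh
python examples/learning_curves.py
```

simulates 15-participant groups on the blocked design (35 baseline, 75
adaptation, 20 washout trials; exclusion and proprioception-test trials
embedded) at four rotation sizes under the PPE model and prints:

```
 size  total_late  implicit  explicit  prop_bias
  15°      14.33°    12.21°     2.12°    -13.19°
  30°      27.85°    22.23°     5.62°    -21.07°
  60°      47.84°    20.59°    27.25°    -17.13°
  90°      65.64°    14.38°    51.26°    -12.40°
```

Total learning scales with rotation size, but the implicit component
(read out from aim-at-target exclusion trials) is *concave* — it peaks at
intermediate sizes and declines at 90° — and the proprioceptive bias (the
perceived-minus-actual error of a passive hand-localization judgment,
negative = toward the perturbation) mirrors it. Both follow from the same
misperceived hand position; PE- or SPE-driven implicit learning would
instead scale linearly with size. The other scripts in `examples/` cover
single-trial size dependency, model fitting and BIC comparison,
instructed re-aiming, and a scaled-down recovery/confusion study. A thin
CLI mirrors these steps (`vmradapt simulate|fit|compare|predict|recover|confusion|clean`).

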