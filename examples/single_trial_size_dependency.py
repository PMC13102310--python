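"""Single-trial learning as a function of perturbation size.

Simulates the trial-by-trial random-perturbation design (signed rotations
of 0, 4, 8, 16, 32, 64 degrees, each flanked by no-feedback null trials)
under the PPE model and under the PE model, and tabulates the pooled
single-trial learning per absolute size.  The PE (and SPE) response is
linear in size; the PPE response rises and then falls because large cursor
eccentricities carry high visual uncertainty and are discounted in the
perceived hand position.
"""

from vmradapt import (
    ModelParams,
    NoiseSpec,
    simulate_group,
    single_trial_learning,
    size_dependency_regression,
)

noise = NoiseSpec(sigma_motor=4.0, sigma_report=0.0)
tables = {}
for kind in ("PPE", "PE"):
    params = ModelParams(model_kind=kind, Be=0.0, Ae=0.0)  # explicit suppressed
    ds = simulate_group("exp3", None, params, noise, n_participants=18, seed=7)
    tables[kind] = single_trial_learning(ds)

print(f"{'|r|':>4} {'PPE model':>10} {'PE model':>10}")
for r in tables["PPE"].index:
    print(f"{r:>3.0f}° {tables['PPE'].loc[r, 'learning']:>9.2f}° "
          f"{tables['PE'].loc[r, 'learning']:>9.2f}°")

reg = size_dependency_regression(tables["PE"].loc[tables["PE"].index > 0])
print(f"\nPE model OLS: learning = {reg.intercept:.2f} + {reg.slope:.3f}*size "
      f"(R² = {reg.r2:.3f}) — a straight line through the origin.")
print("The PPE column instead peaks near 16–32° and declines at 64°.")
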