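"""Implicit drift under instructed re-aiming, for 45° vs 90° offsets.

Participants aim at a designated neighboring target so the rotated cursor
lands on the original target; their hand nonetheless drifts away from the
re-aiming target.  The PPE model predicts *less* drift for the larger
offset (the cursor is more eccentric, hence visually less reliable and
discounted), while the SPE account — and the PE account scored against the
re-aiming target — predict more.
"""

import numpy as np

from vmradapt import ModelParams, build_schedule, run_model

print(f"{'model':>10} {'drift@45°':>10} {'drift@90°':>10}")
for kind, pe_reaim in (("PPE", False), ("SPE", False), ("PE", True)):
    drifts = []
    for offset in (45, 90):
        s = build_schedule("exp4", offset, pe_reaim=pe_reaim)
        traj = run_model(s, ModelParams(model_kind=kind))
        instructed = np.flatnonzero(s.instructed)
        drifts.append(traj.x_i[instructed[-10:]].mean())
    label = kind if not pe_reaim else "PE(reaim)"
    print(f"{label:>10} {drifts[0]:>9.2f}° {drifts[1]:>9.2f}°")

print(
    "\nOnly the PPE row decreases from 45° to 90°, matching the observed\n"
    "smaller drift at large offsets; the error-scaling accounts grow with\n"
    "the offset instead."
)
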