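"""Simulate blocked visuomotor-rotation adaptation and read out the
standard learning measures.

Runs a 15-participant group through the four-size blocked design under the
perceptual-prediction-error (PPE) model with realistic motor noise, and
prints late implicit learning and proprioceptive bias per perturbation
size.  The implicit asymptote is concave in perturbation size — it stops
growing (and shrinks) for large rotations — which is the PPE model's
signature; the proprioceptive bias mirrors it with the opposite sign.
"""

from vmradapt import ModelParams, NoiseSpec, extract_measures, simulate_group

params = ModelParams(model_kind="PPE")  # k=0.204, Bi=0.151, Be=0.513, ...
noise = NoiseSpec(sigma_motor=4.0, sigma_report=2.0)

print(f"{'size':>5} {'total_late':>11} {'implicit':>9} {'explicit':>9} {'prop_bias':>10}")
for size in (15, 30, 60, 90):
    ds = simulate_group("exp1", size, params, noise, n_participants=15, seed=42)
    m = extract_measures(ds, require=("implicit_late", "prop_bias"))
    total_late = m.implicit_late + m.explicit_late
    print(f"{size:>4}° {total_late:>10.2f}° {m.implicit_late:>8.2f}° "
          f"{m.explicit_late:>8.2f}° {m.prop_bias:>9.2f}°")

print(
    "\nImplicit learning peaks at intermediate sizes instead of scaling up;\n"
    "the negative proprioceptive bias (perceived hand pulled toward the\n"
    "rotated cursor) tracks it, as both stem from the same misperception."
)
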