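"""Deterministic trial-by-trial trajectory engine.

Runs a model (PPE / PE / SPE / two-implicit-state) over a full schedule in
one tight loop.  This is the single path used by both the simulator and the
fitting objective; the pure per-trial operations in :mod:`vmradapt.core`
are the reference implementation against which this loop is tested.

State conventions per trial ``t``:

* free-aiming movement trials: aim = explicit state, hand = x_e + x_i;
* instructed re-aiming trials: aim = the instructed reference, the explicit
  state is clamped to it (no performance-error update);
* exclusion / no-feedback-null / washout trials: the participant aims
  straight at the target with no cursor, hand = x_i, and both states decay
  by their retention rates;
* proprioception-test trials: passive, no reach, retention-only decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelKind, ModelParams, UncertaintyForm
from .schedules import PerturbationSchedule

__all__ = ["Trajectory", "run_model"]


@dataclass
class Trajectory:
    """Noise-free model trajectory over a schedule (arrays per trial).

    ``x_e``/``x_i`` are the states *expressed* on each trial (after any
    clamping), ``hand`` the executed hand direction (NaN on passive trials),
    and the error arrays are NaN where no feedback was available.
    """

    x_e: np.ndarray
    x_i: np.ndarray
    hand: np.ndarray
    e_pe: np.ndarray
    e_spe: np.ndarray
    e_pe_reaim: np.ndarray
    e_ppe: np.ndarray
    sigma_v: np.ndarray
    perceived: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.hand


def _sigma_v(params: ModelParams, ecc: float) -> float:
    if params.uncertainty_form is UncertaintyForm.LINEAR:
        return params.k * ecc + params.b
    if params.uncertainty_form is UncertaintyForm.EXPONENTIAL:
        return params.b * math.exp(params.c * ecc)
    return params.b + params.k * ecc**params.gamma


def run_model(
    schedule: PerturbationSchedule,
    params: ModelParams,
    clamp_explicit: np.ndarray | None = None,
) -> Trajectory:
    """Run the deterministic recursion of ``params`` over ``schedule``.

    ``clamp_explicit`` treats explicit learning as known data: an array of
    per-trial aiming directions (NaN = hold the previous value) replaces the
    modeled explicit state, whose own update is disabled.
    """
    n = len(schedule)
    rot = schedule.rotation
    ttype = schedule.trial_type
    instructed = schedule.instructed
    aim_ref = schedule.aim_ref
    pe_reaim = schedule.pe_reaim
    has_fb = schedule.has_feedback
    aims_target = schedule.aims_at_target
    moves = schedule.moves

    kind = ModelKind(params.model_kind)
    two_state = kind is ModelKind.TWO_STATE
    wu = params.sigma_u**-2
    wp = params.sigma_p**-2

    out = Trajectory(*(np.full(n, np.nan) for _ in range(9)))

    xe = 0.0
    xi = 0.0
    xf = 0.0  # two-state components
    xs = 0.0
    frozen_ref = math.nan     # re-aiming reference frozen from the own aim
    last_report_xe = math.nan  # explicit state at the last aiming report

    for t in range(n):
        clamped = clamp_explicit is not None and math.isfinite(clamp_explicit[t])
        if clamped:
            xe = clamp_explicit[t]
        if instructed[t]:
            ref = aim_ref[t]
            if math.isnan(ref):
                if math.isnan(frozen_ref):
                    frozen_ref = last_report_xe if math.isfinite(last_report_xe) else xe
                ref = frozen_ref
            xe_expr = ref  # the aim is clamped to the instructed direction
        else:
            ref = math.nan
            xe_expr = xe

        out.x_e[t] = xe_expr
        out.x_i[t] = xi

        if not moves[t]:  # passive proprioception test: decay only
            if not clamped:
                xe = params.Ae * xe
            if two_state:
                xf *= params.Af
                xs *= params.As
                xi = xf + xs
            else:
                xi = params.Ai * xi
            continue

        if aims_target[t] or not has_fb[t]:
            # aim straight at the target, no cursor: hand reads out x_i
            out.hand[t] = xi
            if not clamped:
                xe = params.Ae * xe
            if two_state:
                xf *= params.Af
                xs *= params.As
                xi = xf + xs
            else:
                xi = params.Ai * xi
            continue

        # movement trial with cursor feedback
        r = rot[t]
        hand = xe_expr + xi
        x_u = xe_expr
        x_v = hand - r
        e_pe = hand - r
        e_spe = x_v - x_u
        e_reaim = x_v - (ref if instructed[t] else x_u)
        ecc = abs(x_v - x_u)
        sv = _sigma_v(params, ecc)
        wv = sv**-2
        tot = wu + wp + wv
        phat = (wu * x_u + wp * hand + wv * x_v) / tot
        e_ppe = phat - x_u

        out.hand[t] = hand
        out.e_pe[t] = e_pe
        out.e_spe[t] = e_spe
        out.e_pe_reaim[t] = e_reaim
        out.e_ppe[t] = e_ppe
        out.sigma_v[t] = sv
        out.perceived[t] = phat

        if ttype[t] == "aiming_report":
            last_report_xe = xe_expr

        # implicit update
        if two_state:
            xf = params.Af * xf - params.Bf * e_pe
            xs = params.As * xs - params.Bs * e_spe
            xi = xf + xs
        else:
            if kind is ModelKind.PPE:
                err = e_ppe
            elif kind is ModelKind.SPE:
                err = e_spe
            else:  # PE
                err = e_reaim if pe_reaim[t] else e_pe
            xi = params.Ai * xi - params.Bi * err

        # explicit update: clamped to the instruction while re-aiming is
        # instructed, otherwise driven by performance error (unless the
        # explicit series is supplied as data)
        if instructed[t]:
            if not clamped:
                xe = ref
        elif not clamped:
            xe = params.Ae * xe - params.Be * e_pe

    return out
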