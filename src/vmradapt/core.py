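"""Deterministic mathematical core: cue integration, uncertainty functions,
trial errors and one-trial state updates for all model variants.

These are pure functions over scalars; the trajectory engine in
:mod:`vmradapt.engine` composes the same arithmetic in a tight loop, and the
two routes are held equal by tests.
"""

from __future__ import annotations

import math

from .params import (
    CueWeights,
    LearningState,
    ModelKind,
    ModelParams,
    SensoryCues,
    TrialErrors,
    UncertaintyForm,
)

__all__ = [
    "visual_uncertainty",
    "cue_weights",
    "perceived_hand",
    "trial_errors",
    "step_state",
    "two_state_implicit_step",
    "predicted_proprioceptive_bias",
]


def visual_uncertainty(
    k: float,
    b: float,
    eccentricity: float,
    form: UncertaintyForm | str = UncertaintyForm.LINEAR,
    *,
    c: float = 0.05,
    gamma: float = 1.0,
) -> float:
    """Visual uncertainty (deg) of the cursor at a given eccentricity.

    The cursor's angular separation from the fixation/aiming direction
    degrades its directional reliability.  The linear form is
    ``sigma_v = k*ecc + b``; the exponential form ``b*exp(c*ecc)`` and
    power-law form ``b + k*ecc**gamma`` are monotone alternatives that
    coincide with ``b`` at zero eccentricity.
    """
    if eccentricity < 0:
        raise ValueError("eccentricity must be >= 0")
    if b <= 0:
        raise ValueError("b must be strictly positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    form = UncertaintyForm(form)
    if form is UncertaintyForm.LINEAR:
        return k * eccentricity + b
    if form is UncertaintyForm.EXPONENTIAL:
        return b * math.exp(c * eccentricity)
    return b + k * eccentricity**gamma


def cue_weights(sigma_u: float, sigma_p: float, sigma_v: float) -> CueWeights:
    """Inverse-variance reliability weights of the three cues.

    ``W_i = (1/sigma_i^2) / sum_j (1/sigma_j^2)`` for i in {u, p, v}.
    """
    for name, s in (("sigma_u", sigma_u), ("sigma_p", sigma_p), ("sigma_v", sigma_v)):
        if s <= 0:
            raise ValueError(f"{name} must be strictly positive")
    wu = sigma_u**-2
    wp = sigma_p**-2
    wv = sigma_v**-2
    total = wu + wp + wv
    return CueWeights(wu / total, wp / total, wv / total)


def perceived_hand(cues: SensoryCues, weights: CueWeights) -> float:
    """Bayesian estimate of hand direction: reliability-weighted cue fusion."""
    return weights.W_u * cues.x_u + weights.W_p * cues.x_p + weights.W_v * cues.x_v


def trial_errors(
    state: LearningState,
    r: float,
    params: ModelParams,
    regime: str = "free_aiming",
    aim_reference: float | None = None,
) -> TrialErrors:
    """Errors experienced on one trial of the given regime.

    In ``free_aiming`` the prediction/aim is the explicit state; in
    ``instructed_reaiming`` it is ``aim_reference`` (the instructed target)
    and the hand is ``aim_reference + x_i``.  In ``no_feedback`` all errors
    are absent and no update occurs.
    """
    if regime == "no_feedback":
        return TrialErrors(None, None, None, None, None, None)
    if regime == "instructed_reaiming":
        if aim_reference is None:
            raise ValueError("instructed_reaiming requires aim_reference")
        x_u = aim_reference
        hand = aim_reference + state.x_i
    elif regime == "free_aiming":
        x_u = state.x_e
        hand = state.x
        if aim_reference is None:
            aim_reference = x_u
    else:
        raise ValueError(f"unknown regime {regime!r}")

    x_v = hand - r  # cursor = hand rotated by the perturbation
    e_pe = hand - r  # cursor deviation from the original target (at 0)
    e_spe = x_v - x_u
    e_pe_reaim = x_v - aim_reference
    ecc = abs(x_v - x_u)
    sv = visual_uncertainty(
        params.k, params.b, ecc, params.uncertainty_form, c=params.c, gamma=params.gamma
    )
    w = cue_weights(params.sigma_u, params.sigma_p, sv)
    phat = perceived_hand(SensoryCues(x_u, hand, x_v, sv), w)
    e_ppe = phat - x_u
    return TrialErrors(e_pe, e_pe_reaim, e_spe, e_ppe, sv, phat)


def _implicit_error(errors: TrialErrors, kind: ModelKind, pe_reaim: bool) -> float:
    if kind is ModelKind.PPE:
        return errors.e_ppe
    if kind is ModelKind.PE:
        return errors.e_pe_reaim if pe_reaim else errors.e_pe
    if kind is ModelKind.SPE:
        return errors.e_spe
    raise ValueError(f"unknown model kind {kind!r}")


def step_state(
    state: LearningState,
    errors: TrialErrors,
    params: ModelParams,
    regime: str = "free_aiming",
    pe_reaim: bool = False,
) -> LearningState:
    """One-trial state-space update.

    Explicit: ``x_e' = Ae*x_e - Be*e_PE`` (suppressed when re-aiming is
    instructed, since the aim is clamped to the instructed direction).
    Implicit: ``x_i' = Ai*x_i - Bi*e``, with the error ``e`` selected by the
    model kind (PPE/PE/SPE).  On no-feedback trials both states decay by
    their retention rates with the error term dropped.  ``pe_reaim`` makes
    the PE model's implicit update use the re-aiming performance error
    (cursor minus re-aiming target) instead of the original-target error.
    """
    kind = ModelKind(params.model_kind)
    new = state.copy()
    if errors.e_pe is None:  # no feedback: retention-only decay
        new.x_e = params.Ae * state.x_e
        if kind is ModelKind.TWO_STATE:
            new.x_i_fast = params.Af * state.x_i_fast
            new.x_i_slow = params.As * state.x_i_slow
            new.x_i = new.x_i_fast + new.x_i_slow
        else:
            new.x_i = params.Ai * state.x_i
        return new

    if kind is ModelKind.TWO_STATE:
        return two_state_implicit_step(state, errors.e_pe, errors.e_spe, params,
                                       regime=regime)

    err = _implicit_error(errors, kind, pe_reaim)
    new.x_i = params.Ai * state.x_i - params.Bi * err
    if regime == "instructed_reaiming":
        new.x_e = state.x_e  # aim clamped; no performance-error update
    else:
        new.x_e = params.Ae * state.x_e - params.Be * errors.e_pe
    return new


def two_state_implicit_step(
    state: LearningState,
    e_pe: float,
    e_spe: float,
    params: ModelParams,
    regime: str = "free_aiming",
) -> LearningState:
    """Two-implicit-state update: fast component driven by PE, slow by SPE.

    ``x_f' = Af*x_f - Bf*e_PE`` and ``x_s' = As*x_s - Bs*e_SPE``; the
    implicit state is their sum.  Conventionally the fast component forgets
    faster and learns faster (Af < As, Bf > Bs).
    """
    for n in ("Af", "Bf", "As", "Bs"):
        if getattr(params, n) is None:
            raise ValueError(f"two-state update requires parameter {n}")
    new = state.copy()
    new.x_i_fast = params.Af * state.x_i_fast - params.Bf * e_pe
    new.x_i_slow = params.As * state.x_i_slow - params.Bs * e_spe
    new.x_i = new.x_i_fast + new.x_i_slow
    if regime == "instructed_reaiming":
        new.x_e = state.x_e
    else:
        new.x_e = params.Ae * state.x_e - params.Be * e_pe
    return new


def predicted_proprioceptive_bias(
    state: LearningState, r: float, params: ModelParams
) -> float:
    """Model-predicted bias of a passive hand-localization judgment.

    The judgment following an adaptation trial inherits the misperception of
    the hand experienced on that trial: perceived hand minus actual hand.
    In the countering-positive frame this is negative, i.e. toward the
    visual perturbation and opposite to the direction of learning.
    """
    errs = trial_errors(state, r, params, regime="free_aiming")
    return errs.perceived_hand - state.x
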