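"""Domain types for the adaptation models.

All directions are angles in degrees, measured relative to the original
reach target, with the direction that *counters* the imposed rotation taken
as positive.  Under this convention the cursor direction on a perturbed
trial is ``hand - r`` where ``r`` is the rotation size, and full adaptation
corresponds to ``hand -> r`` (cursor back on the target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum


class ModelKind(str, Enum):
    """Which error signal drives the implicit state update."""

    PPE = "PPE"          # perceptual prediction error (perceived hand - aim)
    PE = "PE"            # performance error (cursor - target)
    SPE = "SPE"          # sensory prediction error (cursor - aim)
    TWO_STATE = "TWO_STATE"  # fast state on PE, slow state on SPE


class UncertaintyForm(str, Enum):
    """Functional form of visual uncertainty vs. eccentricity."""

    LINEAR = "linear"          # sigma_v = k*ecc + b
    EXPONENTIAL = "exponential"  # sigma_v = b*exp(c*ecc)
    POWER_LAW = "power_law"    # sigma_v = b + k*ecc**gamma


# Fixed sensory-uncertainty parameters, taken from error-clamp estimates:
# they describe paradigm-independent properties of the sensorimotor system.
SIGMA_U_DEFAULT = 5.05   # motor-prediction cue uncertainty (deg)
SIGMA_P_DEFAULT = 11.12  # proprioceptive cue uncertainty (deg)
B_DEFAULT = 1.853        # visual uncertainty at zero eccentricity (deg)


@dataclass
class ModelParams:
    """Retention/learning rates and sensory-uncertainty parameters.

    ``Ae``/``Be`` govern the explicit (deliberate re-aiming) state,
    ``Ai``/``Bi`` the implicit state.  ``k`` and ``b`` are the slope and
    intercept of visual uncertainty as a function of the cursor's
    eccentricity from the aiming/fixation direction.  ``Af/Bf/As/Bs``
    parameterize the fast (PE-driven) and slow (SPE-driven) components of
    the two-implicit-state variant.
    """

    Ae: float = 0.75
    Be: float = 0.513
    Ai: float = 0.98
    Bi: float = 0.151
    k: float = 0.204
    b: float = B_DEFAULT
    sigma_u: float = SIGMA_U_DEFAULT
    sigma_p: float = SIGMA_P_DEFAULT
    model_kind: ModelKind = ModelKind.PPE
    uncertainty_form: UncertaintyForm = UncertaintyForm.LINEAR
    # shape parameters for the non-linear uncertainty forms
    c: float = 0.05      # exponential rate (1/deg)
    gamma: float = 1.0   # power-law exponent
    # two-implicit-state fields (fast on PE, slow on SPE)
    Af: float | None = None
    Bf: float | None = None
    As: float | None = None
    Bs: float | None = None

    def __post_init__(self) -> None:
        self.model_kind = ModelKind(self.model_kind)
        self.uncertainty_form = UncertaintyForm(self.uncertainty_form)
        for name in ("Ae", "Be", "Ai", "Bi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.k < 0:
            raise ValueError(f"k={self.k} must be >= 0")
        for name in ("b", "sigma_u", "sigma_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # Pathway ordering: explicit retains less and learns faster than
        # implicit.  Only meaningful when both pathways are active.
        if self.Be > 0 and self.Bi > 0:
            if self.Ae >= self.Ai:
                raise ValueError(
                    f"Ae={self.Ae} must be < Ai={self.Ai} when both pathways are active"
                )
            if self.Be <= self.Bi:
                raise ValueError(
                    f"Be={self.Be} must be > Bi={self.Bi} when both pathways are active"
                )
        if self.model_kind is ModelKind.TWO_STATE:
            missing = [n for n in ("Af", "Bf", "As", "Bs") if getattr(self, n) is None]
            if missing:
                raise ValueError(f"TWO_STATE model requires {missing}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SensoryCues:
    """Per-trial sensory cues entering hand localization (degrees)."""

    x_u: float  # predicted / aiming direction
    x_p: float  # proprioceptive cue = actual hand direction
    x_v: float  # visual cursor direction
    sigma_v: float  # visual uncertainty for this trial

    def __post_init__(self) -> None:
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be strictly positive")


@dataclass(frozen=True)
class CueWeights:
    """Reliability (inverse-variance) weights; sum to one."""

    W_u: float
    W_p: float
    W_v: float

    def __post_init__(self) -> None:
        s = self.W_u + self.W_p + self.W_v
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {s}")
        for w in (self.W_u, self.W_p, self.W_v):
            if not -1e-12 <= w <= 1 + 1e-12:
                raise ValueError("weights must lie in [0, 1]")


@dataclass
class LearningState:
    """Explicit and implicit adaptation states (degrees)."""

    x_e: float = 0.0
    x_i: float = 0.0
    x_i_fast: float = 0.0
    x_i_slow: float = 0.0

    @property
    def x(self) -> float:
        """Total adaptation: hand direction on a free-aiming trial."""
        return self.x_e + self.x_i

    def copy(self) -> "LearningState":
        return LearningState(self.x_e, self.x_i, self.x_i_fast, self.x_i_slow)


@dataclass(frozen=True)
class TrialErrors:
    """Errors experienced on one trial (degrees); None when feedback absent."""

    e_pe: float | None
    e_pe_reaim: float | None
    e_spe: float | None
    e_ppe: float | None
    sigma_v: float | None
    perceived_hand: float | None = None
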