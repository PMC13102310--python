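"""Constrained least-squares fitting of the adaptation models to
condition-mean learning series.

The objective simulates the chosen model noise-free over each condition's
schedule and sums squared deviations from the observed mean series over the
selected data channels; conditions are fit simultaneously with shared
parameters.  Rate-ordering constraints (explicit retains less and learns
faster than implicit: Ae < Ai, Be > Bi) are enforced by reparameterization
when both members of a pair are free, and by bound restriction when only
one is.  Optimization is bounded local search (L-BFGS-B) from seeded
Latin-hypercube multi-starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .engine import run_model
from .params import ModelKind, ModelParams
from .schedules import PerturbationSchedule

__all__ = [
    "FitSpec",
    "FitResult",
    "ConditionData",
    "objective_sse",
    "fit_model",
    "predict_heldout",
    "fit_data_from_datasets",
]

_DEFAULT_BOUNDS = {
    "k": (0.0, 1.0),
    "Ai": (0.0, 1.0),
    "Bi": (1e-6, 1.0),
    "Ae": (0.0, 1.0),
    "Be": (1e-6, 1.0),
    "c": (0.0, 0.5),
    "gamma": (0.25, 3.0),
    "Af": (0.0, 1.0),
    "Bf": (1e-6, 1.0),
    "As": (0.0, 1.0),
    "Bs": (1e-6, 1.0),
}

_EPS = 1e-6


@dataclass
class ConditionData:
    """One condition's schedule and observed mean series.

    ``channels`` maps channel name (``total`` / ``implicit`` / ``explicit``)
    to a pair of arrays: 0-based trial indices into the schedule, and the
    observed mean values at those trials.  ``clamp_explicit`` optionally
    carries a per-trial observed aiming series (NaN = hold previous) that
    replaces the modeled explicit state.
    """

    schedule: PerturbationSchedule
    channels: dict
    clamp_explicit: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.schedule)
        for name, (idx, vals) in self.channels.items():
            idx = np.asarray(idx, dtype=int)
            vals = np.asarray(vals, dtype=float)
            if len(idx) != len(vals):
                raise ValueError(f"channel {name!r}: index/value length mismatch")
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"channel {name!r}: trial index outside schedule")
            self.channels[name] = (idx, vals)


@dataclass
class FitSpec:
    """What to fit and how.

    ``free`` lists the parameter names to estimate; everything else is taken
    from ``base`` at fit time (sensory uncertainties default to their fixed
    error-clamp values).  ``channels`` selects which observed series enter
    the objective.  ``ai_lower`` optionally raises the implicit-retention
    lower bound (used for the single-trial random design).
    """

    model_kind: ModelKind | str = ModelKind.PPE
    free: tuple = ("k", "Ai", "Bi")
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    channels: tuple = ("total", "implicit")
    channel_weights: dict = field(default_factory=dict)
    clamp_explicit: bool = False
    constrain_rates: bool = True
    ai_lower: float | None = None
    multi_start: int = 20
    seed: int = 0
    tol: float = 1e-8
    maxiter: int = 500

    def __post_init__(self) -> None:
        self.model_kind = ModelKind(self.model_kind)
        self.free = tuple(self.free)
        valid = set(_DEFAULT_BOUNDS)
        bad = set(self.free) - valid
        if bad:
            raise ValueError(f"unknown free parameters {sorted(bad)}")


@dataclass
class FitResult:
    """Best-of-multi-start parameter estimates with diagnostics."""

    params: ModelParams
    free: dict
    sse: float
    n: int
    p: int
    residuals: dict
    success: bool
    on_boundary: bool
    n_starts: int
    seed: int
    spec: FitSpec


class _ParamSpace:
    """Maps the optimizer vector to a valid ``ModelParams``.

    When both members of a constrained pair are free the second is expressed
    as a fraction of the first (Ae = Ai*u, Bi = Be*v with u, v in (0, 1)),
    so box bounds imply the ordering constraints.
    """

    def __init__(self, spec: FitSpec, base: ModelParams):
        self.spec = spec
        self.base = base
        self.names: list[str] = []
        self.bounds: list[tuple[float, float]] = []
        free = set(spec.free)
        self.couple_A = spec.constrain_rates and {"Ae", "Ai"} <= free
        self.couple_B = spec.constrain_rates and {"Be", "Bi"} <= free
        for name in spec.free:
            lo, hi = spec.bounds.get(name, _DEFAULT_BOUNDS[name])
            if name == "Ai" and spec.ai_lower is not None:
                lo = max(lo, spec.ai_lower)
            if spec.constrain_rates:
                # restrict against the fixed counterpart when only one is free
                if name == "Ae" and not self.couple_A and base.Bi > 0:
                    hi = min(hi, self._fixed("Ai") - _EPS)
                if name == "Ai" and not self.couple_A and base.Be > 0:
                    lo = max(lo, self._fixed("Ae") + _EPS)
                if name == "Bi" and not self.couple_B and self._fixed("Be") > 0:
                    hi = min(hi, self._fixed("Be") - _EPS)
                if name == "Be" and not self.couple_B and base.Bi > 0:
                    lo = max(lo, self._fixed("Bi") + _EPS)
            if name == "Ae" and self.couple_A:
                self.names.append("Ae_frac")
                self.bounds.append((0.0, 1.0 - _EPS))
            elif name == "Bi" and self.couple_B:
                self.names.append("Bi_frac")
                self.bounds.append((0.0, 1.0 - _EPS))
            else:
                self.names.append(name)
                self.bounds.append((lo, hi))

    def _fixed(self, name: str) -> float:
        return self.spec.fixed.get(name, getattr(self.base, name))

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_params(self, theta: np.ndarray) -> ModelParams:
        values = dict(self.spec.fixed)
        raw = dict(zip(self.names, theta))
        for name, v in raw.items():
            if name not in ("Ae_frac", "Bi_frac"):
                values[name] = float(v)
        if self.couple_A:
            values["Ae"] = float(raw["Ae_frac"]) * values["Ai"]
        if self.couple_B:
            values["Bi"] = float(raw["Bi_frac"]) * values["Be"]
        values["model_kind"] = self.spec.model_kind
        return replace(self.base, **values)

    def free_values(self, params: ModelParams) -> dict:
        return {name: getattr(params, name) for name in self.spec.free}

    def from_params(self, params: ModelParams) -> np.ndarray:
        """Inverse map: a valid parameter set to an optimizer vector."""
        theta = []
        for name in self.names:
            if name == "Ae_frac":
                theta.append(params.Ae / max(params.Ai, _EPS))
            elif name == "Bi_frac":
                theta.append(params.Bi / max(params.Be, _EPS))
            else:
                theta.append(getattr(params, name))
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(np.asarray(theta, dtype=float), lo, hi)


def _predict_channels(params: ModelParams, cond: ConditionData, spec: FitSpec) -> dict:
    clamp = cond.clamp_explicit if spec.clamp_explicit else None
    traj = run_model(cond.schedule, params, clamp_explicit=clamp)
    preds = {}
    for name, (idx, _) in cond.channels.items():
        if name not in spec.channels:
            continue
        if name == "explicit":
            preds[name] = traj.x_e[idx]
        else:  # total and implicit are both executed hand directions
            preds[name] = traj.hand[idx]
    return preds


def objective_sse(params: ModelParams, data: list[ConditionData], spec: FitSpec) -> float:
    """Pooled sum of squared residuals of the model means over all
    conditions and selected channels."""
    sse = 0.0
    for cond in data:
        preds = _predict_channels(params, cond, spec)
        for name, pred in preds.items():
            _, obs = cond.channels[name]
            w = spec.channel_weights.get(name, 1.0)
            resid = obs - pred
            sse += w * float(np.dot(resid, resid))
    return sse


def _n_points(data: list[ConditionData], spec: FitSpec) -> int:
    return sum(
        len(cond.channels[name][0])
        for cond in data
        for name in cond.channels
        if name in spec.channels
    )


def fit_model(
    data: list[ConditionData] | ConditionData,
    spec: FitSpec,
    base: ModelParams | None = None,
    extra_starts: list[ModelParams] | None = None,
) -> FitResult:
    """Best of multi-start bounded local minimization of the pooled SSE.

    ``base`` supplies the fixed parameter values (defaults to the package
    defaults with the spec's model kind).  ``extra_starts`` adds parameter
    sets to the start list, e.g. a nested model's optimum.  Deterministic
    given ``spec.seed``.  Non-convergence on all starts is flagged on the
    result rather than raised.
    """
    if isinstance(data, ConditionData):
        data = [data]
    if base is None:
        base = ModelParams(model_kind=spec.model_kind)
    missing = [
        name
        for cond in data
        for name in spec.channels
        if name not in cond.channels
    ]
    if missing:
        raise ValueError(f"requested channels missing from data: {sorted(set(missing))}")
    space = _ParamSpace(spec, base)
    lo = np.array([b[0] for b in space.bounds])
    hi = np.array([b[1] for b in space.bounds])

    n_lhs = max(spec.multi_start, 1)
    sampler = qmc.LatinHypercube(d=space.dim, seed=spec.seed)
    starts = [lo + (hi - lo) * row for row in sampler.random(n_lhs)]
    starts.append((lo + hi) / 2.0)
    for p0 in extra_starts or []:
        starts.append(space.from_params(p0))

    def fun(theta: np.ndarray) -> float:
        return objective_sse(space.to_params(theta), data, spec)

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": spec.tol, "gtol": 1e-10, "maxiter": spec.maxiter},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res

    params = space.to_params(best.x)
    n = _n_points(data, spec)
    p = space.dim
    residuals = {}
    for i, cond in enumerate(data):
        preds = _predict_channels(params, cond, spec)
        for name, pred in preds.items():
            residuals[f"cond{i}:{name}"] = cond.channels[name][1] - pred
    atol = 1e-9 + 1e-6 * (hi - lo)
    on_boundary = bool(np.any(best.x <= lo + atol) or np.any(best.x >= hi - atol))
    return FitResult(
        params=params,
        free=space.free_values(params),
        sse=float(best.fun),
        n=n,
        p=p,
        residuals=residuals,
        success=any_success,
        on_boundary=on_boundary,
        n_starts=len(starts),
        seed=spec.seed,
        spec=spec,
    )


def predict_heldout(
    fit: FitResult,
    schedule: PerturbationSchedule,
    clamp_explicit: np.ndarray | None = None,
    params_override: dict | None = None,
) -> dict:
    """Noise-free model series on a (possibly new) schedule from a fit.

    Returns the full per-trial ``total`` (hand), ``implicit`` and
    ``explicit`` model series plus the error trajectories.
    ``params_override`` substitutes individual parameters (e.g. a
    condition-specific visual-uncertainty slope) before predicting.
    """
    params = fit.params if not params_override else replace(fit.params, **params_override)
    traj = run_model(schedule, params, clamp_explicit=clamp_explicit)
    return {
        "total": traj.hand,
        "implicit": traj.x_i,
        "explicit": traj.x_e,
        "e_ppe": traj.e_ppe,
        "e_pe": traj.e_pe,
        "e_spe": traj.e_spe,
        "e_pe_reaim": traj.e_pe_reaim,
    }


def fit_data_from_datasets(datasets, channels=("total", "implicit"),
                           participants=None) -> list[ConditionData]:
    """Build fit input from simulated datasets (one per condition)."""
    from .simulate import condition_means

    out = []
    for ds in datasets if isinstance(datasets, (list, tuple)) else [datasets]:
        means = condition_means(ds, participants=participants)
        chans = {k: v for k, v in means.items() if k in channels}
        clamp = None
        if "explicit" in means:
            idx, vals = means["explicit"]
            clamp = np.full(len(ds.schedule), np.nan)
            clamp[idx] = vals
        out.append(ConditionData(ds.schedule, chans, clamp_explicit=clamp))
    return out
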