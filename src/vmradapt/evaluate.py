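"""Model comparison and validation statistics.

Goodness of fit uses the Gaussian concentrated log-likelihood, so the
information criteria are ``AIC = n*ln(SSE/n) + 2p`` and
``BIC = n*ln(SSE/n) + p*ln(n)``.  Parameter-recovery agreement is Lin's
concordance correlation coefficient with population (1/n) moments.  Model
identification is by minimum BIC over candidate fits, tabulated as a
confusion matrix over generative models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .fitting import (
    ConditionData,
    FitResult,
    FitSpec,
    fit_data_from_datasets,
    fit_model,
    objective_sse,
)
from .params import ModelKind, ModelParams
from .simulate import NoiseSpec, condition_means, simulate_group

__all__ = [
    "GoodnessReport",
    "goodness",
    "concordance",
    "bootstrap_fits",
    "parameter_recovery",
    "confusion",
    "size_dependency_regression",
    "RecoveryReport",
    "ConfusionMatrix",
    "BootstrapResult",
    "RegressionResult",
]


@dataclass(frozen=True)
class GoodnessReport:
    R2: float  # 1 - SSE/SST; may be negative, NaN when SST = 0
    RMSE: float
    AIC: float
    BIC: float
    n: int
    p: int


def goodness(fit: FitResult, data: list[ConditionData] | ConditionData | None = None) -> GoodnessReport:
    """Goodness-of-fit metrics of a least-squares fit.

    R-squared is computed about the grand mean of all fitted observations;
    when the observations are constant it is undefined and reported as NaN.
    """
    n, p = fit.n, fit.p
    if n <= p:
        raise ValueError("goodness requires more data points than parameters")
    if data is not None:
        if isinstance(data, ConditionData):
            data = [data]
        sse = objective_sse(fit.params, data, fit.spec)
        obs = np.concatenate([
            cond.channels[name][1]
            for cond in data
            for name in cond.channels
            if name in fit.spec.channels
        ])
        sst = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else math.nan
    else:
        sse = fit.sse
        r2 = math.nan  # SST needs the observations; pass data to get R2
    rmse = math.sqrt(sse / n)
    base = n * math.log(sse / n) if sse > 0 else -math.inf
    return GoodnessReport(
        R2=r2, RMSE=rmse, AIC=base + 2 * p, BIC=base + p * math.log(n), n=n, p=p
    )


def concordance(sim_values, rec_values) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``CCC = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))**2)``;
    1 for perfect agreement on the identity line.  Undefined (NaN) when both
    sequences are constant with equal means.
    """
    x = np.asarray(sim_values, dtype=float)
    y = np.asarray(rec_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n) moments
    cov = float(np.mean((x - mx) * (y - my)))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return math.nan
    return 2.0 * cov / denom


@dataclass
class BootstrapResult:
    """Participant-bootstrap distribution of fitted parameters."""

    names: tuple
    samples: np.ndarray        # (n_boot, p)
    indices: np.ndarray        # (n_boot, n_participants) resampled ids
    sd: dict
    percentiles: dict          # name -> (2.5%, 50%, 97.5%)
    n_boot: int
    seed: int


def bootstrap_fits(
    datasets,
    spec: FitSpec,
    n_boot: int = 5000,
    seed: int = 0,
    base: ModelParams | None = None,
    channels: tuple = ("total", "implicit"),
    point_fit: FitResult | None = None,
) -> BootstrapResult:
    """Resample participants with replacement, rebuild condition means, and
    refit; returns the parameter distribution.

    Each resample is refit from a single start at the point estimate (plus
    the spec's seed), which keeps the procedure deterministic for a fixed
    seed.  ``datasets`` may cover several conditions fit simultaneously;
    the same participant indices are drawn per condition.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    datasets = datasets if isinstance(datasets, (list, tuple)) else [datasets]
    if point_fit is None:
        point_fit = fit_model(fit_data_from_datasets(datasets, channels), spec, base=base)
    warm_spec = FitSpec(**{**spec.__dict__, "multi_start": 1})
    rng = np.random.default_rng(seed)
    pids = [ds.participants for ds in datasets]
    n_per = [len(p) for p in pids]
    names = tuple(spec.free)
    samples = np.empty((n_boot, len(names)))
    indices = np.empty((n_boot, max(n_per)), dtype=int)
    for bidx in range(n_boot):
        draws = [rng.integers(0, npart, size=npart) for npart in n_per]
        indices[bidx, : n_per[0]] = draws[0]
        data = []
        for ds, ids, draw in zip(datasets, pids, draws):
            means = condition_means(ds, participants=ids[draw])
            chans = {k: v for k, v in means.items() if k in channels}
            data.append(ConditionData(ds.schedule, chans))
        res = fit_model(data, warm_spec, base=base, extra_starts=[point_fit.params])
        samples[bidx] = [res.free[nm] for nm in names]
    sd = {nm: float(samples[:, j].std(ddof=1)) for j, nm in enumerate(names)}
    pct = {
        nm: tuple(np.percentile(samples[:, j], [2.5, 50, 97.5]))
        for j, nm in enumerate(names)
    }
    return BootstrapResult(names, samples, indices, sd, pct, n_boot, seed)


@dataclass
class RecoveryReport:
    """Simulated-vs-recovered parameter agreement."""

    ccc: dict                  # per-parameter CCC (NaN when degenerate)
    simulated: dict            # name -> array of true values
    recovered: dict            # name -> array of estimates
    n_sims: int
    seed: int

    @property
    def min_ccc(self) -> float:
        return min(v for v in self.ccc.values())


# realistic free-parameter ranges bracketing the published estimates
DEFAULT_RANGES = {"k": (0.10, 0.30), "Ai": (0.90, 0.995), "Bi": (0.08, 0.25)}


def _study_spec(design: str, model_kind, ranges: dict, multi_start: int,
                seed: int) -> FitSpec:
    channels = ("total",) if design == "exp4" else ("total", "implicit")
    free = tuple(n for n in ranges if n != "k" or ModelKind(model_kind) is ModelKind.PPE)
    return FitSpec(
        model_kind=model_kind,
        free=free,
        bounds={n: ranges[n] for n in free},
        channels=channels,
        multi_start=multi_start,
        seed=seed,
    )


def parameter_recovery(
    design: str,
    conditions,
    model_kind=ModelKind.PPE,
    ranges: dict | None = None,
    noise: NoiseSpec = NoiseSpec(),
    n_sims: int = 100,
    seed: int = 0,
    n_participants: int = 15,
    base: ModelParams | None = None,
    multi_start: int = 3,
) -> RecoveryReport:
    """Draw true parameters, simulate group data with motor noise, refit,
    and score per-parameter concordance.

    True values are drawn uniformly within ``ranges`` (defaults bracket the
    published estimates); the fit searches the same ranges.  Parameters not
    in ``ranges`` stay at ``base`` in both generation and fitting.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    ranges = dict(ranges or DEFAULT_RANGES)
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"degenerate range for {name}")
    if base is None:
        base = ModelParams(model_kind=model_kind)
    spec = _study_spec(design, model_kind, ranges, multi_start, seed)
    names = list(spec.free)
    rng = np.random.default_rng(seed)
    sim = {nm: np.empty(n_sims) for nm in names}
    rec = {nm: np.empty(n_sims) for nm in names}
    for s in range(n_sims):
        draws = {nm: float(rng.uniform(*ranges[nm])) for nm in names}
        true = base.with_(**draws)
        dsets = [
            simulate_group(design, cond, true, noise, n_participants,
                           seed=int(rng.integers(2**31 - 1)))
            for cond in conditions
        ]
        data = fit_data_from_datasets(dsets, spec.channels)
        res = fit_model(data, spec, base=base)
        for nm in names:
            sim[nm][s] = draws[nm]
            rec[nm][s] = res.free[nm]
    ccc = {nm: concordance(sim[nm], rec[nm]) for nm in names}
    return RecoveryReport(ccc, sim, rec, n_sims, seed)


@dataclass
class ConfusionMatrix:
    """Model-identification proportions: rows = generative, cols = selected."""

    kinds: tuple
    matrix: np.ndarray
    n_sims: int
    seed: int
    ties: int = 0

    def row(self, kind) -> np.ndarray:
        return self.matrix[self.kinds.index(ModelKind(kind))]

    @property
    def accuracy(self) -> np.ndarray:
        return np.diag(self.matrix)


def confusion(
    design: str,
    conditions,
    generative=(ModelKind.PPE, ModelKind.PE, ModelKind.SPE),
    ranges: dict | None = None,
    noise: NoiseSpec = NoiseSpec(),
    n_sims: int = 50,
    seed: int = 0,
    n_participants: int = 15,
    candidates=None,
    base: ModelParams | None = None,
    multi_start: int = 3,
) -> ConfusionMatrix:
    """Simulate from each generative model, fit all candidates, select by
    minimum BIC, and tabulate selection proportions.

    BIC ties are broken toward the candidate with fewer free parameters and
    counted on the result.
    """
    generative = tuple(ModelKind(g) for g in generative)
    candidates = tuple(ModelKind(c) for c in (candidates or generative))
    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    ranges = dict(ranges or DEFAULT_RANGES)
    if base is None:
        base = ModelParams()
    rng = np.random.default_rng(seed)
    mat = np.zeros((len(generative), len(candidates)))
    ties = 0
    for gi, gkind in enumerate(generative):
        gnames = [nm for nm in ranges if nm != "k" or gkind is ModelKind.PPE]
        for _ in range(n_sims):
            draws = {nm: float(rng.uniform(*ranges[nm])) for nm in gnames}
            true = base.with_(model_kind=gkind, **draws)
            dsets = [
                simulate_group(design, cond, true, noise, n_participants,
                               seed=int(rng.integers(2**31 - 1)))
                for cond in conditions
            ]
            bics = []
            for ckind in candidates:
                spec = _study_spec(design, ckind, ranges, multi_start,
                                   int(rng.integers(2**31 - 1)))
                data = fit_data_from_datasets(dsets, spec.channels)
                res = fit_model(data, spec, base=base.with_(model_kind=ckind))
                bics.append((goodness(res, data).BIC, res.p))
            best_bic = min(b for b, _ in bics)
            winners = [j for j, (b, _) in enumerate(bics)
                       if math.isclose(b, best_bic, abs_tol=1e-9)]
            if len(winners) > 1:
                ties += 1
                winners.sort(key=lambda j: bics[j][1])  # fewer parameters win
            mat[gi, winners[0]] += 1
    return ConfusionMatrix(candidates, mat / n_sims, n_sims, seed, ties)


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    r2: float


def size_dependency_regression(table) -> RegressionResult:
    """Ordinary least squares of single-trial learning on perturbation size.

    ``table`` is the output of :func:`vmradapt.simulate.single_trial_learning`
    (or any mapping of size to mean learning).
    """
    if hasattr(table, "index") and "learning" in getattr(table, "columns", []):
        x = np.asarray(table.index, dtype=float)
        y = table["learning"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in table)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct sizes")
    res = linregress(x, y)
    return RegressionResult(float(res.intercept), float(res.slope),
                            float(res.rvalue) ** 2)
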