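"""Synthetic behavioral data: run simulated participants through a model
and extract the study's behavioral measures.

Latent learning states evolve deterministically (the group shares one
noise-free trajectory); Gaussian motor and report noise is added only to
the executed and reported quantities, never to the states.  This keeps the
generator's condition mean equal to the deterministic model trajectory and
makes latent truth available as an oracle for every extracted measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schedules as sched
from .engine import Trajectory, run_model
from .params import ModelParams
from .schedules import PROP_LOCATIONS, PerturbationSchedule, build_schedule

__all__ = [
    "NoiseSpec",
    "SimulatedDataset",
    "simulate_participant",
    "simulate_group",
    "extract_measures",
    "single_trial_learning",
    "condition_means",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise of the generator (degrees).

    ``sigma_motor`` is trial-to-trial reach variability (default matches
    typical baseline reach dispersion); ``sigma_report`` applies to aiming
    and perceptual reports.
    """

    sigma_motor: float = 4.0
    sigma_report: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_motor < 0 or self.sigma_report < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    ZERO = None  # filled below


NoiseSpec.ZERO = NoiseSpec(0.0, 0.0)


@dataclass
class SimulatedDataset:
    """Per-participant trial records of one condition plus provenance."""

    design: str
    condition: str
    schedule: PerturbationSchedule | None
    trials: pd.DataFrame  # long form, one row per participant x trial
    params: ModelParams | None = None
    noise: NoiseSpec | None = None
    seed: int | None = None

    @property
    def participants(self) -> np.ndarray:
        return np.unique(self.trials["participant_id"])

    def for_participant(self, pid) -> pd.DataFrame:
        return self.trials[self.trials["participant_id"] == pid]


def simulate_participant(
    schedule: PerturbationSchedule,
    params: ModelParams,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.Generator = 0,
    participant_id: str = "p01",
    trajectory: Trajectory | None = None,
) -> pd.DataFrame:
    """One participant's trial records over a schedule.

    The latent trajectory is deterministic; observation noise is drawn from
    ``seed``.  Identical seeds give bit-identical records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traj = trajectory if trajectory is not None else run_model(schedule, params)
    n = len(schedule)
    hand = np.full(n, np.nan)
    aim_report = np.full(n, np.nan)
    percept = np.full(n, np.nan)

    moves = schedule.moves
    hand[moves] = traj.hand[moves] + rng.normal(0.0, noise.sigma_motor, moves.sum())

    # perceptual bias carried from the most recent feedback trial
    last_bias = 0.0
    prop_cycle = 0
    for t in range(n):
        tt = schedule.trial_type[t]
        if tt in ("feedback", "aiming_report", "probe"):
            last_bias = traj.perceived[t] - traj.hand[t]
        if tt == "prop_test":
            loc = PROP_LOCATIONS[prop_cycle % len(PROP_LOCATIONS)]
            prop_cycle += 1
            hand[t] = loc  # passive placement, robot-controlled
            percept[t] = loc + last_bias + rng.normal(0.0, noise.sigma_report)
        elif tt == "aiming_report":
            aim_report[t] = traj.x_e[t] + rng.normal(0.0, noise.sigma_report)
        elif tt == "probe":
            aim_report[t] = traj.x_e[t] + rng.normal(0.0, noise.sigma_report)
            percept[t] = traj.perceived[t] + rng.normal(0.0, noise.sigma_report)

    df = schedule.to_frame()
    df.insert(0, "participant_id", participant_id)
    df.insert(1, "condition", schedule.condition)
    df["hand_deg"] = hand
    df["aim_report_deg"] = aim_report
    df["percept_report_deg"] = percept
    df["x_e"] = traj.x_e
    df["x_i"] = traj.x_i
    return df


def simulate_group(
    design: str,
    condition,
    params: ModelParams,
    noise: NoiseSpec = NoiseSpec(),
    n_participants: int = 15,
    seed: int = 0,
    schedule: PerturbationSchedule | None = None,
    **schedule_kw,
) -> SimulatedDataset:
    """Simulate ``n_participants`` independent participants of one condition.

    Per-participant random streams are spawned from the group seed, so the
    group is reproducible and participants are mutually independent.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    if schedule is None:
        schedule = build_schedule(design, condition, **schedule_kw)
    traj = run_model(schedule, params)
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    frames = [
        simulate_participant(
            schedule, params, noise, np.random.default_rng(s),
            participant_id=f"p{i + 1:02d}", trajectory=traj,
        )
        for i, s in enumerate(streams)
    ]
    return SimulatedDataset(
        design=schedule.design,
        condition=schedule.condition,
        schedule=schedule,
        trials=pd.concat(frames, ignore_index=True),
        params=params,
        noise=noise,
        seed=seed,
    )


def _require_schedule(dataset: SimulatedDataset) -> PerturbationSchedule:
    if dataset.schedule is not None:
        return dataset.schedule
    pid = dataset.participants[0]
    return sched.schedule_from_frame(dataset.for_participant(pid),
                                     dataset.design, dataset.condition)


def condition_means(dataset: SimulatedDataset,
                    participants: np.ndarray | None = None) -> dict:
    """Condition-mean observed series, keyed by fitting channel.

    ``total``: mean hand direction on cursor-feedback trials;
    ``implicit``: mean hand direction on aim-at-target no-feedback trials
    (exclusion / null / washout); ``explicit``: mean reported aim.  Each
    channel is a ``(trial_index_0based, values)`` pair.  ``participants``
    restricts/reweights the average (used by the participant bootstrap).
    """
    schedule = _require_schedule(dataset)
    df = dataset.trials
    if participants is not None:
        df = pd.concat(
            [df[df["participant_id"] == p] for p in participants],
            ignore_index=True,
        )
    by_trial = df.groupby("trial")
    hand = by_trial["hand_deg"].mean()
    aim = by_trial["aim_report_deg"].mean()

    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    idx_fb = np.flatnonzero(schedule.has_feedback)
    channels["total"] = (idx_fb, hand.reindex(idx_fb + 1).to_numpy())
    idx_im = np.flatnonzero(schedule.aims_at_target)
    if idx_im.size:
        channels["implicit"] = (idx_im, hand.reindex(idx_im + 1).to_numpy())
    idx_ex = np.flatnonzero(np.isin(schedule.trial_type,
                                    [sched.AIMING_REPORT, sched.PROBE]))
    if idx_ex.size:
        channels["explicit"] = (idx_ex, aim.reindex(idx_ex + 1).to_numpy())
    return channels


@dataclass
class Measures:
    """Condition summaries of the standard behavioral measures."""

    total_series: pd.Series          # mean total learning by trial
    implicit_series: pd.Series       # mean exclusion-trial hand by trial
    explicit_series: pd.Series       # mean reported aim by trial (may be empty)
    implicit_late: float             # mean over adaptation exclusion trials
    explicit_late: float             # total - implicit at late adaptation
    prop_bias: float = np.nan        # mean perceived - actual, adaptation
    prop_series: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    probe_ppe: float = np.nan        # mean percept report - aim report
    probe_series: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def extract_measures(dataset: SimulatedDataset, require: tuple = ()) -> Measures:
    """The behavioral measures of one condition.

    ``require`` names measures (``prop_bias``, ``probe_ppe``, ``implicit_late``,
    ``explicit_series``) that must be supported by the design; requesting a
    measure the design cannot provide raises ``ValueError``.

    Implicit learning is read from aim-at-target exclusion trials, explicit
    learning from aiming reports where present (else total minus implicit),
    proprioceptive bias from passive-test report errors, and probe-trial
    perceptual error from the difference between the post-movement hand
    percept report and the pre-movement aim report.
    """
    schedule = _require_schedule(dataset)
    available = {
        "total_series": True,
        "implicit_series": bool(schedule.aims_at_target.any()),
        "implicit_late": "exclusion" in schedule.trial_type,
        "explicit_series": bool(np.isin(schedule.trial_type,
                                        [sched.AIMING_REPORT, sched.PROBE]).any()),
        "prop_bias": "prop_test" in schedule.trial_type,
        "probe_ppe": "probe" in schedule.trial_type,
    }
    for name in require:
        if not available.get(name, False):
            raise ValueError(f"measure {name!r} is not available in design "
                             f"{dataset.design!r}")
    df = dataset.trials.copy()
    tmap = pd.Series(schedule.trial_type, index=np.arange(1, len(schedule) + 1))
    phase = pd.Series(schedule.phase, index=tmap.index)
    df["_ttype"] = df["trial"].map(tmap)
    df["_phase"] = df["trial"].map(phase)

    move_fb = df[df["_ttype"].isin(["feedback", "aiming_report", "probe"])]
    total_series = move_fb.groupby("trial")["hand_deg"].mean()

    excl = df[df["_ttype"].isin(["exclusion", "null_nofeedback", "washout"])]
    implicit_series = excl.groupby("trial")["hand_deg"].mean()

    reports = df[df["aim_report_deg"].notna()]
    explicit_series = reports.groupby("trial")["aim_report_deg"].mean()

    late_excl = excl[(excl["_phase"] == "adaptation") & (excl["_ttype"] == "exclusion")]
    implicit_late = float(late_excl["hand_deg"].mean()) if len(late_excl) else np.nan
    ad_fb = move_fb[move_fb["_phase"] == "adaptation"]
    if len(ad_fb):
        last_cycle = ad_fb["trial"].max()
        total_late = float(
            ad_fb[ad_fb["trial"] > last_cycle - 8]["hand_deg"].mean()
        )
    else:
        total_late = np.nan
    explicit_late = total_late - implicit_late

    m = Measures(
        total_series=total_series,
        implicit_series=implicit_series,
        explicit_series=explicit_series,
        implicit_late=implicit_late,
        explicit_late=explicit_late,
    )

    prop = df[(df["_ttype"] == "prop_test") & (df["_phase"] == "adaptation")]
    if len(prop):
        err = prop["percept_report_deg"] - prop["hand_deg"]
        m.prop_series = err.groupby(prop["trial"]).mean()
        m.prop_bias = float(err.mean())

    probe = df[(df["_ttype"] == "probe") & (df["_phase"] == "adaptation")]
    if len(probe):
        ppe = probe["percept_report_deg"] - probe["aim_report_deg"]
        m.probe_series = ppe.groupby(probe["trial"]).mean()
        m.probe_ppe = float(ppe.mean())
    return m


def single_trial_learning(dataset: SimulatedDataset) -> pd.DataFrame:
    """Single-trial learning vs. absolute perturbation size (random design).

    For each perturbation trial flanked by no-feedback null trials, learning
    is the hand-direction change from the preceding to the following null
    trial, sign-aligned with the perturbation and pooled over clockwise and
    counter-clockwise rotations.  Returns a table indexed by ``abs_rotation``
    with the pooled mean and per-size trial counts.
    """
    if dataset.design != "exp3":
        raise ValueError("single_trial_learning requires an exp3-design dataset")
    schedule = _require_schedule(dataset)
    tt = schedule.trial_type
    rot = schedule.rotation
    adapt = schedule.phase == "adaptation"

    fb_pos = [
        t
        for t in range(1, len(schedule) - 1)
        if adapt[t] and tt[t] == "feedback"
        and tt[t - 1] == "null_nofeedback" and tt[t + 1] == "null_nofeedback"
    ]
    rows = []
    for pid in dataset.participants:
        h = (
            dataset.for_participant(pid)
            .set_index("trial")["hand_deg"]
            .reindex(np.arange(1, len(schedule) + 1))
            .to_numpy()
        )
        for t in fb_pos:
            delta = h[t + 1] - h[t - 1]
            r = rot[t]
            aligned = delta * np.sign(r) if r != 0 else delta
            rows.append((abs(r), aligned))
    table = pd.DataFrame(rows, columns=["abs_rotation", "learning"])
    out = table.groupby("abs_rotation")["learning"].agg(["mean", "count"])
    out.columns = ["learning", "n_trials"]
    return out
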