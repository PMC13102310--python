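"""Perturbation schedules for the visuomotor-rotation experiment designs.

A schedule is the per-trial description of one condition: the imposed
rotation, the trial type (feedback, exclusion, no-feedback null,
proprioception test, aiming report, perceptual probe, washout) and the
aiming regime (free aiming vs. instructed re-aiming).  All participants in
a condition share the identical schedule; participant-level noise lives in
the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# trial-type vocabulary
FEEDBACK = "feedback"
EXCLUSION = "exclusion"
NULL = "null_nofeedback"
PROP_TEST = "prop_test"
AIMING_REPORT = "aiming_report"
PROBE = "probe"
WASHOUT = "washout"

TRIAL_TYPES = (FEEDBACK, EXCLUSION, NULL, PROP_TEST, AIMING_REPORT, PROBE, WASHOUT)

#: trial types on which the cursor is visible and errors drive learning
FEEDBACK_TYPES = frozenset({FEEDBACK, AIMING_REPORT, PROBE})
#: trial types performed with the instruction to aim straight at the target
#: and no cursor: the hand reads out the implicit state
AIM_AT_TARGET_TYPES = frozenset({EXCLUSION, NULL, WASHOUT})

DESIGNS = (
    "bond2015",
    "exp1",
    "exp2_onestep",
    "exp2_stepwise",
    "exp3",
    "exp4",
    "exp5",
    "exp6",
)

# fixed internal seed for the published-in-repo pseudo-random rotation order
# of the single-trial design; part of the design, not a tunable
_EXP3_ORDER_SEED = 191919
EXP3_SIZES = (0, 4, 8, 16, 32, 64)
EXP3_REPEATS = 9

# passive proprioception-test locations relative to the target (bookkeeping)
PROP_LOCATIONS = (5.0, -5.0, 15.0, -15.0)


@dataclass
class PerturbationSchedule:
    """Ordered per-trial design of one experimental condition."""

    design: str
    condition: str
    rotation: np.ndarray        # signed rotation r per trial (deg)
    trial_type: np.ndarray      # str, from TRIAL_TYPES
    instructed: np.ndarray      # bool: instructed re-aiming regime
    aim_ref: np.ndarray         # instructed aiming direction (deg); NaN means
                                # "freeze at the participant's own aim"
    pe_reaim: np.ndarray        # bool: PE model uses the re-aiming error here
    phase: np.ndarray           # baseline / adaptation / reaiming / washout
    cycle: np.ndarray           # 1-based cycle/block index within phase
    target: np.ndarray = field(default=None)  # target identity, bookkeeping

    def __post_init__(self) -> None:
        if self.target is None:
            self.target = np.zeros(len(self.rotation), dtype=int)
        n = len(self.rotation)
        for name in ("trial_type", "instructed", "aim_ref", "pe_reaim", "phase", "cycle"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"schedule field {name} has wrong length")
        unknown = set(np.unique(self.trial_type)) - set(TRIAL_TYPES)
        if unknown:
            raise ValueError(f"unknown trial types {unknown}")
        if np.any(self.rotation[self.phase == "baseline"] != 0):
            raise ValueError("baseline trials must have zero rotation")

    def __len__(self) -> int:
        return len(self.rotation)

    @property
    def has_feedback(self) -> np.ndarray:
        return np.isin(self.trial_type, list(FEEDBACK_TYPES))

    @property
    def aims_at_target(self) -> np.ndarray:
        return np.isin(self.trial_type, list(AIM_AT_TARGET_TYPES))

    @property
    def moves(self) -> np.ndarray:
        """Trials on which the participant actively reaches."""
        return self.trial_type != PROP_TEST

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "phase": self.phase,
                "cycle": self.cycle,
                "trial_type": self.trial_type,
                "rotation_deg": self.rotation,
                "regime": np.where(self.instructed, "instructed_reaiming", "free_aiming"),
                "aim_ref_deg": self.aim_ref,
                "pe_reaim": self.pe_reaim,
                "target": self.target,
            }
        )


class _Builder:
    """Accumulates trials phase by phase."""

    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, phase, ttype, r=0.0, instructed=False, aim_ref=np.nan,
            pe_reaim=False, cycle=0, target=0) -> None:
        self.rows.append((phase, ttype, float(r), instructed, float(aim_ref),
                          pe_reaim, int(cycle), int(target)))

    def block(self, phase, n, r=0.0, *, special=None, cycle0=0, **kw) -> None:
        """Add ``n`` trials; ``special`` maps 1-based positions to types."""
        special = special or {}
        for i in range(1, n + 1):
            self.add(phase, special.get(i, FEEDBACK), r, cycle=cycle0 + i, **kw)

    def build(self, design, condition) -> PerturbationSchedule:
        phase, ttype, r, instr, ref, pr, cyc, tgt = map(list, zip(*self.rows))
        return PerturbationSchedule(
            design=design,
            condition=str(condition),
            rotation=np.array(r, dtype=float),
            trial_type=np.array(ttype, dtype=object),
            instructed=np.array(instr, dtype=bool),
            aim_ref=np.array(ref, dtype=float),
            pe_reaim=np.array(pr, dtype=bool),
            phase=np.array(phase, dtype=object),
            cycle=np.array(cyc, dtype=int),
            target=np.array(tgt, dtype=int),
        )


def exp3_rotation_sequence() -> np.ndarray:
    """The fixed pseudo-random signed rotation order of the single-trial
    design: 0, +/-4, +/-8, +/-16, +/-32, +/-64 deg, each nine times (99
    perturbation trials), shuffled once with a fixed seed.  The sequence is
    identical for every participant and has exactly zero mean."""
    vals = [0.0] * EXP3_REPEATS
    for s in EXP3_SIZES[1:]:
        vals += [float(s)] * EXP3_REPEATS + [float(-s)] * EXP3_REPEATS
    seq = np.array(vals)
    rng = np.random.default_rng(_EXP3_ORDER_SEED)
    rng.shuffle(seq)
    return seq


def _exp1(b: _Builder, size: float) -> None:
    b.block("baseline", 35, 0.0, special={i: PROP_TEST for i in (5, 10, 15, 20)})
    special = {i: PROP_TEST for i in (15, 20, 25, 30, 35)}
    special.update({i: EXCLUSION for i in (50, 55, 60, 65)})
    b.block("adaptation", 75, size, special=special)
    b.block("washout", 20, 0.0, special={i: WASHOUT for i in range(1, 21)})


def _exp2(b: _Builder, rotations: list[float]) -> None:
    b.block("baseline", 35, 0.0)
    special = {i: PROP_TEST for i in (5, 10, 15, 20)}
    special.update({i: EXCLUSION for i in (30, 35)})
    for blk, r in enumerate(rotations, start=1):
        for i in range(1, 41):
            b.add("adaptation", special.get(i, FEEDBACK), r, cycle=(blk - 1) * 40 + i)
    b.block("washout", 20, 0.0, special={i: WASHOUT for i in range(1, 21)})


def _exp3(b: _Builder) -> None:
    for i in range(1, 16):  # 15 feedback + 15 interleaved null trials
        b.add("baseline", FEEDBACK, 0.0, cycle=2 * i - 1)
        b.add("baseline", NULL, 0.0, cycle=2 * i)
    seq = exp3_rotation_sequence()
    targets = np.tile([0, 1, 2], len(seq) // 3)
    t = 0
    for j, r in enumerate(seq, start=1):  # null-perturbation alternation
        t += 1
        b.add("adaptation", NULL, 0.0, cycle=t, target=targets[j - 1])
        t += 1
        b.add("adaptation", FEEDBACK, r, cycle=t, target=targets[j - 1])


def _exp4(b: _Builder, offset: float, pe_reaim: bool) -> None:
    b.block("baseline", 40, 0.0)
    for i in range(1, 121):
        b.add("adaptation", FEEDBACK, offset, instructed=True, aim_ref=offset,
              pe_reaim=pe_reaim, cycle=(i - 1) // 8 + 1)


def _exp5(b: _Builder) -> None:
    for c in range(1, 4):
        for _ in range(4):
            b.add("baseline", FEEDBACK, 0.0, cycle=c)
    for _ in range(4):
        b.add("baseline", NULL, 0.0, cycle=4)
    for c in range(1, 61):
        if c in (5, 19, 33, 47):
            tt = AIMING_REPORT
        elif c in (6, 20, 34, 48):
            tt = EXCLUSION
        else:
            tt = FEEDBACK
        for _ in range(4):
            b.add("adaptation", tt, 45.0, cycle=c)
    for c in range(1, 41):  # instructed re-aiming at the participant's own aim
        tt = EXCLUSION if c in (1, 11, 21) else FEEDBACK
        for _ in range(4):
            if tt == EXCLUSION:
                b.add("reaiming", EXCLUSION, 45.0, cycle=c)
            else:
                b.add("reaiming", FEEDBACK, 45.0, instructed=True,
                      aim_ref=np.nan, pe_reaim=True, cycle=c)
    for c in range(1, 16):
        for _ in range(4):
            b.add("washout", WASHOUT, 0.0, cycle=c)


def _exp6(b: _Builder, size: float) -> None:
    b.block("baseline", 20, 0.0, special={i: PROBE for i in (4, 8, 12, 16, 20)})
    # the first eight adaptation trials are never probed
    b.block("adaptation", 44, size,
            special={i: PROBE for i in range(12, 45, 4)})
    b.block("washout", 20, 0.0, special={i: WASHOUT for i in range(1, 21)})


def _bond2015(b: _Builder, size: float) -> None:
    # Generic emulation of a report-every-trial blocked design: short
    # baseline, 80 adaptation trials with per-trial aiming reports, and an
    # exclusion washout.
    b.block("baseline", 8, 0.0)
    b.block("adaptation", 80, size,
            special={i: AIMING_REPORT for i in range(1, 81)})
    b.block("washout", 16, 0.0, special={i: WASHOUT for i in range(1, 17)})


_EXP1_SIZES = (15.0, 30.0, 60.0, 90.0)
_EXP4_OFFSETS = (45.0, 90.0)
_EXP6_SIZES = (15.0, 30.0, 90.0)


def build_schedule(design: str, condition: float | str | None = None, *,
                   pe_reaim: bool = False) -> PerturbationSchedule:
    """Build the per-trial schedule of one design/condition.

    ``condition`` is the perturbation size (deg) for the blocked designs
    (``exp1``, ``exp6``, ``bond2015``) or the re-aiming offset for ``exp4``;
    the remaining designs take no condition.  ``pe_reaim`` marks the
    instructed trials of ``exp4`` so that the PE model is scored against the
    re-aiming target rather than the original target.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    b = _Builder()
    if design in ("exp1", "bond2015"):
        size = float(condition) if condition is not None else None
        if size not in _EXP1_SIZES:
            raise ValueError(f"{design} condition must be one of {_EXP1_SIZES}")
        (_exp1 if design == "exp1" else _bond2015)(b, size)
        condition = f"{size:g}"
    elif design == "exp2_stepwise":
        _exp2(b, [15.0, 30.0, 45.0, 60.0])
        condition = "stepwise"
    elif design == "exp2_onestep":
        _exp2(b, [60.0, 60.0, 60.0, 60.0])
        condition = "onestep"
    elif design == "exp3":
        _exp3(b)
        condition = "random"
    elif design == "exp4":
        offset = float(condition) if condition is not None else None
        if offset not in _EXP4_OFFSETS:
            raise ValueError(f"exp4 condition must be one of {_EXP4_OFFSETS}")
        _exp4(b, offset, pe_reaim)
        condition = f"{offset:g}"
    elif design == "exp5":
        _exp5(b)
        condition = "45"
    elif design == "exp6":
        size = float(condition) if condition is not None else None
        if size not in _EXP6_SIZES:
            raise ValueError(f"exp6 condition must be one of {_EXP6_SIZES}")
        _exp6(b, size)
        condition = f"{size:g}"
    return b.build(design, condition)


def schedule_from_frame(df: pd.DataFrame, design: str = "custom",
                        condition: str = "custom") -> PerturbationSchedule:
    """Reconstruct a schedule from a long-form trial table (one participant).

    Used when ingesting external data: the table must carry ``trial_type``,
    ``rotation_deg`` and ``regime``; ``aim_ref_deg`` is honored when present
    (instructed trials default to aiming at the rotation offset).
    """
    df = df.sort_values("trial")
    n = len(df)
    instructed = (df["regime"].astype(str) == "instructed_reaiming").to_numpy()
    if "aim_ref_deg" in df.columns:
        aim_ref = pd.to_numeric(df["aim_ref_deg"]).to_numpy(dtype=float)
    else:
        aim_ref = np.where(instructed, df["rotation_deg"].to_numpy(dtype=float), np.nan)
    return PerturbationSchedule(
        design=design,
        condition=condition,
        rotation=df["rotation_deg"].to_numpy(dtype=float),
        trial_type=df["trial_type"].to_numpy(dtype=object),
        instructed=instructed,
        aim_ref=aim_ref,
        pe_reaim=df["pe_reaim"].to_numpy(dtype=bool) if "pe_reaim" in df.columns
        else np.zeros(n, dtype=bool),
        phase=df["phase"].to_numpy(dtype=object) if "phase" in df.columns
        else np.array(["adaptation"] * n, dtype=object),
        cycle=df["cycle"].to_numpy(dtype=int) if "cycle" in df.columns
        else np.zeros(n, dtype=int),
    )
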