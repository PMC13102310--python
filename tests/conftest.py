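import numpy as np
import pytest

from vmradapt import ModelParams, NoiseSpec
from vmradapt.schedules import PerturbationSchedule


@pytest.fixture
def ppe_params():
    return ModelParams(model_kind="PPE")


@pytest.fixture
def zero_noise():
    return NoiseSpec(0.0, 0.0)


def single_trial_probe_schedule(r: float) -> PerturbationSchedule:
    """Minimal null / perturbation / null schedule starting from rest,
    used to read out the exact one-trial learning response."""
    n = 3
    return PerturbationSchedule(
        design="exp3",
        condition="single",
        rotation=np.array([0.0, r, 0.0]),
        trial_type=np.array(
            ["null_nofeedback", "feedback", "null_nofeedback"], dtype=object
        ),
        instructed=np.zeros(n, dtype=bool),
        aim_ref=np.full(n, np.nan),
        pe_reaim=np.zeros(n, dtype=bool),
        phase=np.array(["adaptation"] * n, dtype=object),
        cycle=np.arange(1, n + 1),
    )
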