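import numpy as np
import pytest

from swaykit import CohortSpec, Condition, ForcePlateTrial


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_spec():
    """A cheap cohort spec: short trials, few participants."""
    return CohortSpec(n_per_group=(6, 8), duration=20.0, seed=0)


@pytest.fixture
def tiny_trial():
    """A 2-second synthetic trial with a known slow+fast structure."""
    fs = 200.0
    t = np.arange(int(2 * fs)) / fs
    slow = 5.0 * np.sin(2 * np.pi * 0.4 * t)
    fast = 0.8 * np.sin(2 * np.pi * 4.0 * t)
    return ForcePlateTrial(
        participant_id="p1",
        condition=Condition.from_code("EOOB"),
        t=t,
        cop_ml=slow + fast,
        cop_ap=0.5 * slow + fast,
        f_ml=-0.7 * fast,
        f_ap=-0.7 * fast,
        fs=fs,
    )


def make_trial(t, cop_ml, cop_ap, f_ml, f_ap, fs, code="EOOB", pid="p"):
    return ForcePlateTrial(
        participant_id=pid,
        condition=Condition.from_code(code),
        t=np.asarray(t, float),
        cop_ml=np.asarray(cop_ml, float),
        cop_ap=np.asarray(cop_ap, float),
        f_ml=np.asarray(f_ml, float),
        f_ap=np.asarray(f_ap, float),
        fs=fs,
    )
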