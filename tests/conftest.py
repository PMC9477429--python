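import numpy as np
import pytest

from adcascade import SubjectParameters
from adcascade.cohort import SLOW_PROGRESSION_STATS
from adcascade.reference import GROUP_STATS


@pytest.fixture(scope="session")
def ad_params() -> SubjectParameters:
    """Published AD-group mean parameters (fast progression)."""
    d = {k: v[0] for k, v in GROUP_STATS["AD"].items()}
    d["T0"] = 50.0
    return SubjectParameters.from_dict(d)


@pytest.fixture(scope="session")
def slow_params() -> SubjectParameters:
    """Slow-progression benchmark means: every biomarker stays in its
    dynamic phase through the usual observation window, so parameters
    are identifiable and treatment produces measurable responses."""
    d = {k: v[0] for k, v in SLOW_PROGRESSION_STATS.items()}
    d["T0"] = 50.0
    return SubjectParameters.from_dict(d)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
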