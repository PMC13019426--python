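import numpy as np
import pytest
from hypothesis import settings

from sabre_kd.inference import FitResult

# property tests must behave identically on every run/machine
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def catalyst_truth() -> dict[str, float]:
    """Ground-truth catalyst parameters used by the titration fixtures."""
    return {"r2_f": 0.231, "r2_cl": 2.92, "k_eq": 0.050}


@pytest.fixture
def catalyst_fit(catalyst_truth) -> FitResult:
    """A FitResult carrying the titration truth, as downstream fits expect it."""
    return FitResult(estimates=dict(catalyst_truth), rss=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
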