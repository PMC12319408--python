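import numpy as np
import pytest

from respicall.reduction import ReductionParams
from respicall.simulate import CohortParams, TraceSimParams, simulate_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_trace_params():
    """No noise, no drift, no lag, no bursts: exact inversion territory."""
    return TraceSimParams(
        o2_noise_sd_pct=0.0,
        co2_noise_sd_pct=0.0,
        wvp_noise_sd_kpa=0.0,
        o2_drift_pct_per_h=0.0,
        co2_drift_pct_per_h=0.0,
        lag_s=0.0,
        burst_prob_per_rep=0.0,
    )


@pytest.fixture
def clean_trace(clean_trace_params):
    return simulate_trace({1: 0.9, 2: 0.5}, clean_trace_params, rng=0).trace


@pytest.fixture
def default_reduction_params():
    return ReductionParams()


@pytest.fixture
def small_cohort_params():
    return CohortParams(n_individuals=40)
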