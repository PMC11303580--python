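"""Shared fixtures: published-estimate truth and small simulated trials."""

import numpy as np
import pytest

from ecupop.foce import EstimationOptions
from ecupop.simulate import default_truth, phase1_design, phase3_design, simulate_study


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def phase1_small(truth):
    """Small phase I trial (18 healthy subjects), fixed seed."""
    return simulate_study(phase1_design(18), truth, seed=101)


@pytest.fixture(scope="session")
def phase3_small(truth):
    """Small phase III trial (8 PNH patients), fixed seed."""
    return simulate_study(phase3_design(8), truth, seed=102)


@pytest.fixture(scope="session")
def fast_options():
    return EstimationOptions(compute_se=False)


@pytest.fixture(scope="session")
def typical_pk(truth):
    """Typical two-compartment parameters at the reference weight."""
    pk = truth.pk
    return dict(cl=pk.cl, vc=pk.vc_healthy, vp=pk.vp, q=pk.q)
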