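"""Shared fixtures: canonical parameter sets and fast experiment designs."""

import numpy as np
import pytest

from frapkit import ExperimentDesign, PhysicalParams


@pytest.fixture
def fig_re_params():
    """Rapid-equilibration benchmark values (D_v = 0, k_on/k_off = 2)."""
    return PhysicalParams(D_u=20.0, D_v=0.0, k_on=2.0, k_off=1.0)


@pytest.fixture
def fig_se_params():
    """Slow-equilibration benchmark values (κ = 5, D_eff = 12.5623)."""
    return PhysicalParams(D_u=15.0, D_v=0.374, k_on=1000.0, k_off=5000.0)


@pytest.fixture
def default_design():
    """Full-resolution standard design: 1024 frames over 15 s."""
    return ExperimentDesign()


@pytest.fixture
def small_design():
    """Coarser, short design for tests that only need plumbing speed."""
    return ExperimentDesign(n_frames=96, duration=12.0, dr=0.05,
                            R_domain=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
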