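"""Shared fixtures: one pattern-forming run and its reflection scan are
computed once per session and reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from braggrass.braggsim import SimConfig, run_simulation
from braggrass.diagnostics import pattern_spectrum, reflection_scan
from braggrass.equilibria import critical_amplitude


@pytest.fixture(scope="session")
def test_config() -> SimConfig:
    """Default study conditions at test resolution (32 nodes per wavelength)."""
    return SimConfig(nodes_per_wavelength=32)


@pytest.fixture(scope="session")
def a_star(test_config) -> float:
    return critical_amplitude(test_config.wp.T, test_config.wp, test_config.sp)


@pytest.fixture(scope="session")
def pattern_run(test_config):
    """25-period coupled run at the default amplitude (inside the window)."""
    return run_simulation(test_config)


@pytest.fixture(scope="session")
def reflection_curves(test_config, pattern_run):
    """Frozen-topography K_R scan of the session pattern, 3 amplitudes."""
    res = pattern_run
    spec = pattern_spectrum(res.state.n1, res.grid, res.basic.kappa)
    return reflection_scan(
        res.state.n1, res.basic, test_config, res.grid, spec.k_dominant,
        kappa_ratios=np.linspace(0.5, 1.5, 9), multipliers=(0.5, 1.0, 2.0),
    )
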