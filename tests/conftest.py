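"""Shared fixtures: small Monte Carlo tables and hand-built photon records.

The transport fixtures are session-scoped — the same table serves every
test that only replays it (white-Monte-Carlo reuse, same as the library's
own design).
"""

from __future__ import annotations

import numpy as np
import pytest

from dcsmc.medium import (
    adult_head_preset,
    homogeneous_preset,
    wavelength_1064,
)
from dcsmc.oracles import synthetic_table
from dcsmc.transport import TransportConfig, simulate


@pytest.fixture(scope="session")
def wl():
    return wavelength_1064()


@pytest.fixture(scope="session")
def homog_table(wl):
    """Homogeneous scalp-optics medium, enough photons for ToF statistics."""
    med = homogeneous_preset()
    cfg = TransportConfig(
        n_photons=150_000, rng_seed=101, max_tof=1.5e-9, max_radius=50.0
    )
    return simulate(med, wl, cfg)


@pytest.fixture(scope="session")
def head_table(wl):
    """Small default adult-head table for replay/sensitivity plumbing tests."""
    med = adult_head_preset()
    cfg = TransportConfig(
        n_photons=120_000, rng_seed=202, max_tof=1.5e-9, max_radius=40.0
    )
    return simulate(med, wl, cfg)


@pytest.fixture()
def random_table(wl):
    """A reproducible hand-built 4-layer table of random photon records."""
    med = adult_head_preset()
    rng = np.random.default_rng(7)
    n = 400
    L = rng.exponential(20.0, size=(n, 4))
    Y = rng.exponential(30.0, size=(n, 4))
    return synthetic_table(med, L, Y)
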