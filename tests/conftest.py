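"""Shared fixtures: force field, desk-scale isotope runs, monomer runs.

The desk-scale profile (32 molecules, 8 beads, ~1.5 ps equilibration +
1.5 ps production) keeps a full isotope scan to a couple of minutes
while preserving the qualitative physics the suite asserts: gyration
orderings, spectral band orderings, hydrogen-bond statistics.
"""

from __future__ import annotations

import numpy as np
import pytest

from isopimd.engine import IntegratorSettings, run_simulation
from isopimd.forcefield import IsotopeSystem, load_constants

DESK_N_MOL = 32
DESK_NB = 8
DESK_SEED = 20240917


@pytest.fixture(scope="session")
def ff():
    return load_constants()


def _desk_settings(temperature: float, seed: int = DESK_SEED, **kw) -> IntegratorSettings:
    defaults = dict(
        n_beads=DESK_NB,
        temperature=temperature,
        n_equil=6000,
        n_prod=6000,
        seed=seed,
        frame_stride=10,
        velocity_stride=4,
        bead_stride=40,
    )
    defaults.update(kw)
    return IntegratorSettings(**defaults)


@pytest.fixture(scope="session")
def isotope_runs_300k():
    """Matched desk-scale NVT runs at 300 K for all four compositions."""
    runs = {}
    for comp in ("H2O", "HDO", "D2O", "T2O"):
        system = IsotopeSystem(DESK_N_MOL, comp)
        runs[comp] = run_simulation(system, _desk_settings(300.0))
    return runs


@pytest.fixture(scope="session")
def h2o_cold_run():
    """H2O at 240 K for cooling-trend checks against the 300 K run."""
    system = IsotopeSystem(DESK_N_MOL, "H2O")
    return run_simulation(system, _desk_settings(240.0))


@pytest.fixture(scope="session")
def monomer_run_300k():
    """Isolated H2O molecule at matched (T, n_b): the E_0 reference."""
    system = IsotopeSystem(1, "H2O")
    settings = _desk_settings(300.0, n_equil=2000, n_prod=8000, bead_stride=100)
    return run_simulation(system, settings, interactions_on=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
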