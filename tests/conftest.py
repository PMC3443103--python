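"""Shared fixtures: reference bond-law parameters and the independent
continuous-time Markov-chain oracle used to validate the simulator."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from flowbond import BondLaw, ForceLevels

# Flow-chamber bond-law parameters (force pN, k0 s^-1, a s^-1) for the three
# shear conditions, plus the zero-force row obtained by Bell extrapolation.
TABLE_ROWS = [
    (8.80, 0.519, 1.171),
    (15.84, 1.277, 2.270),
    (26.4, 4.934, 6.126),
]
ZERO_FORCE = (0.168, 0.512)
HALF_FORCE = {8.80: (0.295, 0.775), 15.84: (0.463, 1.078), 26.4: (0.911, 1.772)}


@pytest.fixture(scope="session")
def highest_force_levels() -> ForceLevels:
    """Full / half / zero-force laws for the highest-shear condition."""
    return ForceLevels(
        full=BondLaw(4.934, 6.126, force=26.4),
        half=BondLaw(0.911, 1.772, force=13.2),
        unloaded=BondLaw(0.168, 0.512, force=0.0),
    )


@pytest.fixture(scope="session")
def intermediate_force_levels() -> ForceLevels:
    return ForceLevels(
        full=BondLaw(1.277, 2.270, force=15.84),
        half=BondLaw(0.463, 1.078, force=7.92),
        unloaded=BondLaw(0.168, 0.512, force=0.0),
    )


def ctmc_survival(
    k_full: float,
    k_half: float,
    k_unloaded: float,
    k_r: float,
    sharing: bool,
    initial_bonds: int,
    times: np.ndarray,
) -> np.ndarray:
    """Analytic survival of the memoryless (no-strengthening) dimer model.

    Independent of the simulator: a 3-state continuous-time Markov chain
    (2 bonds, 1 bond, detached) solved by matrix exponential.  With force
    sharing the 2->1 rate is 2 * k_half; without it, k_full + k_unloaded.
    """
    rate_21 = 2.0 * k_half if sharing else k_full + k_unloaded
    q = np.array(
        [
            [-rate_21, rate_21, 0.0],
            [k_r, -(k_r + k_full), k_full],
            [0.0, 0.0, 0.0],
        ]
    )
    p0 = np.array([1.0, 0.0, 0.0]) if initial_bonds == 2 else np.array([0.0, 1.0, 0.0])
    return np.array([1.0 - (p0 @ expm(q * t))[2] for t in np.asarray(times, float)])
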