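"""Shared fixtures: seeded simulator runs reused across test modules.

All randomness in the suite is seeded; simulations at the standard study
design (G = 10,000, 5 replicates) are session-scoped because they are the
expensive inputs to several independent checks.
"""

import numpy as np
import pytest

from fractionate import (
    SimConfig,
    SweepParams,
    calibrate,
    run_fractionation,
)


@pytest.fixture(scope="session")
def std_run_t5():
    """One (mu=1, nu=3) trajectory to t=5 at the standard design."""
    return run_fractionation(
        SweepParams(nu=3.0, mu=1.0), SimConfig(sweeps=5, replicates=5, seed=123)
    )


@pytest.fixture(scope="session")
def seeded_runs_t5():
    """Five independently seeded (mu=1, nu=3) trajectories to t=5."""
    return [
        run_fractionation(
            SweepParams(nu=3.0, mu=1.0),
            SimConfig(sweeps=5, replicates=5, seed=40 + s),
        )
        for s in range(5)
    ]


@pytest.fixture(scope="session")
def recalibrated_coeffs():
    """Coefficient set recalibrated from this package's own simulator."""
    return calibrate([0.1, 0.2, 1 / 3, 0.5], range(1, 8), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
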