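import numpy as np
import pytest

from ecfret import KineticScenario
from ecfret.simulate import (
    SPOT_ACCEPTOR_ONLY, SPOT_DONOR_ONLY, render_trace, simulate_state_path,
)
from ecfret.tracepipe import CorrectionFactors


def make_spot_traces(spot_class, n, scenario, rng, bleach_a=None):
    """Render n traces of one spot class under a scenario."""
    out = []
    for _ in range(n):
        truth = simulate_state_path(scenario, scenario.duration, rng,
                                    spot_class=spot_class)
        if bleach_a is not None:
            truth.bleach_time_a = bleach_a
        out.append(render_trace(truth, scenario, seed=rng))
    return out


@pytest.fixture(scope="session")
def cf_true():
    """Correction factors matching the default simulation scenario."""
    return CorrectionFactors(lk=0.10, dir=0.05)


@pytest.fixture(scope="session")
def apo_scenario():
    """No-ATP scenario: every doubly-labeled complex stays associated."""
    return KineticScenario(atp=0.0, frac_responsive=1.0, frac_inactive=0.0)


@pytest.fixture(scope="session")
def calibration_sets(apo_scenario):
    """(donor-only traces, acceptor-only traces) for correction estimation."""
    rng = np.random.default_rng(2024)
    donor = make_spot_traces(SPOT_DONOR_ONLY, 15, apo_scenario, rng)
    acceptor = make_spot_traces(SPOT_ACCEPTOR_ONLY, 15, apo_scenario, rng)
    return donor, acceptor
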