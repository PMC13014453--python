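import numpy as np
import pytest

from hbpmf import (
    PullingProtocol,
    ReplicateSet,
    ToyHBondPotential,
    WorkTrace,
    simulate_set,
)


@pytest.fixture(scope="session")
def protocol() -> PullingProtocol:
    return PullingProtocol()


@pytest.fixture(scope="session")
def binary_potential() -> ToyHBondPotential:
    return ToyHBondPotential()


@pytest.fixture(scope="session")
def ternary_potential() -> ToyHBondPotential:
    return ToyHBondPotential(shielding=0.6)


@pytest.fixture(scope="session")
def binary_set(binary_potential, protocol) -> ReplicateSet:
    """25 unshielded pulling replicates shared across tests."""
    return simulate_set(binary_potential, protocol, 25, 4200,
                        interaction_id="bond_A", condition="binary")


@pytest.fixture(scope="session")
def ternary_set(ternary_potential, protocol) -> ReplicateSet:
    return simulate_set(ternary_potential, protocol, 25, 8400,
                        interaction_id="bond_A", condition="ternary")


def make_trace(work, replicate_id=0, seed=0, target=None, cv=None) -> WorkTrace:
    """Hand-built trace helper: equally spaced time, nondecreasing target."""
    work = np.asarray(work, dtype=float)
    n = len(work)
    t = np.arange(n, dtype=float)
    target = np.linspace(2.5, 5.0, n) if target is None else np.asarray(target, float)
    cv = target.copy() if cv is None else np.asarray(cv, float)
    return WorkTrace(replicate_id=replicate_id, time=t, target=target,
                     cv_value=cv, work=work, seed=seed)
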