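import numpy as np
import pytest

from qspwm.receptor import (
    LigandSpec,
    PresynapticPhysiology,
    ReceptorPool,
    SynapseSimConfig,
)


@pytest.fixture(scope="session")
def simple_phys():
    return PresynapticPhysiology(r0=1.0, rmax=0.5, S=2.0, B0=0.5)


@pytest.fixture()
def coarse_synapse(simple_phys):
    """A small, fast synapse configuration for dynamics tests."""
    pools = [
        ReceptorPool("post", [LigandSpec("NT", "neurotransmitter", 1e-4, 100.0)]),
        ReceptorPool("auto", [LigandSpec("NT", "neurotransmitter", 1e-4, 150.0)]),
    ]
    return SynapseSimConfig(
        pools=pools,
        autoreceptor="auto",
        presyn=simple_phys,
        tonic_rate_hz=5.0,
        nt_halflife_ms=20.0,
        quantal_increment_nM=200.0,
        transient_s=1.0,
        averaging_s=2.0,
        dt_ms=0.02,
    )


@pytest.fixture(scope="session")
def fast_network_cfg():
    """Default network config (the calibrated healthy network)."""
    from qspwm.network import NetworkConfig

    return NetworkConfig()
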