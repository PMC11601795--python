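"""Shared fixtures: small geometries, parameter sets and short networks."""

import pytest

from myoflow import (ContractileParams, CouplingConfig, PassiveParams,
                     SignallingParams, VesselSpec, WallGeometry, WallModel,
                     attach_boundaries, build_symmetric_tree, default_network)
from myoflow.experiments import default_inlet_spec, make_signal


@pytest.fixture
def geom():
    """Reference wall geometry of the 135 um (load-free) root vessel."""
    return WallGeometry.from_load_free(135e-4, 0.30)


@pytest.fixture
def cp():
    return ContractileParams()


@pytest.fixture
def pp():
    return PassiveParams()


@pytest.fixture
def sig_params():
    return SignallingParams()


@pytest.fixture
def wall(geom, cp, pp):
    return WallModel(geom, cp, pp)


@pytest.fixture
def tree():
    """Default 4-generation symmetric network with the standard boundaries."""
    topo = default_network()
    signal = make_signal(default_inlet_spec(seed=3))
    attach_boundaries(topo, signal, Pout=50.0, P_ext=10.0)
    return topo, signal


@pytest.fixture
def single_vessel_topology():
    """A one-vessel 'network' builder with configurable boundaries."""

    def build(signal, n_elements=2, L=0.42, D_o=135.0, h_w=0.30,
              Pout=50.0, Z_mode="characteristic"):
        v = VesselSpec(generation="G0", L=L, D_o=D_o, h_w=h_w,
                       n_elements=n_elements)
        topo = build_symmetric_tree(v, generations=1)
        attach_boundaries(topo, signal, Pout=Pout, Z_mode=Z_mode)
        return topo

    return build


@pytest.fixture
def rigid_cfg():
    return CouplingConfig(mode="strong", dt=1e-4, rigid_walls=True)
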