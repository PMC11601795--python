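"""YAML (de)serialization of complete run configurations.

A run configuration bundles the network, the inlet signal specification, the
coupling settings and every parameter set.  Omitted sections fall back to
the package defaults, so a minimal file like

.. code-block:: yaml

    signal: {kind: periodic_variable_mean, seed: 1}
    coupling: {mode: weak, dt: 2.5e-4, averaged_active_stress: true}
    t_end: 10.0

runs the bundled symmetric tree with default physiology.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .coupling import CouplingConfig
from .errors import ConfigurationError
from .experiments import SignalSpec, make_signal
from .flow_solver import FluidProperties
from .network import (VesselSpec, attach_boundaries,
                      build_symmetric_tree, default_network)
from .signalling import LogisticLink, SignallingParams
from .wall_mechanics import ContractileParams, PassiveParams

__all__ = ["RunConfig", "load_config", "save_config", "build_run"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation."""

    signal: SignalSpec = field(
        default_factory=lambda: SignalSpec("periodic_variable_mean", {}, 0))
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    t_end: float = 10.0
    sample_dt: float = 1e-2
    Pout_mmHg: float = 50.0
    P_ext_mmHg: float = 10.0
    network: dict | None = None          # build_symmetric_tree kwargs or None
    signalling: SignallingParams = field(default_factory=SignallingParams)
    contractile: ContractileParams = field(default_factory=ContractileParams)
    passive: PassiveParams = field(default_factory=PassiveParams)
    fluid: FluidProperties = field(default_factory=FluidProperties)


def _dataclass_from(cls, payload: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "signal" in raw:
        s = dict(raw["signal"])
        cfg.signal = SignalSpec(kind=s.pop("kind"), seed=s.pop("seed", 0),
                                params=s.pop("params", s))
    if "coupling" in raw:
        cfg.coupling = _dataclass_from(CouplingConfig, raw["coupling"])
    if "signalling" in raw:
        s = dict(raw["signalling"])
        links = s.pop("link_table", None)
        if links is not None:
            s["link_table"] = {k: LogisticLink(**v) for k, v in links.items()}
        cfg.signalling = _dataclass_from(SignallingParams, s)
    if "contractile" in raw:
        cfg.contractile = _dataclass_from(ContractileParams, raw["contractile"])
    if "passive" in raw:
        cfg.passive = _dataclass_from(PassiveParams, raw["passive"])
    if "fluid" in raw:
        cfg.fluid = _dataclass_from(FluidProperties, raw["fluid"])
    cfg.network = raw.get("network")
    for key in ("t_end", "sample_dt", "Pout_mmHg", "P_ext_mmHg"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    return cfg


def save_config(cfg: RunConfig, path):
    payload = {
        "signal": {"kind": cfg.signal.kind, "seed": cfg.signal.seed,
                   "params": dict(cfg.signal.params)},
        "coupling": asdict(cfg.coupling),
        "signalling": {**asdict(cfg.signalling),
                       "link_table": {k: asdict(v) for k, v in
                                      cfg.signalling.link_table.items()}},
        "contractile": asdict(cfg.contractile),
        "passive": asdict(cfg.passive),
        "fluid": asdict(cfg.fluid),
        "t_end": cfg.t_end,
        "sample_dt": cfg.sample_dt,
        "Pout_mmHg": cfg.Pout_mmHg,
        "P_ext_mmHg": cfg.P_ext_mmHg,
        "network": cfg.network,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def build_run(cfg: RunConfig):
    """Materialize (topology, signal, kwargs) for coupling.run_simulation."""
    signal = make_signal(cfg.signal)
    if cfg.network is None:
        topo = default_network()
    else:
        net = dict(cfg.network)
        root = VesselSpec(**net.pop("root"))
        topo = build_symmetric_tree(root, **net)
    attach_boundaries(topo, signal, Pout=cfg.Pout_mmHg, P_ext=cfg.P_ext_mmHg)
    kwargs = dict(signalling=cfg.signalling, contractile=cfg.contractile,
                  passive=cfg.passive, props=cfg.fluid)
    return topo, signal, kwargs
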