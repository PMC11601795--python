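"""Vessel network topologies.

A network is a rooted binary tree of vessels.  Each vessel is described by
its stretched length L, load-free outer diameter D_o, thickness-to-mean-radius
ratio h_w and the number of axial elements of its 1-D discretization.  The
bundled idealized tree mimics a rat middle cerebral artery (G0) branching
symmetrically into three further generations: at every bifurcation the
daughter diameter follows from a parent/daughter area ratio of 1.35
(daughter D = parent D * sqrt(area_ratio/2)) and the wall thins along the
tree (h_w of G1..G3 at 90/80/70% of the G0 value).

Boundary conditions: a pressure signal at the root inlet, and at every
terminal a fixed outlet pressure behind a characteristic impedance Z that
absorbs outgoing waves.  Pressures at this interface are in mmHg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

from .errors import ConfigurationError
from .units import UM

__all__ = [
    "VesselSpec",
    "BoundaryAttachment",
    "NetworkTopology",
    "build_symmetric_tree",
    "attach_boundaries",
    "default_network",
    "DEFAULT_LENGTHS_CM",
]

#: Repository-default stretched lengths (cm) for generations G0..G3 of the
#: bundled symmetric tree.  These are plausible rat-MCA values chosen as
#: package defaults; any network-specific lengths should be supplied by the
#: user.
DEFAULT_LENGTHS_CM = (0.42, 0.26, 0.16, 0.10)

#: Default load-free outer diameter (um) and thickness ratio of the root
#: vessel (rat middle cerebral artery, control case).
DEFAULT_ROOT_DO_UM = 135.0
DEFAULT_ROOT_HW = 0.30


@dataclass
class VesselSpec:
    """One vessel segment.

    L in cm (stretched, i.e. including the axial pre-stretch), D_o the
    load-free outer diameter in micrometres, h_w the load-free
    thickness-to-mean-radius ratio.
    """

    generation: str
    L: float
    D_o: float
    h_w: float
    n_elements: int = 2

    def __post_init__(self):
        if not (self.L > 0 and self.D_o > 0):
            raise ConfigurationError("vessel length and diameter must be positive")
        if not (0.0 < self.h_w < 1.0):
            raise ConfigurationError("h_w must lie in (0, 1)")
        if self.n_elements < 1:
            raise ConfigurationError("each vessel needs at least one element")

    @property
    def D_o_cm(self) -> float:
        return self.D_o * UM


@dataclass
class BoundaryAttachment:
    """Inlet or outlet boundary condition of the fluid domain.

    kind: "inlet_pressure" (pressure signal, mmHg, callable of time) or
    "outlet_pressure_with_impedance" (fixed pressure P_mmHg behind an
    impedance Z, dyn s/cm^5; Z = 0 degrades to a plain pressure outlet;
    Z = None means "compute the characteristic impedance from the initial
    state").
    """

    kind: str
    signal: Callable[[float], float] | None = None
    P_mmHg: float | None = None
    Z: float | None = 0.0
    Z_mode: str = "fixed"  # "fixed" | "characteristic"

    def __post_init__(self):
        if self.kind not in ("inlet_pressure", "outlet_pressure_with_impedance"):
            raise ConfigurationError(f"unknown boundary kind {self.kind!r}")
        if self.Z is not None and self.Z < 0:
            raise ConfigurationError("impedance must be non-negative")


@dataclass
class NetworkTopology:
    """A tree of vessels with junctions and boundary attachments.

    junctions maps a parent vessel index to its two daughter indices.  Node
    numbering for the fluid solver: vessel v owns n_elements+1 consecutive
    nodes; junction continuity is imposed by extra equations, not by node
    sharing, so areas may jump across a bifurcation.
    """

    vessels: list[VesselSpec]
    junctions: dict[int, tuple[int, int]] = field(default_factory=dict)
    inlet: BoundaryAttachment | None = None
    outlets: dict[int, BoundaryAttachment] = field(default_factory=dict)
    P_ext_mmHg: float = 10.0

    # -- node numbering --------------------------------------------------
    @property
    def node_offsets(self) -> list[int]:
        off, acc = [], 0
        for v in self.vessels:
            off.append(acc)
            acc += v.n_elements + 1
        return off

    @property
    def n_nodes(self) -> int:
        return sum(v.n_elements + 1 for v in self.vessels)

    def first_node(self, v: int) -> int:
        return self.node_offsets[v]

    def last_node(self, v: int) -> int:
        return self.node_offsets[v] + self.vessels[v].n_elements

    def mid_node(self, v: int) -> int:
        """Interior node at the middle of the vessel's axial length."""
        return self.node_offsets[v] + self.vessels[v].n_elements // 2

    @property
    def terminals(self) -> list[int]:
        children = {d for ds in self.junctions.values() for d in ds}
        parents = set(self.junctions)
        return [i for i in range(len(self.vessels)) if i not in parents]

    @property
    def root(self) -> int:
        children = {d for ds in self.junctions.values() for d in ds}
        roots = [i for i in range(len(self.vessels)) if i not in children]
        if len(roots) != 1:
            raise ConfigurationError("network must have exactly one root vessel")
        return roots[0]

    def generations(self) -> dict[str, list[int]]:
        gens: dict[str, list[int]] = {}
        for i, v in enumerate(self.vessels):
            gens.setdefault(v.generation, []).append(i)
        return gens

    def validate(self):
        for j, (d1, d2) in self.junctions.items():
            for v in (j, d1, d2):
                if not 0 <= v < len(self.vessels):
                    raise ConfigurationError(f"junction references unknown vessel {v}")
        _ = self.root
        missing = [t for t in self.terminals if t not in self.outlets]
        if self.inlet is not None and missing:
            raise ConfigurationError(f"dangling terminals without outlet attachment: {missing}")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        """Topology (vessels + junctions + outlet settings) as JSON.

        Inlet signals are callables and are not serialized; re-attach them
        after ``from_json``.
        """
        payload = {
            "vessels": [asdict(v) for v in self.vessels],
            "junctions": {str(k): list(v) for k, v in self.junctions.items()},
            "P_ext_mmHg": self.P_ext_mmHg,
            "outlets": {
                str(k): {"P_mmHg": o.P_mmHg, "Z": o.Z, "Z_mode": o.Z_mode}
                for k, o in self.outlets.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkTopology":
        payload = json.loads(text)
        topo = cls(
            vessels=[VesselSpec(**v) for v in payload["vessels"]],
            junctions={int(k): tuple(v) for k, v in payload["junctions"].items()},
            P_ext_mmHg=payload.get("P_ext_mmHg", 10.0),
        )
        for k, o in payload.get("outlets", {}).items():
            topo.outlets[int(k)] = BoundaryAttachment(
                kind="outlet_pressure_with_impedance", **o
            )
        return topo


def build_symmetric_tree(root: VesselSpec, generations: int = 4,
                         area_ratio: float = 1.35,
                         hw_scaling=(0.9, 0.8, 0.7),
                         lengths=None) -> NetworkTopology:
    """Symmetric binary tree with generation-wise morphometric scaling.

    Daughter load-free diameters are parent * sqrt(area_ratio/2); h_w of
    generation g >= 1 is root.h_w * hw_scaling[g-1]; lengths per generation
    come from ``lengths`` (defaults to diameter-proportional scaling of the
    root length).  Generation g holds 2^g vessels, heap-ordered (daughters of
    vessel i are 2i+1 and 2i+2).
    """
    if generations < 1:
        raise ConfigurationError("need at least one generation")
    if not area_ratio > 0:
        raise ConfigurationError("area_ratio must be positive")
    ratio = (area_ratio / 2.0) ** 0.5
    vessels: list[VesselSpec] = []
    for g in range(generations):
        D = root.D_o * ratio**g
        if g == 0:
            hw = root.h_w
        else:
            hw = root.h_w * (hw_scaling[g - 1] if g - 1 < len(hw_scaling) else hw_scaling[-1])
        L = lengths[g] if lengths is not None else root.L * ratio**g
        for _ in range(2**g):
            vessels.append(VesselSpec(generation=f"G{g}", L=L, D_o=D, h_w=hw,
                                      n_elements=root.n_elements))
    junctions = {}
    for i in range(2 ** (generations - 1) - 1):
        junctions[i] = (2 * i + 1, 2 * i + 2)
    return NetworkTopology(vessels=vessels, junctions=junctions)


def attach_boundaries(topology: NetworkTopology, Pin_signal,
                      Pout: float = 50.0, Z_mode: str = "characteristic",
                      P_ext: float = 10.0) -> NetworkTopology:
    """Attach the inlet pressure signal and impedance-backed outlets.

    Pin_signal: callable t (s) -> pressure (mmHg).  Pout and P_ext in mmHg.
    Z_mode "characteristic" computes each terminal's characteristic impedance
    from the initial area/compliance at simulation start; "none" uses plain
    pressure outlets (Z = 0).
    """
    if Z_mode not in ("characteristic", "none"):
        raise ConfigurationError(f"unknown Z_mode {Z_mode!r}")
    topology.inlet = BoundaryAttachment(kind="inlet_pressure", signal=Pin_signal)
    for t in topology.terminals:
        topology.outlets[t] = BoundaryAttachment(
            kind="outlet_pressure_with_impedance",
            P_mmHg=Pout,
            Z=None if Z_mode == "characteristic" else 0.0,
            Z_mode=Z_mode if Z_mode == "characteristic" else "fixed",
        )
    topology.P_ext_mmHg = P_ext
    topology.validate()
    return topology


def default_network(n_elements: int = 2) -> NetworkTopology:
    """The bundled 4-generation symmetric cerebral tree (no boundaries yet)."""
    root = VesselSpec(generation="G0", L=DEFAULT_LENGTHS_CM[0],
                      D_o=DEFAULT_ROOT_DO_UM, h_w=DEFAULT_ROOT_HW,
                      n_elements=n_elements)
    return build_symmetric_tree(root, generations=4, lengths=DEFAULT_LENGTHS_CM)
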