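"""Fluid-structure coupling and full-simulation driver.

One time step couples three sub-solves at every network node:

1. the global linear fluid solve (new P, Q with wall areas/compliances frozen
   at the current iterate),
2. the signalling update (driven by the freshly solved luminal pressure),
3. the wall solve (new sliding and area per node) and compliance update.

``strong`` mode repeats this sequence as a fixed-point iteration until the
root-mean-square relative change of the luminal areas across the whole
network falls below the tolerance epsilon (1e-6 by default); ``weak`` mode
performs exactly one pass.  Each iteration restarts the signalling and wall
updates from the stored time-level-n states, so the converged step is
self-consistent rather than accumulated.

The driver records probe time series (default: the node at the middle of the
axial length of the first vessel of each generation) on a fixed sampling
grid and returns them as a pandas DataFrame along with run metadata.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StepError
from .flow_solver import FluidProperties, FluidState, FlowSolver
from .network import NetworkTopology
from .signalling import SignallingParams, SignallingState, step_signalling
from .units import MMHG
from .wall_mechanics import ContractileParams, PassiveParams, WallGeometry, WallModel

__all__ = [
    "CouplingConfig",
    "SimulationRecord",
    "Simulator",
    "rmsre",
    "advance_step",
    "run_simulation",
]


@dataclass(frozen=True)
class CouplingConfig:
    """Numerical settings of one simulation.

    mode: "strong" (fixed-point iteration to area tolerance epsilon) or
    "weak" (single sequential pass).  averaged_active_stress selects the
    two-unknown wall variant.  rigid_walls freezes the areas entirely
    (C_A = 0), mainly for verification against algebraic network solutions.
    """

    mode: str = "strong"
    epsilon: float = 1e-6
    max_iters: int = 50
    dt: float = 2.5e-4
    averaged_active_stress: bool = False
    rigid_walls: bool = False

    def __post_init__(self):
        if self.mode not in ("strong", "weak"):
            raise ConfigurationError(f"unknown coupling mode {self.mode!r}")
        if not self.epsilon > 0:
            raise ConfigurationError("epsilon must be positive")
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be >= 1")
        if not self.dt > 0:
            raise ConfigurationError("dt must be positive")


def rmsre(values, reference):
    """Root mean square relative error sqrt(mean(((v - r)/r)^2))."""
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if values.shape != reference.shape:
        raise ConfigurationError("rmsre operands must have equal shapes")
    if np.any(reference == 0.0):
        raise ConfigurationError("rmsre reference contains zero entries")
    return float(np.sqrt(np.mean(((values - reference) / reference) ** 2)))


@dataclass
class SimulationRecord:
    """Probe time series (DataFrame indexed by time) plus run metadata."""

    data: pd.DataFrame
    meta: dict

    def to_csv(self, path):
        self.data.to_csv(path, index_label="t")

    def meta_json(self) -> str:
        return json.dumps(self.meta, indent=2, default=str)


class Simulator:
    """Time-marching driver for one network simulation.

    Builds the flow solver, the per-node wall model and the signalling state
    from a topology with attached boundaries, then advances with
    ``advance_step`` / ``run``.
    """

    def __init__(self, topology: NetworkTopology, config: CouplingConfig,
                 signal, *,
                 signalling: SignallingParams | None = None,
                 contractile: ContractileParams | None = None,
                 passive: PassiveParams | None = None,
                 props: FluidProperties | None = None,
                 n_CL: int = 5,
                 probes=None):
        topology.validate()
        self.topo = topology
        self.config = config
        self.signal = signal
        self.sig_params = signalling or SignallingParams()
        self.cp = contractile or ContractileParams()
        pp = passive or PassiveParams()
        # the network's external pressure overrides the parameter-set default
        self.pp = replace(pp, P_ext=topology.P_ext_mmHg * MMHG)
        self.props = props or FluidProperties()
        self.flow = FlowSolver(topology, self.props)

        geoms = []
        for v in topology.vessels:
            g = WallGeometry.from_load_free(v.D_o_cm, v.h_w, n_CL=n_CL)
            geoms.extend([g] * (v.n_elements + 1))
        self.wall = WallModel(geoms, self.cp, self.pp,
                              averaged=config.averaged_active_stress)

        if probes is None:
            probes = [(gen, idx[0]) for gen, idx in sorted(topology.generations().items())]
        self.probes = [(label, topology.mid_node(v)) for label, v in probes]

        self.reset()

    # -- state ------------------------------------------------------------
    def reset(self):
        """(Re)initialize: P = first inlet value, Q = 0, wall at reference."""
        p0 = float(self.signal(0.0)) * MMHG
        self.wall_state = self.wall.initial_state()
        if self.config.rigid_walls:
            self.wall_state.C_A = np.zeros_like(self.wall_state.C_A)
        self.sig = SignallingState.zeros(self.wall.n_nodes)
        self.fluid = FluidState(
            P=np.full(self.flow.N, p0),
            Q=np.zeros(self.flow.N),
            A=self.wall_state.A.copy(),
            C_A=self.wall_state.C_A.copy(),
            startup=True,
        )
        if self.config.rigid_walls:
            for att in self.topo.outlets.values():
                if att.Z is None:
                    att.Z = 0.0
                    att.Z_mode = "fixed"
            self.flow.Z = np.where(np.isfinite(self.flow.Z), self.flow.Z, 0.0)
            self.flow._fill_constant_rows()
        else:
            self.flow.set_impedances(self.fluid.A, self.fluid.C_A)
        self.t = 0.0
        self.step_count = 0
        self.last_iters = 0
        self.last_rmsre = 0.0
        self.max_iters_seen = 0

    # -- single step -------------------------------------------------------
    def advance_step(self):
        """Advance one time step; returns (iterations, final area RMSRE)."""
        cfg = self.config
        dt = cfg.dt
        t_next = self.t + dt
        p_in = float(self.signal(t_next)) * MMHG

        base_wall = self.wall_state
        base_sig = self.sig
        A_k = base_wall.A
        C_k = base_wall.C_A

        errs = []
        growth = 0
        sig_new, wall_new = base_sig, base_wall
        for k in range(cfg.max_iters):
            P_new, Q_new = self.flow.solve_step(self.fluid, A_k, C_k, dt, p_in)
            if cfg.rigid_walls:
                err = 0.0
                errs.append(err)
                break
            sig_new = step_signalling(base_sig, P_new / MMHG, dt, self.sig_params)
            wall_new = self.wall.step(P_new, base_wall,
                                      sig_new.xi[..., 5], sig_new.xi7, dt)
            err = rmsre(wall_new.A, A_k)
            errs.append(err)
            A_k, C_k = wall_new.A, wall_new.C_A
            if cfg.mode == "weak" or err < cfg.epsilon:
                break
            if len(errs) >= 2 and errs[-1] > errs[-2]:
                growth += 1
                if growth >= 10:
                    raise StepError(
                        "coupling iteration diverging (RMSRE grew over 10 "
                        f"consecutive iterations, last {err:.3e})",
                        residual_norms=errs[-10:], time=t_next,
                    )
            else:
                growth = 0
        else:
            raise StepError(
                f"fixed-point coupling did not reach epsilon={cfg.epsilon:g} "
                f"in {cfg.max_iters} iterations (last RMSRE {errs[-1]:.3e})",
                residual_norms=errs[-3:], time=t_next,
            )

        # commit
        self.fluid.P_prev = self.fluid.P
        self.fluid.Q_prev = self.fluid.Q
        self.fluid.P = P_new
        self.fluid.Q = Q_new
        self.fluid.A = A_k
        self.fluid.C_A = C_k
        self.fluid.startup = False
        if not cfg.rigid_walls:
            self.wall_state = wall_new
            self.sig = sig_new
        self.t = t_next
        self.step_count += 1
        self.last_iters = len(errs)
        self.last_rmsre = errs[-1]
        self.max_iters_seen = max(self.max_iters_seen, len(errs))
        return len(errs), errs[-1]

    # -- probe sampling ----------------------------------------------------
    def _sample(self):
        row = {}
        d_i, d_o = (None, None)
        if not self.config.rigid_walls:
            d_i, d_o = self.wall.radii(self.wall_state)
        for label, node in self.probes:
            row[f"{label}:P"] = self.fluid.P[node] / MMHG
            row[f"{label}:Q"] = self.fluid.Q[node]
            row[f"{label}:A"] = self.fluid.A[node]
            if d_i is not None:
                row[f"{label}:d_i"] = d_i[node]
                row[f"{label}:d_o"] = d_o[node]
                row[f"{label}:u_fs"] = self.wall_state.u_fs[node].mean()
                row[f"{label}:xi0"] = self.sig.xi[node, 0]
                row[f"{label}:xi5"] = self.sig.xi[node, 5]
                row[f"{label}:xi6"] = self.sig.xi[node, 6]
        row["coupling_iters"] = self.last_iters
        row["coupling_rmsre"] = self.last_rmsre
        return row

    # -- full run ----------------------------------------------------------
    def run(self, t_end: float, sample_dt: float = 1e-2) -> SimulationRecord:
        """March from the current time to t_end, sampling every sample_dt."""
        dt = self.config.dt
        stride = max(1, round(sample_dt / dt))
        if abs(stride * dt - sample_dt) > 1e-9 * sample_dt:
            raise ConfigurationError("sample_dt must be an integer multiple of dt")
        n_steps = round((t_end - self.t) / dt)
        t0 = time.perf_counter()
        times = [self.t]
        rows = [self._sample()]
        for i in range(n_steps):
            self.advance_step()
            if (i + 1) % stride == 0:
                times.append(self.t)
                rows.append(self._sample())
        wct = time.perf_counter() - t0
        data = pd.DataFrame(rows, index=pd.Index(np.asarray(times), name="t"))
        meta = {
            "dt": dt,
            "mode": self.config.mode,
            "averaged_active_stress": self.config.averaged_active_stress,
            "rigid_walls": self.config.rigid_walls,
            "epsilon": self.config.epsilon,
            "t_end": t_end,
            "sample_dt": sample_dt,
            "n_steps": n_steps,
            "max_coupling_iters": self.max_iters_seen,
            "wall_clock_s": wct,
            "topology_sha1": hashlib.sha1(
                self.topo.to_json().encode()).hexdigest(),
            "signal_seed": getattr(self.signal, "seed", None),
            "versions": _versions(),
        }
        return SimulationRecord(data=data, meta=meta)


def _versions():
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}


def advance_step(sim: Simulator):
    """Advance one coupled step (functional wrapper over Simulator)."""
    return sim.advance_step()


def run_simulation(topology: NetworkTopology, config: CouplingConfig, signal,
                   t_end: float, sample_dt: float = 1e-2,
                   **kwargs) -> SimulationRecord:
    """Build a Simulator and run it from t = 0 to t_end."""
    sim = Simulator(topology, config, signal, **kwargs)
    return sim.run(t_end, sample_dt=sample_dt)
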