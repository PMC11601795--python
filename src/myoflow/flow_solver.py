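"""Linearized 1-D pressure-flow solver for compliant vessel networks.

Mass and momentum conservation for laminar axisymmetric flow with a
Poiseuille profile, written in pressure-flow form,

    C_A dP/dt + dQ/dz = 0,
    (rho/A) dQ/dt + (rho/A) d/dz(Q^2/A) + dP/dz + 8 pi mu Q / A^2 = 0,

are linearized about the previous time level: the compliance C_A and area A
multiplying the time derivatives are frozen at their current coupling
iterate, the convective term is evaluated fully at the previous step, and
the viscous drag uses the frozen area but the new flow (taking the drag
explicitly is unconditionally unstable at the calibers and time steps this
solver targets, since dt * 8 pi mu / (rho A) routinely exceeds the explicit
stability bound in 30-100 um lumens).

Each vessel is split into two-node elements; the equations are integrated
over each element with the trapezoidal rule and discretized in time with
second-order backward differences (backward Euler on the startup step).
Element contributions, junction conditions (static pressure continuity +
mass conservation) and boundary rows (inlet pressure; terminal
pressure-behind-impedance P - Z Q = P_out) assemble into one global linear
system per step, solved by a direct method — dense LAPACK for small systems,
sparse LU above ~600 unknowns.  Unknowns are column-scaled (pressure/flow)
and rows are equilibrated before the solve to tame the CGS spread of
magnitudes.

All quantities here are CGS: pressure dyn/cm^2, flow ml/s, area cm^2,
compliance cm^2/(dyn/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import AssemblyError, ConfigurationError
from .network import BoundaryAttachment, NetworkTopology  # noqa: F401  (re-export)
from .units import MMHG

__all__ = [
    "FluidProperties",
    "FluidState",
    "ElementSystem",
    "BoundaryAttachment",
    "element_matrices",
    "FlowSolver",
    "assemble_and_solve",
    "characteristic_impedance",
]

#: above this many unknowns the assembled system is solved with sparse LU
DENSE_LIMIT = 600


@dataclass(frozen=True)
class FluidProperties:
    """Blood density (g/cm^3) and dynamic viscosity (poise)."""

    rho: float = 1.04
    mu: float = 0.05


@dataclass
class FluidState:
    """Nodal fields at one time level plus the previous level for BDF2."""

    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray
    C_A: np.ndarray
    P_prev: np.ndarray | None = None
    Q_prev: np.ndarray | None = None
    startup: bool = True

    def copy(self) -> "FluidState":
        return FluidState(
            P=self.P.copy(), Q=self.Q.copy(), A=self.A.copy(), C_A=self.C_A.copy(),
            P_prev=None if self.P_prev is None else self.P_prev.copy(),
            Q_prev=None if self.Q_prev is None else self.Q_prev.copy(),
            startup=self.startup,
        )


@dataclass
class ElementSystem:
    """2x2 element matrices and right-hand side: F_e P + G_e Q = h_e."""

    F_e: np.ndarray
    G_e: np.ndarray
    h_e: np.ndarray


def element_matrices(P_n, Q_n, A_n, C_A_n, length: float, dt: float,
                     props: FluidProperties, P_nm1=None, Q_nm1=None,
                     startup: bool = True) -> ElementSystem:
    """Element system for one two-node element (rows: mass, momentum).

    Nodal arrays are length-2 (element endpoints).  The convective term sits
    in h_e at the previous step; viscous drag is implicit in Q^{n+1} (frozen
    area), so it contributes to G_e rather than h_e.
    """
    if not length > 0:
        raise ConfigurationError("element length must be positive")
    A_n = np.asarray(A_n, dtype=float)
    if np.any(A_n <= 0):
        raise AssemblyError("zero or negative luminal area in element")
    P_n = np.asarray(P_n, dtype=float)
    Q_n = np.asarray(Q_n, dtype=float)
    C_A_n = np.asarray(C_A_n, dtype=float)
    if startup or P_nm1 is None:
        beta = 1.0 / dt
        gam_p = P_n / dt
        gam_q = Q_n / dt
    else:
        beta = 1.5 / dt
        gam_p = (4.0 * P_n - np.asarray(P_nm1, dtype=float)) / (2.0 * dt)
        gam_q = (4.0 * Q_n - np.asarray(Q_nm1, dtype=float)) / (2.0 * dt)

    half = 0.5 * length
    F_e = np.zeros((2, 2))
    G_e = np.zeros((2, 2))
    h_e = np.zeros(2)

    # mass row
    F_e[0, :] = half * C_A_n * beta
    G_e[0, 0] = -1.0
    G_e[0, 1] = 1.0
    h_e[0] = half * (C_A_n * gam_p).sum()

    # momentum row
    fric = 8.0 * np.pi * props.mu / A_n**2
    rhoA = props.rho / A_n
    F_e[1, 0] = -1.0
    F_e[1, 1] = 1.0
    G_e[1, :] = half * (rhoA * beta + fric)
    mom = Q_n**2 / A_n
    conv = 0.5 * props.rho * (1.0 / A_n).sum() * (mom[1] - mom[0])
    h_e[1] = half * (rhoA * gam_q).sum() - conv
    return ElementSystem(F_e=F_e, G_e=G_e, h_e=h_e)


def characteristic_impedance(A, C_A, rho: float):
    """Z = rho c / A with pulse wave speed c = sqrt(A / (rho C_A))."""
    A = np.asarray(A, dtype=float)
    C_A = np.asarray(C_A, dtype=float)
    if np.any(A <= 0):
        raise ConfigurationError("area must be positive")
    if np.any(C_A <= 0):
        raise ConfigurationError("non-physical compliance (C_A <= 0)")
    c = np.sqrt(A / (rho * C_A))
    return rho * c / A


class FlowSolver:
    """Assembles and solves the global linear system for one network.

    The sparsity pattern, node numbering and constraint rows are precomputed
    from the topology; per step only the element values and the inlet value
    change.  Terminal impedances are set once via ``set_impedances`` (from
    the initial state when the attachment requests its characteristic value).
    """

    def __init__(self, topology: NetworkTopology, props: FluidProperties | None = None):
        topology.validate()
        if topology.inlet is None:
            raise AssemblyError("network has no inlet attachment")
        self.topo = topology
        self.props = props or FluidProperties()
        self.N = topology.n_nodes

        # elements: (node_a, node_b, length)
        na, nb, lengths = [], [], []
        for vi, v in enumerate(topology.vessels):
            off = topology.node_offsets[vi]
            dz = v.L / v.n_elements
            for e in range(v.n_elements):
                na.append(off + e)
                nb.append(off + e + 1)
                lengths.append(dz)
        self.el_a = np.asarray(na)
        self.el_b = np.asarray(nb)
        self.el_len = np.asarray(lengths)
        self.n_el = len(na)

        self.inlet_node = topology.first_node(topology.root)
        self.term_nodes = np.asarray([topology.last_node(t) for t in topology.terminals])
        self.term_vessels = list(topology.terminals)
        self.Pout = np.asarray([topology.outlets[t].P_mmHg * MMHG
                                for t in topology.terminals])
        self.Z = np.asarray([topology.outlets[t].Z if topology.outlets[t].Z is not None
                             else np.nan for t in topology.terminals])

        self._build_pattern()

    # -- impedances -------------------------------------------------------
    def set_impedances(self, A0, C_A0):
        """Resolve 'characteristic' terminal impedances from the initial state."""
        for k, t in enumerate(self.term_vessels):
            att = self.topo.outlets[t]
            if att.Z_mode == "characteristic" or att.Z is None:
                node = self.term_nodes[k]
                z = float(characteristic_impedance(A0[node], C_A0[node], self.props.rho))
                self.Z[k] = z
                att.Z = z
        self._fill_constant_rows()

    # -- assembly pattern --------------------------------------------------
    def _build_pattern(self):
        N = self.N
        rows, cols = [], []
        # element rows: 2 per element, 4 entries each
        for e in range(self.n_el):
            a, b = self.el_a[e], self.el_b[e]
            r = 2 * e
            rows += [r, r, r, r]
            cols += [a, b, N + a, N + b]            # mass: P_a P_b Q_a Q_b
            rows += [r + 1] * 4
            cols += [a, b, N + a, N + b]            # momentum
        self._n_dyn_rows = 2 * self.n_el
        r = self._n_dyn_rows
        const_rows, const_cols, const_vals = [], [], []
        for j, (d1, d2) in self.topo.junctions.items():
            pj = self.topo.last_node(j)
            s1 = self.topo.first_node(d1)
            s2 = self.topo.first_node(d2)
            const_rows += [r, r];       const_cols += [pj, s1];  const_vals += [1.0, -1.0]
            const_rows += [r + 1, r + 1]; const_cols += [pj, s2]; const_vals += [1.0, -1.0]
            const_rows += [r + 2, r + 2, r + 2]
            const_cols += [N + pj, N + s1, N + s2]
            const_vals += [1.0, -1.0, -1.0]
            r += 3
        self.inlet_row = r
        const_rows.append(r); const_cols.append(self.inlet_node); const_vals.append(1.0)
        r += 1
        self.outlet_rows = []
        for k in range(len(self.term_nodes)):
            node = self.term_nodes[k]
            const_rows += [r, r]
            const_cols += [node, N + node]
            const_vals += [1.0, np.nan]             # -Z, filled by set_impedances
            self.outlet_rows.append(r)
            r += 1
        if r != 2 * N:
            raise AssemblyError(
                f"system not square: {r} equations for {2 * N} unknowns "
                "(unconstrained or over-constrained nodes)"
            )
        self._const = (np.asarray(const_rows), np.asarray(const_cols),
                       np.asarray(const_vals))
        self._el_rows = np.asarray(rows)
        self._el_cols = np.asarray(cols)
        self._dense = 2 * N <= DENSE_LIMIT
        if self._dense:
            self._template = np.zeros((2 * N, 2 * N))
            self._el_flat = self._el_rows * 2 * N + self._el_cols
        self._fill_constant_rows()

    def _fill_constant_rows(self):
        cr, cc, cv = self._const
        cv = cv.copy()
        # impedance entries are the (P, -Z Q) pairs of the outlet rows
        zi = np.where(np.isnan(self._const[2]))[0]
        for k, idx in enumerate(zi):
            cv[idx] = -self.Z[k] if np.isfinite(self.Z[k]) else 0.0
        self._const_vals = cv
        if self._dense:
            self._template[:] = 0.0
            self._template[cr, cc] = cv

    # -- element values ----------------------------------------------------
    def _element_values(self, state: FluidState, A, C_A, dt: float):
        """Per-element matrix entries and rhs, vectorized over elements."""
        a, b = self.el_a, self.el_b
        if state.startup or state.P_prev is None:
            beta = 1.0 / dt
            gam_p = state.P / dt
            gam_q = state.Q / dt
        else:
            beta = 1.5 / dt
            gam_p = (4.0 * state.P - state.P_prev) / (2.0 * dt)
            gam_q = (4.0 * state.Q - state.Q_prev) / (2.0 * dt)
        if np.any(A <= 0):
            raise AssemblyError("zero or negative luminal area")
        half = 0.5 * self.el_len
        rho, mu = self.props.rho, self.props.mu

        Ca, Cb = C_A[a], C_A[b]
        Aa, Ab = A[a], A[b]
        mass = np.empty((self.n_el, 4))
        mass[:, 0] = half * Ca * beta
        mass[:, 1] = half * Cb * beta
        mass[:, 2] = -1.0
        mass[:, 3] = 1.0
        rhs_mass = half * (Ca * gam_p[a] + Cb * gam_p[b])

        fric_a = 8.0 * np.pi * mu / Aa**2
        fric_b = 8.0 * np.pi * mu / Ab**2
        mom = np.empty((self.n_el, 4))
        mom[:, 0] = -1.0
        mom[:, 1] = 1.0
        mom[:, 2] = half * (rho / Aa * beta + fric_a)
        mom[:, 3] = half * (rho / Ab * beta + fric_b)
        qa, qb = state.Q[a], state.Q[b]
        conv = 0.5 * rho * (1.0 / Aa + 1.0 / Ab) * (qb**2 / Ab - qa**2 / Aa)
        rhs_mom = half * (rho / Aa * gam_q[a] + rho / Ab * gam_q[b]) - conv
        return mass, mom, rhs_mass, rhs_mom

    # -- solve -------------------------------------------------------------
    def solve_step(self, state: FluidState, A, C_A, dt: float, p_in: float):
        """One linear solve: new (P, Q) given the frozen-coefficient state.

        ``state`` carries levels n and n-1; A/C_A are the current coupling
        iterate; p_in is the inlet pressure at t^{n+1} in dyn/cm^2.
        Returns (P_new, Q_new).
        """
        if np.isnan(self.Z).any():
            raise AssemblyError("terminal impedances unset; call set_impedances first")
        N = self.N
        mass, mom, rhs_mass, rhs_mom = self._element_values(state, A, C_A, dt)
        b = np.zeros(2 * N)
        b[0:self._n_dyn_rows:2] = rhs_mass
        b[1:self._n_dyn_rows:2] = rhs_mom
        b[self.inlet_row] = p_in
        b[self.outlet_rows] = self.Pout

        el_vals = np.empty(self.n_el * 8)
        el_vals[0::8], el_vals[1::8], el_vals[2::8], el_vals[3::8] = mass.T
        el_vals[4::8], el_vals[5::8], el_vals[6::8], el_vals[7::8] = mom.T

        # column scaling (pressure / flow) + row equilibration
        p_scale, q_scale = 100.0 * MMHG, 1e-3
        col_scale = np.concatenate([np.full(N, p_scale), np.full(N, q_scale)])

        if self._dense:
            M = self._template.copy()
            M.flat[self._el_flat] = el_vals
            M *= col_scale[None, :]
            row_norm = np.abs(M).max(axis=1)
            if np.any(row_norm == 0.0):
                raise AssemblyError("singular global system (empty row)")
            M /= row_norm[:, None]
            try:
                y = np.linalg.solve(M, b / row_norm)
            except np.linalg.LinAlgError as exc:
                raise AssemblyError(f"singular global system: {exc}") from exc
        else:
            cr, cc, cv = self._const
            rows = np.concatenate([self._el_rows, cr])
            cols = np.concatenate([self._el_cols, cc])
            vals = np.concatenate([el_vals, self._const_vals])
            M = sp.csr_matrix((vals * col_scale[cols], (rows, cols)), shape=(2 * N, 2 * N))
            row_norm = np.abs(M).max(axis=1).toarray().ravel()
            if np.any(row_norm == 0.0):
                raise AssemblyError("singular global system (empty row)")
            D = sp.diags(1.0 / row_norm)
            y = spla.spsolve((D @ M).tocsc(), b / row_norm)
        x = col_scale * y
        P_new, Q_new = x[:N], x[N:]
        if not np.all(np.isfinite(P_new)) or not np.all(np.isfinite(Q_new)):
            raise AssemblyError("non-finite fluid solution")
        return P_new, Q_new

    # -- diagnostics -------------------------------------------------------
    def junction_imbalance(self, Q):
        """|Q_parent - Q_d1 - Q_d2| at every junction (ml/s)."""
        out = []
        for j, (d1, d2) in self.topo.junctions.items():
            out.append(abs(Q[self.topo.last_node(j)]
                           - Q[self.topo.first_node(d1)]
                           - Q[self.topo.first_node(d2)]))
        return np.asarray(out)


def assemble_and_solve(state: FluidState, topology: NetworkTopology, dt: float,
                       p_in_mmHg: float, props: FluidProperties | None = None):
    """One-shot convenience wrapper: build a solver, solve one step.

    Terminal impedances must be resolvable (fixed Z on the attachments).
    Returns (P_new, Q_new) in CGS.
    """
    solver = FlowSolver(topology, props)
    solver.set_impedances(state.A, state.C_A)
    return solver.solve_step(state, state.A, state.C_A, dt, p_in_mmHg * MMHG)
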