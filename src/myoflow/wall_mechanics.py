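"""Chemo-mechanical model of the myogenically active arterial wall.

The wall is an axisymmetric, incompressible, hyperelastic thick-walled tube
whose volume is occupied by circumferentially aligned smooth muscle cells
(SMCs).  The thickness is split into ``n_CL`` concentric SMC layers; the
transmural radial momentum balance

    P = P_ext + int_{Ri}^{Ri+H} (lam_t dPsi/dlam_t - lam_r dPsi/dlam_r)
                                 dR / (lam_t lam_z r)

links luminal pressure P to the stretch state of every layer.  The strain
energy Psi = Psi_p + Psi_a has a passive neo-Hookean + exponential
collagen-fibre part and an active part generated by contractile fibres (CFs):
chains of N_CU contractile units (CUs, actin-myosin overlap regions) in
series, anchored to the actin cortex at both ends.  Cycling phosphorylated
cross-bridges (XBs) produce a driving force Fc and an attachment stiffness
k_tCU, both proportional to the filament overlap (a Gaussian in the
normalized relative filament sliding u_fs) and to the LC20 phosphorylation
level xi5.  The cortex stiffness k_AC follows a Hill curve in the F-actin
content xi7 = 1 - xi6.  The relative sliding of each layer evolves as

    d(u_fs)/dt = (Fa - Fc)/tau_m + (1/(2 N_CU)) d(lam_t)/dt,

so tone builds where cycling XBs out-pull the elastic reaction Fa of the
CU/cortex series arrangement.

Everything here is expressed in CGS units (cm, s, dyn); pressures cross this
module's boundary in dyn/cm^2 (converted from mmHg by the caller).  All
functions broadcast over a leading node axis so a whole network of wall
cross-sections is advanced in one call.

Time discretization: two-step backward differences (backward Euler on the
startup step) on both d(u_fs)/dt and d(lam_t)/dt; the resulting nonlinear
residual system (one sliding equation per layer plus the pressure balance) is
solved by a damped Newton iteration with an arrowhead-structured Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError, StepError
from .units import MMHG

__all__ = [
    "WallGeometry",
    "ContractileParams",
    "PassiveParams",
    "WallState",
    "WallModel",
    "filament_overlap",
    "contractile_system",
    "series_stiffness",
    "kinematics",
    "strain_energy",
    "strain_energy_derivatives",
    "transmural_pressure",
    "wall_residuals",
    "step_wall",
    "U_FS_INIT",
]

#: standard initial relative filament sliding
U_FS_INIT = -2e-2

#: pressure perturbation (dyn/cm^2) targeted by the centered compliance difference
COMPLIANCE_DP = 0.1 * MMHG


# ----------------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class WallGeometry:
    """Reference (load-free) geometry of one vessel wall cross-section.

    Ri and H are the reference luminal radius and wall thickness (cm),
    k_omega the residual-strain opening parameter, lambda_z the axial
    pre-stretch and n_CL the (odd) number of SMC layers, which doubles as the
    number of Simpson integration points across the thickness.
    """

    Ri: float
    H: float
    k_omega: float = 1.0
    lambda_z: float = 1.0
    n_CL: int = 5

    def __post_init__(self):
        if not (self.Ri > 0 and self.H > 0):
            raise ConfigurationError("Ri and H must be positive")
        if not (self.k_omega > 0 and self.lambda_z > 0):
            raise ConfigurationError("k_omega and lambda_z must be positive")
        if self.n_CL < 1 or self.n_CL % 2 == 0:
            raise ConfigurationError("n_CL must be odd (Simpson integration)")

    @classmethod
    def from_load_free(cls, D_o: float, h_w: float, **kwargs) -> "WallGeometry":
        """Build the reference geometry from load-free morphometry.

        D_o is the load-free outer diameter (cm) and h_w the ratio of wall
        thickness to mean radius in the load-free state.  With the default
        k_omega = lambda_z = 1 the load-free configuration is the stress-free
        reference, which gives the closed form
        R_mean = (D_o/2)/(1 + h_w/2), H = h_w R_mean, Ri = R_mean - H/2.
        """
        if not (0.0 < h_w < 1.0):
            raise ConfigurationError("h_w must lie in (0, 1)")
        r_mean = 0.5 * D_o / (1.0 + 0.5 * h_w)
        H = h_w * r_mean
        return cls(Ri=r_mean - 0.5 * H, H=H, **kwargs)


@dataclass(frozen=True)
class ContractileParams:
    """Microstructural parameters of the contractile machinery (CGS).

    Displacements of the contractile unit (the sliding u_fs, its optimum and
    the power-stroke u_PS) are normalized by the myosin filament length, so
    k_XB is a force per unit normalized elongation and forces stay in dyn.
    The defaults are documented repository values chosen once to produce
    realistic myogenic tone over 10-120 mmHg for ~100 um cerebral vessels
    (see docs/methods.md): the steady active first Piola-Kirchhoff stress is
    N_CF * Fc <= N_CF (L_m/delta_m) n_XB_max k_XB u_PS ~ 4.2e5 dyn/cm^2 and
    the active stiffness N_CF * k_ser is of the same order, which puts the
    equilibrium elastic elongation of a contractile fibre at a few tens of
    percent — the scale of the standard initial sliding (-2e-2 over 2 N_CU).
    """

    L_m: float = 2.2e-4        # myosin filament length (cm)
    delta_m: float = 1.43e-6   # myosin monomer head spacing (cm)
    n_XB_max: float = 1.0      # max phosphorylation rate (normalized)
    k_XB: float = 0.4          # cross-bridge stiffness (dyn per unit sliding)
    u_PS: float = 4.5e-3       # power-stroke displacement (normalized by L_m)
    N_CU: float = 10.0         # contractile units in series per fibre
    s_f0: float = 4.4e-5       # overlap width parameter (cm); s_f0/L_m = 0.2
    u_fs_opt: float = 0.01     # sliding of optimal filament overlap
    N_CF: float = 1.5e6        # surface density of contractile fibres (1/cm^2)
    k_AC_max: float = 2.0      # max actin-cortex stiffness (dyn/cm)
    n_AC: float = 2.0          # cortex Hill coefficient
    K_AC: float = 0.25         # cortex half-activation (F-actin level)
    tau_m: float = 6.188e-2    # filament-sliding time constant (s)

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"contractile parameter {name} must be positive")


@dataclass(frozen=True)
class PassiveParams:
    """Passive constitutive parameters of the media and external pressure.

    Psi_p = c0 (I1 - 3) + c1/(2 c2) (exp[c2 (I4 - 1)^2] - 1) with the collagen
    family at angle phi from the circumferential direction (phi = 0 default).
    P_ext is in dyn/cm^2 (10 mmHg default).
    """

    c0: float = 2.0e4
    c1: float = 2.0e4
    c2: float = 8.0
    phi: float = 0.0
    P_ext: float = 10.0 * MMHG

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0 or self.c2 < 0:
            raise ConfigurationError("c0, c1, c2 must be non-negative")


@dataclass
class WallState:
    """State of one or many wall cross-sections, vectorized over nodes.

    u_fs and lambda_theta have shape (n_nodes, n_dyn) where n_dyn = n_CL for
    the layer-resolved model and 1 for the averaged-active-stress variant (in
    which case lambda_theta holds the thickness-averaged stretch).  The
    *_old copies hold the previous time level for the two-step backward
    differences; ``startup`` selects the backward-Euler bootstrap.
    """

    u_fs: np.ndarray
    lambda_theta: np.ndarray
    A: np.ndarray
    C_A: np.ndarray
    u_old: np.ndarray | None = None
    lam_old: np.ndarray | None = None
    A_old: np.ndarray | None = None
    startup: bool = True

    def copy(self) -> "WallState":
        return WallState(
            u_fs=self.u_fs.copy(),
            lambda_theta=self.lambda_theta.copy(),
            A=self.A.copy(),
            C_A=self.C_A.copy(),
            u_old=None if self.u_old is None else self.u_old.copy(),
            lam_old=None if self.lam_old is None else self.lam_old.copy(),
            A_old=None if self.A_old is None else self.A_old.copy(),
            startup=self.startup,
        )


# ----------------------------------------------------------------------------
# contractile system (single CF, forces in dyn, stiffnesses in dyn/cm)
# ----------------------------------------------------------------------------

def filament_overlap(u_fs, params: ContractileParams):
    """Gaussian filament-overlap factor, 1 at the optimal sliding."""
    u_fs = np.asarray(u_fs, dtype=float)
    width = params.s_f0 / params.L_m
    return np.exp(-((u_fs - params.u_fs_opt) ** 2) / (2.0 * width**2))


def series_stiffness(k_tCU, k_AC):
    """Series stiffness of an N_CU chain anchored by two cortex springs.

    Returns k_tCU k_AC / (2 k_tCU + k_AC); the fully disengaged limit
    k_tCU = k_AC = 0 returns 0 by convention (no machinery, no force).
    """
    k_tCU = np.asarray(k_tCU, dtype=float)
    denom = 2.0 * k_tCU + k_AC
    return np.where(denom > 0.0, k_tCU * k_AC / np.where(denom > 0.0, denom, 1.0), 0.0)


def contractile_system(u_fs, xi5, xi7, lambda_theta, params: ContractileParams):
    """Forces and stiffnesses of the contractile fibre.

    Returns (Fc, Fa, k_tCU, k_AC): the XB-cycling driving force, the elastic
    reaction of the CU/cortex series arrangement, the CU-chain stiffness and
    the actin-cortex stiffness.
    """
    L_fo = filament_overlap(u_fs, params)
    heads = params.L_m / params.delta_m
    Fc = L_fo * heads * np.asarray(xi5, dtype=float) * params.n_XB_max * params.k_XB * params.u_PS
    k_tCU = L_fo * params.L_m * np.asarray(xi5, dtype=float) * params.n_XB_max * params.k_XB / (
        2.0 * params.delta_m * params.N_CU
    )
    xi7 = np.asarray(xi7, dtype=float)
    hill = xi7**params.n_AC
    k_AC = params.k_AC_max * hill / (hill + params.K_AC**params.n_AC)
    elong = np.asarray(lambda_theta, dtype=float) - 1.0 - 2.0 * params.N_CU * u_fs
    Fa = elong * series_stiffness(k_tCU, k_AC)
    return Fc, Fa, k_tCU, k_AC


# ----------------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------------

def kinematics(ri, R, geom: WallGeometry):
    """Deformed radius and stretches at reference radius R for luminal radius ri.

    r = sqrt((R^2 - Ri^2)/(k_omega lambda_z) + ri^2);  lam_t = k_omega r / R;
    lam_r = R / (r k_omega lambda_z).  Incompressibility
    lam_r lam_t lam_z = 1 holds identically.
    """
    ri = np.asarray(ri, dtype=float)
    R = np.asarray(R, dtype=float)
    arg = (R**2 - geom.Ri**2) / (geom.k_omega * geom.lambda_z) + ri**2
    if np.any(arg <= 0.0):
        raise GeometryError("deformed radius undefined (negative square-root argument)")
    r = np.sqrt(arg)
    lam_t = geom.k_omega * r / R
    lam_r = R / (r * geom.k_omega * geom.lambda_z)
    return r, lam_r, lam_t


# ----------------------------------------------------------------------------
# strain energy
# ----------------------------------------------------------------------------

def strain_energy(lambda_r, lambda_theta, lambda_z, u_fs, xi5, xi7,
                  contractile: ContractileParams, passive: PassiveParams):
    """(Psi_a, Psi_p) per unit reference volume (dyn/cm^2).

    Psi_a integrates the active first Piola-Kirchhoff stress along lam_t at
    frozen sliding: N_CF/2 * k_ser * (lam_t - 1 - 2 N_CU u_fs)^2.
    """
    lam_t = np.asarray(lambda_theta, dtype=float)
    lam_r = np.asarray(lambda_r, dtype=float)
    _, _, k_tCU, k_AC = contractile_system(u_fs, xi5, xi7, lam_t, contractile)
    elong = lam_t - 1.0 - 2.0 * contractile.N_CU * np.asarray(u_fs, dtype=float)
    psi_a = 0.5 * contractile.N_CF * series_stiffness(k_tCU, k_AC) * elong**2

    I1 = lam_r**2 + lam_t**2 + lambda_z**2
    I4 = lam_t**2 * np.cos(passive.phi) ** 2 + lambda_z**2 * np.sin(passive.phi) ** 2
    q = passive.c2 * (I4 - 1.0) ** 2
    if np.any(q > 500.0):
        raise GeometryError("material instability: collagen exponential overflow")
    if passive.c2 > 0:
        fib = passive.c1 / (2.0 * passive.c2) * (np.exp(q) - 1.0)
    else:
        fib = 0.0 * lam_t
    psi_p = passive.c0 * (I1 - 3.0) + fib
    return psi_a, psi_p


def strain_energy_derivatives(lambda_r, lambda_theta, lambda_z, u_fs, xi5, xi7,
                              contractile: ContractileParams, passive: PassiveParams):
    """(dPsi_a/dlam_t, dPsi_p/dlam_t, dPsi_p/dlam_r).

    dPsi_a/dlam_t = N_CF k_ser (lam_t - 1 - 2 N_CU u_fs) with k_ser the
    CU/cortex series stiffness (sliding frozen); the passive derivatives
    follow from the neo-Hookean and collagen-fibre invariants.
    """
    lam_t = np.asarray(lambda_theta, dtype=float)
    lam_r = np.asarray(lambda_r, dtype=float)
    _, _, k_tCU, k_AC = contractile_system(u_fs, xi5, xi7, lam_t, contractile)
    elong = lam_t - 1.0 - 2.0 * contractile.N_CU * np.asarray(u_fs, dtype=float)
    dpsi_a = contractile.N_CF * series_stiffness(k_tCU, k_AC) * elong

    cos2 = np.cos(passive.phi) ** 2
    I4 = lam_t**2 * cos2 + lambda_z**2 * np.sin(passive.phi) ** 2
    q = passive.c2 * (I4 - 1.0) ** 2
    if np.any(q > 500.0):
        raise GeometryError("material instability: collagen exponential overflow")
    dpsi_p_t = 2.0 * passive.c0 * lam_t + 2.0 * passive.c1 * (I4 - 1.0) * np.exp(q) * lam_t * cos2
    dpsi_p_r = 2.0 * passive.c0 * lam_r
    return dpsi_a, dpsi_p_t, dpsi_p_r


# ----------------------------------------------------------------------------
# transmural momentum balance
# ----------------------------------------------------------------------------

def _simpson_weights(n: int, H):
    """Composite Simpson weights on n equally spaced nodes spanning [0, H].

    n odd >= 3; n = 1 degrades to the midpoint rule (weight H).  The weights
    sum to H exactly.
    """
    if n == 1:
        return np.asarray([1.0]), np.asarray([0.5])
    if n % 2 == 0 or n < 3:
        raise ConfigurationError("Simpson integration needs an odd number of nodes")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w /= 3.0 * (n - 1)  # times H later
    s = np.linspace(0.0, 1.0, n)
    return w, s


class _WallKernel:
    """Vectorized geometry arrays + transmural-pressure evaluations.

    Holds per-node reference layer radii and quadrature weights; every method
    broadcasts over (n_nodes, n_CL).
    """

    def __init__(self, Ri, H, k_omega, lambda_z, n_CL,
                 contractile: ContractileParams, passive: PassiveParams):
        self.Ri = np.atleast_1d(np.asarray(Ri, dtype=float))
        self.H = np.atleast_1d(np.asarray(H, dtype=float))
        self.k_omega = np.atleast_1d(np.asarray(k_omega, dtype=float))
        self.lambda_z = np.atleast_1d(np.asarray(lambda_z, dtype=float))
        self.n_CL = int(n_CL)
        self.cp = contractile
        self.pp = passive
        w, s = _simpson_weights(self.n_CL, None)
        # reference radii of the SMC layers / integration nodes, (n, n_CL)
        self.R = self.Ri[:, None] + self.H[:, None] * s[None, :]
        self.w = self.H[:, None] * w[None, :]
        self.n_nodes = self.Ri.shape[0]
        # precomputed constants for the fused evaluation path
        cp, pp = self.cp, self.pp
        self._dR2 = (self.R**2 - self.Ri[:, None] ** 2) / (self.k_omega * self.lambda_z)[:, None]
        self._kR = self.k_omega[:, None] / self.R
        self._inv_lz = 1.0 / self.lambda_z[:, None]
        self._wn = self.w / self.H[:, None]
        self._cos2 = np.cos(pp.phi) ** 2
        self._lz2sin2 = (self.lambda_z[:, None] ** 2) * np.sin(pp.phi) ** 2
        self._Kn = cp.K_AC**cp.n_AC
        width = cp.s_f0 / cp.L_m
        self._nhiw2 = -1.0 / (2.0 * width**2)
        self._fc_coef = (cp.L_m / cp.delta_m) * cp.n_XB_max * cp.k_XB * cp.u_PS
        self._kt_coef = cp.L_m * cp.n_XB_max * cp.k_XB / (2.0 * cp.delta_m * cp.N_CU)
        self._twoN = 2.0 * cp.N_CU

    # -- fused hot-path evaluation ---------------------------------------
    def evaluate(self, A, u, xi5, xi7, averaged: bool):
        """Everything the Newton loop needs, in one vectorized pass.

        Returns (g, ptm, lam_t, lam_dyn, Fa, Fc): per-layer pressure-balance
        integrand, transmural pressure, layer stretches, dynamic stretch
        ((n,1) thickness average when ``averaged``), and the contractile-fibre
        reaction/driving forces at the dynamic stretch.
        """
        cp, pp = self.cp, self.pp
        r2 = self._dR2 + (A / np.pi)[:, None]
        if r2.min() <= 0.0:
            raise GeometryError("deformed layer radius undefined")
        r = np.sqrt(r2)
        lam_t = self._kR * r
        lam_dyn = (self._wn * lam_t).sum(1, keepdims=True) if averaged else lam_t

        xi5c = xi5[:, None]
        xi7c = xi7[:, None]
        du = u - cp.u_fs_opt
        act = np.exp(du * du * self._nhiw2) * xi5c      # overlap * phosphorylation
        Fc = self._fc_coef * act
        kt = self._kt_coef * act
        hill = xi7c**cp.n_AC
        kac = cp.k_AC_max * hill / (hill + self._Kn)
        denom = 2.0 * kt + kac
        series = np.where(denom > 0.0, kt * kac / np.where(denom > 0.0, denom, 1.0), 0.0)
        elong = lam_dyn - 1.0 - self._twoN * u
        Fa = elong * series
        psi_a = cp.N_CF * series * elong                # dPsi_a/dlam_t, uniform if averaged

        lam_r = self._inv_lz / lam_t
        I4m1 = lam_t * lam_t * self._cos2 + self._lz2sin2 - 1.0
        q = pp.c2 * I4m1 * I4m1
        if q.max() > 500.0:
            raise GeometryError("material instability: collagen exponential overflow")
        dpsi_p_t = 2.0 * pp.c0 * lam_t + 2.0 * pp.c1 * I4m1 * np.exp(q) * lam_t * self._cos2
        dpsi_p_r = 2.0 * pp.c0 * lam_r
        g = (lam_t * (psi_a + dpsi_p_t) - lam_r * dpsi_p_r) * self._inv_lz / (lam_t * r)
        ptm = pp.P_ext + (self.w * g).sum(1)
        return g, ptm, lam_t, lam_dyn, Fa, Fc

    # -- kinematics -----------------------------------------------------
    def stretches(self, A):
        """Layer radii and stretches for luminal areas A: (r, lam_r, lam_t)."""
        A = np.asarray(A, dtype=float)
        ri2 = A / np.pi
        arg = (self.R**2 - self.Ri[:, None] ** 2) / (self.k_omega * self.lambda_z)[:, None] + ri2[:, None]
        if np.any(arg <= 0.0):
            raise GeometryError("deformed layer radius undefined")
        r = np.sqrt(arg)
        lam_t = self.k_omega[:, None] * r / self.R
        lam_r = 1.0 / (lam_t * self.lambda_z[:, None])
        return r, lam_r, lam_t

    def lam_bar(self, lam_t):
        """Thickness-averaged circumferential stretch (Simpson average)."""
        return (self.w * lam_t).sum(axis=1, keepdims=True) / self.H[:, None]

    # -- pressure balance ----------------------------------------------
    def integrand(self, A, u_fs, xi5, xi7, averaged: bool):
        """Per-layer integrand g_k of the transmural balance plus kinematics.

        u_fs is (n, n_CL) layer-resolved or (n, 1) averaged; in the averaged
        variant the active stress is a single value per node computed from the
        thickness-averaged stretch and applied uniformly across layers.
        Returns (g, lam_t, lam_dyn) with lam_dyn the stretch entering the
        sliding dynamics ((n, n_CL) or (n, 1)).
        """
        g, _, lam_t, lam_dyn, _, _ = self.evaluate(
            np.asarray(A, dtype=float), np.asarray(u_fs, dtype=float),
            np.asarray(xi5, dtype=float), np.asarray(xi7, dtype=float), averaged)
        return g, lam_t, lam_dyn

    def pressure(self, A, u_fs, xi5, xi7, averaged: bool):
        """Transmural pressure (dyn/cm^2) at luminal areas A."""
        _, ptm, _, _, _, _ = self.evaluate(
            np.asarray(A, dtype=float), np.asarray(u_fs, dtype=float),
            np.asarray(xi5, dtype=float), np.asarray(xi7, dtype=float), averaged)
        return ptm


def transmural_pressure(A, u_fs_layers, xi5, xi7, geom: WallGeometry,
                        contractile: ContractileParams, passive: PassiveParams):
    """Luminal pressure (dyn/cm^2) balancing wall stress at area A.

    The through-thickness integral is evaluated with Simpson's rule on the
    geometry's n_CL layer nodes.  Scalar convenience wrapper over the
    vectorized kernel; A may be an array (u_fs broadcast accordingly).
    """
    A = np.atleast_1d(np.asarray(A, dtype=float))
    n = A.shape[0]
    kern = _WallKernel(np.full(n, geom.Ri), np.full(n, geom.H),
                       np.full(n, geom.k_omega), np.full(n, geom.lambda_z),
                       geom.n_CL, contractile, passive)
    u = np.broadcast_to(np.asarray(u_fs_layers, dtype=float), (n, geom.n_CL))
    xi5 = np.broadcast_to(np.asarray(xi5, dtype=float), (n,))
    xi7 = np.broadcast_to(np.asarray(xi7, dtype=float), (n,))
    P = kern.pressure(A, u, xi5, xi7, averaged=False)
    return P if P.shape != (1,) else float(P[0])


# ----------------------------------------------------------------------------
# time stepping
# ----------------------------------------------------------------------------

class WallModel:
    """All wall cross-sections of a simulation, advanced in lock-step.

    One instance bundles per-node geometry with the shared contractile and
    passive parameter sets and exposes ``step`` (advance every node to a new
    luminal pressure), ``compliance`` and ``initial_state``.  ``averaged``
    selects the averaged-active-stress variant (a single sliding variable per
    node driven by the thickness-averaged stretch).
    """

    def __init__(self, geometries, contractile: ContractileParams | None = None,
                 passive: PassiveParams | None = None, averaged: bool = False):
        if isinstance(geometries, WallGeometry):
            geometries = [geometries]
        self.geometries = list(geometries)
        n_CL = {g.n_CL for g in self.geometries}
        if len(n_CL) != 1:
            raise ConfigurationError("all wall nodes must share n_CL")
        self.cp = contractile or ContractileParams()
        self.pp = passive or PassiveParams()
        self.averaged = bool(averaged)
        self.kern = _WallKernel(
            [g.Ri for g in self.geometries],
            [g.H for g in self.geometries],
            [g.k_omega for g in self.geometries],
            [g.lambda_z for g in self.geometries],
            n_CL.pop(), self.cp, self.pp,
        )
        self.n_nodes = self.kern.n_nodes
        self.n_dyn = 1 if self.averaged else self.kern.n_CL

    # -- state ----------------------------------------------------------
    def initial_state(self) -> WallState:
        """Standard initial state: lam_t = 1, u_fs = -2e-2 for every layer."""
        kw = self.kern.k_omega
        ri = self.kern.Ri / kw
        A = np.pi * ri**2
        u = np.full((self.n_nodes, self.n_dyn), U_FS_INIT)
        _, lam_t, lam_dyn = self.kern.integrand(A, u, np.zeros(self.n_nodes),
                                                np.zeros(self.n_nodes), self.averaged)
        state = WallState(
            u_fs=u, lambda_theta=lam_dyn.copy(), A=A,
            C_A=np.zeros(self.n_nodes), startup=True,
        )
        state.C_A = self.compliance(state, np.zeros(self.n_nodes), np.zeros(self.n_nodes))
        return state

    # -- residuals -------------------------------------------------------
    def _bdf_coeffs(self, state: WallState, dt: float):
        if state.startup or state.u_old is None:
            beta = 1.0 / dt
            gam_u = state.u_fs / dt
            gam_l = state.lambda_theta / dt
        else:
            beta = 1.5 / dt
            gam_u = (4.0 * state.u_fs - state.u_old) / (2.0 * dt)
            gam_l = (4.0 * state.lambda_theta - state.lam_old) / (2.0 * dt)
        return beta, gam_u, gam_l

    def residuals(self, u, A, P_new, state: WallState, xi5, xi7, dt: float,
                  _aux: bool = False):
        """Residuals of the coupled sliding/pressure system at iterate (u, A).

        Rows: F_k = beta u_k - gam_u,k - (Fa_k - Fc_k)/tau_m
                    - (beta lam_k(A) - gam_l,k)/(2 N_CU)   for each layer,
              J   = P_new - P_transmural(A, u).
        """
        beta, gam_u, gam_l = self._bdf_coeffs(state, dt)
        g, ptm, _, lam_dyn, Fa, Fc = self.kern.evaluate(
            np.asarray(A, dtype=float), np.asarray(u, dtype=float),
            np.asarray(xi5, dtype=float), np.asarray(xi7, dtype=float),
            self.averaged)
        F = (beta * u - gam_u
             - (Fa - Fc) / self.cp.tau_m
             - (beta * lam_dyn - gam_l) / (2.0 * self.cp.N_CU))
        J = P_new - ptm
        if _aux:
            return F, J, g, lam_dyn
        return F, J

    # -- Newton solve ----------------------------------------------------
    def step(self, P_new, state: WallState, xi5, xi7, dt: float) -> WallState:
        """Advance all wall nodes to luminal pressure P_new (dyn/cm^2).

        Does not mutate ``state``; strong coupling re-invokes this from the
        same base state with updated pressures.
        """
        P_new = np.asarray(P_new, dtype=float)
        xi5 = np.asarray(xi5, dtype=float)
        xi7 = np.asarray(xi7, dtype=float)
        if not dt > 0:
            raise ConfigurationError("dt must be positive")

        # predictor: linear extrapolation when history exists
        if state.A_old is not None and not state.startup:
            A = np.clip(2.0 * state.A - state.A_old, 0.25 * state.A, 4.0 * state.A)
            u = 2.0 * state.u_fs - state.u_old
        else:
            A = state.A.copy()
            u = state.u_fs.copy()

        du_eps = 1e-7
        tol = 1e-10
        w = self.kern.w
        for it in range(60):
            F0, J0, g0, _ = self.residuals(u, A, P_new, state, xi5, xi7, dt, _aux=True)
            # arrowhead Jacobian by structured finite differences:
            # u_k only enters its own sliding row and its own layer integrand
            Fu, _, gu, _ = self.residuals(u + du_eps, A, P_new, state, xi5, xi7, dt, _aux=True)
            dA_eps = 1e-7 * A
            FA, JA = self.residuals(u, A + dA_eps, P_new, state, xi5, xi7, dt)
            D = (Fu - F0) / du_eps                        # dF_k/du_k
            if self.averaged:
                rrow = -((w * (gu - g0)).sum(axis=1) / du_eps)[:, None]  # dJ/du
            else:
                rrow = -w * (gu - g0) / du_eps            # dJ/du_k
            c = (FA - F0) / dA_eps[:, None]               # dF_k/dA
            a = (JA - J0) / dA_eps                        # dJ/dA

            rFD = (rrow * F0 / D).sum(axis=1)
            rcD = (rrow * c / D).sum(axis=1)
            denom = a - rcD
            if np.any(denom == 0.0) or not np.all(np.isfinite(denom)):
                raise StepError("singular wall Jacobian",
                                residual_norms=(np.abs(F0).max(), np.abs(J0).max()))
            dA = (-J0 + rFD) / denom
            dA = np.clip(dA, -0.2 * A, 0.2 * A)
            du = (-F0 - c * dA[:, None]) / D
            du = np.clip(du, -0.05, 0.05)
            A = A + dA
            u = u + du
            if max(np.abs(dA / A).max(), np.abs(du).max()) < tol:
                break
        else:
            raise StepError(
                "wall Newton iteration did not converge",
                residual_norms=(float(np.abs(F0).max()), float(np.abs(J0).max())),
            )

        _, _, lam_dyn = self.kern.integrand(A, u, xi5, xi7, self.averaged)
        new = WallState(
            u_fs=u, lambda_theta=lam_dyn, A=A, C_A=state.C_A.copy(),
            u_old=state.u_fs.copy(), lam_old=state.lambda_theta.copy(),
            A_old=state.A.copy(), startup=False,
        )
        new.C_A = self.compliance(new, xi5, xi7)
        return new

    # -- compliance ------------------------------------------------------
    def compliance(self, state: WallState, xi5, xi7):
        """dA/dP by a centered difference at frozen sliding and signalling.

        The area perturbation targets a pressure perturbation of ~0.1 mmHg
        using the previous compliance as the scale (first call: 1e-4 A).
        """
        A = state.A
        dA = np.where(state.C_A > 0.0, state.C_A * COMPLIANCE_DP, 1e-4 * A)
        dA = np.clip(dA, 1e-7 * A, 1e-2 * A)
        p_hi = self.kern.pressure(A + dA, state.u_fs, xi5, xi7, self.averaged)
        p_lo = self.kern.pressure(A - dA, state.u_fs, xi5, xi7, self.averaged)
        dPdA = (p_hi - p_lo) / (2.0 * dA)
        if np.any(dPdA <= 0.0):
            raise StepError("non-positive wall stiffness dP/dA")
        return 1.0 / dPdA

    # -- diagnostics ------------------------------------------------------
    def radii(self, state: WallState):
        """Deformed luminal and outer diameters (d_i, d_o) in cm."""
        r, _, _ = self.kern.stretches(state.A)
        ri = np.sqrt(state.A / np.pi)
        return 2.0 * ri, 2.0 * r[:, -1]


def wall_residuals(model: WallModel, u_fs_layers, A, P, state: WallState,
                   xi5, xi7, dt: float):
    """Residual vector(s) of the wall system: n_dyn sliding rows + 1 pressure row."""
    u = np.asarray(u_fs_layers, dtype=float).reshape(model.n_nodes, model.n_dyn)
    A = np.atleast_1d(np.asarray(A, dtype=float))
    F, J = model.residuals(u, A, np.atleast_1d(np.asarray(P, dtype=float)),
                           state, np.atleast_1d(xi5), np.atleast_1d(xi7), dt)
    return np.concatenate([F, J[:, None]], axis=1)


def step_wall(P_new, state: WallState, xi5, xi7, model: WallModel, dt: float) -> WallState:
    """Advance the wall state one step (functional wrapper over WallModel.step)."""
    return model.step(np.atleast_1d(P_new), state,
                      np.atleast_1d(xi5), np.atleast_1d(xi7), dt)
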