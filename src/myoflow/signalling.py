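"""Pressure-driven intracellular signalling of vascular smooth muscle cells.

Seven normalized activity levels describe how luminal pressure is transduced
into the two quantities the contractile machinery consumes:

======  ==============================================  ==================
state   meaning                                         dynamics
======  ==============================================  ==================
xi0     Ca2+ concentration                              relaxation, tau_c
xi1     ROCK activity                                   relaxation, tau_c
xi2     HSP27 phosphorylation (PKC pathway)             relaxation, tau_c
xi3     MLCP phosphorylation                            quasi-instantaneous
xi4     cofilin phosphorylation                         quasi-instantaneous
xi5     LC20 (myosin light chain) phosphorylation       quasi-instantaneous
xi6     G-actin content                                 quasi-instantaneous
======  ==============================================  ==================

Each causal edge of the signalling graph is a logistic ("activation") link
chi_i.  The slow rows relax toward their link outputs with a shared time
constant tau_c; the fast rows are algebraic because their time constants are
taken as infinitesimal, which removes the stiffness a tiny explicit tau would
introduce.  The F-actin content used by the cortex stiffness is the
complement of the G-actin pool, xi7 = 1 - xi6.

The LC20 balance has a production/degradation structure,

    d(xi5)/dt ~ chi5 (1 - xi5) - (1 - chi6) xi5,

so its quasi-steady value is chi5 / (chi5 + 1 - chi6); the G-actin target is
the logical OR of two depolymerizing influences, (1-chi7) + (1-chi8)
- (1-chi7)(1-chi8) = 1 - chi7*chi8.

The only external input of the graph is luminal pressure (in mmHg at this
interface).  Pharmacological modulation enters as a calcium-mode switch:
``control`` drives Ca2+ with the full pressure link, ``diltiazem`` replaces
it with a low-amplitude residual (stretch-operated channels only) and
``zero_ca`` clamps the Ca2+ target to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "LogisticLink",
    "SignallingParams",
    "SignallingState",
    "evaluate_link",
    "default_link_table",
    "pressure_to_calcium_target",
    "quasi_steady_targets",
    "signalling_rhs",
    "step_signalling",
    "steady_signalling",
    "CALCIUM_MODES",
]

CALCIUM_MODES = ("control", "diltiazem", "zero_ca")

#: Index names of the slow (relaxation) rows integrated in time.
SLOW = (0, 1, 2)


@dataclass(frozen=True)
class LogisticLink:
    """One edge of the signalling graph: a logistic activation function.

    ``evaluate_link`` returns 1/(1+exp(-slope*(x - half_activation))), or its
    complement when ``inverted`` — always in (0, 1) and strictly monotone.
    ``input_source`` names the driving variable ("pressure" or "xi<k>").
    """

    slope: float
    half_activation: float
    input_source: str
    inverted: bool = False


def evaluate_link(link: LogisticLink, x):
    """Logistic activation of ``link`` at driving value ``x``."""
    if link.slope == 0.0 or not np.isfinite(link.slope) or not np.isfinite(link.half_activation):
        raise ConfigurationError(f"invalid logistic link parameters: {link}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("non-finite input to logistic link")
    # expit-style guarded evaluation; the clip keeps exp() overflow-free
    return _link(link, x)


def _link(link: LogisticLink, x):
    # validation-free logistic used on the hot stepping path
    z = np.clip(link.slope * (np.asarray(x, dtype=float) - link.half_activation),
                -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(-z))
    return 1.0 - out if link.inverted else out


def default_link_table() -> dict[str, LogisticLink]:
    """Default wiring and parameters of the nine links chi0..chi8.

    The pressure-facing links (chi0 Ca2+, chi1 ROCK, chi2 HSP27/PKC) rise
    sigmoidally over 10-120 mmHg; chi1 is centred high (80 mmHg) so ROCK — and
    the MLCP phosphorylation it commands — barely moves below 60 mmHg.  The
    intracellular links are centred near half activity with order-unity
    sharpness.  Values are illustrative repository defaults (the wiring is a
    documented modelling choice, see docs/methods.md) and fully overridable.
    """
    return {
        "chi0": LogisticLink(0.060, 45.0, "pressure"),          # P -> Ca2+
        "chi1": LogisticLink(0.050, 80.0, "pressure"),          # P -> ROCK
        "chi2": LogisticLink(0.060, 55.0, "pressure"),          # P -> HSP27/PKC
        "chi3": LogisticLink(6.0, 0.5, "xi1", inverted=True),   # ROCK -| MLCP (via 1-chi3)
        "chi4": LogisticLink(6.0, 0.5, "xi2"),                  # HSP27 -> cofilin
        "chi5": LogisticLink(12.0, 0.55, "xi0"),                # Ca2+ -> LC20 phosphorylation
        "chi6": LogisticLink(4.0, 0.7, "xi3"),                  # MLCP-P -| dephosphorylation
        "chi7": LogisticLink(6.0, 0.5, "xi2"),                  # HSP27 -| G-actin
        "chi8": LogisticLink(6.0, 0.5, "xi4"),                  # cofilin -| G-actin
    }


@dataclass(frozen=True)
class SignallingParams:
    """Time constants, link table and calcium mode of the signalling model.

    tau_c (s) is shared by the three slow pressure-facing pathways
    (tau_c0 = tau_c1 = tau_c2 = tau_c, default 10 s).  tau_c3..tau_c6 are
    quasi-instantaneous: ``None`` means the corresponding row is replaced by
    its algebraic target at every step.  ca_max_nM scales the normalized xi0
    to a concentration for output (230 nM full scale).
    """

    tau_c: float = 10.0
    tau_c3: float | None = None
    tau_c4: float | None = None
    tau_c5: float | None = None
    tau_c6: float | None = None
    link_table: dict[str, LogisticLink] = field(default_factory=default_link_table)
    calcium_mode: str = "control"
    ca_max_nM: float = 230.0
    # residual pressure->Ca2+ coupling through stretch-operated channels
    # remaining under L-type channel block (30 uM Diltiazem)
    diltiazem_amplitude: float = 0.1
    diltiazem_link: LogisticLink = LogisticLink(0.03, 60.0, "pressure")

    def __post_init__(self):
        if not self.tau_c > 0.0:
            raise ConfigurationError("tau_c must be positive")
        if self.calcium_mode not in CALCIUM_MODES:
            raise ConfigurationError(
                f"unknown calcium mode {self.calcium_mode!r}; expected one of {CALCIUM_MODES}"
            )

    def with_mode(self, mode: str) -> "SignallingParams":
        return replace(self, calcium_mode=mode)


@dataclass
class SignallingState:
    """The seven normalized signalling variables, vectorized over nodes.

    ``xi`` has shape (..., 7).  ``f_prev`` stores the previous derivative of
    the slow rows for the two-step Adams-Bashforth update; ``None`` marks the
    startup step (forward Euler).
    """

    xi: np.ndarray
    f_prev: np.ndarray | None = None

    @classmethod
    def zeros(cls, shape=()) -> "SignallingState":
        """All variables initialized to 0 (the standard initial condition)."""
        return cls(xi=np.zeros(tuple(np.atleast_1d(shape)) + (7,) if shape else (7,)))

    @property
    def xi7(self):
        """F-actin content, the complement of the G-actin pool."""
        return 1.0 - self.xi[..., 6]

    def copy(self) -> "SignallingState":
        return SignallingState(
            xi=self.xi.copy(),
            f_prev=None if self.f_prev is None else self.f_prev.copy(),
        )


def pressure_to_calcium_target(P, params: SignallingParams):
    """Target value of xi0 for luminal pressure ``P`` (mmHg) in the active mode."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ConfigurationError("luminal pressure must be non-negative")
    mode = params.calcium_mode
    if mode == "control":
        return evaluate_link(params.link_table["chi0"], P)
    if mode == "diltiazem":
        return params.diltiazem_amplitude * evaluate_link(params.diltiazem_link, P)
    if mode == "zero_ca":
        return np.zeros_like(P)
    raise ConfigurationError(f"unknown calcium mode {mode!r}")


def _slow_targets(P, params: SignallingParams):
    """Link outputs driving the three relaxation rows (xi0, xi1, xi2)."""
    links = params.link_table
    return np.stack(
        [
            pressure_to_calcium_target(P, params),
            _link(links["chi1"], P),
            _link(links["chi2"], P),
        ],
        axis=-1,
    )


def quasi_steady_targets(xi0, xi1, xi2, params: SignallingParams):
    """Algebraic values of the fast rows, chained from the slow variables.

    Returns (xi3, xi4, xi5, xi6).
    """
    links = params.link_table
    # row 3 relaxes toward (1 - chi3); with the default inverted chi3 this
    # makes MLCP phosphorylation rise with ROCK activity
    xi3 = 1.0 - _link(links["chi3"], xi1)
    xi4 = _link(links["chi4"], xi2)
    chi5 = _link(links["chi5"], xi0)
    chi6 = _link(links["chi6"], xi3)
    xi5 = chi5 / (chi5 + 1.0 - chi6)
    chi7 = _link(links["chi7"], xi2)
    chi8 = _link(links["chi8"], xi4)
    xi6 = 1.0 - chi7 * chi8
    return xi3, xi4, xi5, xi6


def signalling_rhs(state: SignallingState, P, params: SignallingParams):
    """Time derivative (1/s) of all seven signalling rows.

    The fast rows use their configured time constants when set; a
    quasi-instantaneous (``None``) tau is reported with a 1 s placeholder so
    the returned bracket structure — and hence every steady state — is exact.
    """
    xi = np.asarray(state.xi, dtype=float)
    if not np.all(np.isfinite(xi)) :
        raise ConfigurationError("non-finite signalling state")
    links = params.link_table
    taus_fast = [params.tau_c3, params.tau_c4, params.tau_c5, params.tau_c6]
    for tau in (params.tau_c, *[t for t in taus_fast if t is not None]):
        if not tau > 0.0:
            raise ConfigurationError("signalling time constants must be positive")
    t3, t4, t5, t6 = [1.0 if t is None else t for t in taus_fast]

    d = np.empty_like(xi)
    slow = _slow_targets(P, params)
    d[..., 0] = (slow[..., 0] - xi[..., 0]) / params.tau_c
    d[..., 1] = (slow[..., 1] - xi[..., 1]) / params.tau_c
    d[..., 2] = (slow[..., 2] - xi[..., 2]) / params.tau_c
    d[..., 3] = ((1.0 - evaluate_link(links["chi3"], xi[..., 1])) - xi[..., 3]) / t3
    d[..., 4] = (evaluate_link(links["chi4"], xi[..., 2]) - xi[..., 4]) / t4
    chi5 = evaluate_link(links["chi5"], xi[..., 0])
    chi6 = evaluate_link(links["chi6"], xi[..., 3])
    d[..., 5] = (chi5 * (1.0 - xi[..., 5]) - (1.0 - chi6) * xi[..., 5]) / t5
    chi7 = evaluate_link(links["chi7"], xi[..., 2])
    chi8 = evaluate_link(links["chi8"], xi[..., 4])
    d[..., 6] = ((1.0 - chi7 * chi8) - xi[..., 6]) / t6
    return d


def step_signalling(state: SignallingState, P_now, dt: float, params: SignallingParams) -> SignallingState:
    """Advance the signalling state by ``dt`` given pressure ``P_now`` (mmHg).

    The slow rows use the explicit two-step Adams-Bashforth update (forward
    Euler on the first step); the fast rows are set to their algebraic
    quasi-steady targets chained from the freshly advanced slow variables.
    """
    if not dt > 0.0:
        raise ConfigurationError("dt must be positive")
    xi = np.asarray(state.xi, dtype=float)
    slow = xi[..., SLOW]
    f_now = (_slow_targets(P_now, params) - slow) / params.tau_c
    if state.f_prev is None:
        slow_new = slow + dt * f_now
    else:
        slow_new = slow + dt * (1.5 * f_now - 0.5 * state.f_prev)

    xi_new = np.empty_like(xi)
    xi_new[..., SLOW] = slow_new
    xi3, xi4, xi5, xi6 = quasi_steady_targets(
        slow_new[..., 0], slow_new[..., 1], slow_new[..., 2], params
    )
    xi_new[..., 3] = xi3
    xi_new[..., 4] = xi4
    xi_new[..., 5] = xi5
    xi_new[..., 6] = xi6
    return SignallingState(xi=xi_new, f_prev=f_now)


def steady_signalling(P, params: SignallingParams, shape=None) -> SignallingState:
    """The unique fixed point of the signalling system at constant pressure."""
    slow = _slow_targets(P, params)
    xi3, xi4, xi5, xi6 = quasi_steady_targets(
        slow[..., 0], slow[..., 1], slow[..., 2], params
    )
    xi = np.concatenate(
        [slow, np.stack([xi3, xi4, xi5, xi6], axis=-1)], axis=-1
    )
    if shape is not None:
        xi = np.broadcast_to(xi, tuple(np.atleast_1d(shape)) + (7,)).copy()
    return SignallingState(xi=xi, f_prev=np.zeros(xi.shape[:-1] + (3,)))
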