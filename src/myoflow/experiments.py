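"""Pressure-signal generators and scripted numerical experiments.

Signals are pure functions of their specification (and seed), returned as
vectorized callables t (s) -> pressure (mmHg).  The experiment harnesses
reproduce the study protocols: a pressure-step myography run on a single
cannulated vessel, a numerical-settings accuracy/efficiency comparison on a
network, and a steady-state autoregulation (pressure-flow) sweep.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import CouplingConfig, Simulator, rmsre
from .errors import ConfigurationError, SignalSpecError
from .network import NetworkTopology, attach_boundaries
from .signalling import SignallingParams, SignallingState, step_signalling
from .units import MMHG
from .wall_mechanics import ContractileParams, PassiveParams, WallGeometry, WallModel

__all__ = [
    "SignalSpec",
    "make_signal",
    "default_inlet_spec",
    "single_vessel_protocol",
    "trace_rmsre",
    "default_cases",
    "settings_comparison",
    "autoregulation_curve",
]


@dataclass(frozen=True)
class SignalSpec:
    """Specification of a deterministic pressure signal.

    kinds and their parameters (all pressures mmHg, times s):

    - ``constant``: level
    - ``step_train``: levels (sequence, cycled), hold (s per level),
      optionally transition (linear blend duration, default 0)
    - ``ramp``: t0, t1, p0, p1 (flat outside [t0, t1])
    - ``piecewise_linear``: times (strictly increasing), values
    - ``periodic_variable_mean``: period, amplitude, mean_low, mean_high,
      segment, t_max — a sinusoid superposed on a piecewise-linear mean whose
      breakpoint levels are drawn uniformly from [mean_low, mean_high] by the
      seeded generator every ``segment`` seconds up to t_max (held beyond)
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        kinds = ("constant", "step_train", "ramp", "piecewise_linear",
                 "periodic_variable_mean")
        if self.kind not in kinds:
            raise SignalSpecError(f"unknown signal kind {self.kind!r}")


def default_inlet_spec(seed: int = 0) -> SignalSpec:
    """The documented variable-mean periodic inlet signal used for the
    network accuracy studies: a 2 Hz, 4 mmHg sinusoid on a mean that walks
    through seeded uniform levels in [58, 82] mmHg every 2 s.  The mean
    stays safely above the 50 mmHg outlet so network flow never reverses.
    """
    return SignalSpec(
        kind="periodic_variable_mean",
        params={"period": 0.5, "amplitude": 4.0, "mean_low": 58.0,
                "mean_high": 82.0, "segment": 2.0, "t_max": 20.0},
        seed=seed,
    )


def make_signal(spec: SignalSpec):
    """Compile a SignalSpec into a vectorized callable t -> mmHg."""
    p = spec.params
    kind = spec.kind

    if kind == "constant":
        level = float(p["level"])

        def signal(t):
            return np.full_like(np.asarray(t, dtype=float), level) if np.ndim(t) else level

    elif kind == "step_train":
        levels = np.asarray(p["levels"], dtype=float)
        hold = float(p["hold"])
        trans = float(p.get("transition", 0.0))
        if hold <= 0 or trans < 0 or trans >= hold:
            raise SignalSpecError("step_train needs 0 <= transition < hold")

        def signal(t):
            t = np.asarray(t, dtype=float)
            idx = np.floor(t / hold).astype(int)
            cur = levels[idx % len(levels)]
            if trans > 0:
                prev = levels[(idx - 1) % len(levels)]
                frac = np.clip((t - idx * hold) / trans, 0.0, 1.0)
                cur = prev + (cur - prev) * frac
            return cur if cur.ndim else float(cur)

    elif kind == "ramp":
        t0, t1 = float(p["t0"]), float(p["t1"])
        p0, p1 = float(p["p0"]), float(p["p1"])
        if not t1 > t0:
            raise SignalSpecError("ramp needs t1 > t0")

        def signal(t):
            t = np.asarray(t, dtype=float)
            out = p0 + (p1 - p0) * np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
            return out if out.ndim else float(out)

    elif kind == "piecewise_linear":
        times = np.asarray(p["times"], dtype=float)
        values = np.asarray(p["values"], dtype=float)
        if times.ndim != 1 or times.shape != values.shape or len(times) < 2:
            raise SignalSpecError("piecewise_linear needs matching times/values")
        if np.any(np.diff(times) <= 0):
            raise SignalSpecError("piecewise_linear breakpoints must be increasing")

        def signal(t):
            out = np.interp(np.asarray(t, dtype=float), times, values)
            return out if out.ndim else float(out)

    else:  # periodic_variable_mean
        period = float(p.get("period", 0.5))
        amplitude = float(p.get("amplitude", 4.0))
        lo = float(p.get("mean_low", 58.0))
        hi = float(p.get("mean_high", 82.0))
        segment = float(p.get("segment", 2.0))
        t_max = float(p.get("t_max", 20.0))
        if period <= 0 or segment <= 0 or not hi >= lo:
            raise SignalSpecError("invalid periodic_variable_mean parameters")
        rng = np.random.default_rng(spec.seed)
        n_seg = int(np.ceil(t_max / segment)) + 1
        bp_t = np.arange(n_seg + 1) * segment
        bp_v = rng.uniform(lo, hi, size=n_seg + 1)

        def signal(t):
            t = np.asarray(t, dtype=float)
            mean = np.interp(t, bp_t, bp_v)
            out = mean + amplitude * np.sin(2.0 * np.pi * t / period)
            return out if out.ndim else float(out)

    signal.spec = spec
    signal.seed = spec.seed
    return signal


# ---------------------------------------------------------------------------
# single-vessel pressure-step protocol (wall only, prescribed pressure)
# ---------------------------------------------------------------------------

def single_vessel_protocol(signal, mode: str = "control", *,
                           geometry: WallGeometry | None = None,
                           signalling: SignallingParams | None = None,
                           contractile: ContractileParams | None = None,
                           passive: PassiveParams | None = None,
                           dt: float = 0.5, t_end: float = 600.0) -> pd.DataFrame:
    """Myography-style run: prescribe luminal pressure on one cannulated
    vessel (no flow solver) and record diameters and Ca2+.

    Returns a DataFrame indexed by time with columns P (mmHg), d_i, d_o (cm),
    Ca_nM (xi0 scaled to the 230 nM full range), all seven signalling
    variables xi0..xi6 and the mean relative filament sliding u_fs.  The wall
    is layer-resolved (no averaged active stress).
    """
    geometry = geometry or WallGeometry.from_load_free(135e-4, 0.30)
    sig_params = (signalling or SignallingParams()).with_mode(mode)
    wall = WallModel(geometry, contractile, passive, averaged=False)
    wall_state = wall.initial_state()
    sig = SignallingState.zeros(1)

    n_steps = round(t_end / dt)
    rows = []
    t = 0.0

    def sample():
        d_i, d_o = wall.radii(wall_state)
        row = {
            "P": float(signal(t)),
            "d_i": d_i[0], "d_o": d_o[0],
            "Ca_nM": sig.xi[0, 0] * sig_params.ca_max_nM,
            "u_fs": wall_state.u_fs[0].mean(),
        }
        row.update({f"xi{k}": sig.xi[0, k] for k in range(7)})
        rows.append(row)

    sample()
    times = [0.0]
    for _ in range(n_steps):
        t += dt
        P = float(signal(t))
        sig = step_signalling(sig, np.full(1, P), dt, sig_params)
        wall_state = wall.step(np.full(1, P * MMHG), wall_state,
                               sig.xi[..., 5], sig.xi7, dt)
        times.append(t)
        sample()
    return pd.DataFrame(rows, index=pd.Index(times, name="t"))


def trace_rmsre(sim: pd.Series, reference: pd.Series, window=None) -> float:
    """RMSRE of a simulated trace against a reference trace.

    Both are time-indexed Series; the simulation is interpolated onto the
    reference times (restricted to ``window`` = (t0, t1) when given).
    """
    ref_t = np.asarray(reference.index, dtype=float)
    ref_v = np.asarray(reference.values, dtype=float)
    if window is not None:
        keep = (ref_t >= window[0]) & (ref_t <= window[1])
        ref_t, ref_v = ref_t[keep], ref_v[keep]
    if len(ref_t) == 0:
        raise ConfigurationError("empty scoring window")
    sim_v = np.interp(ref_t, np.asarray(sim.index, dtype=float),
                      np.asarray(sim.values, dtype=float))
    return rmsre(sim_v, ref_v)


# ---------------------------------------------------------------------------
# numerical-settings comparison
# ---------------------------------------------------------------------------

def default_cases() -> list[dict]:
    """The five standard numerical settings (case 1 is the reference)."""
    return [
        {"name": "case1", "dt": 1e-4,   "mode": "strong", "averaged": False},
        {"name": "case2", "dt": 2e-4,   "mode": "strong", "averaged": False},
        {"name": "case3", "dt": 2.5e-4, "mode": "strong", "averaged": False},
        {"name": "case4", "dt": 2.5e-4, "mode": "weak",   "averaged": False},
        {"name": "case5", "dt": 2.5e-4, "mode": "weak",   "averaged": True},
    ]


def _run_case(topology: NetworkTopology, signal, case: dict, t_end: float,
              sample_dt: float, **kwargs):
    topo = copy.deepcopy(topology)
    cfg = CouplingConfig(mode=case["mode"], dt=case["dt"],
                         averaged_active_stress=case["averaged"])
    sim = Simulator(topo, cfg, signal, **kwargs)
    return sim.run(t_end, sample_dt=sample_dt)


def settings_comparison(topology: NetworkTopology, signal, cases=None, *,
                        t_end: float = 10.0, sample_dt: float = 1e-2,
                        **kwargs) -> pd.DataFrame:
    """Accuracy/efficiency table of numerical settings against a reference.

    Runs every case on (a deep copy of) the same network and signal; the
    first case is the reference.  For each other case, per-generation
    mid-vessel flow and area RMSREs are computed on the shared sampling grid
    (the t = 0 sample is excluded: flow starts identically at 0), then
    reduced to mean/min/max across generations; the wall-clock time is
    reported relative to the reference.

    Returns a DataFrame indexed by case name.
    """
    cases = cases or default_cases()
    records = [_run_case(topology, signal, c, t_end, sample_dt, **kwargs)
               for c in cases]
    ref = records[0]
    gens = sorted({c.split(":")[0] for c in ref.data.columns if ":" in c})
    rows = {}
    for case, rec in zip(cases[1:], records[1:]):
        row = {"relative_wct_pct": 100.0 * rec.meta["wall_clock_s"]
                                   / ref.meta["wall_clock_s"]}
        for var in ("Q", "A"):
            errs = {}
            for g in gens:
                a = rec.data[f"{g}:{var}"].values[1:]
                b = ref.data[f"{g}:{var}"].values[1:]
                errs[g] = rmsre(a, b)
                row[f"{var}_rmsre:{g}"] = errs[g]
            vals = np.asarray(list(errs.values()))
            names = list(errs)
            row[f"mean_{var}_rmsre"] = vals.mean()
            row[f"min_{var}_rmsre"] = vals.min()
            row[f"min_{var}_gen"] = names[int(vals.argmin())]
            row[f"max_{var}_rmsre"] = vals.max()
            row[f"max_{var}_gen"] = names[int(vals.argmax())]
        rows[case["name"]] = row
    out = pd.DataFrame(rows).T
    out.attrs["reference"] = cases[0]["name"]
    out.attrs["reference_wct_s"] = ref.meta["wall_clock_s"]
    return out


# ---------------------------------------------------------------------------
# steady-state autoregulation curve
# ---------------------------------------------------------------------------

def autoregulation_curve(topology: NetworkTopology, final_pressures, *,
                         modes=("control", "zero_ca"),
                         p_start: float = 50.0,
                         ramp_window=(120.0, 130.0),
                         t_end: float = 360.0,
                         dt: float = 2.5e-4,
                         coupling_mode: str = "weak",
                         averaged: bool = True,
                         drift_window: float = 10.0,
                         drift_tol: float = 1e-5,
                         Pout: float = 50.0, P_ext: float = 10.0,
                         sample_dt: float = 1e-2,
                         **kwargs) -> pd.DataFrame:
    """Steady-state flow and diameter across final inlet pressures and modes.

    For each (final pressure, calcium mode): hold p_start, ramp linearly to
    the final pressure over ``ramp_window``, run to t_end, then report the
    root-vessel flow and the per-generation mid-vessel luminal diameters at
    the final sample, plus a steadiness flag (max relative drift of all probe
    variables over the trailing ``drift_window`` below ``drift_tol``).  When
    both modes are present, per-generation diameter ratios (control over
    zero_ca) are appended as columns ``ratio_d_i:G*``.
    """
    sig_params = kwargs.pop("signalling", None) or SignallingParams()
    results = {}
    for p_final in final_pressures:
        spec = SignalSpec("ramp", {"t0": ramp_window[0], "t1": ramp_window[1],
                                   "p0": p_start, "p1": p_final})
        signal = make_signal(spec)
        for mode in modes:
            topo = copy.deepcopy(topology)
            if topo.inlet is None:
                attach_boundaries(topo, signal, Pout=Pout, P_ext=P_ext)
            else:
                topo.inlet.signal = signal
            cfg = CouplingConfig(mode=coupling_mode, dt=dt,
                                 averaged_active_stress=averaged)
            sim = Simulator(topo, cfg, signal,
                            signalling=sig_params.with_mode(mode), **kwargs)
            rec = sim.run(t_end, sample_dt=sample_dt)
            gens = sorted({c.split(":")[0] for c in rec.data.columns if ":" in c})
            tail = rec.data[rec.data.index >= t_end - drift_window]
            drift = 0.0
            for g in gens:
                for var in ("Q", "d_i"):
                    col = tail[f"{g}:{var}"]
                    scale = max(abs(col.iloc[-1]), 1e-30)
                    drift = max(drift, float((col.max() - col.min()) / scale))
            row = {"steady": drift < drift_tol, "drift": drift,
                   "Q_root": rec.data[f"{gens[0]}:Q"].iloc[-1]}
            for g in gens:
                row[f"d_i:{g}"] = rec.data[f"{g}:d_i"].iloc[-1]
            results[(p_final, mode)] = row
    out = pd.DataFrame(results).T
    out.index.names = ["P_final", "mode"]
    if set(modes) >= {"control", "zero_ca"}:
        gens = [c.split(":")[1] for c in out.columns if c.startswith("d_i:")]
        for g in gens:
            ctrl = out.loc[(slice(None), "control"), f"d_i:{g}"].droplevel("mode")
            free = out.loc[(slice(None), "zero_ca"), f"d_i:{g}"].droplevel("mode")
            ratio = ctrl / free
            for p_final in ratio.index:
                out.loc[(p_final, "control"), f"ratio_d_i:{g}"] = ratio[p_final]
    return out
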