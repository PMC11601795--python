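# Methods

`myoflow` simulates blood flow through networks of small cerebral arteries
whose smooth muscle develops pressure-dependent (myogenic) tone.  Three
coupled sub-models run per time step at every network node: the 1-D
pressure–flow equations over the whole tree, an intracellular signalling
system per wall cross-section, and a multi-layer chemo-mechanical wall model
that returns luminal area and compliance to the fluid.  This note records the
governing equations as implemented, the numerical choices, the default
parameters and their provenance, and the limitations a user should know
before trusting a result.

## 1-D haemodynamics

Mass and momentum conservation for laminar, axisymmetric flow with a
Poiseuille velocity profile, in pressure–flow form:

    C_A ∂P/∂t + ∂Q/∂z = 0
    (ρ/A) ∂Q/∂t + (ρ/A) ∂(Q²/A)/∂z + ∂P/∂z + 8πμ Q/A² = 0

with compliance C_A = ∂A/∂P supplied by the wall model.  The system is
linearized in time: the coefficients C_A and A multiplying the time
derivatives are frozen at the current coupling iterate, and the convective
term is evaluated fully at the previous step.  The viscous drag keeps its
frozen-area coefficient but acts on the *new* flow.  This last choice is
deliberate: treating the drag explicitly is unconditionally unstable at the
calibers this package targets — for a 30–100 µm lumen the drag rate
8πμ/(ρA) is 10⁴–10⁵ s⁻¹, so dt·k ≫ 1 at any affordable time step — whereas
the term is linear in Q and costs nothing to take implicitly.

Each vessel is divided into two-node elements (two per vessel by default).
Both equations are integrated over each element with the trapezoidal rule;
time derivatives use second-order backward differences (BDF2), bootstrapped
with backward Euler on the first step.  Junctions impose static pressure
continuity and mass conservation as explicit constraint rows (no
pressure-loss model, and no total-pressure correction); vessels do not share
nodes, so area and material properties may jump across a bifurcation.  The
inlet row prescribes the pressure signal; each terminal row imposes
P − Z·Q = P_out with a characteristic impedance Z = ρc/A,
c = √(A/(ρC_A)), evaluated once from the initial state (a flag-free
re-evaluation can be requested through `FlowSolver.set_impedances`, which
the wave-reflection test uses to match Z at the settled working pressure —
the reference-state compliance sits in the soft toe of the passive curve).

The global system (2 unknowns per node) is assembled each step and solved
directly: dense LAPACK up to ~600 unknowns, sparse LU beyond.  Unknown
columns are scaled by representative pressure/flow magnitudes and rows are
equilibrated before the solve; the CGS spread of coefficient magnitudes
(~10¹⁴) otherwise erodes the factorization.  Both paths are deterministic
and iteration-free.

## Intracellular signalling

Seven normalized variables per wall cross-section: Ca²⁺ (ξ0), ROCK (ξ1),
HSP27/PKC-pathway phosphorylation (ξ2), MLCP phosphorylation (ξ3), cofilin
phosphorylation (ξ4), LC20 phosphorylation (ξ5), G-actin content (ξ6).
Each causal edge is a logistic link χ(x) = 1/(1+e^(−k(x−x₀))).  The three
pressure-facing rows relax toward their link outputs with a shared time
constant τ_c; the remaining rows are quasi-instantaneous and are replaced by
their algebraic targets each step, avoiding the stiffness a small explicit
time constant would introduce:

    ξ3 = 1 − χ3(ξ1)          (χ3 inverted: MLCP-P rises with ROCK)
    ξ4 = χ4(ξ2)
    ξ5 = χ5(ξ0) / (χ5(ξ0) + 1 − χ6(ξ3))     (production/degradation balance)
    ξ6 = 1 − χ7(ξ2)·χ8(ξ4)                  (logical OR of two actin sinks)

The F-actin level that loads the cortex stiffness is defined as
ξ7 ≡ 1 − ξ6 (complement of the G-actin pool).  The slow rows are integrated
with the explicit two-step Adams–Bashforth method (forward Euler on the
first step).  Within a strongly coupled step the drive pressure is the
current fluid iterate, so signalling participates in the fixed point.

The link wiring and parameters are repository defaults, chosen once so that
(a) Ca²⁺ rises sigmoidally across 10–120 mmHg (half-activation 45 mmHg),
(b) ROCK — and through it MLCP phosphorylation — barely moves below
60 mmHg (half-activation 80 mmHg), and (c) cytoskeletal stiffening engages
at intermediate pressures.  They are illustrative, not fitted to recordings;
every link is exposed in configuration.  Pharmacology is a mode switch on
the Ca²⁺ drive: `control` uses the full pressure link, `diltiazem` a
low-amplitude residual (stretch-operated channels under L-type block:
amplitude 0.1, gentle slope centred at 60 mmHg), `zero_ca` clamps the
target to zero.  Because luminal pressure is the only external input of the
graph, signalling is computed once per wall node; per-layer copies would be
bitwise identical.

Defaults: τ_c = 10 s (the value that best matches step-response transients
of pressurized cerebral vessels); Ca²⁺ output scale 230 nM.

## Wall mechanics

The wall is an incompressible hyperelastic thick-walled tube whose volume is
treated as smooth muscle, subdivided into n_CL = 5 concentric layers.
Kinematics map reference radius R to deformed radius
r = √((R²−Ri²)/(k_ω λ_z) + r_i²); λ_θ = k_ω r/R and λ_r = R/(r k_ω λ_z), so
λ_r λ_θ λ_z = 1 identically.  The transmural balance

    P = P_ext + ∫ (λ_θ ∂Ψ/∂λ_θ − λ_r ∂Ψ/∂λ_r) dR/(λ_θ λ_z r)

is integrated with composite Simpson's rule on n_CL equally spaced nodes
spanning the full thickness [Ri, Ri+H]; each node doubles as an SMC layer
location.  (Placing the nodes at mid-shell positions was considered and
rejected: a 5-point rule supported on 80 % of the thickness misestimates the
integral by the missing edge strips, far outside the accuracy the 5-point
rule itself achieves on the full interval — the bundled quadrature test
demands 0.5 % against a 1001-point reference.)

Passive energy (media + circumferential collagen family at angle φ = 0):

    Ψ_p = c0(I1 − 3) + c1/(2c2)·(exp[c2(I4 − 1)²] − 1)

Active machinery per layer: contractile fibres (surface density N_CF) are
chains of N_CU contractile units in series with an actin-cortex spring at
each end.  Displacements are normalized by the myosin filament length L_m.
Cycling cross-bridges produce the driving force
Fc = L̄_fo (L_m/δ_m) ξ5 n_XB k_XB u_PS and chain stiffness
k_tCU = L̄_fo L_m ξ5 n_XB k_XB/(2 δ_m N_CU), both scaled by the Gaussian
filament-overlap factor L̄_fo(u_fs).  The cortex stiffness is a Hill
function of F-actin, k_AC = k_AC_max ξ7ⁿ/(ξ7ⁿ + K_ACⁿ).  The elastic
reaction is Fa = (λ_θ − 1 − 2N_CU u_fs)·k_ser with the series stiffness
k_ser = k_tCU k_AC/(2k_tCU + k_AC) (defined as 0 when both stiffnesses
vanish — no engaged machinery, no force).  Sliding evolves as
du_fs/dt = (Fa − Fc)/τ_m + (1/(2N_CU)) dλ_θ/dt, and the active
circumferential stress is ∂Ψ_a/∂λ_θ = N_CF k_ser (λ_θ − 1 − 2N_CU u_fs).

Per time step the n_CL sliding equations plus the pressure balance form a
nonlinear residual system in (u_fs,1..n_CL, A).  Both du_fs/dt and dλ_θ/dt
are discretized with the same two-step backward differences as the fluid
(backward Euler bootstrap) and solved by a damped Newton iteration.  The
Jacobian is an arrowhead (each u_fs,k touches only its own row and its own
layer's integrand) assembled from two structured directional differences per
iteration and solved by the Schur complement on the area column — all
vectorized across every node of the network at once.  Updates are limited to
20 % in area and 0.05 in sliding per iteration; convergence at 10⁻¹⁰
relative, failure raises a step error carrying residual norms.

The *averaged active stress* variant replaces the per-layer sliding by a
single variable driven by the Simpson-averaged λ̄_θ and applies the
resulting active stress uniformly across the thickness (passive stresses
stay layer-resolved), shrinking the per-node system to two unknowns.

Compliance: C_A = dA/dP by a centered difference of the transmural relation
at frozen sliding and signalling; the area perturbation targets a pressure
perturbation of 0.1 mmHg (small against the 10–120 mmHg working range, well
above solver noise), using the previous step's compliance as the scale.

### Wall parameter defaults

| parameter | value | note |
|---|---|---|
| c0 | 2.0e4 dyn/cm² | neo-Hookean ground matrix |
| c1, c2 | 2.0e4 dyn/cm², 8.0 | collagen fibre stiffening |
| L_m, δ_m | 2.2 µm, 14.3 nm | myosin filament length / head spacing |
| k_XB, u_PS | 0.4 dyn, 4.5e-3 | per-XB stiffness; power stroke (÷L_m) |
| N_CU, N_CF | 10, 1.5e6 cm⁻² | units per fibre; fibre surface density |
| s_f0/L_m, u_fs_opt | 0.2, 0.01 | overlap width / optimum |
| k_AC_max, n_AC, K_AC | 2.0 dyn, 2, 0.25 | cortex Hill curve |
| τ_m | 6.188e-2 s | sliding time constant (10³ × the aortic estimate) |
| k_ω, λ_z | 1.0, 1.0 | residual strain / axial stretch (not reported for these vessels) |

The contractile scales were calibrated once, before any acceptance run, to
three requirements and then frozen: negligible basal tone at 10–20 mmHg,
roughly 10 % diameter reduction versus passive at 50–60 mmHg, and a steady
active first Piola-Kirchhoff stress bounded by N_CF·Fc ≈ 4.2e5 dyn/cm²
(≈ 42 kPa, at the low end of reported active stresses in muscular arteries).
With k_ω = λ_z = 1 the stress-free reference equals the load-free state, so
a vessel specified by load-free outer diameter D_o and thickness ratio h_w
has R_mean = (D_o/2)/(1 + h_w/2), H = h_w R_mean, Ri = R_mean − H/2.

A consequence of this calibration worth knowing: at sliding equilibrium
(Fa = Fc) the active stress collapses to N_CF·Fc(L̄_fo), which depends on
the through-thickness stretch profile only through the weak overlap factor.
The averaged-active-stress variant therefore tracks the layer-resolved model
extremely closely here (steady diameters within ~10⁻⁵ relative), much closer
than the 2 % bound asserted for thin walls.

## Coupling

Strong mode iterates {fluid solve → signalling → wall solve → compliance}
within the step until the root-mean-square relative change of the luminal
areas over all wall nodes falls below ε = 10⁻⁶ (iteration cap 50, default);
weak mode performs exactly one pass.  Every iteration restarts signalling
and wall updates from the stored time-level-n states, so the accepted step
is a genuine fixed point rather than an accumulation.  Divergence is a
first-class outcome: RMSRE growth over 10 consecutive iterations, an
iteration-cap hit, or any non-finite field aborts the run with diagnostics
and a timestamp.  No under-relaxation is applied to the area updates; plain
substitution converges in 1–3 iterations at the study time steps because the
per-step area change is small.

Initial conditions: nodal pressure equals the first inlet value, flow is
zero, all signalling variables are zero, sliding is −2e-2 and λ_θ = 1
(areas at the reference configuration).  The first step therefore contains a
large wall-equilibration transient; this is intentional and reproducible.

## Inlet signals and the synthetic-data generators

All driving data are generated, seeded and pure functions of their
specification: constant levels, alternating step trains (the cannulated
myography protocol, 10↔60 mmHg), linear ramps (50→120 mmHg surges), and a
*variable-mean periodic* signal — a 2 Hz, 4 mmHg sinusoid superposed on a
piecewise-linear mean whose breakpoints are drawn uniformly from
[58, 82] mmHg every 2 s by a seeded generator.  That envelope keeps the
inlet above the 50 mmHg outlet so network flow never reverses (flow RMSRE is
undefined through zero crossings).  The generator emulates a fluctuating
upstream perfusion pressure with a cardiac-frequency component; it does not
reproduce measured MCA waveforms (no dicrotic features, rat heart rates are
faster than 2 Hz, and the mean walk is uncorrelated), so accuracy figures
obtained with it characterize the numerics, not any particular physiology.

## Experiment harnesses and problem sizes

The settings-comparison harness runs a case table (reference first) on deep
copies of one network, samples mid-vessel probes every 10⁻² s, excludes the
t = 0 sample (both solutions start at zero flow) and reports per-generation
and mean/min/max RMSRE for flow and area plus wall-clock relative to the
reference.  The shipped table compares the strong/layer-resolved reference
at dt = 10⁻⁴ s against coarser, weak and averaged variants at
dt ≤ 2.5e-4 s over a 10 s horizon — the horizon this package adopts for its
accuracy study; `scripts/acceptance.py` reproduces exactly that comparison.
The steady-state autoregulation harness ramps the inlet from 50 mmHg to a
set of final pressures under control and 0 Ca²⁺ modes and reports root-vessel
flow and per-generation diameter ratios, flagging non-steady termination by
the relative drift over a trailing window (10⁻⁵ over 10 s at full scale; the
test suite uses an 8 s horizon with a 2 s window, where the control runs are
still approaching tone equilibrium — the reported orderings are insensitive
to this, the absolute flows are not converged steady values).

## Known limitations

- No flow/shear-driven tone, metabolic control, or parenchymal beds; the
  autoregulation curve rises with inlet pressure rather than plateauing.
- The signalling graph parameters are plausible defaults, not identified
  against intracellular recordings; quantitative Ca²⁺/diameter traces should
  be read as illustrative.
- Single collagen family at φ = 0, SMC-only wall volume, no viscoelasticity
  or axial force balance.
- Vessel collapse (negative transmural pressure) is outside the admissible
  range; the wall solver raises rather than continuing.
- Three-element Windkessel outlets are not implemented (characteristic
  impedance only), and the fluid linearization assumes the convective term
  is small at these calibers.
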