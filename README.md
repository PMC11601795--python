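# myoflow

Blood flow dynamics across myogenically active cerebral arterial networks.

Small cerebral arteries are not passive pipes: their smooth muscle senses
luminal pressure and constricts against it (myogenic tone), which stabilizes
downstream flow and perfusion pressure when upstream pressure swings.
`myoflow` is a research simulator for this behaviour, aimed at computational
physiologists and vascular biomechanics groups who want to connect
intracellular signalling hypotheses to network-level haemodynamics — e.g. to
ask how a Ca²⁺-channel blocker or a pressure surge redistributes flow across
an arterial tree.

## What it computes

Three coupled models, advanced together in time:

- **1-D network haemodynamics** — mass and momentum conservation in
  pressure–flow form, `C_A ∂P/∂t + ∂Q/∂z = 0` and
  `(ρ/A)∂Q/∂t + (ρ/A)∂(Q²/A)/∂z + ∂P/∂z + 8πμQ/A² = 0`, discretized with
  trapezoidal two-node elements and BDF2 in time, with junction continuity
  and reflection-absorbing characteristic-impedance outlets (Z = ρc/A,
  c = √(A/ρC_A)).
- **Intracellular signalling** — seven normalized variables (Ca²⁺, ROCK,
  HSP27, MLCP-P, cofilin-P, LC20 phosphorylation ξ5, G-actin ξ6) wired by
  logistic links and driven by luminal pressure; pharmacological modes for
  Diltiazem and extracellular Ca²⁺ removal.
- **Wall chemo-mechanics** — an incompressible hyperelastic thick-walled
  tube of smooth-muscle layers; cross-bridge cycling generates force
  `Fc ∝ L̄_fo ξ5` against contractile-unit/actin-cortex elastic chains, the
  filament sliding u_fs evolves as
  `du_fs/dt = (Fa − Fc)/τ_m + (1/2N_CU) dλ_θ/dt`, and the transmural balance
  `P = P_ext + ∫(λ_θ Ψ_λθ − λ_r Ψ_λr) dR/(λ_θ λ_z r)` returns luminal area
  and compliance `C_A = dA/dP` to the fluid.

Fluid and wall are coupled either **weakly** (one sequential pass per step)
or **strongly** (fixed-point iteration until the area RMSRE across the
network falls below ε = 10⁻⁶).  See `docs/methods.md` for the full model
account, parameter tables and limitations.

## Worked example: pressure-step myography

A cannulated 135 µm (load-free) rat middle cerebral artery, pressure stepped
between 10 and 60 mmHg, under control conditions vs abolished tone (0 Ca²⁺):

```python
from myoflow import SignalSpec, make_signal, single_vessel_protocol

signal = make_signal(SignalSpec("step_train", {"levels": [10.0, 60.0], "hold": 120.0}))
control = single_vessel_protocol(signal, "control", dt=0.5, t_end=240.0)
passive = single_vessel_protocol(signal, "zero_ca", dt=0.5, t_end=240.0)

for t in (100.0, 230.0):
    c, p = control.loc[t], passive.loc[t]
    print(f"t={t:5.0f} s  P={c.P:4.0f} mmHg   "
          f"d_o control={c.d_o*1e4:6.1f} um (Ca {c.Ca_nM:5.1f} nM, xi5 {c.xi5:.2f})   "
          f"d_o 0Ca={p.d_o*1e4:6.1f} um")
```

prints

```
t=  100 s  P=  10 mmHg   d_o control= 134.4 um (Ca  25.1 nM, xi5 0.01)   d_o 0Ca= 134.8 um
t=  230 s  P=  60 mmHg   d_o control= 148.1 um (Ca 163.5 nM, xi5 0.50)   d_o 0Ca= 157.1 um
```

At 10 mmHg there is essentially no tone (Ca²⁺ 25 nM, LC20 phosphorylation
ξ5 ≈ 0) and the control vessel matches the passive one.  Pressurizing to
60 mmHg raises wall Ca²⁺ to 164 nM (of a 230 nM full scale) and
phosphorylates half the myosin light chains; the developed tone holds the
outer diameter 9 µm below the passive vessel.  The transients relax with the
signalling time constant τ_c = 10 s.

Network simulations run the same physiology over a symmetric 4-generation
middle-cerebral-artery tree (generation diameters scaled by a parent/daughter
area ratio of 1.35, wall thinning 90/80/70 %), either through the library
(`Simulator`, `settings_comparison`, `autoregulation_curve`) or the CLI:

```bash
myoflow run config.yaml -o out/            # probe CSV + run metadata
myoflow compare-cases config.yaml -o out/  # accuracy/cost table across settings
myoflow autoreg-curve config.yaml -o out/  # steady pressure-flow sweep
```

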