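# Methods

## Scope and model chain

`deptrap` models the trapping of single cells by negative
dielectrophoresis (nDEP) above a planar ring electrode at the floor of
a shallow microfluidic channel. The chain is:

1. **Dielectrics** — the frequency response of cell and medium enters
   through the Clausius–Mossotti (CM) factor
   `f_CM = (ε*_p − ε*_m)/(ε*_p + 2ε*_m)` with `ε* = ε − jσ/ω`.
2. **Field** — the electro-quasistatic potential of the ring trap,
   solved once per geometry/voltage; the DEP drive is `∇E²_rms`.
3. **Transport** — overdamped trajectories under DEP force, Stokes
   drag, optional channel flow and optional buoyant gravity.
4. **Pipeline** — a declarative config ties the three together into a
   reproducible ensemble experiment.

## Dielectric model

Cells are either homogeneous spheres or, by default, single-shell
cells: a conductive cytoplasm sphere (ε = 7.1×10⁻¹⁰ F/m, σ = 0.75 S/m)
coated by a thin insulating membrane (ε = 1.8×10⁻¹² F/m,
σ = 1×10⁻⁷ S/m). The shell is collapsed to an equivalent homogeneous
sphere with the radius-ratio-cubed Maxwell–Garnett form

```
ε*_eff = ε*_mem (γ³ + 2K)/(γ³ − K),  γ = R/(R−d),
K = (ε*_cyt − ε*_mem)/(ε*_cyt + 2ε*_mem)
```

before the CM factor is evaluated. Two parameters are not measurable
from the device description and carry package defaults:

* **membrane thickness d = 5 nm** — lipid-bilayer scale; the result is
  insensitive to it at MHz frequencies;
* **medium conductivity σ_m = 1.5 S/m** — typical of neuronal culture
  media. With it the default operating point (10 MHz) gives
  Re[f_CM] = −0.488, deep in the nDEP regime; the test-suite pins this
  sign, since the whole trapping concept relies on nDEP.

All permittivities are handled as absolute values (F/m). Sinusoidal
drive is specified peak-to-peak: amplitude = Vpp/2,
Vrms = Vpp/(2√2), ω = 2πf.

`crossover_frequency` finds the pDEP/nDEP sign change of Re[f_CM] by
bracketing in log-frequency (Brent's method, relative tolerance well
below 1e-6); with the default cell/medium pair there is no crossover —
the response is nDEP over the entire 1 kHz–1 GHz band.

## Field solver

Because the electrode is a ring, the potential is treated as
cylindrically symmetric and solved on a uniform (r, z) grid from

```
(1/r) ∂r(r ∂r φ) + ∂²z φ = 0
```

with the standard second-order 5-point stencil, the regularised axis
stencil at r = 0 (∂φ/∂r = 0), Dirichlet strips at z = 0 (ring annulus
at +Vrms, counter plane at 0 from its inner radius to the domain rim)
and homogeneous Neumann (insulation) everywhere else. Electrodes are
infinitesimally thin: the 250 nm ITO and the SiO₂ passivation (which
covers pads, not trap electrodes) are neglected. A single ring is
modelled; neighbouring traps in the array sit ~120 µm apart and their
cross-coupling is ignored. The solve domain spans half the channel
width radially (125 µm) and the full 40 µm height; extents snap to
whole grid cells.

Numerical choices:

* sparse **direct solve** (`scipy.sparse.linalg.spsolve`); the PDE rows
  are scaled by h² so the post-solve residual check against
  `solver_tolerance` (default 1e-8, achieved ~1e-15) is meaningful;
* default spacing 0.5 µm (81 × 251 nodes, sub-second solve); spacing
  is validated against the ring radius so the trap is resolved;
* `E = −∇φ` and `∇E²` by central differences with **second-order
  one-sided edges** — first-order edges would contaminate `∇E²` near
  the boundaries by O(h) through the squaring;
* off-grid sampling is bilinear, exact at nodes.

The solver is verified against three closed forms: the parallel-plate
override (|E| = Vrms/h to 0.1%), the axisymmetric quadratic harmonic
`a z² − a r²/2` (reproduced to rounding; derived fields to second
order), and a smooth Bessel-mode harmonic `e^{kz} J₀(kr)` for the
grid-refinement ratio. The refinement test uses the Bessel mode rather
than the capacitor field because the 5-point stencil is *exact* for
linear and quadratic potentials — the capacitor error is machine noise
at any spacing, so an error-ratio test is only well-posed on a
non-polynomial solution.

**Field topology.** With the default geometry and drive, E² on a plane
2.5 µm above the floor has its minimum on the trap axis and its maximum
at the ring's outer edge in the electrode gap — the invisible-wall
structure that collects an inner cell and repels outer ones. This
statement is evaluated over the trap region (r ≤ 60 µm, the counter
electrode's inner edge). Beyond it the field above the grounded plane
decays monotonically toward zero, so the *global* minimum over the
numerical domain sits at the arbitrary outer rim — a truncation
artifact with no physical content, which is why the claim is scoped to
the region the electrodes define.

## Transport model

Particle Reynolds and Stokes numbers at this scale are ~10⁻⁴–10⁻²,
so inertia is dropped and velocity balances force:

```
dx/dt = u_flow(z) x̂ + (F_DEP + F_gravity)/(6πηR)
```

* **Flow**: plane-Poiseuille between floor and ceiling,
  `u(z) = 6 u_mean (z/h)(1 − z/h)` with `u_mean = Q/(hw)`; the channel
  is ~6× wider than tall, so the side-wall correction is neglected. At
  the default 2.5 µL/min, u_mean = 4.17 mm/s.
* **Gravity**: buoyancy-corrected weight, defaults ρ_cell = 1050,
  ρ_medium = 1000 kg/m³, η = 1.0 mPa·s → settling at ~2.7 µm/s.
* **Integration**: classical fixed-step RK4, default dt = 0.1 ms over
  a 2 s window; every step is recorded. Convergence is 4th order
  (verified against the exponential closed form of a linear restoring
  trap, matched to 1e-6 relative at dt = 1e-4 s).
* **Walls**: the particle centre is confined to R ≤ z ≤ h − R; at
  contact the wall-normal velocity is absorbed and sliding continues
  (no Faxén drag correction — a documented simplification).
* The axisymmetric field is mapped to 3-D by distance from the trap
  axis; the azimuthal force component is zero by symmetry. Beyond the
  solved radial extent the DEP force is taken as zero (far field); a
  particle crossing the domain rim ends its trajectory as advected.

Outcome labels follow the precedence **trapped > advected > repelled >
settled**: trapped means field on, final lateral distance inside the
ring inner radius and final speed below 1 µm/s; advected means the
particle left the domain; repelled means it ended ≥ 5 µm above its
start while laterally outside the ring; settled means floor contact
with the field off. A trajectory matching no rule is labelled by its
tendency (rising → repelled, floor contact → settled, else advected).

**Gravity default in the trap scenario.** The packaged default config
runs the ensemble with gravity *off*. Over the 2 s simulated window
sedimentation (≲ 5 µm) is marginal for inner particles but qualitatively
wrong for outer ones: with gravity on, a particle beyond the counter
electrode is first pushed radially outward into the weak-field zone and
then sinks, whereas the modelled device repels such particles upward —
which is also what a DEP-drift-only trajectory model produces. Gravity
remains fully implemented and configurable; switching the drive off
with gravity on reproduces the plate-down-for-culture behaviour.

**Lyapunov structure.** With flow and gravity off, nDEP dynamics is a
descent flow on the E² landscape (velocity ∝ −∇E²), and the constrained
wall sliding preserves descent since the projected gradient still has
non-negative inner product with the gradient. The suite asserts E² is
non-increasing at every recorded step to 1e-9 relative.

## Ensemble scenario

The synthetic ensemble emulates an initially uniform cell suspension:
default 50 particles, uniform over x ∈ [−120, 120] µm, y = 0,
z ∈ [5, 35] µm (5 µm wall clearance for the 5 µm cell), seed 42, drawn
from numpy's PCG64 (`default_rng`) — one named generator, explicitly
seeded, no global state. The ensemble lives in the (x, z) cross-section
plane the trap is visualised in; snapshots are captured at 0.3, 1 and
2 s. With flow off, every particle seeded inside the ring (lateral
< 20 µm, z < 20 µm) ends trapped at the centre by 2 s and every
particle beyond 60 µm ends above its initial height.

Frequency sweeps reuse a single field solve: the DEP force factorises
exactly into the geometry term ∇E² (fixed at fixed voltage) and the
dielectric factor Re[f_CM], so only the prefactor changes per
frequency. With a low-conductivity medium the same machinery shows the
pDEP regime: Re[f_CM] > 0 and nothing collects at the ring centre.

Determinism: a config (which includes the seed) fully determines every
artifact byte. Trajectory CSVs are thinned by a configurable
`export_stride` (default: every 100th recorded state plus the final
one); the in-memory trajectories keep every step.

## What the synthetic conditions do not capture

Brownian motion (for a 5 µm cell the DEP velocities here exceed
diffusive displacement scales by orders of magnitude, but near-zero
field regions would show jitter), particle–particle dipolar
interactions and hydrodynamic coupling, cell deformability, electrode
polarization/double layers, AC electro-osmosis and electrothermal flow,
and the multi-trap relay sequencing of a full electrode array. Passing
tests therefore validate the single-trap, dilute, drift-dominated
picture — not crowding or near-electrode electrokinetics.

## Problem sizes

Defaults were chosen so a full ensemble experiment is interactive on
one core: the 0.5 µm field solve is ~0.3 s, and 50 particles × 20 000
RK4 steps integrate in ~15 s. Test and acceptance runs reuse a cached
2 µm field where only topology matters.
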