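# Methods

## The model

`sproutsim` simulates the proteolytic release of matrix-sequestered VEGF
around a single endothelial sprout at molecular-kinetic detail.  The sprout
is an impermeable cylinder (radius 2 µm) spanning the lower half of an
axisymmetric tissue domain; its leading 40 µm is the tip cell.  A 43 nm
basement membrane (BM) sheathes the sprout.  Three diffusible species —
VEGF₁₆₅, its N-terminal cleavage product VEGF₁₁₄, and a generic active
protease P — move through ECM and BM treated as porous media, alongside two
immobile species, free HSPG binding sites H and the complex VEGF₁₆₅·HSPG.

Volumetric chemistry (mass action in the interstitial pores):

    V165 + H  ⇌  V165·H            kon_H = 4.2e5 M⁻¹s⁻¹, koff_H = 0.01 s⁻¹ (Kd ≈ 24 nM)
    V165 + P  →  V114 + P          kP = 631 M⁻¹s⁻¹ (37 °C effective one-step)
    V165·H + P →  V114 + P + H     same kP (HSPG does not protect VEGF here)
    P → ∅                          kdeg (optional inactivation)

Surface chemistry, confined to the BM layer: VEGFR2 under constant insertion
sR2 = kint·[R2]ₜₒₜ and internalization kint binds free VEGF₁₆₅ and VEGF₁₁₄
with identical constants (kon 1e7 M⁻¹s⁻¹, koff 1e-3 s⁻¹, so the apparent
dissociation constant including internalization is (koff+kint)/kon = 128 pM).
HSPG-bound VEGF cannot reach receptors.  Cleaved VEGF has lost its
matrix-binding domain and never binds HSPG.

Two boundary-condition cases:

* **isolated** — a 1200 µm × 1200 µm half-domain with Dirichlet fluid
  concentrations on all outer faces (far-field VEGF₁₆₅ 1 pM); measures the
  capability of one cell.
* **tissue** — an 80 µm × 50 µm cell of a sprout array: no-flux at the
  radial edge, VEGF secreted across z = +L and cleared by a first-order
  sink at z = −L, calibrated so the protease-free state has a 1 pM mean and
  a 5%/40 µm gradient at z = 0.

## Frames and units

Porous-media concentrations come in two frames related by the available
volume fraction K_av: `bulk = fluid · K_av` (K_ECM = 0.85, K_BM = 0.20).
Field states are stored bulk-frame; BM-layer states fluid-frame; every rate
law evaluates bimolecular products on *fluid* concentrations, because rate
constants are measured in free solution.  Internally lengths are µm, time s,
concentrations molar; amounts are tracked as molar·µm³ (1e-15 mol), which
makes receptor surface densities come out in mol/10¹⁵ µm² — the natural
magnitude for ~10⁴ receptors per cell (3.22e-8).

## Discretisation

Conservative finite volumes on a cylindrical (z, r) mesh: 8 µm axial
spacing, one radial voxel for the sprout interior (excluded from the fluid
domain for z < 0), 4 µm radial cells near the sprout widening to 8 µm
beyond 50 µm.  The `fine` policy halves all spacings; the refinement study
(coarse vs fine on the tissue case) moves every reported metric by < 5%.
The axis r = 0 is a zero-area face (no flux by symmetry), not a ghost-node
limit treatment.

The BM is geometrically unresolvable (43 nm vs 4 µm cells), so it is
carried as one dedicated state vector per axial wall node plus a tip
end-cap node.  Exchange with the first ECM ring uses a two-resistance
series conductance that keeps the interstitial-fluid concentration and the
diffusive flux continuous at the material interface; the ECM half-cell
resistance uses the cylindrical (log) form.  A brute-force 1-D solution
resolving the membrane with 20 sub-nodes agrees with this lumping to well
under 5%.  Tip-cell area includes the end cap: A_tip = 2πR·L_tip + πR² ≈
515 µm².

## Time stepping and iteration

First-order fully implicit steps; each step's coupled nonlinear system is
solved by red-black successive over-relaxation in which every unknown —
field cells, BM nodes, receptor pools — is updated from its own implicit
equation with partners at current iterates (each scalar update is exact
because bilinear kinetics are linear in one unknown at a time).  The sweep
terminates when the largest fractional per-node change is ≤ 1e-7 (fractional
changes are floored at 1e-9 of the species maximum so that near-zero nodes
are judged on an absolute scale).

Three safeguards around plain SOR, all documented consequences of testing:

* **Constant-mode deflation** — with flux/Robin-only boundaries the global
  mass mode is so weakly pinned that SOR updates fall below tolerance while
  the solve is far from done; each sweep therefore ends with a uniform
  shift that zeroes the summed residual (exact for the offending mode).
* **Projected-error stall guard** — for the same boundary class, sweep
  convergence additionally requires the geometric-series projection of the
  remaining change (from the observed contraction factor) to be below
  tolerance.  Dirichlet-pinned species skip both safeguards.
* **Step backoff** — a step that exhausts its sweep budget is retried at
  half the dt.

Pseudo-time marching starts at dt = 0.1 s growing ×1.2 per step to a 600 s
cap (receptor transients are stiff early; late drift is slow).  The initial
guess for each step is the linear extrapolation of the two previous states
(clipped at zero); near steadiness the extrapolation is switched off,
because continuing a noise-level drift is exactly what a cheap implicit
solve will accept.  Steady state is declared when the sustained drift —
the fractional change measured across five-step windows, per simulated
hour — stays below 1e-6 for two consecutive windows; single-step changes
sit at the per-step solver noise and are not a reliable signal.  This is
the package's operational definition of "steady", since none is inherited.

**Steady-state presolve.**  Because each species' steady equation is
linear given its partners, the march is seeded by direct sparse solves in
cascade order (protease, which nothing feeds back on; then VEGF₁₆₅; then
VEGF₁₁₄, which feeds back on nothing).  The bound HSPG pool is eliminated
analytically inside the VEGF₁₆₅ solve: at pM VEGF — four orders below Kd —
the equilibrium complex is linear in free VEGF, so cleavage of the bound
pool folds into an effective sink kP·[P]·(1+γ) with γ the bound/free
ratio under cleavage, kon·H_tot/(koff + kP·[P]).  Only the weak receptor
feedback is Picard-iterated.  The march, started at the dt cap, remains
the arbiter: if the seed is off, the drift criterion keeps marching.
This cuts the isolated-sprout scenarios from tens of minutes to tens of
seconds and leaves every steady-state answer unchanged (the
dt-path-independence test runs with the presolve disabled).

The SOR relaxation factor defaults to ω = 1.5 and is tunable; scenario runs
use the classical mesh-tuned estimate 2/(1+sin(π/n)), which matters on the
300×157 isolated-sprout grid.

## Scenario protocol

Every experiment is (1) a protease-free reference solve, (2) imposition of
the HSPG pools from binding equilibrium ([V₁₆₅H] = [V][H]ₜₒₜ/(Kd+[V]),
valid because the soluble steady state is HSPG-independent without
proteases), then (3) the protease stage: secreted flux (3e6 molecules/h
over the tip), a clamped uniform field, or a fixed count tethered in the
tip's BM pores (1e5 molecules ≙ 37.5 µM).  In the secreted mode the
protease field is marched to its own steady state first — it has no VEGF
feedback — and then frozen under the VEGF march.

The tissue case is initialised in stages: a Dirichlet gradient solve
without HSPG while receptors equilibrate; conversion to flux boundaries by
a flux audit of that solution (q = area-averaged influx at z = +L, k_clear
= efflux over bulk concentration at z = −L); re-convergence; HSPG
imposition.  The audit reproduces the reference clearance coefficient
(0.0866 µm/s, overall 5.41e-4 s⁻¹) to a few tenths of a percent.  The
companion printed secretion flux (7.68e-5 molecules µm⁻²s⁻¹) is *not*
consistent with the other printed constants (it would put ~1.7 pM rather
than 1 pM at z = 0 against the printed clearance); the calibration is kept
self-consistent instead, which is what the conversion predictions depend
on.

"Pericellular" metrics are area-weighted means over the tip cell's BM
nodes (wall nodes within 40 µm of the front, plus the end cap).  Reported
pericellular values elsewhere come without a stated averaging convention,
so this definition is fixed here and used everywhere.

## Synthetic cleavage time courses

VEGF₁₆₅ is a homodimer with two equivalent cleavage sites; the generator
integrates the sequential linear system D → I → C with first-cut rate
2·k₁[P] and second-cut k₂[P] (defaults k₂ = k₁), reports the fully
uncleaved dimer as "intact" (selectable to D+I), and adds Gaussian
densitometry noise (default study condition: effective kP = 631 M⁻¹s⁻¹,
40 nM protease, 10 points over 8 h, 2% noise).  It emulates ideal assay
sampling — no baseline drift, saturation, or protease decay — so parameter
recovery here bounds identifiability, not raw-assay robustness.  The fit
is nonlinear least squares of exp(−kP·[P]·t) with a case-resampling
bootstrap (200 replicates, seed 1729) for the uncertainty half-width.
Fitting at 25 °C vs 37 °C data is reflected in the shipped presets
(328 vs 631 M⁻¹s⁻¹); the simulator default is the 37 °C value.

## Numerical choices and degenerate inputs

* kP = 0 is a valid, tested configuration (proteolysis off).
* Zero receptors, zero HSPG, and bare-tip (no BM over the tip) variants are
  supported; the bare-tip surface nodes take ECM porosity and HSPG density
  and no membrane resistance.
* Conversion metrics guard against zero soluble VEGF (NaN, flagged) and
  clamp bound-conversion to [0, 1] against rounding.
* The isolated-case Dirichlet values are interpreted as interstitial-fluid
  concentrations (bulk values are K_av-scaled); they are compared against
  measured interstitial levels, which are pore concentrations.
* Problem sizes: the isolated case runs on its full 1200 µm domain
  (300×157 cells); directional-response suites (kdeg, domain size,
  receptor count) use geometrically similar 120–240 µm domains, which keep
  the monotone trends while staying cheap.

## Known limitations

* VEGFR1/NRP1 co-receptor coupling is out of scope; capture probabilities
  here are VEGFR2-only (hence ~0.8%, far below NRP1-assisted capture).
* No interstitial flow, no MMP activation/inhibition dynamics, no
  Michaelis–Menten saturation (the estimated Km far exceeds pM VEGF).
* The two-step heterodimer intermediate exists only in the kinetics-fitting
  module; the transport model uses the effective one-step reduction.
* The reported Damköhler number for surface-species lateral diffusion
  (Da = 160) is not reproducible from any printed constant combination and
  is treated as a documentation note, not a model input.
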