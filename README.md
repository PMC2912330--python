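# sproutsim

Reaction–diffusion modelling of proteolytic VEGF release around an
endothelial sprout.

Proteases (plasmin, MMPs) cleave matrix-binding VEGF₁₆₅ into freely
diffusible VEGF₁₁₄, releasing growth factor stored on extracellular-matrix
heparan sulfate proteoglycans (HSPGs).  Whether a single protease-secreting
cell can direct this release — and recapture the product through its own
receptors — is a quantitative question: it depends on the cleavage rate
constant, matrix binding kinetics, porous-media transport, and receptor
uptake all at once.  `sproutsim` puts those pieces into one tested
finite-volume simulator for people who want to interrogate the numbers:
quantitative cell biologists and modellers working on angiogenesis,
growth-factor gradients, or pericellular proteolysis.

## The model

An endothelial sprout (cylinder, radius 2 µm; tip cell 40 µm) sits in an
axisymmetric porous tissue domain.  Bulk and pore concentrations are
related by the available volume fraction K_av (`C_bulk = C_fluid·K_av`).
The coupled system, solved on a cylindrical (z, r) finite-volume mesh with
a single-node 43 nm basement-membrane (BM) layer along the sprout wall:

* transport: ∂[C]/∂t = ∇·(D_C ∇[C]) + R for C ∈ {V₁₆₅, V₁₁₄, P}
  (D = 68.8 µm²/s in ECM, 18.0 µm²/s in BM)
* binding: V₁₆₅ + H ⇌ V₁₆₅·H (kon = 4.2·10⁵ M⁻¹s⁻¹, koff = 0.01 s⁻¹,
  Kd ≈ 24 nM); immobile H, site-conserved
* proteolysis: V₁₆₅ + P → V₁₁₄ + P and V₁₆₅·H + P → V₁₁₄ + P + H, both at
  the effective one-step kP = 631 M⁻¹s⁻¹ (37 °C)
* receptors: VEGFR2 under insertion/internalization turnover
  (10⁴/cell, kint = 2.8·10⁻⁴ s⁻¹) binding free VEGF only
* two boundary cases: an isolated sprout in a 1200 µm domain with far-field
  clamps, or one sprout of many in an 80×50 µm tissue cell with calibrated
  secretion/clearance boundaries.

Time integration is fully implicit with red-black successive
over-relaxation; steady states are the quantity of interest.  See
`docs/methods.md` for the numerical treatment, parameter provenance and
limitations.

## A worked example

```bash
python examples/03_tissue_case_conversion.py
```

prints (abridged):

```
calibrated boundary conditions (from the Dirichlet-stage flux audit):
  VEGF secretion flux q = 4.53e-05 molecules um^-2 s^-1
  clearance k_clear     = 0.0869 um/s (overall rate 0.000543 s^-1)

steady state with a uniform 10 nM protease field, at z = 0:
  soluble VEGF165: 0.707 pM at the tip BM
  soluble conversion V114/(V165+V114) = 26.5 %
  HSPG-bound VEGF165 depleted by       26.6 %
```

Reading: against a ~0.9 h whole-tissue VEGF clearance time, a uniform
10 nM protease field (the collective output of many cells) converts about
a quarter of soluble VEGF₁₆₅ — while total soluble VEGF is unchanged, and
the matrix-bound pool shrinks in proportion.  Contrast with
`examples/04_single_cell_secretion.py`: one cell secreting 3·10⁶
enzymes/h in isolation accumulates only ~0.28 nM protease at its own
surface and produces a negligible 2.4·10⁻⁴ pM of cleaved VEGF — release
of matrix-bound VEGF is a tissue-level, not single-cell, phenomenon.

Other entry points: `examples/01_closed_form_estimates.py` (the analytic
numbers that frame the model), `examples/02_fit_cleavage_rate.py`
(effective-kP fitting from cleavage time courses), and the CLI:

```bash
sproutsim list-presets
sproutsim run --preset fig5-10nM
sproutsim sweep --preset fig5-10nM --axis protease_level=1e-9,1e-8,1e-7
sproutsim fit-kp course.csv
```

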