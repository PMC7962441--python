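# Methods

## Physical model

The phantom is a cylinder of dye-loaded gelatin (20 mm diameter, 11 mm
thick) irradiated from above by a 1064-nm beam.  The optical model is
absorption-only: scattering is neglected, so the fluence rate is separable,
`I(x,y,z) = I₀(x,y)·exp(−μ_a z)`, and the heat source is `Q = μ_a I`.
This is appropriate for a strongly absorbing dye phantom (μ_a = 1 mm⁻¹
gives a 1-mm penetration depth); it is *not* a tissue-optics model.

Two sources are implemented:

* **flat** — one macro-spot of radius r₀ = 4 mm.  Both a top-hat
  (`P/(π r₀²)` inside r ≤ r₀) and a power-normalised Gaussian
  (`P/(π r₀²)·e^{−r²/r₀²}`) profile are supported.  The Gaussian is the
  shape an end-firing multimode fiber actually delivers and is the profile
  used for the headline reproduction runs; the top-hat is retained as the
  literal reading of the printed source formula and runs as a sensitivity
  arm.
* **mla** — 145 Gaussian micro-beams (1/e radius 0.175 mm) on a 0.5-mm
  square lattice.  Lattice sites are ranked by distance from the optical
  axis (ties = complete shells, so the selection keeps the full point
  symmetry) and the innermost 145 kept; they fit inside r = 3.36 mm.  Power
  is split equally; per-beam mean irradiance at 1 W is 72 mW/mm² versus
  20 mW/mm² for the same power over the macro spot — the fractional
  concentration effect the package exists to quantify.

Heat transport is the Pennes equation reduced to a solid phantom: pure
conduction plus the optical source.  The advection velocity is exposed as a
constant fixed to 0 (a solid cannot advect) and no perfusion term is
modelled.  The top face carries a convective Robin condition
(h = 10 W/m²K against 20 °C air); all other faces are insulated.  Melting
is a *diagnostic threshold* (35 °C on the per-voxel peak temperature), not
a phase-change model: no latent heat, no material removal during the run.

Default material constants (gelatin phantom): μ_a = 1 mm⁻¹, ρ = 1060 kg/m³,
C_p = 3600 J/kg·K, k = 0.303 W/m·K, initial temperature 5 °C
(refrigerator-solidified gelatin), melt threshold 35 °C.

## Discretisation

Conservative cell-centred finite volumes on a uniform grid (default
dx = 0.1 mm, ~3.5 cells across a micro-beam diameter).  Cell-centring
places the first unknown at dx/2 from each face, which makes the
symmetry-plane and insulated boundaries exact zero-flux conditions; the
cylindrical wall is voxelised (staircase), acceptable because the beam
never comes within 4 mm of it.  The top Robin flux uses the series
resistance of half-cell conduction plus surface convection.  The source
array is cell-averaged: analytic averaging of `e^{−μ_a z}` in depth, 3×3
supersampling laterally, which keeps the absorbed power exact to <0.01 %.

Three symmetries: `full3d`, `quarter3d` (valid for both sources because the
lattice retains mirror symmetry), and `axisym_rz` for rotationally
symmetric flat-beam problems (used for cheap convergence and
cross-validation studies).

Time integration:

* **explicit** forward Euler (reference): monotone under the CFL bound
  dt ≤ dx²/(6α) (α = k/ρC_p ≈ 7.9·10⁻⁸ m²/s → dt ≈ 0.021 s at
  dx = 0.1 mm); the solver refuses larger explicit steps.  With the
  flux-form update, the global energy ledger (absorbed optical power vs
  stored heat + convective losses) closes to machine precision; the test
  suite enforces ≤1 % at every stored step.
* **adi** — Douglas–Gunn alternating-direction-implicit splitting,
  unconditionally stable, for long (e.g. 180-s) exposures; agrees with the
  explicit scheme within 0.06 °C on a shared 10-s problem (tested bound
  0.3 °C).

Verification anchors: the axisymmetric and quarter-3D solutions of the same
flat-beam problem agree within 0.03 °C; with h = 0 and μ_a = 50 mm⁻¹ the
surface layer follows the 1-D constant-flux solution
`ΔT = (2q/k)√(αt)·ierfc(z/2√(αt))` within 0.5 %; halving dx changes the
flat melt depth by <10⁻³ mm and the peak temperature by <10⁻² °C.

## Endpoints

Melt depth interpolates the deepest 35 °C crossing of the central-axis peak
profile linearly between grid planes; melt volume counts voxels whose peak
reached threshold (no sub-voxel interpolation), with an optional dx/2
refinement error bar; melt width is the widest chord of the surface
peak-isotherm.  Surface dosimetry of IR-like frames: `T_C` is the
centre-pixel value, `T_P` the mean over a one-pixel-wide annulus at
r = 4 mm (annulus, not a single pixel, for noise robustness), and the
treated area is pixel counting at/above threshold — deliberately the same
conventions a thermographer would apply to camera frames, so solver-derived
and synthetic frames are processed identically.

## Statistics

Group sizes of four make asymptotic rank tests untrustworthy, so the
Mann–Whitney U test enumerates all C(n_a+n_b, n_a) labelings of the pooled
midranks; the two-sided p-value is the fraction of labelings whose U
deviates from n_a·n_b/2 at least as much as observed.  Midranks make the
enumeration tie-aware, which matters for ordinal 1–3 histology scores
(complete separation at n = 4 vs 4 yields the attainable minimum
p = 2/70 ≈ 0.029).  Kruskal–Wallis uses the tie-corrected H and enumerates
exactly for total n ≤ 12 (34 650 partitions at 4+4+4), falling back to the
chi-square approximation above that; the method used is recorded in the
result.  Testing is two-sided throughout (the conservative convention;
direction is not prespecified by the design), and Bonferroni multiplicity
is the number of pairwise tests actually performed (3 for three groups).
A 10 000-replicate null simulation confirms the exact test's achieved size
at nominal 0.05 never exceeds 0.05.

## Synthetic data

The generators produce the *structure* the analysis assumes, not real-data
claims:

* frames: `T = T_base + ΔT_max(1−e^{−t/τ})·S(ρ) + ε`, S a unit-peak
  Gaussian or order-8 super-Gaussian (flat-top), ε i.i.d. Gaussian.
  Defaults (25 °C base, ~30–37 °C rise, τ = 40 s, 0.3 °C noise, 0.25 mm
  pixels) echo saturating solution-surface heating under the two delivery
  modes; they are labelled non-normative.
* caliper tables: control grows exponentially (0.25 /day), the flat arm
  regresses mildly to day 7 (0.05 /day) then regrows (0.35 /day), the mla
  arm decays monotonically (0.30 /day → day-14/day-0 ≈ 0.015, "almost
  eradicated"); day-0 volumes are lognormal around 60 mm³, measurement
  noise is multiplicative lognormal (cv 0.10) per axis, and the l/w aspect
  ratio is drawn once per animal from [1.0, 1.6].  Chosen once as
  field-realistic xenograft kinetics for days {0, 3, 7, 14}.

Not emulated: camera perspective/emissivity effects, biological
heterogeneity beyond lognormal size variation, treatment-volume coupling.
Passing tests therefore demonstrate correctness of the *pipeline* under the
assumed structure, not validity of that structure for any real dataset.

## Ambiguities resolved and problem sizes

The source conditions admit two power readings of the phantom exposure
(nominal 1 W/cm² over the 8-mm spot = 0.503 W, vs the tabulated 1 W laser
power) and two flat-beam shapes (top-hat per the printed formula, Gaussian
per the methods text).  All four arms are exercised by the acceptance
tests.  The headline reproduction uses the literal 1 W with the Gaussian
flat profile: it is the only arm in which the phantom melts at all, and it
reproduces both the reported flat melt depth (0.77 vs 0.8 mm) and the
measured flat crater volume (5.8 vs 4.9 ± 1.1 mm³).  With the micro-beam
lattice fully resolved, the MLA arm melts deeper (1.53 mm) and hotter
(+19.8 °C peak) than the reference simulation figures (1.1 mm, +7.1 °C),
which are consistent with a source representation that under-resolves the
0.35-mm micro-beams; the discrepancy is reported as-is rather than tuned
away, since the reference mesh resolution is unstated.

Default problem sizes: production runs use the quarter-symmetry grid at
dx = 0.1 mm (1.1 M cells, 750 explicit steps for 15 s, ≈0.5 min each);
convergence and cross-validation studies use the axisymmetric grid
(seconds) or coarser 3-D grids, sizes chosen so the full suite and the
acceptance script each run in minutes on a single core.

## Known limitations

Absorption-only optics (no scattering, no diffraction of the micro-lens
foci, beam waists assumed at the surface); no phase change or material
removal; voxelised cylinder wall; uniform material properties; the
exact Kruskal–Wallis enumeration cost grows multinomially (guarded by the
n ≤ 12 switch); synthetic fixtures are parametric idealisations as noted
above.
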