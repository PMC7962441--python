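# fracptt

Modelling and dosimetry for **fractional photothermal therapy (PTT)**: what
changes when the laser energy of a tumor treatment is delivered not as one
flat-fiber macro-beam but as a lattice of high-irradiance micro-beams from a
multi-lens array (MLA)?

The package is aimed at biomedical-optics researchers who want to

* simulate laser heating of an absorbing gelatin phantom under either
  delivery mode and extract ablation endpoints (melt depth/width/volume,
  peak temperatures, surface profiles);
* analyse surface IR-thermography frames (`T_C`/`T_P` centre-vs-edge
  dosimetry, treated area above a temperature threshold);
* compare small-animal tumor outcomes with exact nonparametric statistics.

## Model

Light is attenuated by Beer–Lambert absorption and deposited as volumetric
heat,

```
Q(x, y, z) = μ_a · I(x, y, z),          I(x, y, z) = I₀(x, y) · exp(−μ_a z),
```

where the surface irradiance `I₀` is either a single macro-spot profile
(top-hat or Gaussian, `P/(π r₀²)` scale, r₀ = 4 mm) or a sum of 145
Gaussian micro-beams (1/e radius 0.175 mm, 0.5 mm pitch, equal power split).
Heat transport follows the Pennes bio-heat equation for a solid
(zero-advection, zero-perfusion) phantom,

```
ρ C_p ∂T/∂t = ∇·(k ∇T) + Q,
```

with a convective (Robin) condition `−n·(−k∇T) = h (T − T_air)` on the
irradiated top surface and insulated remaining faces.  The solver is a
conservative cell-centred finite-volume scheme (explicit reference
integrator plus a Douglas–Gunn ADI option) on full/quarter 3-D Cartesian or
axisymmetric r–z grids.  Gelatin "ablation" is diagnosed by the 35 °C
peak-temperature isotherm.

Outcome statistics use the caliper volume `V = l·w²/2` and
Mann–Whitney U / Kruskal–Wallis tests whose p-values are computed by full
enumeration of group labelings (midranks, tie-aware) with Bonferroni
correction — appropriate at n = 4 per group, where asymptotic p-values are
unreliable.

A synthetic-data module generates IR-like frame stacks (saturating
exponential heating × Gaussian/flat-top spatial shape + sensor noise) and
three-arm tumor caliper tables (exponential growth / regress-then-regrow /
monotone decay), so the full pipeline runs without any external data.

## Worked example

```python
from fracptt import BeamSpec, MaterialProps, PhantomGeometry, solve, ablation_report

material = MaterialProps()                       # dye-loaded gelatin: μ_a=1/mm, 5 °C start
geometry = PhantomGeometry(dx_mm=0.1, symmetry="quarter3d")
flat = BeamSpec(mode="flat", irradiance_W_cm2=1.0, total_power_W=1.0,
                flat_profile="gaussian")
mla = BeamSpec(mode="mla", irradiance_W_cm2=1.0, total_power_W=1.0)

for name, beam in [("flat", flat), ("mla", mla)]:
    rep = ablation_report(solve(beam, geometry, material, duration_s=15.0))
    print(name, round(rep.melt_depth_mm, 2), round(rep.melt_volume_mm3, 1),
          round(rep.peak_surface_T_C, 1))
```

prints

```
flat 0.77 5.8 41.7
mla 1.53 37.5 61.4
```

i.e. after a 15-s, 1-W exposure the flat Gaussian macro-beam melts the
phantom to 0.77 mm on axis (5.8 mm³ total), while the same power split into
145 micro-beams melts to 1.53 mm with a 19.8 °C higher peak surface
temperature — the concentration effect (72 vs 20 mW/mm² local irradiance)
that motivates fractional delivery.

The same pipeline is scriptable from the shell:

```
fracptt simulate -c config.yaml -o runs/flat       # solver + ablation report
fracptt compare runs/mla runs/flat                 # fold-change table
fracptt synth caliper -o caliper.csv --seed 1      # synthetic fixtures
fracptt dosimetry --caliper caliper.csv -o stats/  # growth + exact tests
```

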