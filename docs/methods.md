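# Methods

## Physical model

**Electro-quasistatic approximation.** At 8 MHz the free-space wavelength
(~37 m) is far larger than the body, and tissue conductivities (0.04–0.61
S/m) are comparable to or larger than the displacement term ωε₀εᵣ (≈0.09 S/m
for muscle).  The fields therefore satisfy the complex scalar-potential
problem ∇·(γ∇φ) = 0 with γ = σ + iωε₀εᵣ.  We keep the complex admittivity
rather than a purely resistive model because for the boluses and fat the
displacement part is not negligible.  The drive is modeled as an ideal
constant potential V between the two electrode disks; the ±V/2 gauge split
is arbitrary and verified irrelevant.  V is interpreted as an RMS value, so
SAR = σ|E|²/ρ with no factor ½; this convention is echoed in every report.

**Pennes bioheat.**  ρc ∂T/∂t = ∇·(k∇T) − ρ w_SI ρ_b c_b (T − T_b) +
ρ(SAR + q_m).  Perfusion w is tabulated in mL/(min·kg) and converted once at
table load: w_SI = w·10⁻⁶/60 m³/(s·kg).  Blood constants are standard
literature values (ρ_b = 1050 kg/m³, c_b = 3617 J/(kg·K), T_b = 37 °C) and
are configurable; they are not part of the tissue tables.

## Boundary conditions

* Overlay boluses circulate chilled saline and are held at their fluid
  temperature (Dirichlet, default 5 °C).
* Regular boluses are Dirichlet at their fluid temperature only when they
  touch skin directly (the no-overlay arm, default 5 °C); when they rest on
  an overlay bolus they are outside the thermal domain.
* Exposed skin couples to 25 °C ambient air through a convective (Robin)
  boundary with h = 10 W/(m²·K), applied per face in series with the
  half-cell conduction resistance.
* Electrodes are adiabatic thermally and perfect conductors electrically
  (Dirichlet potential, coupled through the half-cell admittivity of the
  adjacent material).
* The grid boundary is insulating (zero normal current / adiabatic); the
  surrounding air is essentially non-conductive and is included in the
  electric domain with γ = iωε₀ only.
* The intergluteal-cleft bolus is saline-soaked gauze, not circulated: it is
  a passive material (c = 4180 J/(kg·K), k = 6 W/(m·K), no perfusion, no
  metabolic heat) that absorbs RF power, initialized at 10 °C in the
  transient path.
* Bolus water thermal conductivity k = 0.6 W/(m·K) is used only to couple
  the fixed-temperature bolus nodes to the skin faces.

## Discretization and solvers

7-point finite volume on the regular voxel grid, harmonic-mean face
coefficients (exact for series layered media — verified against the 1D
transfer-matrix closed form to better than 10⁻⁶).  The electric system is
complex symmetric and solved directly (SuperLU) up to ~4·10⁵ unknowns, above
that by ILU-preconditioned BiCGStab; converged solutions satisfy a relative
residual ≤ 10⁻⁸ (direct solves reach ~10⁻¹⁴).  E for SAR uses central
differences inside a material and one-sided differences at material and
electrode interfaces, so the field discontinuity at tissue boundaries is not
smeared.  The steady Pennes system is solved directly; the transient path is
backward Euler with a single LU factorization reused across all steps
(dt = 1 s grossly violates the explicit stability limit at millimetre
spacing, so an implicit scheme is mandatory).  The whole chain is linear in
V²: potential scales as V, SAR as V², and the temperature elevation above
the zero-power baseline as V² — asserted numerically to 10⁻⁸ and exploited
for exact potential calibration (closed form followed by a verification
re-solve).

Thin-slab fast profile: a 3-voxel axial slab through the tumor center with
all structures extruded along z and Neumann z-faces; the solvers detect the
z-invariance and solve a single layer.  Default spacings: 5 mm (3D), 2 mm
(thin slab).  Problem sizes used by the shipped studies: ~1.2·10⁵ voxels
(2 mm slab), ~4·10⁴ active electric unknowns per arm.

## Synthetic phantom

The phantom emulates an obese prone pelvis (BMI ≈ 29 analog): elliptical
torso 0.40 × 0.26 m, subcutaneous fat 25 mm ventral / 40 mm dorsal / 25 mm
lateral, smooth cos²-profile buttock pads thickening the dorsal fat to
65 mm around the midline, a V-shaped intergluteal cleft (55 mm deep, 20 mm
half-opening) carved into the pads, two lateral pelvic-bone blocks plus a
midline sacral block placed cranially of the target slice, paired lateral
visceral-fat pockets, and a 30 mm radius spherical tumor on the midline
30 mm dorsal of the torso mid-plane — just ventral to the cleft bottom, the
configuration in which a cleft bolus can matter.  The tumor carries muscle
properties.  Electrodes are 30 cm disks dorsal and ventral; regular boluses
fill the gap between electrode plane and skin (or overlay bolus); overlay
boluses are 10 mm conformal shells following the torso surface out to 10 cm
beyond the electrode rim, bridging (not entering) the cleft opening, and
ending 2 cm above/below the lateral equator so the dorsal and ventral pads
stay separate.  All dimensions are configurable; an optional seeded
smooth-harmonic surface roughness (default off) perturbs the torso outline.

What the phantom does *not* emulate: patient-specific anatomy (organ-level
structure, realistic bone, skin layer), fat distribution asymmetries, and
thermoregulation (temperature-dependent perfusion).  Consequently the
package reproduces the *mechanisms* of bolus optimization — hot-spot
localization per saline concentration, the overlay-bolus efficiency gain,
the cleft-bolus heating gain — rather than patient-specific temperature
values.

## Choices made where the design was open

* **Calibration statistic.**  "Heat the deep target to 40 °C" is read as the
  tumor *median* steady temperature (mean/max selectable); the choice is
  echoed in every report.
* **Overheating threshold semantics.**  Strict inequality (T > 44 °C), with
  the efficiency ratio rounded to 2 decimals only at reporting.
* **SF-edge band.**  The 2 cm band is restricted to subcutaneous-fat voxels
  within 2 cm (Euclidean) of the rim of the active cooling-bolus footprint —
  the overlay-bolus rim when present, else the regular-bolus rim.
* **"Outside the electrodes".**  Tissue voxels whose lateral (x, z)
  projection falls outside the 30 cm electrode disk footprint.
* **Cleft-bolus comparison.**  The paired arms run at the same electrode
  potential (that of the calibrated no-bolus arm) so the gain isolates the
  bolus effect; recalibrating each arm is available by flag.
* **Saline lookup.**  No interpolation between tabulated (concentration,
  temperature) pairs; untabulated pairs raise.

## Known limitations

* On this phantom the calibrated drives are 85–98 V, above the conventional
  40–70 V window (the solver warns): the air-filled cleft and the 65 mm
  buttock pads block the dorsal midline current path, so reaching 40 °C at
  10 cm depth costs more drive than in a patient-specific model.
* With the tabulated 8 MHz properties the fat:muscle SAR contrast along a
  series current path is ≈14:1; dorsal fat 3–4 cm deep is beyond the reach
  of surface cooling, so once the tumor is calibrated to 40 °C some deep
  subcutaneous fat exceeds 44 °C in *every* overlay-bolus arm of this
  phantom.  The concentration study therefore discriminates arms by
  hot-spot *location* and by overheated volume, not by the presence or
  absence of overheating.
* The cleft-bolus temperature gain (~3 K here) is geometry-amplified: the
  tumor sits 1.5 cm from the cleft bottom, much closer than a cervical
  target in a patient.
* After the transient study duration of 3000 s the field is still ~0.3 K
  from the true steady state in deep fat (slowest perfusion–conduction mode
  τ ≈ 1100 s), although the per-step change is <3·10⁻⁴ K/s; the experiment
  layer therefore uses the direct steady solve.
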