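# Methods

## Physical model and assumptions

The engine computes the electrostatic field of long parallel cylindrical
conductors (needle electrodes) in a homogeneous, isotropic 2-D tissue slice
perpendicular to the insertion axis. The assumptions, in decreasing order of
consequence:

- **Two dimensions.** The plane of interest is assumed far from the needle
  tips, where the field is translation-invariant along the insertion axis.
  Parallel insertion is standard in deep-seated ECT/NTIRE, so the 2-D slice
  is a reasonable teaching and planning abstraction; tip effects and oblique
  insertion are out of scope.
- **Homogeneous conductivity.** Real tumors are usually more conductive
  than surrounding tissue, which lowers the intratumoral field. The
  configuration accepts a tumor/surrounding conductivity ratio and carries
  it through save/load so existing documents remain valid, but the solver
  ignores it and emits a warning saying so. Coverage numbers therefore tend
  to be *optimistic* for conductive tumors.
- **Electrostatics.** Pulse timing, membrane charging dynamics, Joule
  heating and drug transport are not modelled; only the field magnitude a
  pulse establishes, which is the planning quantity thresholds refer to.
- **One pair at a time.** Clinical pulse generators energize a single
  anode–cathode pair per pulse. A layout is decomposed into pairs (within
  each group, the singleton-polarity electrode partners every opposite
  electrode; groups never mix), and the mesh keeps the pointwise maximum of
  the per-pair fields — the quantity that decides whether a cell is ever
  electroporated during the pulse train. Fields of different pairs are
  never superposed.

## The two-conductor solution

For one pair the method of images replaces each conductor of radius ρ₀ by a
line charge on its electrical axis, displaced by the eccentricity
e = d/2 − √((d/2)² − ρ₀²) from the geometric center toward the partner
(exact identity: e·(d − e) = ρ₀²). The potential is C·ln(ρ_B/ρ_A) with
C = V_AB / (2 ln[(d + √(d² − 4ρ₀²))/(2ρ₀)]), and the field is its gradient
magnitude, evaluated in closed form. Sanity anchors used throughout the
tests: each conductor circle is an equipotential at ±V_AB/2, and the
midpoint field of a symmetric pair is 2C/s with s = √((d/2)² − ρ₀²).

Numerical notes:

- ρ₀ is the conductor **radius** in all mathematics. The user-facing
  configuration field is `electrode_diameter_mm` (as practitioners quote
  it) and is halved on ingestion; only the radius interpretation makes the
  conductor surface an equipotential circle of the electrode's physical
  size.
- All logarithms are natural; the electrostatic derivation (q/2πε₀
  prefactors) admits no other base.
- Pair bearings use the two-argument arctangent of (Δy, Δx), so vertical
  pairs and all four quadrants are handled; the A→B and B→A directions are
  distinct by construction.
- The eccentricity is computed as ρ₀²/(d/2 + s), the cancellation-free
  algebraic form, so thin wires (ρ₀ ≪ d) do not lose precision to
  subtraction.
- Internally everything is SI (meters, volts, V/m); mm, mm², V/cm, V/mm and
  V/in appear only at the configuration and report boundaries
  (1 V/mm = 10 V/cm; 1 V/in = (1/2.54) V/cm).

## Mesh, masking, regions

The display mesh samples **pixel centers**: x_i = (i + 0.5)/n_x · L − L/2,
row 0 at the top (largest y), default 400 × 400 = 160,000 points over the
tissue square of side L = √(tissue area). Points within ρ₀ of *any*
electrode center are masked `inside_electrode` — the conductor occupies
that area regardless of which pair is pulsed, and the line-charge formula
diverges inside it (the electrical axes always lie within the mask, since
e < ρ₀). Masked points are excluded from extrema, coverage percentages
(numerator and denominator) and color auto-scaling.

The tumor is a centered circle whose diameter is the configured
tumor-to-tissue ratio times the tissue side (a *diameter* ratio, chosen over
an area ratio because it reads directly off the display); a pixel is tumor
iff its center is strictly inside the circle. Coverage uses the inclusive
comparison E ≥ threshold, matching the reading "reaches the threshold".
Percentages are pixel-count fractions, so they carry a resolution
dependence of order one pixel row along the region boundary (~0.5% at
400 × 400 for centimeter-scale features); they are not analytically
integrated areas.

## Validation oracles

Two independent numerical routes check the closed forms:

- **Gradient oracle.** Second-order central differences of the potential
  (step 10⁻⁶·d_AB by default) reproduce the analytic field magnitude; the
  suite checks ≤ 10⁻⁴ relative error at 100 randomized pairs/points and the
  O(h²) convergence order.
- **Relaxation oracle.** The single-pair boundary-value problem is solved
  by successive over-relaxation (ω = 1.9, residual tolerance 10⁻⁸ V,
  deterministic row-major sweeps, ≤ 50,000 iterations; the inner loop is
  numba-compiled) on an n × n corner-inclusive grid with Dirichlet data
  ±V_AB/2 on the conductors and the analytic potential on the outer ring.
  The outer-ring choice isolates interior accuracy: it tests that the
  analytic potential satisfies the field equation, not the (arbitrary)
  truncation of the domain.

  The discrete conductor is the node set within ρ₀ + h/2 of the center
  (h = grid spacing). A Dirichlet node constrains the discrete solution
  only at the node itself, so the bare set {r ≤ ρ₀} behaves like a
  conductor about half a spacing *smaller* than the physical one and biases
  the entire exterior solution by O(h) — about 2% at n = 200 for the
  classic pair. Padding by half a cell centers the staircase on the true
  circle; measured agreement with the analytic potential is then ~0.15%
  max relative deviation at nodes ≥ 5ρ₀ from the electrodes.

## Rendering

Rendering is pure pixel arithmetic over the FieldMap (numpy + Pillow), so
identical inputs produce byte-identical PNGs; matplotlib supplies only the
palette lookup tables (hot, gray, viridis, plasma). Color position is
linear in field value by default (a log-scale flag exists); explicit scales
clamp out-of-range values to the palette endpoints; the auto-scale upper
end is the 99.5th percentile of unmasked values, because the analytic field
grows without bound at the conductor surfaces and the raw maximum would
wash out the map. Masked pixels are drawn as polarity-colored electrode
markers (red anode, blue cathode); the tumor boundary is a one-pixel ring.
The color bar repeats the ramp vertically with five ticks and marks E_rev
and E_irrev with labeled lines when they fall inside the scale.

## Configuration bounds

Validation enforces the tool's admissible ranges — tissue area 1.61 to
16129.00 mm², electrode diameter 0.10 to 2.00 mm, 2–12 electrodes in 1–6
groups, each group exactly one electrode of one polarity plus at least one
of the other, positive per-group voltage, electrodes inside the square and
non-overlapping (center distance > 2ρ₀ + 1 nm) — and reports *every*
violation with the field name, offending value and admissible range.
Unknown keys load with a warning (forward tolerance); a schema-version
mismatch is an explicit error, not a silent reinterpretation. JSON is
canonical; YAML is accepted on input. Output numbers are formatted with 6
significant digits and a '.' decimal separator regardless of locale.

## Fixture layouts and what the tests cover

`make_fixture_layout` builds the three canonical study layouts used by the
tests, examples and CLI demo: `pair` (two opposed electrodes; default
spacing 1.6 cm and 1300 V in the worked examples, the classic cutaneous
scenario), `two_rows` (3 anodes facing 3 cathodes in 3 groups) and `hex6`
(6 electrodes on a circle, alternating polarity, 3 adjacent pairs). Default
electrode radius 0.5 mm (1 mm diameter needles), tissue square 2.5× the
layout extent, tumor diameter half the tissue side. These are idealized
geometries on exact coordinates; they exercise every code path of the
engine but do not emulate patient anatomy, tissue heterogeneity or
electrode placement error, so passing tests certify the *solver*, not any
clinical plan.

## Known limitations

- No conductivity contrast (see above) — the single largest physical gap.
- Percentages inherit pixel-count granularity; very small tumors on coarse
  meshes quantize visibly.
- The analytic solution is exact only for two conductors; max-composition
  is the right aggregate for sequential pulsing but ignores the (small)
  field distortion each passive conductor causes during another pair's
  pulse.
- The relaxation oracle handles single-pair layouts only — it is a
  validation instrument, not a general solver.
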