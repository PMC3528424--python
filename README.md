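# porefield

Analytical electric-field engine for needle-electrode electroporation
treatment planning and teaching.

Electrochemotherapy (ECT) and non-thermal irreversible electroporation
(NTIRE) succeed only where the local electric field magnitude reaches a
tissue-dependent threshold — typically 300 V/cm for reversible
permeabilization and 800 V/cm for irreversible ablation. A widespread
shortcut estimates the field between two electrodes as E ≈ U/d
(voltage over distance), which is exact only between infinite parallel
plates. For the needle electrodes actually used in ECT/NTIRE the shortcut
is badly wrong, and treatment plans built on it can leave parts of the
tumor under-treated. `porefield` computes the exact 2-D field instead.

## The model

Two long parallel cylindrical conductors of radius ρ₀, centers d_AB apart,
carrying voltage V_AB, are solved by the method of images: each conductor
is replaced by an equivalent line charge on its *electrical axis*, displaced
from the geometric center toward the other conductor by the eccentricity

    e = d_AB/2 − √((d_AB/2)² − ρ₀²),   so that   e·(d_AB − e) = ρ₀².

With electrical axes at (x′_A, y′_A), (x′_B, y′_B) and distances ρ_A, ρ_B
from a field point, the potential and field magnitude are

    V(x,y) = C · ln(ρ_B/ρ_A),
    E(x,y) = C · √{ [(x′_A−x)/ρ_A² − (x′_B−x)/ρ_B²]²
                  + [(y′_A−y)/ρ_A² − (y′_B−y)/ρ_B²]² },
    C = V_AB / (2 ln[(d_AB + √(d_AB² − 4ρ₀²)) / (2ρ₀)]).

This construction makes each conductor surface an exact equipotential at
±V_AB/2. Multi-electrode layouts (2–12 electrodes in 1–6 groups, each group
one singleton-polarity electrode plus one or more of the other) are
decomposed into anode–cathode pairs — pulse generators energize one pair at
a time — and the engine keeps the pointwise **maximum** of the pair fields
over a 400 × 400 pixel-center mesh. Threshold analytics then report the
percentage of the tumor circle and of the surrounding tissue at or above
E_rev and E_irrev.

The engine treats the tissue slice as homogeneous in conductivity; the
tumor/surrounding conductivity ratio is accepted in configurations and
round-tripped, but does not enter the physics.

An independent validation path is built in: a successive over-relaxation
(SOR) finite-difference Laplace solver and central-difference gradients of
the potential cross-check the closed forms to sub-percent accuracy.

## Worked example

1300 V across a needle pair 1.6 cm apart, electrode radius 0.1 cm
(`python examples/pair_field_basics.py`):

```
eccentricity e          : 0.0062746 cm
electrical axes at x'   : +/-0.7937254 cm
potential scale C       : 234.77 V
anode surface potential : +650.0 V
midpoint field 2C/s     : 591.6 V/cm
naive U/d estimate      : 812.5 V/cm
```

The exact midpoint field (≈592 V/cm) is about 27% below the U/d estimate
(812.5 V/cm): between needles the field sags in the middle and peaks at the
electrode surfaces. A plan assuming 812 V/cm at the center would predict
irreversible coverage (800 V/cm) that the tissue never receives.

Coverage analytics for the same pair in a 4 cm tissue square with a 2 cm
tumor, at the default 300/800 V/cm thresholds (400 × 400 mesh):

```
tumor >= 300 V/cm (reversible)  : 87.4 %
tumor >= 800 V/cm (irreversible): 16.3 %
surrounding >= 300 V/cm         : 6.9 %
```

A single pair at 1300 V reversibly electroporates only ~87% of this tumor —
precisely the kind of coverage gap the field map makes visible.

The other scripts in `examples/` each exercise one capability: hexagonal
six-needle coverage, PNG rendering with a threshold-annotated color bar,
config validation with complete error lists, and the SOR oracle cross-check.

## Command line

```sh
porefield demo pair            # emit a ready-to-run JSON config
porefield validate pair.json   # check it (all violations listed)
porefield field pair.json -o map.tsv     # 400x400 TSV field matrix
porefield render pair.json -o map.png --colorbar bar.png
porefield report pair.json -o coverage.json  # + JSON-lines record log
```

## Layout

- `src/porefield/geometry.py` — electrodes, groups, layouts, pair
  enumeration, electrical-axis construction
- `src/porefield/field.py` — pair potential/field, max-composition mesh
  engine, TSV export
- `src/porefield/coverage.py` — thresholds, unit conversion, region masks,
  coverage reports, record log
- `src/porefield/oracle.py` — numeric gradient and SOR Laplace oracles
- `src/porefield/viz.py` — palettes, field-map rendering, color bar
- `src/porefield/config.py` — JSON/YAML schema, bounds validation,
  persistence
- `src/porefield/cli.py` — the `porefield` command

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
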