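"""Closed-form field of one needle-electrode pair, and why U/d misleads.

1300 V across two parallel needle electrodes 1.6 cm apart (radius 0.1 cm):
the image-charge solution gives the exact midpoint field, which the naive
voltage-over-distance estimate overshoots by more than a third.
"""

from porefield import (
    eccentricity,
    make_fixture_layout,
    pair_field,
    pair_geometries,
    pair_potential,
)

V, D, RHO0 = 1300.0, 16e-3, 1e-3

layout = make_fixture_layout("pair", D, V, electrode_radius=RHO0)
(pair,) = pair_geometries(layout)

print(f"eccentricity e          : {eccentricity(D, RHO0) * 100:.7f} cm")
print(f"electrical axes at x'   : +/-{pair.xp_b * 100:.7f} cm")
print(f"potential scale C       : {pair.c:.2f} V")
print(f"anode surface potential : {pair_potential(pair.anode.x + RHO0, 0.0, pair):+.1f} V")
print(f"midpoint field 2C/s     : {pair_field(0.0, 0.0, pair) / 100:.1f} V/cm")
print(f"naive U/d estimate      : {V / (D * 100):.1f} V/cm")
print()
print("The true midpoint field (~592 V/cm) is well below U/d (812.5 V/cm):")
print("between needle electrodes the field sags in the middle and peaks at")
print("the electrode surfaces, so the parallel-plate shortcut overestimates")
print("coverage right where treatment failure would occur.")
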