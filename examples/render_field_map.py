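"""Render a color-coded field map and its threshold-annotated color bar.

Writes two PNGs next to this script: the 400 x 400 field display (hot
palette, electrodes as red/blue markers, tumor circle overlaid) and a
vertical color bar with the 300/800 V/cm thresholds marked.
"""

from pathlib import Path

from porefield import (
    RenderSpec,
    Thresholds,
    colorize,
    evaluate_mesh,
    make_fixture_layout,
    render_colorbar,
    save_png,
)

layout = make_fixture_layout("two_rows", 8e-3, 1000.0, tissue_side=0.04, tumor_diameter=0.02)
fmap = evaluate_mesh(layout)

spec = RenderSpec(palette="hot", scale_min=0.0, scale_max=1000.0, unit="V/cm")
out_dir = Path(__file__).parent
save_png(colorize(fmap, spec, tumor_diameter=layout.tumor_diameter), out_dir / "field_map.png")
save_png(render_colorbar(spec, Thresholds()), out_dir / "colorbar.png")

print(f"wrote {out_dir / 'field_map.png'} (400 x 400, hot palette, 0-1000 V/cm scale)")
print(f"wrote {out_dir / 'colorbar.png'} (green lines mark 300 and 800 V/cm)")
print("Pixels at or above the 800 V/cm line would be irreversibly electroporated.")
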