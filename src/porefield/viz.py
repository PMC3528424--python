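"""Color-coded rendering of field maps.

The display mirrors the treatment-planning view: a square raster of the
tissue slice with the field magnitude mapped through a palette ramp,
electrode cross-sections drawn in polarity-distinct colors, the tumor
boundary circle overlaid, and a vertical color bar annotated with the
electroporation thresholds.  Rendering is pure pixel arithmetic (numpy +
Pillow), so identical inputs give byte-identical PNGs; matplotlib is used
only as the source of the palette lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .coverage import Thresholds, convert_field_unit
from .field import FieldMap

__all__ = ["PALETTES", "RenderSpec", "colorize", "render_colorbar", "save_png"]

#: Palette name -> matplotlib colormap name.  "hot" approximates the
#: black-red-yellow-white ramp of the classic display; "gray" is the
#: monochrome scheme.
PALETTES: dict[str, str] = {
    "hot": "hot",
    "gray": "gray",
    "viridis": "viridis",
    "plasma": "plasma",
}

ANODE_RGB = (255, 40, 40)  # anode cross-sections drawn red
CATHODE_RGB = (40, 80, 255)  # cathode cross-sections drawn blue
TUMOR_RGB = (255, 255, 255)  # tumor boundary circle
AUTO_SCALE_PERCENTILE = 99.5


def _palette_lut(name: str, n: int = 256) -> np.ndarray:
    """(n, 3) uint8 lookup table for a named palette ramp."""
    if name not in PALETTES:
        raise ValueError(f"unknown palette {name!r}; supported: {sorted(PALETTES)}")
    import matplotlib

    cmap = matplotlib.colormaps[PALETTES[name]]
    ramp = cmap(np.linspace(0.0, 1.0, n))[:, :3]
    return (ramp * 255 + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class RenderSpec:
    """How a field map is turned into pixels.

    ``scale_min``/``scale_max`` are in ``unit``; None means auto-scale
    (min 0, max = 99.5th percentile of unmasked values, which keeps the
    unbounded near-electrode values from washing out the map).  Values
    outside the scale clamp to the palette endpoints.  ``log_scale`` maps
    color position by log10 of the value instead of linearly (off by
    default).
    """

    palette: str = "hot"
    scale_min: float | None = None
    scale_max: float | None = None
    unit: str = "V/cm"
    annotate_thresholds: bool = True
    show_tumor_circle: bool = True
    show_electrodes: bool = True
    output_size: int = 400
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.palette not in PALETTES:
            raise ValueError(f"unknown palette {self.palette!r}; supported: {sorted(PALETTES)}")
        if (
            self.scale_min is not None
            and self.scale_max is not None
            and not (self.scale_min < self.scale_max)
        ):
            raise ValueError(
                f"scale_min {self.scale_min} must be < scale_max {self.scale_max}"
            )
        if self.output_size < 1:
            raise ValueError("output_size must be >= 1")


def _resolve_scale(fmap: FieldMap, spec: RenderSpec) -> tuple[float, float]:
    """Explicit or auto color scale, in V/m."""
    to_si = lambda v: convert_field_unit(v, spec.unit, "V/m")  # noqa: E731
    free = fmap.values[~fmap.mask]
    lo = to_si(spec.scale_min) if spec.scale_min is not None else 0.0
    if spec.scale_max is not None:
        hi = to_si(spec.scale_max)
    else:
        hi = float(np.percentile(free, AUTO_SCALE_PERCENTILE)) if free.size else 1.0
    if not (lo < hi):
        raise ValueError(f"degenerate color scale [{lo}, {hi}] V/m")
    return lo, hi


def _normalize(values: np.ndarray, lo: float, hi: float, log_scale: bool) -> np.ndarray:
    """Map values to [0, 1] color positions, clamping out-of-range."""
    if log_scale:
        floor = max(lo, hi * 1e-6)
        t = np.log10(np.clip(values, floor, hi) / floor) / np.log10(hi / floor)
    else:
        t = (values - lo) / (hi - lo)
    return np.clip(t, 0.0, 1.0)


def colorize(fmap: FieldMap, spec: RenderSpec, tumor_diameter: float | None = None) -> Image.Image:
    """Render a field map to an RGB image.

    One pixel per mesh point, nearest-neighbor upscaled when
    ``output_size`` exceeds the mesh; masked points are drawn as electrode
    markers (red anode / blue cathode); the tumor boundary circle is
    overlaid when enabled and a diameter is given.
    """
    lo, hi = _resolve_scale(fmap, spec)
    lut = _palette_lut(spec.palette)
    idx = (_normalize(fmap.values, lo, hi, spec.log_scale) * (len(lut) - 1) + 0.5).astype(int)
    rgb = lut[idx]  # (n_y, n_x, 3)

    if spec.show_electrodes:
        rgb[(fmap.polarity > 0) & fmap.mask] = ANODE_RGB
        rgb[(fmap.polarity < 0) & fmap.mask] = CATHODE_RGB

    if spec.show_tumor_circle and tumor_diameter and tumor_diameter > 0:
        xg, yg = fmap.spec.grid()
        r = np.sqrt(xg * xg + yg * yg)
        # one-pixel-wide ring at the tumor radius
        px = fmap.spec.extent / max(fmap.spec.n_x, fmap.spec.n_y)
        ring = np.abs(r - tumor_diameter / 2) <= px / 2
        rgb[ring] = TUMOR_RGB

    img = Image.fromarray(rgb, mode="RGB")
    if spec.output_size > max(fmap.spec.n_x, fmap.spec.n_y):
        scale = spec.output_size / max(fmap.spec.n_x, fmap.spec.n_y)
        img = img.resize(
            (round(fmap.spec.n_x * scale), round(fmap.spec.n_y * scale)),
            resample=Image.Resampling.NEAREST,
        )
    return img


def render_colorbar(
    spec: RenderSpec,
    thr: Thresholds | None = None,
    *,
    scale: tuple[float, float] | None = None,
    width: int = 120,
    height: int = 400,
) -> Image.Image:
    """Vertical palette ramp with numeric ticks and threshold annotations.

    ``scale`` is (lo, hi) in ``spec.unit``; falls back to the explicit
    render scale.  E_rev and E_irrev are marked with labeled lines when
    ``annotate_thresholds`` and the value lies inside the scale; ticks and
    geometry do not depend on the palette.
    """
    if scale is not None:
        lo, hi = scale
    elif spec.scale_min is not None and spec.scale_max is not None:
        lo, hi = spec.scale_min, spec.scale_max
    else:
        raise ValueError("render_colorbar needs an explicit scale")
    if not (lo < hi):
        raise ValueError(f"degenerate color scale [{lo}, {hi}]")

    ramp_w = width // 3
    lut = _palette_lut(spec.palette, n=height)
    column = lut[::-1]  # top of the bar = scale_max
    ramp = np.repeat(column[:, None, :], ramp_w, axis=1)
    img = Image.new("RGB", (width, height), (255, 255, 255))
    img.paste(Image.fromarray(ramp, mode="RGB"), (0, 0))
    draw = ImageDraw.Draw(img)

    def y_of(value: float) -> int:
        t = (value - lo) / (hi - lo)
        return round((1.0 - t) * (height - 1))

    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        val = lo + frac * (hi - lo)
        y = y_of(val)
        draw.line([(ramp_w, y), (ramp_w + 6, y)], fill=(0, 0, 0))
        draw.text((ramp_w + 8, min(max(y - 5, 0), height - 12)),
                  format(val, ".4g"), fill=(0, 0, 0))

    if thr is not None and spec.annotate_thresholds:
        for value, label in ((thr.e_rev, "E_rev"), (thr.e_irrev, "E_irrev")):
            v = convert_field_unit(value, thr.unit, spec.unit)
            if lo <= v <= hi:
                y = y_of(v)
                draw.line([(0, y), (ramp_w + 6, y)], fill=(0, 255, 0))
                draw.text((ramp_w + 8, min(max(y + 2, 0), height - 12)),
                          f"{label}={v:.4g}", fill=(0, 128, 0))
    return img


def save_png(img: Image.Image, path: str | Path) -> None:
    img.save(Path(path), format="PNG")
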