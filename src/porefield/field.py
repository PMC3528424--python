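"""Closed-form pair potential/field and the multi-pair mesh engine.

For one anode-cathode pair with electrical axes at (x'_A, y'_A) and
(x'_B, y'_B) and potential scale

    C = V_AB / (2 ln[(d + sqrt(d^2 - 4 rho0^2)) / (2 rho0)]),

the potential at a point T is V(T) = C ln(rho_B / rho_A), with rho_A and
rho_B the distances of T from the two electrical axes, and the field
magnitude is the gradient magnitude

    E(x, y) = C sqrt{ [(x'_A-x)/rho_A^2 - (x'_B-x)/rho_B^2]^2
                    + [(y'_A-y)/rho_A^2 - (y'_B-y)/rho_B^2]^2 }.

Multi-electrode layouts are decomposed into anode-cathode pairs (one pair
pulsed at a time); the engine keeps the pointwise MAXIMUM of the pair
fields at every mesh point, since the local maximum over the pulse train is
what decides whether a cell is electroporated.  Fields are in V/m.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import (
    Layout,
    OverlappingElectrodesError,
    PairGeometry,
    _pair_constant,
    pair_geometries,
)

__all__ = [
    "MeshSpec",
    "FieldMap",
    "SingularPointError",
    "pair_constant",
    "pair_potential",
    "pair_field",
    "evaluate_mesh",
    "write_fieldmap_tsv",
]


class SingularPointError(ValueError):
    """Evaluation requested exactly on an electrical axis, where the
    line-charge potential diverges."""


@dataclass(frozen=True)
class MeshSpec:
    """Rectangular sampling mesh over the tissue square.

    Sample points are pixel centers: ``x_i = (i + 0.5) / n_x * L - L / 2``
    (likewise for y).  Row 0 of the value matrix is the TOP of the display
    (largest y).  Default resolution is 400 x 400 = 160,000 points.
    """

    n_x: int = 400
    n_y: int = 400
    extent: float = 0.04  # tissue side length L (m)

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError(f"mesh must be at least 2x2, got {self.n_x}x{self.n_y}")
        if not (self.extent > 0):
            raise ValueError(f"mesh extent must be positive, got {self.extent}")

    @property
    def xs(self) -> np.ndarray:
        """Pixel-center x coordinates, left to right (m)."""
        i = np.arange(self.n_x)
        return (i + 0.5) / self.n_x * self.extent - self.extent / 2

    @property
    def ys(self) -> np.ndarray:
        """Pixel-center y coordinates ordered top (max y) to bottom, matching row order."""
        j = np.arange(self.n_y)
        return self.extent / 2 - (j + 0.5) / self.n_y * self.extent

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate matrices of shape (n_y, n_x), row 0 = top."""
        return np.meshgrid(self.xs, self.ys)


@dataclass(frozen=True)
class FieldMap:
    """Field magnitude sampled on a mesh.

    ``values[r, c]`` is the field magnitude E in V/m at mesh pixel (r, c);
    ``mask`` flags points inside any physical electrode circle, where the
    analytic solution does not apply (values there are set to 0 and
    excluded from statistics and color scaling); ``polarity`` is 0 on
    tissue, +1 inside an anode, -1 inside a cathode (rendering aid).
    """

    spec: MeshSpec
    values: np.ndarray  # (n_y, n_x) float64, V/m
    mask: np.ndarray  # (n_y, n_x) bool, True = inside_electrode
    polarity: np.ndarray  # (n_y, n_x) int8

    def __post_init__(self) -> None:
        expect = (self.spec.n_y, self.spec.n_x)
        for name in ("values", "mask", "polarity"):
            a = getattr(self, name)
            if a.shape != expect:
                raise ValueError(f"{name} shape {a.shape} != mesh shape {expect}")
        tissue = self.values[~self.mask]
        if tissue.size and not (np.isfinite(tissue).all() and (tissue >= 0).all()):
            raise ValueError("tissue field values must be finite and non-negative")

    @property
    def n_points(self) -> int:
        return self.spec.n_x * self.spec.n_y


def pair_constant(v_ab: float, d_ab: float, rho0: float) -> float:
    """Potential scale C > 0 of the two-wire solution (natural log).

    Diverges as the conductors approach contact (d_ab -> 2 rho0) and is
    proportional to the applied voltage.
    """
    if not (v_ab > 0):
        raise ValueError(f"pair voltage must be positive, got {v_ab}")
    return _pair_constant(v_ab, d_ab, rho0)


def _axis_offsets(x, y, pair: PairGeometry):
    dx_a = pair.xp_a - np.asarray(x, dtype=float)
    dy_a = pair.yp_a - np.asarray(y, dtype=float)
    dx_b = pair.xp_b - np.asarray(x, dtype=float)
    dy_b = pair.yp_b - np.asarray(y, dtype=float)
    ra2 = dx_a * dx_a + dy_a * dy_a
    rb2 = dx_b * dx_b + dy_b * dy_b
    return dx_a, dy_a, dx_b, dy_b, ra2, rb2


def pair_potential(x, y, pair: PairGeometry):
    """Scalar potential V(x, y) of one pair, in volts.

    Positive near the anode, negative near the cathode, zero on the
    perpendicular bisector of the electrical axes; +/- V_AB/2 on the two
    conductor surfaces.  Accepts scalars or broadcastable arrays.
    """
    *_, ra2, rb2 = _axis_offsets(x, y, pair)
    if np.any(ra2 == 0.0) or np.any(rb2 == 0.0):
        raise SingularPointError("potential requested exactly on an electrical axis")
    out = pair.c * 0.5 * (np.log(rb2) - np.log(ra2))
    return float(out) if np.isscalar(x) and np.isscalar(y) else out


def pair_field(x, y, pair: PairGeometry):
    """Field magnitude |grad V| of one pair, in V/m (scalars or arrays)."""
    dx_a, dy_a, dx_b, dy_b, ra2, rb2 = _axis_offsets(x, y, pair)
    if np.any(ra2 == 0.0) or np.any(rb2 == 0.0):
        raise SingularPointError("field requested exactly on an electrical axis")
    ex = dx_a / ra2 - dx_b / rb2
    ey = dy_a / ra2 - dy_b / rb2
    out = pair.c * np.sqrt(ex * ex + ey * ey)
    return float(out) if np.isscalar(x) and np.isscalar(y) else out


def evaluate_mesh(layout: Layout, spec: MeshSpec | None = None) -> FieldMap:
    """Evaluate the max-composition field of a layout on a mesh.

    At every pixel center the value is the maximum of the pair fields over
    all anode-cathode pairs of the layout.  Pixels within rho0 of ANY
    electrode's geometric center are masked ``inside_electrode`` (the
    conductor occupies that area regardless of which pair is pulsed) and
    their values zeroed.
    """
    if spec is None:
        spec = MeshSpec(extent=layout.tissue_side)
    if not math.isclose(spec.extent, layout.tissue_side, rel_tol=1e-12):
        raise ValueError(
            f"mesh extent {spec.extent} must equal layout tissue side {layout.tissue_side}"
        )
    xg, yg = spec.grid()
    values = np.zeros((spec.n_y, spec.n_x))
    for pair in pair_geometries(layout):
        np.maximum(values, pair_field(xg, yg, pair), out=values)

    mask = np.zeros(values.shape, dtype=bool)
    polarity = np.zeros(values.shape, dtype=np.int8)
    r2 = layout.electrode_radius**2
    for e in layout.electrodes:
        inside = (xg - e.x) ** 2 + (yg - e.y) ** 2 <= r2
        mask |= inside
        polarity[inside] = 1 if e.polarity.value == "anode" else -1
    values = np.where(mask, 0.0, values)
    return FieldMap(spec=spec, values=values, mask=mask, polarity=polarity)


def layout_hash(layout: Layout) -> str:
    """Stable short hash of the physical layout (for output provenance)."""
    payload = json.dumps(
        {
            "rho0": layout.electrode_radius,
            "side": layout.tissue_side,
            "tumor": layout.tumor_diameter,
            "groups": [
                {
                    "v": g.voltage,
                    "e": [[e.x, e.y, e.polarity.value] for e in g.electrodes],
                }
                for g in layout.groups
            ],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_fieldmap_tsv(fmap: FieldMap, path: str | Path, layout: Layout | None = None) -> None:
    """Write the field map as a TSV matrix plus a JSON sidecar header.

    n_y rows x n_x columns, row 0 = top of the display; masked cells are
    written as "NA"; values use 6 significant digits with '.' decimals.
    The sidecar ``<path>.json`` records extent, units and the layout hash.
    """
    path = Path(path)
    with path.open("w") as fh:
        for r in range(fmap.spec.n_y):
            cells = [
                "NA" if fmap.mask[r, c] else format(fmap.values[r, c], ".6g")
                for c in range(fmap.spec.n_x)
            ]
            fh.write("\t".join(cells) + "\n")
    header = {
        "n_x": fmap.spec.n_x,
        "n_y": fmap.spec.n_y,
        "extent_m": fmap.spec.extent,
        "units": "V/m",
        "row0": "top (max y)",
        "sampling": "pixel centers",
        "layout_hash": layout_hash(layout) if layout is not None else None,
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=2) + "\n")
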