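"""Threshold coverage analytics ("data collector").

Given a field map and the tumor/surrounding partition of the tissue slice,
reports the field extrema and the percentage of each region reaching the
reversible (E_rev) and irreversible (E_irrev) electroporation thresholds.
Coverage of the whole tumor above E_rev is the success criterion for
electrochemotherapy; coverage above E_irrev for non-thermal irreversible
ablation.  Defaults are 300 and 800 V/cm; thresholds may be expressed in
V/cm, V/mm or V/in and are converted to V/m before comparison.  A point
counts as covered when E >= threshold (inclusive).  Pixels inside
electrodes are excluded from both numerators and denominators and from the
extrema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .field import FieldMap, MeshSpec, layout_hash
from .geometry import Layout

__all__ = [
    "FIELD_UNITS",
    "Thresholds",
    "CoverageReport",
    "convert_field_unit",
    "region_masks",
    "coverage_report",
    "append_record",
]

#: V/m per one unit of each supported field-strength unit.
FIELD_UNITS: dict[str, float] = {
    "V/m": 1.0,
    "V/cm": 100.0,
    "V/mm": 1000.0,
    "V/in": 100.0 / 2.54,
}


def convert_field_unit(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a field strength between V/m, V/cm, V/mm and V/in."""
    for u in (from_unit, to_unit):
        if u not in FIELD_UNITS:
            raise ValueError(f"unknown field unit {u!r}; supported: {sorted(FIELD_UNITS)}")
    return value * FIELD_UNITS[from_unit] / FIELD_UNITS[to_unit]


@dataclass(frozen=True)
class Thresholds:
    """Reversible/irreversible electroporation thresholds, unit-tagged."""

    e_rev: float = 300.0
    e_irrev: float = 800.0
    unit: str = "V/cm"

    def __post_init__(self) -> None:
        if self.unit not in FIELD_UNITS:
            raise ValueError(f"unknown field unit {self.unit!r}")
        if not (0 < self.e_rev <= self.e_irrev):
            raise ValueError(
                f"need 0 < e_rev <= e_irrev, got e_rev={self.e_rev}, e_irrev={self.e_irrev}"
            )

    @property
    def e_rev_si(self) -> float:
        return convert_field_unit(self.e_rev, self.unit, "V/m")

    @property
    def e_irrev_si(self) -> float:
        return convert_field_unit(self.e_irrev, self.unit, "V/m")


@dataclass(frozen=True)
class CoverageReport:
    """Extrema and threshold coverage over tumor and surrounding tissue.

    Percentages are pixel-count fractions of UNMASKED region pixels (hence
    resolution-dependent); a region with zero unmasked pixels reports None
    rather than 0.  Extrema are in the report's ``unit``.
    """

    e_max: float
    e_min: float
    tumor_pct_rev: float | None
    tumor_pct_irrev: float | None
    surround_pct_rev: float | None
    surround_pct_irrev: float | None
    n_tumor_px: int
    n_surround_px: int
    n_masked_px: int
    unit: str = "V/cm"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def region_masks(layout: Layout, spec: MeshSpec) -> np.ndarray:
    """Boolean tumor mask on the mesh (True = tumor, False = surrounding).

    A pixel center belongs to the tumor iff its distance from the origin is
    strictly less than tumor_diameter / 2.
    """
    xg, yg = spec.grid()
    return xg * xg + yg * yg < (layout.tumor_diameter / 2) ** 2


def _pct(values: np.ndarray, threshold_si: float) -> float | None:
    if values.size == 0:
        return None
    return 100.0 * float(np.count_nonzero(values >= threshold_si)) / values.size


def coverage_report(
    fmap: FieldMap, tumor_mask: np.ndarray, thr: Thresholds
) -> CoverageReport:
    """Compute the coverage statistics of a field map.

    ``tumor_mask`` must be on the same mesh as ``fmap``.
    """
    if tumor_mask.shape != fmap.values.shape:
        raise ValueError(
            f"region mask shape {tumor_mask.shape} != field map shape {fmap.values.shape}"
        )
    free = ~fmap.mask
    tumor_vals = fmap.values[tumor_mask & free]
    surround_vals = fmap.values[~tumor_mask & free]
    all_vals = fmap.values[free]
    if all_vals.size == 0:
        raise ValueError("field map has no unmasked points")
    to_unit = lambda v: convert_field_unit(v, "V/m", thr.unit)  # noqa: E731
    return CoverageReport(
        e_max=to_unit(float(all_vals.max())),
        e_min=to_unit(float(all_vals.min())),
        tumor_pct_rev=_pct(tumor_vals, thr.e_rev_si),
        tumor_pct_irrev=_pct(tumor_vals, thr.e_irrev_si),
        surround_pct_rev=_pct(surround_vals, thr.e_rev_si),
        surround_pct_irrev=_pct(surround_vals, thr.e_irrev_si),
        n_tumor_px=int(np.count_nonzero(tumor_mask & free)),
        n_surround_px=int(np.count_nonzero(~tumor_mask & free)),
        n_masked_px=int(np.count_nonzero(fmap.mask)),
        unit=thr.unit,
    )


def append_record(path: str | Path, report: CoverageReport, layout: Layout) -> None:
    """Append one JSON-lines record (report + layout snapshot) to the log."""
    record = {
        "report": report.to_dict(),
        "layout": {
            "hash": layout_hash(layout),
            "electrode_radius_m": layout.electrode_radius,
            "tissue_side_m": layout.tissue_side,
            "tumor_diameter_m": layout.tumor_diameter,
            "groups": [
                {
                    "voltage_V": g.voltage,
                    "electrodes": [
                        {"id": e.id, "x_m": e.x, "y_m": e.y, "polarity": e.polarity.value}
                        for e in g.electrodes
                    ],
                }
                for g in layout.groups
            ],
        },
    }
    with Path(path).open("a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
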