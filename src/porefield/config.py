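"""Configuration schema, validation and persistence.

The user-facing configuration is a JSON document (YAML accepted on input)
with lengths in the units practitioners use — tissue area in mm², electrode
coordinates and diameter in mm — converted to SI meters on ingestion.  The
tissue is a square of side sqrt(area); the tumor a centered circle whose
diameter is ``tumor_to_tissue_ratio`` times the tissue side.  Validation
enforces the tool's admissible ranges and reports EVERY violation, naming
the field, the offending value and the admissible range, rather than
stopping at the first.

``conductivity_ratio`` (tumor/surrounding) is accepted and round-tripped
but not used in the field computation, which treats the slice as
homogeneous; a warning records this.

Canonical example (units embedded in the key names)::

    {
      "schema_version": 1,
      "tissue_area_mm2": 1600.0,
      "tumor_to_tissue_ratio": 0.5,
      "electrode_diameter_mm": 1.0,
      "conductivity_ratio": 1.0,
      "thresholds": {"e_rev": 300.0, "e_irrev": 800.0, "unit": "V/cm"},
      "mesh": {"n_x": 400, "n_y": 400},
      "render": {"palette": "hot"},
      "groups": [
        {"voltage_V": 1000.0,
         "electrodes": [
            {"id": "a1", "x_mm": -8.0, "y_mm": 0.0, "polarity": "anode"},
            {"id": "c1", "x_mm": 8.0, "y_mm": 0.0, "polarity": "cathode"}]}
      ],
      "seed": 0
    }
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .coverage import FIELD_UNITS, Thresholds
from .field import MeshSpec
from .geometry import (
    Electrode,
    ElectrodeGroup,
    Layout,
    LayoutError,
    Polarity,
)
from .viz import PALETTES, RenderSpec

__all__ = [
    "SCHEMA_VERSION",
    "BOUNDS",
    "AppConfig",
    "ConfigError",
    "validate_config",
    "load_config",
    "save_config",
    "default_config_dict",
]

SCHEMA_VERSION = 1

#: Admissible ranges of the user-facing settings.
BOUNDS = {
    "tissue_area_mm2": (1.61, 16129.00),
    "electrode_diameter_mm": (0.10, 2.00),
    "electrode_count": (2, 12),
    "group_count": (1, 6),
    "tumor_to_tissue_ratio": (0.0, 1.0),
}

_KNOWN_KEYS = {
    "schema_version",
    "tissue_area_mm2",
    "tumor_to_tissue_ratio",
    "electrode_diameter_mm",
    "conductivity_ratio",
    "thresholds",
    "mesh",
    "render",
    "groups",
    "seed",
}


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class AppConfig:
    """A fully validated application configuration (SI units inside)."""

    layout: Layout
    thresholds: Thresholds
    mesh: MeshSpec
    render: RenderSpec
    seed: int = 0
    warnings: tuple[str, ...] = dc_field(default=(), compare=False)

    def to_dict(self) -> dict:
        """User-facing dict (mm / mm² units), round-trippable via validate_config."""
        lay = self.layout
        side_mm = lay.tissue_side * 1e3
        return {
            "schema_version": SCHEMA_VERSION,
            "tissue_area_mm2": side_mm * side_mm,
            "tumor_to_tissue_ratio": lay.tumor_diameter / lay.tissue_side,
            "electrode_diameter_mm": 2 * lay.electrode_radius * 1e3,
            "conductivity_ratio": lay.conductivity_ratio,
            "thresholds": {
                "e_rev": self.thresholds.e_rev,
                "e_irrev": self.thresholds.e_irrev,
                "unit": self.thresholds.unit,
            },
            "mesh": {"n_x": self.mesh.n_x, "n_y": self.mesh.n_y},
            "render": {
                "palette": self.render.palette,
                "scale_min": self.render.scale_min,
                "scale_max": self.render.scale_max,
                "unit": self.render.unit,
                "annotate_thresholds": self.render.annotate_thresholds,
                "show_tumor_circle": self.render.show_tumor_circle,
                "show_electrodes": self.render.show_electrodes,
                "output_size": self.render.output_size,
                "log_scale": self.render.log_scale,
            },
            "groups": [
                {
                    "voltage_V": g.voltage,
                    "electrodes": [
                        {
                            "id": e.id,
                            "x_mm": e.x * 1e3,
                            "y_mm": e.y * 1e3,
                            "polarity": e.polarity.value,
                        }
                        for e in g.electrodes
                    ],
                }
                for g in self.layout.groups
            ],
            "seed": self.seed,
        }


def _range_err(field: str, value, lo, hi, unit: str = "") -> str:
    u = f" {unit}" if unit else ""
    return f"{field} = {value}{u} outside admissible range [{lo}, {hi}]{u}"


def _num(raw: dict, key: str, errors: list[str], default=None, required=False):
    v = raw.get(key, default)
    if v is None:
        if required:
            errors.append(f"missing required field {key!r}")
        return None
    if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
        errors.append(f"{key} must be a finite number, got {v!r}")
        return None
    return float(v)


def validate_config(raw: dict) -> AppConfig:
    """Validate a raw configuration dict into an AppConfig.

    Raises ConfigError carrying the COMPLETE list of violations; on
    success, ``AppConfig.warnings`` records accepted-but-ignored settings
    (unknown keys, the unused conductivity ratio).
    """
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping/object"])
    errors: list[str] = []
    warnings: list[str] = []

    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        warnings.append(f"ignoring unknown keys: {', '.join(unknown)}")

    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            [
                f"schema_version {version!r} not supported (expected {SCHEMA_VERSION}); "
                "no migration path is defined"
            ]
        )

    lo, hi = BOUNDS["tissue_area_mm2"]
    area = _num(raw, "tissue_area_mm2", errors, default=1600.0)
    if area is not None and not (lo <= area <= hi):
        errors.append(_range_err("tissue_area_mm2", area, lo, hi, "mm^2"))
        area = None

    lo, hi = BOUNDS["electrode_diameter_mm"]
    diam = _num(raw, "electrode_diameter_mm", errors, default=1.0)
    if diam is not None and not (lo <= diam <= hi):
        errors.append(_range_err("electrode_diameter_mm", diam, lo, hi, "mm"))
        diam = None

    lo, hi = BOUNDS["tumor_to_tissue_ratio"]
    ratio = _num(raw, "tumor_to_tissue_ratio", errors, default=0.5)
    if ratio is not None and not (lo <= ratio <= hi):
        errors.append(_range_err("tumor_to_tissue_ratio", ratio, lo, hi))
        ratio = None

    cond = _num(raw, "conductivity_ratio", errors, default=1.0)
    if cond is not None and cond <= 0:
        errors.append(f"conductivity_ratio = {cond} must be positive")
        cond = None
    if cond is not None and "conductivity_ratio" in raw:
        warnings.append(
            "conductivity_ratio is stored but not used in field computation "
            "(the engine treats the tissue as homogeneous in conductivity)"
        )

    # thresholds
    thr_raw = raw.get("thresholds", {})
    thresholds = None
    if not isinstance(thr_raw, dict):
        errors.append("thresholds must be a mapping")
    else:
        terr: list[str] = []
        e_rev = _num(thr_raw, "e_rev", terr, default=300.0)
        e_irrev = _num(thr_raw, "e_irrev", terr, default=800.0)
        unit = thr_raw.get("unit", "V/cm")
        if unit not in FIELD_UNITS:
            terr.append(f"thresholds.unit = {unit!r} not in {sorted(FIELD_UNITS)}")
        if not terr and e_rev is not None and e_irrev is not None:
            try:
                thresholds = Thresholds(e_rev=e_rev, e_irrev=e_irrev, unit=unit)
            except ValueError as exc:
                terr.append(f"thresholds: {exc}")
        errors.extend("thresholds." + e if not e.startswith("thresholds") else e for e in terr)

    # mesh
    mesh_raw = raw.get("mesh", {})
    mesh = None
    if not isinstance(mesh_raw, dict):
        errors.append("mesh must be a mapping")
    elif area is not None:
        side = math.sqrt(area) * 1e-3
        try:
            mesh = MeshSpec(
                n_x=int(mesh_raw.get("n_x", 400)),
                n_y=int(mesh_raw.get("n_y", 400)),
                extent=side,
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"mesh: {exc}")

    # render
    render_raw = raw.get("render", {})
    render = None
    if not isinstance(render_raw, dict):
        errors.append("render must be a mapping")
    else:
        try:
            render = RenderSpec(
                palette=render_raw.get("palette", "hot"),
                scale_min=render_raw.get("scale_min"),
                scale_max=render_raw.get("scale_max"),
                unit=render_raw.get("unit", "V/cm"),
                annotate_thresholds=bool(render_raw.get("annotate_thresholds", True)),
                show_tumor_circle=bool(render_raw.get("show_tumor_circle", True)),
                show_electrodes=bool(render_raw.get("show_electrodes", True)),
                output_size=int(render_raw.get("output_size", 400)),
                log_scale=bool(render_raw.get("log_scale", False)),
            )
            if render.unit not in FIELD_UNITS:
                errors.append(f"render.unit = {render.unit!r} not in {sorted(FIELD_UNITS)}")
                render = None
        except (TypeError, ValueError) as exc:
            errors.append(f"render: {exc}")

    # groups / electrodes
    groups_raw = raw.get("groups")
    layout = None
    if not isinstance(groups_raw, list) or not groups_raw:
        errors.append("groups must be a non-empty list")
    else:
        lo, hi = BOUNDS["group_count"]
        if not (lo <= len(groups_raw) <= hi):
            errors.append(_range_err("number of groups", len(groups_raw), lo, hi))
        n_total = sum(
            len(g.get("electrodes", [])) for g in groups_raw if isinstance(g, dict)
        )
        lo, hi = BOUNDS["electrode_count"]
        if not (lo <= n_total <= hi):
            errors.append(_range_err("total electrode count", n_total, lo, hi))

        groups: list[ElectrodeGroup] = []
        for gi, g_raw in enumerate(groups_raw):
            tag = f"groups[{gi}]"
            if not isinstance(g_raw, dict):
                errors.append(f"{tag} must be a mapping")
                continue
            gerr: list[str] = []
            voltage = _num(g_raw, "voltage_V", gerr, required=True)
            electrodes: list[Electrode] = []
            e_list = g_raw.get("electrodes")
            if not isinstance(e_list, list):
                gerr.append("electrodes must be a list")
                e_list = []
            for ei, e_raw in enumerate(e_list):
                etag = f"electrodes[{ei}]"
                if not isinstance(e_raw, dict):
                    gerr.append(f"{etag} must be a mapping")
                    continue
                eerr: list[str] = []
                x = _num(e_raw, "x_mm", eerr, required=True)
                y = _num(e_raw, "y_mm", eerr, required=True)
                pol_raw = e_raw.get("polarity")
                pol = None
                try:
                    pol = Polarity(pol_raw)
                except ValueError:
                    eerr.append(f"polarity = {pol_raw!r} must be 'anode' or 'cathode'")
                if eerr:
                    gerr.extend(f"{etag}: {e}" for e in eerr)
                elif x is not None and y is not None and pol is not None:
                    electrodes.append(
                        Electrode(x * 1e-3, y * 1e-3, pol, str(e_raw.get("id", f"g{gi}e{ei}")))
                    )
            if not gerr and voltage is not None:
                try:
                    groups.append(ElectrodeGroup(tuple(electrodes), voltage))
                except LayoutError as exc:
                    gerr.append(str(exc))
            errors.extend(f"{tag}: {e}" for e in gerr)

        if not errors and area is not None and diam is not None and ratio is not None:
            side = math.sqrt(area) * 1e-3
            try:
                layout = Layout(
                    groups=tuple(groups),
                    electrode_radius=diam / 2 * 1e-3,
                    tissue_side=side,
                    tumor_diameter=ratio * side,
                    conductivity_ratio=cond if cond is not None else 1.0,
                )
            except LayoutError as exc:
                errors.append(str(exc))

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0

    if errors:
        raise ConfigError(errors)
    assert layout is not None and thresholds is not None
    assert mesh is not None and render is not None
    return AppConfig(
        layout=layout,
        thresholds=thresholds,
        mesh=mesh,
        render=render,
        seed=seed,
        warnings=tuple(warnings),
    )


def load_config(path: str | Path) -> AppConfig:
    """Load and validate a JSON (or YAML) configuration file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError([f"cannot parse {path.name}: {exc}"]) from exc
    return validate_config(raw)


def save_config(cfg: AppConfig, path: str | Path) -> None:
    """Write the canonical JSON form (schema-version tagged)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")


def default_config_dict(kind: str = "pair") -> dict:
    """Raw config dict for a named demo layout (see make_fixture_layout)."""
    from .geometry import make_fixture_layout

    spacing = 16e-3  # 1.6 cm, the classic needle-pair spacing
    layout = make_fixture_layout(kind, spacing, voltage=1000.0)
    cfg = AppConfig(
        layout=layout,
        thresholds=Thresholds(),
        mesh=MeshSpec(extent=layout.tissue_side),
        render=RenderSpec(),
    )
    return cfg.to_dict()
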