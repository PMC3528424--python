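"""Electrode layout model and the electrical-axis construction.

A needle-electrode layout is a set of long parallel cylindrical conductors
seen in cross-section on a 2-D tissue slice.  Electrodes are grouped; each
group holds exactly one electrode of one polarity and one or more of the
other, and carries a single applied voltage.  Pulse generators energize one
anode-cathode pair at a time, so a group of n electrodes decomposes into
n - 1 pairs sharing the group voltage.

For each pair, the image-charge (method of images) solution replaces the
two finite-radius conductors by equivalent line charges sitting on the
*electrical axes*: points displaced from the geometric centers toward each
other by the eccentricity

    e = d/2 - sqrt((d/2)^2 - rho0^2),

where d is the center-to-center distance and rho0 the conductor radius.
The displacement makes each conductor surface an exact equipotential of the
two-line-charge field.  All lengths are SI meters internally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Polarity",
    "Electrode",
    "ElectrodeGroup",
    "Layout",
    "PairGeometry",
    "LayoutError",
    "OverlappingElectrodesError",
    "eccentricity",
    "electrical_axes",
    "enumerate_pairs",
    "make_fixture_layout",
]

#: Minimum clearance between conductor surfaces before a pair is rejected (m).
CLEARANCE_EPS = 1e-9


class LayoutError(ValueError):
    """An electrode layout violates a structural invariant."""


class OverlappingElectrodesError(LayoutError):
    """Two conductors overlap or touch (center distance <= 2*rho0)."""


class Polarity(enum.Enum):
    ANODE = "anode"
    CATHODE = "cathode"


@dataclass(frozen=True)
class Electrode:
    """Cross-section of one needle electrode: center position and polarity."""

    x: float
    y: float
    polarity: Polarity
    id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise LayoutError(f"electrode {self.id!r}: non-finite coordinates")
        if not isinstance(self.polarity, Polarity):
            raise LayoutError(f"electrode {self.id!r}: invalid polarity {self.polarity!r}")


@dataclass(frozen=True)
class ElectrodeGroup:
    """Electrodes pulsed together at one voltage.

    Exactly one electrode of one polarity and at least one of the other:
    one cathode and one or more anodes, or one anode and one or more
    cathodes.  The singleton electrode partners every opposite electrode.
    """

    electrodes: tuple[Electrode, ...]
    voltage: float  # applied pair voltage V_AB (V)

    def __post_init__(self) -> None:
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        if len(self.electrodes) < 2:
            raise LayoutError("group must contain at least 2 electrodes")
        if not (self.voltage > 0 and math.isfinite(self.voltage)):
            raise LayoutError(f"group voltage must be positive, got {self.voltage}")
        n_anode = sum(e.polarity is Polarity.ANODE for e in self.electrodes)
        n_cathode = len(self.electrodes) - n_anode
        if min(n_anode, n_cathode) != 1:
            raise LayoutError(
                "group must hold exactly one electrode of one polarity and "
                f">=1 of the other (got {n_anode} anodes, {n_cathode} cathodes)"
            )

    @property
    def hub(self) -> Electrode:
        """The singleton-polarity electrode shared by every pair of the group."""
        n_anode = sum(e.polarity is Polarity.ANODE for e in self.electrodes)
        single = Polarity.ANODE if n_anode == 1 else Polarity.CATHODE
        return next(e for e in self.electrodes if e.polarity is single)


@dataclass(frozen=True)
class Layout:
    """Full electrode configuration on a square tissue slice.

    The tissue is a square of side ``tissue_side`` centered at the origin;
    the tumor is a centered circle of diameter ``tumor_diameter``.
    ``conductivity_ratio`` (tumor/surrounding) is stored for round-tripping
    but does not enter the field computation: the engine treats the slice
    as homogeneous in conductivity.
    """

    groups: tuple[ElectrodeGroup, ...]
    electrode_radius: float  # rho0 (m)
    tissue_side: float  # (m)
    tumor_diameter: float  # (m)
    conductivity_ratio: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not (1 <= len(self.groups) <= 6):
            raise LayoutError(f"group count must be in [1, 6], got {len(self.groups)}")
        n = len(self.electrodes)
        if not (2 <= n <= 12):
            raise LayoutError(f"total electrode count must be in [2, 12], got {n}")
        if not (self.electrode_radius > 0):
            raise LayoutError("electrode_radius must be positive")
        if not (self.tissue_side > 0):
            raise LayoutError("tissue_side must be positive")
        if not (0 <= self.tumor_diameter <= self.tissue_side):
            raise LayoutError(
                f"tumor_diameter must lie in [0, tissue_side={self.tissue_side}], "
                f"got {self.tumor_diameter}"
            )
        half = self.tissue_side / 2
        for e in self.electrodes:
            if abs(e.x) > half or abs(e.y) > half:
                raise LayoutError(
                    f"electrode {e.id!r} at ({e.x}, {e.y}) m lies outside the "
                    f"tissue square of side {self.tissue_side} m"
                )
        for g in self.groups:
            es = g.electrodes
            for i in range(len(es)):
                for j in range(i + 1, len(es)):
                    d = math.hypot(es[i].x - es[j].x, es[i].y - es[j].y)
                    if d <= 2 * self.electrode_radius + CLEARANCE_EPS:
                        raise OverlappingElectrodesError(
                            f"electrodes {es[i].id!r} and {es[j].id!r} are "
                            f"{d:.6g} m apart; conductors of radius "
                            f"{self.electrode_radius:.6g} m overlap or touch"
                        )

    @property
    def electrodes(self) -> tuple[Electrode, ...]:
        return tuple(e for g in self.groups for e in g.electrodes)


@dataclass(frozen=True)
class PairGeometry:
    """Derived image-charge quantities for one anode-cathode pair.

    Attributes mirror the two-wire construction: ``d_ab`` center distance,
    ``rho0`` conductor radius, ``e`` eccentricity, ``s`` half-distance
    between the electrical axes, ``theta1``/``theta2`` the A->B and B->A
    bearings, ``(xp_a, yp_a)``/``(xp_b, yp_b)`` the electrical axes of the
    anode and cathode, and ``c`` the potential scale V_AB / (2 ln K).
    """

    d_ab: float
    rho0: float
    e: float
    s: float
    theta1: float
    theta2: float
    xp_a: float
    yp_a: float
    xp_b: float
    yp_b: float
    c: float
    voltage: float
    anode: Electrode = field(default=None, repr=False)  # type: ignore[assignment]
    cathode: Electrode = field(default=None, repr=False)  # type: ignore[assignment]


def eccentricity(d_ab: float, rho0: float) -> float:
    """Displacement of the electrical axis from the geometric center.

    ``e = d/2 - sqrt((d/2)^2 - rho0^2)``, satisfying the exact identity
    ``e * (d - e) = rho0**2``.  Requires ``d_ab > 2*rho0`` (non-touching
    conductors); ``rho0 = 0`` returns 0 (thin-wire limit).
    """
    if not (d_ab > 0) or rho0 < 0:
        raise LayoutError(f"need d_ab > 0 and rho0 >= 0, got d_ab={d_ab}, rho0={rho0}")
    if rho0 == 0.0:
        return 0.0
    half = d_ab / 2
    if d_ab <= 2 * rho0:
        raise OverlappingElectrodesError(
            f"center distance {d_ab:.6g} m <= electrode diameter {2 * rho0:.6g} m: "
            "conductors overlap or touch"
        )
    # rho0^2 / (half + s) is the algebraically equivalent, cancellation-free
    # form of half - sqrt(half^2 - rho0^2).
    s = math.sqrt(half * half - rho0 * rho0)
    return rho0 * rho0 / (half + s)


def electrical_axes(
    anode: Electrode,
    cathode: Electrode,
    rho0: float,
    voltage: float = 1.0,
) -> PairGeometry:
    """Construct the full image-charge geometry of one pair.

    Each electrical axis is displaced by the eccentricity ``e`` from its
    geometric center toward the other electrode (quadrant-aware atan2
    bearings, valid for any pair orientation); the axes end up ``2 s``
    apart with ``s = sqrt((d/2)^2 - rho0^2)``.
    """
    dx = cathode.x - anode.x
    dy = cathode.y - anode.y
    d_ab = math.hypot(dx, dy)
    if d_ab == 0.0:
        raise LayoutError("electrodes have coincident centers")
    ecc = eccentricity(d_ab, rho0)
    s = math.sqrt((d_ab / 2) ** 2 - rho0 * rho0) if rho0 > 0 else d_ab / 2
    theta1 = math.atan2(dy, dx)  # bearing anode -> cathode
    theta2 = math.atan2(-dy, -dx)  # bearing cathode -> anode
    return PairGeometry(
        d_ab=d_ab,
        rho0=rho0,
        e=ecc,
        s=s,
        theta1=theta1,
        theta2=theta2,
        xp_a=anode.x + ecc * math.cos(theta1),
        yp_a=anode.y + ecc * math.sin(theta1),
        xp_b=cathode.x + ecc * math.cos(theta2),
        yp_b=cathode.y + ecc * math.sin(theta2),
        c=_pair_constant(voltage, d_ab, rho0),
        voltage=voltage,
        anode=anode,
        cathode=cathode,
    )


def _pair_constant(v_ab: float, d_ab: float, rho0: float) -> float:
    # C = V_AB / (2 ln[(d + sqrt(d^2 - 4 rho0^2)) / (2 rho0)]); natural log.
    if rho0 <= 0:
        raise LayoutError("pair constant requires rho0 > 0")
    if d_ab <= 2 * rho0:
        raise OverlappingElectrodesError(
            f"center distance {d_ab:.6g} m <= electrode diameter {2 * rho0:.6g} m"
        )
    k = (d_ab + math.sqrt(d_ab * d_ab - 4 * rho0 * rho0)) / (2 * rho0)
    return v_ab / (2 * math.log(k))


def enumerate_pairs(layout: Layout) -> list[tuple[Electrode, Electrode, float]]:
    """Decompose the layout into (anode, cathode, voltage) pairs.

    Within each group every majority-polarity electrode is paired with the
    group's singleton opposite electrode; no pairs cross groups.
    """
    pairs: list[tuple[Electrode, Electrode, float]] = []
    for g in layout.groups:
        hub = g.hub
        for e in g.electrodes:
            if e is hub:
                continue
            if hub.polarity is Polarity.ANODE:
                pairs.append((hub, e, g.voltage))
            else:
                pairs.append((e, hub, g.voltage))
    return pairs


def pair_geometries(layout: Layout) -> list[PairGeometry]:
    """Electrical-axis geometry for every activated pair of the layout."""
    return [
        electrical_axes(a, c, layout.electrode_radius, voltage=v)
        for a, c, v in enumerate_pairs(layout)
    ]


def make_fixture_layout(
    kind: str,
    spacing: float,
    voltage: float = 1000.0,
    *,
    electrode_radius: float = 0.5e-3,
    tissue_side: float | None = None,
    tumor_diameter: float | None = None,
) -> Layout:
    """Build a canonical centered test layout.

    ``pair``: two opposed electrodes ``spacing`` apart on the x axis.
    ``two_rows``: three anodes facing three cathodes (rows ``spacing``
    apart, three groups pairing opposite row positions).
    ``hex6``: six electrodes on a circle of radius ``spacing`` at 60-degree
    steps with alternating polarity, grouped as three adjacent pairs.
    """
    if spacing <= 2 * electrode_radius:
        raise LayoutError(
            f"spacing {spacing:.6g} m must exceed electrode diameter "
            f"{2 * electrode_radius:.6g} m"
        )
    if kind == "pair":
        groups = [
            ElectrodeGroup(
                (
                    Electrode(-spacing / 2, 0.0, Polarity.ANODE, "a1"),
                    Electrode(+spacing / 2, 0.0, Polarity.CATHODE, "c1"),
                ),
                voltage,
            )
        ]
        extent = spacing
    elif kind == "two_rows":
        groups = []
        for i, yy in enumerate((-spacing, 0.0, spacing)):
            groups.append(
                ElectrodeGroup(
                    (
                        Electrode(-spacing / 2, yy, Polarity.ANODE, f"a{i + 1}"),
                        Electrode(+spacing / 2, yy, Polarity.CATHODE, f"c{i + 1}"),
                    ),
                    voltage,
                )
            )
        extent = 2 * spacing
    elif kind == "hex6":
        ring = [
            Electrode(
                spacing * math.cos(math.radians(60 * k)),
                spacing * math.sin(math.radians(60 * k)),
                Polarity.ANODE if k % 2 == 0 else Polarity.CATHODE,
                f"e{k + 1}",
            )
            for k in range(6)
        ]
        groups = [ElectrodeGroup((ring[2 * j], ring[2 * j + 1]), voltage) for j in range(3)]
        extent = 2 * spacing
    else:
        raise LayoutError(f"unknown fixture kind {kind!r} (expected pair|two_rows|hex6)")
    side = tissue_side if tissue_side is not None else 2.5 * extent
    tumor = tumor_diameter if tumor_diameter is not None else side / 2
    return Layout(
        groups=tuple(groups),
        electrode_radius=electrode_radius,
        tissue_side=side,
        tumor_diameter=tumor,
    )
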