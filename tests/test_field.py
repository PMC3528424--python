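"""Closed-form pair potential/field and the max-composition mesh engine."""

import json
import math

import numpy as np
import pytest

from porefield import (
    Electrode,
    ElectrodeGroup,
    FieldMap,
    Layout,
    MeshSpec,
    OverlappingElectrodesError,
    Polarity,
    SingularPointError,
    evaluate_mesh,
    make_fixture_layout,
    pair_constant,
    pair_field,
    pair_geometries,
    pair_potential,
    write_fieldmap_tsv,
)
from tests.conftest import CLASSIC_D, CLASSIC_RHO0, CLASSIC_V

# Frozen with 50-digit arithmetic for V=1300 V, d=1.6 cm, rho0=0.1 cm.
C_CLASSIC = 234.770663346  # V
E_MID_CLASSIC = 591.566466998  # V/cm
E_NAIVE_UD = 812.5  # V/cm, the misleading voltage-over-distance estimate


class TestPairConstant:
    def test_classic_value(self):
        assert pair_constant(CLASSIC_V, CLASSIC_D, CLASSIC_RHO0) == pytest.approx(
            C_CLASSIC, rel=1e-10
        )

    def test_linearity_in_voltage(self):
        c1 = pair_constant(650.0, CLASSIC_D, CLASSIC_RHO0)
        c2 = pair_constant(1300.0, CLASSIC_D, CLASSIC_RHO0)
        assert c2 == pytest.approx(2 * c1, rel=1e-15)

    def test_diverges_as_conductors_approach_contact(self):
        rho0 = 1e-3
        cs = [pair_constant(1000.0, 2 * rho0 * (1 + eps), rho0) for eps in (1e-2, 1e-4, 1e-6)]
        assert cs[0] < cs[1] < cs[2]
        # ln K ~ 2 sqrt(eps) near contact, so C grows ~ 1/sqrt(eps)
        assert cs[2] > 50 * cs[0]

    def test_touching_rejected(self):
        with pytest.raises(OverlappingElectrodesError):
            pair_constant(1000.0, 2e-3, 1e-3)


class TestPairPotential:
    def test_midpoint_is_zero(self, classic_pair):
        assert pair_potential(0.0, 0.0, classic_pair) == pytest.approx(0.0, abs=1e-10)

    def test_conductor_surfaces_at_half_voltage(self, classic_pair):
        """The image construction makes each conductor circle an equipotential
        at +/- V_AB/2 -- +650 V / -650 V for the 1300 V pair."""
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        for e, sign in ((classic_pair.anode, +1), (classic_pair.cathode, -1)):
            v = pair_potential(
                e.x + CLASSIC_RHO0 * np.cos(theta),
                e.y + CLASSIC_RHO0 * np.sin(theta),
                classic_pair,
            )
            assert np.allclose(v, sign * CLASSIC_V / 2, rtol=1e-9)
            spread = (v.max() - v.min()) / abs(v.mean())
            assert spread <= 1e-6

    def test_antisymmetric_under_electrode_swap(self, classic_pair, rng):
        from porefield import electrical_axes

        a, c = classic_pair.anode, classic_pair.cathode
        swapped = electrical_axes(
            Electrode(c.x, c.y, Polarity.ANODE),
            Electrode(a.x, a.y, Polarity.CATHODE),
            CLASSIC_RHO0,
            voltage=CLASSIC_V,
        )
        for _ in range(20):
            x, y = rng.uniform(-1.5e-2, 1.5e-2, 2)
            assert pair_potential(x, y, swapped) == pytest.approx(
                -pair_potential(x, y, classic_pair), rel=1e-12, abs=1e-9
            )

    def test_zero_on_perpendicular_bisector(self, classic_pair, rng):
        ys = rng.uniform(-1.8e-2, 1.8e-2, 20)
        v = pair_potential(np.zeros_like(ys), ys, classic_pair)
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_harmonic_away_from_electrodes(self, classic_pair, rng):
        """The 5-point Laplacian vanishes within the h^2 discretization error
        of a harmonic function (sum of two log potentials)."""
        h = 1e-5
        for _ in range(20):
            x, y = rng.uniform(-1.5e-2, 1.5e-2, 2)
            r_min = min(
                math.hypot(x - classic_pair.xp_a, y - classic_pair.yp_a),
                math.hypot(x - classic_pair.xp_b, y - classic_pair.yp_b),
            )
            if r_min < 3 * CLASSIC_RHO0:
                continue
            lap = (
                pair_potential(x + h, y, classic_pair)
                + pair_potential(x - h, y, classic_pair)
                + pair_potential(x, y + h, classic_pair)
                + pair_potential(x, y - h, classic_pair)
                - 4 * pair_potential(x, y, classic_pair)
            ) / h**2
            # residual bound: h^2/12 * 4th-derivative scale (~ C/r^4) plus
            # floating cancellation noise ~ eps*|V|/h^2
            bound = 10 * (h**2 * classic_pair.c / r_min**4 + 1e-15 * CLASSIC_V / h**2)
            assert abs(lap) <= bound

    def test_singular_on_electrical_axis(self, classic_pair):
        with pytest.raises(SingularPointError):
            pair_potential(classic_pair.xp_a, classic_pair.yp_a, classic_pair)


class TestPairField:
    def test_midpoint_closed_form(self, classic_pair):
        """Midpoint field is 2C/s ~ 591.6 V/cm -- NOT the naive U/d = 812.5 V/cm."""
        e_mid = pair_field(0.0, 0.0, classic_pair) / 100  # V/m -> V/cm
        assert e_mid == pytest.approx(E_MID_CLASSIC, rel=1e-10)
        assert e_mid == pytest.approx(
            2 * classic_pair.c / classic_pair.s / 100, rel=1e-12
        )
        assert abs(e_mid - E_NAIVE_UD) > 200  # the U/d estimate is far off

    def test_matches_gradient_at_midpoint(self, classic_pair):
        h = 1e-6 * classic_pair.d_ab
        dvdx = (
            pair_potential(h, 0.0, classic_pair) - pair_potential(-h, 0.0, classic_pair)
        ) / (2 * h)
        assert pair_field(0.0, 0.0, classic_pair) == pytest.approx(abs(dvdx), rel=1e-6)

    def test_monotone_decay_along_bisector(self, classic_pair):
        ys = np.linspace(0.0, 1.9e-2, 200)
        e = pair_field(np.zeros_like(ys), ys, classic_pair)
        assert np.all(np.diff(e) < 0)

    def test_far_field_dipole_decay(self):
        # r^2 * E approaches a constant along a ray for r >> d_AB
        lay = make_fixture_layout(
            "pair", 2e-3, 1000.0, electrode_radius=0.2e-3, tissue_side=2.0
        )
        (pair,) = pair_geometries(lay)
        rs = np.array([0.2, 0.4, 0.8])
        vals = rs**2 * pair_field(rs / np.sqrt(2), rs / np.sqrt(2), pair)
        assert vals[1] == pytest.approx(vals[2], rel=0.02)
        assert vals[0] == pytest.approx(vals[2], rel=0.05)

    def test_nonnegative(self, classic_pair, rng):
        x = rng.uniform(-2e-2, 2e-2, 100)
        y = rng.uniform(-2e-2, 2e-2, 100)
        assert np.all(pair_field(x, y, classic_pair) >= 0)


class TestEvaluateMesh:
    def test_default_mesh_is_400_by_400(self, classic_layout):
        fmap = evaluate_mesh(classic_layout)
        assert fmap.spec.n_x == fmap.spec.n_y == 400
        assert fmap.n_points == 160_000
        assert fmap.values.shape == (400, 400)

    def test_single_pair_equals_pair_field(self, classic_layout, small_mesh, classic_pair):
        fmap = evaluate_mesh(classic_layout, small_mesh)
        xg, yg = small_mesh.grid()
        expect = pair_field(xg, yg, classic_pair)
        free = ~fmap.mask
        assert np.array_equal(fmap.values[free], expect[free])
        assert np.all(fmap.values[fmap.mask] == 0.0)

    def test_duplicated_group_changes_nothing(self, classic_layout, small_mesh):
        """max(a, a) = a: two identical groups give the single-group map."""
        g = classic_layout.groups[0]
        lay2 = Layout(
            groups=(
                g,
                ElectrodeGroup(
                    tuple(
                        Electrode(e.x, e.y, e.polarity, e.id + "b") for e in g.electrodes
                    ),
                    g.voltage,
                ),
            ),
            electrode_radius=classic_layout.electrode_radius,
            tissue_side=classic_layout.tissue_side,
            tumor_diameter=classic_layout.tumor_diameter,
        )
        f1 = evaluate_mesh(classic_layout, small_mesh)
        f2 = evaluate_mesh(lay2, small_mesh)
        assert np.array_equal(f1.values, f2.values)
        assert np.array_equal(f1.mask, f2.mask)

    def test_voltage_scaling_is_exact(self, small_mesh):
        lay1 = make_fixture_layout("hex6", 1e-2, 500.0, tissue_side=0.04)
        lay2 = make_fixture_layout("hex6", 1e-2, 1000.0, tissue_side=0.04)
        f1 = evaluate_mesh(lay1, small_mesh)
        f2 = evaluate_mesh(lay2, small_mesh)
        assert np.array_equal(f2.values, 2.0 * f1.values)
        assert np.array_equal(f1.mask, f2.mask)

    def test_rotating_layout_rotates_the_map(self, small_mesh):
        """90-degree frame invariance: the map of the rotated layout is the
        rotated map, exactly to floating round-off."""
        lay = make_fixture_layout("pair", CLASSIC_D, CLASSIC_V, electrode_radius=CLASSIC_RHO0)
        # rotate by +90 degrees: (x, y) -> (-y, x)
        rot_groups = tuple(
            ElectrodeGroup(
                tuple(Electrode(-e.y, e.x, e.polarity, e.id) for e in g.electrodes),
                g.voltage,
            )
            for g in lay.groups
        )
        lay_rot = Layout(
            groups=rot_groups,
            electrode_radius=lay.electrode_radius,
            tissue_side=lay.tissue_side,
            tumor_diameter=lay.tumor_diameter,
        )
        f0 = evaluate_mesh(lay, small_mesh)
        f1 = evaluate_mesh(lay_rot, small_mesh)
        assert np.allclose(f1.values, np.rot90(f0.values, 1), rtol=1e-12, atol=1e-9)
        assert np.array_equal(f1.mask, np.rot90(f0.mask, 1))

    def test_mask_covers_all_electrodes_globally(self, small_mesh):
        lay = make_fixture_layout("two_rows", 1e-2, 800.0, tissue_side=0.04)
        fmap = evaluate_mesh(lay, small_mesh)
        xg, yg = small_mesh.grid()
        for e in lay.electrodes:
            inside = (xg - e.x) ** 2 + (yg - e.y) ** 2 <= lay.electrode_radius**2
            assert np.all(fmap.mask[inside])

    def test_mesh_extent_must_match_tissue_side(self, classic_layout):
        with pytest.raises(ValueError):
            evaluate_mesh(classic_layout, MeshSpec(n_x=50, n_y=50, extent=0.05))


class TestMeshSpec:
    def test_pixel_centers(self):
        spec = MeshSpec(n_x=4, n_y=4, extent=0.04)
        assert spec.xs == pytest.approx([-0.015, -0.005, 0.005, 0.015])
        assert spec.ys == pytest.approx([0.015, 0.005, -0.005, -0.015])  # row 0 = top

    def test_too_small_mesh_rejected(self):
        with pytest.raises(ValueError):
            MeshSpec(n_x=1, n_y=400, extent=0.04)


class TestTsvExport:
    def test_matrix_shape_na_cells_and_sidecar(self, classic_layout, small_mesh, tmp_path):
        fmap = evaluate_mesh(classic_layout, small_mesh)
        out = tmp_path / "map.tsv"
        write_fieldmap_tsv(fmap, out, layout=classic_layout)
        rows = out.read_text().splitlines()
        assert len(rows) == small_mesh.n_y
        assert all(len(r.split("\t")) == small_mesh.n_x for r in rows)
        n_na = sum(r.split("\t").count("NA") for r in rows)
        assert n_na == int(fmap.mask.sum()) > 0
        # row 0 is the top of the display: first row of values matches values[0]
        first_free_col = int(np.argmax(~fmap.mask[0]))
        cell = rows[0].split("\t")[first_free_col]
        assert float(cell) == pytest.approx(fmap.values[0, first_free_col], rel=1e-5)
        header = json.loads((tmp_path / "map.tsv.json").read_text())
        assert header["n_x"] == small_mesh.n_x and header["units"] == "V/m"
        assert header["layout_hash"]
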