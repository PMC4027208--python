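"""Geometric CVs: COM distance, inertia axes, torsions, POA/DFA, walls."""

import numpy as np
import pytest

import gqmetad as gq
from gqmetad.collective_variables import (AxisDegeneracyError,
                                          UndefinedTorsionError, _dihedral)
from conftest import quad_group, quad_orientation, with_ligand


def rod(n=5, axis=(0, 0, 1.0), spacing=1.0, center=(0, 0, 0)):
    """n beads on a line through ``center`` (which is also the COM)."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    steps = (np.arange(n) - (n - 1) / 2.0)[:, None] * spacing
    return steps * axis + np.asarray(center, dtype=float)


def group_for(coords, masses=None, label="g"):
    n = len(coords)
    masses = np.ones(n) if masses is None else np.asarray(masses)
    return gq.AtomGroup(np.arange(n), masses, label)


class TestCenterOfMass:
    @pytest.mark.parametrize("coords,masses,expected", [
        ([[0, 0, 0], [2, 0, 0]], [1, 1], [1, 0, 0]),
        ([[3, -1, 2]], [5], [3, -1, 2]),
        ([[0, 0, 0], [4, 0, 0]], [1, 3], [3, 0, 0]),
    ])
    def test_weighted_mean(self, coords, masses, expected):
        coords = np.asarray(coords, dtype=float)
        g = group_for(coords, masses)
        assert np.allclose(gq.center_of_mass(g, coords), expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gq.AtomGroup([], [], "empty")


class TestMajorInertiaAxis:
    def test_rod_axis_with_sign_from_reference(self):
        coords = rod(5)
        g = group_for(coords)
        axis = gq.major_inertia_axis(g, coords, (0, 4))
        assert np.allclose(axis, [0, 0, 1], atol=1e-12)
        flipped = gq.major_inertia_axis(g, coords, (4, 0))
        assert np.allclose(flipped, [0, 0, -1], atol=1e-12)

    def test_quadruplex_axis_parallel_to_symmetry_axis(self, quadruplex):
        axis = gq.major_inertia_axis(quad_group(quadruplex),
                                     quadruplex.coords,
                                     quad_orientation(quadruplex))
        assert np.linalg.norm(np.cross(axis, quadruplex.symmetry_axis)) < 1e-6
        assert axis @ quadruplex.symmetry_axis > 0  # 5' -> 3' is +z

    def test_spherical_top_raises_degeneracy(self):
        # regular tetrahedron: all principal moments equal
        coords = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                          dtype=float)
        g = group_for(coords)
        with pytest.raises(AxisDegeneracyError):
            gq.major_inertia_axis(g, coords, (0, 1))

    def test_oblate_quadruplex_raises_degeneracy(self):
        q = gq.build_toy_quadruplex(2, 3.4, 8.0)
        with pytest.raises(AxisDegeneracyError):
            gq.major_inertia_axis(quad_group(q), q.coords,
                                  quad_orientation(q))

    def test_sign_stable_along_gradual_rotation(self, quadruplex):
        """The oriented axis never flips between frames rotated < 10°."""
        g = quad_group(quadruplex)
        prev = None
        for ang in np.linspace(0, np.pi, 40):  # 4.6° increments
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
            coords = quadruplex.coords @ rot.T
            axis = gq.major_inertia_axis(g, coords,
                                         quad_orientation(quadruplex))
            if prev is not None:
                assert axis @ prev > 0
            prev = axis


class TestComDistance:
    def test_identical_groups_zero(self, quadruplex):
        g = quad_group(quadruplex)
        assert gq.com_distance(g, g, quadruplex.coords) == 0.0

    def test_three_four_five(self):
        coords = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        g1 = gq.AtomGroup([0], [1.0], "a")
        g2 = gq.AtomGroup([1], [1.0], "b")
        assert gq.com_distance(g1, g2, coords) == pytest.approx(5.0)
        assert gq.com_distance(g2, g1, coords) == pytest.approx(5.0)


class TestAxisTorsion:
    def setup_rods(self, axis2, ref2=(0, 4)):
        c1 = rod(5, (0, 0, 1), center=(0, 0, 0))
        c2 = rod(5, axis2, center=(5, 0, 0))
        coords = np.vstack([c1, c2])
        g1 = gq.AtomGroup(np.arange(5), np.ones(5), "a")
        g2 = gq.AtomGroup(np.arange(5, 10), np.ones(5), "b")
        return coords, g1, g2, (0, 4), (5 + ref2[0], 5 + ref2[1])

    def test_parallel_axes_zero(self):
        coords, g1, g2, r1, r2 = self.setup_rods((0, 0, 1))
        assert gq.axis_torsion(g1, g2, coords, r1, r2) == pytest.approx(
            0.0, abs=1e-12)

    def test_antiparallel_axes_pi(self):
        coords, g1, g2, r1, r2 = self.setup_rods((0, 0, 1), ref2=(4, 0))
        assert gq.axis_torsion(g1, g2, coords, r1, r2) == pytest.approx(
            np.pi, abs=1e-12)

    def test_quarter_turn_matches_brute_force_dihedral(self):
        coords, g1, g2, r1, r2 = self.setup_rods((0, 1, 0))
        phi = gq.axis_torsion(g1, g2, coords, r1, r2)
        a1 = gq.major_inertia_axis(g1, coords, r1)
        a2 = gq.major_inertia_axis(g2, coords, r2)
        com1 = gq.center_of_mass(g1, coords)
        com2 = gq.center_of_mass(g2, coords)
        assert abs(phi) == pytest.approx(np.pi / 2, abs=1e-10)
        assert phi == pytest.approx(
            _brute_force_dihedral(com1 + a1, com1, com2, com2 + a2),
            abs=1e-12)

    def test_coincident_coms_rejected(self):
        c1 = rod(5, (0, 0, 1), center=(0, 0, 0))
        c2 = rod(5, (0, 1, 0), center=(0, 0, 0))
        coords = np.vstack([c1, c2])
        g1 = gq.AtomGroup(np.arange(5), np.ones(5), "a")
        g2 = gq.AtomGroup(np.arange(5, 10), np.ones(5), "b")
        with pytest.raises(UndefinedTorsionError):
            gq.axis_torsion(g1, g2, coords, (0, 4), (5, 9))


def _brute_force_dihedral(p0, p1, p2, p3):
    """Independent dihedral via projections onto the plane normal to b1."""
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    v = (p0 - p1) - ((p0 - p1) @ b1) * b1
    w = (p3 - p2) - ((p3 - p2) @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return np.arctan2(y, x)


def test_dihedral_convention_against_brute_force(rng):
    for _ in range(50):
        pts = rng.normal(size=(4, 3))
        assert _dihedral(*pts) == pytest.approx(
            _brute_force_dihedral(*pts), abs=1e-10)


class TestPoaDfa:
    def make_scene(self, quadruplex, position):
        lig = gq.RigidLigand(position=np.asarray(position, dtype=float))
        return with_ligand(quadruplex, lig)

    def test_point_at_axis_owner_com(self, quadruplex):
        coords, g = self.make_scene(quadruplex, [0.0, 0.0, 0.0])
        ref = quad_orientation(quadruplex)
        # scaffold bead sits at the quadruplex COM (origin)
        poa = gq.projection_on_axis(g["scaffold"], g["quadruplex"], coords,
                                    ref)
        assert poa == pytest.approx(0.0, abs=1e-10)

    def test_displacement_along_axis(self, quadruplex):
        coords, g = self.make_scene(quadruplex, [0.0, 0.0, 5.0])
        ref = quad_orientation(quadruplex)
        assert gq.projection_on_axis(g["scaffold"], g["quadruplex"], coords,
                                     ref) == pytest.approx(5.0, abs=1e-10)
        assert gq.distance_from_axis(g["scaffold"], g["quadruplex"], coords,
                                     ref) == pytest.approx(0.0, abs=1e-10)

    def test_perpendicular_displacement(self, quadruplex):
        coords, g = self.make_scene(quadruplex, [7.0, 0.0, 0.0])
        ref = quad_orientation(quadruplex)
        assert gq.projection_on_axis(g["scaffold"], g["quadruplex"], coords,
                                     ref) == pytest.approx(0.0, abs=1e-10)
        assert gq.distance_from_axis(g["scaffold"], g["quadruplex"], coords,
                                     ref) == pytest.approx(7.0, abs=1e-10)

    def test_pythagorean_identity_random_configs(self, quadruplex, rng):
        ref = quad_orientation(quadruplex)
        for _ in range(100):
            coords, g = self.make_scene(quadruplex, rng.uniform(-15, 15, 3))
            poa = gq.projection_on_axis(g["scaffold"], g["quadruplex"],
                                        coords, ref)
            dfa = gq.distance_from_axis(g["scaffold"], g["quadruplex"],
                                        coords, ref)
            delta = (gq.center_of_mass(g["scaffold"], coords)
                     - gq.center_of_mass(g["quadruplex"], coords))
            assert poa ** 2 + dfa ** 2 == pytest.approx(delta @ delta,
                                                        abs=1e-10)


class TestSymmetryInvariance:
    """Symmetry-equivalent ligand placements get identical d, POA, DFA."""

    def test_quarter_turn_placement(self, quadruplex, rng):
        ref = quad_orientation(quadruplex)
        for _ in range(10):
            pos = rng.uniform(-12, 12, 3)
            rot_pos = quadruplex.symmetry_rotation(pos)
            vals = []
            for p in (pos, rot_pos):
                lig = gq.RigidLigand(position=p)
                coords, g = with_ligand(quadruplex, lig)
                vals.append((
                    gq.com_distance(g["scaffold"], g["quadruplex"], coords),
                    gq.projection_on_axis(g["scaffold"], g["quadruplex"],
                                          coords, ref),
                    gq.distance_from_axis(g["scaffold"], g["quadruplex"],
                                          coords, ref)))
            assert np.allclose(vals[0], vals[1], atol=1e-8)


class TestRigidMotionInvariance:
    def test_all_cvs_invariant(self, quadruplex, rng):
        lig = gq.RigidLigand(position=np.array([6.0, 2.0, 5.0]), theta=0.7,
                             phi=0.3)
        coords, g = with_ligand(quadruplex, lig)
        ref = quad_orientation(quadruplex)
        lref = (quadruplex.n_beads, quadruplex.n_beads + 1)

        def all_cvs(c):
            return np.array([
                gq.com_distance(g["scaffold"], g["quadruplex"], c),
                gq.projection_on_axis(g["scaffold"], g["quadruplex"], c, ref),
                gq.distance_from_axis(g["scaffold"], g["quadruplex"], c, ref),
                gq.axis_torsion(g["ligand"], g["quadruplex"], c, lref, ref),
            ])

        base = all_cvs(coords)
        for _ in range(10):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x),
                 1 - 2 * (x * x + y * y)]])
            moved = coords @ rot.T + rng.uniform(-20, 20, 3)
            assert np.allclose(all_cvs(moved), base, atol=1e-8)


class TestWall:
    @pytest.mark.parametrize("value,expected_e,expected_d", [
        (20.0, 0.0, 0.0),
        (27.0, 0.0, 0.0),
        (28.0, 10.0, 20.0),
    ])
    def test_half_harmonic(self, value, expected_e, expected_d):
        wall = gq.WallSpec(cv_label="d", limit=27.0, spring=10.0)
        e, de = gq.wall_energy(value, wall)
        assert e == pytest.approx(expected_e)
        assert de == pytest.approx(expected_d)

    def test_label_mismatch_rejected(self):
        wall = gq.WallSpec(cv_label="d")
        with pytest.raises(ValueError):
            gq.wall_energy(20.0, wall, label="phi")


class TestCvGradient:
    def test_com_distance_gradient_matches_analytic(self):
        coords = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        spec = gq.CVSpec("com_distance",
                         [gq.AtomGroup([0], [1.0], "a"),
                          gq.AtomGroup([1], [1.0], "b")])
        grad = gq.cv_gradient(spec, coords)
        u = np.array([3, 4, 0]) / 5.0
        assert np.allclose(grad[0], -u, atol=1e-6)
        assert np.allclose(grad[1], u, atol=1e-6)

    def test_poa_gradient_is_axis_for_point_bead(self, quadruplex):
        lig = gq.RigidLigand(position=np.array([3.0, 2.0, 6.0]))
        coords, g = with_ligand(quadruplex, lig)
        ref = quad_orientation(quadruplex)
        spec = gq.CVSpec("projection_on_axis",
                         [g["scaffold"], g["quadruplex"]],
                         orientation_reference=ref)
        grad = gq.cv_gradient(spec, coords)
        axis = gq.major_inertia_axis(g["quadruplex"], coords, ref)
        assert np.allclose(grad[quadruplex.n_beads], axis, atol=1e-6)

    def test_translation_invariance_of_distance_gradient(self, quadruplex):
        lig = gq.RigidLigand(position=np.array([8.0, 1.0, 2.0]))
        coords, g = with_ligand(quadruplex, lig)
        spec = gq.CVSpec("com_distance", [g["scaffold"], g["quadruplex"]])
        grad = gq.cv_gradient(spec, coords)
        assert np.abs(grad.sum(axis=0)).max() < 1e-8
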