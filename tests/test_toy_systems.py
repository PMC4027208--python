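"""Generators: analytic landscapes, toy structures, samplers, quadrature."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import ks_1samp

import gqmetad as gq
from gqmetad.grids import grid_saddle_energy
from gqmetad.toy_systems import (FunctionPotential, HoppingLandscapeSpec,
                                 ParameterError)

KT300 = gq.kT(300.0)


# ---------------------------------------------------------------------------
# double well
# ---------------------------------------------------------------------------

class TestDoubleWell:
    @pytest.mark.parametrize("asym", [0.0, 0.9])
    def test_minimum_gap_equals_asymmetry(self, asym):
        pot = gq.make_double_well(6.0, 4.0, asym)
        left = minimize_scalar(lambda x: float(pot.energy(x)),
                               bounds=(-3.0, -1.0), method="bounded",
                               options={"xatol": 1e-12})
        right = minimize_scalar(lambda x: float(pot.energy(x)),
                                bounds=(1.0, 3.0), method="bounded",
                                options={"xatol": 1e-12})
        assert right.fun - left.fun == pytest.approx(asym, abs=1e-8)
        assert right.x - left.x == pytest.approx(4.0, abs=0.01)

    def test_gradient_vanishes_at_minima(self):
        pot = gq.make_double_well(6.0, 4.0, 0.9)
        for m in pot.minima:
            assert abs(pot.gradient(np.array(m)).item()) < 1e-6

    @pytest.mark.parametrize("kwargs", [
        {"barrier": -1.0, "separation": 4.0},
        {"barrier": 6.0, "separation": 0.0},
        {"barrier": 1.0, "separation": 4.0, "asymmetry": 2.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            gq.make_double_well(**kwargs)


@pytest.mark.parametrize("potname", ["double_well", "hopping"])
def test_gradient_matches_finite_differences(potname, hopping, rng):
    """Analytic gradients agree with central differences at random points."""
    pot = gq.make_double_well(6.0, 4.0, 0.9) if potname == "double_well" \
        else hopping
    span = pot.bounds[:, 1] - pot.bounds[:, 0]
    h = 1e-5 * span
    pts = rng.uniform(pot.bounds[:, 0] + 2 * h, pot.bounds[:, 1] - 2 * h,
                      size=(100, pot.ndim))
    grad = pot.gradient(pts)
    for i in range(pot.ndim):
        dp = pts.copy()
        dm = pts.copy()
        dp[:, i] += h[i]
        dm[:, i] -= h[i]
        fd = (pot.energy(dp) - pot.energy(dm)) / (2 * h[i])
        assert np.all(np.abs(grad[:, i] - fd) <= 1e-5 * (1 + np.abs(fd)))


# ---------------------------------------------------------------------------
# hopping landscape
# ---------------------------------------------------------------------------

class TestHoppingLandscape:
    def test_default_minima_match_spec(self, hopping):
        spec = hopping.spec
        for name, center in spec.centers.items():
            loc = hopping.basin_minima[name]
            assert np.abs(loc - np.asarray(center)).max() < 0.1
        e_aa = hopping.basin_energies["Aa"]
        assert hopping.basin_energies["Ab"] - e_aa == pytest.approx(0.9,
                                                                    abs=0.05)
        assert hopping.basin_energies["B"] - e_aa == pytest.approx(1.4,
                                                                   abs=0.05)

    def test_saddle_by_flood_fill_oracle(self, hopping):
        """Flood-fill threshold search on a 500x500 grid locates the Ab->Aa
        saddle 1.5 kcal/mol above the Ab minimum."""
        n = 500
        xs = np.linspace(0, 12, n)
        ys = np.linspace(0, 12, n)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        energy = hopping.energy(np.stack([xx, yy], axis=-1))
        idx = {}
        for name in ("Aa", "Ab"):
            c = hopping.basin_minima[name]
            idx[name] = (int(np.abs(xs - c[0]).argmin()),
                         int(np.abs(ys - c[1]).argmin()))
        saddle = grid_saddle_energy(energy, idx["Aa"], idx["Ab"])
        assert saddle - hopping.basin_energies["Ab"] == pytest.approx(
            1.5, abs=0.1)

    def test_degenerate_offsets_give_equal_probabilities(self):
        """Three identical wells at the vertices of a wide equilateral
        triangle carry equal Boltzmann mass."""
        side = 8.0
        centers = {"Aa": (5.0, 5.0), "Ab": (5.0, 5.0 + side),
                   "B": (5.0 + side * math.sqrt(3) / 2, 5.0 + side / 2)}
        spec = HoppingLandscapeSpec(centers=centers,
                                    offsets={"Ab": 0.0, "B": 0.0},
                                    barrier_ab_aa=4.0,
                                    domain=((0.0, 18.0), (0.0, 18.0)))
        pot = gq.make_hopping_landscape(spec)
        masses = []
        for c in centers.values():
            q = gq.boltzmann_quadrature(
                pot, KT300, [(c[0] - 2.5, c[0] + 2.5),
                             (c[1] - 2.5, c[1] + 2.5)], n=401)
            masses.append(q.mass)
        masses = np.asarray(masses)
        assert (masses.max() - masses.min()) / masses.mean() < 1e-6

    def test_overlapping_centers_rejected(self):
        spec = HoppingLandscapeSpec(centers={"Aa": (4.0, 4.0),
                                             "Ab": (4.0, 5.5),
                                             "B": (9.0, 6.0)})
        with pytest.raises(ParameterError, match="overlap"):
            gq.make_hopping_landscape(spec)

    def test_negative_offset_rejected(self):
        spec = HoppingLandscapeSpec(offsets={"Ab": -0.5, "B": 1.4})
        with pytest.raises(ParameterError):
            gq.make_hopping_landscape(spec)


# ---------------------------------------------------------------------------
# toy quadruplex and rigid ligand
# ---------------------------------------------------------------------------

class TestToyQuadruplex:
    def test_bead_count_and_symmetry(self, quadruplex):
        assert quadruplex.n_beads == 24
        rotated = quadruplex.symmetry_rotation(quadruplex.coords)
        # the rotation permutes strands; compare as unsorted point sets
        # per z-layer and mass class
        for coords in (quadruplex.coords,):
            d = np.linalg.norm(rotated[:, None, :] - coords[None, :, :],
                               axis=-1)
            match = d.min(axis=1)
            assert match.max() < 1e-8

    def test_center_of_mass_at_origin(self):
        for bps in (2, 5, 9):
            q = gq.build_toy_quadruplex(bps, 3.4, 8.0)
            assert np.abs(q.center_of_mass()).max() < 1e-10
            assert q.n_beads == 4 * bps

    def test_oblate_structure_still_builds(self):
        q = gq.build_toy_quadruplex(2, 3.4, 8.0)
        assert q.n_beads == 8
        # with two beads per strand the cross-section dominates: the two
        # smallest inertia eigenvalues are the degenerate in-plane pair, so
        # the axis contract refuses to pick one (checked in the CV tests)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            gq.build_toy_quadruplex(1, 3.4, 8.0)
        with pytest.raises(ParameterError):
            gq.build_toy_quadruplex(6, -1.0, 8.0)

    def test_terminal_beads_break_end_swap_symmetry(self, quadruplex):
        m5 = quadruplex.masses[quadruplex.indices("end5")]
        m3 = quadruplex.masses[quadruplex.indices("end3")]
        assert np.all(m5 != m3)


class TestRigidLigand:
    def test_bond_length_invariant_under_pose_changes(self, rng):
        lig = gq.RigidLigand(bond_length=4.0)
        for _ in range(20):
            moved = lig.placed(rng.normal(size=3), theta=rng.uniform(0, np.pi),
                               phi=rng.uniform(-np.pi, np.pi))
            c = moved.coords()
            assert np.linalg.norm(c[1] - c[0]) == pytest.approx(4.0,
                                                                abs=1e-12)


# ---------------------------------------------------------------------------
# Langevin sampler
# ---------------------------------------------------------------------------

def harmonic(k=2.0):
    return FunctionPotential(
        ["x"], ["A"], [(-4.0, 4.0)],
        lambda p: 0.5 * k * p[..., 0] ** 2,
        lambda p: k * p)


class TestLangevin:
    def test_harmonic_variance_matches_equipartition(self):
        pot = harmonic(2.0)
        params = gq.LangevinParams(n_steps=200_000, seed=7)
        traj = gq.langevin_run(pot, params, start=[0.0], record_stride=1)
        x = traj.coords[:, 0]
        block_vars = np.array([b.var() for b in np.array_split(x, 20)])
        se = block_vars.std(ddof=1) / math.sqrt(len(block_vars))
        assert abs(x.var() - KT300 / 2.0) < 3 * se

    def test_zero_temperature_stays_at_minimum(self):
        pot = harmonic(2.0)
        params = gq.LangevinParams(temperature=1e-12, n_steps=20_000, seed=0)
        traj = gq.langevin_run(pot, params, start=[0.0], record_stride=10)
        assert np.abs(traj.coords).max() < 1e-6

    def test_same_seed_reproduces_cv_series(self):
        pot = gq.make_double_well(6.0, 4.0, 0.9)
        params = gq.LangevinParams(n_steps=5_000, seed=42)
        t1 = gq.langevin_run(pot, params, start=[-2.0])
        t2 = gq.langevin_run(pot, params, start=[-2.0])
        assert np.array_equal(t1.cvs["d"], t2.cvs["d"])

    def test_histogram_converges_to_boltzmann(self):
        """KS distance to the quadrature CDF decreases with run length."""
        pot = harmonic(2.0)
        xs = np.linspace(-4, 4, 2001)
        w = np.exp(-np.asarray(pot.energy(xs)) / KT300)
        cdf_grid = np.cumsum(w)
        cdf_grid /= cdf_grid[-1]

        def cdf(v):
            return np.interp(v, xs, cdf_grid)

        dists = {n: [] for n in (4_000, 100_000)}
        for seed in (0, 1, 2):
            for n in dists:
                params = gq.LangevinParams(n_steps=n, seed=seed)
                traj = gq.langevin_run(pot, params, start=[0.0],
                                       record_stride=4)
                dists[n].append(ks_1samp(traj.coords[:, 0], cdf).statistic)
        short, long_ = (np.mean(dists[n]) for n in sorted(dists))
        assert long_ < short

    def test_start_outside_domain_rejected(self):
        pot = harmonic()
        with pytest.raises(ParameterError):
            gq.langevin_run(pot, gq.LangevinParams(n_steps=10, seed=0),
                            start=[9.0])


# ---------------------------------------------------------------------------
# Boltzmann quadrature oracle
# ---------------------------------------------------------------------------

class TestBoltzmannQuadrature:
    def test_harmonic_partition_closed_form(self):
        k = 2.0
        q = gq.boltzmann_quadrature(harmonic(k), KT300)
        assert q.mass == pytest.approx(math.sqrt(2 * math.pi * KT300 / k),
                                       rel=1e-6)

    def test_symmetric_double_well_halves_equal(self):
        pot = gq.make_double_well(6.0, 4.0, 0.0)
        lo, hi = pot.bounds[0]
        left = gq.boltzmann_quadrature(pot, KT300, [(lo, 0.0)])
        right = gq.boltzmann_quadrature(pot, KT300, [(0.0, hi)])
        assert left.mass == pytest.approx(right.mass, abs=1e-10 * left.mass)

    def test_asymmetric_gap_recovered(self, double_well_asym):
        pot = double_well_asym
        lo, hi = pot.bounds[0]
        left = gq.boltzmann_quadrature(pot, KT300, [(lo, 0.0)])
        right = gq.boltzmann_quadrature(pot, KT300, [(0.0, hi)])
        gap = right.free_energy - left.free_energy
        assert gap == pytest.approx(0.9, abs=0.02)
        # doubling the resolution leaves the result unchanged to 1e-6
        left2 = gq.boltzmann_quadrature(pot, KT300, [(lo, 0.0)], n=8193)
        assert left2.mass == pytest.approx(left.mass, rel=1e-6)

    def test_empty_region_rejected(self):
        with pytest.raises(ParameterError):
            gq.boltzmann_quadrature(harmonic(), KT300, [(2.0, 2.0)])
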