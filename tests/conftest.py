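import numpy as np
import pytest

from gqmetad import (AtomGroup, RigidLigand, build_toy_quadruplex,
                     make_double_well, make_hopping_landscape)


@pytest.fixture(scope="session")
def quadruplex():
    return build_toy_quadruplex(6, 3.4, 8.0)


@pytest.fixture(scope="session")
def hopping():
    """Default three-basin landscape (offsets 0.9/1.4, barrier 1.5)."""
    return make_hopping_landscape()


@pytest.fixture(scope="session")
def double_well_asym():
    return make_double_well(6.0, 4.0, 0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dw_metad_runs(double_well_asym):
    """Three independent well-tempered runs on the asymmetric double well.

    Production-style settings: w0 = 0.5 kcal/mol, pace 1 ps, width 0.23 Å,
    T = 300 K, ΔT = 2700 K, 5e5 overdamped steps of 0.01 ps.
    """
    import gqmetad as gq

    wt = gq.WellTemperedParams(widths=(0.23,))
    runs = []
    for seed in (1, 2, 3):
        lp = gq.LangevinParams(n_steps=500_000, seed=seed)
        runs.append(gq.run_metadynamics(double_well_asym, lp, wt,
                                        lp.n_steps, start=[-2.0]))
    return runs


def quad_group(quad):
    return AtomGroup(np.arange(quad.n_beads), quad.masses, "quadruplex")


def quad_orientation(quad):
    """5'-end bead -> 3'-end bead of strand A (axis points to the 3' side)."""
    return int(quad.indices("end5")[0]), int(quad.indices("end3")[0])


def with_ligand(quad, ligand: RigidLigand):
    """Stack quadruplex and ligand coordinates; return (coords, groups)."""
    coords = np.vstack([quad.coords, ligand.coords()])
    n = quad.n_beads
    groups = {
        "quadruplex": quad_group(quad),
        "scaffold": AtomGroup([n], [ligand.scaffold_mass], "scaffold"),
        "tail": AtomGroup([n + 1], [ligand.tail_mass], "tail"),
        "ligand": AtomGroup([n, n + 1], ligand.masses, "ligand"),
    }
    return coords, groups
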