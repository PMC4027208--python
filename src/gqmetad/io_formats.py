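"""Text file dialects: COLVAR, HILLS, FES grids and PDB structures.

The COLVAR and HILLS dialects follow the PLUMED convention of a
``#! FIELDS ...`` header followed by whitespace-separated numeric rows, so
practitioners' existing tooling can read them; they are documented
field-by-field here rather than guaranteed compatible with any specific
PLUMED version.  Numbers are written with the shortest representation that
round-trips exactly, so a write/read/write cycle is byte-stable and
reconstructing a bias from its HILLS file reproduces the bias energy to
machine precision.

Additional ``#`` comment lines carry provenance (generating subcommand and
configuration digest); parsers ignore them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .grids import FESGrid
from .metadynamics import BiasState, Hill
from .toy_systems import RigidLigand, ToyQuadruplex

__all__ = [
    "ColvarData",
    "ParseError",
    "read_colvar",
    "read_fes",
    "read_hills",
    "read_pdb",
    "write_colvar",
    "write_fes",
    "write_hills",
    "write_pdb",
]


class ParseError(ValueError):
    """Malformed dialect file; the message names the offending line."""


def _fmt(v: float) -> str:
    return repr(float(v))


def _meta_lines(meta: Mapping[str, str] | None) -> list[str]:
    if not meta:
        return []
    return [f"# {k}: {v}" for k, v in meta.items()]


# ---------------------------------------------------------------------------
# COLVAR
# ---------------------------------------------------------------------------

@dataclass
class ColvarData:
    """Parsed COLVAR file: CV time series plus the instantaneous bias."""

    times: np.ndarray
    cvs: dict[str, np.ndarray]
    bias: np.ndarray
    periodic: dict[str, bool] = field(default_factory=dict)


def write_colvar(path, times, cvs: Mapping[str, Sequence[float]],
                 bias=None, periodic: Mapping[str, bool] | None = None,
                 meta: Mapping[str, str] | None = None) -> None:
    """Write a COLVAR file: ``#! FIELDS time <cv...> bias`` then one row
    per frame.  Periodicity is declared per CV in ``#! SET`` lines."""
    times = np.asarray(times, dtype=float)
    labels = list(cvs)
    series = [np.asarray(cvs[lb], dtype=float) for lb in labels]
    bias = np.zeros(len(times)) if bias is None \
        else np.asarray(bias, dtype=float)
    periodic = periodic or {}
    lines = ["#! FIELDS time " + " ".join(labels) + " bias"]
    for lb in labels:
        lines.append(f"#! SET periodic_{lb} "
                     f"{'true' if periodic.get(lb, False) else 'false'}")
    lines += _meta_lines(meta)
    for i, t in enumerate(times):
        row = [_fmt(t)] + [_fmt(s[i]) for s in series] + [_fmt(bias[i])]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar(path) -> ColvarData:
    labels, periodic = None, {}
    rows = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line.split()
            if len(parts) >= 2 and parts[1] == "FIELDS":
                if parts[2] != "time" or parts[-1] != "bias":
                    raise ParseError(f"{path}:{ln}: FIELDS must start with "
                                     "'time' and end with 'bias'")
                labels = parts[3:-1]
            elif len(parts) == 4 and parts[1] == "SET" \
                    and parts[2].startswith("periodic_"):
                periodic[parts[2][len("periodic_"):]] = parts[3] == "true"
            else:
                raise ParseError(f"{path}:{ln}: malformed header line")
            continue
        if line.startswith("#"):
            continue
        if labels is None:
            raise ParseError(f"{path}:{ln}: data before FIELDS header")
        vals = line.split()
        if len(vals) != len(labels) + 2:
            raise ParseError(f"{path}:{ln}: expected {len(labels) + 2} "
                             f"columns, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from None
    if labels is None:
        raise ParseError(f"{path}: missing FIELDS header")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(labels) + 2)
    times = data[:, 0]
    if np.any(np.diff(times) < 0):
        bad = int(np.argmax(np.diff(times) < 0)) + 2
        raise ParseError(f"{path}: times not non-decreasing at data row {bad}")
    cvs = {lb: data[:, 1 + i] for i, lb in enumerate(labels)}
    return ColvarData(times, cvs, data[:, -1], periodic)


# ---------------------------------------------------------------------------
# HILLS
# ---------------------------------------------------------------------------

def write_hills(path, bias: BiasState, bias_factor: float,
                meta: Mapping[str, str] | None = None) -> None:
    """Write the deposited hills: one line per hill with time, centers,
    widths, height and the well-tempered bias factor; the header records
    CV labels, periodicity and the grid so the bias is reconstructible."""
    labels = list(bias.cv_labels)
    fields = ["time"] + [f"center_{lb}" for lb in labels] \
        + [f"sigma_{lb}" for lb in labels] + ["height", "biasf"]
    lines = ["#! FIELDS " + " ".join(fields)]
    for i, lb in enumerate(labels):
        lines.append(f"#! SET periodic_{lb} "
                     f"{'true' if bias.periodic[i] else 'false'}")
        ax = bias.axes[i]
        lines.append(f"#! SET grid_min_{lb} {_fmt(ax[0])}")
        lines.append(f"#! SET grid_max_{lb} {_fmt(ax[-1])}")
        lines.append(f"#! SET grid_n_{lb} {len(ax)}")
    lines += _meta_lines(meta)
    for h in bias.hills:
        row = [_fmt(h.time)] + [_fmt(c) for c in h.center] \
            + [_fmt(w) for w in h.width] + [_fmt(h.height),
                                            _fmt(bias_factor)]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path) -> tuple[BiasState, float]:
    """Parse a HILLS file; returns the reconstructed bias (hills replayed
    onto the stored grid) and the bias factor."""
    labels = None
    periodic: dict[str, bool] = {}
    gmin: dict[str, float] = {}
    gmax: dict[str, float] = {}
    gn: dict[str, int] = {}
    hill_rows = []
    bias_factor = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line.split()
            if parts[1] == "FIELDS":
                if parts[2] != "time" or parts[-2] != "height" \
                        or parts[-1] != "biasf":
                    raise ParseError(f"{path}:{ln}: unexpected HILLS fields")
                centers = [p[len("center_"):] for p in parts[3:]
                           if p.startswith("center_")]
                labels = centers
            elif parts[1] == "SET":
                key, val = parts[2], parts[3]
                if key.startswith("periodic_"):
                    periodic[key[9:]] = val == "true"
                elif key.startswith("grid_min_"):
                    gmin[key[9:]] = float(val)
                elif key.startswith("grid_max_"):
                    gmax[key[9:]] = float(val)
                elif key.startswith("grid_n_"):
                    gn[key[7:]] = int(val)
                else:
                    raise ParseError(f"{path}:{ln}: unknown SET key {key!r}")
            else:
                raise ParseError(f"{path}:{ln}: malformed header line")
            continue
        if line.startswith("#"):
            continue
        if labels is None:
            raise ParseError(f"{path}:{ln}: data before FIELDS header")
        vals = line.split()
        if len(vals) != 2 * len(labels) + 3:
            raise ParseError(f"{path}:{ln}: truncated or malformed hill "
                             f"line (expected {2 * len(labels) + 3} "
                             f"columns, got {len(vals)})")
        try:
            hill_rows.append([float(v) for v in vals])
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric hill entry") from None
    if labels is None:
        raise ParseError(f"{path}: missing FIELDS header")
    for lb in labels:
        if lb not in gmin or lb not in gmax or lb not in gn:
            raise ParseError(f"{path}: missing grid specification for "
                             f"CV {lb!r}")
    bias = BiasState(labels, [(gmin[lb], gmax[lb], gn[lb]) for lb in labels],
                     [periodic.get(lb, False) for lb in labels])
    d = len(labels)
    for row in hill_rows:
        bias.add_hill(Hill(row[0], tuple(row[1:1 + d]),
                           tuple(row[1 + d:1 + 2 * d]), row[1 + 2 * d]))
        bias_factor = row[2 + 2 * d]
    return bias, (bias_factor if bias_factor is not None else float("nan"))


# ---------------------------------------------------------------------------
# FES grid files
# ---------------------------------------------------------------------------

def write_fes(path, fes: FESGrid, meta: Mapping[str, str] | None = None
              ) -> None:
    """One row per bin: bin centers, F (nan on unvisited bins), occupancy
    count and a visited flag; the header stores labels, units and the
    uniform bin edges."""
    labels = list(fes.cv_labels)
    fields = labels + ["free_energy", "count", "visited"]
    lines = ["#! FIELDS " + " ".join(fields),
             f"#! SET temperature {_fmt(fes.temperature)}"]
    for i, lb in enumerate(labels):
        e = fes.edges[i]
        lines.append(f"#! SET unit_{lb} {fes.units[i]}")
        lines.append(f"#! SET periodic_{lb} "
                     f"{'true' if fes.periodic[i] else 'false'}")
        lines.append(f"#! SET edges_{lb} {_fmt(e[0])} {_fmt(e[-1])} "
                     f"{len(e) - 1}")
    lines += _meta_lines(meta)
    counts = fes.counts if fes.counts is not None \
        else np.zeros(fes.shape)
    centers = [fes.centers(i) for i in range(fes.ndim)]
    for idx in np.ndindex(fes.shape):
        row = [_fmt(centers[i][idx[i]]) for i in range(fes.ndim)]
        row += [_fmt(fes.values[idx]), _fmt(counts[idx]),
                "1" if fes.visited[idx] else "0"]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fes(path) -> FESGrid:
    labels = None
    units: dict[str, str] = {}
    periodic: dict[str, bool] = {}
    edges_spec: dict[str, tuple[float, float, int]] = {}
    temperature = 300.0
    rows = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            parts = line.split()
            if parts[1] == "FIELDS":
                labels = parts[2:-3]
            elif parts[1] == "SET":
                key = parts[2]
                if key == "temperature":
                    temperature = float(parts[3])
                elif key.startswith("unit_"):
                    units[key[5:]] = parts[3]
                elif key.startswith("periodic_"):
                    periodic[key[9:]] = parts[3] == "true"
                elif key.startswith("edges_"):
                    edges_spec[key[6:]] = (float(parts[3]), float(parts[4]),
                                           int(parts[5]))
                else:
                    raise ParseError(f"{path}:{ln}: unknown SET key {key!r}")
            continue
        if line.startswith("#"):
            continue
        if labels is None:
            raise ParseError(f"{path}:{ln}: data before FIELDS header")
        vals = line.split()
        if len(vals) != len(labels) + 3:
            raise ParseError(f"{path}:{ln}: wrong column count")
        rows.append([float(v) for v in vals])
    if labels is None or not rows:
        raise ParseError(f"{path}: missing header or data")
    edges = tuple(np.linspace(*edges_spec[lb][:2], edges_spec[lb][2] + 1)
                  for lb in labels)
    shape = tuple(len(e) - 1 for e in edges)
    data = np.asarray(rows)
    if len(data) != int(np.prod(shape)):
        raise ParseError(f"{path}: row count does not match the grid shape")
    nd = len(labels)
    values = data[:, nd].reshape(shape)
    counts = data[:, nd + 1].reshape(shape)
    visited = data[:, nd + 2].reshape(shape).astype(bool)
    return FESGrid(tuple(labels), tuple(units[lb] for lb in labels), edges,
                   values, visited, temperature, counts=counts,
                   periodic=tuple(periodic.get(lb, False) for lb in labels))


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

_RESNAME_BY_LABEL = {"end5": "E5D", "core": "COR", "end3": "E3D"}
_LABEL_BY_RESNAME = {v: k for k, v in _RESNAME_BY_LABEL.items()}
_LIGAND_RESNAMES = ("SCF", "TAL")


def write_pdb(path, quadruplex: ToyQuadruplex,
              ligand: RigidLigand | None = None) -> None:
    """Write the bead model as a PDB: beads as CA atoms, one residue per
    bead, strands as chains A-D and the ligand (scaffold then tail bead)
    as chain L."""
    import MDAnalysis as mda

    n_quad = quadruplex.n_beads
    n = n_quad + (2 if ligand is not None else 0)
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("name", ["CA"] * n)
    resnames = [_RESNAME_BY_LABEL[lb] for lb in quadruplex.bead_labels]
    chains = list(quadruplex.strand_ids)
    coords = [quadruplex.coords]
    if ligand is not None:
        resnames += list(_LIGAND_RESNAMES)
        chains += ["L", "L"]
        coords.append(ligand.coords())
    u.add_TopologyAttr("resname", resnames)
    u.add_TopologyAttr("resid", np.arange(1, n + 1))
    u.add_TopologyAttr("chainID", chains)
    u.add_TopologyAttr("element", ["C"] * n)
    u.atoms.positions = np.vstack(coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_pdb(path, bond_length: float | None = None
             ) -> tuple[ToyQuadruplex, RigidLigand | None]:
    """Read a bead-model PDB back into structures.

    Masses are not stored in PDB files; they are restored from the bead
    labels using the builder defaults, which is sufficient because the
    round-trip contract covers coordinates (to PDB precision) and labels.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    chains = u.atoms.chainIDs
    resnames = u.atoms.resnames
    pos = u.atoms.positions.astype(float)
    quad_sel = chains != "L"
    labels = [_LABEL_BY_RESNAME[rn] for rn in resnames[quad_sel]]
    default_mass = {"end5": 104.0, "core": 100.0, "end3": 112.0}
    masses = np.array([default_mass[lb] for lb in labels])
    quad = ToyQuadruplex(pos[quad_sel], masses, labels,
                         [str(c) for c in chains[quad_sel]])
    ligand = None
    lig_sel = chains == "L"
    if np.any(lig_sel):
        lp = pos[lig_sel]
        if len(lp) != 2:
            raise ParseError(f"{path}: ligand chain L must have two beads")
        vec = lp[1] - lp[0]
        r = float(np.linalg.norm(vec))
        ligand = RigidLigand(bond_length=bond_length or r,
                             position=lp[0],
                             theta=float(np.arccos(np.clip(vec[2] / r, -1, 1))),
                             phi=float(np.arctan2(vec[1], vec[0])))
    return quad, ligand
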