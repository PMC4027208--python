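"""Reading free-energy surfaces: basins, barriers and binding free energy.

These are the operations that turn a gridded FES into the headline numbers
of a binding study: the local minima and their watershed basins, basin
free-energy differences (read min-to-min, as one reads depths off a
contour plot, or basin-integrated for thermodynamic consistency), the
lowest saddle between two basins, the bound/unbound binding free energy
with the standard region definitions (bound 7.0 <= d <= 14.0 Å, unbound
24 < d < 26 Å), and the convergence of that estimate over simulation time
together with the bound/unbound recrossing count that a trustworthy
estimate requires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import FESGrid, grid_saddle_energy
from .metadynamics import BiasState
from .reweighting import WeightSeries
from .toy_systems import ParameterError, Trajectory
from .units import kT as _kT

__all__ = [
    "Basin",
    "BindingFreeEnergy",
    "BindingRegions",
    "barrier_height",
    "basin_delta_g",
    "binding_delta_g",
    "convergence_profile",
    "count_recrossings",
    "delta_g_uncertainty",
    "find_minima",
]

log = logging.getLogger(__name__)


@dataclass
class Basin:
    """A local FES minimum and the grid cells draining to it."""

    label: str
    min_index: tuple[int, ...]
    min_location: tuple[float, ...]
    min_value: float              # kcal/mol, on the anchored surface
    members: np.ndarray           # boolean mask over the grid
    probability: float            # basin-integrated Boltzmann probability


@dataclass
class BindingRegions:
    """Bound and unbound ranges on the COM-distance CV d, in Å."""

    bound: tuple[float, float] = (7.0, 14.0)
    unbound: tuple[float, float] = (24.0, 26.0)

    def __post_init__(self):
        b0, b1 = self.bound
        u0, u1 = self.unbound
        if not (b0 < b1 and u0 < u1):
            raise ParameterError("regions must have positive width")
        if b1 >= u0:
            raise ParameterError("bound region must lie entirely below the "
                                 "unbound region")


@dataclass
class BindingFreeEnergy:
    delta_g: float                # kcal/mol
    uncertainty: float            # kcal/mol, >= 0
    mode: str                     # "integral" | "minimum"
    regions: BindingRegions = field(default_factory=BindingRegions)

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


# ---------------------------------------------------------------------------
# basins
# ---------------------------------------------------------------------------

def _neighbor_offsets(ndim: int):
    if ndim == 1:
        return [(-1,), (1,)]
    return [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)
            if (i, j) != (0, 0)]


def find_minima(fes: FESGrid, depth_cutoff: float = 3.0) -> list[Basin]:
    """Local minima with F <= cutoff, each seeding a watershed basin.

    A minimum is a visited bin strictly lower than every visited neighbor
    (full connectivity).  Visited bins are assigned to basins by flooding
    in order of increasing F; ties break lexicographically on the bin
    index, so the segmentation is deterministic.  Minima above the cutoff
    still seed (their cells are not returned), keeping the watershed of
    the reported basins well defined.
    """
    g = fes.anchored()
    vals = g.values
    visited = g.visited
    ndim = g.ndim
    shape = vals.shape
    offs = _neighbor_offsets(ndim)

    def neighbors(idx):
        for off in offs:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= i < s for i, s in zip(nb, shape)) and visited[nb]:
                yield nb

    order = sorted((tuple(int(i) for i in idx)
                    for idx in np.argwhere(visited)),
                   key=lambda idx: (vals[idx], idx))
    seeds = [idx for idx in order
             if all(vals[idx] < vals[nb] for nb in neighbors(idx))]
    if not any(vals[s] <= depth_cutoff for s in seeds):
        warnings.warn("no minima under the depth cutoff", stacklevel=2)

    assignment: dict[tuple[int, ...], int] = {}
    for rank, s in enumerate(seeds):
        assignment[s] = rank
    for idx in order:
        if idx in assignment:
            continue
        assigned = [nb for nb in neighbors(idx) if nb in assignment]
        if assigned:
            best = min(assigned, key=lambda nb: (vals[nb], nb))
            assignment[idx] = assignment[best]
        # an isolated plateau cell with no assigned neighbor stays
        # unassigned; it belongs to no basin

    probs = g.probabilities()
    basins = []
    kept = [s for s in seeds if vals[s] <= depth_cutoff]
    for n, s in enumerate(kept):
        rank = assignment[s]
        mask = np.zeros(shape, dtype=bool)
        for idx, r in assignment.items():
            if r == rank:
                mask[idx] = True
        loc = tuple(float(g.centers(ax)[s[ax]]) for ax in range(ndim))
        basins.append(Basin(f"M{n}", s, loc, float(vals[s]), mask,
                            float(probs[mask].sum())))
    return basins


def basin_delta_g(fes: FESGrid, a: Basin, b: Basin,
                  mode: str = "minimum") -> float:
    """Free-energy difference of basin b relative to basin a, kcal/mol.

    ``minimum`` reads F_min(b) - F_min(a) (how depths are read off a
    plotted FES); ``integral`` uses -kT ln(P_a / P_b) from basin-summed
    probabilities and is invariant under uniform FES shifts.
    """
    if mode == "minimum":
        g = fes.anchored()
        return float(g.values[b.min_index] - g.values[a.min_index])
    if mode == "integral":
        if a.probability <= 0 or b.probability <= 0:
            raise ParameterError("integral mode requires visited, "
                                 "non-empty basins")
        return float(-_kT(fes.temperature)
                     * np.log(a.probability / b.probability))
    raise ParameterError(f"unknown basin ΔG mode {mode!r}")


def barrier_height(fes: FESGrid, a: Basin, b: Basin) -> float:
    """Lowest-saddle barrier between two basins, relative to the higher
    minimum, by threshold flood-fill bisection on the visited grid."""
    g = fes.anchored()
    if a.min_index == b.min_index:
        return 0.0
    try:
        saddle = grid_saddle_energy(g.values, a.min_index, b.min_index,
                                    mask=g.visited)
    except ValueError as exc:
        raise ParameterError(
            f"basins {a.label} and {b.label} are not connected through "
            f"visited bins: {exc}") from exc
    return float(saddle - max(g.values[a.min_index], g.values[b.min_index]))


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------

def _region_mask(fes: FESGrid, lo: float, hi: float, name: str,
                 require_visited: bool = True) -> np.ndarray:
    centers = fes.centers(0)
    mask = (centers >= lo) & (centers <= hi)
    if require_visited:
        mask &= fes.visited
    if not np.any(mask):
        raise ParameterError(f"{name} region [{lo}, {hi}] overlaps no "
                             "visited bins")
    return mask


def binding_delta_g(fes_1d: FESGrid, regions: BindingRegions | None = None,
                    mode: str = "integral",
                    standard_state_width: float | None = None
                    ) -> BindingFreeEnergy:
    """Binding free energy ΔG = G(bound) - G(unbound) from a 1D FES on d.

    Integral mode (default): ΔG = -kT ln( Σ_bound e^{-F/kT} Δd /
    Σ_unbound e^{-F/kT} Δd ); minimum mode: F_min(bound) -
    F_min(unbound).  No standard-state volume correction is applied unless
    ``standard_state_width`` is given, in which case -kT ln(w_unbound / w0)
    is added.
    """
    if fes_1d.ndim != 1:
        raise ParameterError("binding ΔG requires a 1D FES on the distance d")
    regions = regions or BindingRegions()
    kt = _kT(fes_1d.temperature)
    bmask = _region_mask(fes_1d, *regions.bound, "bound")
    umask = _region_mask(fes_1d, *regions.unbound, "unbound")
    widths = fes_1d.bin_widths(0)
    vals = fes_1d.values
    if mode == "integral":
        wb = np.sum(np.exp(-vals[bmask] / kt) * widths[bmask])
        wu = np.sum(np.exp(-vals[umask] / kt) * widths[umask])
        dg = -kt * np.log(wb / wu)
    elif mode == "minimum":
        dg = float(vals[bmask].min() - vals[umask].min())
    else:
        raise ParameterError(f"unknown binding ΔG mode {mode!r}")
    if standard_state_width is not None:
        w_u = widths[umask].sum()
        dg += -kt * np.log(w_u / standard_state_width)
    return BindingFreeEnergy(float(dg), 0.0, mode, regions)


def count_recrossings(d_series: np.ndarray,
                      regions: BindingRegions | None = None) -> int:
    """Number of bound<->unbound transitions along a d time series.

    A transition is counted each time the most recently visited region
    switches; frames outside both regions are ignored.
    """
    regions = regions or BindingRegions()
    d = np.asarray(d_series, dtype=float)
    state = np.zeros(len(d), dtype=int)
    state[(d >= regions.bound[0]) & (d <= regions.bound[1])] = 1
    state[(d >= regions.unbound[0]) & (d <= regions.unbound[1])] = 2
    seq = state[state != 0]
    if len(seq) < 2:
        return 0
    return int(np.count_nonzero(np.diff(seq) != 0))


def convergence_profile(bias: BiasState, regions: BindingRegions,
                        temperature: float, delta_T: float,
                        checkpoints: Sequence[float] | None = None,
                        traj: Trajectory | None = None, d_label: str = "d",
                        ) -> tuple[np.ndarray, np.ndarray, int | None]:
    """ΔG(bound, unbound) as a function of simulation time.

    Replays the hills history, evaluating the binding free energy from the
    instantaneous well-tempered FES at each checkpoint (default: 200
    checkpoints spanning the deposition history).  Also reports the number
    of bound/unbound recrossings when a trajectory is supplied — repeated
    recrossings are what make the final estimate trustworthy.  Regions
    never visited leave the profile defined (from the bias grid) with a
    recrossing count of 0.
    """
    if bias.ndim != 1:
        raise ParameterError("convergence profile requires a 1D bias on d")
    if not bias.hills:
        raise ParameterError("no hills deposited")
    hills = sorted(bias.hills, key=lambda h: h.time)
    if checkpoints is None:
        t_end = hills[-1].time
        checkpoints = np.linspace(hills[0].time, t_end,
                                  min(200, len(hills)))
    checkpoints = np.asarray(sorted(checkpoints))
    if len(checkpoints) < 2:
        raise ParameterError("need at least two checkpoints")
    gamma_ratio = (temperature + delta_T) / delta_T
    kt = _kT(temperature)
    centers = bias.axes[0]
    bmask = (centers >= regions.bound[0]) & (centers <= regions.bound[1])
    umask = (centers >= regions.unbound[0]) & (centers <= regions.unbound[1])
    if not np.any(bmask) or not np.any(umask):
        raise ParameterError("bias grid does not cover the bound/unbound "
                             "regions")
    from .metadynamics import BiasState as _BS
    scratch = _BS(bias.cv_labels, [(centers[0], centers[-1], len(centers))],
                  bias.periodic)
    dg = np.empty(len(checkpoints))
    ih = 0
    for k, t in enumerate(checkpoints):
        while ih < len(hills) and hills[ih].time <= t + 1e-12:
            scratch.add_hill(hills[ih])
            ih += 1
        f = -gamma_ratio * scratch.grid_v
        f = f - f.min()
        wb = np.exp(-f[bmask] / kt).sum()
        wu = np.exp(-f[umask] / kt).sum()
        # uniform node spacing: widths cancel up to the region-width ratio
        h = centers[1] - centers[0]
        dg[k] = -kt * np.log((wb * h) / (wu * h))
    n_recross = None
    if traj is not None:
        n_recross = count_recrossings(traj.cvs[d_label], regions)
    return checkpoints, dg, n_recross


def delta_g_uncertainty(traj: Trajectory, weights: WeightSeries,
                        regions: BindingRegions | None = None,
                        n_blocks: int = 4, d_label: str = "d",
                        temperature: float = 300.0) -> float:
    """Block standard error of the binding ΔG.

    The trajectory is split into ``n_blocks`` contiguous blocks, each
    reweighted independently; the reported uncertainty is the standard
    error of the per-block ΔG values.  Blocks in which either region is
    unvisited are skipped (logged).
    """
    if n_blocks < 2:
        raise ParameterError("need at least two blocks")
    regions = regions or BindingRegions()
    kt = _kT(temperature)
    d = np.asarray(traj.cvs[d_label], dtype=float)
    w = weights.weights
    edges = np.linspace(0, len(d), n_blocks + 1).astype(int)
    values = []
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        db, wb_ = d[sl], w[sl]
        in_b = (db >= regions.bound[0]) & (db <= regions.bound[1])
        in_u = (db >= regions.unbound[0]) & (db <= regions.unbound[1])
        pb, pu = wb_[in_b].sum(), wb_[in_u].sum()
        if pb <= 0 or pu <= 0:
            log.info("block %d skipped: empty %s region", b,
                     "bound" if pb <= 0 else "unbound")
            continue
        values.append(-kt * np.log(pb / pu))
    if len(values) < 2:
        raise ParameterError("fewer than two usable blocks")
    values = np.asarray(values)
    return float(values.std(ddof=1) / np.sqrt(len(values)))
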