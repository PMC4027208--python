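"""Regular-grid free-energy surfaces and grid numerics shared by several stages.

A :class:`FESGrid` holds a free-energy surface F(s) tabulated on a regular
grid over one or two collective variables.  Bins that were never visited by
the estimator carry an explicit "unvisited" flag (their F value is NaN); the
minimum over visited bins is anchored at zero because only free-energy
differences are physically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .units import kT as _kT

__all__ = ["FESGrid", "grid_saddle_energy"]


@dataclass
class FESGrid:
    """Free-energy surface on a regular grid over 1 or 2 CVs.

    Parameters
    ----------
    cv_labels : labels of the CV axes, in axis order.
    units : unit string per axis ("A" or "rad").
    edges : bin edges per axis; axis i has ``len(edges[i]) - 1`` bins.
    values : free energy per bin, kcal/mol; NaN on unvisited bins.
    visited : boolean mask, True where the bin was visited.
    temperature : simulation temperature in K (used by probability readers).
    counts : optional raw occupancy counts per bin.
    """

    cv_labels: tuple[str, ...]
    units: tuple[str, ...]
    edges: tuple[np.ndarray, ...]
    values: np.ndarray
    visited: np.ndarray
    temperature: float = 300.0
    counts: np.ndarray | None = None
    periodic: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.cv_labels = tuple(self.cv_labels)
        self.units = tuple(self.units)
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        self.values = np.asarray(self.values, dtype=float)
        self.visited = np.asarray(self.visited, dtype=bool)
        if self.periodic is None:
            self.periodic = tuple(False for _ in self.cv_labels)
        else:
            self.periodic = tuple(bool(p) for p in self.periodic)
        shape = tuple(len(e) - 1 for e in self.edges)
        if self.values.shape != shape or self.visited.shape != shape:
            raise ValueError(
                f"grid shape mismatch: edges imply {shape}, values "
                f"{self.values.shape}, visited {self.visited.shape}"
            )
        if not np.any(self.visited):
            raise ValueError("FESGrid has no visited bins")
        if not np.all(np.isfinite(self.values[self.visited])):
            raise ValueError("non-finite free energy on a visited bin")

    # -- geometry -----------------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def bin_widths(self, axis: int) -> np.ndarray:
        return np.diff(self.edges[axis])

    def bin_volume(self) -> np.ndarray:
        """Per-bin volume (length in 1D, area in 2D) broadcast to grid shape."""
        vol = self.bin_widths(0)
        if self.ndim == 2:
            vol = np.multiply.outer(vol, self.bin_widths(1))
        return vol

    # -- transformations ----------------------------------------------------
    def anchored(self) -> "FESGrid":
        """Return a copy shifted so the minimum over visited bins is zero."""
        shift = np.nanmin(self.values[self.visited])
        vals = self.values.copy()
        vals[self.visited] -= shift
        return FESGrid(self.cv_labels, self.units, self.edges, vals,
                       self.visited, self.temperature, self.counts,
                       self.periodic)

    def probabilities(self) -> np.ndarray:
        """Normalised Boltzmann probabilities per bin (zero on unvisited)."""
        kt = _kT(self.temperature)
        p = np.zeros_like(self.values)
        p[self.visited] = np.exp(-self.values[self.visited] / kt)
        p *= self.bin_volume()
        total = p.sum()
        if total <= 0:
            raise ValueError("degenerate FES: zero total probability")
        return p / total

    def marginal(self, axis: int) -> "FESGrid":
        """1D marginal free energy along one axis of a 2D grid."""
        if self.ndim != 2:
            raise ValueError("marginal() requires a 2D grid")
        keep = axis
        drop = 1 - axis
        p = self.probabilities().sum(axis=drop)
        visited = p > 0
        kt = _kT(self.temperature)
        vals = np.full(p.shape, np.nan)
        vals[visited] = -kt * np.log(p[visited] / self.bin_widths(keep)[visited])
        g = FESGrid((self.cv_labels[keep],), (self.units[keep],),
                    (self.edges[keep],), vals, visited, self.temperature,
                    periodic=(self.periodic[keep],))
        return g.anchored()


def grid_saddle_energy(values: np.ndarray, idx_a: Sequence[int],
                       idx_b: Sequence[int],
                       mask: np.ndarray | None = None) -> float:
    """Lowest saddle energy between two grid cells by threshold flood-fill.

    Finds the minimal threshold E* such that the sublevel set {F <= E*}
    (restricted to ``mask``) connects ``idx_a`` to ``idx_b``; E* is the
    energy of the lowest saddle on the best path, to within the discrete
    set of grid values.  Raises ValueError if the cells are never connected.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    idx_a = tuple(int(i) for i in idx_a)
    idx_b = tuple(int(i) for i in idx_b)
    if idx_a == idx_b:
        return float(values[idx_a])
    if not (mask[idx_a] and mask[idx_b]):
        raise ValueError("saddle endpoints lie on unvisited bins")

    finite_vals = np.unique(values[mask])
    lo, hi = 0, len(finite_vals) - 1

    def connected(threshold: float) -> bool:
        sub = mask & (values <= threshold)
        if not (sub[idx_a] and sub[idx_b]):
            return False
        labels, _ = ndimage.label(sub)
        return labels[idx_a] == labels[idx_b]

    if not connected(finite_vals[hi]):
        raise ValueError("grid cells are not connected through visited bins")
    # bisection over the sorted unique energy values
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if connected(finite_vals[mid]):
            hi = mid
        else:
            lo = mid
    if connected(finite_vals[lo]):
        hi = lo
    return float(finite_vals[hi])
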