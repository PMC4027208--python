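"""Reconstructing unbiased Boltzmann statistics from a biased trajectory.

A metadynamics run samples exp(-β(E + V(s,t))) rather than the Boltzmann
distribution.  Because the well-tempered bias converges slowly in time, a
frame at time t can be unbiased with the time-dependent weight

    w(t) ∝ exp( β [ V(s(t), t) - c(t) ] ),

where c(t) is the bias offset

    c(t) = (1/β) ln [ ∫ ds exp(-β F(s,t)) / ∫ ds exp(-β (F(s,t) + V(s,t))) ]

with F(s,t) = -((T+ΔT)/ΔT) V(s,t) the running free-energy estimate.  The
integrals are evaluated by quadrature on the bias grid and c is
interpolated linearly in time between deposition checkpoints.  With the
normalised weights, the free-energy surface can be reconstructed along any
collective variables evaluated on the stored frames — e.g. the
projection-on-axis / distance-from-axis pair, or a tail torsion — without
re-running the biased simulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import FESGrid
from .metadynamics import BiasState, Hill
from .toy_systems import ParameterError, Trajectory
from .units import kT as _kT

__all__ = ["CtSeries", "WeightSeries", "compute_ct", "frame_weights",
           "reweighted_fes"]

log = logging.getLogger(__name__)


@dataclass
class CtSeries:
    """Time-dependent bias offset c(t) at deposition checkpoints."""

    times: np.ndarray             # ps
    values: np.ndarray            # kcal/mol

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("checkpoint times must be non-decreasing")

    def at(self, t) -> np.ndarray:
        """c linearly interpolated at arbitrary times (c = 0 before the
        first checkpoint)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values,
                         left=0.0)


@dataclass
class WeightSeries:
    """Per-frame unbiasing weights, normalised to sum 1."""

    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.times.shape != self.weights.shape:
            raise ValueError("times and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def _fresh_grid_like(bias: BiasState) -> BiasState:
    return BiasState(bias.cv_labels,
                     [(a[0], a[-1], len(a)) for a in bias.axes],
                     bias.periodic)


def compute_ct(bias: BiasState, checkpoints: Sequence[float],
               temperature: float, delta_T: float) -> CtSeries:
    """Evaluate c(t) at the given checkpoint times by grid quadrature.

    The hills history is replayed in time order on a scratch copy of the
    bias grid; at each checkpoint the two Boltzmann integrals are taken
    over the grid (the uniform node spacing cancels in the ratio).  A
    checkpoint before the first hill yields c = 0.
    """
    if temperature <= 0 or delta_T <= 0:
        raise ParameterError("temperature and ΔT must be positive")
    checkpoints = np.asarray(sorted(float(t) for t in checkpoints))
    kt = _kT(temperature)
    gamma_ratio = (temperature + delta_T) / delta_T
    scratch = _fresh_grid_like(bias)
    hills = sorted(bias.hills, key=lambda h: h.time)
    values = np.empty(len(checkpoints))
    ih = 0
    for k, t in enumerate(checkpoints):
        while ih < len(hills) and hills[ih].time <= t + 1e-12:
            scratch.add_hill(hills[ih])
            ih += 1
        v = scratch.grid_v
        f = -gamma_ratio * v
        # log-sum-exp ratio, stable against large accumulated bias
        a = -f / kt
        b = -(f + v) / kt
        ref = max(a.max(), b.max())
        num = np.exp(a - ref).sum()
        den = np.exp(b - ref).sum()
        values[k] = kt * (np.log(num) - np.log(den))
    return CtSeries(checkpoints, values)


def frame_weights(traj: Trajectory, bias: BiasState, ct: CtSeries,
                  temperature: float) -> WeightSeries:
    """Normalised per-frame unbiasing weights exp(β [V(s,t) - c(t)]).

    Uses the instantaneous bias recorded on the trajectory; when absent it
    is recomputed from the hills deposited before each frame time (logged,
    since the recomputation is the slow path).
    """
    kt = _kT(temperature)
    v = np.asarray(traj.bias, dtype=float)
    if v.size and not np.any(np.isfinite(v)):
        v = None
    if v is None or v.size == 0:
        log.warning("trajectory carries no bias record; recomputing from "
                    "the hills history")
        hills = sorted(bias.hills, key=lambda h: h.time)
        htimes = np.array([h.time for h in hills])
        scratch = _fresh_grid_like(bias)
        v = np.empty(len(traj.times))
        order = np.argsort(traj.times)
        ih = 0
        labels = list(bias.cv_labels)
        pts = np.stack([traj.cvs[lb] for lb in labels], axis=-1)
        for idx in order:
            t = traj.times[idx]
            while ih < len(hills) and htimes[ih] <= t + 1e-12:
                scratch.add_hill(hills[ih])
                ih += 1
            v[idx] = scratch.energy(pts[idx], method="direct")
    logw = (v - ct.at(traj.times)) / kt
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    # guard against accumulated rounding in the normalisation
    w /= w.sum()
    return WeightSeries(traj.times.copy(), w)


def reweighted_fes(traj: Trajectory, weights: WeightSeries,
                   cv_labels: Sequence[str], bins,
                   ranges: Sequence[tuple[float, float]] | None = None,
                   temperature: float = 300.0,
                   periodic: Sequence[bool] | None = None) -> FESGrid:
    """Weighted-histogram free-energy surface along new CVs.

    ``cv_labels`` pick per-frame series from the trajectory (evaluated
    during the run or in post-processing).  F = -kT ln(p / binwidth) on
    occupied bins, anchored at zero; empty bins are flagged unvisited, not
    imputed.
    """
    if len(cv_labels) not in (1, 2):
        raise ParameterError("reweighted FES supports 1 or 2 CVs")
    if len(weights.weights) != len(traj.times):
        raise ParameterError("weights do not match trajectory length")
    series = []
    for lb in cv_labels:
        if lb not in traj.cvs:
            raise ParameterError(f"CV {lb!r} not present on the trajectory")
        series.append(np.asarray(traj.cvs[lb], dtype=float))
    sample = np.stack(series, axis=-1)
    hist, edges = np.histogramdd(sample, bins=bins, range=ranges,
                                 weights=weights.weights)
    counts, _ = np.histogramdd(sample, bins=[e for e in edges])
    visited = hist > 0
    if np.count_nonzero(visited) == 1:
        warnings.warn("all weight concentrated in a single bin; the "
                      "reweighted FES is degenerate", stacklevel=2)
    widths = [np.diff(e) for e in edges]
    vol = widths[0] if len(edges) == 1 else np.multiply.outer(*widths)
    kt = _kT(temperature)
    vals = np.full(hist.shape, np.nan)
    vals[visited] = -kt * np.log(hist[visited] / vol[visited])
    units = ["A"] * len(cv_labels)
    if periodic is None:
        periodic = [False] * len(cv_labels)
    for i, p in enumerate(periodic):
        if p:
            units[i] = "rad"
    grid = FESGrid(tuple(cv_labels), tuple(units), tuple(edges), vals,
                   visited, temperature, counts=counts,
                   periodic=tuple(periodic))
    return grid.anchored()
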