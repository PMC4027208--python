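# Methods

`gqmetad` re-creates, at desk scale, the computational chain used to map
the binding of a small ligand to a parallel, 4-fold-symmetric DNA
G-quadruplex: enhanced sampling with well-tempered metadynamics along
geometric collective variables (CVs), reconstruction of the Boltzmann
ensemble by reweighting, and extraction of basins, barriers and the
bound/unbound binding free energy from the resulting free-energy surfaces
(FES).  The explicit-solvent, all-atom system of a real study is replaced
by synthetic landscapes and a bead model whose ground truth is known by
quadrature, so every estimator in the chain is testable against an exact
oracle.

## Model and sampling

**Dynamics.** Sampling is overdamped (Brownian) Euler–Maruyama in the
collective coordinates,

    x(t+dt) = x(t) + dt·F/(mγ) + sqrt(2 k_B T dt/(mγ)) ξ,

with F = −∇(E + V_bias + walls).  This is the simplest scheme with a
provable Boltzmann stationary distribution; inertial dynamics would add
parameters without changing any stationary property the pipeline
estimates.  Non-periodic domain bounds reflect; periodic (angle)
coordinates wrap.  Units are fixed globally: kcal/mol, Å, ps, K, rad;
k_B = 0.0019872041 kcal/(mol·K).

**Well-tempered bias.**  Gaussians of width σ per CV are deposited every
τ ps with heights w(t) = w0·exp(−V(s,t)/(k_B ΔT)).  The configured
deposition rate is w0/τ; the defaults w0 = 0.5 kcal/mol and τ = 1 ps
realise an initial rate of 0.5 kcal/mol/ps with a conventional pace (the
rate, not its split, is the physically quoted quantity).  Defaults
elsewhere: T = 300 K, ΔT = 2700 K (bias factor γ = 10), σ = 0.23 Å for
distances and 0.05 rad for torsions, upper wall on d at 27.0 Å with
k = 10 kcal/mol/Å².  The FES estimate is F(s) = −((T+ΔT)/ΔT)·V(s), shifted
so its minimum is zero; the *final* bias is used (not a time average).
Walls are part of the sampled system and never folded into the recovered
FES.

The bias is stored twice: as the exact hills list (reference path for
energies, forces, and the tempered-height bookkeeping, which is therefore
reproducible to machine precision from the HILLS file) and as an
incrementally updated grid cache (node spacing σ/16, Gaussian tails cut at
7σ where they are < 3e-11 of the height).  The sampler reads linear
interpolants of V and ∂V/∂s from the cache; the documented fast energy
path is a cubic spline on the cache, which agrees with direct summation to
better than 1e-4 kcal/mol (scipy's `RegularGridInterpolator(method="cubic")`
was measured at ~2e-4 and rejected in favour of
`CubicSpline`/`RectBivariateSpline`).

**Reweighting.**  Frames of the biased run are unbiased with the
time-dependent weight w ∝ exp(β[V(s(t),t) − c(t)]), where

    c(t) = (1/β)·ln[ ∫ds e^(−βF(s,t)) / ∫ds e^(−β(F(s,t)+V(s,t))) ],

F(s,t) = −((T+ΔT)/ΔT)V(s,t), and the integrals are grid quadratures at
each deposition checkpoint; c is linearly interpolated in time and is zero
before the first hill.  New-CV values are evaluated on stored frames in
post-processing — no new biased run is needed to change representation.
Reweighted surfaces are weighted histograms, F = −kT ln(p/Δs) on occupied
bins, min-anchored; empty bins carry an explicit unvisited flag, never an
imputed value.

## Collective variables

* **d** — distance between two groups' mass centers.
* **φ, ψ** — dihedral between the oriented major inertia axes of two
  groups, realised as the four-point dihedral (com1+axis1, com1, com2,
  com2+axis2); the COM–COM vector is the central bond.  The construction
  is a package choice (several are geometrically admissible), as is using
  *oriented* axes.
* **POA / DFA** — signed projection of a group's COM on the receptor's
  major inertia axis, and the perpendicular distance from it.  The origin
  is the axis owner's COM; POA² + DFA² = |ΔCOM|² identically.

The "major" inertia axis is the *long* axis — the smallest-eigenvalue
eigenvector of the mass-weighted inertia tensor (for the elongated
quadruplex this is the stacking axis; the largest-eigenvalue choice would
be perpendicular to the stack).  Its sign is fixed by a named reference
bead pair, by default 5'-end → 3'-end, making the 3' side the positive POA
direction; a relative gap < 1e-6 between the two smallest eigenvalues
raises an explicit degeneracy error instead of silently picking an
arbitrary axis (the 2-beads-per-strand quadruplex is the canonical oblate
case).  CV gradients for biasing are uniform central finite differences
(step 1e-5, O(step²)); analytic inertia-eigenvector derivatives would buy
nothing at this scale.

## Synthetic systems

**Double well (1D).**  Two *identical* Gaussian wells of depth `barrier`
a distance `separation` apart, plus a tanh switch that raises the right
half by `asymmetry`.  Because the wells are vertical translates of each
other, the minimum-to-minimum gap *and* the well-region free-energy gap
both equal `asymmetry` essentially exactly (a naive unequal-depth
construction makes the deeper well narrower and biases the region gap by
~0.05 kcal/mol — measurable at kT = 0.596).  The switch is flat to < 1e-8
at the well centers; default width σ = separation/7.5 keeps the wells
non-overlapping to < 1e-12.

**Hopping landscape (2D).**  Three Gaussian wells Aa, Ab, B on a plateau
(default 4 kcal/mol above Aa), with an elongated Gaussian channel between
Aa and Ab producing a sub-plateau saddle.  Defaults mirror the study
conditions the analysis targets: offsets 0.9 (Ab) and 1.4 (B) kcal/mol,
Ab→Aa barrier 1.5 kcal/mol, well width 1.0 Å, centers Aa(4,4), Ab(4,8),
B(9,6) on a 12×12 Å domain.  Because overlapping Gaussians shift minima
and saddle, amplitudes, centers and the channel amplitude are calibrated
by a damped fixed-point iteration against the measured minima
(L-BFGS-B polish) and the line saddle until all residuals are < 1e-7 —
far inside the construction tolerances (0.05 kcal/mol, 0.1 Å).  An
independent flood-fill saddle search on a 500×500 grid confirms the
barrier in the tests.

**Toy quadruplex and ligand.**  Four parallel strands of stacked beads on
a square cross-section (default 6 beads/strand, rise 3.4 Å, side 8 Å),
exactly invariant under 90° rotation about z and centered at the origin.
Terminal beads carry distinct labels and masses (end5 104, core 100,
end3 112 amu) so the model, like a real quadruplex, is not symmetric
under end swap and the POA sign distinguishes the two faces.  The ligand
is a rigid two-bead body (scaffold + tail, bond 4 Å): enough structure to
anchor every CV the pipeline defines.  Structures round-trip through PDB
(beads as CA atoms, strands as chains A–D, ligand chain L) at the
format's 1e-3 Å precision; masses are not a PDB concept and are restored
from bead labels.

**Quadrature oracle.**  `boltzmann_quadrature` integrates exp(−E/kT) by
Simpson's rule (4097 points in 1D, 801 per axis in 2D; doubling the
resolution moves results by < 1e-6 relative), and `marginal_free_energy`
produces exact per-bin marginals.  Every free-energy claim the tests make
is checked against these, never against the sampler itself.

## FES analysis

Minima are visited bins strictly below all visited neighbours (full
connectivity); basins are grown by flooding bins in increasing-F order,
with lexicographic tie-breaks so the segmentation is deterministic.
Basin ΔΔG defaults to minimum-to-minimum — how depths are read off a
plotted surface — with a basin-integrated −kT ln(P_a/P_b) mode for
thermodynamic consistency (shift-invariant by construction).  Barriers
are lowest saddles found by bisection on the threshold at which the two
minima's sublevel sets connect (`scipy.ndimage.label`), reported relative
to the higher minimum; this matches reading a contour plot and is
resolution-limited by design.  Binding ΔG between the bound
(7.0 ≤ d ≤ 14.0 Å) and unbound (24 < d < 26 Å) regions defaults to the
region-integrated form and applies no standard-state correction (the
definition is a direct FES difference); −kT ln(V_u/V₀) can be added on
request.  Convergence is monitored by replaying the hills history and
recomputing ΔG at checkpoints, together with the count of bound↔unbound
recrossings; the uncertainty is a block standard error over contiguous,
independently reweighted trajectory blocks (the simplest defensible
estimator where no method is prescribed).

## Problem sizes and numerical behaviour

The packaged analyses use 3 seeds × 5×10⁵ steps (dt = 0.01 ps, friction
1/ps, mass 1 amu) for the 1D recovery — recovering the 0.9 kcal/mol
inter-well gap to ~0.1 kcal/mol — and 3 seeds × 1.2×10⁶ steps for the
hopping pipeline, where biasing cv1 alone and reweighting onto cv2
reproduces the quadrature marginal to ≲0.35 kcal/mol below 4 kcal/mol and
recovers the basin offsets and channel barrier to ~0.1–0.2 kcal/mol.
Seed-to-seed scatter is dominated by the unbiased coordinate's barrier
crossings (the channel is crossed thermally, not by the bias), which is
why seed-averaged probabilities are used before taking −kT ln.

Two finite-run effects are worth knowing.  First, the instantaneous
well-tempered ΔG(t) wanders with a slowly decaying amplitude (~0.3
kcal/mol at 5000 ps on the double well), so convergence statements are
made on seed-averaged profiles.  Second, the effective potential E + V
flattens by the theoretical factor ΔT/(T+ΔT) only over the continuously
revisited region; at rarely visited domain edges V lags the global offset
c(t), which grows without bound — a property of the method, not a bug.

## What the generators do and do not emulate

The synthetic systems reproduce the *statistical* structure the analysis
assumes — multi-basin landscapes with known offsets and barriers, a
receptor whose long inertia axis is its symmetry axis, Boltzmann sampling
at a set temperature, symmetry-equivalent binding sites that share CV
values.  They do not emulate solvent, ions, molecular flexibility,
realistic kinetics, or the magnitude of a real binding free energy;
passing tests demonstrate that the estimators are correct and internally
consistent, not that a real simulation of this length would converge.
Real-system absolute numbers (a ΔG_bind near −9 kcal/mol, microsecond
convergence times) are outside what any desk-scale model can or should
reproduce.

## Known limitations

* CV-space dynamics: the bead structures are used for geometry and I/O;
  metadynamics runs on analytic landscapes, not on the bead model's full
  configuration space.
* Finite-difference CV gradients are O(10³) slower than analytic ones
  would be; irrelevant here, limiting for large bead counts.
* The barrier estimator is grid-resolution-limited and can only return
  values from the discrete set of bin energies.
* 1D and 2D grids only (as in the analyses the pipeline reproduces);
  higher-dimensional FES objects are out of scope.
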