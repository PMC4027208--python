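# gqmetad

Desk-scale machinery for studying how a small ligand binds a parallel,
4-fold-symmetric DNA G-quadruplex with enhanced sampling: well-tempered
metadynamics along geometric collective variables, reweighting of the
biased ensemble onto new collective variables, and free-energy-surface
analysis (basins, barriers, bound/unbound binding free energy,
convergence).  The explicit-solvent molecular system of a production
study is replaced by synthetic landscapes and a toy quadruplex bead
model whose ground truth is known by quadrature, so every estimator in
the chain can be validated exactly.

Audience: molecular-simulation practitioners who want a small, fully
testable reference implementation of the well-tempered metadynamics /
reweighting / FES-analysis pipeline, and method developers who need
trustworthy oracles for each stage.

## The model in brief

Well-tempered metadynamics deposits Gaussians along the trajectory of the
collective variables s with heights that decay with the accumulated bias,

    w(t) = w0 · exp( −V(s,t) / (k_B ΔT) ),

and recovers the free-energy surface from the converged bias as

    F(s) = −((T + ΔT)/ΔT) · V(s),

with T the simulation temperature and ΔT the CV-temperature offset
(bias factor γ = (T+ΔT)/T; 10 for the default 300 K / 2700 K).  Defaults
mirror a production protocol: deposition rate 0.5 kcal/mol/ps
(w0 = 0.5 kcal/mol, τ = 1 ps), Gaussian widths 0.23 Å on distances and
0.05 rad on torsions, and an upper wall on the COM distance d at 27.0 Å.

Frames of the biased run are unbiased with the time-dependent weight
w ∝ exp(β[V(s(t),t) − c(t)]), c(t) being the running bias offset computed
by grid quadrature, so the FES can be re-expressed along *different*
collective variables — the projection of the ligand scaffold on the
receptor's major inertia axis (POA), its distance from that axis (DFA),
or a tail torsion ψ — without any new biased simulation.

The geometric CVs (COM distance d, inertia-axis torsions φ/ψ, POA, DFA)
exploit the receptor's 4-fold symmetry: symmetry-equivalent binding sites
receive identical CV values, so all four grooves are sampled as one.

See `docs/methods.md` for the full account, including the synthetic
generators (an asymmetric double well and a three-basin "hopping"
landscape with offsets 0.9/1.4 kcal/mol and a 1.5 kcal/mol channel
barrier, matching the statistical structure the analysis assumes) and the
numerical choices.

## Worked example

Bias one coordinate of the three-basin landscape, reweight onto the
other, and read the basins off the reweighted surface (this is
`analysis/03_hopping_reweighting.py` condensed):

```python
import numpy as np, gqmetad as gq

pot = gq.make_hopping_landscape()            # offsets 0.9/1.4, barrier 1.5
wt  = gq.WellTemperedParams(widths=(0.23,))  # w0=0.5, τ=1 ps, ΔT=2700 K
lp  = gq.LangevinParams(n_steps=1_200_000, seed=1)

traj, bias = gq.run_metadynamics(pot, lp, wt, lp.n_steps,
                                 bias_cv_indices=[0], start=[4.0, 4.0],
                                 record_stride=5)
ct      = gq.compute_ct(bias, [h.time for h in bias.hills], 300.0, 2700.0)
weights = gq.frame_weights(traj, bias, ct, 300.0)
edges   = np.linspace(0.0, 12.0, 49)
surface = gq.reweighted_fes(traj, weights, ["cv1", "cv2"], [edges, edges],
                            temperature=300.0)
basins  = gq.find_minima(surface, depth_cutoff=2.0)
```

Averaged over three seeds the analysis drivers print:

```
$ python analysis/02_double_well_metadynamics.py
quadrature inter-well ΔF = 0.900 kcal/mol
recovered ΔF per seed: 0.842, 1.166, 1.063
mean ΔF = 1.024 kcal/mol (abs. error 0.124)

$ python analysis/03_hopping_reweighting.py
reweighted marginal vs quadrature (F<=4): max |dev| = 0.225 kcal/mol
basin offsets: Ab 0.810 (gen 0.9), B 1.228 (gen 1.4) kcal/mol
Ab->Aa barrier: 1.584 (gen 1.5) kcal/mol

$ python analysis/04_binding_free_energy.py
quadrature ΔG(bound, unbound) = -3.852 kcal/mol
metadynamics estimate          = -3.692 ± 0.221 kcal/mol (block SE, 4 blocks)
bound/unbound recrossings      = 30
```

Reading: the biased runs recover the generator's inter-well gap
(0.9 kcal/mol) and basin offsets/barrier to one or two tenths of a
kcal/mol; the reweighted surface along the *unbiased* coordinate agrees
with exact quadrature everywhere below 4 kcal/mol; and the binding
estimator reproduces the quadrature bound/unbound free-energy difference
within its block standard error, with the many recrossings that make the
estimate trustworthy.

There is also a CLI for config-driven runs
(`gqmetad generate|sample|metad|reweight|fes|bind --config run.yaml`),
writing PLUMED-style COLVAR/HILLS files, FES grids and tab-separated
reports; identical config + seed reruns are byte-identical.

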