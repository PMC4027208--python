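#!/usr/bin/env python
"""Bound/unbound binding free energy with wall, convergence and recrossings.

A 1D binding-like landscape on the COM distance d (a 4 kcal/mol binding
well centred at 10 Å on a flat unbound plateau) is sampled by
well-tempered metadynamics with the upper wall at 27.0 Å.  ΔG between the
bound (7.0 <= d <= 14.0 Å) and unbound (24 < d < 26 Å) regions is read
from the recovered FES, its convergence followed over simulation time,
the bound/unbound recrossings counted, and a block standard error
attached via reweighting — the full estimator chain of a binding study.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import gqmetad as gq
from gqmetad.toy_systems import GaussianWellPotential, _isotropic_term

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)
(RESULTS / "figures").mkdir(exist_ok=True)
T, DT = 300.0, 2700.0
KT = gq.kT(T)


def binding_potential() -> GaussianWellPotential:
    terms = [_isotropic_term(4.0, [10.0], 1.5, 1)]
    return GaussianWellPotential(["d"], ["A"], [(2.0, 30.0)], terms)


def main() -> None:
    pot = binding_potential()
    regions = gq.BindingRegions(bound=(7.0, 14.0), unbound=(24.0, 26.0))
    ref = (gq.boltzmann_quadrature(pot, KT, [regions.bound]).free_energy
           - gq.boltzmann_quadrature(pot, KT, [regions.unbound]).free_energy)

    wall = gq.WallSpec(cv_label="d", limit=27.0, spring=10.0)
    wt = gq.WellTemperedParams(widths=(0.23,))
    lp = gq.LangevinParams(n_steps=600_000, seed=1)
    traj, bias = gq.run_metadynamics(pot, lp, wt, lp.n_steps, walls=[wall],
                                     start=[10.0], record_stride=5)

    fes = gq.fes_from_bias(bias, T, DT)
    result = gq.binding_delta_g(fes, regions)
    times, profile, n_recross = gq.convergence_profile(
        bias, regions, T, DT, traj=traj)

    ct = gq.compute_ct(bias, [h.time for h in bias.hills], T, DT)
    weights = gq.frame_weights(traj, bias, ct, T)
    se = gq.delta_g_uncertainty(traj, weights, regions, n_blocks=4,
                                temperature=T)

    with open(RESULTS / "binding_free_energy.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"quadrature_delta_g\t{ref:.4f}\n")
        fh.write(f"delta_g_bind\t{result.delta_g:.4f}\n")
        fh.write(f"block_standard_error\t{se:.4f}\n")
        fh.write(f"recrossings\t{n_recross}\n")
        fh.write("\ntime\tdelta_g\n")
        for t, g in zip(times, profile):
            fh.write(f"{t:.2f}\t{g:.5f}\n")

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    axes[0].plot(fes.centers(0), fes.values, "C0-")
    for lo, hi, color in (*[(regions.bound[0], regions.bound[1], "C2")],
                          *[(regions.unbound[0], regions.unbound[1], "C3")]):
        axes[0].axvspan(lo, hi, color=color, alpha=0.2)
    axes[0].set_xlabel("d (Å)")
    axes[0].set_ylabel("F (kcal/mol)")
    axes[1].plot(times, profile, "C0-")
    axes[1].axhline(ref, color="k", ls="--", lw=1, label="quadrature")
    axes[1].set_xlabel("time (ps)")
    axes[1].set_ylabel("ΔG bound-unbound (kcal/mol)")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(RESULTS / "figures" / "binding_convergence.png", dpi=150)

    print(f"quadrature ΔG(bound, unbound) = {ref:.3f} kcal/mol")
    print(f"metadynamics estimate          = {result.delta_g:.3f} "
          f"± {se:.3f} kcal/mol (block SE, 4 blocks)")
    print(f"bound/unbound recrossings      = {n_recross}")
    print(f"final-quarter ΔG(t) range      = "
          f"{profile[times >= 0.75 * times[-1]].max() - profile[times >= 0.75 * times[-1]].min():.3f} kcal/mol")


if __name__ == "__main__":
    main()
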