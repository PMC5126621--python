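"""Recover a perturbed ligand pose with the Monte-Carlo refinement loop.

The ligand is displaced ~1.5 Å from its planted pose and the refinement
(perturb → repack → minimize → Metropolis, annealed kT, best-of-N decoys,
chained rounds until convergence) is asked to bring it back.
"""

import numpy as np

import pocketmc as pm
from pocketmc import RefinementConfig, refine_to_convergence
from pocketmc.binding import pose_rmsd

system = pm.make_mini_pocket(seed=7, n_residues=12)
start = pm.perturb_pose(system, 1.5, seed=0)
print(f"start RMSD from planted pose: "
      f"{pose_rmsd(start.ligand, system.structure.ligand):.2f} Å")

# a reduced protocol: 2×2×2 = 8 perturbation steps per decoy, 20 decoys per
# round (the full protocol uses 8×4×6 = 192 steps and 200 decoys)
cfg = RefinementConfig(outer_cycles=2, mid_blocks=2, inner_steps=2,
                       n_decoys=20, max_K=4, convergence_tol=0.05, seed=0)
refined, trace = refine_to_convergence(start, cfg)

print(f"rounds run (K): {trace.K}, converged: {trace.converged}")
print("per-round lowest decoy energies:",
      [round(e, 2) for e in trace.cycle_energies])
print(f"final RMSD from planted pose: "
      f"{pose_rmsd(refined.ligand, system.structure.ligand):.2f} Å")
# A final RMSD well below 1 Å means the protocol re-docked the ligand into
# the planted minimum; the trace is non-increasing by construction.
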