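# Methods

`pocketmc` implements an iterative Monte-Carlo refinement of
protein–cofactor–water–ligand complexes and a qualitative competitive-binding
analysis on top of it.  This note records the model, the protocol, the
synthetic benchmark systems, the numerical choices, and what the tests do and
do not demonstrate.

## Scoring function

The score is a deliberately small four-term molecular-mechanics model, in
kcal/mol with distances in Å:

* **Lennard-Jones 12-6** with per-element ε/σ tables and Lorentz–Berthelot
  combination (ε: C 0.12, N 0.16, O 0.18, S 0.22, H 0.015; σ: C 3.40,
  N 3.15, O 3.00, S 3.55, H 1.00).  Carbons use slightly enlarged united-atom
  radii; nonpolar hydrogens are implicit.
* **Screened Coulomb** `k·q_i·q_j / (ε(r)·r)` with `k = 332.0637`
  kcal·Å/(mol·e²) and a distance-dependent dielectric `ε(r) = 4r`, the
  standard implicit-screening choice for docking-style scores.  Partial
  charges come from a minimal built-in table: polar backbone and side-chain
  atoms carry modest fixed charges; apolar atoms are neutral.
* **Directional hydrogen bond**: a 10-12 well of depth 2.0 kcal/mol with its
  minimum at a donor–acceptor distance of 2.9 Å, active only when the
  D–H···A angle is ≥ 120° and D···A ≤ 3.5 Å.  The polar hydrogen carries the
  donor geometry, and each donor hydrogen is *saturated*: all repulsive
  close contacts count, but only its single deepest attractive bond does
  (without saturation one donor "bifurcates" across two acceptors and
  H-bond counts double-dip).
* **Torsion prior**: `½·k_t·(1 + cos 3θ)` (k_t = 1.0 kcal/mol) over
  side-chain χ angles and ligand rotatable torsions, with minima at the
  staggered conformers.

Nonbonded pairs closer than three bonds within a component are excluded;
all nonbonded terms are tapered to zero by a smoothstep over the last 1 Å
before the 9 Å cutoff, so minimization gradients stay continuous.  Energies
are totals over an entire complex; only energy *differences* are meaningful,
and no attempt is made to reproduce the magnitudes of any published scoring
function.  There is no solvation or entropy term: ligand comparisons assume
equal active-site access and comparable entropic cost across ligands.

The pair/H-bond/torsion sums are evaluated by fused numba kernels over
precomputed pair lists; a pure-Python per-pair path (`pair_energy`) defines
the model atom-by-atom and is what the test oracles sum over.

## Refinement protocol

One **decoy trajectory** executes `outer × mid × inner` perturbation steps
(default 8 × 4 × 6 = 192).  Each step:

1. rigid-body perturbation of every mobile hetero component (ligand,
   cofactor, catalytic water; translation ≤ 0.5 Å, rotation ≤ 10°, plus one
   random ligand-torsion twist),
2. small moves (φ, ψ ± ≤ 5°) on each flexible residue, and compensating
   shear moves on sequence-adjacent flexible pairs, with downstream
   propagation within contiguous chain segments,
3. greedy side-chain repacking of the flexible residues over a built-in
   staggered rotamer library (χ ∈ {−60°, 60°, 180°}, uniform priors), with
   the *current* conformation always competing as a candidate,
4. Davidon–Fletcher–Powell minimization over the pose degrees of freedom
   (hetero-component rigid bodies + ligand torsions; a small per-step
   iteration budget, default 6), and
5. a Metropolis accept/reject against the last accepted state at the
   current kT.

kT anneals linearly from 3.0 to 1.0 over the outer cycles of each
trajectory.  Flexible residues are those with any atom within 4 Å of the
ligand — on the first round also within 4 Å of the cofactor, plus all
residues declared catalytically active.

An **optimization round** draws `n_decoys` (default 200) independent
trajectories from per-decoy child seeds and keeps the lowest-energy decoy
(ties to the lowest index).  Rounds chain — the winner seeds the next — and
stop when the best energies of two subsequent rounds agree within a
tolerance (default 1e−3 kcal/mol; "the same energy" is numerically
meaningless as exact equality) or when a safety cap of 50 rounds is hit.
The incumbent best is carried forward, so the reported trace is
non-increasing even if a later round samples only worse decoys.

Numerical choices in the minimizer: forward-difference gradients (h = 1e−3),
Armijo backtracking, a 0.5 trust-radius cap on the step norm (clashed starts
otherwise eject a rigid body from the pocket in one step), and an exact
restricted objective — only pairs touching atoms the DOF can move are summed,
since fixed–fixed pairs are constant; reported energies are corrected back to
totals.

## Binding analysis

The energy ladder optimizes the complex at each composition rung — apo,
+catalytic water, +water+cofactor, full ternary complex — with the same
convergence loop; the ligand alone is scored once without optimization.
The binding energy is `E_bind = E_complex − (E_ref + E_lig)` with `E_ref`
the optimized ligand-free rung, computed once per screen and shared across
ligands.  Pose classes come from the angle between best-fit planes of the
ligand core and the cofactor ring: ≤ 30° parallel → unproductive, ≥ 60°
perpendicular → productive, in between → ambiguous (the thresholds are
declared, not fitted).  "Not binding" is operationalized as a positive
E_bind or a centroid drift > 8 Å from the pocket during refinement.
Pose RMSD is heavy-atom, name-matched, in the fixed receptor frame (no
re-superposition).

## Synthetic benchmark systems

`make_mini_pocket` builds, deterministically from a seed, a 10–40-residue
pocket around a planted ligand: a fully planar six-carbon ring bearing
three in-plane acceptor oxygens (unequal angular gaps, so no pose permutes
them) and a short in-plane sp3 tail with one rotatable torsion.  Planarity
makes the ligand its own mirror image, and three non-collinear
hydrogen-bond anchors geometrically determine the bound pose of a rigid
body — the planted pose is a *designed* optimum, not one orientation on a
soft mode.  The cavity lining comprises:

* groove-shaped hydrophobic contacts (three pseudo-CB carbons bracketing
  the ring plane) aimed at the two ring carbons not carrying substituents,
  placed at 4.05 Å — slightly past the C–C Lennard-Jones optimum and just
  outside the 4 Å flexible-selection radius, so the cage contributes ~90%
  of the pair well depth while remaining rigid under the protocol (a
  crystal-like scaffold), plus vertical cap residues over the ring and the
  tail;
* one to three serines (complementarity ≥ 0.3 / 0.5 / 0.7) donating ideal
  hydrogen bonds to the ligand oxygens; these sit inside the flexible zone
  and are the residues the protocol actually samples.  Outside the serine
  hydroxyls the scaffold is stripped of charges and H-bond roles: the only
  polar partners in a generated pocket are the planted ones, so no stray
  backbone donor offers a competing quasi-degenerate H-bond network;
* an apolar planar six-carbon ring as the cofactor stand-in (geometry for
  pose classification only — no cofactor chemistry), clamped by its own
  contact residues;
* a catalytic water placed by a global site search: candidate positions off
  every acceptor face, each relaxed by a short rigid-body minimization, the
  lowest total energy wins;
* filler residues on an outer shell to reach the requested size.

The assembled complex is then made a rest point of *every* degree of freedom
the protocol can move: continuous minimization over hetero components,
ligand torsions and flexible-residue dihedrals; a basin-hop over perturbed
starts that includes the protocol's own discrete repacking; and finally a
short run of the Monte-Carlo refinement itself, whose basin is adopted
(repacked, re-minimized) if it is deeper.  Generation ends by verifying that
≥ 95% of random 0.3 Å ligand displacements raise the energy; a failed check
retries with a fresh sub-seed.  `complementarity` scales how many contacts
and H-bond partners line the cavity.

Decoy ligands match the active's heavy-atom count (±2), oxygen count and
net charge, but are acyclic molecules with a verified non-isomorphic
element-labelled bond graph and the oxygens scrambled to random
non-adjacent interior positions.  Topology difference is enforced by graph
non-isomorphism rather than a fingerprint-similarity threshold, keeping the
generator dependency-light.  Embeddings are checked for self-collisions and
each decoy is relaxed to its own internal torsion minimum, so screens start
from strain-free inputs (internal strain would otherwise leak into binding
energies when the complex relaxes it).  `perturb_pose` applies a
random rigid motion split evenly (in RMS) between translation and rotation
so the expected heavy-atom RMSD matches the requested magnitude.

**What the synthetic systems do not emulate:** real protein folds and
connectivity (pocket residues are isolated chain segments with gapped
numbering, so backbone moves do not propagate across the pocket), solvent
beyond one water, cofactor chemistry, crystallographic artifacts, and
realistic charge distributions.  Passing the recovery and discrimination
tests therefore demonstrates that the *protocol and scoring machinery* are
internally consistent — a planted optimum is refindable and a
shape/charge-matched wrong-topology ligand scores worse — not that the
score predicts affinities of real molecules.

## Problem sizes

The test-suite and the acceptance script run the protocol at reduced scale:
10–15-residue pockets, 8-step trajectories (2 × 2 × 2), 6–20 decoys per
round and 2–4 rounds, with the full default cycle structure (192 steps,
200 decoys) exercised where the protocol constants themselves are the
quantity under test.  These sizes are the package's declared benchmark
conditions; the protocol scales to larger systems at proportional cost.

## Known limitations

* The DFP minimizer uses numerical gradients; its precision floor
  (~1e−2 kcal/mol on a full complex) sets the meaningful resolution of
  energy comparisons near a minimum.
* The planted pose is the deepest basin found by the generation-time search;
  a sufficiently long refinement on an unluckily shaped system can still, in
  a minority of seeds, locate a marginally deeper nearby basin.  The
  recovery and discrimination checks are therefore framed over seed
  ensembles (≥ 8/10), not as per-system guarantees.
* Hydrogen placement is geometric (one polar H per donor along the open
  valence); no protonation-state prediction.
* The greedy repacker can miss cooperative multi-residue rotamer
  rearrangements; with the minimal library and mostly-rigid pockets this
  has not been observed to matter beyond the energy scales above.
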