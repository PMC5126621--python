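"""Iterative Monte-Carlo decoy refinement with simulated annealing.

One *decoy trajectory* runs ``outer × mid × inner`` perturbation steps
(default 8 × 4 × 6 = 192).  Each step perturbs the mobile hetero components
and the flexible residues (small/shear backbone moves), repacks the flexible
side chains, minimizes the pose degrees of freedom with a
Davidon–Fletcher–Powell quasi-Newton descent, and accepts or rejects the
result by the Metropolis criterion at the current temperature.  kT anneals
linearly from ``kt_start`` to ``kt_end`` over the outer cycles.

An *optimization round* generates ``n_decoys`` independent trajectories
(default 200) from the same start and keeps the lowest-energy decoy.  Rounds
are chained — the best decoy seeds the next round — until the best energy of
two subsequent rounds agrees within a tolerance, or a round cap is hit.
The first round selects flexible residues around both cofactor and ligand
(plus the declared active residues); later rounds use the ligand
neighbourhood only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .energy import EnergyBreakdown, EnergyParams, ScoringContext, default_params
from .moves import (
    MoveSpec,
    RotamerLibrary,
    apply_shear_move,
    apply_small_move,
    default_rotamer_library,
    perturb_component,
    refresh_parent_positions,
    repack_side_chains,
    select_flexible_residues,
)
from .structures import Structure, StructureError, rotation_about_axis

__all__ = [
    "RefinementConfig",
    "Decoy",
    "RefinementTrace",
    "DofSpec",
    "metropolis_accept",
    "anneal_kt",
    "minimize_energy",
    "generate_decoy",
    "optimization_round",
    "refine_to_convergence",
]


@dataclass
class RefinementConfig:
    """Protocol parameters of the refinement loop.

    ``outer_cycles × mid_blocks × inner_steps`` is the number of perturbation
    steps per decoy trajectory; defaults give 8 × 4 × 6 = 192.
    """

    outer_cycles: int = 8
    mid_blocks: int = 4
    inner_steps: int = 6
    n_decoys: int = 200
    kt_start: float = 3.0
    kt_end: float = 1.0
    selection_radius: float = 4.0
    convergence_tol: float = 1e-3
    max_K: int = 50
    seed: int = 0
    moves: MoveSpec = field(default_factory=MoveSpec)
    traj_min_iters: int = 6         # DFP iterations inside each trajectory step
    traj_min_gtol: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.outer_cycles, self.mid_blocks, self.inner_steps) < 1:
            raise ValueError("cycle counts must be ≥ 1")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be ≥ 1")
        if not (self.kt_start >= self.kt_end > 0):
            raise ValueError("need kt_start ≥ kt_end > 0")

    @property
    def steps_per_decoy(self) -> int:
        return self.outer_cycles * self.mid_blocks * self.inner_steps


@dataclass
class Decoy:
    """One stochastically refined snapshot of the complex."""

    structure: Structure
    energy: float
    index: int
    n_steps: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("decoy energy must be finite")


@dataclass
class RefinementTrace:
    """Per-round lowest-decoy energies of a convergence run."""

    cycle_energies: list
    K: int
    converged: bool

    def __post_init__(self) -> None:
        if len(self.cycle_energies) != self.K:
            raise ValueError("trace length must equal K")
        for a, b in zip(self.cycle_energies, self.cycle_energies[1:]):
            if b > a + 1e-9:
                raise ValueError("trace energies must be non-increasing")


# --------------------------------------------------------------------------
# Metropolis / annealing
# --------------------------------------------------------------------------

def metropolis_accept(
    e_new: float, e_old: float, kt: float, rng: np.random.Generator
) -> bool:
    """Accept downhill always; uphill with probability exp(−ΔE/kT)."""
    if not (np.isfinite(e_new) and np.isfinite(e_old)):
        raise ValueError("non-finite energies in Metropolis test")
    if kt <= 0:
        raise ValueError("kt must be positive")
    delta = e_new - e_old
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / kt))


def anneal_kt(cfg: RefinementConfig, outer_index: int) -> float:
    """Linear annealing: kt_start at the first outer cycle, kt_end at the last."""
    if not (0 <= outer_index < cfg.outer_cycles):
        raise IndexError(f"outer index {outer_index} out of range")
    if cfg.outer_cycles == 1:
        return cfg.kt_start
    f = outer_index / (cfg.outer_cycles - 1)
    return cfg.kt_start + f * (cfg.kt_end - cfg.kt_start)


# --------------------------------------------------------------------------
# degrees of freedom and DFP minimization
# --------------------------------------------------------------------------

@dataclass
class DofSpec:
    """Declared degrees of freedom for minimization.

    ``residue_dihedrals``: (res_id, kind) with kind "phi", "psi" or
    ("chi", k).  ``rigid_components``: indices into structure.components
    getting 6 rigid-body DOF each.  ``ligand_torsions``: include the
    ligand's rotatable torsions.
    """

    residue_dihedrals: list = field(default_factory=list)
    rigid_components: list = field(default_factory=list)
    ligand_torsions: bool = False


def pose_dofs(s: Structure, include_chis: bool = False,
              flexible_ids: Iterable = ()) -> DofSpec:
    """The pose DOF used inside trajectories: rigid-body motion of every
    mobile hetero component plus the ligand's rotatable torsions (and
    optionally the flexible residues' χ angles)."""
    rigid = [i for i, c in enumerate(s.components)
             if c.kind in ("ligand", "cofactor", "catalytic_water")]
    dihedrals = []
    if include_chis:
        flex = {tuple(r) for r in flexible_ids}
        for res in s.protein_residues():
            if res.res_id in flex:
                dihedrals.extend((res.res_id, ("chi", k)) for k in range(len(res.chis)))
    lig = s.ligand
    return DofSpec(residue_dihedrals=dihedrals, rigid_components=rigid,
                   ligand_torsions=bool(lig and lig.rotatable_torsions))


class _DofMap:
    """Maps a flat DOF vector to a coordinate array, starting from a frozen
    baseline.  Angles are radians, translations Å."""

    def __init__(self, ctx: ScoringContext, dof: DofSpec):
        self.ctx = ctx
        s = ctx.structure
        self.entries: list = []  # ("dihedral", axis pair getter, movers) | ("rigid", idx)
        for res_id, kind in dof.residue_dihedrals:
            res = s.residue_by_id(res_id)
            ridx = ctx.residue_index[res_id]
            names = [a.name for a in res.atoms]
            gi = {n: g for n, g in zip(names, ridx)}
            if kind == "phi":
                axis = (gi["N"], gi["CA"])
                movers = [g for n, g in zip(names, ridx) if n not in ("N", "H", "CA")]
            elif kind == "psi":
                axis = (gi["CA"], gi["C"])
                movers = [g for n, g in zip(names, ridx) if n in ("O", "OXT")]
            else:
                _, k = kind
                axis, movers = self._chi_axis(res, names, ridx, k)
            self.entries.append(("dihedral", axis, np.array(movers, dtype=int),
                                 (res_id, kind)))
        for ci in dof.rigid_components:
            idx = np.array(ctx.component_index[ci], dtype=int)
            if len(idx):
                self.entries.append(("rigid", None, idx, ci))
        self.ligand_torsions: list = []
        if dof.ligand_torsions:
            lig_ci = next(i for i, c in enumerate(s.components) if c.kind == "ligand")
            base = ctx.component_index[lig_ci][0]
            lig = s.components[lig_ci].ligand
            g = lig.graph()
            for (a, b, c_, d) in lig.rotatable_torsions:
                g2 = g.copy()
                g2.remove_edge(b, c_)
                distal = [base + i for i in nx.node_connected_component(g2, c_) if i != c_]
                self.ligand_torsions.append(((base + b, base + c_),
                                             np.array(distal, dtype=int)))
        self.n_dof = (
            sum(1 for e in self.entries if e[0] == "dihedral")
            + 6 * sum(1 for e in self.entries if e[0] == "rigid")
            + len(self.ligand_torsions)
        )
        if self.n_dof == 0:
            raise ValueError("minimization needs at least one degree of freedom")
        movers: set = set()
        for entry in self.entries:
            movers.update(int(i) for i in entry[2])
        for _, distal in self.ligand_torsions:
            movers.update(int(i) for i in distal)
        self.mover_indices = sorted(movers)

    @staticmethod
    def _chi_axis(res, names, ridx, k):
        from .moves import _chi_axis_atoms, _remoteness
        prox, dist = _chi_axis_atoms(res, k)
        gi = {n: g for n, g in zip(names, ridx)}
        cut = _remoteness(dist.name) or 0
        movers = []
        for n, g in zip(names, ridx):
            rem = _remoteness(n)
            a = res.atom(n)
            if rem is not None and n not in ("N", "CA", "C", "O", "H", "OXT"):
                if rem > cut or (a.is_hydrogen and rem >= cut and n != dist.name):
                    movers.append(g)
        return (gi[prox.name], gi[dist.name]), movers

    def apply(self, x: np.ndarray, baseline: np.ndarray) -> np.ndarray:
        coords = baseline.copy()
        i = 0
        for entry in self.entries:
            if entry[0] == "dihedral":
                _, (a0, a1), movers, _ = entry
                ang = math.degrees(x[i]); i += 1
                if ang != 0.0 and len(movers):
                    R = rotation_about_axis(coords[a1] - coords[a0], ang)
                    coords[movers] = (coords[movers] - coords[a0]) @ R.T + coords[a0]
            else:
                _, _, idx, _ = entry
                rot = x[i:i + 3]; trans = x[i + 3:i + 6]; i += 6
                theta = np.linalg.norm(rot)
                centroid = coords[idx].mean(axis=0)
                if theta > 1e-12:
                    R = rotation_about_axis(rot, math.degrees(theta))
                    coords[idx] = (coords[idx] - centroid) @ R.T + centroid
                coords[idx] = coords[idx] + trans
        for (b, c_), distal in self.ligand_torsions:
            ang = math.degrees(x[i]); i += 1
            if ang != 0.0 and len(distal):
                R = rotation_about_axis(coords[c_] - coords[b], ang)
                coords[distal] = (coords[distal] - coords[b]) @ R.T + coords[b]
        return coords

    def update_state(self, x: np.ndarray) -> None:
        """Fold the applied deltas back into the residue dihedral state."""
        from .structures import wrap_angle
        s = self.ctx.structure
        i = 0
        for entry in self.entries:
            if entry[0] == "dihedral":
                res_id, kind = entry[3]
                res = s.residue_by_id(res_id)
                ang = math.degrees(x[i]); i += 1
                if kind == "phi":
                    res.phi = wrap_angle(res.phi + ang)
                elif kind == "psi":
                    res.psi = wrap_angle(res.psi + ang)
                else:
                    k = kind[1]
                    if k < len(res.chis):
                        res.chis[k] = wrap_angle(res.chis[k] + ang)
            else:
                i += 6
        # ligand torsion state lives in the coordinates themselves


def _dfp(f: Callable, x0: np.ndarray, gtol: float, max_iter: int,
         h: float = 1e-3, max_step: float = 0.5) -> Tuple[np.ndarray, float]:
    """Davidon–Fletcher–Powell quasi-Newton descent with forward-difference
    gradients, Armijo backtracking and a trust-radius cap on the step norm
    (clashed starts otherwise produce energy gradients large enough to throw
    a rigid body out of the pocket in one step); returns the best point
    visited."""
    n = len(x0)
    x = x0.copy()
    fx = f(x)
    best_x, best_f = x.copy(), fx

    def grad(xv, fv):
        g = np.empty(n)
        for i in range(n):
            xp = xv.copy()
            xp[i] += h
            g[i] = (f(xp) - fv) / h
        return g

    H = np.eye(n)
    g = grad(x, fx)
    for _ in range(max_iter):
        gn = np.linalg.norm(g)
        if gn < gtol:
            break
        d = -H @ g
        # backtracking line search
        slope = float(g @ d)
        if slope >= 0:
            H = np.eye(n)
            d = -g
            slope = -float(g @ g)
        dn = np.linalg.norm(d)
        if dn > max_step:
            d = d * (max_step / dn)
            slope = float(g @ d)
        alpha, ok = 1.0, False
        for _ls in range(12):
            xn = x + alpha * d
            fn = f(xn)
            if fn <= fx + 1e-4 * alpha * slope:
                ok = True
                break
            alpha *= 0.5
        if not ok:
            break
        s_vec = alpha * d
        x = xn
        fx = fn
        if fx < best_f:
            best_x, best_f = x.copy(), fx
        g_new = grad(x, fx)
        y = g_new - g
        sy = float(s_vec @ y)
        if sy > 1e-12:
            Hy = H @ y
            H = H + np.outer(s_vec, s_vec) / sy - np.outer(Hy, Hy) / float(y @ Hy)
        g = g_new
    return best_x, best_f


def minimize_energy(
    s: Structure,
    dof: DofSpec,
    p: Optional[EnergyParams] = None,
    max_iter: int = 200,
    gtol: float = 1e-4,
    ctx: Optional[ScoringContext] = None,
    return_energy: bool = False,
):
    """Quasi-Newton (DFP) minimization over the declared DOF.

    Returns a structure whose energy is ≤ the input energy (the input is
    returned unchanged if no descent step succeeds).  When a live scoring
    context is passed, its structure is minimized in place.
    """
    p = p or default_params()
    in_place = ctx is not None
    if not in_place:
        s = s.copy()
        ctx = ScoringContext(s, p)
    baseline = ctx.gather_coords()
    e0 = ctx.evaluate(baseline).total
    if not np.isfinite(e0):
        raise ValueError("energy non-finite at minimization start")
    dmap = _DofMap(ctx, dof)

    # pairs among never-moved atoms are constant, so the objective can be
    # the (exact, cheaper) energy restricted to pairs touching moved atoms
    movers = dmap.mover_indices
    if len(movers) < ctx.n:
        def f(x):
            return ctx.subset_energy(movers, dmap.apply(x, baseline))
    else:
        def f(x):
            return ctx.evaluate(dmap.apply(x, baseline)).total

    f0 = f(np.zeros(dmap.n_dof))
    x_best, f_best = _dfp(f, np.zeros(dmap.n_dof), gtol=gtol, max_iter=max_iter)
    e_final = e0
    if f_best <= f0:
        final = dmap.apply(x_best, baseline)
        # accept on the true total (donor saturation in the H-bond term can
        # make the restricted objective deviate across the subset boundary)
        e_cand = ctx.evaluate(final).total
        if e_cand <= e0:
            ctx.scatter_coords(final)
            dmap.update_state(x_best)
            for comp in ctx.structure.components:
                refresh_parent_positions(comp.all_atoms())
            e_final = e_cand
    out = ctx.structure
    return (out, e_final) if return_energy else out


# --------------------------------------------------------------------------
# decoy generation and convergence loop
# --------------------------------------------------------------------------

def _flexible_ids(s: Structure, first_cycle: bool, radius: float) -> set:
    """Flexible-set rule, degrading gracefully for ligand-free states (used
    when optimizing the apo / reference rungs of the energy ladder)."""
    if s.component("ligand") is not None:
        return select_flexible_residues(s, first_cycle, radius)
    from scipy.spatial.distance import cdist
    targets = [a.position for c in s.components
               if c.kind in ("cofactor", "catalytic_water") for a in c.all_atoms()]
    selected = {tuple(r) for r in s.active_residue_ids}
    if targets:
        T = np.array(targets)
        for res in s.protein_residues():
            if cdist(res.coords(), T).min() <= radius:
                selected.add(res.res_id)
    if not selected:
        selected = {res.res_id for res in s.protein_residues()}
    return selected


def _downstream(chain_residues: list, i: int) -> list:
    """Residues following index i while the numbering stays consecutive."""
    out = []
    num = chain_residues[i].res_id[1]
    for r in chain_residues[i + 1:]:
        if r.res_id[1] == num + 1:
            out.append(r)
            num += 1
        else:
            break
    return out


def generate_decoy(
    start: Structure,
    cfg: RefinementConfig,
    p: Optional[EnergyParams] = None,
    rng: Optional[np.random.Generator] = None,
    first_cycle: bool = True,
    index: int = 0,
    lib: Optional[RotamerLibrary] = None,
) -> Decoy:
    """Run one full perturb/repack/minimize/Metropolis trajectory."""
    p = p or default_params()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lib = lib or default_rotamer_library()
    current = start.copy()
    flexible = _flexible_ids(current, first_cycle, cfg.selection_radius)
    for r in current.protein_residues():
        r.flexible = r.res_id in flexible

    ctx = ScoringContext(current, p)
    e_curr = ctx.evaluate().total
    if not np.isfinite(e_curr):
        raise ValueError("starting energy is non-finite")
    n_steps = 0
    for outer in range(cfg.outer_cycles):
        kt = anneal_kt(cfg, outer)
        for _block in range(cfg.mid_blocks):
            for _step in range(cfg.inner_steps):
                n_steps += 1
                prop = current.copy()
                # rigid-body jiggle of the mobile hetero components
                for ci, comp in enumerate(prop.components):
                    if comp.kind in ("ligand", "cofactor", "catalytic_water"):
                        prop.components[ci] = perturb_component(comp, cfg.moves, rng)
                # backbone small moves (and shear where contiguous) on flexible residues
                for chain in prop.protein_chains():
                    residues = chain.residues
                    for i, res in enumerate(residues):
                        if res.res_id in flexible:
                            apply_small_move(res, cfg.moves, rng,
                                             downstream=_downstream(residues, i),
                                             in_place=True)
                    for i in range(len(residues) - 1):
                        r1, r2 = residues[i], residues[i + 1]
                        if (r1.res_id in flexible and r2.res_id in flexible
                                and r2.res_id[1] - r1.res_id[1] == 1):
                            apply_shear_move(r1, r2, cfg.moves, rng,
                                             downstream=_downstream(residues, i + 1),
                                             in_place=True)
                pctx = ScoringContext(prop, p)
                if flexible:
                    repack_side_chains(prop, flexible, lib, p, ctx=pctx)
                try:
                    dof = pose_dofs(prop)
                    if dof.rigid_components or dof.residue_dihedrals:
                        _, e_new = minimize_energy(
                            prop, dof, p, max_iter=cfg.traj_min_iters,
                            gtol=cfg.traj_min_gtol, ctx=pctx, return_energy=True)
                    else:
                        e_new = pctx.evaluate().total
                except ValueError:
                    e_new = pctx.evaluate().total
                if metropolis_accept(e_new, e_curr, kt, rng):
                    current = prop
                    e_curr = e_new
    return Decoy(structure=current, energy=float(e_curr), index=index, n_steps=n_steps)


def optimization_round(
    start: Structure,
    cfg: RefinementConfig,
    p: Optional[EnergyParams] = None,
    first_cycle: bool = True,
    round_index: int = 0,
    collect_energies: Optional[list] = None,
) -> Decoy:
    """Generate ``cfg.n_decoys`` independent decoys and return the lowest in
    energy (ties resolved to the lowest decoy index)."""
    p = p or default_params()
    best: Optional[Decoy] = None
    for j in range(cfg.n_decoys):
        rng = np.random.default_rng([cfg.seed, round_index, j])
        d = generate_decoy(start, cfg, p, rng=rng, first_cycle=first_cycle, index=j)
        if collect_energies is not None:
            collect_energies.append(d.energy)
        if best is None or d.energy < best.energy:
            best = d
    return best


def refine_to_convergence(
    start: Structure,
    cfg: RefinementConfig,
    p: Optional[EnergyParams] = None,
    trace_callback: Optional[Callable] = None,
    decoy_log: Optional[dict] = None,
) -> Tuple[Structure, RefinementTrace]:
    """Chain optimization rounds until the lowest energies of two subsequent
    rounds agree within ``cfg.convergence_tol`` (or ``cfg.max_K`` rounds).

    The incumbent best structure is carried forward, so the reported trace is
    non-increasing even if a later round samples only worse decoys.
    """
    p = p or default_params()
    current = start
    e_inc = math.inf
    trace: list = []
    converged = False
    for k in range(cfg.max_K):
        round_energies: Optional[list] = [] if decoy_log is not None else None
        best = optimization_round(current, cfg, p, first_cycle=(k == 0),
                                  round_index=k, collect_energies=round_energies)
        if decoy_log is not None:
            decoy_log[k] = round_energies
        if best.energy < e_inc:
            e_inc = best.energy
            current = best.structure
        trace.append(e_inc)
        if trace_callback is not None:
            trace_callback(k, e_inc)
        if k > 0 and abs(trace[-1] - trace[-2]) <= cfg.convergence_tol:
            converged = True
            break
    return current, RefinementTrace(cycle_energies=trace, K=len(trace), converged=converged)
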