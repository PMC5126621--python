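"""Synthetic benchmark systems: a rigid mini-pocket with a planted ligand pose.

The generator builds, deterministically from a seed, a small binding pocket
(10–40 residues) whose side chains line a cavity shaped around a planted
small-molecule pose: hydrophobic residues sit at the Lennard-Jones optimum of
the ligand's ring carbons, a serine donates a hydrogen bond to the ligand's
acceptor oxygen, a planar ring stands in for the nicotinamide face of the
cofactor below the cavity, and one catalytic water completes the complex.
After assembly the ligand pose is polished by a rigid-body + torsion
minimization and verified to be a strict local minimum of the package's
energy model (random sub-Å perturbations must raise the energy); generation
retries with a fresh sub-seed if the check fails.

Decoy ligands are property-matched negatives: same heavy-atom count (±2) and
net charge as the active, but an acyclic, non-isomorphic bond topology with
the polar atom at a scrambled position.  They play the role of generated
decoy molecules in a virtual-screening validation: a sound protocol should
score them worse than the planted active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

from .energy import EnergyParams, ScoringContext, default_params
from .refine import DofSpec, minimize_energy, pose_dofs
from .structures import (
    Atom,
    Component,
    Ligand,
    Residue,
    Structure,
    StructureError,
    ELEMENT_VDW,
    _add_polar_hydrogens_residue,
    _assign_protein_atom_params,
    _derive_rotatable_torsions,
    _init_chi_state,
    rotate_points,
)

__all__ = [
    "SyntheticSystem",
    "make_mini_pocket",
    "make_decoy_ligands",
    "perturb_pose",
    "make_active_ligand",
]

# nicotinamide-face stand-in: atom names counted as the cofactor ring.
# The stand-in is purely geometric (apolar carbons): it defines the plane
# that pose classification measures against, without cofactor chemistry.
COFACTOR_RING_NAMES = ("C1Q", "C2Q", "C3Q", "C4Q", "C5Q", "C6Q")


@dataclass
class SyntheticSystem:
    """A generated pocket + planted ligand pose + generation metadata."""

    structure: Structure
    planted_pose: np.ndarray
    seed: int
    descriptor: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# ligand construction
# --------------------------------------------------------------------------

def _carbon(name: str, pos) -> Atom:
    return Atom(name=name, element="C", position=np.asarray(pos, float),
                partial_charge=0.0, vdw_radius=ELEMENT_VDW["C"], hb_role="none")


def make_active_ligand(name: str = "LIG") -> Ligand:
    """The planted active: a planar six-carbon ring bearing three acceptor
    oxygens and a short sp3 tail with one rotatable torsion.

    Planarity plus three non-collinear hydrogen-bond anchors fully determine
    the bound pose of a rigid body (reflection through the plane is the
    identity for a planar molecule), which is what makes the planted pose a
    well-defined optimum rather than one orientation on a soft mode.
    """
    ring_r = 1.40
    atoms = []
    for i in range(6):
        ang = math.radians(60.0 * i)
        atoms.append(_carbon(f"C{i + 1}", [ring_r * math.cos(ang),
                                           ring_r * math.sin(ang), 0.0]))
    # acceptor oxygens on C1, C2 and C5, in plane, pointing outward; the
    # unequal angular gaps (60°/180°/120°) leave no pose that permutes them
    oxy = []
    for ci, nm in ((0, "O1"), (1, "O2"), (4, "O3")):
        c = atoms[ci].position
        out = c / np.linalg.norm(c)
        oxy.append(Atom(name=nm, element="O", position=c + 1.23 * out,
                        partial_charge=-0.40, vdw_radius=ELEMENT_VDW["O"],
                        hb_role="acceptor"))
        atoms[ci].partial_charge = +0.40
    # tail on C4, kept in the ring plane (planar ligand ⇒ flip symmetry is
    # the identity), bent in-plane for asymmetry
    c4 = atoms[3].position
    out4 = c4 / np.linalg.norm(c4)
    c7 = _carbon("C7", c4 + 1.50 * out4)
    tilt = rotate_points(out4[None, :], np.zeros(3), np.array([0.0, 0.0, 1.0]),
                         35.0)[0]
    c8 = _carbon("C8", c7.position + 1.53 * tilt)
    atoms.extend([*oxy, c7, c8])  # indices: O1=6, O2=7, O3=8, C7=9, C8=10
    bonds = [(i, (i + 1) % 6, 1) for i in range(6)]
    bonds += [(0, 6, 1), (1, 7, 1), (4, 8, 1), (3, 9, 1), (9, 10, 1)]
    lig = Ligand(atoms=atoms, bonds=bonds,
                 rotatable_torsions=[(2, 3, 9, 10)],
                 name=name, core_atoms=list(range(6)))
    return lig


# --------------------------------------------------------------------------
# pocket assembly
# --------------------------------------------------------------------------

def _perp_frame(u: np.ndarray) -> tuple:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _build_residue(res_id, res_name: str, tip_pos: np.ndarray, outward: np.ndarray,
                   tip_name: str = "CB", extra_tips=()) -> Residue:
    """A pocket residue whose side-chain tip sits at ``tip_pos`` with the
    backbone receding along ``outward`` (away from the cavity).

    ``extra_tips`` adds further (name, position) side-chain atoms — used to
    build groove-shaped contacts that bracket the ligand plane.  Their names
    deliberately avoid the χ-chain nomenclature so repacking never rotates
    them.
    """
    u = outward / np.linalg.norm(outward)
    e1, _ = _perp_frame(u)
    atoms = [Atom(name=tip_name, element=tip_name[0], position=tip_pos)]
    for nm, pos in extra_tips:
        atoms.append(Atom(name=nm, element=nm[0], position=np.asarray(pos, float)))
    if tip_name == "OG":  # serine: CB between OG and CA
        cb = tip_pos + 1.41 * u
        atoms.append(Atom(name="CB", element="C", position=cb))
        ca = cb + 1.53 * _unit(u + 0.3 * e1)
    else:
        ca = tip_pos + 1.53 * _unit(u + 0.2 * e1)
    # N-CA-C fan at ~112°, carbonyl O anti to N across C
    n = ca + 1.46 * _unit(u + 1.45 * e1)
    if tip_name == "OG":
        # stagger χ1 (N-CA-CB-OG → 180°) so the side chain starts torsion-free
        from .structures import dihedral_angle
        cb_pos = atoms[1].position
        chi = dihedral_angle(n, ca, cb_pos, tip_pos)
        for delta in (chi - 180.0, 180.0 - chi):
            cand = rotate_points(n[None, :], ca, cb_pos - ca, delta)[0]
            if abs(abs(dihedral_angle(cand, ca, cb_pos, tip_pos)) - 180.0) < 1e-6:
                n = cand
                break
    c = ca + 1.52 * _unit(u - 1.45 * e1)
    # carbonyl O along the bisector away from both N and the side chain
    away = _unit(c - n) + _unit(c - atoms[0].position)
    o = c + 1.23 * _unit(away)
    atoms += [
        Atom(name="CA", element="C", position=ca),
        Atom(name="N", element="N", position=n),
        Atom(name="C", element="C", position=c),
        Atom(name="O", element="O", position=o),
    ]
    res = Residue(res_id=res_id, res_name=res_name, atoms=atoms)
    _add_polar_hydrogens_residue(res)
    _init_chi_state(res)
    for a in res.atoms:
        _assign_protein_atom_params(res_name, a)
    # the synthetic scaffold is polar only where designed: outside the
    # serine hydroxyl, charges and H-bond roles are stripped so the only
    # hydrogen-bond partners in a generated pocket are the ones planted
    for a in res.atoms:
        if not (res_name == "SER" and a.name in ("OG", "HG")):
            a.partial_charge = 0.0
            a.hb_role = "none"
    res.atoms = [a for a in res.atoms
                 if not (a.is_hydrogen and not (res_name == "SER" and a.name == "HG"))]
    return res


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _clear_of(point, residues, lig=None, cof=None, min_dist=3.2) -> bool:
    """True when ``point`` keeps ``min_dist`` from everything already built."""
    pts = [a.position for r in residues for a in r.atoms]
    if lig is not None:
        pts += [a.position for a in lig.atoms]
    if cof is not None:
        pts += [a.position for a in cof.atoms]
    if not pts:
        return True
    return float(np.min(np.linalg.norm(np.array(pts) - point, axis=1))) >= min_dist


def _make_cofactor(center=np.array([0.8, 0.0, -4.6]), radius: float = 1.35) -> Component:
    atoms = []
    for i, name in enumerate(COFACTOR_RING_NAMES):
        ang = math.radians(60.0 * i + 30.0)
        pos = center + radius * np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms.append(Atom(name=name, element="C", position=pos,
                          partial_charge=0.0,
                          vdw_radius=ELEMENT_VDW["C"],
                          hb_role="none"))
    return Component(kind="cofactor", name="NAP", atoms=atoms)


def _make_catalytic_water(o_pos: np.ndarray) -> Component:
    o = Atom(name="O", element="O", position=o_pos, partial_charge=-0.80,
             vdw_radius=ELEMENT_VDW["O"], hb_role="both")
    half = math.radians(104.5 / 2)
    hs = []
    for sign, nm in ((1.0, "H1"), (-1.0, "H2")):
        pos = o_pos + 0.96 * np.array([sign * math.sin(half), 0.0, math.cos(half)])
        hs.append(Atom(name=nm, element="H", position=pos, partial_charge=0.40,
                       vdw_radius=ELEMENT_VDW["H"], hb_role="donor",
                       is_hydrogen=True, parent_position=o.position.copy()))
    return Component(kind="catalytic_water", name="HOH_W1", atoms=[o, *hs])


_FIB_INC = math.pi * (3.0 - math.sqrt(5.0))  # golden angle, for filler placement


def make_mini_pocket(
    seed: int,
    n_residues: int = 15,
    complementarity: float = 0.8,
    params: Optional[EnergyParams] = None,
    _verify_trials: int = 60,
) -> SyntheticSystem:
    """Generate a rigid mini-pocket whose planted ligand pose is a verified
    local minimum of the energy model.

    ``complementarity`` in [0, 1] scales how much of the cavity lining is
    shape-matched to the ligand: the number of hydrophobic contact residues
    and whether the hydrogen-bond partner serine is present.
    """
    if not (10 <= n_residues <= 40):
        raise ValueError("n_residues must be in [10, 40]")
    if not (0.0 <= complementarity <= 1.0):
        raise ValueError("complementarity must be in [0, 1]")
    params = params or default_params()
    last_err = None
    for attempt in range(100):
        rng = np.random.default_rng([seed, attempt])
        try:
            return _assemble_pocket(seed, attempt, rng, n_residues,
                                    complementarity, params, _verify_trials)
        except StructureError as err:  # infeasible geometry; retry
            last_err = err
    raise StructureError(f"pocket generation failed after 100 attempts: {last_err}")


def _assemble_pocket(seed, attempt, rng, n_residues, complementarity, params,
                     verify_trials) -> SyntheticSystem:
    lig = make_active_ligand()
    # contact distance: slightly past the C–C Lennard-Jones optimum (3.82 Å)
    # and just outside the default 4 Å flexible-selection radius, so the
    # hydrophobic cage still contributes ~90% of the pair well depth but the
    # pocket stays rigid under the refinement protocol, as a crystal-like
    # scaffold should
    r_cc = 4.05

    residues = []
    num = 10

    def next_id():
        nonlocal num
        rid = ("A", num)
        num += 10  # gaps: pocket residues are independent chain segments
        return rid

    # hydrophobic contact residues aimed at ring carbons (skip C1/C2, which
    # carry the oxygens, and C4, which carries the tail)
    ring_slots = [2, 5]  # C3 and C6: the ring carbons not carrying O or tail
    n_contacts = int(np.clip(round(complementarity * 6), 2, 6))
    zhat = np.array([0.0, 0.0, 1.0])
    groove = math.radians(25.0)
    for k, slot in enumerate(ring_slots[: min(n_contacts, 2)]):
        atom = lig.atoms[slot]
        u = _unit(atom.position)  # radial, in plane
        u = _unit(rotate_points(u[None, :], np.zeros(3), zhat,
                                rng.uniform(-5.0, 5.0))[0])
        # a three-atom groove bracketing the ring plane: confines both the
        # vertical position and the tilt of the planted ring
        tips = [(f"CB{j + 2}",
                 atom.position + r_cc * (math.cos(groove) * u + s * math.sin(groove) * zhat))
                for j, s in enumerate((1.0, -1.0))]
        residues.append(_build_residue(next_id(), "ALA",
                                       atom.position + r_cc * u, u,
                                       extra_tips=tips))
    extra = n_contacts - 2
    # vertical cap(s) over the ring and over the tail carbon
    if extra >= 1:
        residues.append(_build_residue(next_id(), "ALA",
                                       np.array([0.0, 0.0, r_cc]), np.array([0.0, 0.0, 1.0])))
    if extra >= 2:
        c8 = lig.atoms[10].position
        u = _unit(c8 - np.array([0.0, 0.0, -1.0]))
        residues.append(_build_residue(next_id(), "ALA", c8 + r_cc * u, u))

    # hydrogen-bond partner serines for the acceptor oxygens
    ser_ids = []
    n_sers = (0 if complementarity < 0.3 else
              1 if complementarity < 0.5 else
              2 if complementarity < 0.7 else 3)
    for oi in (6, 7, 8)[:n_sers]:
        o_pos = lig.atoms[oi].position
        u = _unit(o_pos)
        og = o_pos + 2.9 * u
        ser = _build_residue(next_id(), "SER", og, u, tip_name="OG")
        # point the hydroxyl hydrogen at the acceptor for ideal D–H···A geometry
        hg = ser.atom("HG")
        hg.position = og + 1.0 * _unit(o_pos - og)
        hg.parent_position = og.copy()
        ser_ids.append(ser.res_id)
        residues.append(ser)

    # clamp residues holding the cofactor ring from below, so the cofactor
    # sits in a shallow cage of its own rather than on an open face
    cof = _make_cofactor()
    cof_center = np.mean([a.position for a in cof.atoms], axis=0)
    clamp_dirs = [_unit(cof.atoms[ci].position - cof_center) - 0.35 * zhat
                  for ci in (0, 2, 4)] + [np.array([0.15, 0.0, -1.0])]
    for k, d in enumerate(clamp_dirs):
        if len(residues) >= n_residues - 1:
            break
        d = _unit(d)
        anchor = cof_center if k == len(clamp_dirs) - 1 else cof.atoms[(0, 2, 4)[k]].position
        tip = anchor + r_cc * d
        if not _clear_of(tip, residues, lig, cof, min_dist=3.2):
            continue
        residues.append(_build_residue(next_id(), "ALA", tip, d))

    # filler residues on an outer shell (golden-angle spiral, avoiding the
    # cofactor zone below the cavity)
    i = 0
    phase = rng.uniform(0.0, 2.0 * math.pi)
    while len(residues) < n_residues:
        z = 1.0 - (i % 23) / 11.5
        shell_r = 7.5 + 0.2 * (i // 23)  # widen the shell once a layer is full
        i += 1
        if i > 2000:
            raise StructureError("could not place filler residues")
        if z < -0.45:
            continue  # leave the cofactor face open
        r_xy = math.sqrt(max(0.0, 1.0 - z * z))
        th = _FIB_INC * i + phase
        u = np.array([r_xy * math.cos(th), r_xy * math.sin(th), z])
        tip = shell_r * u
        # keep fillers clear of everything already placed
        placed = [a.position for r in residues for a in r.atoms]
        placed += [a.position for a in lig.atoms]
        if placed and min(np.linalg.norm(tip - p) for p in placed) < 3.4:
            continue
        residues.append(_build_residue(next_id(), "ALA", tip, u))

    # the catalytic water's coordinates are set by a global site search once
    # the rest of the complex is assembled (below)
    water = _make_catalytic_water(np.array([0.0, 0.0, 30.0]))

    chain = Component(kind="protein_chain", name="A", residues=residues)
    lig_comp = Component(kind="ligand", name=lig.name, atoms=lig.atoms, ligand=lig)
    s = Structure(
        components=[chain, cof, water, lig_comp],
        provenance=f"synthetic(seed={seed},attempt={attempt})",
        active_residue_ids=ser_ids,
    )

    # polish every degree of freedom the refinement protocol can move —
    # hetero components, ligand torsions, and the dihedrals of residues in
    # the flexible zone — into a rest point of the energy model, then
    # basin-hop from perturbed starts so the planted pose is the deepest
    # basin in reach; record the resulting ligand pose as the planted pose
    def _dbg(stage):
        if logger.isEnabledFor(logging.DEBUG):
            e = ScoringContext(s, params).evaluate()
            logger.debug("stage %-12s E=%8.3f (lj %7.3f coul %6.3f hb %7.3f tor %6.3f)",
                         stage, e.total, e.lj, e.coulomb, e.hbond, e.torsion)

    _dbg("assembled")
    _optimize_water_site(s, params)
    _dbg("water")
    s = minimize_energy(s, _protocol_dofs(s), params, max_iter=150, gtol=1e-6)
    _dbg("minimized")
    s = _basin_polish(s, params, rng)
    _dbg("basin")
    s = _repack_flexible(s, params)
    s = minimize_energy(s, _protocol_dofs(s), params, max_iter=200, gtol=1e-7)
    _dbg("repack+min")
    # final authority: a short run of the refinement protocol itself; if its
    # stochastic search still digs up a deeper basin, that basin (repacked
    # and re-minimized) becomes the planted state, so the landscape the
    # generator advertises agrees with what the protocol can reach
    from .refine import RefinementConfig, refine_to_convergence
    mc_cfg = RefinementConfig(outer_cycles=2, mid_blocks=2, inner_steps=2,
                              n_decoys=4, max_K=2, convergence_tol=0.01,
                              traj_min_iters=10,
                              seed=int(rng.integers(2 ** 31)))
    mc_best, trace = refine_to_convergence(s, mc_cfg, params)
    e_cur = ScoringContext(s, params).evaluate().total
    if trace.cycle_energies[-1] < e_cur - 1e-3:
        cand = _repack_flexible(mc_best, params)
        cand = minimize_energy(cand, _protocol_dofs(cand), params,
                               max_iter=200, gtol=1e-7)
        if ScoringContext(cand, params).evaluate().total < e_cur:
            s = cand
    _dbg("mc-adopted")
    planted = s.ligand.coords()

    sys = SyntheticSystem(
        structure=s,
        planted_pose=planted,
        seed=seed,
        descriptor={
            "n_residues": n_residues,
            "complementarity": complementarity,
            "n_contacts": n_contacts,
            "n_hbond_partners": len(ser_ids),
            "attempt": attempt,
        },
    )
    _verify_local_minimum(sys, params, rng, trials=verify_trials)
    return sys


def _protocol_dofs(s: Structure, radius: float = 4.5) -> "DofSpec":
    """All DOF the refinement protocol samples: hetero-component rigid
    bodies, ligand torsions, and φ/ψ/χ of every residue the flexible-zone
    rule can select (with a margin over the default 4 Å radius)."""
    from .moves import select_flexible_residues, _n_chis
    dof = pose_dofs(s)
    flex = select_flexible_residues(s, first_cycle=True, radius=radius)
    for res in s.protein_residues():
        if res.res_id in flex:
            dof.residue_dihedrals.append((res.res_id, "phi"))
            dof.residue_dihedrals.append((res.res_id, "psi"))
            for k in range(_n_chis(res)):
                dof.residue_dihedrals.append((res.res_id, ("chi", k)))
    return dof


def _basin_polish(s: Structure, params: EnergyParams, rng: np.random.Generator,
                  n_trials: int = 5, max_adoptions: int = 6) -> Structure:
    """Basin-hop over the mobile components (ligand pose, catalytic water,
    cofactor): minimize from randomly displaced starts and adopt any deeper
    basin, so the recorded planted complex is the deepest rest point the
    search can reach."""
    e_best = ScoringContext(s, params).evaluate().total
    adoptions = 0
    trial = 0
    while trial < n_trials and adoptions < max_adoptions:
        trial += 1
        # jiggle every mobile component, the water hardest (it migrates most)
        probe = SyntheticSystem(structure=s, planted_pose=s.ligand.coords(), seed=0)
        start = perturb_pose(probe, float(rng.uniform(0.3, 1.5)),
                             seed=int(rng.integers(2 ** 31)))
        for comp in start.components:
            if comp.kind in ("catalytic_water", "cofactor"):
                mag = 3.0 if comp.kind == "catalytic_water" else 1.0
                shift = rng.normal(size=3)
                shift *= rng.uniform(0.0, mag) / np.linalg.norm(shift)
                for a in comp.all_atoms():
                    a.position = a.position + shift
                    if a.parent_position is not None:
                        a.parent_position = a.parent_position + shift
        # trials run the protocol's own relaxation: continuous pose descent
        # plus a discrete repack of the flexible side chains, then a final
        # pose descent
        cand = minimize_energy(start, pose_dofs(start), params,
                               max_iter=120, gtol=1e-6)
        cand = _repack_flexible(cand, params)
        cand = minimize_energy(cand, pose_dofs(cand), params,
                               max_iter=60, gtol=1e-6)
        e = ScoringContext(cand, params).evaluate().total
        if e < e_best - 1e-6:
            s, e_best = cand, e
            adoptions += 1
            trial = 0  # restart the probe budget from the new basin
    return s


def _optimize_water_site(s: Structure, params: EnergyParams) -> None:
    """Place the catalytic water at its best hydrogen-bonding site.

    Candidate sites are generated off every acceptor's open face; each is
    relaxed by a short rigid-body minimization of the water and the lowest
    total energy wins.  Without this search, the refinement MC relocates a
    badly parked water and undercuts the planted energy.
    """
    from .energy import ScoringContext
    from .refine import DofSpec, minimize_energy
    wi = next(i for i, c in enumerate(s.components) if c.kind == "catalytic_water")
    comp = s.components[wi]
    others = [a for c in s.components for a in c.all_atoms()
              if c.kind != "catalytic_water"]
    pos_others = np.array([a.position for a in others])
    centroid = pos_others.mean(axis=0)
    acceptors = [a for a in others
                 if not a.is_hydrogen and a.hb_role in ("acceptor", "both")]
    ctx = ScoringContext(s, params)
    dof = DofSpec(rigid_components=[wi])
    best_e, best_coords = np.inf, None

    def set_water(o_pos, target):
        o, h1, h2 = comp.atoms
        o.position = np.asarray(o_pos, float)
        toward = _unit(np.asarray(target) - o.position)
        h1.position = o.position + 0.96 * toward
        e1, _ = _perp_frame(toward)
        half = math.radians(104.5)
        h2.position = o.position + 0.96 * (toward * math.cos(half) + e1 * math.sin(half))
        for h in (h1, h2):
            h.parent_position = o.position.copy()

    for A in acceptors:
        d = A.position - centroid
        n = np.linalg.norm(d)
        radial = d / n if n > 1e-6 else np.array([0.0, 0.0, 1.0])
        e1, e2 = _perp_frame(radial)
        directions = [radial]
        for axis in (e1, e2):
            for ang in (55.0, -55.0):
                directions.append(
                    rotate_points(radial[None, :], np.zeros(3), axis, ang)[0])
        for direction in directions:
            cand = A.position + 2.9 * direction
            if np.min(np.linalg.norm(pos_others - cand, axis=1)) < 2.2:
                continue
            set_water(cand, A.position)
            minimize_energy(s, dof, params, max_iter=40, gtol=1e-5, ctx=ctx)
            e = ctx.evaluate().total
            if e < best_e:
                best_e = e
                best_coords = [a.position.copy() for a in comp.atoms]
    if best_coords is not None:
        for a, xyz in zip(comp.atoms, best_coords):
            a.position = xyz
        o = comp.atoms[0]
        for h in comp.atoms[1:]:
            h.parent_position = o.position.copy()


def _repack_flexible(s: Structure, params: EnergyParams) -> Structure:
    from .moves import default_rotamer_library, repack_side_chains, select_flexible_residues
    flex = select_flexible_residues(s, first_cycle=True, radius=4.5)
    if not flex:
        return s
    return repack_side_chains(s, flex, default_rotamer_library(), params)


def _verify_local_minimum(sys: SyntheticSystem, params: EnergyParams,
                          rng: np.random.Generator, trials: int = 60,
                          magnitude: float = 0.3, min_fraction: float = 0.95) -> None:
    ctx = ScoringContext(sys.structure, params)
    e0 = ctx.evaluate().total
    n_up = 0
    for t in range(trials):
        pert = perturb_pose(sys, magnitude, seed=int(rng.integers(2 ** 31)))
        e = ScoringContext(pert, params).evaluate().total
        if e > e0:
            n_up += 1
    if n_up < math.ceil(min_fraction * trials):
        raise StructureError(
            f"planted pose not a robust local minimum ({n_up}/{trials} uphill)"
        )


# --------------------------------------------------------------------------
# decoy ligands
# --------------------------------------------------------------------------

def _embed_tree(g: nx.Graph, rng: np.random.Generator) -> dict:
    """Crude 3D embedding of an acyclic molecule: 1.52 Å bonds, ~111° angles,
    randomized placement directions (the caller checks for self-collisions
    and retries)."""
    pos = {}
    root = 0
    pos[root] = np.zeros(3)
    order = list(nx.bfs_edges(g, root))
    for parent, child in order:
        grand = next((p for p, c in order if c == parent), None)
        if grand is None:
            d = np.array([1.0, 0.0, 0.0])
        else:
            back = _unit(pos[parent] - pos[grand])
            e1, e2 = _perp_frame(back)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            side = math.cos(phi) * e1 + math.sin(phi) * e2
            d = _unit(back * math.cos(math.radians(69.0))
                      + side * math.sin(math.radians(69.0)))
        pos[child] = pos[parent] + 1.52 * d
    return pos


def _embedding_clash_free(g: nx.Graph, pos: dict, min_dist: float = 2.2) -> bool:
    spl = dict(nx.all_pairs_shortest_path_length(g, cutoff=1))
    nodes = sorted(g.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if v in spl.get(u, {}):
                continue  # bonded pair
            if np.linalg.norm(pos[u] - pos[v]) < min_dist:
                return False
    return True


def make_decoy_ligands(active: Ligand, n: int = 6, seed: int = 0) -> list:
    """Property-matched decoy ligands: heavy-atom count within ±2 of the
    active, same net charge, different (non-isomorphic) bond topology and a
    scrambled polar-atom position."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    active_heavy = len(active.heavy_indices())
    net_charge = round(sum(a.partial_charge for a in active.atoms), 6)
    g_active = _element_graph(active)
    decoys = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        for _attempt in range(50):
            m = int(np.clip(active_heavy + rng.integers(-2, 3), 4, active_heavy + 2))
            g = nx.path_graph(m)
            # add a random branch to vary the topology
            if m >= 5 and rng.random() < 0.7:
                node = int(rng.integers(1, m - 2))
                g.add_edge(node, m)
                m += 1
            elements = ["C"] * g.number_of_nodes()
            # scrambled polar-atom placement: the active's oxygen count at
            # random, pairwise non-adjacent interior nodes
            n_oxy = sum(1 for a in active.atoms
                        if a.element == "O" and not a.is_hydrogen)
            interior = [v for v in g.nodes if g.degree[v] >= 2]
            rng.shuffle(interior)
            o_nodes = []
            for v in interior:
                if len(o_nodes) == n_oxy:
                    break
                if all(not g.has_edge(v, o) for o in o_nodes):
                    o_nodes.append(v)
            for v in o_nodes:
                elements[v] = "O"
            pos = None
            for _try in range(40):
                cand_pos = _embed_tree(g, rng)
                if _embedding_clash_free(g, cand_pos):
                    pos = cand_pos
                    break
            if pos is None:
                continue  # re-draw the topology
            atoms = []
            for v in sorted(g.nodes):
                el = elements[v]
                q = -0.40 if el == "O" else 0.0
                atoms.append(Atom(
                    name=f"{el}{v + 1}", element=el, position=pos[v],
                    partial_charge=q, vdw_radius=ELEMENT_VDW[el],
                    hb_role="acceptor" if el == "O" else "none",
                ))
            # neutralize on carbon neighbours, then match the active's net charge
            for v in o_nodes:
                nb = next(u for u in g.neighbors(v) if elements[u] == "C")
                atoms[nb].partial_charge += 0.40
            atoms[-1].partial_charge += net_charge - round(
                sum(a.partial_charge for a in atoms), 6)
            bonds = [(u, v, 1) for u, v in g.edges]
            lig = Ligand(atoms=atoms, bonds=bonds, name=f"DC{i + 1:02d}")
            lig.rotatable_torsions = _derive_rotatable_torsions(lig)
            _relax_ligand_torsions(lig)
            if not nx.is_isomorphic(
                _element_graph(lig), g_active,
                node_match=lambda a, b: a["el"] == b["el"],
            ):
                decoys.append(lig)
                break
        else:
            raise StructureError("could not generate a non-isomorphic decoy")
    return decoys


def _relax_ligand_torsions(lig: Ligand, params: Optional[EnergyParams] = None) -> None:
    """Bring a freshly embedded ligand to its own internal torsion minimum,
    so screens start from strain-free inputs (internal strain would
    otherwise leak into binding energies as the complex relaxes it)."""
    if not lig.rotatable_torsions:
        return
    params = params or default_params()
    comp = Component(kind="ligand", name=lig.name, atoms=lig.atoms, ligand=lig)
    pseudo = Structure(components=[comp], provenance="ligand-only")
    out = minimize_energy(pseudo, DofSpec(ligand_torsions=True), params,
                          max_iter=80, gtol=1e-6)
    lig.set_coords(out.ligand.coords())


def _element_graph(lig: Ligand) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(lig.atoms):
        if not a.is_hydrogen:
            g.add_node(i, el=a.element)
    for i, j, *_ in lig.bonds:
        if not lig.atoms[i].is_hydrogen and not lig.atoms[j].is_hydrogen:
            g.add_edge(i, j)
    return g


# --------------------------------------------------------------------------
# pose perturbation
# --------------------------------------------------------------------------

def perturb_pose(sys: SyntheticSystem, magnitude: float, seed: int = 0) -> Structure:
    """Displace the ligand by a random rigid motion with expected heavy-atom
    RMSD ≈ ``magnitude`` Å; the rest of the system is untouched."""
    if magnitude < 0:
        raise ValueError("magnitude must be ≥ 0")
    out = sys.structure.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    lig = out.ligand
    heavy = lig.heavy_indices()
    coords = lig.coords()
    centroid = coords[heavy].mean(axis=0)

    target = magnitude / math.sqrt(2.0)
    axis = _unit(rng.normal(size=3))
    # rms distance of heavy atoms from the rotation axis
    rel = coords[heavy] - centroid
    perp = rel - np.outer(rel @ axis, axis)
    rho = math.sqrt(float(np.mean(np.sum(perp * perp, axis=1))))
    if rho > 1e-6:
        theta = 2.0 * math.degrees(math.asin(min(1.0, target / (2.0 * rho))))
        coords = rotate_points(coords, centroid, axis, theta)
        trans_mag = target
    else:
        trans_mag = magnitude
    coords = coords + _unit(rng.normal(size=3)) * trans_mag
    lig.set_coords(coords)
    return out
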