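"""Stochastic perturbation operators for the refinement trajectories.

Four families of moves act on a complex:

* **flexible-residue selection** — residues with any atom within a radius of
  the ligand (first refinement cycle: also of the cofactor, plus every
  residue declared catalytically active) become flexible;
* **small moves** — independent uniform perturbations of a residue's φ and ψ
  backbone dihedrals, carrying the side chain rigidly;
* **shear moves** — compensating ±δ perturbations on the ψ/φ pair of two
  adjacent residues, which limits downstream lever-arm displacement;
* **rigid-body perturbations** of the hetero components (ligand, cofactor,
  catalytic water), with one extra random torsion twist for the ligand.

Backbone rotations propagate to downstream residues when a ``downstream``
chain is supplied (standard kinematics, pivoting at the moved residue);
residues that are not sequence-contiguous simply have no downstream set.
Side-chain repacking is a greedy sweep over a small built-in rotamer
library, iterated to a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .energy import EnergyParams, ScoringContext, default_params
from .structures import (
    Component,
    Residue,
    Structure,
    StructureError,
    rotate_points,
    wrap_angle,
)

__all__ = [
    "MoveSpec",
    "RotamerLibrary",
    "default_rotamer_library",
    "select_flexible_residues",
    "apply_small_move",
    "apply_shear_move",
    "repack_side_chains",
    "perturb_component",
    "backbone_rotate",
    "set_chi",
]


@dataclass
class MoveSpec:
    """Magnitude caps for the stochastic moves (degrees / Å)."""

    small_max_angle: float = 5.0
    shear_max_angle: float = 5.0
    ligand_translation_max: float = 0.5
    ligand_rotation_max: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in ("small_max_angle", "shear_max_angle",
                  "ligand_translation_max", "ligand_rotation_max"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be ≥ 0")


@dataclass
class RotamerLibrary:
    """χ-angle rotamers with prior probabilities, keyed by residue name."""

    entries: dict = field(default_factory=dict)  # res_name -> [(chis tuple, prob)]

    def __post_init__(self) -> None:
        for name, rots in self.entries.items():
            total = sum(p for _, p in rots)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"rotamer priors for {name} sum to {total}, not 1")

    def rotamers(self, res_name: str) -> list:
        if res_name not in self.entries:
            raise KeyError(f"no rotamer entry for residue type {res_name!r}")
        return self.entries[res_name]


_ONE_CHI = {"SER", "CYS", "THR", "VAL"}
_TWO_CHI = {"LEU", "ILE", "PHE", "TYR", "TRP", "ASP", "ASN", "HIS", "MET", "GLU", "GLN",
            "LYS", "ARG"}
_NO_CHI = {"ALA", "GLY", "PRO"}


def load_rotamer_library(text: str) -> RotamerLibrary:
    """Parse a rotamer library from YAML text.

    Format: ``{RES_NAME: [[[chi1, chi2, ...], probability], ...], ...}``.
    """
    import yaml

    data = yaml.safe_load(text) or {}
    entries = {
        name: [(tuple(float(c) for c in chis), float(prob))
               for chis, prob in rots]
        for name, rots in data.items()
    }
    return RotamerLibrary(entries=entries)


def default_rotamer_library() -> RotamerLibrary:
    """Minimal staggered-rotamer library: χ at −60/60/180, uniform priors."""
    angles = (-60.0, 60.0, 180.0)
    entries: dict = {}
    for name in _NO_CHI:
        entries[name] = [((), 1.0)]
    for name in _ONE_CHI:
        entries[name] = [((a,), 1.0 / 3.0) for a in angles]
    for name in _TWO_CHI:
        combos = list(product(angles, angles))
        entries[name] = [(c, 1.0 / len(combos)) for c in combos]
    return RotamerLibrary(entries=entries)


# --------------------------------------------------------------------------
# flexible-residue selection
# --------------------------------------------------------------------------

def select_flexible_residues(
    s: Structure, first_cycle: bool, radius: float = 4.0
) -> set:
    """Residue ids whose atoms lie within ``radius`` Å of the ligand (and of
    the cofactor on the first cycle, plus all declared active residues)."""
    if radius <= 0:
        raise ValueError("selection radius must be positive")
    lig = s.component("ligand")
    if lig is None:
        raise StructureError("flexible-residue selection requires a ligand")
    targets = [a.position for a in lig.all_atoms()]
    if first_cycle:
        cof = s.component("cofactor")
        if cof is not None:
            targets.extend(a.position for a in cof.all_atoms())
    T = np.array(targets)
    selected = set()
    for res in s.protein_residues():
        d = cdist(res.coords(), T)
        if d.min() <= radius:
            selected.add(res.res_id)
    if first_cycle:
        selected.update(tuple(r) for r in s.active_residue_ids)
    return selected


# --------------------------------------------------------------------------
# backbone kinematics
# --------------------------------------------------------------------------

_SIDECHAIN_REMOTENESS = {"A": 1, "B": 2, "G": 3, "D": 4, "E": 5, "Z": 6, "H": 7}


def _remoteness(atom_name: str) -> Optional[int]:
    if len(atom_name) < 2:
        return None
    return _SIDECHAIN_REMOTENESS.get(atom_name[1])


def backbone_rotate(
    residues: Sequence[Residue], index: int, dphi: float, dpsi: float
) -> None:
    """Rotate φ and ψ of ``residues[index]`` in place, carrying the side chain
    rigidly and propagating the rotation to all later residues in the list."""
    res = residues[index]
    downstream_atoms = [a for r in residues[index + 1:] for a in r.atoms]
    n = res.atom("N")
    ca = res.atom("CA")
    if dphi != 0.0:
        axis = ca.position - n.position
        movers = [a for a in res.atoms
                  if a.name not in ("N", "H", "CA")] + downstream_atoms
        _rotate_atoms(movers, n.position, axis, dphi)
        res.phi = wrap_angle(res.phi + dphi)
    if dpsi != 0.0 and res.has_atom("C"):
        c = res.atom("C")
        axis = c.position - ca.position
        movers = [a for a in res.atoms if a.name in ("O", "OXT")] + downstream_atoms
        _rotate_atoms(movers, ca.position, axis, dpsi)
        res.psi = wrap_angle(res.psi + dpsi)


def _rotate_atoms(atoms: Iterable, origin: np.ndarray, axis: np.ndarray,
                  angle_deg: float) -> None:
    atoms = list(atoms)
    if not atoms:
        return
    pts = np.array([a.position for a in atoms])
    new = rotate_points(pts, origin, axis, angle_deg)
    for a, xyz in zip(atoms, new):
        a.position = xyz
    # polar hydrogens track their donor heavy atoms; callers refresh parents


def refresh_parent_positions(res_or_atoms) -> None:
    """Re-link polar hydrogens to their (possibly moved) donor heavy atoms."""
    atoms = res_or_atoms.atoms if hasattr(res_or_atoms, "atoms") else list(res_or_atoms)
    heavies = [a for a in atoms if not a.is_hydrogen]
    for h in atoms:
        if not h.is_hydrogen or h.parent_position is None:
            continue
        best, best_d = None, 1.35
        for b in heavies:
            d = float(np.linalg.norm(h.position - b.position))
            if d < best_d:
                best, best_d = b, d
        if best is not None:
            h.parent_position = best.position.copy()


def apply_small_move(
    r: Residue, spec: MoveSpec, rng: np.random.Generator,
    downstream: Sequence[Residue] = (), in_place: bool = False,
) -> Residue:
    """Perturb φ and ψ by independent uniform draws in [−max, +max].

    Returns the perturbed residue (a copy unless ``downstream`` residues are
    supplied or ``in_place`` is set, in which case the rotation mutates the
    given residues so downstream atoms move consistently).
    """
    dphi, dpsi = rng.uniform(-spec.small_max_angle, spec.small_max_angle, size=2)
    if not (downstream or in_place):
        r = r.copy()
    backbone_rotate([r, *downstream], 0, dphi, dpsi)
    refresh_parent_positions(r)
    return r


def apply_shear_move(
    r1: Residue, r2: Residue, spec: MoveSpec, rng: np.random.Generator,
    downstream: Sequence[Residue] = (), in_place: bool = False,
) -> tuple:
    """Compensating move: ψ of ``r1`` by −δ, φ of the adjacent ``r2`` by +δ."""
    if r1.res_id[0] != r2.res_id[0] or r2.res_id[1] - r1.res_id[1] != 1:
        raise StructureError(
            f"shear move requires adjacent residues, got {r1.res_id} / {r2.res_id}"
        )
    delta = float(rng.uniform(0.0, spec.shear_max_angle))
    if not (downstream or in_place):
        r1, r2 = r1.copy(), r2.copy()
    chain = [r1, r2, *downstream]
    backbone_rotate(chain, 0, 0.0, -delta)
    backbone_rotate(chain, 1, delta, 0.0)
    refresh_parent_positions(r1)
    refresh_parent_positions(r2)
    return r1, r2


# --------------------------------------------------------------------------
# side-chain repacking
# --------------------------------------------------------------------------

_CHI_AXES = [
    ("CA", "CB"),
    (("CB",), ("CG", "CG1", "OG", "OG1", "SG")),
]


def _chi_axis_atoms(res: Residue, chi_index: int):
    if chi_index == 0:
        return res.atom("CA"), res.atom("CB")
    prox_names, dist_names = _CHI_AXES[1]
    prox = res.atom("CB")
    dist = next((res.atom(n) for n in dist_names if res.has_atom(n)), None)
    if dist is None:
        raise StructureError(f"residue {res.res_id} has no χ{chi_index + 1} axis")
    return prox, dist


def set_chi(res: Residue, chi_index: int, angle: float) -> None:
    """Set side-chain dihedral χ(chi_index+1) to ``angle`` by rotating all
    atoms distal to the χ axis (backbone never moves)."""
    prox, dist = _chi_axis_atoms(res, chi_index)
    current = res.chis[chi_index] if chi_index < len(res.chis) else 0.0
    delta = wrap_angle(angle - current)
    if delta == 0.0:
        return
    cut = _remoteness(dist.name) or 0
    movers = []
    for a in res.atoms:
        rem = _remoteness(a.name)
        if rem is not None and rem > cut and a.name not in ("N", "CA", "C", "O", "H", "OXT"):
            movers.append(a)
        elif a.is_hydrogen and rem is not None and rem >= cut and a is not dist:
            movers.append(a)
    _rotate_atoms(movers, prox.position, dist.position - prox.position, delta)
    while len(res.chis) <= chi_index:
        res.chis.append(0.0)
    res.chis[chi_index] = wrap_angle(angle)
    refresh_parent_positions(res)


_G_NAMES = ("CG", "CG1", "OG", "OG1", "SG")
_D_NAMES = ("CD", "CD1", "OD1", "ND1", "SD", "ND2")


def _n_chis(res: Residue) -> int:
    if not res.has_atom("CB") or not any(res.has_atom(n) for n in _G_NAMES):
        return 0
    return 2 if any(res.has_atom(n) for n in _D_NAMES) else 1


def repack_side_chains(
    s: Structure,
    residues: Iterable,
    lib: RotamerLibrary,
    p: Optional[EnergyParams] = None,
    max_sweeps: int = 5,
    ctx: Optional[ScoringContext] = None,
) -> Structure:
    """Greedy rotamer optimization of the listed residues.

    Each residue is assigned the library rotamer minimizing its interaction
    energy with the fixed environment; sweeps repeat until a fixed point
    (at most ``max_sweeps``).  Backbone atoms never move.  Returns a new
    structure unless a live scoring context is supplied, in which case the
    context's structure is repacked in place.
    """
    p = p or default_params()
    in_place = ctx is not None
    if not in_place:
        s = s.copy()
        ctx = ScoringContext(s, p)
    target_ids = [tuple(r) for r in residues]
    res_map = {r.res_id: r for r in ctx.structure.protein_residues()}
    for rid in target_ids:
        if rid not in res_map:
            raise KeyError(f"no residue {rid}")
        lib.rotamers(res_map[rid].res_name)  # raises on missing entry

    coords = ctx.gather_coords()
    for _ in range(max_sweeps):
        changed = False
        for rid in sorted(target_ids):
            res = res_map[rid]
            nchi = _n_chis(res)
            if nchi == 0:
                continue
            idx = ctx.residue_index[rid]
            best_e, best_chis = None, None
            # the input conformation competes as a candidate rotamer, so a
            # side chain already better-placed than any library entry stays
            candidates = [tuple(res.chis[:nchi])]
            candidates += [chis[:nchi] for chis, _prob in lib.rotamers(res.res_name)]
            for chis in candidates:
                for k, ang in enumerate(chis):
                    set_chi(res, k, ang)
                for gi, a in zip(idx, res.atoms):
                    coords[gi] = a.position
                e = ctx.subset_energy(idx, coords)
                if best_e is None or e < best_e - 1e-12:
                    best_e, best_chis = e, chis
            best_chis = best_chis or ()
            current = tuple(res.chis[:len(best_chis)])
            if tuple(best_chis) != current:
                changed = True
            for k, ang in enumerate(best_chis):
                set_chi(res, k, ang)
            for gi, a in zip(idx, res.atoms):
                coords[gi] = a.position
        if not changed:
            break
    return ctx.structure


# --------------------------------------------------------------------------
# hetero-component rigid-body perturbation
# --------------------------------------------------------------------------

_MOBILE_KINDS = ("ligand", "cofactor", "catalytic_water")


def perturb_component(
    c: Component, spec: MoveSpec, rng: np.random.Generator
) -> Component:
    """Rigid-body jiggle of a hetero component: random translation of norm
    ≤ ``ligand_translation_max`` plus rotation about the centroid of angle
    ≤ ``ligand_rotation_max``; a ligand additionally receives one random
    rotatable-torsion twist."""
    if c.kind not in _MOBILE_KINDS:
        raise StructureError(f"cannot perturb component of kind {c.kind!r}")
    out = c.copy()
    atoms = out.all_atoms()
    pts = np.array([a.position for a in atoms])
    centroid = pts.mean(axis=0)

    direction = rng.normal(size=3)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    shift = direction * rng.uniform(0.0, spec.ligand_translation_max)

    axis = rng.normal(size=3)
    nrm = np.linalg.norm(axis)
    axis = axis / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    angle = float(rng.uniform(0.0, spec.ligand_rotation_max))

    new = rotate_points(pts, centroid, axis, angle) + shift
    for a, xyz in zip(atoms, new):
        a.position = xyz
    if out.kind == "ligand" and out.ligand is not None and out.ligand.rotatable_torsions:
        k = int(rng.integers(len(out.ligand.rotatable_torsions)))
        twist = float(rng.uniform(-spec.ligand_rotation_max, spec.ligand_rotation_max))
        _twist_ligand_torsion(out.ligand, k, twist)
    refresh_parent_positions(atoms)
    return out


def _twist_ligand_torsion(lig, torsion_index: int, delta_deg: float) -> None:
    """Rotate the distal side of a rotatable bond by ``delta_deg``."""
    import networkx as nx

    a, b, c_, d = lig.rotatable_torsions[torsion_index]
    g = lig.graph()
    g.remove_edge(b, c_)
    distal = nx.node_connected_component(g, c_)
    origin = lig.atoms[b].position
    axis = lig.atoms[c_].position - origin
    movers = [lig.atoms[i] for i in distal if i != c_]
    _rotate_atoms(movers, origin, axis, delta_deg)
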