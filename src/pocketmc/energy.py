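"""Stand-in molecular mechanics scoring function (kcal/mol).

Four terms, each weighted:

* Lennard-Jones 12-6 with per-element ε/σ tables and Lorentz–Berthelot
  combination;
* screened Coulomb ``k q_i q_j / (ε(r) r)`` with a distance-dependent
  dielectric ``ε(r) = 4r`` and ``k = 332.0637`` kcal·Å/(mol·e²);
* a directional hydrogen-bond term: a 10-12 well between the donor heavy
  atom D and the acceptor A, switched on only when the D–H···A angle clears
  a cutoff (the polar hydrogen carries the donor geometry);
* a threefold cosine torsion prior with minima at the staggered rotamers,
  applied to side-chain χ angles and ligand rotatable torsions.

All nonbonded terms are tapered smoothly to zero over the last Å before the
cutoff.  Pairs closer than three bonds within a component are excluded.
This is an intentionally small, self-contained score: it supports relative
ranking and protocol mechanics, not absolute affinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .structures import (
    Atom,
    Structure,
    Ligand,
    StructureError,
    infer_bonds,
    dihedral_angle,
)

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "default_params",
    "pair_energy",
    "complex_energy",
    "ligand_energy",
    "ScoringContext",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)


@dataclass
class EnergyParams:
    """Parameters of the scoring function; all energies kcal/mol, lengths Å."""

    lj_epsilon: dict = field(default_factory=lambda: {
        "C": 0.12, "N": 0.16, "O": 0.18, "S": 0.22, "P": 0.20, "H": 0.015,
    })
    lj_sigma: dict = field(default_factory=lambda: {
        "C": 3.40, "N": 3.15, "O": 3.00, "S": 3.55, "P": 3.70, "H": 1.00,
    })
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric_factor: float = 4.0        # ε(r) = dielectric_factor · r
    hbond_well_depth: float = 2.0
    hbond_r0: float = 2.9                 # D···A distance of the 10-12 minimum
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 120.0     # minimum D–H···A angle, degrees
    nonbonded_cutoff: float = 9.0
    switch_width: float = 1.0
    torsion_barrier: float = 1.0
    term_weights: dict = field(default_factory=lambda: {
        "lj": 1.0, "coulomb": 1.0, "hbond": 1.0, "torsion": 1.0,
    })

    def __post_init__(self) -> None:
        if self.hbond_well_depth <= 0 or self.hbond_distance_cutoff <= 0:
            raise ValueError("H-bond well depth and cutoff must be positive")
        if self.nonbonded_cutoff <= 0 or self.switch_width <= 0:
            raise ValueError("cutoffs must be positive")
        if not all(np.isfinite(list(self.term_weights.values()))):
            raise ValueError("term weights must be finite")

    def eps_of(self, element: str) -> float:
        return self.lj_epsilon.get(element.upper(), 0.10)

    def sigma_of(self, element: str) -> float:
        return self.lj_sigma.get(element.upper(), 3.4)


def default_params() -> EnergyParams:
    return EnergyParams()


@dataclass
class EnergyBreakdown:
    lj: float = 0.0
    coulomb: float = 0.0
    hbond: float = 0.0
    torsion: float = 0.0
    total: float = 0.0

    @classmethod
    def assemble(cls, lj: float, coulomb: float, hbond: float, torsion: float,
                 weights: dict) -> "EnergyBreakdown":
        total = (weights["lj"] * lj + weights["coulomb"] * coulomb
                 + weights["hbond"] * hbond + weights["torsion"] * torsion)
        return cls(lj=lj, coulomb=coulomb, hbond=hbond, torsion=torsion, total=total)

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            lj=self.lj + other.lj,
            coulomb=self.coulomb + other.coulomb,
            hbond=self.hbond + other.hbond,
            torsion=self.torsion + other.torsion,
            total=self.total + other.total,
        )


def _switch(r: float, cutoff: float, width: float) -> float:
    if r >= cutoff:
        return 0.0
    if r <= cutoff - width:
        return 1.0
    t = (cutoff - r) / width
    return t * t * (3.0 - 2.0 * t)


def pair_energy(a: Atom, b: Atom, p: EnergyParams) -> EnergyBreakdown:
    """Nonbonded interaction energy of a single atom pair.

    H-bond geometry is evaluated when one partner is a polar hydrogen that
    knows its donor heavy-atom position and the other is an acceptor.
    """
    if a is b:
        raise ValueError("pair_energy requires two distinct atoms")
    dr = a.position - b.position
    r = float(np.linalg.norm(dr))
    if r == 0.0:
        raise ZeroDivisionError("coincident atoms: r = 0")
    if r >= p.nonbonded_cutoff:
        return EnergyBreakdown()
    sw = _switch(r, p.nonbonded_cutoff, p.switch_width)

    eps = math.sqrt(p.eps_of(a.element) * p.eps_of(b.element))
    sig = 0.5 * (p.sigma_of(a.element) + p.sigma_of(b.element))
    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6) * sw

    coul = 0.0
    if a.partial_charge != 0.0 and b.partial_charge != 0.0:
        coul = (p.coulomb_constant * a.partial_charge * b.partial_charge
                / (p.dielectric_factor * r * r)) * sw

    hb = 0.0
    for h, acc in ((a, b), (b, a)):
        if (h.is_hydrogen and h.parent_position is not None
                and not acc.is_hydrogen and acc.hb_role in ("acceptor", "both")):
            hb += _hbond_energy(h.parent_position, h.position, acc.position, p)
    return EnergyBreakdown.assemble(lj, coul, hb, 0.0, p.term_weights)


def _hbond_energy(d_pos, h_pos, a_pos, p: EnergyParams) -> float:
    r_da = float(np.linalg.norm(np.asarray(d_pos) - np.asarray(a_pos)))
    if r_da == 0.0 or r_da > p.hbond_distance_cutoff:
        return 0.0
    v1 = np.asarray(d_pos) - np.asarray(h_pos)
    v2 = np.asarray(a_pos) - np.asarray(h_pos)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    cosang = float(np.dot(v1, v2) / (n1 * n2))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    if angle < p.hbond_angle_cutoff:
        return 0.0
    q = p.hbond_r0 / r_da
    e = p.hbond_well_depth * (5.0 * q ** 12 - 6.0 * q ** 10)
    return e * _switch(r_da, p.hbond_distance_cutoff, min(p.switch_width, 0.5))


# --------------------------------------------------------------------------
# fused scoring kernels
# --------------------------------------------------------------------------

@njit(cache=False)
def _kernel_nonbonded(coords, pi, pj, eps4, sig6, qqk, cutoff, width):
    lj = 0.0
    coul = 0.0
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        if r >= cutoff:
            continue
        t = (cutoff - r) / width
        if t > 1.0:
            t = 1.0
        sw = t * t * (3.0 - 2.0 * t)
        sr6 = sig6[k] / (r2 * r2 * r2)
        lj += eps4[k] * (sr6 * sr6 - sr6) * sw
        coul += qqk[k] / r2 * sw
    return lj, coul


@njit(cache=False)
def _kernel_hbond(coords, triples, depth, r0, dcut, cos_cut, w, n_atoms):
    # a donor hydrogen is saturated by its best acceptor: per H, repulsive
    # close contacts all count, but only the deepest attractive bond does
    total = 0.0
    best_neg = np.zeros(n_atoms)
    for k in range(triples.shape[0]):
        d_i, h_i, a_i = triples[k, 0], triples[k, 1], triples[k, 2]
        dx = coords[d_i, 0] - coords[a_i, 0]
        dy = coords[d_i, 1] - coords[a_i, 1]
        dz = coords[d_i, 2] - coords[a_i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= 0.0 or r > dcut:
            continue
        v1x = coords[d_i, 0] - coords[h_i, 0]
        v1y = coords[d_i, 1] - coords[h_i, 1]
        v1z = coords[d_i, 2] - coords[h_i, 2]
        v2x = coords[a_i, 0] - coords[h_i, 0]
        v2y = coords[a_i, 1] - coords[h_i, 1]
        v2z = coords[a_i, 2] - coords[h_i, 2]
        n1 = math.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        n2 = math.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
        if n1 == 0.0 or n2 == 0.0:
            continue
        c = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
        if c > cos_cut:  # angle below the cutoff
            continue
        q2 = (r0 / r) ** 2
        q10 = q2 ** 5
        t = (dcut - r) / w
        if t > 1.0:
            t = 1.0
        sw = t * t * (3.0 - 2.0 * t)
        e = depth * (5.0 * q10 * q2 - 6.0 * q10) * sw
        if e >= 0.0:
            total += e
        elif e < best_neg[h_i]:
            best_neg[h_i] = e
    for i in range(n_atoms):
        total += best_neg[i]
    return total


@njit(cache=False)
def _kernel_torsion(coords, quads, barrier):
    total = 0.0
    for k in range(quads.shape[0]):
        a, b, c_, d = quads[k, 0], quads[k, 1], quads[k, 2], quads[k, 3]
        b0x = coords[b, 0] - coords[a, 0]
        b0y = coords[b, 1] - coords[a, 1]
        b0z = coords[b, 2] - coords[a, 2]
        b1x = coords[c_, 0] - coords[b, 0]
        b1y = coords[c_, 1] - coords[b, 1]
        b1z = coords[c_, 2] - coords[b, 2]
        b2x = coords[d, 0] - coords[c_, 0]
        b2y = coords[d, 1] - coords[c_, 1]
        b2z = coords[d, 2] - coords[c_, 2]
        n1x = b0y * b1z - b0z * b1y
        n1y = b0z * b1x - b0x * b1z
        n1z = b0x * b1y - b0y * b1x
        n2x = b1y * b2z - b1z * b2y
        n2y = b1z * b2x - b1x * b2z
        n2z = b1x * b2y - b1y * b2x
        m1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
        m2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
        if m1 == 0.0 or m2 == 0.0:
            continue
        c = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        cos3 = 4.0 * c ** 3 - 3.0 * c  # cos(3θ); cos is even, sign is moot
        total += 0.5 * barrier * (1.0 + cos3)
    return total


# --------------------------------------------------------------------------
# vectorised whole-complex scoring
# --------------------------------------------------------------------------

class ScoringContext:
    """Precomputed arrays for repeated scoring of one complex topology.

    The context is built once from a Structure; afterwards any coordinate
    array with the same atom ordering can be evaluated cheaply.  Index
    groups per component/residue are exposed so that the move and
    minimization machinery can act on coordinate slices directly.
    """

    def __init__(self, structure: Structure, params: EnergyParams):
        self.params = params
        self.structure = structure
        atoms: list = []
        self.residue_index: dict = {}       # res_id -> (slice of atom indices)
        self.component_index: dict = {}     # position in components -> index list
        for ci, comp in enumerate(structure.components):
            idx = []
            if comp.kind == "protein_chain":
                for res in comp.residues:
                    ridx = list(range(len(atoms), len(atoms) + len(res.atoms)))
                    self.residue_index[res.res_id] = ridx
                    atoms.extend(res.atoms)
                    idx.extend(ridx)
            else:
                idx = list(range(len(atoms), len(atoms) + len(comp.all_atoms())))
                atoms.extend(comp.all_atoms())
            self.component_index[ci] = idx
        self.atoms = atoms
        n = len(atoms)
        self.n = n
        for a in atoms:
            if not np.isfinite(a.partial_charge) or not np.isfinite(a.vdw_radius):
                raise StructureError(f"unparameterized atom {a.name}")

        q = np.array([a.partial_charge for a in atoms])
        eps = np.array([params.eps_of(a.element) for a in atoms])
        sig = np.array([params.sigma_of(a.element) for a in atoms])

        excl = self._build_exclusions(structure)
        self.pair_mask = ~excl
        self.pair_mask[np.tril_indices(n)] = False
        self.excl = excl

        # flattened nonbonded pair list (upper triangle, exclusions removed)
        pi, pj = np.nonzero(self.pair_mask)
        self.pair_i, self.pair_j = pi, pj
        self.pair_eps4 = 4.0 * np.sqrt(eps[pi] * eps[pj])
        self.pair_sig6 = (0.5 * (sig[pi] + sig[pj])) ** 6
        self.pair_qqk = (params.coulomb_constant * q[pi] * q[pj]
                         / params.dielectric_factor)

        # H-bond machinery: (donor heavy index, polar H index) pairs; acceptors
        self.donor_pairs = self._find_donor_pairs(structure)
        self.acceptors = np.array(
            [i for i, a in enumerate(atoms)
             if not a.is_hydrogen and a.hb_role in ("acceptor", "both")],
            dtype=int,
        )
        # flattened candidate (D, H, A) triples with the excluded ones removed
        trip = []
        for dheavy, h in self.donor_pairs:
            for acc in self.acceptors:
                if acc == dheavy or excl[h, acc] or excl[dheavy, acc]:
                    continue
                trip.append((dheavy, h, acc))
        self.hb_triples = np.array(trip, dtype=int).reshape(-1, 3)

        # torsion quadruples (global indices)
        self.torsions = self._collect_torsions(structure)
        self.torsion_arr = np.array(self.torsions, dtype=int).reshape(-1, 4)
        self._subset_cache: dict = {}

    # -- topology helpers --------------------------------------------------

    def _component_bonds(self, comp, base: int) -> list:
        if comp.kind == "ligand" and comp.ligand is not None:
            return [(base + i, base + j) for i, j, *_ in comp.ligand.bonds]
        return [(base + i, base + j) for i, j in infer_bonds(comp.all_atoms())]

    def _build_exclusions(self, structure: Structure) -> np.ndarray:
        n = self.n
        A = np.zeros((n, n), dtype=bool)
        for ci, comp in enumerate(structure.components):
            idx = self.component_index[ci]
            if not idx:
                continue
            base = idx[0]
            if comp.kind == "protein_chain":
                offset = base
                prev_c = None
                for res in comp.residues:
                    local = infer_bonds(res.atoms)
                    for i, j in local:
                        A[offset + i, offset + j] = A[offset + j, offset + i] = True
                    # peptide bond between consecutive residue numbers
                    names = [a.name for a in res.atoms]
                    if prev_c is not None and "N" in names:
                        pc_idx, pres = prev_c
                        if res.res_id[1] == pres + 1:
                            ni = offset + names.index("N")
                            A[pc_idx, ni] = A[ni, pc_idx] = True
                    prev_c = (
                        (offset + names.index("C"), res.res_id[1]) if "C" in names else None
                    )
                    offset += len(res.atoms)
            else:
                for i, j in self._component_bonds(comp, base):
                    A[i, j] = A[j, i] = True
        # exclude graph distance <= 2 (1-2 and 1-3)
        A2 = A | (A.astype(np.int8) @ A.astype(np.int8) > 0)
        np.fill_diagonal(A2, True)
        return A2

    def _find_donor_pairs(self, structure: Structure) -> np.ndarray:
        pairs = []
        pos = 0
        for comp in structure.components:
            if comp.kind == "protein_chain":
                groups = [res.atoms for res in comp.residues]
            else:
                groups = [comp.all_atoms()]
            for grp in groups:
                coords = np.array([a.position for a in grp])
                for i, a in enumerate(grp):
                    if not a.is_hydrogen:
                        continue
                    # bonded heavy atom = nearest heavy within bonding distance
                    best, best_d = None, 1.3
                    for j, b in enumerate(grp):
                        if b.is_hydrogen:
                            continue
                        d = float(np.linalg.norm(coords[i] - coords[j]))
                        if d < best_d:
                            best, best_d = j, d
                    if best is not None and grp[best].element in ("O", "N", "S"):
                        pairs.append((pos + best, pos + i))
                pos += len(grp)
        return np.array(pairs, dtype=int).reshape(-1, 2)

    _CHI_CHAIN = ["N", "CA", "CB", ("CG", "CG1", "OG", "OG1", "SG"),
                  ("CD", "CD1", "OD1", "ND1", "SD", "ND2"), ("CE", "NE", "OE1", "NE2")]

    def _collect_torsions(self, structure: Structure) -> list:
        quads = []
        for comp in structure.components:
            if comp.kind == "ligand" and comp.ligand is not None:
                base = self.component_index[structure.components.index(comp)][0]
                for (a, b, c, d) in comp.ligand.rotatable_torsions:
                    quads.append((base + a, base + b, base + c, base + d))
            elif comp.kind == "protein_chain":
                for res in comp.residues:
                    ridx = self.residue_index[res.res_id]
                    names = {a.name: gi for a, gi in zip(res.atoms, ridx)}
                    chain = []
                    for entry in self._CHI_CHAIN:
                        options = (entry,) if isinstance(entry, str) else entry
                        hit = next((names[o] for o in options if o in names), None)
                        if hit is None:
                            break
                        chain.append(hit)
                    for k in range(len(chain) - 3):
                        quads.append(tuple(chain[k:k + 4]))
        return quads

    # -- coordinates -------------------------------------------------------

    def gather_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def scatter_coords(self, coords: np.ndarray) -> None:
        for a, xyz in zip(self.atoms, coords):
            a.position = np.array(xyz, dtype=float)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, coords: Optional[np.ndarray] = None) -> EnergyBreakdown:
        p = self.params
        if coords is None:
            coords = self.gather_coords()
        if self.n == 0:
            return EnergyBreakdown()
        lj, coul = self._nonbonded(coords)
        hb = self._hbond_sum(coords)
        tor = self._torsion_sum(coords)
        return EnergyBreakdown.assemble(lj, coul, hb, tor, p.term_weights)

    def _nonbonded(self, coords: np.ndarray, arrays=None) -> tuple:
        p = self.params
        if arrays is None:
            arrays = (self.pair_i, self.pair_j, self.pair_eps4,
                      self.pair_sig6, self.pair_qqk)
        pi, pj, eps4, sig6, qqk = arrays
        if len(pi) == 0:
            return 0.0, 0.0
        return _kernel_nonbonded(np.ascontiguousarray(coords), pi, pj, eps4,
                                 sig6, qqk, p.nonbonded_cutoff, p.switch_width)

    def _hbond_sum(self, coords: np.ndarray, triples=None) -> float:
        p = self.params
        trip = self.hb_triples if triples is None else triples
        if len(trip) == 0:
            return 0.0
        cos_cut = math.cos(math.radians(p.hbond_angle_cutoff))
        return _kernel_hbond(np.ascontiguousarray(coords), trip,
                             p.hbond_well_depth, p.hbond_r0,
                             p.hbond_distance_cutoff, cos_cut,
                             min(p.switch_width, 0.5), self.n)

    def _torsion_sum(self, coords: np.ndarray, quads=None) -> float:
        p = self.params
        quads = self.torsion_arr if quads is None else quads
        if len(quads) == 0:
            return 0.0
        return _kernel_torsion(np.ascontiguousarray(coords), quads,
                               p.torsion_barrier)

    def subset_energy(self, indices: Sequence[int], coords: np.ndarray) -> float:
        """Weighted interaction energy of an atom subset with everything else
        (plus its internal nonbonded pairs, H-bonds and torsions it touches).

        Used by side-chain repacking, where only the relative energy across
        rotamers of one residue matters.  Selections are cached per subset.
        """
        key = tuple(sorted(int(i) for i in indices))
        sel = self._subset_cache.get(key)
        if sel is None:
            involve = np.zeros(self.n, dtype=bool)
            involve[list(key)] = True
            pmask = involve[self.pair_i] | involve[self.pair_j]
            arrays = tuple(np.ascontiguousarray(a[pmask]) for a in (
                self.pair_i, self.pair_j, self.pair_eps4,
                self.pair_sig6, self.pair_qqk))
            if len(self.hb_triples):
                hb = np.ascontiguousarray(
                    self.hb_triples[involve[self.hb_triples].any(axis=1)])
            else:
                hb = self.hb_triples
            if len(self.torsion_arr):
                tq = np.ascontiguousarray(
                    self.torsion_arr[involve[self.torsion_arr].any(axis=1)])
            else:
                tq = self.torsion_arr
            sel = (arrays, hb, tq)
            self._subset_cache[key] = sel
        arrays, hb_t, t_q = sel
        lj, coul = self._nonbonded(coords, arrays)
        hb = self._hbond_sum(coords, hb_t)
        tor = self._torsion_sum(coords, t_q)
        w = self.params.term_weights
        return w["lj"] * lj + w["coulomb"] * coul + w["hbond"] * hb + w["torsion"] * tor


def complex_energy(s: Structure, p: Optional[EnergyParams] = None) -> EnergyBreakdown:
    """Total energy of a prepared complex: all nonbonded pairs (1-2/1-3
    excluded) plus torsion priors.  Deterministic for fixed input."""
    p = p or default_params()
    if not s.components or not s.all_atoms():
        return EnergyBreakdown()
    ctx = ScoringContext(s, p)
    return ctx.evaluate()


def ligand_energy(l: Ligand, p: Optional[EnergyParams] = None) -> EnergyBreakdown:
    """Intra-ligand energy: nonbonded pairs ≥3 bonds apart plus torsion priors."""
    p = p or default_params()
    if len(l.atoms) > 1 and not l.bonds:
        raise StructureError("ligand has no bonds")
    g = l.graph()
    import networkx as nx
    if len(l.atoms) > 1 and not nx.is_connected(g):
        raise StructureError("ligand bond graph is disconnected")
    from .structures import Component, Structure as _Structure
    comp = Component(kind="ligand", name=l.name, atoms=l.atoms, ligand=l)
    pseudo = _Structure(components=[comp], provenance="ligand-only")
    if len(l.atoms) <= 1:
        return EnergyBreakdown()
    return ScoringContext(pseudo, p).evaluate()
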