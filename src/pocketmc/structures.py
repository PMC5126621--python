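"""Molecular structure containers, preparation rules and geometric primitives.

The package works on a deliberately small structural model: a protein is a
list of residues carrying explicit heavy atoms plus *polar* hydrogens only
(nonpolar hydrogens are implicit in slightly enlarged carbon radii), and the
hetero content of a complex is typed into cofactor, catalytic water, ligand
and "other" components.  Coordinates are Cartesian, in Å, in the frame of the
source PDB file; residue identity is the verbatim (chain, number) key.

PDB reading/writing is delegated to :mod:`gemmi`; MOL/SDF ligand files go
through :mod:`rdkit`.  Everything else in this module is plain numpy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Component",
    "Structure",
    "Ligand",
    "StructureError",
    "PDBParseError",
    "ParameterizationError",
    "read_pdb",
    "write_pdb",
    "prepare_apo",
    "read_ligand_sdf",
    "write_ligand_sdf",
    "ligand_from_atoms",
    "dihedral_angle",
    "rotation_about_axis",
    "rotate_points",
    "best_fit_plane_normal",
    "infer_bonds",
]


class StructureError(ValueError):
    """Invalid or inconsistent molecular structure."""


class PDBParseError(StructureError):
    """A PDB record could not be parsed."""


class ParameterizationError(StructureError):
    """No charge/radius parameters available for a residue or atom."""


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis has zero length")
    x, y, z = axis / n
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def rotate_points(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate ``points`` (n×3) about the line through ``origin`` along ``axis``."""
    R = rotation_about_axis(axis, angle_deg)
    return (np.asarray(points) - origin) @ R.T + origin


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle into (−180, 180]."""
    a = (angle_deg + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points`` (≥3 atoms).

    Raises :class:`StructureError` when the points are (near-)collinear, in
    which case the plane is undefined.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise StructureError("plane fit needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-6 * max(svals[0], 1e-12):
        raise StructureError("points are collinear; best-fit plane undefined")
    return vt[2]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

HBRole = str  # one of {"donor", "acceptor", "both", "none"}


@dataclass
class Atom:
    """One atom: label, element, position (Å), charge (e), vdW radius (Å).

    ``parent_position`` is set on polar hydrogens at preparation time and
    records the heavy donor atom the hydrogen is bonded to; it lets a lone
    atom pair carry enough information for directional H-bond scoring.
    """

    name: str
    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float = 0.0
    hb_role: HBRole = "none"
    is_hydrogen: bool = False
    parent_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: element must be non-empty")

    def copy(self) -> "Atom":
        a = replace(self)
        a.position = self.position.copy()
        if self.parent_position is not None:
            a.parent_position = np.asarray(self.parent_position).copy()
        return a


@dataclass
class Residue:
    """An amino-acid residue with backbone/side-chain dihedral state.

    ``phi``/``psi``/``chis`` are dihedral state variables in degrees,
    maintained by the move operators; for residues read from a file without
    chain context they start at the builder's nominal values.
    """

    res_id: tuple  # (chain, number)
    res_name: str
    atoms: list
    phi: float = 180.0
    psi: float = 180.0
    chis: list = field(default_factory=list)
    flexible: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.res_id}: no atoms")
        self.phi = wrap_angle(self.phi)
        self.psi = wrap_angle(self.psi)
        self.chis = [wrap_angle(c) for c in self.chis]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.res_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def copy(self) -> "Residue":
        return Residue(
            res_id=self.res_id,
            res_name=self.res_name,
            atoms=[a.copy() for a in self.atoms],
            phi=self.phi,
            psi=self.psi,
            chis=list(self.chis),
            flexible=self.flexible,
        )


COMPONENT_KINDS = (
    "protein_chain",
    "cofactor",
    "catalytic_water",
    "water",  # transient: unresolved waters before prepare_apo
    "ligand",
    "other_het",
)


@dataclass
class Ligand:
    """A small molecule: atoms, an explicit bond list and rotatable torsions.

    Bonds are (i, j, order) atom-index triples; rotatable torsions are
    (a, b, c, d) index quadruples whose central b–c bond must be a bond.
    """

    atoms: list
    bonds: list
    rotatable_torsions: list = field(default_factory=list)
    name: str = "LIG"
    core_atoms: Optional[list] = None  # indices of the planar core (ring); defaults to heavy atoms

    def __post_init__(self) -> None:
        n = len(self.atoms)
        g = self.graph()
        if n > 1 and not nx.is_connected(g):
            raise StructureError(f"ligand {self.name}: bond graph is disconnected")
        bond_set = {frozenset((i, j)) for i, j, *_ in self.bonds}
        for (a, b, c, d) in self.rotatable_torsions:
            if frozenset((b, c)) not in bond_set:
                raise StructureError(
                    f"ligand {self.name}: torsion {(a, b, c, d)} central pair is not a bond"
                )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j) for i, j, *_ in self.bonds)
        return g

    def heavy_indices(self) -> list:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        for a, xyz in zip(self.atoms, np.asarray(coords, dtype=float)):
            a.position = np.array(xyz, dtype=float)

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        idx = self.heavy_indices() if heavy_only else range(len(self.atoms))
        return np.mean([self.atoms[i].position for i in idx], axis=0)

    def copy(self) -> "Ligand":
        return Ligand(
            atoms=[a.copy() for a in self.atoms],
            bonds=[tuple(b) for b in self.bonds],
            rotatable_torsions=[tuple(t) for t in self.rotatable_torsions],
            name=self.name,
            core_atoms=list(self.core_atoms) if self.core_atoms is not None else None,
        )


@dataclass
class Component:
    """One constituent of a complex: a protein chain or a hetero group."""

    kind: str
    name: str
    residues: list = field(default_factory=list)  # protein chains
    atoms: list = field(default_factory=list)  # hetero groups
    ligand: Optional[Ligand] = None  # set when kind == "ligand"

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise StructureError(f"unknown component kind {self.kind!r}")
        if self.kind == "ligand" and self.ligand is not None and not self.atoms:
            self.atoms = self.ligand.atoms

    def all_atoms(self) -> list:
        if self.kind == "protein_chain":
            return [a for r in self.residues for a in r.atoms]
        return list(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.all_atoms()])

    def copy(self) -> "Component":
        if self.kind == "ligand" and self.ligand is not None:
            lig = self.ligand.copy()
            return Component(kind=self.kind, name=self.name, atoms=lig.atoms, ligand=lig)
        return Component(
            kind=self.kind,
            name=self.name,
            residues=[r.copy() for r in self.residues],
            atoms=[a.copy() for a in self.atoms],
        )


@dataclass
class Structure:
    """A complex: components plus bookkeeping about catalytically active residues."""

    components: list
    provenance: str = ""
    active_residue_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.protein_residues():
            if r.res_id in seen:
                raise StructureError(f"duplicate residue id {r.res_id}")
            seen.add(r.res_id)
        if sum(1 for c in self.components if c.kind == "catalytic_water") > 1:
            raise StructureError("more than one catalytic water in the complex")
        if sum(1 for c in self.components if c.kind == "ligand") > 1:
            raise StructureError("more than one ligand in the complex")

    # -- accessors ---------------------------------------------------------

    def protein_chains(self) -> list:
        return [c for c in self.components if c.kind == "protein_chain"]

    def protein_residues(self) -> Iterator[Residue]:
        for c in self.protein_chains():
            yield from c.residues

    def component(self, kind: str) -> Optional[Component]:
        for c in self.components:
            if c.kind == kind:
                return c
        return None

    @property
    def ligand(self) -> Optional[Ligand]:
        c = self.component("ligand")
        return c.ligand if c is not None else None

    def all_atoms(self) -> list:
        return [a for c in self.components for a in c.all_atoms()]

    def residue_by_id(self, res_id: tuple) -> Residue:
        for r in self.protein_residues():
            if r.res_id == tuple(res_id):
                return r
        raise KeyError(f"no residue {res_id}")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.all_atoms()])

    def copy(self) -> "Structure":
        return Structure(
            components=[c.copy() for c in self.components],
            provenance=self.provenance,
            active_residue_ids=[tuple(x) for x in self.active_residue_ids],
        )

    def without(self, kinds: Sequence[str]) -> "Structure":
        """A copy with the listed component kinds stripped."""
        s = self.copy()
        s.components = [c for c in s.components if c.kind not in set(kinds)]
        return s

    def validate_prepared(self) -> None:
        """Check the post-preparation invariants: one catalytic water, all
        atoms carrying a finite charge and a positive radius."""
        if self.component("catalytic_water") is None:
            raise StructureError("prepared complex must contain exactly one catalytic water")
        for a in self.all_atoms():
            if not np.isfinite(a.partial_charge):
                raise StructureError(f"atom {a.name}: non-finite charge")
            if not (a.vdw_radius > 0):
                raise StructureError(f"atom {a.name}: non-positive vdW radius")


# --------------------------------------------------------------------------
# parameter tables (declared, minimal)
# --------------------------------------------------------------------------

# united-atom flavoured vdW radii, Å (carbons slightly enlarged: nonpolar H implicit)
ELEMENT_VDW = {"C": 1.90, "N": 1.75, "O": 1.65, "S": 2.00, "P": 2.05, "H": 0.60, "F": 1.5,
               "CL": 1.9, "BR": 2.0}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# backbone partial charges, e
_BACKBONE_CHARGE = {"N": -0.40, "H": 0.30, "CA": 0.10, "C": 0.50, "O": -0.50, "OXT": -0.50}

# cofactor / water names recognised as such on input
COFACTOR_NAMES = {"NAP", "NDP", "NAD", "NAI", "NIC"}
WATER_NAMES = {"HOH", "WAT", "DOD"}
REMOVED_HET_NAMES = {"GOL"}  # cryoprotectant glycerols are stripped at preparation


def _assign_protein_atom_params(res_name: str, atom: Atom) -> None:
    name = atom.name
    if atom.is_hydrogen:
        atom.vdw_radius = ELEMENT_VDW["H"]
        if name == "H":
            atom.partial_charge = _BACKBONE_CHARGE["H"]
        else:
            atom.partial_charge = 0.35
        atom.hb_role = "donor"
        return
    atom.vdw_radius = ELEMENT_VDW.get(atom.element.upper(), 1.8)
    if name in _BACKBONE_CHARGE:
        atom.partial_charge = _BACKBONE_CHARGE[name]
    elif atom.element == "O":
        atom.partial_charge = -0.50
    elif atom.element == "N":
        atom.partial_charge = -0.40
    elif atom.element == "S":
        atom.partial_charge = -0.15
    else:
        atom.partial_charge = 0.0
    # H-bond typing by position in the residue
    if name == "O" or name == "OXT":
        atom.hb_role = "acceptor"
    elif name == "N":
        atom.hb_role = "none" if res_name == "PRO" else "donor"
    elif atom.element == "O":
        # side-chain oxygens: carboxylates accept, hydroxyls do both
        atom.hb_role = "acceptor" if res_name in ("ASP", "GLU", "ASN", "GLN") else "both"
    elif atom.element == "N":
        atom.hb_role = "donor"


def _assign_het_atom_params(atom: Atom, known_charges: bool) -> None:
    atom.vdw_radius = ELEMENT_VDW.get(atom.element.upper(), 1.8)
    if atom.is_hydrogen:
        atom.vdw_radius = ELEMENT_VDW["H"]
        if atom.hb_role == "none":
            atom.hb_role = "donor"
        if not known_charges:
            atom.partial_charge = 0.0
        return
    if not known_charges:
        atom.partial_charge = 0.0
    if atom.hb_role == "none":
        if atom.element == "O":
            atom.hb_role = "acceptor"
        elif atom.element == "N":
            atom.hb_role = "acceptor"


# --------------------------------------------------------------------------
# bond inference
# --------------------------------------------------------------------------

_BOND_HEAVY_MAX = 1.95  # Å, generic covalent cutoff (C–S is the longest we model)
_BOND_H_MAX = 1.25


def infer_bonds(atoms: Sequence[Atom]) -> list:
    """Distance-based covalent bonds among ``atoms`` → list of (i, j) pairs.

    Suitable for prepared structures at standard geometry; ligands read from
    SDF keep their explicit bond block instead.
    """
    pos = np.array([a.position for a in atoms])
    n = len(atoms)
    bonds = []
    if n < 2:
        return bonds
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            cut = _BOND_H_MAX if (atoms[i].is_hydrogen or atoms[j].is_hydrogen) else _BOND_HEAVY_MAX
            if atoms[i].is_hydrogen and atoms[j].is_hydrogen:
                continue
            if d[i, j] <= cut:
                bonds.append((i, j))
    return bonds


# --------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# --------------------------------------------------------------------------

def _validate_pdb_text(text: str) -> None:
    found = False
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            found = True
            if len(line) < 54:
                raise PDBParseError(f"line {ln}: truncated coordinate record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PDBParseError(f"line {ln}: unparsable coordinates") from None
    if not found:
        raise PDBParseError("no ATOM or HETATM records found")


def _atom_from_gemmi(ga: "gemmi.Atom") -> Atom:
    el = ga.element.name.upper() if ga.element.name else ga.name[:1]
    return Atom(
        name=ga.name,
        element=el if el != "X" else ga.name.strip()[0],
        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
        is_hydrogen=(el == "H" or el == "D"),
    )


def read_pdb(text: str, chain_filter: Optional[str] = None) -> Structure:
    """Parse PDB text into a typed :class:`Structure`.

    ATOM records become protein residues (one component per chain); HETATM
    groups are typed by residue name: NAP/NDP → cofactor, HOH → water (a lone
    water is taken directly as the catalytic water), the first remaining
    multi-atom group → ligand, everything else → other_het.  Only altloc
    '' / 'A' atoms are kept.
    """
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBParseError("no model in PDB text")
    model = st[0]

    chains: dict = {}
    het_groups: list = []  # (res_name, chain, num, [Atom])
    n_altloc_dropped = 0
    for ch in model:
        if chain_filter is not None and ch.name != chain_filter:
            continue
        for res in ch:
            atoms = []
            for ga in res:
                if ga.altloc not in ("", "\x00", "A"):
                    n_altloc_dropped += 1
                    continue
                atoms.append(_atom_from_gemmi(ga))
            if not atoms:
                continue
            if res.het_flag == "H" or (res.name not in STANDARD_AA
                                       and res.name in (*WATER_NAMES, *COFACTOR_NAMES,
                                                        *REMOVED_HET_NAMES)):
                het_groups.append((res.name, ch.name, res.seqid.num, atoms))
            else:
                chains.setdefault(ch.name, []).append(
                    Residue(res_id=(ch.name, res.seqid.num), res_name=res.name, atoms=atoms)
                )
    if n_altloc_dropped:
        logger.info("dropped %d alternate-location atoms (kept altloc A/blank)", n_altloc_dropped)

    components = [
        Component(kind="protein_chain", name=name, residues=residues)
        for name, residues in chains.items()
    ]

    waters = [g for g in het_groups if g[0] in WATER_NAMES]
    ligand_assigned = False
    for res_name, chain, num, atoms in het_groups:
        if res_name in WATER_NAMES:
            continue
        if res_name in COFACTOR_NAMES:
            components.append(Component(kind="cofactor", name=res_name, atoms=atoms))
        elif res_name in REMOVED_HET_NAMES:
            components.append(Component(kind="other_het", name=res_name, atoms=atoms))
        elif not ligand_assigned and len([a for a in atoms if not a.is_hydrogen]) >= 2:
            lig = ligand_from_atoms(atoms, name=res_name)
            components.append(Component(kind="ligand", name=res_name, atoms=lig.atoms, ligand=lig))
            ligand_assigned = True
        else:
            components.append(Component(kind="other_het", name=res_name, atoms=atoms))

    if len(waters) == 1:
        res_name, chain, num, atoms = waters[0]
        components.append(
            Component(kind="catalytic_water", name=f"{res_name}_{chain}{num}", atoms=atoms)
        )
    else:
        for res_name, chain, num, atoms in waters:
            components.append(Component(kind="water", name=f"{res_name}_{chain}{num}", atoms=atoms))

    if not components:
        raise StructureError("empty structure after chain filter")
    return Structure(components=components, provenance="pdb")


def ligand_from_atoms(atoms: Sequence[Atom], name: str = "LIG") -> Ligand:
    """Build a Ligand from bare atoms, inferring bonds by distance and
    rotatable torsions as acyclic single bonds between non-terminal heavy atoms."""
    atoms = [a for a in atoms]
    bonds = [(i, j, 1) for i, j in infer_bonds(atoms)]
    lig = Ligand(atoms=atoms, bonds=bonds, rotatable_torsions=[], name=name)
    lig.rotatable_torsions = _derive_rotatable_torsions(lig)
    return lig


def _derive_rotatable_torsions(lig: Ligand) -> list:
    g = lig.graph()
    ring_edges = set()
    for cyc in nx.cycle_basis(g):
        for i in range(len(cyc)):
            ring_edges.add(frozenset((cyc[i], cyc[(i + 1) % len(cyc)])))
    heavy = set(lig.heavy_indices())
    torsions = []
    for i, j, *rest in lig.bonds:
        order = rest[0] if rest else 1
        if order != 1 or frozenset((i, j)) in ring_edges:
            continue
        if i not in heavy or j not in heavy:
            continue
        ni = [k for k in g.neighbors(i) if k != j and k in heavy]
        nj = [k for k in g.neighbors(j) if k != i and k in heavy]
        if ni and nj:
            torsions.append((min(ni), i, j, min(nj)))
    return torsions


_HET_RES_NAMES = {"catalytic_water": "HOH", "water": "HOH"}


def write_pdb(s: Structure) -> str:
    """Serialize a Structure to PDB text (coordinates to 3 decimals)."""
    if not s.components or not s.all_atoms():
        raise StructureError("cannot write an empty structure")
    st = gemmi.Structure()
    model = gemmi.Model("1")
    used_chains = set()
    for comp in s.protein_chains():
        ch = gemmi.Chain(comp.name)
        used_chains.add(comp.name)
        for res in comp.residues:
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.res_id[1], " ")
            gr.het_flag = "A"
            for a in res.atoms:
                gr.add_atom(_atom_to_gemmi(a))
            ch.add_residue(gr)
        model.add_chain(ch)

    het_chain_name = next(c for c in "ZYXWVU" if c not in used_chains)
    het = gemmi.Chain(het_chain_name)
    num = 500
    for comp in s.components:
        if comp.kind == "protein_chain":
            continue
        gr = gemmi.Residue()
        if comp.kind in _HET_RES_NAMES:
            gr.name = _HET_RES_NAMES[comp.kind]
        else:
            gr.name = (comp.name.split("_")[0] or "UNK")[:3]
        gr.seqid = gemmi.SeqId(num, " ")
        num += 1
        gr.het_flag = "H"
        for a in comp.all_atoms():
            gr.add_atom(_atom_to_gemmi(a))
        het.add_residue(gr)
    if len(het) > 0:
        model.add_chain(het)
    st.add_model(model)
    return st.make_pdb_string(gemmi.PdbWriteOptions(cryst1_record=False, end_record=True))


def _atom_to_gemmi(a: Atom) -> "gemmi.Atom":
    ga = gemmi.Atom()
    ga.name = a.name
    ga.element = gemmi.Element(a.element.capitalize())
    ga.pos = gemmi.Position(*a.position)
    ga.occ = 1.0
    ga.b_iso = 0.0
    return ga


# --------------------------------------------------------------------------
# preparation
# --------------------------------------------------------------------------

_DONOR_H_NAMES = {
    # side-chain donor heavy atom -> name of the polar hydrogen we place
    "OG": "HG", "OG1": "HG1", "OH": "HH", "SG": "HG", "NZ": "HZ",
    "NE": "HE", "NH1": "HH1", "NH2": "HH2", "ND1": "HD1", "NE2": "HE2",
    "ND2": "HD2", "NE1": "HE1",
}


def _place_hydrogen(res_atoms: Sequence[Atom], heavy: Atom, h_name: str,
                    bond_length: float = 1.0) -> Atom:
    """Place one polar hydrogen on ``heavy`` along its open-valence direction
    (opposite the mean of its covalent bond vectors)."""
    vecs = []
    for other in res_atoms:
        if other is heavy or other.is_hydrogen:
            continue
        v = other.position - heavy.position
        r = np.linalg.norm(v)
        if r <= _BOND_HEAVY_MAX:
            vecs.append(v / r)
    if vecs:
        direction = -np.sum(vecs, axis=0)
        n = np.linalg.norm(direction)
        direction = direction / n if n > 1e-6 else np.array([0.0, 0.0, 1.0])
    else:
        direction = np.array([0.0, 0.0, 1.0])
    h = Atom(
        name=h_name,
        element="H",
        position=heavy.position + bond_length * direction,
        partial_charge=0.35,
        vdw_radius=ELEMENT_VDW["H"],
        hb_role="donor",
        is_hydrogen=True,
        parent_position=heavy.position.copy(),
    )
    return h


def _add_polar_hydrogens_residue(res: Residue) -> None:
    # backbone amide H
    if res.has_atom("N") and not res.has_atom("H") and res.res_name != "PRO":
        n = res.atom("N")
        h = _place_hydrogen(res.atoms, n, "H")
        h.partial_charge = _BACKBONE_CHARGE["H"]
        res.atoms.append(h)
    for heavy_name, h_name in _DONOR_H_NAMES.items():
        if res.has_atom(heavy_name) and not res.has_atom(h_name):
            heavy = res.atom(heavy_name)
            res.atoms.append(_place_hydrogen(res.atoms, heavy, h_name))


def _hydrate_water(comp: Component) -> None:
    """Add the two hydrogens of a bare water oxygen (deterministic frame)."""
    heavies = [a for a in comp.atoms if not a.is_hydrogen]
    if len(heavies) != 1 or any(a.is_hydrogen for a in comp.atoms):
        return  # already hydrated (or not a lone oxygen)
    o = heavies[0]
    d = 0.96
    half = math.radians(104.5 / 2.0)
    for sign, nm in ((1.0, "H1"), (-1.0, "H2")):
        pos = o.position + d * np.array([sign * math.sin(half), 0.0, math.cos(half)])
        comp.atoms.append(
            Atom(name=nm, element="H", position=pos, partial_charge=0.40,
                 vdw_radius=ELEMENT_VDW["H"], hb_role="donor", is_hydrogen=True,
                 parent_position=o.position.copy())
        )


_CHI_NAME_CHAIN = ["N", "CA", "CB", ("CG", "CG1", "OG", "OG1", "SG"),
                   ("CD", "CD1", "OD1", "ND1", "SD", "ND2")]


def _init_chi_state(res: Residue) -> None:
    """Initialize the residue's χ state variables from its coordinates."""
    if res.chis:
        return
    chain = []
    for entry in _CHI_NAME_CHAIN:
        options = (entry,) if isinstance(entry, str) else entry
        hit = next((o for o in options if res.has_atom(o)), None)
        if hit is None:
            break
        chain.append(res.atom(hit).position)
    res.chis = [
        dihedral_angle(*chain[k:k + 4]) for k in range(len(chain) - 3)
    ]


def prepare_apo(s: Structure, catalytic_water_id: Optional[tuple] = None) -> Structure:
    """Prepare a raw structure for scoring.

    Removes all waters except the declared catalytic one and strips
    glycerols; places polar hydrogens by geometric rules; assigns partial
    charges and vdW radii from the built-in table.  Protein heavy-atom
    coordinates are never altered, and the operation is idempotent.

    ``catalytic_water_id`` identifies the retained water by the trailing
    ``chain+number`` of its component name (e.g. ``("A", 200)``); a
    structure whose water has already been resolved needs no id.
    """
    out = s.copy()
    waters = [c for c in out.components if c.kind == "water"]
    existing = out.component("catalytic_water")
    keep: Optional[Component] = existing
    if waters:
        if catalytic_water_id is not None:
            tag = f"{catalytic_water_id[0]}{catalytic_water_id[1]}"
            for w in waters:
                if w.name.endswith(tag):
                    keep = w
                    break
        if keep is None and catalytic_water_id is not None:
            logger.warning("declared catalytic water %s not found; none retained",
                           catalytic_water_id)
        if keep is not None and keep.kind == "water":
            keep.kind = "catalytic_water"
    out.components = [
        c for c in out.components
        if c.kind != "water" and not (c.kind == "other_het" and c.name.split("_")[0] in REMOVED_HET_NAMES)
    ]

    for comp in out.components:
        if comp.kind == "protein_chain":
            for res in comp.residues:
                if res.res_name not in STANDARD_AA:
                    raise ParameterizationError(
                        f"no parameters for protein residue {res.res_name} {res.res_id}"
                    )
                _add_polar_hydrogens_residue(res)
                _init_chi_state(res)
                for a in res.atoms:
                    _assign_protein_atom_params(res.res_name, a)
        elif comp.kind == "catalytic_water":
            _hydrate_water(comp)
            for a in comp.atoms:
                if a.is_hydrogen:
                    a.partial_charge = 0.40
                    a.vdw_radius = ELEMENT_VDW["H"]
                    a.hb_role = "donor"
                else:
                    a.partial_charge = -0.80
                    a.vdw_radius = ELEMENT_VDW["O"]
                    a.hb_role = "both"
        else:
            has_charges = any(a.partial_charge != 0.0 for a in comp.all_atoms())
            if not has_charges and comp.kind in ("ligand", "cofactor", "other_het"):
                logger.warning(
                    "component %s (%s): no parameters known; neutral charges assigned",
                    comp.name, comp.kind,
                )
            for a in comp.all_atoms():
                _assign_het_atom_params(a, known_charges=has_charges)
    return out


# --------------------------------------------------------------------------
# SDF ligand IO (rdkit-backed)
# --------------------------------------------------------------------------

def read_ligand_sdf(text: str, name: Optional[str] = None) -> Ligand:
    """Parse the first molecule of a MOL/SDF block into a Ligand.

    The explicit bond block defines the bond graph; rotatable torsions are
    derived as acyclic single bonds between non-terminal heavy atoms.
    """
    from rdkit import Chem

    mol = Chem.MolFromMolBlock(text, removeHs=False, sanitize=False)
    if mol is None:
        raise StructureError("could not parse MOL/SDF block")
    conf = mol.GetConformer()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        el = at.GetSymbol()
        atoms.append(
            Atom(name=f"{el}{i + 1}", element=el.upper(),
                 position=np.array([p.x, p.y, p.z]),
                 is_hydrogen=(el == "H"))
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()) or 1)
        for b in mol.GetBonds()
    ]
    lig = Ligand(atoms=atoms, bonds=bonds, name=name or (mol.GetProp("_Name") or "LIG"))
    lig.rotatable_torsions = _derive_rotatable_torsions(lig)
    return lig


def write_ligand_sdf(lig: Ligand) -> str:
    """Serialize a Ligand to an SDF block via rdkit."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in lig.atoms:
        rw.AddAtom(Chem.Atom(a.element.capitalize()))
    for i, j, *rest in lig.bonds:
        order = rest[0] if rest else 1
        rw.AddBond(int(i), int(j), Chem.BondType.values[order])
    mol = rw.GetMol()
    conf = Chem.Conformer(len(lig.atoms))
    for i, a in enumerate(lig.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.position)))
    mol.AddConformer(conf)
    mol.SetProp("_Name", lig.name)
    for at in mol.GetAtoms():
        at.SetNoImplicit(True)
    return Chem.MolToMolBlock(mol, kekulize=False) + "$$$$\n"
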