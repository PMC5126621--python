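"""Ligand–protein interaction fingerprints: hydrogen bonds and hydrophobic
contacts, aggregated per residue, plus cross-ligand consensus residues.

Criteria follow common 2-D interaction-diagram conventions and are
config-exposed: a hydrogen bond is a donor–acceptor pair with D···A within a
distance cutoff (default 3.5 Å) and D–H···A angle above an angle cutoff
(default 120°); a hydrophobic contact is a carbon–carbon pair within a
distance cutoff (default 3.9 Å), reported once per protein residue with the
minimum distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .structures import Structure, StructureError

__all__ = [
    "HBond",
    "HydrophobicContact",
    "InteractionReport",
    "find_hbonds",
    "find_hydrophobic_contacts",
    "interaction_report",
    "shared_residues",
]


@dataclass(frozen=True)
class HBond:
    donor_residue: tuple  # protein res_id, or ("LIG", ligand name)
    donor_atom: str
    acceptor_residue: tuple
    acceptor_atom: str
    distance: float  # D···A, Å
    angle: float     # D–H···A, degrees


@dataclass(frozen=True)
class HydrophobicContact:
    residue: tuple      # protein res_id
    residue_atom: str
    ligand_atom: str
    distance: float     # minimum C···C over the residue, Å


@dataclass
class InteractionReport:
    ligand_name: str
    hbonds: list = field(default_factory=list)
    hydrophobic_contacts: list = field(default_factory=list)

    def residues(self) -> set:
        """Protein residues touched by any interaction kind."""
        out = set()
        for hb in self.hbonds:
            for rid in (hb.donor_residue, hb.acceptor_residue):
                if rid[0] != "LIG":
                    out.add(rid)
        for c in self.hydrophobic_contacts:
            out.add(c.residue)
        return out


def _polar_sites(atoms, owner):
    """(donor heavy, H, owner) and (acceptor, owner) lists for an atom group."""
    donors, acceptors = [], []
    heavies = [a for a in atoms if not a.is_hydrogen]
    for a in atoms:
        if a.is_hydrogen:
            best, best_d = None, 1.35
            for b in heavies:
                d = float(np.linalg.norm(a.position - b.position))
                if d < best_d:
                    best, best_d = b, d
            if best is not None and best.element in ("O", "N", "S"):
                donors.append((best, a, owner))
        elif a.hb_role in ("acceptor", "both"):
            acceptors.append((a, owner))
    return donors, acceptors


def find_hbonds(
    s: Structure, dist_cutoff: float = 3.5, angle_cutoff: float = 120.0
) -> List[HBond]:
    """All ligand↔protein hydrogen bonds within the geometric cutoffs."""
    lig = s.component("ligand")
    if lig is None:
        raise StructureError("interaction analysis requires a ligand")
    lig_owner = ("LIG", lig.name)
    lig_donors, lig_acceptors = _polar_sites(lig.all_atoms(), lig_owner)
    prot_donors, prot_acceptors = [], []
    for res in s.protein_residues():
        d, a = _polar_sites(res.atoms, res.res_id)
        prot_donors.extend(d)
        prot_acceptors.extend(a)

    out = []
    for donors, acceptors in ((lig_donors, prot_acceptors),
                              (prot_donors, lig_acceptors)):
        for heavy, h, d_owner in donors:
            for acc, a_owner in acceptors:
                r = float(np.linalg.norm(heavy.position - acc.position))
                if r > dist_cutoff or r == 0.0:
                    continue
                v1 = heavy.position - h.position
                v2 = acc.position - h.position
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                ang = math.degrees(math.acos(
                    max(-1.0, min(1.0, float(np.dot(v1, v2)) / denom))))
                if ang >= angle_cutoff:
                    out.append(HBond(d_owner, heavy.name, a_owner, acc.name,
                                     round(r, 6), round(ang, 6)))
    return sorted(set(out), key=lambda hb: (hb.distance, hb.donor_atom, hb.acceptor_atom))


def find_hydrophobic_contacts(s: Structure, cutoff: float = 3.9) -> List[HydrophobicContact]:
    """Carbon–carbon ligand↔protein contacts, one per residue (min distance)."""
    lig = s.component("ligand")
    if lig is None:
        raise StructureError("interaction analysis requires a ligand")
    lig_carbons = [a for a in lig.all_atoms() if a.element == "C"]
    out = []
    for res in s.protein_residues():
        best = None
        for ra in res.atoms:
            if ra.element != "C":
                continue
            for la in lig_carbons:
                d = float(np.linalg.norm(ra.position - la.position))
                if d <= cutoff and (best is None or d < best[0]):
                    best = (d, ra.name, la.name)
        if best is not None:
            out.append(HydrophobicContact(res.res_id, best[1], best[2], round(best[0], 6)))
    return out


def interaction_report(
    s: Structure, dist_cutoff: float = 3.5, angle_cutoff: float = 120.0,
    hydrophobic_cutoff: float = 3.9,
) -> InteractionReport:
    lig = s.component("ligand")
    if lig is None:
        raise StructureError("interaction analysis requires a ligand")
    return InteractionReport(
        ligand_name=lig.name,
        hbonds=find_hbonds(s, dist_cutoff, angle_cutoff),
        hydrophobic_contacts=find_hydrophobic_contacts(s, hydrophobic_cutoff),
    )


def shared_residues(reports: Sequence[InteractionReport], threshold: float = 0.8) -> set:
    """Residues interacting (either kind) in ≥ ``threshold`` of the reports."""
    if not reports:
        raise ValueError("shared_residues requires at least one report")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    counts: dict = {}
    for rep in reports:
        for rid in rep.residues():
            counts[rid] = counts.get(rid, 0) + 1
    n = len(reports)
    return {rid for rid, c in counts.items() if c / n >= threshold - 1e-12}
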