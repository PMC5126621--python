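"""Hydrogen-bond / hydrophobic fingerprints and shared-residue consensus."""

import numpy as np
import pytest

import pocketmc as pm
from pocketmc.interactions import (
    InteractionReport,
    find_hbonds,
    find_hydrophobic_contacts,
    interaction_report,
    shared_residues,
)

from conftest import make_atom


def _complex_with(ligand_atoms, residue_atoms, res_name="ALA"):
    lig = pm.Ligand(atoms=ligand_atoms,
                    bonds=[(i, i + 1, 1) for i in range(len(ligand_atoms) - 1)],
                    name="LIG")
    res = pm.Residue(res_id=("A", 1), res_name=res_name, atoms=residue_atoms)
    chain = pm.Component(kind="protein_chain", name="A", residues=[res])
    comp = pm.Component(kind="ligand", name="LIG", atoms=lig.atoms, ligand=lig)
    wat = pm.Component(kind="catalytic_water", name="HOH",
                       atoms=[make_atom("O", "O", pos=(50, 50, 50),
                                        hb_role="both")])
    return pm.Structure(components=[chain, comp, wat])


def _donor_residue(og_pos, hg_toward):
    og = make_atom("OG", "O", pos=og_pos, q=-0.5, hb_role="both")
    hg_dir = np.array(hg_toward) - np.array(og_pos)
    hg_dir = hg_dir / np.linalg.norm(hg_dir)
    hg = make_atom("HG", "H", pos=tuple(np.array(og_pos) + hg_dir), q=0.4,
                   hb_role="donor", is_h=True)
    cb = make_atom("CB", "C", pos=tuple(np.array(og_pos) + [0, 0, 1.4]))
    ca = make_atom("CA", "C", pos=tuple(np.array(og_pos) + [0, 0, 2.9]))
    return [og, hg, cb, ca]


class TestHBonds:
    def test_ideal_geometry_detected(self):
        lig = [make_atom("O1", "O", pos=(0, 0, 0), hb_role="acceptor"),
               make_atom("C1", "C", pos=(1.3, 0, 0))]
        s = _complex_with(lig, _donor_residue((2.8, 0, 0), hg_toward=(0, 0, 0)),
                          res_name="SER")
        hbs = find_hbonds(s, dist_cutoff=3.5, angle_cutoff=120.0)
        assert len(hbs) == 1
        hb = hbs[0]
        assert hb.donor_atom == "OG" and hb.acceptor_atom == "O1"
        assert hb.distance == pytest.approx(2.8)
        assert hb.angle == pytest.approx(180.0)

    def test_long_pair_absent(self):
        lig = [make_atom("O1", "O", pos=(0, 0, 0), hb_role="acceptor"),
               make_atom("C1", "C", pos=(1.3, 0, 0))]
        s = _complex_with(lig, _donor_residue((5.0, 0, 0), hg_toward=(0, 0, 0)),
                          res_name="SER")
        assert find_hbonds(s) == []

    def test_bent_angle_rejected(self):
        lig = [make_atom("O1", "O", pos=(0, 0, 0), hb_role="acceptor"),
               make_atom("C1", "C", pos=(1.3, 0, 0))]
        # hydrogen pointing away from the acceptor
        s = _complex_with(lig, _donor_residue((2.8, 0, 0), hg_toward=(5.6, 0, 0)),
                          res_name="SER")
        assert find_hbonds(s) == []

    def test_matches_exhaustive_scan(self, pocket12):
        s = pocket12.structure
        fast = find_hbonds(s, 3.5, 120.0)
        # independent nested-loop scan
        lig = s.component("ligand")
        found = []
        prot_sites = []
        for res in s.protein_residues():
            heavies = [a for a in res.atoms if not a.is_hydrogen]
            for a in res.atoms:
                prot_sites.append((res.res_id, a, heavies))
        lig_heavies = [a for a in lig.all_atoms() if not a.is_hydrogen]
        def sites(atoms, heavies):
            donors, acceptors = [], []
            for a in atoms:
                if a.is_hydrogen:
                    near = [b for b in heavies
                            if np.linalg.norm(a.position - b.position) < 1.35
                            and b.element in ("O", "N", "S")]
                    if near:
                        d = min(near, key=lambda b: np.linalg.norm(a.position - b.position))
                        donors.append((d, a))
                elif a.hb_role in ("acceptor", "both"):
                    acceptors.append(a)
            return donors, acceptors
        ld, la = sites(lig.all_atoms(), lig_heavies)
        count = 0
        for res in s.protein_residues():
            heavies = [a for a in res.atoms if not a.is_hydrogen]
            pd, pa = sites(res.atoms, heavies)
            for donors, acceptors in ((ld, pa), (pd, la)):
                for heavy, h in donors:
                    for acc in acceptors:
                        r = np.linalg.norm(heavy.position - acc.position)
                        if r > 3.5 or r == 0:
                            continue
                        v1 = heavy.position - h.position
                        v2 = acc.position - h.position
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang >= 120.0:
                            count += 1
        assert len(fast) == count

    def test_monotone_in_cutoffs(self, pocket12):
        s = pocket12.structure
        tight = find_hbonds(s, 3.0, 140.0)
        loose = find_hbonds(s, 3.5, 120.0)
        assert set(tight) <= set(loose)


class TestHydrophobic:
    def test_carbon_pair_within_cutoff(self):
        lig = [make_atom("C1", "C", pos=(0, 0, 0)),
               make_atom("C2", "C", pos=(1.5, 0, 0))]
        res = [make_atom("CB", "C", pos=(0, 3.5, 0)),
               make_atom("CA", "C", pos=(0, 5.0, 0))]
        s = _complex_with(lig, res)
        contacts = find_hydrophobic_contacts(s, cutoff=3.9)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.5)
        assert contacts[0].residue == ("A", 1)

    def test_polar_atom_excluded(self):
        lig = [make_atom("O1", "O", pos=(0, 0, 0), hb_role="acceptor"),
               make_atom("C5", "C", pos=(0, 0, 9.0))]
        res = [make_atom("CB", "C", pos=(0, 3.5, 0)),
               make_atom("CA", "C", pos=(0, 5.0, 0))]
        s = _complex_with(lig, res)
        assert find_hydrophobic_contacts(s, cutoff=3.9) == []

    def test_residue_level_aggregation_min_distance(self):
        lig = [make_atom("C1", "C", pos=(0, 0, 0)),
               make_atom("C2", "C", pos=(1.5, 0, 0))]
        res = [make_atom("CB", "C", pos=(0, 3.5, 0)),
               make_atom("CG", "C", pos=(0, 3.2, 0)),
               make_atom("CA", "C", pos=(0, 5.0, 0))]
        s = _complex_with(lig, res, res_name="VAL")
        contacts = find_hydrophobic_contacts(s, cutoff=3.9)
        assert len(contacts) == 1  # one row per residue
        assert contacts[0].distance == pytest.approx(3.2)

    def test_matches_exhaustive_scan(self, pocket12):
        s = pocket12.structure
        fast = {(c.residue, round(c.distance, 6))
                for c in find_hydrophobic_contacts(s, 3.9)}
        slow = {}
        lig_c = [a for a in s.component("ligand").all_atoms() if a.element == "C"]
        for res in s.protein_residues():
            ds = [np.linalg.norm(ra.position - la.position)
                  for ra in res.atoms if ra.element == "C" for la in lig_c]
            ds = [d for d in ds if d <= 3.9]
            if ds:
                slow[res.res_id] = round(min(ds), 6)
        assert fast == set(slow.items())

    def test_raising_cutoff_never_removes(self, pocket12):
        s = pocket12.structure
        small = {c.residue for c in find_hydrophobic_contacts(s, 3.9)}
        large = {c.residue for c in find_hydrophobic_contacts(s, 4.5)}
        assert small <= large


class TestSharedResidues:
    def _reports(self, residue_sets):
        out = []
        for i, rids in enumerate(residue_sets):
            rep = InteractionReport(ligand_name=f"L{i}")
            from pocketmc.interactions import HydrophobicContact
            rep.hydrophobic_contacts = [
                HydrophobicContact(rid, "CB", "C1", 3.5) for rid in rids]
            out.append(rep)
        return out

    def test_full_consensus(self):
        reps = self._reports([{("A", 1)}] * 5)
        assert shared_residues(reps, 1.0) == {("A", 1)}

    def test_boundary_fraction(self):
        reps = self._reports([{("A", 1)}] * 4 + [set()])
        assert shared_residues(reps, 0.8) == {("A", 1)}
        assert shared_residues(reps, 0.9) == set()

    def test_threshold_monotone(self):
        reps = self._reports([{("A", 1), ("A", 2)}, {("A", 1)}, {("A", 1)}])
        assert shared_residues(reps, 1.0) <= shared_residues(reps, 0.5)

    def test_empty_reports_raise(self):
        with pytest.raises(ValueError):
            shared_residues([], 0.8)

    def test_bad_threshold_raises(self):
        reps = self._reports([{("A", 1)}])
        with pytest.raises(ValueError):
            shared_residues(reps, 0.0)
        with pytest.raises(ValueError):
            shared_residues(reps, 1.5)

    def test_report_from_pocket(self, pocket12):
        rep = interaction_report(pocket12.structure)
        assert rep.ligand_name == "LIG"
        assert rep.hydrophobic_contacts or rep.hbonds
        assert all(c.distance <= 3.9 for c in rep.hydrophobic_contacts)
        assert all(hb.distance <= 3.5 for hb in rep.hbonds)
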