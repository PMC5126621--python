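"""Scoring-function checks: analytic pair values, brute-force oracles and
rigid-motion invariance."""

import math

import numpy as np
import pytest

import pocketmc as pm
from pocketmc.energy import COULOMB_CONSTANT, ScoringContext, default_params
from pocketmc.structures import dihedral_angle, rotate_points

from conftest import make_atom


class TestPairEnergy:
    def test_lj_minimum_is_minus_epsilon(self, params):
        sig = 0.5 * (params.sigma_of("C") + params.sigma_of("C"))
        eps = params.eps_of("C")
        r = 2 ** (1 / 6) * sig
        a = make_atom(pos=(0, 0, 0))
        b = make_atom(name="C2", pos=(r, 0, 0))
        e = pm.pair_energy(a, b, params)
        assert e.lj == pytest.approx(-eps, rel=1e-12)
        assert e.coulomb == 0.0

    def test_lj_root_at_sigma(self, params):
        sig = params.sigma_of("C")
        a = make_atom()
        b = make_atom(name="C2", pos=(sig, 0, 0))
        assert pm.pair_energy(a, b, params).lj == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_closed_form(self, params):
        a = make_atom(q=1.0)
        b = make_atom(name="C2", pos=(3.0, 0, 0), q=1.0)
        expected = COULOMB_CONSTANT / (4.0 * 9.0)  # k q1 q2 / (ε(r)·r), ε(r)=4r
        assert pm.pair_energy(a, b, params).coulomb == pytest.approx(expected, rel=1e-12)

    def test_zero_beyond_cutoff(self, params):
        a = make_atom(q=1.0)
        b = make_atom(name="C2", pos=(2 * params.nonbonded_cutoff, 0, 0), q=-1.0)
        e = pm.pair_energy(a, b, params)
        assert e.total == 0.0

    def test_symmetry(self, params):
        a = make_atom(q=0.3)
        b = make_atom(name="O1", element="O", pos=(2.8, 0.4, -1.0), q=-0.4)
        e1, e2 = pm.pair_energy(a, b, params), pm.pair_energy(b, a, params)
        assert e1.total == pytest.approx(e2.total, rel=1e-14)

    def test_coincident_atoms_raise(self, params):
        a, b = make_atom(), make_atom(name="C2")
        with pytest.raises(ZeroDivisionError):
            pm.pair_energy(a, b, params)

    def test_hbond_geometry_gate(self, params):
        # ideal donor-H...acceptor alignment scores the well depth at r0
        d_pos = np.zeros(3)
        h = make_atom(name="HG", element="H", pos=(1.0, 0, 0), q=0.0,
                      radius=0.6, hb_role="donor", is_h=True)
        h.parent_position = d_pos
        acc = make_atom(name="O1", element="O", pos=(params.hbond_r0, 0, 0),
                        hb_role="acceptor")
        e = pm.pair_energy(h, acc, params)
        assert e.hbond == pytest.approx(-params.hbond_well_depth, rel=1e-9)
        # bent geometry (angle below cutoff) scores nothing
        acc_bent = make_atom(name="O2", element="O", pos=(1.0, 1.2, 0),
                             hb_role="acceptor")
        assert pm.pair_energy(h, acc_bent, params).hbond == 0.0


def _brute_force_total(structure, params):
    """Independent all-pairs summation over pair_energy + torsion priors,
    replicating the model's exclusion rule with its own graph walk."""
    import networkx as nx
    from pocketmc.structures import infer_bonds

    ctx = ScoringContext(structure, params)  # only for the atom ordering
    atoms = ctx.atoms
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    pos = 0
    for comp in structure.components:
        n = len(comp.all_atoms())
        if comp.kind == "ligand" and comp.ligand is not None:
            g.add_edges_from((pos + i, pos + j) for i, j, *_ in comp.ligand.bonds)
        else:
            g.add_edges_from((pos + i, pos + j)
                             for i, j in infer_bonds(comp.all_atoms()))
        pos += n
    spl = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))

    def excluded(i, j):
        return j in spl.get(i, {})

    lj = coul = hb = 0.0
    best_attractive: dict = {}  # donor H index -> deepest bond
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if excluded(i, j):
                continue
            e = pm.pair_energy(atoms[i], atoms[j], params)
            lj += e.lj
            coul += e.coulomb
            if e.hbond != 0.0:
                # the model also vetoes H-bonds whose donor heavy atom is
                # covalently linked to the acceptor, and saturates each
                # donor hydrogen at its single deepest attractive bond
                h, acc = (i, j) if atoms[i].is_hydrogen else (j, i)
                d_idx = min((k for k in g.neighbors(h)),
                            key=lambda k: np.linalg.norm(atoms[k].position
                                                         - atoms[h].position),
                            default=None)
                if d_idx is None or not excluded(d_idx, acc):
                    if e.hbond >= 0:
                        hb += e.hbond
                    else:
                        best_attractive[h] = min(best_attractive.get(h, 0.0),
                                                 e.hbond)
    hb += sum(best_attractive.values())
    tor = 0.0
    for quad in ctx.torsions:
        theta = dihedral_angle(*(atoms[k].position for k in quad))
        tor += 0.5 * params.torsion_barrier * (1.0 + math.cos(3 * math.radians(theta)))
    w = params.term_weights
    return (w["lj"] * lj + w["coulomb"] * coul + w["hbond"] * hb + w["torsion"] * tor)


class TestComplexEnergy:
    def test_empty_structure_is_zero(self, params):
        assert pm.complex_energy(pm.Structure(components=[]), params).total == 0.0

    def test_matches_brute_force_oracle(self, params, pocket12):
        s = pocket12.structure
        fast = pm.complex_energy(s, params).total
        slow = _brute_force_total(s, params)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_rigid_motion_invariance(self, params, pocket12):
        s = pocket12.structure.copy()
        e0 = pm.complex_energy(s, params).total
        R_origin = np.array([1.0, -2.0, 0.5])
        for a in s.all_atoms():
            a.position = rotate_points(a.position[None, :], R_origin,
                                       np.array([1.0, 1.0, 0.3]), 77.0)[0] + 5.0
            if a.parent_position is not None:
                a.parent_position = rotate_points(
                    a.parent_position[None, :], R_origin,
                    np.array([1.0, 1.0, 0.3]), 77.0)[0] + 5.0
        e1 = pm.complex_energy(s, params).total
        assert abs(e1 - e0) < 1e-6

    def test_continuity_at_cutoff(self, params):
        # energy tapers smoothly to zero approaching the cutoff from below
        vals = []
        for r in (params.nonbonded_cutoff - 1e-4, params.nonbonded_cutoff - 1e-2):
            a = make_atom(q=0.5)
            b = make_atom(name="C2", pos=(r, 0, 0), q=0.5)
            vals.append(pm.pair_energy(a, b, params).total)
        assert abs(vals[0]) < 1e-5
        assert abs(vals[1]) < 1e-2

    def test_deterministic(self, params, pocket12):
        e1 = pm.complex_energy(pocket12.structure, params).total
        e2 = pm.complex_energy(pocket12.structure, params).total
        assert e1 == e2


class TestLigandEnergy:
    def test_single_atom_is_zero(self, params):
        lig = pm.Ligand(atoms=[make_atom()], bonds=[], name="X")
        assert pm.ligand_energy(lig, params).total == 0.0

    @staticmethod
    def _butane_like(anti: bool) -> pm.Ligand:
        # a-b-c axis in the xy plane; d on the opposite (anti, 180°) or the
        # same (eclipsed, 0°) side as a
        y = -1.0 if anti else 1.0
        atoms = [make_atom("C1", pos=(-0.5, 1.0, 0)),
                 make_atom("C2", pos=(0.0, 0.0, 0)),
                 make_atom("C3", pos=(1.5, 0.0, 0)),
                 make_atom("C4", pos=(2.0, y, 0))]
        return pm.Ligand(atoms=atoms, bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1)],
                         rotatable_torsions=[(0, 1, 2, 3)], name="BU")

    def test_anti_below_eclipsed(self, params):
        anti = self._butane_like(anti=True)
        ecl = self._butane_like(anti=False)
        assert abs(dihedral_angle(*(a.position for a in anti.atoms))) == pytest.approx(180.0)
        assert dihedral_angle(*(a.position for a in ecl.atoms)) == pytest.approx(0.0)
        e_anti = pm.ligand_energy(anti, params).torsion
        e_ecl = pm.ligand_energy(ecl, params).torsion
        assert e_anti == pytest.approx(0.0, abs=1e-9)
        assert e_anti < e_ecl

    def test_matches_brute_force(self, params, pocket12):
        lig = pocket12.structure.ligand
        comp = pm.Component(kind="ligand", name=lig.name, atoms=lig.atoms, ligand=lig)
        pseudo = pm.Structure(components=[comp])
        assert pm.ligand_energy(lig, params).total == pytest.approx(
            _brute_force_total(pseudo, params), abs=1e-8)

    def test_disconnected_graph_raises(self, params):
        with pytest.raises(pm.StructureError):
            lig = pm.Ligand(atoms=[make_atom("C1"), make_atom("C2", pos=(9, 0, 0))],
                            bonds=[], name="X")
            pm.ligand_energy(lig, params)


class TestBreakdown:
    def test_total_is_weighted_sum(self, params, pocket12):
        e = pm.complex_energy(pocket12.structure, params)
        w = params.term_weights
        assert e.total == pytest.approx(
            w["lj"] * e.lj + w["coulomb"] * e.coulomb
            + w["hbond"] * e.hbond + w["torsion"] * e.torsion, rel=1e-12)
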