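"""Move operators: selection radius, backbone kinematics, repacking, rigid
perturbations."""

import itertools

import numpy as np
import pytest

import pocketmc as pm
from pocketmc.energy import ScoringContext
from pocketmc.moves import (
    MoveSpec,
    backbone_rotate,
    default_rotamer_library,
    set_chi,
)
from pocketmc.structures import StructureError

from conftest import make_atom


def _residue(res_id=("A", 1), name="ALA", origin=(0.0, 0.0, 0.0)):
    o = np.array(origin)
    atoms = [
        make_atom("N", "N", o + [0.0, 0.0, 0.0]),
        make_atom("CA", "C", o + [1.46, 0.0, 0.0]),
        make_atom("C", "C", o + [2.0, 1.42, 0.0]),
        make_atom("O", "O", o + [1.35, 2.42, 0.0]),
        make_atom("CB", "C", o + [2.0, -0.8, 1.2]),
    ]
    return pm.Residue(res_id=res_id, res_name=name, atoms=atoms)


def _extended_chain(n=10):
    """n residues with a collinear backbone along +x (the idealized extended
    conformation, in which consecutive ψ/φ rotation axes are parallel)."""
    residues = []
    for i in range(n):
        o = np.array([3.5 * i, 0.0, 0.0])
        atoms = [
            make_atom("N", "N", o + [0.0, 0.0, 0.0]),
            make_atom("CA", "C", o + [1.2, 0.0, 0.0]),
            make_atom("C", "C", o + [2.3, 0.0, 0.0]),
            make_atom("O", "O", o + [2.3, 1.2, 0.0]),
            make_atom("CB", "C", o + [1.2, -1.0, 0.9]),
        ]
        residues.append(pm.Residue(res_id=("A", i + 1), res_name="ALA", atoms=atoms))
    return residues


class TestSelection:
    def test_radius_threshold(self, pocket12):
        s = pocket12.structure
        lig = s.ligand
        # distances from each residue to the ligand
        L = lig.coords()
        dist = {r.res_id: min(np.linalg.norm(a.position - l)
                              for a in r.atoms for l in L)
                for r in s.protein_residues()}
        sel = pm.select_flexible_residues(s, first_cycle=False, radius=4.0)
        for rid, d in dist.items():
            assert (rid in sel) == (d <= 4.0)

    def test_first_cycle_includes_cofactor_neighbourhood_and_active(self, pocket12):
        s = pocket12.structure
        later = pm.select_flexible_residues(s, first_cycle=False, radius=4.0)
        first = pm.select_flexible_residues(s, first_cycle=True, radius=4.0)
        assert later <= first
        for rid in s.active_residue_ids:
            assert tuple(rid) in first

    def test_order_independent(self, pocket12):
        s = pocket12.structure.copy()
        chain = s.protein_chains()[0]
        chain.residues = list(reversed(chain.residues))
        sel_rev = pm.select_flexible_residues(s, first_cycle=True, radius=4.0)
        sel = pm.select_flexible_residues(pocket12.structure, first_cycle=True,
                                          radius=4.0)
        assert sel == sel_rev

    def test_no_ligand_raises(self, pocket12):
        s = pocket12.structure.without(["ligand"])
        with pytest.raises(StructureError):
            pm.select_flexible_residues(s, first_cycle=True, radius=4.0)


class TestSmallShear:
    def test_zero_max_is_identity(self):
        r = _residue()
        spec = MoveSpec(small_max_angle=0.0)
        out = pm.apply_small_move(r, spec, np.random.default_rng(0))
        np.testing.assert_allclose(out.coords(), r.coords(), atol=1e-12)

    def test_bounded_and_deterministic(self):
        r = _residue()
        spec = MoveSpec(small_max_angle=7.0)
        out1 = pm.apply_small_move(r, spec, np.random.default_rng(42))
        out2 = pm.apply_small_move(r, spec, np.random.default_rng(42))
        np.testing.assert_array_equal(out1.coords(), out2.coords())
        from pocketmc.structures import wrap_angle
        assert abs(wrap_angle(out1.phi - r.phi)) <= 7.0
        assert abs(wrap_angle(out1.psi - r.psi)) <= 7.0

    def test_internal_geometry_preserved(self):
        r = _residue()
        d0 = np.linalg.norm(r.atom("CA").position - r.atom("CB").position)
        out = pm.apply_small_move(r, MoveSpec(small_max_angle=30.0),
                                  np.random.default_rng(1))
        d1 = np.linalg.norm(out.atom("CA").position - out.atom("CB").position)
        assert d1 == pytest.approx(d0, abs=1e-6)
        # N-CA bond length is on the rotation axis and must be exact
        n_ca0 = np.linalg.norm(r.atom("N").position - r.atom("CA").position)
        n_ca1 = np.linalg.norm(out.atom("N").position - out.atom("CA").position)
        assert n_ca1 == pytest.approx(n_ca0, abs=1e-9)

    def test_shear_requires_adjacency(self):
        r1 = _residue(res_id=("A", 1))
        r3 = _residue(res_id=("A", 3), origin=(7, 0, 0))
        with pytest.raises(StructureError):
            pm.apply_shear_move(r1, r3, MoveSpec(), np.random.default_rng(0))

    def test_shear_zero_delta_is_identity(self):
        r1, r2 = _extended_chain(2)
        o1, o2 = (pm.apply_shear_move(r1, r2, MoveSpec(shear_max_angle=0.0),
                                      np.random.default_rng(0)))
        np.testing.assert_allclose(o1.coords(), r1.coords(), atol=1e-12)
        np.testing.assert_allclose(o2.coords(), r2.coords(), atol=1e-12)

    def test_shear_moves_terminus_less_than_small(self):
        # compensating ±δ rotations about near-parallel axes shorten the
        # lever arm: the chain terminus moves far less than after an
        # uncompensated φ rotation of equal size
        delta = 8.0
        chain_a = _extended_chain(10)
        end0 = chain_a[-1].atoms[-1].position.copy()
        backbone_rotate(chain_a, 1, delta, 0.0)  # "small": φ only, no compensation
        disp_small = np.linalg.norm(chain_a[-1].atoms[-1].position - end0)

        chain_b = _extended_chain(10)
        backbone_rotate(chain_b, 0, 0.0, -delta)
        backbone_rotate(chain_b, 1, delta, 0.0)  # shear: compensated pair
        disp_shear = np.linalg.norm(chain_b[-1].atoms[-1].position - end0)
        assert disp_shear < disp_small

    def test_downstream_propagation(self):
        chain = _extended_chain(3)
        last0 = chain[2].coords().copy()
        backbone_rotate(chain, 0, 15.0, 0.0)
        assert not np.allclose(chain[2].coords(), last0)


class TestRepack:
    def test_clash_avoided(self, pocket12, params):
        s = pocket12.structure.copy()
        lib = default_rotamer_library()
        ser = next(r for r in s.protein_residues() if r.res_name == "SER")
        # start from a deliberately clashing rotamer
        set_chi(ser, 0, ser.chis[0] + 120.0)
        e_before = pm.complex_energy(s, params).total
        out = pm.repack_side_chains(s, [ser.res_id], lib, params)
        assert pm.complex_energy(out, params).total <= e_before

    def test_matches_exhaustive_enumeration(self, params):
        s = pm.make_mini_pocket(seed=5, n_residues=12).structure.copy()
        lib = default_rotamer_library()
        sers = [r.res_id for r in s.protein_residues() if r.res_name == "SER"]
        targets = sers[:2] if len(sers) >= 2 else sers
        assert targets, "fixture must contain a serine"
        repacked = pm.repack_side_chains(s, targets, lib, params)
        e_repacked = pm.complex_energy(repacked, params).total

        # brute force: try every candidate combination (library rotamers plus
        # the input conformation, which repacking also considers), scoring
        # the full complex each time
        best = np.inf
        rot_lists = []
        for rid in targets:
            current = tuple(s.residue_by_id(rid).chis[:1])
            rot_lists.append([current] + [chis for chis, _p in lib.rotamers("SER")])
        for combo in itertools.product(*rot_lists):
            trial = s.copy()
            for rid, chis in zip(targets, combo):
                res = trial.residue_by_id(rid)
                for k, ang in enumerate(chis):
                    set_chi(res, k, ang)
            best = min(best, pm.complex_energy(trial, params).total)
        assert e_repacked == pytest.approx(best, abs=1e-6)

    def test_empty_set_is_identity(self, pocket12, params):
        s = pocket12.structure
        out = pm.repack_side_chains(s, [], default_rotamer_library(), params)
        np.testing.assert_allclose(out.coords(), s.coords())

    def test_backbone_never_moves(self, pocket12, params):
        s = pocket12.structure
        sel = [r.res_id for r in s.protein_residues()]
        out = pm.repack_side_chains(s, sel, default_rotamer_library(), params)
        for r_in, r_out in zip(s.protein_residues(), out.protein_residues()):
            for name in ("N", "CA", "C", "O"):
                np.testing.assert_allclose(r_out.atom(name).position,
                                           r_in.atom(name).position, atol=1e-9)

    def test_missing_rotamer_entry_raises(self, pocket12, params):
        lib = pm.RotamerLibrary(entries={"ALA": [((), 1.0)]})
        sel = [r.res_id for r in pocket12.structure.protein_residues()
               if r.res_name == "SER"]
        with pytest.raises(KeyError):
            pm.repack_side_chains(pocket12.structure, sel, lib, params)


class TestPerturbComponent:
    def test_zero_maxima_identity(self, pocket12):
        c = pocket12.structure.component("catalytic_water")
        spec = MoveSpec(ligand_translation_max=0.0, ligand_rotation_max=0.0)
        out = pm.perturb_component(c, spec, np.random.default_rng(0))
        np.testing.assert_allclose(out.coords(), c.coords(), atol=1e-12)

    @pytest.mark.parametrize("kind", ["catalytic_water", "cofactor"])
    def test_rigidity(self, pocket12, kind):
        c = pocket12.structure.component(kind)
        out = pm.perturb_component(c, MoveSpec(), np.random.default_rng(3))
        d0 = np.linalg.norm(c.coords()[:, None] - c.coords()[None, :], axis=-1)
        d1 = np.linalg.norm(out.coords()[:, None] - out.coords()[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_deterministic(self, pocket12):
        c = pocket12.structure.component("ligand")
        o1 = pm.perturb_component(c, MoveSpec(), np.random.default_rng(9))
        o2 = pm.perturb_component(c, MoveSpec(), np.random.default_rng(9))
        np.testing.assert_array_equal(o1.coords(), o2.coords())

    def test_protein_chain_rejected(self, pocket12):
        chain = pocket12.structure.protein_chains()[0]
        with pytest.raises(StructureError):
            pm.perturb_component(chain, MoveSpec(), np.random.default_rng(0))
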