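"""Metropolis acceptance, annealing, DFP minimization and the decoy loop."""

import math

import numpy as np
import pytest

import pocketmc as pm
from pocketmc.refine import (
    DofSpec,
    RefinementConfig,
    RefinementTrace,
    anneal_kt,
    generate_decoy,
    metropolis_accept,
    minimize_energy,
    optimization_round,
    pose_dofs,
)

from conftest import make_atom


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, 0.0, 1.0, rng) for _ in range(100))

    def test_zero_temperature_limit_rejects_uphill(self):
        rng = np.random.default_rng(0)
        assert not metropolis_accept(1.0, 0.0, 1e-9, rng)

    def test_acceptance_frequency_matches_boltzmann(self):
        # ΔE = kT·ln2 → acceptance probability exactly 1/2
        rng = np.random.default_rng(1234)
        kt = 2.0
        de = kt * math.log(2.0)
        n = 10_000
        acc = sum(metropolis_accept(de, 0.0, kt, rng) for _ in range(n))
        p = 0.5
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * sigma

    def test_non_finite_energy_raises(self):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), 0.0, 1.0, np.random.default_rng(0))

    def test_non_positive_kt_raises(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, 0.0, np.random.default_rng(0))


class TestAnnealing:
    def test_endpoints(self):
        cfg = RefinementConfig()
        assert anneal_kt(cfg, 0) == pytest.approx(3.0)
        assert anneal_kt(cfg, cfg.outer_cycles - 1) == pytest.approx(1.0)

    def test_monotone_non_increasing(self):
        cfg = RefinementConfig()
        seq = [anneal_kt(cfg, i) for i in range(cfg.outer_cycles)]
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            anneal_kt(RefinementConfig(), 8)

    def test_single_cycle_uses_start(self):
        cfg = RefinementConfig(outer_cycles=1)
        assert anneal_kt(cfg, 0) == pytest.approx(cfg.kt_start)


class TestMinimize:
    def test_single_torsion_reaches_staggered_minimum(self, params):
        # one rotatable torsion under the threefold prior: the nearest
        # minimum is at the staggered angle, reachable in closed form
        from pocketmc.structures import dihedral_angle, rotate_points
        atoms = [make_atom("C1", pos=(-0.5, 1.0, 0)),
                 make_atom("C2", pos=(0.0, 0.0, 0)),
                 make_atom("C3", pos=(1.5, 0.0, 0)),
                 make_atom("C4", pos=(2.0, -1.0, 0))]  # anti, θ = 180°
        lig = pm.Ligand(atoms=atoms, bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1)],
                        rotatable_torsions=[(0, 1, 2, 3)], name="BU")
        # rotate 30° off the minimum
        axis = atoms[2].position - atoms[1].position
        atoms[3].position = rotate_points(atoms[3].position[None, :],
                                          atoms[1].position, axis, 30.0)[0]
        comp = pm.Component(kind="ligand", name="BU", atoms=atoms, ligand=lig)
        s = pm.Structure(components=[comp])
        dof = DofSpec(ligand_torsions=True)
        out = minimize_energy(s, dof, params, max_iter=200, gtol=1e-8)
        theta = dihedral_angle(*(a.position for a in out.ligand.atoms))
        assert min(abs(abs(theta) - 180.0), abs(abs(theta) - 60.0)) < 1e-3 * 180

    def test_energy_never_increases(self, pocket12, params):
        start = pm.perturb_pose(pocket12, 1.0, seed=4)
        e0 = pm.complex_energy(start, params).total
        out, e1 = minimize_energy(start, pose_dofs(start), params, max_iter=30,
                                  return_energy=True)
        assert e1 <= e0 + 1e-9
        assert pm.complex_energy(out, params).total == pytest.approx(e1, abs=1e-6)

    def test_two_dof_matches_grid_search(self, params):
        # single mobile atom in the field of two fixed atoms: minimize over
        # rigid translation and compare against a dense 2-D grid
        fixed = [make_atom("C1", pos=(0, 0, 0)), make_atom("C2", pos=(4.0, 0, 0))]
        probe = make_atom("C9", pos=(2.0, 2.2, 0.0))
        lig = pm.Ligand(atoms=[probe], bonds=[], name="P")
        comp_f = pm.Component(kind="cofactor", name="F", atoms=fixed)
        comp_l = pm.Component(kind="ligand", name="P", atoms=lig.atoms, ligand=lig)
        s = pm.Structure(components=[comp_f, comp_l])
        out = minimize_energy(s, DofSpec(rigid_components=[1]), params,
                              max_iter=300, gtol=1e-9)
        best = out.ligand.atoms[0].position

        # independent dense grid over the same two coordinates
        xs = np.linspace(0.0, 4.0, 161)
        ys = np.linspace(0.5, 5.0, 181)
        def energy_at(x, y):
            p = np.array([x, y, 0.0])
            e = 0.0
            for f in fixed:
                probe2 = make_atom("C9", pos=tuple(p))
                e += pm.pair_energy(f, probe2, params).total
            return e
        grid = [(energy_at(x, y), x, y) for x in xs for y in ys]
        _, gx, gy = min(grid)
        assert abs(best[0] - gx) <= (xs[1] - xs[0])
        assert abs(best[1] - gy) <= (ys[1] - ys[0])

    def test_no_dof_raises(self, pocket12, params):
        with pytest.raises(ValueError):
            minimize_energy(pocket12.structure, DofSpec(), params)


class TestDecoyLoop:
    def test_step_count_matches_cycle_structure(self, pocket12, params, tiny_cfg):
        d = generate_decoy(pocket12.structure, tiny_cfg, params,
                           rng=np.random.default_rng(0))
        assert d.n_steps == tiny_cfg.steps_per_decoy == 8

    def test_default_cycle_structure_is_192(self):
        assert RefinementConfig().steps_per_decoy == 192

    def test_seeded_reproducibility(self, pocket12, params, tiny_cfg):
        d1 = generate_decoy(pocket12.structure, tiny_cfg, params,
                            rng=np.random.default_rng(7))
        d2 = generate_decoy(pocket12.structure, tiny_cfg, params,
                            rng=np.random.default_rng(7))
        assert d1.energy == d2.energy
        np.testing.assert_array_equal(d1.structure.coords(), d2.structure.coords())

    def test_decoy_structure_valid(self, pocket12, params, tiny_cfg):
        d = generate_decoy(pocket12.structure, tiny_cfg, params,
                           rng=np.random.default_rng(3))
        assert np.isfinite(d.energy)
        d.structure.validate_prepared()
        assert len(d.structure.all_atoms()) == len(pocket12.structure.all_atoms())

    def test_round_returns_minimum_energy_decoy(self, pocket12, params, tiny_cfg):
        energies = []
        best = optimization_round(pocket12.structure, tiny_cfg, params,
                                  collect_energies=energies)
        assert len(energies) == tiny_cfg.n_decoys
        assert best.energy == min(energies)
        assert best.index == int(np.argmin(energies))

    def test_single_decoy_round_equals_generate(self, pocket12, params, tiny_cfg):
        import dataclasses
        cfg = dataclasses.replace(tiny_cfg, n_decoys=1)
        best = optimization_round(pocket12.structure, cfg, params, round_index=0)
        d = generate_decoy(pocket12.structure, cfg, params,
                           rng=np.random.default_rng([cfg.seed, 0, 0]))
        assert best.energy == d.energy


class TestConvergenceLoop:
    def test_trace_definition(self):
        t = RefinementTrace(cycle_energies=[-10.0, -12.0, -12.0005], K=3,
                            converged=True)
        assert t.K == 3 and t.converged

    def test_trace_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            RefinementTrace(cycle_energies=[-10.0, -8.0], K=2, converged=False)

    def test_convergence_by_tolerance(self, pocket12, params, tiny_cfg):
        import dataclasses
        cfg = dataclasses.replace(tiny_cfg, max_K=6, convergence_tol=0.5,
                                  n_decoys=4)
        _, trace = pm.refine_to_convergence(pocket12.structure, cfg, params)
        diffs = [abs(a - b) for a, b in zip(trace.cycle_energies,
                                            trace.cycle_energies[1:])]
        assert all(b <= a + 1e-9 for a, b in zip(trace.cycle_energies,
                                                 trace.cycle_energies[1:]))
        if trace.converged:
            assert diffs[-1] <= cfg.convergence_tol
        else:
            assert trace.K == cfg.max_K

    def test_max_k_cap(self, pocket12, params, tiny_cfg):
        import dataclasses
        cfg = dataclasses.replace(tiny_cfg, max_K=1, convergence_tol=1e-12)
        _, trace = pm.refine_to_convergence(pocket12.structure, cfg, params)
        assert trace.K == 1 and not trace.converged
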