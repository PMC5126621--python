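"""Binding-energy evaluation, pose classification and ligand ranking.

The binding energy of a ligand is the difference between the optimized
energy of the full ternary complex and the sum of its references:

    E_bind = E_complex − (E_ref + E_lig)

where E_complex is the enzyme·cofactor·water·ligand complex, E_ref the same
complex without the ligand, and E_lig the internal energy of the ligand
alone.  Both optimized states come from the same refinement protocol (an
*energy ladder* over component subsets: apo, +water, +water+cofactor, full
complex); the ligand alone is scored without optimization.  Equal active-site
access and equal entropic cost across ligands are assumed, so E_bind is a
qualitative, rank-oriented score.

Pose classes follow the orientation of the ligand core relative to the
cofactor's nicotinamide plane: near-parallel planes are the unproductive
orientation, near-perpendicular the productive (chemistry-capable) one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .energy import EnergyParams, complex_energy, default_params, ligand_energy
from .refine import RefinementConfig, RefinementTrace, refine_to_convergence
from .structures import (
    Component,
    Ligand,
    Structure,
    StructureError,
    best_fit_plane_normal,
)
from .synthetic import COFACTOR_RING_NAMES

__all__ = [
    "BindingRecord",
    "LadderResult",
    "POSITION_CLASSES",
    "energy_ladder",
    "binding_energy",
    "classify_pose",
    "pose_rmsd",
    "rank_ligands",
]

POSITION_CLASSES = ("unproductive", "productive", "ambiguous", "not_binding")

LADDER_STATES = ("apo", "+water", "+water+NADP", "+water+NADP+ligand", "ligand_alone")


@dataclass
class BindingRecord:
    """One ligand × position-class row of a screen report."""

    ligand_name: str
    position: str
    e_complex: float
    e_ref: float
    e_lig: float
    e_bind: float
    attempted: str = ""  # the placement the run started from, for reporting

    def __post_init__(self) -> None:
        if self.position not in POSITION_CLASSES:
            raise ValueError(f"unknown position class {self.position!r}")
        expected = self.e_complex - (self.e_ref + self.e_lig)
        if abs(self.e_bind - expected) > 1e-9:
            raise ValueError(
                f"E_bind identity violated for {self.ligand_name}: "
                f"{self.e_bind} vs {expected}"
            )


@dataclass
class LadderResult:
    """Optimized energies (kcal/mol) of the component-subset states."""

    energies: dict
    structures: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)


def binding_energy(e_complex: float, e_ref: float, e_lig: float) -> float:
    """E_bind = E_complex − (E_ref + E_lig)."""
    for v in (e_complex, e_ref, e_lig):
        if not np.isfinite(v):
            raise ValueError("binding_energy requires finite inputs")
    return e_complex - (e_ref + e_lig)


_STATE_STRIP = {
    "apo": ("ligand", "cofactor", "catalytic_water", "water", "other_het"),
    "+water": ("ligand", "cofactor", "water", "other_het"),
    "+water+NADP": ("ligand", "water", "other_het"),
    "+water+NADP+ligand": ("water", "other_het"),
}


def energy_ladder(
    s: Structure,
    cfg: RefinementConfig,
    p: Optional[EnergyParams] = None,
    states: Sequence[str] = LADDER_STATES,
) -> LadderResult:
    """Optimize the complex at each requested component subset.

    Each optimized state runs the full convergence loop on the stripped
    structure; the ``ligand_alone`` state is a single energy evaluation of
    the ligand as given (its coordinates are not touched).
    """
    p = p or default_params()
    energies: dict = {}
    structures: dict = {}
    traces: dict = {}
    for state in states:
        if state == "ligand_alone":
            lig = s.ligand
            if lig is None:
                raise StructureError("ligand_alone state requested but no ligand present")
            energies[state] = ligand_energy(lig, p).total
            continue
        if state not in _STATE_STRIP:
            raise ValueError(f"unknown ladder state {state!r}")
        sub = s.without(_STATE_STRIP[state])
        if state != "apo":
            needed = {"+water": ["catalytic_water"],
                      "+water+NADP": ["catalytic_water", "cofactor"],
                      "+water+NADP+ligand": ["catalytic_water", "cofactor", "ligand"]}[state]
            for kind in needed:
                if sub.component(kind) is None:
                    raise StructureError(f"state {state!r} requires a {kind} component")
        refined, trace = refine_to_convergence(sub, cfg, p)
        energies[state] = trace.cycle_energies[-1]
        structures[state] = refined
        traces[state] = trace
    return LadderResult(energies=energies, structures=structures, traces=traces)


def classify_pose(
    ligand: Ligand,
    cofactor: Component,
    ring_atom_names: Sequence[str] = COFACTOR_RING_NAMES,
    parallel_max: float = 30.0,
    perpendicular_min: float = 60.0,
) -> str:
    """Orientation class from the angle between the ligand-core plane and the
    cofactor nicotinamide plane: ≤30° → unproductive (parallel), ≥60° →
    productive (perpendicular), otherwise ambiguous."""
    core = ligand.core_atoms if ligand.core_atoms else ligand.heavy_indices()
    core_pts = np.array([ligand.atoms[i].position for i in core])
    ring_pts = np.array([
        a.position for a in cofactor.all_atoms() if a.name in set(ring_atom_names)
    ])
    if len(ring_pts) < 3:
        raise StructureError("cofactor does not expose the declared ring atoms")
    n1 = best_fit_plane_normal(core_pts)
    n2 = best_fit_plane_normal(ring_pts)
    cosang = abs(float(np.dot(n1, n2)))
    theta = math.degrees(math.acos(min(1.0, cosang)))
    if theta <= parallel_max:
        return "unproductive"
    if theta >= perpendicular_min:
        return "productive"
    return "ambiguous"


def pose_rmsd(a: Ligand, b: Ligand) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, matched by
    atom name, in the fixed receptor frame (no re-superposition)."""
    map_a = {at.name: at.position for at in a.atoms if not at.is_hydrogen}
    map_b = {at.name: at.position for at in b.atoms if not at.is_hydrogen}
    if set(map_a) != set(map_b):
        raise StructureError("pose_rmsd: heavy-atom names do not correspond")
    if not map_a:
        raise StructureError("pose_rmsd: no heavy atoms")
    sq = [float(np.sum((map_a[n] - map_b[n]) ** 2)) for n in map_a]
    return math.sqrt(sum(sq) / len(sq))


_CLASS_ORDER = {"unproductive": 0, "productive": 1, "ambiguous": 2}


def rank_ligands(records: Iterable[BindingRecord]) -> list:
    """Order records for reporting: within each position class ascending by
    E_bind, not-binding entries last, ties broken alphabetically."""
    def key(r: BindingRecord):
        not_binding = r.position == "not_binding"
        cls = _CLASS_ORDER.get(r.position, 3)
        return (cls if not not_binding else 99, not_binding,
                r.e_bind if not not_binding else math.inf, r.ligand_name)
    return sorted(records, key=key)
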