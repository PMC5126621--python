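"""End-to-end competitive-binding screen over a ligand set.

For every ligand × position class the screen places a starting pose, runs
the convergence refinement, evaluates the binding-energy ladder, classifies
the refined pose and collects the interaction fingerprint; the report ranks
ligands by E_bind and lists the residues shared across fingerprints.

The reference rungs of the ladder (apo, +water, +water+cofactor) do not
depend on the ligand and are computed once per screen; each ligand run only
refines its own ternary complex.  A run that fails, ends with a positive
binding energy, or drifts out of the pocket is recorded as ``not_binding``
rather than aborting the screen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import (
    BindingRecord,
    LadderResult,
    binding_energy,
    classify_pose,
    energy_ladder,
    rank_ligands,
)
from .energy import EnergyParams, default_params, ligand_energy
from .interactions import InteractionReport, interaction_report, shared_residues
from .refine import RefinementConfig, refine_to_convergence
from .structures import Component, Ligand, Structure, rotate_points
from .synthetic import SyntheticSystem

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ScreenReport",
    "run_screen",
    "place_ligand",
    "report_table",
]

DRIFT_LIMIT = 8.0  # Å: centroid drift beyond this marks a ligand as not binding


@dataclass
class ScreenConfig:
    """Inputs of one screen: receptor system, ligand set, protocol knobs."""

    system: SyntheticSystem
    ligands: list
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    energy: EnergyParams = field(default_factory=default_params)
    positions: Sequence[str] = ("unproductive", "productive")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ligands:
            raise ValueError("screen requires at least one ligand")


@dataclass
class ScreenReport:
    records: list
    interactions: list
    traces: dict
    shared: set
    reference_energies: dict


def place_ligand(
    system: SyntheticSystem, ligand: Ligand, orientation: str = "unproductive"
) -> Structure:
    """Put ``ligand`` into the pocket of ``system``.

    The ligand's heavy-atom principal frame is aligned to the planted pose's
    frame at the planted centroid (the coplanar, unproductive placement); the
    productive placement additionally rotates the ligand 90° about the
    planted long axis and backs it off the cofactor face by 1.2 Å.
    """
    s = system.structure.copy()
    old = s.component("ligand")
    s.components.remove(old)
    lig = ligand.copy()

    planted = np.asarray(system.planted_pose)
    planted_heavy = planted[[i for i, a in enumerate(old.ligand.atoms)
                             if not a.is_hydrogen]]
    target_centroid = planted_heavy.mean(axis=0)
    target_frame = _principal_frame(planted_heavy)

    coords = lig.coords()
    heavy = lig.heavy_indices()
    frame = _principal_frame(coords[heavy])
    R = target_frame @ frame.T
    if np.linalg.det(R) < 0:
        frame[2] = -frame[2]
        R = target_frame @ frame.T
    centroid = coords[heavy].mean(axis=0)
    coords = (coords - centroid) @ R.T + target_centroid
    if orientation == "productive":
        coords = rotate_points(coords, target_centroid, target_frame[0], 90.0)
        coords = coords + np.array([0.0, 0.0, 1.2])
    lig.set_coords(coords)
    s.components.append(Component(kind="ligand", name=lig.name,
                                  atoms=lig.atoms, ligand=lig))
    return s


def _principal_frame(points: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame (rows: long, mid, short axis)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    frame = vt.copy()
    if np.linalg.det(frame) < 0:
        frame[2] = -frame[2]
    return frame


def run_screen(cfg: ScreenConfig) -> ScreenReport:
    """Run the full screen; see the module docstring for the protocol."""
    p = cfg.energy
    system = cfg.system

    # ligand-independent reference rungs, computed once
    ref_states = ("apo", "+water", "+water+NADP")
    ref_ladder = energy_ladder(system.structure, cfg.refinement, p, states=ref_states)
    e_ref = ref_ladder.energies["+water+NADP"]

    pocket_centroid = np.asarray(system.planted_pose).mean(axis=0)
    records: List[BindingRecord] = []
    reports: List[InteractionReport] = []
    traces: dict = {}
    for li, lig in enumerate(cfg.ligands):
        for position in cfg.positions:
            run_cfg = dataclasses.replace(
                cfg.refinement, seed=int((cfg.seed * 1009 + li * 31
                                          + (0 if position == "unproductive" else 17))
                                         % (2 ** 31)))
            tag = f"{lig.name}:{position}"
            try:
                start = place_ligand(system, lig, orientation=position)
                refined, trace = refine_to_convergence(start, run_cfg, p)
                traces[tag] = trace
                e_complex = trace.cycle_energies[-1]
                e_lig = ligand_energy(lig, p).total
                e_bind = binding_energy(e_complex, e_ref, e_lig)
                refined_lig = refined.ligand
                drift = float(np.linalg.norm(
                    refined_lig.centroid() - pocket_centroid))
                if e_bind > 0 or drift > DRIFT_LIMIT:
                    cls = "not_binding"
                else:
                    cls = classify_pose(refined_lig, refined.component("cofactor"))
                records.append(BindingRecord(
                    ligand_name=lig.name, position=cls, attempted=position,
                    e_complex=e_complex, e_ref=e_ref, e_lig=e_lig, e_bind=e_bind))
                if cls != "not_binding":
                    reports.append(interaction_report(refined))
            except Exception as err:  # record, never abort the screen
                logger.warning("run %s failed: %s", tag, err)
                records.append(BindingRecord(
                    ligand_name=lig.name, position="not_binding", attempted=position,
                    e_complex=0.0, e_ref=0.0, e_lig=0.0, e_bind=0.0))
    ranked = rank_ligands(records)
    shared = shared_residues(reports, threshold=0.8) if reports else set()
    return ScreenReport(records=ranked, interactions=reports, traces=traces,
                        shared=shared, reference_energies=dict(ref_ladder.energies))


def report_table(report: ScreenReport) -> pd.DataFrame:
    """Ligand × position-class table of binding energies (kcal/mol)."""
    rows = {}
    for r in report.records:
        rows.setdefault(r.ligand_name, {})
        col = r.attempted or r.position
        rows[r.ligand_name][col] = (
            "Not binding" if r.position == "not_binding" else round(r.e_bind, 3))
    df = pd.DataFrame.from_dict(rows, orient="index")
    for col in ("unproductive", "productive"):
        if col not in df.columns:
            df[col] = np.nan
    order = [c for c in ("unproductive", "productive") if c in df.columns]
    extra = [c for c in df.columns if c not in order]
    df = df[order + extra]
    df.index.name = "ligand"
    return df


def report_json(report: ScreenReport) -> str:
    """Traces and reference energies as a JSON document."""
    payload = {
        "reference_energies": report.reference_energies,
        "traces": {
            tag: {"cycle_energies": t.cycle_energies, "K": t.K,
                  "converged": t.converged}
            for tag, t in report.traces.items()
        },
        "shared_residues": sorted(map(list, report.shared)),
        "records": [dataclasses.asdict(r) for r in report.records],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
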