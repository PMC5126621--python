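"""Fingerprint ligand-protein interactions in a refined complex.

Hydrogen bonds use a D···A ≤ 3.5 Å / D-H···A ≥ 120° rule; hydrophobic
contacts are C···C pairs ≤ 3.9 Å aggregated per residue.
"""

import pocketmc as pm
from pocketmc.interactions import interaction_report, shared_residues

reports = []
for seed in (5, 6, 7):
    system = pm.make_mini_pocket(seed=seed, n_residues=12)
    rep = interaction_report(system.structure)
    reports.append(rep)
    print(f"\nsystem seed {seed} — ligand {rep.ligand_name}")
    for hb in rep.hbonds:
        print(f"  H-bond  {hb.donor_residue} {hb.donor_atom} -> "
              f"{hb.acceptor_residue} {hb.acceptor_atom}  "
              f"{hb.distance:.2f} Å, {hb.angle:.0f}°")
    for c in rep.hydrophobic_contacts[:5]:
        print(f"  contact {c.residue} {c.residue_atom} ~ {c.ligand_atom}  "
              f"{c.distance:.2f} Å")

consensus = shared_residues(reports, threshold=0.8)
print(f"\nresidues interacting in ≥80% of systems: {sorted(consensus)}")
# In these synthetic pockets the serine H-bond partners and the cage
# residues closest to the ring recur across systems, the same way a
# conserved active-site signature recurs across related ligands.
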