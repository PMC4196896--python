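"""Water occupancy, near-residue hydration and ligand contact frequencies.

Generates a uniformly solvated box at bulk water density with 1.4 waters (on
average) pinned within 2 Å of a marker residue, measures the bulk-relative
occupancy grid and the near-residue water count, and computes a ligand
contact table on a small crafted receptor-ligand system.
"""

import numpy as np
import pandas as pd

from gpcrswitch import (
    BWIndex, BWTable, GridSpec, TopologyMap, Trajectory,
    contact_frequency, water_occupancy, waters_near,
)
from gpcrswitch.synth import gen_solvated_box

traj, top, pinned = gen_solvated_box(n_frames=500, seed=0, pinned_fraction=1.4)
grid = water_occupancy(traj, top, GridSpec((0, 0, 0), 1.0, (20, 20, 20)))
mean_occ = grid.normalized("bulk_relative").mean()
near = waters_near(traj, top, "5.36", "CA", cutoff=2.0)

print(f"bulk-relative occupancy mean : {mean_occ:.4f}  (1.0 = bulk hydration)")
print(f"mean waters within 2 A       : {near:.3f}  (generator mean 1.4)")

# a ligand held 2.9 A from one residue is a contact at the 3 A cutoff
rows = [("CA", "ALA", 10 + i, "C") for i in range(5)] + [("C1", "LIG", 900, "C")]
atoms = pd.DataFrame(rows, columns=["name", "resname", "resseq", "element"])
ltop = TopologyMap(atoms=atoms, bw=BWTable(((BWIndex(3, 50), 10, "ALA"),)),
                   ligand_indices=np.array([5]))
coords = np.zeros((4, 6, 3))
for i in range(5):
    coords[:, i] = (np.cos(1.7 * i), 4.0 * i, np.sin(1.7 * i))
coords[:, 0] = 0.0
coords[:, 5] = (2.9, 0.0, 0.0)
ltraj = Trajectory(coords=coords, times=np.arange(4.0))
table = contact_frequency(ltraj, ltop, cutoff=3.0)
print("\nligand contact table (3 A heavy-atom cutoff):")
print(table.to_string(index=False))
print("\nResidue 10 sits 2.9 A from the ligand in every frame -> frequency 1.0.")
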