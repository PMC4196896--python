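"""End-to-end metadynamics validation on an analytic double well.

Runs six well-tempered walkers (γ=10, hill 0.1 kcal/mol every 4 ps) of the
overdamped Langevin toy system on a double-well potential with a 1.5
kcal/mol barrier, reconstructs the FES from the deposited hills and compares
the recovered basin locations and barrier height with the analytic truth.
"""

import numpy as np

from gpcrswitch import reconstruct_fes
from gpcrswitch.synth import DoubleWell2D, LangevinSpec, run_langevin_metad

pot = DoubleWell2D()  # minima (8.5, 9.5) and (10.5, 9.5), barrier 1.5 kcal/mol
spec = LangevinSpec(potential=pot, n_steps=60_000)
res = run_langevin_metad(spec, seed=0)
print(f"simulated {spec.n_walkers} walkers x {spec.n_steps} steps, "
      f"{len(res.hills)} hills deposited")

ax1 = np.arange(7.0, 12.0 + 1e-9, 0.2)
ax2 = np.arange(7.5, 11.5 + 1e-9, 0.2)
F = reconstruct_fes(res.hills, ax1, ax2).values

i_split = np.searchsorted(ax1, pot.center[0])
for (lo, hi), true_min in zip(((0, i_split), (i_split, len(ax1))), pot.minima):
    sub = F[lo:hi]
    i, j = np.unravel_index(np.argmin(sub), sub.shape)
    print(f"basin recovered at ({ax1[lo + i]:.1f}, {ax2[j]:.1f})  true {true_min}")

icol = int(np.argmin(np.abs(ax1 - pot.center[0])))
barrier = F[icol].min() - F.min()
print(f"barrier recovered: {barrier:.2f} kcal/mol  (true {pot.barrier})")
print(
    "\nThe well-tempered estimate F = -(gamma/(gamma-1))*V converges to the"
    "\nunderlying surface as hills fill the wells; residual error shrinks"
    "\nwith longer deposition."
)
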