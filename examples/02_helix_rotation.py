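"""Helix-6 axial rotation measurement on a rigidly rotating ideal helix.

Builds a trajectory in which the measured span rotates sinusoidally about its
own axis (amplitude 6°) while the whole system tumbles rigidly, then recovers
the rotation series relative to the unrotated reference after superposing the
receptor core.  The rotation span (max - min) is the quantity the study uses
to compare the two receptors (12° vs ~5°).
"""

import numpy as np

from gpcrswitch import rotation_series
from gpcrswitch.synth import gen_rotating_helix_traj

t = np.arange(240)
truth = 6.0 * np.sin(2 * np.pi * t / 120)  # ±6° -> 12° span

traj, top, span, _ = gen_rotating_helix_traj(truth, global_tumbling=True, seed=0)
reference, *_ = gen_rotating_helix_traj(np.zeros(1))
core = np.setdiff1d(top.protein_ca_indices(), span.ca_indices)

rs = rotation_series(traj, span, reference.coords[0], core_indices=core)
err = np.abs(rs.angles - truth).max()

print(f"span label          : {rs.label}")
print(f"recovered range     : {rs.range_deg:.2f} deg (true 12.00)")
print(f"max per-frame error : {err:.4f} deg")
print(
    "\nThe global tumbling motion is removed by the core pre-alignment, so the"
    "\nmeasured angle tracks only the imposed axial rotation of the span."
)
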