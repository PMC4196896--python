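"""Micro-switch engagement statistics on a synthetic two-receptor bundle.

Generates marker trajectories in which each micro-switch follows a two-state
Markov chain with a prescribed engaged fraction, then measures the distances,
classifies them against the study thresholds (9.5 Å for the activation
switches, 5 Å for the ionic lock, 4 Å for the salt bridge) and pools the
engagement percentages over replicates.
"""

import numpy as np

from gpcrswitch import builtin_switch_definitions, engagement_summary, evaluate_switch
from gpcrswitch.synth import gen_switch_bundle

# engaged fractions for the two receptor parameter sets
receptors = {
    "5HT1B-like": {"F6.44_activation": 0.54, "D3.49-R3.50_salt_bridge": 0.38,
                   "ionic_lock": 0.14},
    "5HT2B-like": {"F6.44_activation": 0.32, "D3.49-R3.50_salt_bridge": 0.77,
                   "ionic_lock": 0.73},
}

for receptor, p_map in receptors.items():
    print(f"\n{receptor} (generator engaged fractions: {p_map})")
    series_by_switch = {}
    for rep in range(3):
        traj, top, _ = gen_switch_bundle(
            p_by_switch=p_map, n_frames=5000, seed=1, replicate=f"rep{rep}"
        )
        for defn in builtin_switch_definitions():
            if defn.threshold is None:
                continue  # the Y7.53 reporter is never binarized
            s = evaluate_switch(traj, top, defn)
            series_by_switch.setdefault(defn.name, []).append(s)
    for name, series in series_by_switch.items():
        summ = engagement_summary(series)
        target = p_map.get(name)
        note = f"(generator: {100 * target:.0f}%)" if target else ""
        print(f"  {name:28s} pooled {summ.pooled_percent:5.1f}%  {note}")

print(
    "\nPooled percentages are frame-weighted over the concatenated replicates"
    " and recover the generator's stationary engaged fractions within"
    " Markov-chain sampling noise."
)
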