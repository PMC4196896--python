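# gpcrswitch

Measurement and analysis toolkit for the conformational **micro-switches** of
G protein-coupled receptors (GPCRs) in molecular-dynamics trajectories, with
a focus on the serotonin 5-HT1B / 5-HT2B receptor system: distance-based
switch classification and engagement statistics, helix-6 axial rotation,
water-occupancy and ligand-contact analysis, and reconstruction of 2D
free-energy surfaces from well-tempered multiple-walker metadynamics.

It is written for structural bioinformaticians who have receptor
trajectories (DCD/XTC/multi-model PDB against a PDB topology) or
metadynamics hills logs and want the standard activation metrics without
rebuilding them ad hoc — and it ships a synthetic-data module that generates
every input with known ground truth, so the whole pipeline is validated by
parameter recovery.

## The metrics

Residues are addressed by **Ballesteros–Weinstein (BW) generic numbers**
`H.PP` (the most conserved residue of helix H is H.50), supplied as a small
TSV table per receptor. The built-in micro-switch set is:

| switch | distance | engaged when |
|---|---|---|
| F6.44 activation (P-I-F motif) | para ring C of F6.44 ↔ Cα 5.50 | ≤ 9.5 Å |
| F6.41 activation | para ring C of F6.41 ↔ Cα 5.54 | ≤ 9.5 Å |
| ionic lock (D(E)/RY motif) | Arg 3.50 guanidinium C ↔ Glu 6.30 Cδ | ≤ 5 Å |
| D3.49–R3.50 salt bridge | min over carboxylate-O × guanidinium-N pairs | ≤ 4 Å |
| Y7.53 orientation (NPxxY motif) | OH ↔ Cα 3.50 and Cα 2.40 | reported, not binarized |

Thresholds are boundary-inclusive (a distance exactly at the threshold is
engaged). Engagement percentages pooled over replicates are frame-weighted:
`100 · Σ engaged frames / Σ frames`.

Helix rotation is measured per frame as the circular mean, over the span's
Cα atoms, of each atom's angular-coordinate change about the reference
helix axis, after least-squares superposition of the receptor core to
remove rigid-body drift. The axis is fitted exactly on ideal helices
(curvature-normal SVD plus a parametric helix refinement).

For metadynamics along two CV distances (d₁ = F6.44↔5.50, d₂ = F6.41↔5.54),
hills logs (time, cv1, cv2, σ₁, σ₂, height, bias factor; one file per
walker) are merged and the well-tempered free energy is

```
V(s) = Σᵢ wᵢ exp(−Σₖ (sₖ − sₖ,ᵢ)² / 2σₖ²),   F(s) = −(γ/(γ−1)) · V(s),
```

referenced to min F = 0 (γ = 10 gives the 10/9 prefactor). The CV plane is
partitioned at 9.5 Å into inactive / intermediate / active regions plus the
mechanistically disallowed (d₁ active, d₂ inactive) quadrant.

## Worked example

```python
import numpy as np
from gpcrswitch import builtin_switch_definitions, engagement_summary, evaluate_switch
from gpcrswitch.synth import gen_switch_bundle

series = []
for rep in range(3):
    traj, top, truth = gen_switch_bundle(
        p_by_switch={"ionic_lock": 0.73}, n_frames=5000,
        seed=1, replicate=f"rep{rep}",
    )
    lock = [d for d in builtin_switch_definitions() if d.name == "ionic_lock"][0]
    series.append(evaluate_switch(traj, top, lock))
summ = engagement_summary(series)
print(f"pooled {summ.pooled_percent:.1f}% over {summ.n_frames_total} frames")
```

prints

```
pooled 72.7% over 15000 frames
```

i.e. the classifier recovers the generator's 73% stationary closed fraction
of the ionic lock from the raw coordinates, within Markov-chain sampling
noise. The `examples/` directory has one narrative script per capability
(switch engagement, helix rotation, solvation/contacts, FES reconstruction,
and the biased Langevin walker); each prints the numbers it computes and
what they mean.

A thin CLI wraps the same functions for shell use:

```bash
gpcrswitch --outdir bundle --seed 7 synth          # synthetic input bundle
gpcrswitch --config run.yaml --outdir out switches # engagement tables
gpcrswitch --config run.yaml --outdir out fes      # FES + state summary
```

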