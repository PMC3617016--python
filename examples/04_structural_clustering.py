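"""RMSD-metric clustering of toy structural frames.

Generates scaffold+ligand frames with two planted ligand sites, each
frame randomly rotated and translated, then recovers the planted
partition with greedy k-center under the superposition-RMSD metric
(align on the 8-atom scaffold, measure RMSD over the 3 ligand atoms).
"""

import numpy as np

from ppimsm import LigandRMSDMetric, kcenter, make_toy_structures

traj, planted = make_toy_structures(n_frames=60, displacement_sd=0.5, seed=11,
                                    cluster_separation=10.0)
cl = kcenter(traj, k=2, metric=LigandRMSDMetric())
agree = max((cl.labels == planted).mean(), (cl.labels != planted).mean())

print(f"frames: {traj.n_frames}; planted sites 10.0 A apart, jitter sd 0.5 A")
print(f"k-center (k=2) max cluster radius: {cl.radii.max():.2f} A")
print(f"agreement with the planted partition: {100 * agree:.0f}%")
print("-> rigid-body alignment removes the random frame poses, so the")
print("   ligand-RMSD metric sees only the planted conformational change.")
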