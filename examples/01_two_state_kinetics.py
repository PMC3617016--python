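"""Calibrated two-state release kinetics: generator and its exact truth.

Builds the bound/released exchange model for pyrophosphate release —
state 0 near the active site (coordinate ~4 Å), state 1 in the exit
channel (~15 Å) — prints its closed-form stationary populations and mean
first passage times, and checks a short simulation against them.
"""

import numpy as np

from ppimsm import ppi_release_preset, simulate_jump

model = ppi_release_preset()
pi = model.stationary()
M = model.mfpt_matrix()

print("exact stationary populations: "
      f"bound {100 * pi[0]:.2f}%  released {100 * pi[1]:.2f}%")
print(f"exact MFPT bound->released:   {M[0, 1]:.1f} ns")
print(f"exact MFPT released->bound:   {M[1, 0]:.1f} ns")

sim = simulate_jump(model, n_frames=10_000, frame_interval=1.0,
                    n_trajectories=20, seed=0)
occ = (sim.state_paths == 0).mean()
print(f"occupancy of the bound state over 2x10^5 simulated ns: {100 * occ:.2f}%")
print("-> the released basin is ~7-fold more populated; escape from the")
print("   active site takes ~0.5 us on average.")
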