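"""Full analysis pipeline on synthetic release trajectories.

Generates 100 trajectories from the calibrated two-state model, splits
the release coordinate into 50 k-center microstates, estimates the
transition matrix at a 5 ns lag, lumps to 2 macrostates with PCCA+, and
prints populations (with bootstrap uncertainty), implied timescales and
the bound->released mean first passage time.
"""

import numpy as np

from ppimsm.pipeline import PipelineConfig, run_all

cfg = PipelineConfig.from_preset("two_state_release", seed=2013)
res = run_all(cfg)

mm = res.macro_model
b, r = res.bound_macrostate, res.released_macrostate
print("macrostate populations (MSM estimate +/- bootstrap sd):")
print(f"  bound    {100 * mm.populations[b]:6.2f}% +/- {100 * mm.populations_sd[b]:.2f}%")
print(f"  released {100 * mm.populations[r]:6.2f}% +/- {100 * mm.populations_sd[r]:.2f}%")
print(f"generating truth: {100 * res.truth.stationary_probabilities[0]:.2f}% / "
      f"{100 * res.truth.stationary_probabilities[1]:.2f}%")

print("\nimplied timescales (ns) per lag:")
for row, lag in enumerate(res.timescales.lags_time):
    tau = res.timescales.timescales[row, 0]
    print(f"  lag {lag:5.1f} ns  tau_2 = {tau:8.1f}")

print(f"\nMFPT bound->released: {mm.mfpt[b, r]:.0f} +/- {mm.mfpt_sd[b, r]:.0f} ns "
      f"(generating value {res.truth.mfpt_matrix[0, 1]:.0f} ns)")
print(f"residence-check max |predicted-observed|: "
      f"{np.nanmax(res.residence.max_abs_deviation):.4f}")
print("-> populations recover the generating values; the MFPT estimate sits")
print("   below the truth because single-frame misassignments inflate the")
print("   apparent escape rate at this lag (see docs/methods.md).")
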