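# Methods

## Scope and model

`ppimsm` implements the splitting/lumping Markov state model workflow
for a ligand-release process observed through time-ordered trajectory
data: geometric microstates → lagged transition counts → transition
matrix → implied-timescale validation → PCCA+ macrostates →
populations, mean first passage times (MFPT), residence-probability
validation, and free-energy projections.  The motivating system is
pyrophosphate (PPi) release from a bacterial RNA polymerase secondary
channel, a two-state exchange between a bound basin (ligand–Mg²⁺
distance ≈ 4 Å) and a released basin (≈ 15 Å).  The MD data behind such
an analysis are not shippable, so the package carries synthetic
generators whose answers are known exactly; they define the conditions
under which the pipeline is validated.

## Synthetic generators and their ground truth

**Two-state jump process.**  A continuous-time Markov jump process with
generator Q is observed at a fixed frame interval dt; the hidden chain
advances with the exact discrete-time matrix `expm(Q·dt)`.  We use the
matrix exponential at every state count (not only n = 2): it is exact,
removes the need for a per-frame escape-probability warning, and costs
nothing at these sizes.  The calibrated preset uses
k(bound→released) = 2.0000×10⁻³ ns⁻¹ and
k(released→bound) = 2.8833×10⁻⁴ ns⁻¹, giving stationary populations
12.600%/87.400% and MFPT(bound→released) = 1/k = 500 ns exactly.  The
observable is a per-state Gaussian emission — bound N(4.0, 0.8 Å),
released N(15.0, 2.5 Å) — chosen separable but overlapping in the
tails so the clustering stage is exercised nontrivially.  Real MD
coordinates are not conditionally independent given a metastable
state; this emission model is a stand-in, and the consequences of its
tail overlap are analysed below.  One global seed expands to
per-trajectory substreams as `seed + trajectory_index`; within a
substream the draw order is frame uniforms then emission normals, so
runs are reproducible bit for bit.

**Langevin dynamics.**  Overdamped Euler–Maruyama on explicit 1-D/2-D
potentials, `x ← x − (∇U/γ)dt + sqrt(2·kT·dt/γ)·ξ`.  Gaussian-well
potentials carry a steep x¹⁰ confinement wall (5 kT at 70% of the
half-domain) so the Boltzmann integral is finite and trajectories stay
inside the declared bounds; the wall contributes < 10⁻³ kT at the
wells.  The step-size precondition (per-step displacement sd below a
tenth of the smallest well separation) is enforced.  The quadrature of
exp(−U/kT) over each basin is the thermodynamic oracle.  Euler
discretization biases the sampled distribution at O(dt·U″); with equal
well curvatures the bias largely cancels from basin *ratios*, which is
why the double-well presets use equal widths (0.15) and differ only in
depth (3 kT vs 2 kT at x = 0 and 1).

**Toy structures.**  Frames of a rigid 8-atom scaffold (alignment
subset) plus a 3-atom ligand (metric subset) whose position relative to
the scaffold is one of two planted sites, jittered isotropically; every
frame is randomly rotated and translated, so only superposition-aware
metrics can recover the planted partition.

## Estimation choices

* **Counting.**  Sliding-window counts at lag L; a transition into
  state j counts only if the chain stays in j for `dwell_frames`
  consecutive frames from the arrival (trajectory ends truncate the
  check; self-transitions obey the same rule; `dwell_frames = 1`
  disables it).  Dwell is configured in frames precisely because a
  different save interval must not silently change the rule's meaning;
  a 50 ps dwell at a 2 ps save interval is `dwell_frames = 25`.  Counts
  never cross trajectory boundaries.
* **Ergodic restriction.**  The largest strongly connected component of
  the count graph, ranked by size, then in-component counts, then
  lowest state label — fully deterministic.
* **Transition matrix.**  Raw counts row-normalized (no reversible
  estimator); π is the dominant left eigenvector, the fixed point of
  the master equation, not the row-count marginal.  Eigenvalues are
  sorted by modulus with real-part-then-index tie-breaks.
* **PCCA+.**  Needs a real dominant spectrum; since raw count matrices
  need not be reversible, the analysis matrix defaults to the
  symmetrized counts (N+Nᵀ)/2 (`analysis_symmetrize`).  Populations and
  MFPT always come from the raw-count model.  Memberships are computed
  by the inner-simplex construction (vertex rows of maximal spread,
  linear transform into the membership simplex, feasibility repair by
  clipping and row renormalization).  Crisp assignment is the row
  argmax; for m = 2 on a metastable spectrum this coincides with the
  sign split of the second eigenvector (asserted on planted-block
  matrices), though the two can differ for matrices without a
  metastable gap.
* **MFPT.**  Exact linear solve `(I − P_rest) m = Δt·1` with the target
  row fixed at zero, on the lumped macrostate matrix at the model lag;
  a micro-level first-passage solve with macrostate target sets is
  provided as a cross-check (`mfpt_micro_to_macrostates`) and agrees
  with the lumped value for cleanly metastable systems.
* **Bootstrap.**  Whole trajectories resampled with replacement
  (n = 100 replicates by default), microstate definitions and the
  micro→macro assignment held fixed; replicates that lose a macrostate
  or produce a reducible lumped matrix are excluded and counted.  The
  same bootstrap supplies population and MFPT uncertainties.
* **PMF.**  Weighted histogram, F = −ln(w/w_max) in k_BT, minimum at
  zero, empty bins masked (never interpolated).  Default weighting is
  MSM-reweighted (each microstate's frames share its π) because
  seeding-style trajectory sets are not equilibrium-distributed; the
  uniform mode exists for comparison, and on exactly-Markov data the
  two converge as trajectories lengthen.
* **k-center.**  Greedy farthest-point with a fixed, deterministic seed
  frame (index 0 by default) and lowest-index tie-breaks; guarantees a
  max-radius within 2× the optimum (verified against enumeration).
  An optional stride subsamples the frames used to place centers; the
  final assignment always covers all frames.

## Validation conditions and what they show

The shipped `two_state_release` preset — 100 trajectories × 10,000
frames at 1 ns, k = 50 microstates on the release coordinate, lag scan
{1, 2, 5, 10, 20} ns, final lag 5 ns, dwell 1 frame, m = 2, 100
bootstrap replicates — is the desk-scale analogue of a production MSM
study (problem sizes chosen so the full pipeline runs in seconds).
At these conditions the aggregate data contain ~1,100 statistically
independent samples of the slow exchange (relaxation time
1/(k₁₂+k₂₁) ≈ 437 ns), so the generator's own realized occupancy
fluctuates by ~1 percentage point between seeds; recovered populations
track the realized occupancy to < 0.2 points.

**A quantified limitation: MFPT under emission overlap at short lag.**
With the dwell filter off, a frame whose emission falls across the
basin boundary (~6.5 Å) is misassigned for a single frame.  Bound
frames cross with probability ≈ 1.7×10⁻³ and released frames with
≈ 2.7×10⁻⁴ — which, weighted by the 6.9:1 population ratio, makes the
apparent bound→released transition probability at lag 5 ns
≈ 0.0099 (true) + 0.0032 (blips) ≈ 0.0131 for *any* crisp boundary
placement.  The lumped-matrix MFPT is therefore ≈ 5/0.0131 ≈ 380 ns
instead of 500 ns (−24%), and the micro-level cross-check gives the
same value.  The inflation is additive and lag-independent, so it
shrinks at larger lags (≈ −8% at 20 ns) — visible as the slow climb of
the implied timescale — and the re-crossing filter would remove it
entirely, but a dwell ≥ 2 frames cannot be used here: 1-D k = 50
microstates have ~1-frame residence, so the filter annihilates the
counts.  Population estimates are unaffected (< 0.2-point shift).  The
practical lesson matches MSM practice: short-lag kinetic estimates are
sensitive to discretization noise that equilibrium quantities are not.

**Statistical tests.**  Stochastic assertions use fixed seeds and
tolerances derived from the effective sample count (3 standard errors
unless the acceptance surface states otherwise).  The Monte-Carlo MFPT
oracle comparison (20 random chains, 10⁵ paths each, 2-se level) is
asserted as a calibrated batch — at most the binomially expected number
of 2σ exceedances, no 4σ outlier, and pooled bias within 2 se of the
pooled mean — because an exact estimator exceeds a per-chain 2σ bound
on roughly one chain in twenty by construction.

## Known limitations

* The emission model (iid Gaussians given the hidden state) lacks the
  intra-basin autocorrelation of real MD coordinates; passing tests
  show correct estimation machinery, not robustness to slow intra-state
  dynamics.
* No reversible maximum-likelihood estimator, Bayesian MSM, hidden
  Markov model, or transition-path theory; no binary MD formats
  (convert to CSV/XYZ externally).
* PCCA+ assumes a real dominant spectrum; strongly non-reversible count
  matrices must go through the symmetrized analysis option.
* 2-D Langevin dynamics is provided but the Boltzmann oracle
  (quadrature) is 1-D.
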