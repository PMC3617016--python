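# ppimsm

Markov state model (MSM) analysis of ligand-release kinetics, built
around the escape of pyrophosphate (PPi) from a bacterial RNA
polymerase active site through its secondary channel — a two-state
process: a *bound* basin near the catalytic Mg²⁺ ion and a *released*
basin in an elongated channel region.  The package is for computational
biophysicists who want the full splitting/lumping MSM workflow as a
tested, scriptable library, together with synthetic trajectory
generators whose thermodynamics and kinetics are known exactly, so that
every stage of the analysis can be validated quantitatively at desk
scale.

## The model

Trajectory frames are split into geometric microstates by greedy
k-center clustering (Euclidean on reaction coordinates, or RMSD over a
ligand atom subset after rigid superposition on a structural scaffold).
Transitions between microstates are counted with a sliding window at a
lag time Δt, optionally filtered by a re-crossing (dwell) rule: a
transition into state *j* counts only if the system stays in *j* for a
minimum dwell.  Row-normalizing the count matrix gives the transition
matrix **T** of the master equation

    P(nΔt) = P(0) · Tⁿ

with stationary distribution π (the dominant left eigenvector).  Model
quality is judged by the implied timescales

    τ_k = − Δt / ln μ_k(Δt)

which plateau in Δt once the model is Markovian; one clear spectral gap
indicates two metastable macrostates.  Microstates are lumped by PCCA+
(inner-simplex construction on the dominant right eigenvectors), and
the lumped model yields equilibrium populations, mean first passage
times — the exact solution of MFPT_if = Σ_j P_ij (Δt + MFPT_jf) with
MFPT_ff = 0 — bootstrap uncertainties (resampling whole trajectories),
a residence-probability self-consistency check, and potential-of-mean-
force projections F = −k_BT ln p along one or two reaction coordinates.

The synthetic generators provide the ground truth the real system
lacks: a continuous-time two-state jump process calibrated so that the
bound/released populations are 12.60%/87.40% and the bound→released
MFPT is exactly 500 ns; overdamped Langevin dynamics on explicit
multi-well potentials with a Boltzmann quadrature oracle; and rigid
scaffold+ligand structural frames with planted conformational clusters.

## Worked example

```sh
python examples/02_full_pipeline.py
```

```
macrostate populations (MSM estimate +/- bootstrap sd):
  bound     13.23% +/- 1.01%
  released  86.77% +/- 1.01%
generating truth: 12.60% / 87.40%

implied timescales (ns) per lag:
  lag   1.0 ns  tau_2 =    186.7
  lag   2.0 ns  tau_2 =    265.0
  lag   5.0 ns  tau_2 =    353.3
  lag  10.0 ns  tau_2 =    396.1
  lag  20.0 ns  tau_2 =    421.5

MFPT bound->released: 382 +/- 22 ns (generating value 500 ns)
residence-check max |predicted-observed|: 0.0280
```

The pipeline generated 100 trajectories × 10,000 frames (1 ns frame
interval) from the calibrated two-state model, clustered the release
coordinate into 50 microstates, built the MSM at a 5 ns lag, and lumped
it into two macrostates.  The estimated populations agree with the
generating stationary distribution within the bootstrap uncertainty;
the implied timescale climbs toward the generating relaxation time
(437 ns) as the lag grows.  The MFPT estimate sits below the generating
500 ns because single-frame misassignments in the emission-overlap
region inflate the apparent escape rate at this lag — the origin and
size of that bias are quantified in `docs/methods.md`.

The other examples show the generator's exact kinetics
(`01_two_state_kinetics.py`), Brownian dynamics against the Boltzmann
oracle (`03_langevin_pmf.py`), and RMSD-metric structural clustering
(`04_structural_clustering.py`).

A thin CLI wraps the same stages:

```sh
ppimsm all --preset two_state_release --out msm_out/
```

writes `populations.tsv`, `mfpt.tsv`, `implied_timescales.tsv`,
`residence.csv`, `pmf.csv` and a `run_log.json`; reruns with the same
seed are byte-identical.

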