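# Methods

## The synthetic landscape and what it emulates

The generator replaces atomistic molecular dynamics with overdamped Langevin
(Brownian) dynamics directly in the 3-dimensional collective-variable space
used by the analysis: inter-domain angle θ (degrees), hinge RMSD (Å) and PBC
RMSD (Å). The potential is

U(x) = Σ_m −A_m exp(−Σ_d (x_d − μ_{m,d})² / (2 σ_{m,d}²)) + ½ Σ_d k_d [(|x_d − c_d| − h_d)_+]²

a sum of inverted Gaussian wells inside a harmonically walled box, in reduced
units with kT = 1. This form was chosen because its Boltzmann density
exp(−U/kT) is exactly integrable by grid quadrature, so the equilibrium
macrostate probabilities of every preset are known ground truth ("the
Boltzmann oracle") without any sampling. The oracle assigns each grid cell to
the macrostate with the nearest centre in z-scored feature space — the same
Voronoi rule the estimation pipeline uses — and its convergence is checked by
2× grid refinement (shipped presets change by < 10⁻³ per state between 100³
and 200³ grids).

The three well centres sit at θ = 30°, 60°, 100° for the inactive,
intermediate and active states; the hinge-RMSD centres are (1.5, 2.0, 7.0) Å
and the PBC-RMSD centres (1.0, 2.5, 2.5) Å, encoding the defining signature
of the intermediate: an inactive-like (low) hinge RMSD combined with an
active-like (high) PBC RMSD. The angle centres are the field-standard state
definitions; the RMSD centres are this package's own defaults and are fully
configurable.

Five presets share all geometry and differ only in well depths (kT):

| preset              | inactive | intermediate | active | oracle P(active) |
|---------------------|---------:|-------------:|-------:|-----------------:|
| apo                 | 7.8 | 7.3 | 2.3 | ≈ 0.08 |
| agonist             | 4.3 | 5.8 | 7.8 | ≈ 0.64 |
| mutant              | 6.3 | 8.0 | 1.3 | ≈ 0.08 (intermediate-dominant) |
| partial             | 6.8 | 7.3 | 5.3 | ≈ 0.17 |
| partial-restrained  | 3.8 | 4.8 | 8.6 | ≈ 0.81 |

These depths are **calibration defaults, not measured values**. They were
tuned against two shipped contracts: the active-state ordering
apo < partial < agonist ≤ partial-restrained (the qualitative signature of
agonist activation, blocked activation by the mutation, and partial agonism
with/without extra restraints), and end-to-end recoverability of the oracle
probabilities by the estimation pipeline. Ligand restraints are emulated
purely as depth changes between presets; no attempt is made to reproduce any
real free-energy surface.

### What the generator does *not* emulate

Real MD features absent from the toy model: atomistic force fields, solvent,
pressure coupling, anisotropic and position-dependent diffusion, memory
effects in the projected coordinates, and any coupling between the three
features beyond what the well geometry induces. Passing the recovery tests
therefore shows that the *inference machinery* (discretisation, estimators,
lumping, bootstrap, reweighting) is correct on data with realistic
metastability and seeding bias — it does not validate force fields or
collective-variable choices for any real protein.

## Dynamics, steering and seeding

Integration is Euler–Maruyama: x ← x − (D/kT) ∇U Δt + √(2 D Δt) η. The
per-dimension diffusion D_d = D₀ s_d² (s_d = per-dimension spread of the well
centres) makes the dynamics isotropic in scaled feature space; this is the
stand-in for the MD thermostat's friction, which is not reproduced. The
defaults Δt = 1 and D₀ = 0.001 keep the integrator's stationary bias small:
the stability number (mobility × well curvature × Δt) stays ≤ 0.08 in every
dimension of every preset. At coarser settings (D₀ = 0.002 with narrow
wells) the Euler–Maruyama variance inflation visibly depleted the deepest
well, which is why the defaults are what they are.

Steering adds a harmonic restraint of stiffness 3500 kT per scaled unit²
(the reduced-unit analogue of the force constants typically applied to all
steering collective variables) whose centre moves linearly in scaled feature
space between waypoints (inactive → intermediate → active centres, and the
reverse direction; 9000 steps per leg by default). Because the restraint is
orders of magnitude stiffer than the landscape, the integrator automatically
substeps so that the per-substep relaxation factor stays ≤ 0.25.

Seeds are taken where the steered path crosses n equally spaced values of its
cumulative arc length in scaled space (endpoints included; 100 per direction
by default), and one unbiased trajectory of 5000 saved frames (save stride
16 steps) is run per seed. Per-trajectory noise streams derive from
`SeedSequence((master_seed, trajectory_index))`, so pools are reproducible
and independent of generation order; batch and single-trajectory integration
produce bit-identical streams (drawn in fixed 1024-step blocks).

Pool analyses that compare raw occupancy to the oracle discard the first 10 %
of each trajectory; the MSM pipeline itself uses all frames, since seeded
frames legitimately enter the model.

## MSM estimation

Frames are pooled, z-scored (population mean/std frozen at clustering time
and reused for every later distance computation), and discretised with
k-means (scikit-learn, seeded, n_init = 1; 300 microstates by default, 50 in
the desk-scale recovery protocol). Transition counts use a sliding window at
lag τ = 25 frames (1 frame ≙ 1 ns in the default bookkeeping, so τ matches a
25 ns lag; with the default stride one frame is 16 integration steps).
Ergodic trimming keeps the largest strongly connected component of the count
graph, ranked by outgoing count mass; frames in trimmed microstates carry
zero stationary weight.

The default estimator is the reversible maximum-likelihood transition matrix
via the fixed-point iteration on the symmetric flux matrix,

x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),   T_ij = x_ij/x_i,   π_i = x_i/Σx,

initialised from x = C + Cᵀ and iterated until the relative log-likelihood
change drops below 10⁻¹². The non-reversible row-normalised MLE is provided
as a cross-check (its π comes from the leading left eigenvector). Reversible
spectra are computed after a symmetrising π^{1/2} similarity transform;
implied timescales are t_i = −τ/ln λ_i, with λ outside (0, 1) flagged as NaN
rather than reported as a number.

Macrostate lumping is deliberately *manual-style*: each microstate centre
maps to the nearest of the three named macrostate centres in scaled space
(no PCCA). Ties break to the lowest index everywhere (frame assignment and
lumping), with the macrostate order inactive, intermediate, active.

## Bootstrap and ensembles

Uncertainty is a whole-trajectory bootstrap: resample the pool with
replacement (200 trajectories × 100 iterations by default), keep cluster
centres, labels and the macrostate map frozen, recount/re-trim/re-estimate
per iteration, and report mean, standard deviation (ddof = 1), median and
Q1–Q3 (linear interpolation between order statistics). Iterations whose
resampled pool yields no counts are recorded as failed and excluded, with the
count reported. Macrostates absent from an iteration's active set contribute
exactly 0 to that iteration. Note that with a *fixed* resample size the
bootstrap spread estimates σ_pool/√n_resample and is largely independent of
pool size; the "more data → tighter bootstrap" behaviour holds for the
standard bootstrap (resample size = pool size), which is what the
pool-growth test uses.

Ensemble weights are w_f = π_{s(f)}/N_{s(f)} (frames in trimmed microstates
get exactly zero), drawn ensembles sample 10 000 frames with replacement, and
single-state sub-ensembles renormalise the weights of one macrostate's
frames. Weighted quantiles use the cumulative-weight ≥ q convention with
midpoint interpolation at exact hits. RMSF is deviation from the *reference*
structure after fitting on the fit region — not fluctuation about the
ensemble mean — matching the "RMSF to the inactive conformation" convention;
this differs from the textbook definition and is called out in the API docs.

## Problem sizes and numerical choices

The desk-scale recovery protocol (also used by `scripts/acceptance.py`) runs,
per preset: 2 steering directions × 2 legs × 9000 steps, 200 seeded
trajectories × 5000 frames (80 000 steps each), k = 50 microstates over 10⁶
pooled frames, lag 25, 100 bootstrap iterations and a 10 000-frame ensemble —
about a minute per preset on one CPU. With these settings the estimated
macrostate populations match the exact oracle within ±0.03 per state across
all five presets and tested seeds (tolerance ±0.05), and the activation
ordering is preserved.

Other choices worth knowing:

- k-means empty clusters are handled by scikit-learn's relocation (an empty
  cluster never survives), which differs in mechanism but not effect from
  re-seeding at the farthest point.
- The two-state closed forms used in tests: π = (q, p)/(p+q), and
  t = −τ/ln(1−p−q).
- Degenerate inputs: zero-variance features are rejected at scaling time;
  zero-arc-length steered paths fall back to uniform-in-time seeding with a
  warning; all-zero count matrices and empty macrostates raise or warn as
  documented per function.
- Determinism: every stochastic operation is a pure function of its inputs
  and an integer seed; pipeline stages derive sub-seeds as
  `SeedSequence((master, crc32(stage_name)))`, recorded in the run report.

## Known limitations

- Macrostate populations inherit a small discretisation bias from lumping
  whole microstates by their centres: clusters straddling a Voronoi boundary
  move a few per cent of probability between neighbouring states at k = 50.
  This is intrinsic to the centre-based manual lumping rule, shrinks with k,
  and is covered by the ±0.05 recovery tolerance.
- The reversible MLE assumes the pooled trajectories sample transitions
  compatible with detailed balance; strongly non-equilibrium pools (all
  trajectories relaxing one way) can bias π. Seeding both steering
  directions mitigates this.
- Implied-timescale flatness in τ is only checked on synthetic Markovian
  data; for user data the ITS table is reported but lag selection remains the
  user's responsibility.
- The CLI's `bootstrap` subcommand re-clusters from the pool files (the
  library API allows passing a frozen discretisation directly).
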