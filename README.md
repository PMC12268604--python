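# allostate

Markov state model (MSM) analysis of allosteric conformational activation,
with a fully verifiable synthetic stand-in for the molecular dynamics.

Large allosteric proteins switch between inactive, intermediate and active
conformations whose relative geometry can be summarised by a handful of
collective variables — here an inter-domain angle (degrees), a hinge RMSD (Å)
and a phosphate-binding-cassette (PBC) RMSD (Å), all measured against the
inactive conformation. A common workflow for estimating how ligands or
mutations shift the populations of these states is:

1. **steered sampling** drags the system along the path
   inactive → intermediate → active (and back) with a moving harmonic
   restraint on the collective variables;
2. **seeded sampling** launches a pool of short unbiased trajectories from
   snapshots spaced equally along the steered path's arc length
   (100 per direction → a 200-trajectory pool);
3. the pooled features are z-scored, discretised by *k*-means into
   microstates, and a **reversible maximum-likelihood MSM** is estimated at
   lag τ = 25 frames; microstates are lumped into the three named macrostates
   by nearest-centre assignment in scaled feature space, and macrostate
   populations are the sums of the stationary probabilities π;
4. uncertainty comes from a **whole-trajectory bootstrap** (resample the pool
   with replacement, default 200 trajectories × 100 iterations, re-estimate,
   report mean/std/median/IQR);
5. equilibrium **conformational ensembles** are rebuilt by drawing frames
   (default 10 000) with probability π<sub>s(f)</sub>/N<sub>s(f)</sub>, and
   interrogated for weighted distributional observables (distances, χ1
   dihedrals, RMSF to a reference).

The core estimator is the detailed-balance MLE via the self-consistent
iteration x<sub>ij</sub> ← (C<sub>ij</sub>+C<sub>ji</sub>) /
(c<sub>i</sub>/x<sub>i</sub> + c<sub>j</sub>/x<sub>j</sub>), giving
T<sub>ij</sub> = x<sub>ij</sub>/x<sub>i</sub> and π<sub>i</sub> ∝ x<sub>i</sub>.

Because production MD of a ~900-residue protein is not reproducible at desk
scale, the package ships a **synthetic dynamics module** (`allostate.toydyn`):
overdamped Langevin dynamics on a configurable 3-well landscape in the same
feature space, with an *exactly integrable* Boltzmann density. Five presets
("apo", "agonist", "mutant", "partial", "partial-restrained") differ only in
well depths, emulating ligand- and mutation-induced population shifts, and a
grid-quadrature oracle provides ground-truth macrostate probabilities — so
every inferential stage can be validated end to end. A bead-model
`embed_structure` plus the `featurize` module close the loop for structural
trajectories (multi-model PDB / XYZ / feature TSV input is supported for user
data).

## Worked example

```python
from allostate import (PipelineConfig, run_pipeline,
                       boltzmann_macrostate_probs)

cfg = PipelineConfig(preset="agonist", n_clusters=50, seed=1)
report = run_pipeline(cfg)
print(report.macrostate_probabilities)
oracle = boltzmann_macrostate_probs(report.artifacts["preset"],
                                    report.artifacts["partition"])
print({k: round(v, 3) for k, v in oracle.items()})
```

prints (about a minute; 200 trajectories × 5000 frames simulated, clustered
and modelled):

```
{'inactive': 0.1465, 'intermediate': 0.2273, 'active': 0.6262}
{'inactive': 0.133, 'intermediate': 0.223, 'active': 0.645}
```

The first line is the MSM estimate of the macrostate populations for the
agonist-bound-like preset; the second is the exact Boltzmann ground truth of
the same landscape under the identical macrostate partition — the estimate
recovers each population within ±0.02 here. Across all five presets the
active-state population orders as
apo < partial < agonist ≤ partial-restrained
(≈ 0.09 < 0.17 < 0.63 ≤ 0.78 with this seed), the synthetic analogue of
full-agonist activation, blocked activation in the mutant, and partial
agonism with and without extra stabilising restraints.

The same pipeline is exposed on the command line:

```sh
allostate run --preset apo --seed 1 --out-dir runs/apo
allostate steer --preset apo --seed 1 --out steered.tsv
allostate seeds --preset apo --steered steered.tsv --n-seeds 100 --out seeds.json
allostate pool --preset apo --seeds seeds.json --seed 1 --out-dir pool/
allostate msm --pool-dir pool/ --lag 25 --n-clusters 300 --estimator reversible \
    --macro-centres "30,1.5,1;60,2,2.5;100,7,2.5" --seed 1 --out model.json
```

## Layout

- `allostate.toydyn` — landscape presets, Langevin/steering simulation, seed
  extraction, seeded pools, Boltzmann oracle, toy bead structures
- `allostate.featurize` — selections, Kabsch superposition, region RMSD,
  domain angle, distances, χ1, RMSF, PDB/XYZ/TSV I/O
- `allostate.msm` — scaling, k-means discretisation, transition counting,
  ergodic trimming, reversible/non-reversible MLE, implied timescales,
  macrostate lumping
- `allostate.uncertainty` — whole-trajectory bootstrap and summaries
- `allostate.ensembles` — stationary frame weights, drawn and per-state
  ensembles, weighted histograms/quantiles
- `allostate.pipeline` — configuration-driven end-to-end driver and
  cross-system comparison; `allostate.cli` — command-line front end

See `docs/methods.md` for the model, estimators, calibration choices and
known limitations.
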