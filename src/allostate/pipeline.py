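"""Configuration-driven end-to-end driver.

Workflow per system: steer between the state centres in both directions →
extract seeds equally spaced along each steered path → run one short unbiased
trajectory per seed → z-score + k-means microstate discretization →
transition counting at lag τ → ergodic trimming → maximum-likelihood MSM →
nearest-centre macrostate lumping → whole-trajectory bootstrap → stationary
reweighted ensemble.  Defaults mirror the reference protocol: k = 300
microstates, τ = 25 frames (1 frame ≙ 1 ns bookkeeping), 100 seeds per
steering direction, 5 000-frame seeded runs, bootstrap 200 × 100, 10 000-frame
drawn ensembles.

Every stochastic stage receives a sub-seed derived deterministically from the
master seed and the stage name (CRC-32 of the name mixed into a SeedSequence),
so a report is reproducible bit-for-bit from its configuration echo.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ensembles import frame_weights, sample_ensemble
from .msm import (DEFAULT_LAG, DEFAULT_N_CLUSTERS, assign_macrostates,
                  count_transitions, estimate, implied_timescales,
                  kmeans_cluster, largest_connected_set,
                  macrostate_probabilities)
from .toydyn import (FeatureScaling, GeneratorPreset, SteeringSpec,
                     builtin_presets, extract_seeds, generate_seeded_pool,
                     load_preset, simulate_steering)
from .uncertainty import bootstrap_populations, summarize


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31): SeedSequence over the master
    seed and the CRC-32 of the stage name."""
    ss = np.random.SeedSequence((int(master_seed),
                                 zlib.crc32(stage.encode("utf-8"))))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run (defaults = reference protocol)."""

    preset: str | GeneratorPreset = "apo"
    n_clusters: int = DEFAULT_N_CLUSTERS
    lag: int = DEFAULT_LAG
    estimator: str = "reversible"
    n_seeds_per_direction: int = 100
    seeded_traj_frames: int = 5000
    save_stride: int = 16
    steering_steps_per_leg: int = 9000
    steering_save_stride: int = 16
    restraint_constant: float = 3500.0
    macro_centres: np.ndarray | None = None  # default: preset well centres
    bootstrap_n_resample: int = 200
    bootstrap_n_iter: int = 100
    ensemble_n: int = 10_000
    its_lags: tuple = (5, 10, 25, 50)
    compute_its: bool = True
    seed: int = 0
    outdir: str | None = None

    def resolve_preset(self) -> GeneratorPreset:
        if isinstance(self.preset, GeneratorPreset):
            return self.preset
        presets = builtin_presets()
        if self.preset in presets:
            return presets[self.preset]
        p = Path(self.preset)
        if p.exists():
            return load_preset(p)
        raise ValueError(f"unknown preset {self.preset!r}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["preset"] = (self.preset.name if isinstance(self.preset, GeneratorPreset)
                       else self.preset)
        if self.macro_centres is not None:
            d["macro_centres"] = np.asarray(self.macro_centres).tolist()
        d["its_lags"] = list(self.its_lags)
        return d


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a TOML file ([pipeline] table; keys match
    the dataclass fields)."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    p = doc.get("pipeline", doc)
    kwargs = {}
    for f in dataclasses.fields(PipelineConfig):
        if f.name in p:
            kwargs[f.name] = p[f.name]
    if "macro_centres" in kwargs and kwargs["macro_centres"] is not None:
        kwargs["macro_centres"] = np.asarray(kwargs["macro_centres"], float)
    if "its_lags" in kwargs:
        kwargs["its_lags"] = tuple(kwargs["its_lags"])
    return PipelineConfig(**kwargs)


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    system: str
    config: dict
    stage_seeds: dict
    macrostate_probabilities: dict
    bootstrap_summary: dict
    bootstrap_failures: int
    n_active_states: int
    n_microstates: int
    implied_timescales: dict | None
    version: str
    inventory: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items()
             if k != "artifacts"}
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "RunReport":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow for one system preset (see module docstring).
    Deterministic given the master seed; intermediates are written when
    ``config.outdir`` is set."""
    preset = config.resolve_preset()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    inventory: list[str] = []

    def _write(name, writer):
        if outdir:
            writer(outdir / name)
            inventory.append(name)

    stage_seeds = {s: derive_seed(config.seed, s)
                   for s in ("steer-forward", "steer-reverse", "pool",
                             "cluster", "bootstrap", "ensemble")}

    macro_centres = (np.asarray(config.macro_centres, float)
                     if config.macro_centres is not None
                     else preset.well_centres.copy())
    canonical = FeatureScaling.from_preset(preset)

    # --- steering (both directions) ------------------------------------
    spec_fwd = SteeringSpec(waypoints=macro_centres,
                            restraint_constant=config.restraint_constant,
                            steps_per_leg=config.steering_steps_per_leg)
    spec_rev = SteeringSpec(waypoints=macro_centres[::-1],
                            restraint_constant=config.restraint_constant,
                            steps_per_leg=config.steering_steps_per_leg)
    steered_fwd = simulate_steering(preset, spec_fwd,
                                    seed=stage_seeds["steer-forward"],
                                    save_stride=config.steering_save_stride)
    steered_rev = simulate_steering(preset, spec_rev,
                                    seed=stage_seeds["steer-reverse"],
                                    save_stride=config.steering_save_stride)
    _write("steered_forward.tsv", steered_fwd.to_tsv)
    _write("steered_reverse.tsv", steered_rev.to_tsv)

    # --- seeds ----------------------------------------------------------
    seeds_fwd = extract_seeds(steered_fwd, config.n_seeds_per_direction,
                              canonical)
    seeds_rev = extract_seeds(steered_rev, config.n_seeds_per_direction,
                              canonical)
    seeds = seeds_fwd + seeds_rev
    if outdir:
        payload = [{"direction": ("forward" if i < len(seeds_fwd) else "reverse"),
                    "frame": int(fr), "features": list(map(float, x))}
                   for i, (fr, x) in enumerate(seeds)]
        (outdir / "seeds.json").write_text(json.dumps(payload, indent=1))
        inventory.append("seeds.json")

    # --- seeded pool ----------------------------------------------------
    pool = generate_seeded_pool(
        preset, seeds,
        traj_len=config.seeded_traj_frames * config.save_stride,
        save_stride=config.save_stride, seed=stage_seeds["pool"])
    if outdir:
        pooldir = outdir / "pool"
        pooldir.mkdir(exist_ok=True)
        for i, t in enumerate(pool):
            t.to_tsv(pooldir / f"seeded_{i:04d}.tsv")
        inventory.append("pool/")

    # --- discretization + MSM -------------------------------------------
    disc = kmeans_cluster(pool, k=config.n_clusters,
                          seed=stage_seeds["cluster"])
    dtrajs = disc.labels
    C = count_transitions(dtrajs, lag=config.lag, n_states=disc.n_states)
    active = largest_connected_set(C)
    model = estimate(C, estimator=config.estimator, active_set=active,
                     lag=config.lag)
    partition = assign_macrostates(disc, macro_centres)
    probs = macrostate_probabilities(model, partition)

    its = None
    if config.compute_its:
        table = implied_timescales(dtrajs, config.its_lags,
                                   estimator=config.estimator,
                                   n_states=disc.n_states)
        its = {str(lag): [None if np.isnan(t) else float(t) for t in ts]
               for lag, ts in table.items()}

    # --- bootstrap --------------------------------------------------------
    boot = bootstrap_populations(dtrajs, disc, partition, lag=config.lag,
                                 estimator=config.estimator,
                                 n_resample=config.bootstrap_n_resample,
                                 n_iter=config.bootstrap_n_iter,
                                 seed=stage_seeds["bootstrap"])
    summ = summarize(boot)

    # --- stationary reweighted ensemble ----------------------------------
    weights = frame_weights(model, dtrajs)
    drawn = sample_ensemble(weights, n=config.ensemble_n,
                            seed=stage_seeds["ensemble"])

    report = RunReport(
        system=preset.name,
        config=config.echo(),
        stage_seeds=stage_seeds,
        macrostate_probabilities={k: float(v) for k, v in probs.items()},
        bootstrap_summary=summ,
        bootstrap_failures=boot.n_failed,
        n_active_states=int(len(active)),
        n_microstates=int(disc.n_states),
        implied_timescales=its,
        version=__version__,
        inventory=inventory,
        artifacts={"preset": preset, "pool": pool, "discretization": disc,
                   "count_matrix": C, "model": model, "partition": partition,
                   "bootstrap": boot, "weights": weights, "ensemble": drawn,
                   "seeds": seeds},
    )
    if outdir:
        report.to_json(outdir / "report.json")
        _write_summary_tsv(outdir / "bootstrap_summary.tsv", summ)
        report.inventory.extend(["report.json", "bootstrap_summary.tsv"])
    return report


def _write_summary_tsv(path, summ: dict) -> None:
    with open(path, "w") as fh:
        fh.write("macrostate\tmedian\tq1\tq3\n")
        for nm, s in summ.items():
            fh.write(f"{nm}\t{s['median']:.6f}\t{s['q1']:.6f}\t{s['q3']:.6f}\n")


def compare_systems(reports) -> dict:
    """Side-by-side comparison of macrostate populations across systems.

    Returns a dict with a pandas ``table`` (system × state medians and IQRs)
    and ``non_overlapping``: (state, system_a, system_b) triples whose
    bootstrap IQRs do not overlap — the package's criterion for flagging a
    population difference.
    """
    import pandas as pd

    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    names = list(reports[0].bootstrap_summary.keys())
    for r in reports[1:]:
        if list(r.bootstrap_summary.keys()) != names:
            raise ValueError("mismatched macrostate sets between reports")
    rows = []
    for r in reports:
        for nm in names:
            s = r.bootstrap_summary[nm]
            rows.append({"system": r.system, "state": nm,
                         "median": s["median"], "q1": s["q1"], "q3": s["q3"]})
    table = pd.DataFrame(rows)
    flags = []
    for nm in names:
        sub = table[table.state == nm].reset_index(drop=True)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                a, b = sub.iloc[i], sub.iloc[j]
                if a.q3 < b.q1 or b.q3 < a.q1:
                    flags.append((nm, a.system, b.system))
    return {"table": table, "non_overlapping": flags}
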