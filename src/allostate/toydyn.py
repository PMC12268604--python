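"""Synthetic conformational dynamics on a multi-well feature-space landscape.

This module replaces cluster-scale molecular dynamics with overdamped Langevin
(Brownian) dynamics directly in the 3-dimensional feature space used for state
analysis: inter-domain angle (degrees), hinge RMSD (Å) and PBC RMSD (Å).  The
potential is a sum of inverted Gaussian wells plus harmonic confinement walls,
chosen because its Boltzmann density is exactly integrable by grid quadrature —
so the equilibrium macrostate populations of every shipped system preset are
known ground truth, against which the whole inference pipeline can be tested.

The module emulates the full sampling protocol of a steered/seeded MD study:

* :func:`simulate_steering` drags the system along a waypoint path
  (inactive → intermediate → active and back) with a moving harmonic restraint;
* :func:`extract_seeds` picks snapshots equally spaced along the steered
  path's arc length in scaled feature space;
* :func:`generate_seeded_pool` runs one short unbiased trajectory per seed;
* :func:`boltzmann_macrostate_probs` is the exact ground-truth oracle.

Shipped presets ("apo", "agonist", "mutant", "partial", "partial-restrained")
differ only in their well depths, emulating ligand- or mutation-induced shifts
of state populations.  The depths are calibration defaults of this package,
not measured values; they are chosen so the active-state probability ordering
apo < partial < agonist ≤ partial-restrained holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .featurize import StructureFrame, Topology

# reduced units: kT = 1, one integration step = 1 reduced time unit
DEFAULT_FEATURE_NAMES = ("angle_deg", "hinge_rmsd_A", "pbc_rmsd_A")
DEFAULT_UNITS = ("deg", "A", "A")
MACROSTATE_NAMES = ("inactive", "intermediate", "active")

_NOISE_CHUNK = 1024  # steps per block of pre-drawn Gaussian noise


# --------------------------------------------------------------------------
# scaling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureScaling:
    """Per-feature affine scaling (x - mean) / std used wherever features of
    different units (degrees vs Å) enter one Euclidean distance."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        s = np.atleast_1d(np.asarray(self.std, dtype=float))
        if m.shape != s.shape:
            raise ValueError("mean and std must have equal shape")
        if np.any(s <= 0):
            raise ValueError("scaling std must be positive")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "std", s)

    def scale(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std

    def unscale(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.std + self.mean

    @classmethod
    def identity(cls, dim: int) -> "FeatureScaling":
        return cls(np.zeros(dim), np.ones(dim))

    @classmethod
    def from_preset(cls, preset: "GeneratorPreset") -> "FeatureScaling":
        """Canonical scaling of a landscape: mean/population-std of the well
        centres per dimension (falling back to the mean well width where the
        centres do not spread a dimension)."""
        c = preset.well_centres
        std = c.std(axis=0)
        fallback = preset.well_widths.mean(axis=0)
        std = np.where(std > 1e-12, std, fallback)
        return cls(c.mean(axis=0), std)


# --------------------------------------------------------------------------
# preset / landscape
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorPreset:
    """A multi-well free-energy landscape in feature space.

    U(x) = Σ_m −A_m · exp(−Σ_d (x_d − μ_{m,d})² / (2 σ_{m,d}²))
           + ½ Σ_d k_d · max(0, |x_d − c_d| − h_d)²

    with depths A_m ≥ 0 in kT, per-well per-dimension widths σ, and harmonic
    walls of stiffness k outside the confinement box (centre c, half-widths h).
    """

    name: str
    well_centres: np.ndarray      # (m, d), physical feature units
    well_depths: np.ndarray       # (m,), kT
    well_widths: np.ndarray       # (m, d), feature units
    box_centre: np.ndarray        # (d,)
    box_half_widths: np.ndarray   # (d,)
    wall_stiffness: np.ndarray    # (d,), kT / unit²
    diffusion: np.ndarray         # (d,), unit² per step
    timestep: float = 1.0
    temperature_factor: float = 1.0  # kT in reduced units
    feature_names: tuple = DEFAULT_FEATURE_NAMES
    units: tuple = DEFAULT_UNITS

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.well_centres, dtype=float))
        a = np.atleast_1d(np.asarray(self.well_depths, dtype=float))
        w = np.atleast_2d(np.asarray(self.well_widths, dtype=float))
        m, d = c.shape
        if a.shape != (m,) or w.shape != (m, d):
            raise ValueError("inconsistent well array shapes")
        if m < 1:
            raise ValueError("need at least one well")
        if np.any(a < 0):
            raise ValueError("well depths must be >= 0")
        if np.any(w <= 0):
            raise ValueError("well widths must be > 0")
        bc = np.atleast_1d(np.asarray(self.box_centre, dtype=float))
        bh = np.atleast_1d(np.asarray(self.box_half_widths, dtype=float))
        ks = np.atleast_1d(np.asarray(self.wall_stiffness, dtype=float))
        dif = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
        for arr, nm in ((bc, "box_centre"), (bh, "box_half_widths"),
                        (ks, "wall_stiffness"), (dif, "diffusion")):
            if arr.shape != (d,):
                raise ValueError(f"{nm} must have shape ({d},)")
        if np.any(dif < 0):
            raise ValueError("diffusion must be >= 0")
        if self.timestep <= 0 or self.temperature_factor <= 0:
            raise ValueError("timestep and temperature_factor must be > 0")
        if len(self.feature_names) != d:
            # non-canonical dimensionality: fall back to generic names
            object.__setattr__(self, "feature_names",
                               tuple(f"f{i}" for i in range(d)))
            object.__setattr__(self, "units", ("",) * d)
        for attr, val in (("well_centres", c), ("well_depths", a),
                          ("well_widths", w), ("box_centre", bc),
                          ("box_half_widths", bh), ("wall_stiffness", ks),
                          ("diffusion", dif)):
            object.__setattr__(self, attr, val)

    @property
    def n_wells(self) -> int:
        return self.well_centres.shape[0]

    @property
    def dim(self) -> int:
        return self.well_centres.shape[1]

    def inside_box(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(np.abs(p - self.box_centre) <= self.box_half_widths))


def potential_energy(point: np.ndarray, preset: GeneratorPreset) -> float:
    """Landscape energy (kT units) at one feature-space point."""
    p = np.asarray(point, dtype=float)
    if p.shape != (preset.dim,):
        raise ValueError(f"point must have dimension {preset.dim}")
    return float(_potential_batch(p[None], preset)[0])


def _potential_batch(points: np.ndarray, preset: GeneratorPreset) -> np.ndarray:
    """Vectorised energy for an (n, d) array of points."""
    x = np.asarray(points, dtype=float)
    diff = x[:, None, :] - preset.well_centres[None]        # (n, m, d)
    z2 = (diff / preset.well_widths[None]) ** 2
    gauss = np.exp(-0.5 * z2.sum(axis=2))                   # (n, m)
    u = -(gauss * preset.well_depths[None]).sum(axis=1)
    excess = np.abs(x - preset.box_centre) - preset.box_half_widths
    np.maximum(excess, 0.0, out=excess)
    u += 0.5 * (preset.wall_stiffness * excess ** 2).sum(axis=1)
    return u


def _gradient_batch(points: np.ndarray, preset: GeneratorPreset) -> np.ndarray:
    """∇U for an (n, d) array of points, shape (n, d)."""
    x = np.asarray(points, dtype=float)
    diff = x[:, None, :] - preset.well_centres[None]        # (n, m, d)
    inv_w2 = 1.0 / preset.well_widths ** 2                  # (m, d)
    z2 = diff ** 2 * inv_w2[None]
    gauss = np.exp(-0.5 * z2.sum(axis=2))                   # (n, m)
    grad = np.einsum("nm,m,nmd,md->nd", gauss, preset.well_depths,
                     diff, inv_w2)
    dev = x - preset.box_centre
    excess = np.abs(dev) - preset.box_half_widths
    np.maximum(excess, 0.0, out=excess)
    grad += preset.wall_stiffness * excess * np.sign(dev)
    return grad


# --------------------------------------------------------------------------
# exact Boltzmann oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StateCentres:
    """Named macrostate centres in physical feature units, plus the scaling
    under which nearest-centre (Voronoi) assignment is performed."""

    names: tuple
    centres: np.ndarray  # (s, d), physical units
    scaling: FeatureScaling

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centres, dtype=float))
        if len(self.names) != c.shape[0]:
            raise ValueError("one name per centre required")
        object.__setattr__(self, "centres", c)
        object.__setattr__(self, "names", tuple(self.names))

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest-centre index per point (scaled Euclidean; ties -> lowest
        index, which argmin guarantees)."""
        y = self.scaling.scale(np.atleast_2d(points))
        cy = self.scaling.scale(self.centres)
        d2 = ((y[:, None, :] - cy[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def boltzmann_macrostate_probs(preset: GeneratorPreset, partition,
                               grid_resolution: int = 120) -> dict:
    """Exact macrostate probabilities by grid quadrature of exp(−U/kT).

    ``partition`` is any object with ``names``, ``centres`` (physical units)
    and ``scaling`` attributes (e.g. :class:`StateCentres` or an estimated
    macrostate partition).  Each grid cell is assigned to the macrostate whose
    centre is nearest in scaled feature space — the same rule used by the
    estimation pipeline — and the normalised Boltzmann weight is summed per
    macrostate.  The grid extends beyond the confinement box far enough that
    the wall density is negligible.
    """
    if grid_resolution < 50:
        raise ValueError("grid_resolution must be >= 50 per dimension")
    centres = np.atleast_2d(np.asarray(partition.centres, dtype=float))
    inside = np.abs(centres - preset.box_centre) <= preset.box_half_widths
    if not np.all(inside):
        raise ValueError("partition centres must lie inside the confinement box")
    kT = preset.temperature_factor
    margin = 4.0 * np.sqrt(kT / preset.wall_stiffness)
    lo = preset.box_centre - preset.box_half_widths - margin
    hi = preset.box_centre + preset.box_half_widths + margin
    axes = [np.linspace(lo[d] + (hi[d] - lo[d]) / (2 * grid_resolution),
                        hi[d] - (hi[d] - lo[d]) / (2 * grid_resolution),
                        grid_resolution)
            for d in range(preset.dim)]
    scaling = partition.scaling
    cy = scaling.scale(centres)
    sums = np.zeros(len(partition.names))
    # slab over the first axis to bound memory
    rest = np.meshgrid(*axes[1:], indexing="ij") if preset.dim > 1 else []
    rest_flat = [r.ravel() for r in rest]
    n_rest = rest_flat[0].size if rest_flat else 1
    for x0 in axes[0]:
        pts = np.empty((n_rest, preset.dim))
        pts[:, 0] = x0
        for d, r in enumerate(rest_flat, start=1):
            pts[:, d] = r
        w = np.exp(-_potential_batch(pts, preset) / kT)
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite Boltzmann density on grid")
        y = scaling.scale(pts)
        d2 = ((y[:, None, :] - cy[None]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1)
        for s in range(len(sums)):
            sums[s] += w[lab == s].sum()
    total = sums.sum()
    if total <= 0:
        raise ValueError("vanishing partition function")
    probs = sums / total
    return dict(zip(partition.names, probs))


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTrajectory:
    """Ordered per-frame feature vectors with metadata.

    ``provenance`` is one of "equilibrium", "steered", "seeded";
    ``seed_index`` records which seed point started a seeded run.
    """

    frames: np.ndarray  # (F, d)
    feature_names: tuple = DEFAULT_FEATURE_NAMES
    units: tuple = DEFAULT_UNITS
    frame_spacing: float = 1.0
    provenance: str = "equilibrium"
    seed_index: int | None = None

    def __post_init__(self):
        f = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite feature values")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")
        if len(self.feature_names) != f.shape[1]:
            raise ValueError("feature_names do not match frame dimensionality")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "units", tuple(self.units))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dim(self) -> int:
        return self.frames.shape[1]

    # ---- TSV round trip ------------------------------------------------
    def to_tsv(self, path) -> None:
        header = (f"# feature_names={','.join(self.feature_names)}; "
                  f"units={','.join(self.units)}; "
                  f"frame_spacing={self.frame_spacing!r}; "
                  f"provenance={self.provenance}"
                  + (f"; seed_index={self.seed_index}"
                     if self.seed_index is not None else ""))
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.frames, delimiter="\t", fmt="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTrajectory":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("feature TSV must start with a '# key=...' header")
            for item in first.lstrip("#").strip().split(";"):
                k, _, v = item.strip().partition("=")
                meta[k] = v
            frames = np.loadtxt(fh, delimiter="\t", ndmin=2)
        seed_index = meta.get("seed_index")
        return cls(
            frames=frames,
            feature_names=tuple(meta["feature_names"].split(",")),
            units=tuple(meta["units"].split(",")),
            frame_spacing=float(meta["frame_spacing"]),
            provenance=meta.get("provenance", "equilibrium"),
            seed_index=int(seed_index) if seed_index is not None else None,
        )


def _rng_for(seed, *key) -> np.random.Generator:
    """Deterministic, platform-stable generator derived from a master seed and
    an integer key path (the documented per-trajectory stream rule)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _integrate_batch(preset: GeneratorPreset, starts: np.ndarray, rngs,
                     n_steps: int, save_stride: int) -> np.ndarray:
    """Euler–Maruyama for a batch of independent walkers.

    x ← x − (D/kT)·∇U·Δt + √(2 D Δt)·η, with per-walker noise streams drawn
    from the supplied generators in fixed-size blocks so that batch and
    single-walker integration produce bit-identical trajectories.
    """
    x = np.array(starts, dtype=float, copy=True)
    n, d = x.shape
    dt = preset.timestep
    kT = preset.temperature_factor
    mob = preset.diffusion / kT * dt
    amp = np.sqrt(2.0 * preset.diffusion * dt)
    n_saved = n_steps // save_stride
    out = np.empty((n, n_saved, d))
    saved = 0
    limit = 10.0 * preset.box_half_widths
    step = 0
    while step < n_steps:
        m = min(_NOISE_CHUNK, n_steps - step)
        noise = np.empty((n, m, d))
        for i, rng in enumerate(rngs):
            noise[i] = rng.standard_normal((m, d))
        for t in range(m):
            x -= mob * _gradient_batch(x, preset)
            x += amp * noise[:, t]
            step += 1
            if step % save_stride == 0:
                out[:, saved] = x
                saved += 1
        if np.any(np.abs(x - preset.box_centre) > limit):
            raise FloatingPointError(
                "trajectory diverged (>10x box); decrease timestep or diffusion")
    return out


def simulate_feature_trajectory(preset: GeneratorPreset, start: np.ndarray,
                                n_steps: int, save_stride: int = 1,
                                seed: int = 0) -> FeatureTrajectory:
    """Unbiased overdamped Langevin trajectory; saves every ``save_stride``-th
    step (⌊n_steps/save_stride⌋ frames).  Identical seeds give bit-identical
    output."""
    start = np.asarray(start, dtype=float)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not preset.inside_box(start):
        raise ValueError("start must lie inside the confinement box")
    rng = _rng_for(seed)
    frames = _integrate_batch(preset, start[None], [rng], n_steps, save_stride)[0]
    return FeatureTrajectory(frames, preset.feature_names, preset.units,
                             frame_spacing=save_stride * preset.timestep,
                             provenance="equilibrium")


# --------------------------------------------------------------------------
# steering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SteeringSpec:
    """Moving-restraint protocol: the harmonic centre moves linearly in scaled
    feature space between consecutive waypoints.

    ``restraint_constant`` is the stiffness in kT per scaled-feature-unit²;
    its default of 3500 is the reduced-unit analogue of the force constant
    commonly applied to all steering collective variables in atomistic work.
    """

    waypoints: np.ndarray          # (W, d) physical units
    restraint_constant: float = 3500.0
    steps_per_leg: int = 6000
    scaling: FeatureScaling | None = None  # default: canonical preset scaling

    def __post_init__(self):
        w = np.atleast_2d(np.asarray(self.waypoints, dtype=float))
        if w.shape[0] < 2:
            raise ValueError("need at least 2 waypoints")
        if self.restraint_constant <= 0:
            raise ValueError("restraint_constant must be > 0")
        if self.steps_per_leg < 1:
            raise ValueError("steps_per_leg must be >= 1")
        object.__setattr__(self, "waypoints", w)


def simulate_steering(preset: GeneratorPreset, spec: SteeringSpec,
                      seed: int = 0, save_stride: int = 1) -> FeatureTrajectory:
    """Langevin dynamics plus a moving harmonic restraint along the waypoint
    path.  The integrator substeps automatically when the restraint is stiff
    enough to destabilise the plain Euler–Maruyama step."""
    for wp in spec.waypoints:
        if not preset.inside_box(wp):
            raise ValueError("steering waypoints must lie inside the box")
    scaling = spec.scaling or FeatureScaling.from_preset(preset)
    dt = preset.timestep
    kT = preset.temperature_factor
    k = spec.restraint_constant
    # stability: mobility * restraint curvature * dt_sub must stay small
    stiff = float(np.max(preset.diffusion / kT * k / scaling.std ** 2 * dt))
    n_sub = max(1, math.ceil(stiff / 0.25))
    dt_sub = dt / n_sub
    mob = preset.diffusion / kT * dt_sub
    amp = np.sqrt(2.0 * preset.diffusion * dt_sub)
    rng = _rng_for(seed)

    wps = scaling.scale(spec.waypoints)
    n_legs = wps.shape[0] - 1
    n_steps = n_legs * spec.steps_per_leg
    x = np.array(spec.waypoints[0], dtype=float)
    frames = []
    total_sub = n_steps * n_sub
    for s in range(1, total_sub + 1):
        # restraint centre at the *end time* of this substep
        prog = s / n_sub / spec.steps_per_leg
        leg = min(int(prog), n_legs - 1)
        frac = prog - leg
        centre_scaled = wps[leg] + frac * (wps[leg + 1] - wps[leg])
        grad = _gradient_batch(x[None], preset)[0]
        grad += k * (scaling.scale(x) - centre_scaled) / scaling.std
        x = x - mob * grad + amp * rng.standard_normal(x.shape)
        if s % n_sub == 0:
            step = s // n_sub
            if step % save_stride == 0:
                frames.append(x.copy())
        if np.any(np.abs(x - preset.box_centre) > 10.0 * preset.box_half_widths):
            raise FloatingPointError("steering diverged; decrease timestep")
    return FeatureTrajectory(np.array(frames), preset.feature_names,
                             preset.units,
                             frame_spacing=save_stride * preset.timestep,
                             provenance="steered")


# --------------------------------------------------------------------------
# seeds and seeded pool
# --------------------------------------------------------------------------

def extract_seeds(steered: FeatureTrajectory, n_seeds: int,
                  scaling: FeatureScaling) -> list[tuple[int, np.ndarray]]:
    """Frames equally spaced along the steered path's arc length.

    Cumulative Euclidean arc length is computed in scaled feature space; the
    frames nearest to ``n_seeds`` equally spaced arc-length values (endpoints
    included) are returned as strictly increasing (frame index, features)
    pairs.  A degenerate zero-length path falls back to uniform-in-time
    spacing with a warning.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    F = steered.n_frames
    if F < n_seeds:
        raise ValueError("trajectory has fewer frames than requested seeds")
    y = scaling.scale(steered.frames)
    seg = np.linalg.norm(np.diff(y, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        warnings.warn("degenerate steered path (zero arc length); "
                      "falling back to uniform-in-time seed spacing")
        idx = np.round(np.linspace(0, F - 1, n_seeds)).astype(int)
    else:
        targets = np.linspace(0.0, arc[-1], n_seeds)
        idx = np.abs(arc[None, :] - targets[:, None]).argmin(axis=1)
    # enforce strictly increasing indices with fixed endpoints
    idx = idx.astype(int)
    idx[0], idx[-1] = 0, F - 1
    for i in range(1, n_seeds):
        idx[i] = max(idx[i], idx[i - 1] + 1)
    for i in range(n_seeds - 2, -1, -1):
        idx[i] = min(idx[i], idx[i + 1] - 1)
    return [(int(i), steered.frames[i].copy()) for i in idx]


def generate_seeded_pool(preset: GeneratorPreset, seeds,
                         traj_len: int, save_stride: int = 1,
                         seed: int = 0) -> list[FeatureTrajectory]:
    """One unbiased trajectory of ``traj_len`` integration steps per seed
    point.  Each trajectory's noise stream is derived from (master seed,
    trajectory index), so the pool is reproducible and order-independent."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed point")
    starts = np.array([np.asarray(s[1] if isinstance(s, tuple) else s,
                                  dtype=float) for s in seeds])
    for st in starts:
        if not preset.inside_box(st):
            raise ValueError("seed point outside confinement box")
    rngs = [_rng_for(seed, i) for i in range(len(seeds))]
    frames = _integrate_batch(preset, starts, rngs, traj_len, save_stride)
    spacing = save_stride * preset.timestep
    return [FeatureTrajectory(frames[i], preset.feature_names, preset.units,
                              frame_spacing=spacing, provenance="seeded",
                              seed_index=i)
            for i in range(len(seeds))]


# --------------------------------------------------------------------------
# toy structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyTopology:
    """Bead model with four disjoint groups (RR, hinge, PBC, CR) arranged so
    any feature vector can be realised exactly and read back by the
    featurization module (round-trip contract).

    ``base_coords`` is the geometry at ``base_angle`` with both RMSD features
    zero; ``displacement_sign`` holds ±1 for the mobile hinge/PBC bead pairs
    (displaced along z in opposite directions so group centroids are
    invariant) and 0 elsewhere.
    """

    topology: Topology
    base_coords: np.ndarray
    rr_mask: np.ndarray
    hinge_mobile_mask: np.ndarray
    pbc_mask: np.ndarray
    displacement_sign: np.ndarray
    base_angle: float  # degrees


def default_toy_topology() -> ToyTopology:
    """The shipped bead layout.

    CR: residues 1–6 (Cα beads around (20, 0, 0); residue 6 also carries
    N/CB/CG atoms so χ1 is defined).  Hinge: static residues 7–10 and mobile
    residues 11–14 around the origin.  PBC: residues 15–18.  RR: residues
    19–24 around (0, 20, 0), i.e. a 90° base inter-domain angle.
    """
    rows = []  # (resid, resname, atom, group, xyz)

    def add(resid, atom, group, xyz, resname="BEA"):
        rows.append((resid, resname, atom, group, xyz))

    cr_ca = [(22, 0, 0), (18, 0, 0), (20, 2, 0), (20, -2, 0), (20, 0, 2),
             (20, 0, -2)]
    for i, xyz in enumerate(cr_ca, start=1):
        add(i, "CA", "CR", xyz)
    # χ1 atoms of residue 6 (gauche-ish arrangement)
    add(6, "N", "CR", (19.0, 0.0, -2.8))
    add(6, "CB", "CR", (20.9, 0.9, -2.6))
    add(6, "CG", "CR", (21.6, 0.6, -3.9))

    hinge_static = [(0.8, 0.8, 0), (-0.8, 0.8, 0), (0.8, -0.8, 0),
                    (-0.8, -0.8, 0)]
    for i, xyz in enumerate(hinge_static, start=7):
        add(i, "CA", "hinge", xyz)
    hinge_mobile = [(0.0, 1.5, 0.4), (0.0, 1.5, -0.4), (0.0, -1.5, 0.4),
                    (0.0, -1.5, -0.4)]
    for i, xyz in enumerate(hinge_mobile, start=11):
        add(i, "CA", "hinge", xyz)

    pbc = [(3.0, 0.0, -3.0), (3.6, 0.0, -3.0), (3.0, 0.6, -3.0),
           (3.6, 0.6, -3.0)]
    for i, xyz in enumerate(pbc, start=15):
        add(i, "CA", "PBC", xyz)

    rr = [(0, 22, 0), (0, 18, 0), (2, 20, 0), (-2, 20, 0), (0, 20, 2),
          (0, 20, -2)]
    for i, xyz in enumerate(rr, start=19):
        add(i, "CA", "RR", xyz)

    resid = np.array([r[0] for r in rows])
    resname = np.array([r[1] for r in rows], dtype=object)
    name = np.array([r[2] for r in rows], dtype=object)
    group = np.array([r[3] for r in rows], dtype=object)
    coords = np.array([r[4] for r in rows], dtype=float)
    top = Topology(resid, resname, name, group)

    sign = np.zeros(len(rows))
    mobile = (resid >= 11) & (resid <= 14)
    pbc_mask = group == "PBC"
    # ± pairs along z
    sign[np.flatnonzero(mobile)] = [1.0, -1.0, 1.0, -1.0]
    sign[np.flatnonzero(pbc_mask)] = [1.0, -1.0, 1.0, -1.0]
    return ToyTopology(
        topology=top,
        base_coords=coords,
        rr_mask=group == "RR",
        hinge_mobile_mask=mobile,
        pbc_mask=pbc_mask,
        displacement_sign=sign,
        base_angle=90.0,
    )


def default_toy_regions():
    """RegionSpec matching :func:`default_toy_topology`."""
    from .featurize import RegionSpec

    return RegionSpec(
        fit_region="resid 1-10 and name CA",
        rr="group RR",
        hinge="group hinge",
        pbc="group PBC",
        cr="group CR",
        hinge_calc="resid 11-14 and name CA",
        pbc_calc="resid 15-18 and name CA",
    )


def embed_structure(point: np.ndarray, toy: ToyTopology) -> StructureFrame:
    """Realise a feature vector (angle°, hinge RMSD Å, PBC RMSD Å) as bead
    coordinates: the RR group rotates rigidly about the hinge centroid to the
    requested angle; mobile hinge and PBC bead pairs are displaced ±RMSD along
    z (so the featurization round trip is exact)."""
    angle, hinge_rmsd, pbc_rmsd = np.asarray(point, dtype=float)
    if not (0.0 < angle < 180.0):
        raise ValueError("angle must lie strictly inside (0°, 180°)")
    if hinge_rmsd < 0 or pbc_rmsd < 0:
        raise ValueError("RMSD features must be >= 0")
    coords = toy.base_coords.copy()
    theta = math.radians(angle - toy.base_angle)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    coords[toy.rr_mask] = coords[toy.rr_mask] @ rot.T
    coords[toy.hinge_mobile_mask, 2] += (
        toy.displacement_sign[toy.hinge_mobile_mask] * hinge_rmsd)
    coords[toy.pbc_mask, 2] += toy.displacement_sign[toy.pbc_mask] * pbc_rmsd
    return StructureFrame(toy.topology, coords)


def toy_reference_set(toy: ToyTopology, inactive_point=(30.0, 0.0, 0.0)):
    """ReferenceSet whose inactive reference realises ``inactive_point``."""
    from .featurize import ReferenceSet

    return ReferenceSet(inactive=embed_structure(inactive_point, toy))


# --------------------------------------------------------------------------
# shipped presets
# --------------------------------------------------------------------------

_DEFAULT_CENTRES = np.array([
    [30.0, 1.5, 1.0],    # inactive
    [60.0, 2.0, 2.5],    # intermediate
    [100.0, 7.0, 2.5],   # active
])
_DEFAULT_WIDTHS = np.array([[10.0, 0.8, 0.4]] * 3)
_DEFAULT_BOX_CENTRE = np.array([65.0, 4.3, 1.75])
_DEFAULT_BOX_HALF = np.array([43.0, 4.1, 1.75])
_D0 = 0.001        # scaled-space diffusion per step
_WALL_SCALE = 50.0  # wall stiffness in kT per scaled-unit²

# Calibration defaults of this package (NOT measured values): per-preset well
# depths in kT for (inactive, intermediate, active), chosen so the exact
# Boltzmann active-state probabilities order as
# apo < partial < agonist <= partial-restrained.
_PRESET_DEPTHS = {
    "apo": (7.8, 7.3, 2.3),
    "agonist": (4.3, 5.8, 7.8),
    "mutant": (6.3, 8.0, 1.3),
    "partial": (6.8, 7.3, 5.3),
    "partial-restrained": (3.8, 4.8, 8.6),
}


def make_preset(name: str, depths, centres=None, widths=None,
                diffusion_scale: float = _D0) -> GeneratorPreset:
    centres = np.asarray(centres if centres is not None else _DEFAULT_CENTRES,
                         dtype=float)
    widths = np.asarray(widths if widths is not None else _DEFAULT_WIDTHS,
                        dtype=float)
    s = centres.std(axis=0)
    s = np.where(s > 1e-12, s, widths.mean(axis=0))
    return GeneratorPreset(
        name=name,
        well_centres=centres,
        well_depths=np.asarray(depths, dtype=float),
        well_widths=widths,
        box_centre=_DEFAULT_BOX_CENTRE.copy(),
        box_half_widths=_DEFAULT_BOX_HALF.copy(),
        wall_stiffness=_WALL_SCALE / s ** 2,
        diffusion=diffusion_scale * s ** 2,
    )


def builtin_presets() -> dict[str, GeneratorPreset]:
    """The five shipped system presets (emulating apo, full agonist, inactive
    mutant, partial agonist, and restrained partial agonist energetics)."""
    return {nm: make_preset(nm, d) for nm, d in _PRESET_DEPTHS.items()}


def default_macrostate_centres(preset: GeneratorPreset,
                               scaling: FeatureScaling | None = None) -> StateCentres:
    """Macrostate centres at the landscape's well centres, named
    inactive/intermediate/active, under the given (default: canonical)
    scaling."""
    if preset.n_wells != len(MACROSTATE_NAMES):
        raise ValueError("default macrostates require a 3-well preset")
    return StateCentres(
        names=MACROSTATE_NAMES,
        centres=preset.well_centres.copy(),
        scaling=scaling or FeatureScaling.from_preset(preset),
    )


def load_preset(path) -> GeneratorPreset:
    """Load a preset from a TOML file.

    Schema (all keys under ``[preset]``): name (str), well_centres (list of
    d-lists), well_depths (list), well_widths (list of d-lists), box_centre,
    box_half_widths, wall_stiffness, diffusion (d-lists), timestep,
    temperature_factor (floats).  Missing geometry keys fall back to the
    shipped defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    p = doc.get("preset", doc)
    if "name" not in p or "well_depths" not in p:
        raise ValueError("preset file requires at least 'name' and 'well_depths'")
    base = make_preset(p["name"], p["well_depths"],
                       centres=p.get("well_centres"),
                       widths=p.get("well_widths"))
    overrides = {}
    for key in ("box_centre", "box_half_widths", "wall_stiffness", "diffusion"):
        if key in p:
            overrides[key] = np.asarray(p[key], dtype=float)
    for key in ("timestep", "temperature_factor"):
        if key in p:
            overrides[key] = float(p[key])
    return replace(base, **overrides) if overrides else base
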