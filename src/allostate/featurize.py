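"""Structural descriptors for conformational-state analysis.

This module computes the low-dimensional descriptors used throughout the
package to characterise large-scale domain rearrangements: superposition-based
region RMSDs, the inter-domain (RR–hinge–CR) angle, minimum inter-group
Cα distances, atom-group distances, χ1 side-chain dihedrals, and per-residue
RMSF relative to a fixed reference conformation.

Conventions
-----------
* Coordinates are in Å; angles and dihedrals in degrees.
* Residue indices are 1-based and selection ranges are inclusive.
* "Backbone" means atoms named N, CA, C, O.
* Region RMSDs are computed after a single rigid-body superposition on the
  ``fit_region`` selection; the calc region is *not* re-fit.
* RMSF here is the weighted root-mean-square deviation of each residue from a
  fixed reference structure — not the conventional fluctuation about the
  ensemble mean.  This matches the "deviation from the inactive conformation"
  convention used for hinge-melting analyses.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Per-atom metadata shared by all frames of a trajectory.

    Attributes
    ----------
    resid : (N,) int array, 1-based residue indices.
    resname : (N,) str array.
    name : (N,) str array of atom names (e.g. "CA").
    group : (N,) str array of region labels (e.g. "RR", "hinge", "PBC", "CR");
        stored in the chain-ID slot when written to PDB.
    """

    resid: np.ndarray
    resname: np.ndarray
    name: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        n = len(self.resid)
        for f in ("resname", "name", "group"):
            if len(getattr(self, f)) != n:
                raise ValueError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.resid)


@dataclass(frozen=True)
class StructureFrame:
    """A single conformation: coordinates plus shared topology."""

    topology: Topology
    coords: np.ndarray  # (N, 3) Å

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (self.topology.n_atoms, 3):
            raise ValueError("coords shape does not match topology")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class StructuralTrajectory:
    """Frames sharing one topology; coords shape (F, N, 3)."""

    topology: Topology
    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError("coords must be (F, N, 3) matching topology")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coords", c)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureFrame:
        return StructureFrame(self.topology, self.coords[i])

    @classmethod
    def from_frames(cls, frames) -> "StructuralTrajectory":
        frames = list(frames)
        if not frames:
            raise ValueError("empty frame list")
        return cls(frames[0].topology, np.stack([f.coords for f in frames]))


@dataclass(frozen=True)
class RegionSpec:
    """Named atom selections (mini-grammar strings, see :func:`parse_selection`).

    ``fit_region`` is used for every rigid superposition; ``hinge_calc`` /
    ``pbc_calc`` are the RMSD measurement regions (defaulting to the full
    hinge / PBC groups).
    """

    fit_region: str
    rr: str
    hinge: str
    pbc: str
    cr: str
    hinge_calc: str | None = None
    pbc_calc: str | None = None

    @property
    def hinge_rmsd_region(self) -> str:
        return self.hinge_calc if self.hinge_calc is not None else self.hinge

    @property
    def pbc_rmsd_region(self) -> str:
        return self.pbc_calc if self.pbc_calc is not None else self.pbc


@dataclass(frozen=True)
class ReferenceSet:
    """Labelled reference conformations. Features are measured relative to
    the inactive reference."""

    inactive: StructureFrame
    intermediate: StructureFrame | None = None
    active: StructureFrame | None = None


# --------------------------------------------------------------------------
# selection mini-grammar
# --------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def parse_selection(expr: str, topology: Topology) -> np.ndarray:
    """Resolve a selection string to a boolean atom mask.

    Grammar: clauses joined by ``and``; each clause is one of

    * ``all``
    * ``resid <tokens>`` where tokens are 1-based indices or inclusive
      ranges, e.g. ``resid 223-227 231``
    * ``name <atom names>``, e.g. ``name N CA C O``
    * ``group <labels>``, e.g. ``group hinge PBC``
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in (c.strip() for c in expr.split(" and ")):
        if not clause:
            raise ValueError("empty selection clause")
        tokens = clause.split()
        kw, args = tokens[0], tokens[1:]
        if kw == "all":
            continue
        if not args:
            raise ValueError(f"selection clause {clause!r} has no arguments")
        if kw == "resid":
            sub = np.zeros(topology.n_atoms, dtype=bool)
            for tok in args:
                m = _RANGE_RE.match(tok)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    sub |= (topology.resid >= lo) & (topology.resid <= hi)
                else:
                    sub |= topology.resid == int(tok)
            mask &= sub
        elif kw == "name":
            mask &= np.isin(topology.name, args)
        elif kw == "group":
            mask &= np.isin(topology.group, args)
        else:
            raise ValueError(f"unknown selection keyword {kw!r}")
    if not mask.any():
        raise ValueError(f"selection {expr!r} matches no atoms")
    return mask


def _ca_mask(topology: Topology, base: np.ndarray) -> np.ndarray:
    """Restrict a mask to Cα (or designated bead) atoms when present."""
    ca = base & (topology.name == "CA")
    return ca if ca.any() else base


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_mask: np.ndarray | None = None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (N, 3) coordinate arrays sharing an atom order.
    fit_mask : optional boolean mask selecting the fit atoms.

    Returns
    -------
    (rotation, translation, rmsd) such that ``mobile @ rotation.T + translation``
    minimises the RMSD over the fit atoms.  The rotation is always proper
    (determinant +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if fit_mask is not None:
        mob_fit, ref_fit = mob[fit_mask], ref[fit_mask]
    else:
        mob_fit, ref_fit = mob, ref
    if len(mob_fit) < 3:
        raise ValueError("need at least 3 fit atoms")
    mc, rc = mob_fit.mean(axis=0), ref_fit.mean(axis=0)
    a, b = mob_fit - mc, ref_fit - rc
    # collinear fit atoms leave the rotation about the line undetermined
    if np.linalg.matrix_rank(a, tol=1e-8 * max(1.0, np.abs(a).max())) < 2:
        raise ValueError("degenerate (collinear) fit atoms")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    fitted = mob_fit @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_fit) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------

def region_rmsd(traj: StructuralTrajectory, reference: StructureFrame,
                fit_selection: str, calc_selection: str) -> np.ndarray:
    """Per-frame RMSD (Å) of ``calc_selection`` to the reference, after
    superposing each frame on ``fit_selection`` (no re-fit on the calc region)."""
    top = traj.topology
    fit = parse_selection(fit_selection, top)
    calc = parse_selection(calc_selection, top)
    if reference.topology.n_atoms != top.n_atoms:
        raise ValueError("reference topology incompatible with trajectory")
    ref = reference.coords
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[i], ref, fit)
        moved = apply_transform(traj.coords[i][calc], R, t)
        out[i] = np.sqrt(np.mean(np.sum((moved - ref[calc]) ** 2, axis=1)))
    return out


def _group_centroids(traj: StructuralTrajectory, selection: str) -> np.ndarray:
    mask = _ca_mask(traj.topology, parse_selection(selection, traj.topology))
    return traj.coords[:, mask, :].mean(axis=1)


def domain_angle(traj: StructuralTrajectory, regions: RegionSpec) -> np.ndarray:
    """Per-frame inter-domain angle (degrees): the angle at the hinge-group
    centroid between vectors to the RR and CR centroids (unweighted Cα
    centroids). Values lie in (0°, 180°]."""
    rr = _group_centroids(traj, regions.rr)
    hinge = _group_centroids(traj, regions.hinge)
    cr = _group_centroids(traj, regions.cr)
    u, v = rr - hinge, cr - hinge
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("coincident group centroids")
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def min_intergroup_distance(traj: StructuralTrajectory, selection_a: str,
                            selection_b: str) -> np.ndarray:
    """Per-frame minimum distance (Å) over all cross pairs of two selections."""
    ma = parse_selection(selection_a, traj.topology)
    mb = parse_selection(selection_b, traj.topology)
    return np.array([cdist(fr[ma], fr[mb]).min() for fr in traj.coords])


def group_pair_distance(traj: StructuralTrajectory, selection_a: str,
                        selection_b: str, mode: str = "centroid") -> np.ndarray:
    """Per-frame distance (Å) between two atom groups.

    ``mode="centroid"`` uses unweighted centroids; ``mode="min"`` the minimum
    cross-pair distance."""
    if mode == "min":
        return min_intergroup_distance(traj, selection_a, selection_b)
    if mode != "centroid":
        raise ValueError(f"unknown mode {mode!r}")
    ma = parse_selection(selection_a, traj.topology)
    mb = parse_selection(selection_b, traj.topology)
    ca = traj.coords[:, ma, :].mean(axis=1)
    cb = traj.coords[:, mb, :].mean(axis=1)
    return np.linalg.norm(ca - cb, axis=1)


_CHI1_GAMMA = ("CG", "CG1", "SG", "OG", "OG1")


def chi1_dihedral(traj: StructuralTrajectory, resid: int) -> np.ndarray:
    """Per-frame χ1 dihedral (degrees, in (−180°, 180°]) of one residue.

    Defined over atoms N–CA–CB–Cγ, where the γ atom is the first present of
    CG, CG1, SG, OG, OG1.  IUPAC sign convention; no unwrapping.
    """
    top = traj.topology
    res = top.resid == resid
    if not res.any():
        raise ValueError(f"residue {resid} not in topology")

    def _one(name_options):
        for nm in name_options:
            idx = np.flatnonzero(res & (top.name == nm))
            if idx.size:
                return idx[0]
        raise ValueError(f"residue {resid} lacks atom {name_options[0]}")

    i_n = _one(("N",))
    i_ca = _one(("CA",))
    i_cb = _one(("CB",))
    i_g = _one(_CHI1_GAMMA)
    p = traj.coords[:, (i_n, i_ca, i_cb, i_g), :]
    return dihedral_angle(p[:, 0], p[:, 1], p[:, 2], p[:, 3])


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees) of four points, vectorised over leading axes."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components of the outer bonds perpendicular to the central bond
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map −180° to +180° so the range is (−180°, 180°]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def rmsf_to_reference(traj: StructuralTrajectory, reference: StructureFrame,
                      regions: RegionSpec, selection: str | None = None,
                      weights: np.ndarray | None = None) -> "pd_like":
    """Weighted per-residue RMSF (Å) relative to a fixed reference.

    Each frame is superposed on ``regions.fit_region``; then for every residue
    in ``selection`` (default: the hinge group) the Cα deviation from the
    reference is accumulated as sqrt(Σ_f w_f |x_{r,f} − x_{r,ref}|²) with
    normalised frame weights.  This measures deviation from the *reference*
    conformation, not fluctuation about the mean.

    Returns (residue_ids, rmsf_values).
    """
    top = traj.topology
    sel = selection if selection is not None else regions.hinge
    mask = _ca_mask(top, parse_selection(sel, top))
    fit = parse_selection(regions.fit_region, top)
    if weights is None:
        w = np.full(traj.n_frames, 1.0 / traj.n_frames)
    else:
        w = np.asarray(weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("frame weights must sum to 1")
    ref = reference.coords[mask]
    acc = np.zeros(mask.sum())
    for i in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[i], reference.coords, fit)
        moved = apply_transform(traj.coords[i][mask], R, t)
        acc += w[i] * np.sum((moved - ref) ** 2, axis=1)
    return top.resid[mask], np.sqrt(acc)


CANONICAL_FEATURES = ("angle_deg", "hinge_rmsd_A", "pbc_rmsd_A")
CANONICAL_UNITS = ("deg", "A", "A")


def featurize_frame(frame: StructureFrame, regions: RegionSpec,
                    references: ReferenceSet) -> np.ndarray:
    """Feature vector (angle, hinge RMSD, PBC RMSD) of one conformation."""
    traj = StructuralTrajectory(frame.topology, frame.coords[None])
    return featurize_array(traj, regions, references)[0]


def featurize_array(traj: StructuralTrajectory, regions: RegionSpec,
                    references: ReferenceSet) -> np.ndarray:
    ang = domain_angle(traj, regions)
    hng = region_rmsd(traj, references.inactive, regions.fit_region,
                      regions.hinge_rmsd_region)
    pbc = region_rmsd(traj, references.inactive, regions.fit_region,
                      regions.pbc_rmsd_region)
    return np.column_stack([ang, hng, pbc])


def featurize_trajectory(traj: StructuralTrajectory, regions: RegionSpec,
                         references: ReferenceSet, frame_spacing: float = 1.0,
                         provenance: str = "equilibrium"):
    """Reduce a structural trajectory to the canonical 3-feature table.

    Returns a :class:`allostate.toydyn.FeatureTrajectory` (imported lazily to
    keep this module free of simulation dependencies).
    """
    from .toydyn import FeatureTrajectory

    return FeatureTrajectory(
        frames=featurize_array(traj, regions, references),
        feature_names=CANONICAL_FEATURES,
        units=CANONICAL_UNITS,
        frame_spacing=frame_spacing,
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# structure I/O (multi-model PDB via biotite, plain XYZ)
# --------------------------------------------------------------------------

def write_pdb(path, traj: StructuralTrajectory) -> None:
    """Write frames as a multi-model PDB (group label in the chain-ID slot)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = traj.topology
    n = top.n_atoms
    arrays = []
    for fr in traj.coords:
        arr = struc.AtomArray(n)
        arr.coord = fr
        arr.res_id = top.resid.astype(int)
        arr.res_name = np.asarray(top.resname, dtype="U5")
        arr.atom_name = np.asarray(top.name, dtype="U6")
        arr.chain_id = np.asarray([g[0].upper() for g in top.group], dtype="U4")
        arr.element = np.asarray(["C"] * n, dtype="U2")
        arrays.append(arr)
    stack = struc.stack(arrays)
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb(path, group_map: dict | None = None) -> StructuralTrajectory:
    """Read a multi-model PDB; chain IDs become group labels (optionally
    renamed through ``group_map``, e.g. {"R": "RR"})."""
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure(model=None)
    groups = np.asarray(stack.chain_id, dtype=object)
    if group_map:
        groups = np.asarray([group_map.get(g, g) for g in groups], dtype=object)
    top = Topology(
        resid=np.asarray(stack.res_id, dtype=int),
        resname=np.asarray(stack.res_name, dtype=object),
        name=np.asarray(stack.atom_name, dtype=object),
        group=groups,
    )
    return StructuralTrajectory(top, np.asarray(stack.coord, dtype=float))


def read_xyz(path, topology: Topology) -> StructuralTrajectory:
    """Read a plain multi-frame XYZ file against a known topology."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header.split()[0])
            fh.readline()  # comment line
            coords = np.array(
                [fh.readline().split()[1:4] for _ in range(n)], dtype=float
            )
            frames.append(coords)
    if not frames:
        raise ValueError("empty XYZ file")
    return StructuralTrajectory(topology, np.stack(frames))
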