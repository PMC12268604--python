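"""Equilibrium conformational ensembles reweighted by MSM stationary
probabilities.

Every pooled frame receives the sampling weight w_f = π_{s(f)} / N_{s(f)},
where s(f) is the frame's microstate and N_s the number of pooled frames in
that microstate; frames in trimmed (non-active-set) microstates get exactly
zero weight. Ensembles can be drawn (default 10 000 frames, with
replacement), restricted to a single macrostate, and interrogated for
weighted distributional observables (histograms, medians, interquartile
ranges).

Weighted quantile convention: sort by value, accumulate weights; the
q-quantile is the first value whose cumulative weight is ≥ q, except when the
cumulative weight hits q exactly, where the midpoint of the straddling values
is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .msm import MacrostatePartition, TransitionModel
from .toydyn import _rng_for


@dataclass(frozen=True)
class WeightedEnsemble:
    """References to pooled frames with normalised sampling weights.

    ``traj_index`` / ``frame_index`` identify each pooled frame;
    ``sample`` optionally holds the flat indices of a drawn sample
    (with multiplicity).
    """

    traj_index: np.ndarray
    frame_index: np.ndarray
    weights: np.ndarray
    provenance: str = "full-equilibrium"
    sample: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        if w.sum() > 0 and abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def n_frames(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ObservableSpec:
    """Declarative observable over an ensemble.

    ``kind`` is one of "feature" (a feature-table column),
    "group_pair_distance", "min_intergroup_distance", "chi1" or "rmsf";
    ``params`` carries the kind-specific selection parameters; ``bins`` the
    histogram bin edges (optional).
    """

    kind: str
    params: dict = field(default_factory=dict)
    bins: np.ndarray | None = None


def _flat_indices(dtrajs):
    ti = np.concatenate([np.full(len(d), i, dtype=np.int64)
                         for i, d in enumerate(dtrajs)])
    fi = np.concatenate([np.arange(len(d), dtype=np.int64) for d in dtrajs])
    return ti, fi


def frame_weights(model: TransitionModel, dtrajs) -> WeightedEnsemble:
    """MSM stationary weights per pooled frame (w_f = π_s / N_s)."""
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    labels = np.concatenate(dtrajs)
    n_total = int(labels.max()) + 1
    pi_full = model.full_pi(max(n_total, int(model.active_set.max()) + 1))
    occ = np.bincount(labels, minlength=len(pi_full))
    active_empty = (pi_full > 0) & (occ == 0)
    if active_empty.any():
        raise ValueError("active-set microstate(s) with stationary weight but "
                         "no pooled frames; labels inconsistent with model")
    per_state = np.divide(pi_full, occ, out=np.zeros_like(pi_full),
                          where=occ > 0)
    w = per_state[labels]
    w = w / w.sum()
    ti, fi = _flat_indices(dtrajs)
    return WeightedEnsemble(ti, fi, w)


def sample_ensemble(ensemble: WeightedEnsemble, n: int = 10_000,
                    seed: int = 0) -> WeightedEnsemble:
    """Draw ``n`` frames with replacement according to the ensemble weights."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _rng_for(seed)
    idx = rng.choice(ensemble.n_frames, size=n, replace=True,
                     p=ensemble.weights)
    return WeightedEnsemble(ensemble.traj_index, ensemble.frame_index,
                            ensemble.weights, provenance=ensemble.provenance,
                            sample=idx)


def state_subensemble(dtrajs, partition: MacrostatePartition, state: str,
                      model: TransitionModel) -> WeightedEnsemble:
    """Ensemble restricted to frames whose microstate belongs to one named
    macrostate, with weights renormalised within the state."""
    if state not in partition.names:
        raise ValueError(f"unknown macrostate {state!r}")
    s = partition.names.index(state)
    full = frame_weights(model, dtrajs)
    labels = np.concatenate([np.asarray(d, dtype=np.int64) for d in dtrajs])
    in_state = partition.micro_to_macro[labels] == s
    w = np.where(in_state, full.weights, 0.0)
    total = w.sum()
    if total <= 0:
        warnings.warn(f"macrostate {state!r} holds no stationary weight; "
                      "returning an empty ensemble")
        return WeightedEnsemble(full.traj_index, full.frame_index,
                                np.zeros_like(w),
                                provenance=f"macrostate:{state}")
    return WeightedEnsemble(full.traj_index, full.frame_index, w / total,
                            provenance=f"macrostate:{state}")


# --------------------------------------------------------------------------
# weighted statistics
# --------------------------------------------------------------------------

def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q: float) -> float:
    """Cumulative-weight quantile with midpoint interpolation at exact hits
    (see module docstring)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise ValueError("empty (all-zero-weight) sample")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w) / w.sum()
    i = int(np.searchsorted(cw, q, side="left"))
    i = min(i, v.size - 1)
    if i + 1 < v.size and abs(cw[i] - q) <= 1e-12:
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[i])


def evaluate_observable(spec: ObservableSpec, ensemble: WeightedEnsemble,
                        features=None, structures=None) -> np.ndarray:
    """Per-frame observable values for an ensemble's frames (lazy evaluation:
    feature-table and structural ensembles share this path).

    ``features`` is a list of per-trajectory feature arrays (for
    kind="feature" with params {"column": int|name}); ``structures`` a
    :class:`allostate.featurize.StructuralTrajectory` indexed by the
    ensemble's flat frame order (for the geometric kinds).
    """
    from . import featurize as fz

    if spec.kind == "feature":
        if features is None:
            raise ValueError("feature observable requires feature tables")
        col = spec.params["column"]
        arrs = []
        for t in features:
            fr = t.frames if hasattr(t, "frames") else np.asarray(t, float)
            if isinstance(col, str):
                names = list(getattr(t, "feature_names", []))
                arrs.append(fr[:, names.index(col)])
            else:
                arrs.append(fr[:, col])
        flat = np.concatenate(arrs)
        return flat
    if structures is None:
        raise ValueError(f"{spec.kind!r} observable requires structures")
    p = spec.params
    if spec.kind == "group_pair_distance":
        return fz.group_pair_distance(structures, p["selection_a"],
                                      p["selection_b"],
                                      mode=p.get("mode", "centroid"))
    if spec.kind == "min_intergroup_distance":
        return fz.min_intergroup_distance(structures, p["selection_a"],
                                          p["selection_b"])
    if spec.kind == "chi1":
        return fz.chi1_dihedral(structures, p["resid"])
    raise ValueError(f"unknown observable kind {spec.kind!r}")


def observable_distribution(values: np.ndarray, ensemble: WeightedEnsemble,
                            bins=None) -> dict:
    """Weighted histogram plus summary statistics of one observable.

    ``values`` are per-frame observable values in the ensemble's flat frame
    order.  Returns the raw values and weights alongside the summaries so
    every number is recomputable.
    """
    v = np.asarray(values, dtype=float)
    w = ensemble.weights
    if v.shape[0] != w.shape[0]:
        raise ValueError("one value per ensemble frame required")
    if w.sum() <= 0:
        raise ValueError("empty ensemble")
    if bins is None:
        keep = w > 0
        lo, hi = v[keep].min(), v[keep].max()
        bins = np.linspace(lo, hi if hi > lo else lo + 1.0, 51)
    hist, edges = np.histogram(v, bins=bins, weights=w)
    return {
        "values": v,
        "weights": w,
        "hist": hist,
        "bin_edges": edges,
        "mean": float(np.average(v, weights=w)),
        "median": weighted_quantile(v, w, 0.5),
        "q1": weighted_quantile(v, w, 0.25),
        "q3": weighted_quantile(v, w, 0.75),
    }
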