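"""Markov state model estimation on pooled feature trajectories.

Pipeline order: z-score scaling of the pooled features → k-means microstate
discretization → sliding-window transition counting at lag τ → ergodic
trimming to the largest strongly connected set → maximum-likelihood transition
matrix (reversible by default) → stationary distribution, implied timescales,
and lumping of microstates into named macrostates by a nearest-centre rule in
scaled feature space.

The reversible estimator maximises the likelihood Σ C_ij ln T_ij subject to
detailed balance π_i T_ij = π_j T_ji by the classic self-consistent
fixed-point iteration

    x_ij ← (C_ij + C_ji) / (c_i / x_i + c_j / x_j)

with c_i = Σ_j C_ij and x_i = Σ_j x_ij, initialised from x = C + Cᵀ; at
convergence T_ij = x_ij / x_i and π_i = x_i / Σ x.

Tie-breaking everywhere (frame assignment, macrostate lumping) is "lowest
index wins". Macrostate centre defaults put the inactive / intermediate /
active states at domain angles of 30° / 60° / 100°; the RMSD components are
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .toydyn import FeatureScaling, FeatureTrajectory, MACROSTATE_NAMES

DEFAULT_N_CLUSTERS = 300   # microstate count
DEFAULT_LAG = 25           # frames (1 frame ≙ 1 ns in the default bookkeeping)


def _pool_frames(pool) -> np.ndarray:
    arrs = [t.frames if isinstance(t, FeatureTrajectory) else np.asarray(t, float)
            for t in pool]
    if not arrs:
        raise ValueError("empty trajectory pool")
    return np.concatenate(arrs, axis=0)


# --------------------------------------------------------------------------
# scaling + discretization
# --------------------------------------------------------------------------

def fit_scaling(pool) -> FeatureScaling:
    """Pooled per-feature mean and standard deviation (population std).

    Raises on zero-variance features, which cannot be z-scored.
    """
    x = _pool_frames(pool)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    if np.any(std <= 0):
        bad = [i for i, s in enumerate(std) if s <= 0]
        raise ValueError(f"zero-variance feature(s) at column(s) {bad}")
    return FeatureScaling(mean, std)


@dataclass(frozen=True)
class Discretization:
    """k-means microstates in scaled feature space.

    ``centres`` are stored in *scaled* coordinates; ``scaling`` reconstructs
    physical units and assigns new frames consistently.  ``labels`` holds one
    integer array per pooled trajectory.
    """

    centres: np.ndarray          # (k, d), scaled space
    labels: list                 # list of (F_i,) int arrays
    scaling: FeatureScaling
    inertia: float
    seed: int

    @property
    def n_states(self) -> int:
        return self.centres.shape[0]

    def centres_physical(self) -> np.ndarray:
        return self.scaling.unscale(self.centres)


def kmeans_cluster(pool, k: int = DEFAULT_N_CLUSTERS, seed: int = 0,
                   max_iter: int = 300, tol: float = 1e-6,
                   scaling: FeatureScaling | None = None) -> Discretization:
    """k-means microstate discretization of the pooled, z-scored features."""
    from sklearn.cluster import KMeans

    pool = list(pool)
    x = _pool_frames(pool)
    if x.shape[0] < k:
        raise ValueError("fewer pooled frames than requested clusters")
    if scaling is None:
        scaling = fit_scaling(pool)
    y = scaling.scale(x)
    if np.unique(y, axis=0).shape[0] < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=k, n_init=1, max_iter=max_iter, tol=tol,
                random_state=int(seed) % (2 ** 32))
    km.fit(y)
    centres = km.cluster_centers_
    flat = assign_points(y, centres)
    lengths = [t.frames.shape[0] if isinstance(t, FeatureTrajectory)
               else np.asarray(t).shape[0] for t in pool]
    labels, off = [], 0
    for n in lengths:
        labels.append(flat[off:off + n].copy())
        off += n
    return Discretization(centres=centres, labels=labels, scaling=scaling,
                          inertia=float(km.inertia_), seed=int(seed))


def assign_points(scaled_points: np.ndarray, centres: np.ndarray,
                  chunk: int = 100_000) -> np.ndarray:
    """Nearest-centre labels (Euclidean, ties to the lowest centre index)."""
    y = np.atleast_2d(np.asarray(scaled_points, dtype=float))
    if y.shape[1] != centres.shape[1]:
        raise ValueError("dimensionality mismatch with cluster centres")
    out = np.empty(y.shape[0], dtype=np.int64)
    c2 = (centres ** 2).sum(axis=1)
    for lo in range(0, y.shape[0], chunk):
        blk = y[lo:lo + chunk]
        # squared distances via the expansion trick; argmin takes lowest index
        d2 = c2[None, :] - 2.0 * blk @ centres.T
        out[lo:lo + chunk] = d2.argmin(axis=1)
    return out


def assign_frames(features, discretization: Discretization) -> np.ndarray:
    """Microstate labels for new frames under a frozen discretization."""
    x = features.frames if isinstance(features, FeatureTrajectory) \
        else np.atleast_2d(np.asarray(features, dtype=float))
    return assign_points(discretization.scaling.scale(x),
                         discretization.centres)


# --------------------------------------------------------------------------
# counting and connectivity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    counts: np.ndarray  # (k, k) int64
    lag: int
    mode: str = "sliding"

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


def count_transitions(dtrajs, lag: int, n_states: int | None = None,
                      mode: str = "sliding") -> CountMatrix:
    """Sliding-window transition counts: every ordered pair (t, t+lag) within
    each trajectory; no cross-trajectory pairs.  Trajectories shorter than
    lag+1 contribute nothing (with a warning)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode != "sliding":
        raise ValueError(f"unsupported counting mode {mode!r}")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if n_states is None:
        n_states = int(max((d.max() for d in dtrajs if d.size), default=-1)) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    short = 0
    for d in dtrajs:
        if d.size <= lag:
            short += 1
            continue
        np.add.at(C, (d[:-lag], d[lag:]), 1)
    if short:
        warnings.warn(f"{short} trajectorie(s) shorter than lag+1 contributed "
                      "zero counts")
    return CountMatrix(C, lag=lag, mode=mode)


def largest_connected_set(C: CountMatrix | np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the transition graph
    (edge i→j iff C[i,j] > 0), ranked by total outgoing count mass; returns
    sorted state indices."""
    M = C.counts if isinstance(C, CountMatrix) else np.asarray(C)
    if M.shape[0] != M.shape[1]:
        raise ValueError("count matrix must be square")
    if not M.any():
        raise ValueError("all-zero count matrix")
    g = nx.from_numpy_array(M > 0, create_using=nx.DiGraph)
    row_mass = M.sum(axis=1)
    best, best_mass = None, -1.0
    for comp in nx.strongly_connected_components(g):
        mass = row_mass[list(comp)].sum()
        if mass > best_mass or (mass == best_mass and min(comp) < min(best)):
            best, best_mass = comp, mass
    return np.array(sorted(best), dtype=np.int64)


# --------------------------------------------------------------------------
# transition-matrix estimators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition matrix on the active set at lag τ, with its
    stationary distribution."""

    active_set: np.ndarray   # sorted microstate indices
    T: np.ndarray            # (n, n) row-stochastic
    pi: np.ndarray           # (n,) stationary distribution
    lag: int
    estimator: str           # "reversible" | "nonreversible"
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "active_set",
                           np.asarray(self.active_set, dtype=np.int64))

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def full_pi(self, n_total: int) -> np.ndarray:
        """π embedded in the full microstate index space (trimmed states 0)."""
        out = np.zeros(n_total)
        out[self.active_set] = self.pi
        return out


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    from scipy.linalg import eig

    vals, vecs = eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_nonreversible(C: CountMatrix | np.ndarray,
                           active_set: np.ndarray | None = None,
                           lag: int | None = None) -> TransitionModel:
    """Plain maximum likelihood: T = row-normalised counts; π from the leading
    left eigenvector."""
    M = C.counts if isinstance(C, CountMatrix) else np.asarray(C, dtype=float)
    lag = lag if lag is not None else (C.lag if isinstance(C, CountMatrix) else 1)
    if active_set is None:
        active_set = largest_connected_set(M)
    A = M[np.ix_(active_set, active_set)].astype(float)
    rows = A.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("zero row sum on the active set")
    T = A / rows[:, None]
    return TransitionModel(active_set, T, _stationary_from_T(T), lag,
                           "nonreversible")


def reversible_loglik(C: np.ndarray, T: np.ndarray) -> float:
    mask = C > 0
    return float((C[mask] * np.log(T[mask])).sum())


def estimate_reversible(C: CountMatrix | np.ndarray,
                        active_set: np.ndarray | None = None,
                        lag: int | None = None, tol: float = 1e-12,
                        max_iter: int = 100_000) -> TransitionModel:
    """Detailed-balance maximum-likelihood transition matrix via the
    fixed-point iteration on the unnormalised symmetric flux matrix x
    (see module docstring).  Converged when the relative log-likelihood
    change drops below ``tol``."""
    M = C.counts if isinstance(C, CountMatrix) else np.asarray(C, dtype=float)
    lag = lag if lag is not None else (C.lag if isinstance(C, CountMatrix) else 1)
    if active_set is None:
        active_set = largest_connected_set(M)
    A = M[np.ix_(active_set, active_set)].astype(float)
    c = A.sum(axis=1)
    if np.any(c <= 0):
        raise ValueError("zero row sum on the active set; trim connectivity first")
    S = A + A.T
    x = S.copy()
    pos = S > 0
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        xi = x.sum(axis=1)
        q = c / xi
        denom = q[:, None] + q[None, :]
        x = np.where(pos, S / np.where(denom > 0, denom, 1.0), 0.0)
        xi = x.sum(axis=1)
        T = x / xi[:, None]
        ll = reversible_loglik(A, T)
        if abs(ll - ll_old) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    if not converged:
        warnings.warn(f"reversible MLE did not converge in {max_iter} "
                      f"iterations (last rel. change "
                      f"{abs(ll - ll_old) / max(1.0, abs(ll)):.2e})")
    xi = x.sum(axis=1)
    pi = xi / xi.sum()
    T = x / xi[:, None]
    return TransitionModel(active_set, T, pi, lag, "reversible",
                           n_iter=it, converged=converged)


def estimate(C, estimator: str = "reversible", **kw) -> TransitionModel:
    if estimator == "reversible":
        return estimate_reversible(C, **kw)
    if estimator == "nonreversible":
        return estimate_nonreversible(C, **kw)
    raise ValueError(f"unknown estimator {estimator!r}")


# --------------------------------------------------------------------------
# implied timescales
# --------------------------------------------------------------------------

def timescales_from_model(model: TransitionModel,
                          n_timescales: int = 2) -> np.ndarray:
    """Implied timescales t_i = −τ / ln λ_i for the largest nontrivial
    eigenvalues; λ outside (0, 1) yields NaN (undefined at finite data)."""
    if model.estimator == "reversible":
        # symmetrize with π^{1/2} for a stable real spectrum
        s = np.sqrt(model.pi)
        sym = (s[:, None] * model.T) / s[None, :]
        vals = np.linalg.eigvalsh((sym + sym.T) / 2.0)
    else:
        vals = np.real(np.linalg.eigvals(model.T))
    vals = np.sort(vals)[::-1]
    nontrivial = vals[1:1 + n_timescales]
    out = np.full(n_timescales, np.nan)
    for i, lam in enumerate(nontrivial):
        if 0.0 < lam < 1.0:
            out[i] = -model.lag / np.log(lam)
    return out


def implied_timescales(dtrajs, lags, n_timescales: int = 2,
                       estimator: str = "reversible",
                       n_states: int | None = None) -> dict[int, np.ndarray]:
    """Implied-timescale table {lag: timescales (frames)} for lag selection.
    Undefined timescales (λ ≤ 0 or ≥ 1) are reported as NaN."""
    table = {}
    for lag in lags:
        C = count_transitions(dtrajs, lag=int(lag), n_states=n_states)
        model = estimate(C, estimator=estimator)
        table[int(lag)] = timescales_from_model(model, n_timescales)
    return table


# --------------------------------------------------------------------------
# macrostates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MacrostatePartition:
    """Named macrostate centres plus the total microstate→macrostate map."""

    names: tuple
    centres: np.ndarray          # (s, d), physical feature units
    scaling: FeatureScaling
    micro_to_macro: np.ndarray   # (k,) macrostate index per microstate

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "centres",
                           np.atleast_2d(np.asarray(self.centres, float)))
        object.__setattr__(self, "micro_to_macro",
                           np.asarray(self.micro_to_macro, dtype=np.int64))

    @property
    def n_macrostates(self) -> int:
        return len(self.names)


def assign_macrostates(discretization: Discretization,
                       macro_centres: np.ndarray,
                       names=MACROSTATE_NAMES,
                       scaling: FeatureScaling | None = None) -> MacrostatePartition:
    """Map every microstate centre to the nearest macrostate centre in scaled
    feature space (ties to the lowest macrostate index; name order inactive,
    intermediate, active)."""
    macro_centres = np.atleast_2d(np.asarray(macro_centres, dtype=float))
    if macro_centres.shape[0] != len(names):
        raise ValueError("one name per macrostate centre required")
    scaling = scaling or discretization.scaling
    if macro_centres.shape[1] != discretization.centres.shape[1]:
        raise ValueError("macrostate centre dimensionality mismatch")
    mc_scaled = scaling.scale(macro_centres)
    mapping = assign_points(discretization.centres, mc_scaled)
    return MacrostatePartition(tuple(names), macro_centres, scaling, mapping)


def macrostate_probabilities(model: TransitionModel,
                             partition: MacrostatePartition) -> dict[str, float]:
    """Equilibrium macrostate probabilities: sum of π over each macrostate's
    active-set microstates.  Macrostates with no active microstate report 0."""
    if partition.micro_to_macro.shape[0] <= model.active_set.max():
        raise ValueError("partition does not cover the active set")
    macro = partition.micro_to_macro[model.active_set]
    probs = np.zeros(partition.n_macrostates)
    np.add.at(probs, macro, model.pi)
    return dict(zip(partition.names, probs))
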