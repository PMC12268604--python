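"""Trajectory-level bootstrap of macrostate populations.

The seeded trajectory pool is resampled with replacement (default: 200
trajectories per iteration, 100 iterations). Micro- and macrostate
assignments stay frozen across iterations; each iteration only recounts
transitions on the resampled multiset, re-trims connectivity, re-estimates
the transition matrix and re-sums the macrostate probabilities. Macrostates
absent from an iteration's active set contribute 0 for that iteration.
The mean is the reported population, the standard deviation its statistical
uncertainty, and the median plus interquartile range (Q1–Q3) the spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msm import (CountMatrix, Discretization, MacrostatePartition,
                  TransitionModel, estimate, largest_connected_set,
                  macrostate_probabilities)
from .toydyn import _rng_for

DEFAULT_N_RESAMPLE = 200
DEFAULT_N_ITER = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Per-iteration macrostate probability vectors plus bookkeeping."""

    names: tuple
    iterations: np.ndarray   # (n_ok, n_macrostates)
    n_failed: int
    n_resample: int
    n_iter: int
    seed: int
    lag: int
    estimator: str

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "iterations",
                           np.atleast_2d(np.asarray(self.iterations, float)))


def _per_traj_counts(dtrajs, lag: int, n_states: int):
    """One sparse count matrix per trajectory (sliding window)."""
    from scipy import sparse

    mats = []
    for d in dtrajs:
        d = np.asarray(d, dtype=np.int64)
        if d.size <= lag:
            mats.append(sparse.csr_matrix((n_states, n_states), dtype=np.int64))
            continue
        data = np.ones(d.size - lag, dtype=np.int64)
        m = sparse.coo_matrix((data, (d[:-lag], d[lag:])),
                              shape=(n_states, n_states)).tocsr()
        mats.append(m)
    return mats


def bootstrap_populations(dtrajs, discretization: Discretization,
                          partition: MacrostatePartition, lag: int,
                          estimator: str = "reversible",
                          n_resample: int = DEFAULT_N_RESAMPLE,
                          n_iter: int = DEFAULT_N_ITER,
                          seed: int = 0) -> BootstrapResult:
    """Bootstrap the macrostate populations by whole-trajectory resampling.

    ``dtrajs`` are the frozen per-trajectory microstate label arrays from the
    full-pool discretization. Iterations whose resampled pool yields no
    transition counts at all are recorded as failed and excluded from the
    summaries (the failure count is reported).
    """
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if not dtrajs:
        raise ValueError("empty trajectory pool")
    k = discretization.n_states
    mats = _per_traj_counts(dtrajs, lag, k)
    rng = _rng_for(seed)
    rows = []
    n_failed = 0
    for _ in range(n_iter):
        idx = rng.integers(0, len(dtrajs), size=n_resample)
        C = np.zeros((k, k), dtype=np.int64)
        counts_idx = np.bincount(idx, minlength=len(dtrajs))
        for j, mult in enumerate(counts_idx):
            if mult:
                C += mult * np.asarray(mats[j].todense())
        if not C.any():
            n_failed += 1
            continue
        active = largest_connected_set(C)
        model = estimate(CountMatrix(C, lag=lag), estimator=estimator,
                         active_set=active, lag=lag)
        probs = macrostate_probabilities(model, partition)
        rows.append([probs[nm] for nm in partition.names])
    if not rows:
        raise ValueError("all bootstrap iterations failed")
    return BootstrapResult(names=partition.names, iterations=np.array(rows),
                           n_failed=n_failed, n_resample=n_resample,
                           n_iter=n_iter, seed=int(seed), lag=lag,
                           estimator=estimator)


def summarize(result: BootstrapResult) -> dict[str, dict[str, float]]:
    """Per-macrostate mean, std (ddof=1), median, Q1 and Q3 of the bootstrap
    distribution.  Quantiles use linear interpolation between order
    statistics."""
    it = result.iterations
    if it.shape[0] < 1:
        raise ValueError("no successful bootstrap iterations")
    out = {}
    for j, nm in enumerate(result.names):
        col = it[:, j]
        if np.ptp(col) == 0.0:  # identical iterations → exactly zero spread
            std = 0.0
        else:
            std = float(col.std(ddof=1)) if col.size > 1 else 0.0
        q1, med, q3 = np.percentile(col, [25, 50, 75], method="linear")
        out[nm] = {"mean": float(col.mean()), "std": std,
                   "median": float(med), "q1": float(q1), "q3": float(q3)}
    return out


def summary_table(result: BootstrapResult):
    """Bar-plot-ready table (macrostate, median, q1, q3) as a DataFrame."""
    import pandas as pd

    summ = summarize(result)
    return pd.DataFrame(
        [{"macrostate": nm, "median": summ[nm]["median"],
          "q1": summ[nm]["q1"], "q3": summ[nm]["q3"]}
         for nm in result.names]
    )
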