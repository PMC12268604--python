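"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by a different route than
the package (brute-force enumeration, quaternion-parameterised optimisation,
constrained likelihood maximisation), so agreement is an actual cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from allostate import (PipelineConfig, boltzmann_macrostate_probs,
                       builtin_presets, run_pipeline)

PRESET_NAMES = ("apo", "agonist", "mutant", "partial", "partial-restrained")
PIPELINE_SEED = 7


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_counts(dtrajs, lag, n_states):
    """Transition counting by explicit pair enumeration."""
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for d in dtrajs:
        d = np.asarray(d)
        for t in range(len(d) - lag):
            C[d[t], d[t + lag]] += 1
    return C


def warshall_scc(adj):
    """Strongly connected components from Floyd–Warshall reachability."""
    n = adj.shape[0]
    reach = adj.astype(bool).copy()
    np.fill_diagonal(reach, True)
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if reach[i, j] and reach[j, i]}
        comps.append(sorted(comp))
        seen |= comp
    return comps


def reversible_mle_oracle(C):
    """Constrained maximum likelihood over reversible transition matrices,
    by direct numeric optimisation of the symmetric flux matrix in log space
    (analytic gradient), independent of the package's fixed-point iteration.

    Returns (best log-likelihood, T).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    iu = np.triu_indices(n)
    c = C.sum(axis=1)

    def unpack(z):
        x = np.zeros((n, n))
        x[iu] = np.exp(z)
        x = x + x.T - np.diag(np.diag(x))
        return x

    def negll_grad(z):
        x = unpack(z)
        xi = x.sum(axis=1)
        T = x / xi[:, None]
        mask = C > 0
        ll = (C[mask] * np.log(T[mask])).sum()
        # d ll / d x_ij for the symmetric parameterisation
        g_full = np.where(x > 0, (C + C.T) / np.where(x > 0, x, 1.0), 0.0) \
            - (c / xi)[:, None] - (c / xi)[None, :]
        np.fill_diagonal(g_full, np.where(np.diag(x) > 0,
                                          np.diag(C) / np.where(np.diag(x) > 0,
                                                                np.diag(x), 1.0),
                                          0.0) - c / xi)
        grad = g_full[iu] * np.exp(z)  # chain rule through x = e^z
        return -ll, -grad

    best = (-np.inf, None)
    rng = np.random.default_rng(0)
    x0 = C + C.T
    starts = [np.log(np.where(x0[iu] > 0, x0[iu], 1e-3))]
    starts += [starts[0] + rng.normal(0, 0.5, size=len(iu[0]))
               for _ in range(3)]
    for z0 in starts:
        res = minimize(negll_grad, z0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        x = unpack(res.x)
        T = x / x.sum(axis=1)[:, None]
        mask = C > 0
        ll = (C[mask] * np.log(T[mask])).sum()
        if ll > best[0]:
            best = (ll, T)
    return best


def quaternion_superpose_oracle(mobile, reference, seed=0):
    """Minimum RMSD over rigid motions by direct optimisation of a unit
    quaternion plus translation."""

    def quat_to_mat(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(q):
        R = quat_to_mat(q)
        return np.sum((mob @ R.T - ref) ** 2)

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(8):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20000, "maxfev": 20000})
        best = min(best, res.fun)
    return float(np.sqrt(best / len(mob)))


def weighted_quantile_scan(values, weights, q):
    """Brute-force cumulative-weight quantile scan (the documented
    convention: first value with cumweight >= q; midpoint at exact hits)."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    keep = w > 0
    v, w = v[keep], w[keep]
    w = w / w.sum()
    acc = 0.0
    for i in range(len(v)):
        acc += w[i]
        if acc > q + 1e-12:
            return float(v[i])
        if abs(acc - q) <= 1e-12:
            if i + 1 < len(v):
                return float(0.5 * (v[i] + v[i + 1]))
            return float(v[i])
    return float(v[-1])


def dihedral_oracle(p0, p1, p2, p3):
    """Dihedral via plane normals with triple-product sign (independent of
    the package's atan2 construction)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosphi = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    phi = np.degrees(np.arccos(np.clip(cosphi, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:  # sign from the central bond
        phi = -phi
    return 180.0 if np.isclose(phi, -180.0) else float(phi)


def batch_means_se(indicator, n_batches=25):
    """Standard error of a time-average from a correlated 0/1 series via
    batch means."""
    m = len(indicator) // n_batches
    means = np.array([indicator[i * m:(i + 1) * m].mean()
                      for i in range(n_batches)])
    return means.std(ddof=1) / np.sqrt(n_batches)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def pipeline_results():
    """Full pipeline runs for all shipped presets at the study scale used for
    parameter-recovery checks (200 seeded trajectories × 5000 frames, k = 50
    microstates, lag 25 frames, reversible estimator, fixed seed), plus the
    exact Boltzmann reference computed on each run's own estimated partition."""
    out = {}
    for name in PRESET_NAMES:
        cfg = PipelineConfig(preset=name, n_clusters=50, seed=PIPELINE_SEED,
                             compute_its=False)
        report = run_pipeline(cfg)
        oracle = boltzmann_macrostate_probs(report.artifacts["preset"],
                                            report.artifacts["partition"],
                                            grid_resolution=120)
        out[name] = {"report": report, "oracle": oracle}
    return out


@pytest.fixture(scope="session")
def toy_setup():
    """Shipped bead topology, region spec and inactive reference."""
    from allostate.featurize import ReferenceSet
    from allostate.toydyn import (default_toy_regions, default_toy_topology,
                                  embed_structure)

    toy = default_toy_topology()
    regions = default_toy_regions()
    refs = ReferenceSet(inactive=embed_structure((30.0, 0.0, 0.0), toy))
    return toy, regions, refs


@pytest.fixture()
def shallow_double_well():
    """A well-mixing symmetric 1-D double well for sampling-vs-oracle checks."""
    from allostate.toydyn import GeneratorPreset

    return GeneratorPreset(
        name="double-well",
        well_centres=[[-1.0], [1.0]],
        well_depths=[2.0, 2.0],
        well_widths=[[0.4], [0.4]],
        box_centre=[0.0],
        box_half_widths=[2.0],
        wall_stiffness=[25.0],
        diffusion=[0.01],
    )
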