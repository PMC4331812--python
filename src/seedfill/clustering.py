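"""Profile clustering: PAM K-medoids with Krzanowski-Lai K selection.

Differential features are reduced to standardized temporal profiles (per
time-point means, scaled to mean 0 / sd 1 across time points), clustered by
PAM (partitioning around medoids: greedy BUILD initialization then best-swap
refinement) under Euclidean distance, and the number of clusters is chosen
by the Krzanowski-Lai criterion

    DIFF(K) = (K-1)^{2/d} W_{K-1} - K^{2/d} W_K
    KL(K)   = |DIFF(K)| / |DIFF(K+1)|

where W_K is the within-cluster dispersion (sum of squared distances of
members to their medoid) and d the profile dimension; the K maximizing
KL is selected, ties broken toward smaller K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io import OmicsMatrix, SampleDesign

__all__ = [
    "ClusterSolution",
    "make_profiles",
    "pam_kmedoids",
    "krzanowski_lai",
]


@dataclass
class ClusterSolution:
    """A K-medoids partition of profiles."""

    K: int
    medoid_ids: list[str]
    assignment: pd.Series  # feature id -> cluster index (0..K-1)
    cost: float  # total distance of members to their medoid
    W: float  # total squared distance of members to their medoid
    kl_table: pd.DataFrame | None = field(default=None, repr=False)
    chosen_K: int | None = None


def make_profiles(
    matrix: OmicsMatrix,
    design: SampleDesign | None = None,
    feature_ids=None,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardized per-time-point mean profiles.

    Replicates are averaged within each time point and each feature's
    profile is scaled to mean 0 and standard deviation 1 across time
    points; the result is invariant to affine transforms (positive slope)
    of the input. Constant (zero-variance) profiles cannot be standardized
    and are returned separately as ``dropped``.
    """
    if feature_ids is not None:
        matrix = matrix.subset(feature_ids)
    means = matrix.time_means()
    arr = means.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("profiles require a mean at every time point")
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    scale = np.maximum(arr.max(axis=1, keepdims=True) - arr.min(axis=1, keepdims=True), 1.0)
    constant = (sd <= 1e-12 * scale).ravel()
    std = np.where(constant[:, None], 0.0, (arr - mu) / np.where(sd == 0, 1.0, sd))
    profiles = pd.DataFrame(std, index=means.index, columns=means.columns)
    dropped = [str(f) for f, c in zip(means.index, constant) if c]
    profiles = profiles.loc[~constant]
    # lexicographic feature order makes every downstream tie-break
    # independent of input row order
    profiles = profiles.sort_index(kind="stable")
    return profiles, dropped


def _build(D: np.ndarray, K: int) -> list[int]:
    """Greedy BUILD phase: deterministic, ties to the smallest index."""
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    d_nearest = D[first].copy()
    for _ in range(1, K):
        # gain of adding each candidate: sum of reductions in nearest distance
        gain = np.maximum(d_nearest[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        cand = int(np.argmax(gain))
        medoids.append(cand)
        d_nearest = np.minimum(d_nearest, D[cand])
    return sorted(medoids)


def _swap(D: np.ndarray, medoids: list[int], max_iter: int = 200) -> tuple[list[int], float]:
    """Best-improvement SWAP to a local optimum (vectorized over candidates)."""
    n = D.shape[0]
    medoids = sorted(medoids)
    for _ in range(max_iter):
        M = np.asarray(medoids)
        dm = D[:, M]  # n x K
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = dm[np.arange(n), nearest]
        d2 = dm[np.arange(n), order[:, 1]] if len(M) > 1 else np.full(n, np.inf)
        cost = d1.sum()

        cand = np.setdiff1d(np.arange(n), M)
        if cand.size == 0:  # K == n: nothing to swap
            break
        A = D[cand]  # c x n
        term_else = np.minimum(A - d1[None, :], 0.0)
        term_if = np.minimum(A, d2[None, :]) - d1[None, :]
        onehot = np.zeros((n, len(M)))
        onehot[np.arange(n), nearest] = 1.0
        delta = term_else.sum(axis=1)[:, None] + (term_if - term_else) @ onehot
        h_idx, m_idx = np.unravel_index(int(np.argmin(delta)), delta.shape)
        if delta[h_idx, m_idx] >= -1e-12 * max(cost, 1.0):
            break
        medoids = sorted(set(medoids) - {int(M[m_idx])} | {int(cand[h_idx])})
    M = np.asarray(sorted(medoids))
    d1 = D[:, M].min(axis=1)
    return list(M), float(d1.sum())


def pam_kmedoids(
    profiles: pd.DataFrame,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterSolution:
    """PAM under Euclidean distance; best of ``n_restarts`` by total cost.

    Restart 0 uses the deterministic BUILD initialization; the others start
    from seeded random medoid sets. Results are deterministic given the
    seed, with ties broken by lexicographic feature id (profiles are kept
    in sorted id order).
    """
    ids = [str(i) for i in profiles.index]
    n = len(ids)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of profiles ({n})")
    X = profiles.to_numpy(dtype=float)
    D = squareform(pdist(X, metric="euclidean"))

    best: tuple[float, list[int]] | None = None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 101]))
    for r in range(max(1, n_restarts)):
        init = _build(D, K) if r == 0 else sorted(rng.choice(n, size=K, replace=False).tolist())
        medoids, cost = _swap(D, init)
        key = (cost, medoids)
        if best is None or key < best:
            best = key
    cost, medoids = best[0], best[1]
    M = np.asarray(medoids)
    assign_idx = np.argmin(D[:, M], axis=1)
    W = float(np.sum(D[np.arange(n), M[assign_idx]] ** 2))
    assignment = pd.Series(assign_idx, index=profiles.index, name="cluster")
    return ClusterSolution(
        K=K,
        medoid_ids=[ids[m] for m in medoids],
        assignment=assignment,
        cost=float(cost),
        W=W,
    )


def krzanowski_lai(
    profiles: pd.DataFrame,
    K_range=range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, int, dict[int, ClusterSolution]]:
    """Select K by the Krzanowski-Lai criterion over ``K_range``.

    W_K is evaluated on K_range extended by one on each side so KL(K) is
    defined for every K in the range. Returns (table with W/DIFF/KL per K,
    chosen K, solutions per K).
    """
    ks = sorted(set(int(k) for k in K_range))
    n, d = profiles.shape
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("K_range must lie within [2, n_profiles - 1]")
    k_lo, k_hi = ks[0], ks[-1]
    eval_ks = [k for k in range(k_lo - 1, k_hi + 2) if 1 <= k <= n]
    sols: dict[int, ClusterSolution] = {}
    W: dict[int, float] = {}
    for k in eval_ks:
        sol = pam_kmedoids(profiles, k, seed=seed, n_restarts=n_restarts)
        sols[k] = sol
        W[k] = sol.W

    expo = 2.0 / d
    diff = {
        k: (k - 1) ** expo * W[k - 1] - k**expo * W[k]
        for k in eval_ks
        if k - 1 in W
    }
    rows = []
    kl: dict[int, float] = {}
    for k in ks:
        kl_k = np.nan
        if k in diff and (k + 1) in diff:
            denom = abs(diff[k + 1])
            kl_k = abs(diff[k]) / denom if denom > 0 else np.inf
            kl[k] = kl_k
        rows.append(
            {"K": k, "W": W[k], "DIFF": diff.get(k, np.nan), "KL": kl_k}
        )
    table = pd.DataFrame(rows).set_index("K")
    if not kl:
        raise ValueError("K_range too small to evaluate the KL criterion")
    best_kl = max(kl.values())
    chosen_K = min(k for k, v in kl.items() if v == best_kl)  # parsimony ties
    sols[chosen_K].kl_table = table
    sols[chosen_K].chosen_K = chosen_K
    return table, chosen_K, sols
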