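"""Category-level statistics.

Three families of tests operate on groups of features:

* **MRPP** (multiresponse permutation procedure): for one category of
  features, tests whether the joint abundance distribution of its members
  differs among time points. The statistic is the group-size-weighted mean
  of within-group pairwise Euclidean distances, compared with its
  permutation null (sample-to-group labels shuffled, group sizes fixed).
* **Fisher over-representation**: one-sided hypergeometric test of whether
  a category is enriched in a selected feature list against a background.
* **Class-by-cluster distribution tests**: given a clustering of features
  and a categorical label per feature (e.g. metabolite chemical class),
  tests of (i) whether each label's members spread evenly across clusters
  (chi-square goodness of fit against uniform), (ii) whether each cluster's
  label composition differs from the remaining features (Monte-Carlo
  chi-square on the 2xJ table with fixed margins), and (iii) the overall
  IxJ label-by-cluster association (Monte-Carlo chi-square). An exact
  conditional (Fisher) test for 2xK tables is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .differential import QValueSettings, storey_q
from .io import CategoryCatalog, OmicsMatrix, SampleDesign

__all__ = [
    "MrppResult",
    "FisherResult",
    "ContingencyResult",
    "mrpp_test",
    "fisher_overrep",
    "fisher_exact_2xk",
    "class_by_cluster_tests",
    "category_fdr",
]


@dataclass
class MrppResult:
    category_id: str
    m: int  # member features measured
    delta_obs: float  # weighted mean within-group distance
    p: float
    B: int
    A: float  # chance-corrected within-group agreement, informational
    q: float | None = None


@dataclass
class FisherResult:
    category_id: str
    a: int  # selected & in category
    b: int  # selected & not in category
    c: int  # not selected & in category
    d: int  # not selected & not in category
    p: float
    odds_ratio: float


@dataclass
class ContingencyResult:
    label: str
    table: np.ndarray
    p: float
    method: str  # "exact", "monte_carlo" or "chi2"
    statistic: float
    B: int | None = None


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------


def _mrpp_delta(D: np.ndarray, groups: np.ndarray, sizes: np.ndarray) -> float:
    """delta = sum_g (n_g / N) * mean pairwise distance within group g."""
    N = groups.size
    delta = 0.0
    for g, n_g in enumerate(sizes):
        idx = np.where(groups == g)[0]
        if n_g < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        mean_d = sub[np.triu_indices(n_g, 1)].mean()
        delta += (n_g / N) * mean_d
    return float(delta)


def _mrpp_deltas_batch(
    D: np.ndarray, perms: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """delta for each row of ``perms`` (B x N permutations of sample indices).

    Group g occupies a fixed slice of each permuted row, so the within-group
    pair sums reduce to fancy indexing into the sample distance matrix.
    """
    N = perms.shape[1]
    deltas = np.zeros(perms.shape[0])
    start = 0
    for n_g in sizes:
        idx = perms[:, start : start + n_g]
        start += n_g
        if n_g < 2:
            continue
        ii, jj = np.triu_indices(n_g, 1)
        pair_sum = D[idx[:, ii], idx[:, jj]].sum(axis=1)
        deltas += (n_g / N) * pair_sum / len(ii)
    return deltas


def _group_assignments(n: int, sizes: np.ndarray):
    """All distinct assignments of n items into ordered groups of given sizes.

    Yields each assignment as a tuple laying out group 0's member indices
    first, then group 1's, etc. The count is the multinomial coefficient,
    so this is for exhaustive permutation nulls on small sample sets.
    """
    from itertools import combinations

    def rec(remaining: tuple, k: int):
        if k == len(sizes) - 1:
            yield remaining
            return
        for chosen in combinations(remaining, int(sizes[k])):
            rest = tuple(x for x in remaining if x not in set(chosen))
            for tail in rec(rest, k + 1):
                yield chosen + tail

    yield from rec(tuple(range(n)), 0)


def mrpp_test(
    matrix: OmicsMatrix,
    category: CategoryCatalog,
    B: int = 10_000,
    seed: int = 0,
    design: SampleDesign | None = None,
    exhaustive: bool = False,
) -> MrppResult:
    """MRPP test of a category's joint distribution changing over time.

    Each sample is the vector of the category's member values (normalized
    ln scale, no per-feature standardization so the test keeps absolute
    accumulation change); groups are the time points. The permutation
    p-value is (1 + #{delta_perm <= delta_obs}) / (B + 1), so p has
    resolution 1/(B+1) and never reaches 0. With ``exhaustive=True`` every
    distinct label assignment is enumerated instead (small sample sets
    only) and p is the exact proportion with delta_perm <= delta_obs.
    The chance-corrected statistic A = 1 - delta/E[delta_perm] is reported
    informationally.
    """
    design = design or matrix.design
    members = sorted(category.member_ids & set(matrix.feature_ids))
    if len(members) < 2:
        raise ValueError(
            f"category {category.category_id!r} is not testable "
            f"({len(members)} measured members)"
        )
    times = design.times
    if len(times) < 2:
        raise ValueError("MRPP needs at least two groups (time points)")
    X = matrix.values.loc[members].to_numpy(dtype=float).T  # samples x members
    ok = np.all(np.isfinite(X), axis=1)
    X = X[ok]
    time_labels = np.asarray(design.time_points, dtype=float)[ok]
    groups = np.searchsorted(np.asarray(times), time_labels)
    sizes = np.bincount(groups, minlength=len(times))
    if np.count_nonzero(sizes) < 2:
        raise ValueError("fewer than two non-empty groups after missing-data removal")

    D = squareform(pdist(X, metric="euclidean"))
    delta_obs = _mrpp_delta(D, groups, sizes)

    nz_sizes = sizes[sizes > 0]
    order = np.argsort(groups, kind="stable")  # identity layout: group slices
    if exhaustive:
        perms = np.array(
            [list(a) for a in _group_assignments(order.size, nz_sizes)], dtype=int
        )
        deltas = _mrpp_deltas_batch(D, perms, nz_sizes)
        count = int(np.sum(deltas <= delta_obs + 1e-12))
        p = count / perms.shape[0]
        B = perms.shape[0]
        mean_perm = float(deltas.mean())
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 211]))
        count = 0
        perm_sum = 0.0
        chunk = 2000
        done = 0
        N = order.size
        while done < B:
            b = min(chunk, B - done)
            perms = np.argsort(rng.random((b, N)), axis=1)
            deltas = _mrpp_deltas_batch(D, perms, nz_sizes)
            count += int(np.sum(deltas <= delta_obs + 1e-12))
            perm_sum += float(deltas.sum())
            done += b
        p = (1 + count) / (B + 1)
        mean_perm = perm_sum / B if B else np.nan
    A = 1.0 - delta_obs / mean_perm if mean_perm > 0 else 0.0
    return MrppResult(
        category_id=category.category_id,
        m=len(members),
        delta_obs=delta_obs,
        p=float(p),
        B=B,
        A=float(A),
    )


# ---------------------------------------------------------------------------
# Fisher over-representation
# ---------------------------------------------------------------------------


def fisher_overrep(
    selected: set[str],
    category: CategoryCatalog,
    background: set[str],
) -> FisherResult:
    """One-sided hypergeometric over-representation test.

    p = P(overlap >= observed) drawing |selected| features from the
    background, of which |category & background| are category members.
    The odds ratio uses a 0.5 substitution on zero cells for reporting.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValueError("selected feature list must be a subset of the background")
    cat = category.member_ids & background
    a = len(selected & cat)
    b = len(selected - cat)
    c = len(cat - selected)
    d = len(background) - a - b - c
    p = float(stats.hypergeom.sf(a - 1, len(background), len(cat), len(selected)))
    aa, bb, cc, dd = (x if x > 0 else 0.5 for x in (a, b, c, d))
    return FisherResult(
        category_id=category.category_id,
        a=a, b=b, c=c, d=d,
        p=min(p, 1.0),
        odds_ratio=float(aa * dd / (bb * cc)),
    )


# ---------------------------------------------------------------------------
# exact conditional test for 2xK tables
# ---------------------------------------------------------------------------


def fisher_exact_2xk(row: np.ndarray, other: np.ndarray) -> float:
    """Exact conditional (Fisher) test for a 2xK table with fixed margins.

    The null probability of a table with first row (k_1..k_K) and column
    totals (c_1..c_K) is prod_j C(c_j, k_j) / C(N, r). The p-value sums the
    probabilities of all margin-preserving tables no more probable than the
    observed one. Implemented as branch-and-bound over the first row with
    suffix log-sum / log-max / log-min tables, so large tables (row totals
    in the hundreds) stay fast.
    """
    row = np.asarray(row, dtype=int)
    other = np.asarray(other, dtype=int)
    if row.shape != other.shape or row.ndim != 1:
        raise ValueError("row and other must be 1-D with equal length")
    if np.any(row < 0) or np.any(other < 0):
        raise ValueError("counts must be non-negative")
    cols = row + other
    K = row.size
    r = int(row.sum())
    N = int(cols.sum())
    if r == 0 or r == N:
        return 1.0

    lg = np.array([lgamma(i + 1) for i in range(N + 1)])

    def lchoose(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -np.inf
        return lg[n] - lg[k] - lg[n - k]

    # per-column log-binomial weights
    w = [np.array([lchoose(int(c), k) for k in range(min(int(c), r) + 1)]) for c in cols]

    # suffix tables over remaining total t: logsumexp, max, min of achievable
    # sum of weights using columns j..K-1
    NEG = -np.inf
    S = np.full((K + 1, r + 1), NEG)
    MX = np.full((K + 1, r + 1), NEG)
    MN = np.full((K + 1, r + 1), np.inf)
    S[K, 0] = 0.0
    MX[K, 0] = 0.0
    MN[K, 0] = 0.0
    for j in range(K - 1, -1, -1):
        wj = w[j]
        for t in range(r + 1):
            kmax = min(len(wj) - 1, t)
            best_mx, best_mn = NEG, np.inf
            acc = []
            for k in range(kmax + 1):
                rest = t - k
                if S[j + 1, rest] == NEG:
                    continue
                acc.append(wj[k] + S[j + 1, rest])
                best_mx = max(best_mx, wj[k] + MX[j + 1, rest])
                best_mn = min(best_mn, wj[k] + MN[j + 1, rest])
            if acc:
                arr = np.asarray(acc)
                hi = arr.max()
                S[j, t] = hi + np.log(np.exp(arr - hi).sum())
                MX[j, t] = best_mx
                MN[j, t] = best_mn

    log_obs = sum(w[j][row[j]] for j in range(K))
    thresh = log_obs + 1e-7  # include probability ties

    total = NEG  # log of accumulated tail probability * C(N, r)

    def logaddexp(a: float, b: float) -> float:
        if a == NEG:
            return b
        if b == NEG:
            return a
        hi = max(a, b)
        return hi + np.log(np.exp(a - hi) + np.exp(b - hi))

    stack = [(0, r, 0.0)]
    while stack:
        j, t, acc = stack.pop()
        if S[j, t] == NEG:
            continue
        if acc + MX[j, t] <= thresh:
            total = logaddexp(total, acc + S[j, t])
            continue
        if acc + MN[j, t] > thresh:
            continue
        wj = w[j]
        kmax = min(len(wj) - 1, t)
        for k in range(kmax + 1):
            stack.append((j + 1, t - k, acc + wj[k]))
    p = exp(total - lchoose(N, r)) if total != NEG else 0.0
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# class-by-cluster distribution tests
# ---------------------------------------------------------------------------


def _chi2_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    mask = expected > 0
    return float((((obs - expected) ** 2)[mask] / expected[mask]).sum())


def _mc_chi2_ixj(table: np.ndarray, B: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo chi-square test of independence on an IxJ table.

    Null tables with the observed margins are sampled (Patefield algorithm
    via :func:`scipy.stats.random_table`); extremeness is the Pearson
    chi-square statistic. Returns (statistic, p) with
    p = (1 + #{stat_perm >= stat_obs}) / (B + 1).
    """
    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = int(table.sum())
    expected = np.outer(rows, cols) / N
    stat_obs = _chi2_stat(table, expected)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 311]))
    dist = stats.random_table(rows, cols)
    count = 0
    chunk = 20_000
    done = 0
    mask = expected > 0
    while done < B:
        b = min(chunk, B - done)
        draws = dist.rvs(size=b, random_state=rng)  # b x I x J
        stat = (((draws - expected) ** 2)[:, mask] / expected[mask]).sum(axis=1)
        count += int(np.sum(stat >= stat_obs - 1e-12))
        done += b
    return stat_obs, (1 + count) / (B + 1)


def _mc_chi2_2xj(
    row: np.ndarray, other: np.ndarray, B: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo chi-square test on a 2xJ table with fixed margins."""
    return _mc_chi2_ixj(np.vstack([row, other]), B=B, seed=seed)


def class_by_cluster_tests(
    assignment: pd.Series,
    classes: pd.Series,
    B: int = 100_000,
    seed: int = 0,
    per_class_method: str = "chi2_uniform",
) -> dict[str, list[ContingencyResult] | ContingencyResult]:
    """Distribution tests of a categorical label against a clustering.

    ``assignment`` maps feature -> cluster, ``classes`` maps feature ->
    label (e.g. chemical class); both must cover the same features.

    Returns a dict with three entries:

    * ``per_class``: for each label, does it spread evenly over the
      clusters? Default is the chi-square goodness-of-fit of the label's
      cluster counts against a uniform distribution (df = n_clusters - 1).
      ``per_class_method="fisher_exact"`` instead runs the exact
      conditional test of the label's 2xK cluster distribution against all
      other features.
    * ``per_cluster``: for each cluster, does its label composition differ
      from the remaining features? Monte-Carlo chi-square on the 2xJ
      table with fixed margins.
    * ``overall``: IxJ label-by-cluster association, Monte-Carlo
      chi-square; plus ``cluster_size_uniformity``, the chi-square
      goodness-of-fit of the cluster sizes themselves against uniform.
    """
    assignment = assignment.astype(str)
    classes = classes.astype(str)
    if set(assignment.index) != set(classes.index):
        raise ValueError("assignment and classes must cover the same features")
    classes = classes.loc[assignment.index]
    cluster_ids = sorted(assignment.unique())
    class_ids = sorted(classes.unique())
    table = pd.crosstab(classes, assignment).reindex(
        index=class_ids, columns=cluster_ids, fill_value=0
    )
    T = table.to_numpy(dtype=int)
    if np.any(T.sum(axis=1) == 0) or np.any(T.sum(axis=0) == 0):
        raise ValueError("every class and cluster must have at least one feature")
    K = len(cluster_ids)

    per_class: list[ContingencyResult] = []
    for i, cls in enumerate(class_ids):
        obs = T[i]
        if per_class_method == "chi2_uniform":
            expected = np.full(K, obs.sum() / K)
            stat = _chi2_stat(obs, expected)
            p = float(stats.chi2.sf(stat, K - 1))
            per_class.append(
                ContingencyResult(str(cls), obs.copy(), p, "chi2", stat)
            )
        elif per_class_method == "fisher_exact":
            other = T.sum(axis=0) - obs
            p = fisher_exact_2xk(obs, other)
            per_class.append(
                ContingencyResult(
                    str(cls), np.vstack([obs, other]), p, "exact", np.nan
                )
            )
        else:
            raise ValueError(f"unknown per_class_method {per_class_method!r}")

    per_cluster: list[ContingencyResult] = []
    for j, clu in enumerate(cluster_ids):
        row = T[:, j]
        other = T.sum(axis=1) - row
        stat, p = _mc_chi2_2xj(row, other, B=B, seed=seed + j)
        per_cluster.append(
            ContingencyResult(
                str(clu), np.vstack([row, other]), float(p), "monte_carlo", stat, B
            )
        )

    stat, p = _mc_chi2_ixj(T, B=B, seed=seed)
    overall = ContingencyResult("overall", T.copy(), float(p), "monte_carlo", stat, B)

    sizes = T.sum(axis=0)
    stat_u = _chi2_stat(sizes, np.full(K, sizes.sum() / K))
    size_unif = ContingencyResult(
        "cluster_size_uniformity",
        sizes.copy(),
        float(stats.chi2.sf(stat_u, K - 1)),
        "chi2",
        stat_u,
    )

    return {
        "per_class": per_class,
        "per_cluster": per_cluster,
        "overall": overall,
        "cluster_size_uniformity": size_unif,
    }


def category_fdr(
    results: list[MrppResult],
    settings: QValueSettings | str = QValueSettings(),
) -> list[MrppResult]:
    """Attach Storey q-values to a family of MRPP results (in place)."""
    if not results:
        return results
    q = storey_q([r.p for r in results], settings)
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results
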