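"""Metabolite-transcript co-analysis: volcano comparisons and correlation.

A volcano comparison contrasts two time points feature by feature (Welch
t-test on replicate values, fold change as the difference of group means on
the natural-log scale). Correlation co-analysis computes the Pearson
correlation of a query feature's temporal profile (per-time-point means)
against every feature of a target matrix, with the two-sided p-value from
the exact t transform

    t = r * sqrt((n - 2) / (1 - r^2)),  df = n - 2,

e.g. r = 0.86 over n = 5 time points gives p = 0.06. Correlated feature
sets can then be fed into hypergeometric over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .category_stats import FisherResult, fisher_overrep
from .differential import QValueSettings, storey_q
from .io import CategoryCatalog, OmicsMatrix

__all__ = [
    "VolcanoRecord",
    "CorrelationRecord",
    "volcano",
    "correlation_pvalue",
    "correlate_query",
    "correlated_set_overrep",
]


@dataclass
class VolcanoRecord:
    feature_id: str
    log_fc: float  # mean(group2) - mean(group1), natural-log scale
    p: float
    q: float | None = None


@dataclass
class CorrelationRecord:
    query_id: str
    target_id: str
    r: float
    n: int
    p: float
    defined: bool = True  # False when a profile has zero variance


def volcano(
    matrix: OmicsMatrix,
    group1_time: float,
    group2_time: float,
    settings: QValueSettings | str = QValueSettings(),
) -> pd.DataFrame:
    """Welch two-sample comparison of two time points, per feature.

    Returns a DataFrame indexed by feature id with columns ``log_fc``
    (group2 - group1 mean difference on the ln scale), ``p`` and ``q``.
    Degenerate features (no variance and equal means) get p = 1.
    """
    groups = matrix.design.groups()
    for t in (group1_time, group2_time):
        if t not in groups:
            raise ValueError(f"time point {t} not in design")
        if len(groups[t]) < 2:
            raise ValueError(f"time point {t} has fewer than 2 replicates")
    X1 = matrix.values.iloc[:, groups[float(group1_time)]].to_numpy(dtype=float)
    X2 = matrix.values.iloc[:, groups[float(group2_time)]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        m1 = np.nanmean(X1, axis=1)
        m2 = np.nanmean(X2, axis=1)
        res = stats.ttest_ind(X2, X1, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    log_fc = m2 - m1
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    log_fc = np.where(np.isfinite(log_fc), log_fc, 0.0)
    out = pd.DataFrame(
        {"log_fc": log_fc, "p": p, "degenerate": degenerate},
        index=matrix.values.index,
    )
    out["q"] = storey_q(out["p"].to_numpy(), settings)
    return out


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the exact t transform."""
    if n < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def correlate_query(
    query_profile: pd.Series | np.ndarray,
    targets: OmicsMatrix,
    query_id: str = "query",
) -> pd.DataFrame:
    """Pearson correlation of a query temporal profile vs all targets.

    ``query_profile`` holds the query's per-time-point means, in the order
    of the target design's sorted time points. Targets are reduced to their
    own per-time-point means. Zero-variance profiles give an undefined r
    (flagged, r = NaN, p = 1).
    """
    x = np.asarray(query_profile, dtype=float)
    tmeans = targets.time_means()
    n = x.size
    if tmeans.shape[1] != n:
        raise ValueError(
            f"query has {n} time points but targets have {tmeans.shape[1]}"
        )
    if n < 3:
        raise ValueError("need at least 3 shared time points")
    Y = tmeans.to_numpy(dtype=float)
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sy = np.sqrt((Yc**2).sum(axis=1))
    defined = (sx > 0) & (sy > 0) & np.all(np.isfinite(Y), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    p = np.ones(Y.shape[0])
    for i in np.where(defined)[0]:
        p[i] = correlation_pvalue(r[i], n)
    r = np.where(defined, r, np.nan)
    return pd.DataFrame(
        {
            "query_id": query_id,
            "r": r,
            "n": n,
            "p": p,
            "defined": defined,
        },
        index=tmeans.index.rename("target_id"),
    )


def correlated_set_overrep(
    records: pd.DataFrame,
    r_band: tuple[float, float],
    p_max: float,
    catalogs: list[CategoryCatalog],
) -> list[FisherResult]:
    """Over-representation of categories among correlation-selected targets.

    Targets with r inside ``r_band`` (inclusive) and p < ``p_max`` form the
    selected list; the background is every target in ``records``. Categories
    with fewer than two background members are skipped.
    """
    lo, hi = r_band
    if lo > hi:
        raise ValueError("r_band must be (lo, hi) with lo <= hi")
    background = set(str(i) for i in records.index)
    sel_mask = (
        records["defined"]
        & (records["r"] >= lo)
        & (records["r"] <= hi)
        & (records["p"] < p_max)
    )
    selected = set(str(i) for i in records.index[sel_mask])
    if not selected:
        warnings.warn("empty correlation selection; no over-representation tests run")
        return []
    out = []
    for cat in catalogs:
        if len(cat.member_ids & background) < 2:
            continue
        out.append(fisher_overrep(selected, cat, background))
    return sorted(out, key=lambda fr: (fr.p, fr.category_id))
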