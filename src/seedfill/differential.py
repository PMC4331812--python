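"""Normalization and per-feature time-course differential testing.

The screen mirrors a classical microarray/metabolomics workflow: abundances
are natural-log transformed and median-centered within each sample (chip),
then each feature is fit with a fixed-effects linear model

    value ~ replication + time      (both categorical)

and the overall F-test for dropping the time term asks whether the feature's
mean level changes at all across the developmental time points. The p-values
are converted to Storey q-values to control the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix, SampleDesign

__all__ = [
    "QValueSettings",
    "detection_filter",
    "ln_median_center",
    "timecourse_ftest",
    "storey_q",
    "differential_analysis",
]

_EPS = 1e-12


@dataclass(frozen=True)
class QValueSettings:
    """How the proportion of true nulls (pi0) is estimated.

    ``fixed_1`` sets pi0 = 1 and makes the q-values identical to
    Benjamini-Hochberg adjusted p-values. ``lambda_0.5`` uses the Storey
    point estimate #{p > 0.5} / (0.5 m), clipped into (0, 1].
    """

    pi0_method: str = "lambda_0.5"

    def __post_init__(self) -> None:
        if self.pi0_method not in ("fixed_1", "lambda_0.5"):
            raise ValueError(f"unknown pi0 method {self.pi0_method!r}")

    def estimate_pi0(self, pvalues: np.ndarray) -> float:
        m = pvalues.size
        if self.pi0_method == "fixed_1":
            return 1.0
        pi0 = np.sum(pvalues > 0.5) / (0.5 * m)
        return float(min(1.0, max(pi0, 1.0 / m)))


def detection_filter(matrix: OmicsMatrix) -> tuple[OmicsMatrix, list[str]]:
    """Keep features detected in every replicate of at least one time point.

    Operates on the raw scale where NaN marks a below-detection cell.
    Returns the filtered matrix and the list of dropped feature ids.
    """
    if matrix.value_scale != "raw":
        raise ValueError("detection filter applies to raw matrices")
    vals = matrix.values.to_numpy(dtype=float)
    keep = np.zeros(vals.shape[0], dtype=bool)
    for _, idx in matrix.design.groups().items():
        block = vals[:, idx]
        keep |= np.all(np.isfinite(block) & (block > 0), axis=1)
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    return matrix.subset(kept_ids), dropped


def ln_median_center(matrix: OmicsMatrix) -> OmicsMatrix:
    """Natural-log transform and subtract the per-sample median.

    After the transform every sample's median over features is exactly zero.
    Remaining below-detection cells are excluded from medians and stay
    missing.
    """
    if matrix.value_scale != "raw":
        raise ValueError("expected a raw matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("non-positive value cannot be log transformed")
    ln = np.log(vals)
    med = np.nanmedian(ln, axis=0, keepdims=True)
    centered = pd.DataFrame(
        ln - med, index=matrix.values.index, columns=matrix.values.columns
    )
    return OmicsMatrix(centered, matrix.design, value_scale="ln_centered")


def _design_matrices(design: SampleDesign) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept+rep+time) and reduced (intercept+rep) dummy matrices."""
    times = np.asarray(design.time_points, dtype=float)
    reps = np.asarray(design.replicates, dtype=int)
    n = len(times)
    cols = [np.ones(n)]
    for r in sorted(set(reps))[1:]:
        cols.append((reps == r).astype(float))
    reduced = np.column_stack(cols)
    for t in sorted(set(times))[1:]:
        cols.append((times == t).astype(float))
    full = np.column_stack(cols)
    return full, reduced


def _rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares for each column of Y, and the model rank."""
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, abs(R[0, 0]))))
    if rank < X.shape[1]:  # rank-deficient: fall back to pinv projection
        proj = X @ np.linalg.pinv(X)
        resid = Y - proj @ Y
    else:
        resid = Y - Q @ (Q.T @ Y)
    return np.sum(resid**2, axis=0), rank


def timecourse_ftest(
    matrix: OmicsMatrix, design: SampleDesign | None = None
) -> pd.DataFrame:
    """Overall F-test per feature for any change in mean across time points.

    Returns a DataFrame indexed by feature id with columns ``F``, ``p``,
    ``df_num``, ``df_den`` and ``degenerate``. Features with zero residual
    degrees of freedom or constant values get p = 1 and the degenerate flag
    so downstream set operations stay total.
    """
    design = design or matrix.design
    if len(design.times) < 2:
        raise ValueError("need at least two time points for a time-course F-test")
    Y = matrix.values.to_numpy(dtype=float).T  # samples x features
    complete = np.all(np.isfinite(Y), axis=0)

    n_feat = Y.shape[1]
    F = np.full(n_feat, 0.0)
    p = np.ones(n_feat)
    df_num = np.full(n_feat, len(design.times) - 1, dtype=int)
    df_den = np.zeros(n_feat, dtype=int)
    degenerate = np.zeros(n_feat, dtype=bool)

    def _fit_block(Yb: np.ndarray, des: SampleDesign) -> tuple[np.ndarray, ...]:
        full, reduced = _design_matrices(des)
        rss_f, rank_f = _rss(full, Yb)
        rss_r, rank_r = _rss(reduced, Yb)
        dnum = rank_f - rank_r
        dden = Yb.shape[0] - rank_f
        return rss_f, rss_r, dnum, dden

    if complete.any():
        Yb = Y[:, complete]
        rss_f, rss_r, dnum, dden = _fit_block(Yb, design)
        tot = np.sum((Yb - Yb.mean(axis=0)) ** 2, axis=0)
        deg = (dden <= 0) | (dnum <= 0) | (tot <= _EPS * np.maximum(1.0, tot.max(initial=1.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            Fb = ((rss_r - rss_f) / max(dnum, 1)) / (rss_f / max(dden, 1))
        Fb = np.where(deg | ~np.isfinite(Fb), 0.0, np.maximum(Fb, 0.0))
        pb = np.where(deg, 1.0, stats.f.sf(Fb, max(dnum, 1), max(dden, 1)))
        idx = np.where(complete)[0]
        F[idx], p[idx] = Fb, pb
        df_num[idx], df_den[idx] = dnum, dden
        degenerate[idx] = deg

    # features with missing cells: fit on their observed samples only
    for j in np.where(~complete)[0]:
        obs = np.isfinite(Y[:, j])
        sub_times = [design.time_points[i] for i in range(design.n_samples) if obs[i]]
        if obs.sum() < 3 or len(set(sub_times)) < 2:
            degenerate[j] = True
            continue
        des = SampleDesign(
            sample_ids=tuple(
                s for s, o in zip(design.sample_ids, obs) if o
            ),
            time_points=tuple(
                t for t, o in zip(design.time_points, obs) if o
            ),
            replicates=tuple(r for r, o in zip(design.replicates, obs) if o),
        )
        Yb = Y[obs, j][:, None]
        rss_f, rss_r, dnum, dden = _fit_block(Yb, des)
        tot = float(np.sum((Yb - Yb.mean()) ** 2))
        if dden <= 0 or dnum <= 0 or tot <= _EPS:
            degenerate[j] = True
            continue
        Fj = float(((rss_r[0] - rss_f[0]) / dnum) / (rss_f[0] / dden))
        F[j] = max(Fj, 0.0)
        p[j] = float(stats.f.sf(F[j], dnum, dden))
        df_num[j], df_den[j] = dnum, dden

    return pd.DataFrame(
        {
            "F": F,
            "p": p,
            "df_num": df_num,
            "df_den": df_den,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )


def storey_q(
    pvalues, settings: QValueSettings | str = QValueSettings()
) -> np.ndarray:
    """Storey q-values: q(i) = min_{j>=i} pi0 * m * p(j) / j, clipped to 1.

    With pi0 = 1 this is exactly the Benjamini-Hochberg adjusted p-value.
    The output preserves the input order.
    """
    if isinstance(settings, str):
        settings = QValueSettings(settings)
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = settings.estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_analysis(
    matrix: OmicsMatrix,
    settings: QValueSettings | str = QValueSettings(),
) -> tuple[pd.DataFrame, OmicsMatrix, list[str]]:
    """Full screen: detection filter -> ln/median-center -> F-test -> q.

    Returns (results table with q and passed_detection, the normalized
    matrix, dropped feature ids).
    """
    filtered, dropped = detection_filter(matrix)
    normalized = ln_median_center(filtered)
    res = timecourse_ftest(normalized)
    res["q"] = storey_q(res["p"].to_numpy(), settings)
    res["passed_detection"] = True
    if dropped:
        pad = pd.DataFrame(
            {
                "F": 0.0,
                "p": 1.0,
                "df_num": 0,
                "df_den": 0,
                "degenerate": True,
                "q": 1.0,
                "passed_detection": False,
            },
            index=pd.Index(dropped),
        )
        res = pd.concat([res, pad])
    return res, normalized, dropped
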