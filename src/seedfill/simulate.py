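"""Synthetic seed-fill omics generator with known ground truth.

Emulates the shape of a developing-seed study: five harvests (25-50 days
after flowering), a metabolomics platform (273 analytes in 8 chemical
classes, 6 replicates) and a transcriptomics platform (thousands of probes,
2 replicates). Features carry smooth temporal templates from a small set of
shape families (steady rise, steady decline, late rise, mid peak, early
plateau, and their mirrored variants), log-normal noise on the abundance
scale, and additive per-replicate offsets for the linear model's
replication term to absorb. Category catalogs, promoters with planted
motifs, and planted metabolite-transcript correlations give every
downstream statistic a recoverable truth.

Everything is reproducible from the spec's single seed; each product draws
from its own named substream so adding one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    CHEMICAL_CLASSES,
    CategoryCatalog,
    FeatureAnnotation,
    MotifDef,
    OmicsMatrix,
    PromoterSet,
    SampleDesign,
    IUPAC_CODES,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_timecourse",
    "simulate_catalogs",
    "simulate_promoters",
    "plant_correlation",
]

#: Default metabolite class sizes: AA 31, AR 7, eFA 12, fFA 12, OA 15,
#: SGD 41, ST 30, UK 125 (sums to 273).
DEFAULT_CLASS_COUNTS = dict(
    zip(CHEMICAL_CLASSES, (31, 7, 12, 12, 15, 41, 30, 125))
)

_SUBSTREAM = {
    "metab": 1,
    "trans": 2,
    "catalogs": 3,
    "promoters": 4,
    "correlation": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _SUBSTREAM[stream]])
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the generator.

    ``noise_sd`` is the standard deviation of the measurement noise on the
    natural-log scale; ``effect_scale`` is the amplitude of the temporal
    templates on the same scale, so noise_sd/effect_scale is the inverse
    signal-to-noise ratio. ``frac_null`` features get flat templates.
    """

    seed: int = 0
    times: tuple[float, ...] = (25.0, 30.0, 35.0, 45.0, 50.0)
    n_rep_metab: int = 6
    n_rep_trans: int = 2
    n_metab: int = 273
    n_trans: int = 2869
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    k_metab: int = 5
    k_trans: int = 8
    noise_sd: float = 0.25
    effect_scale: float = 1.0
    frac_null: float = 0.0
    #: additive per-replicate offset SD on the ln scale; None = noise_sd / 2.
    #: Zero gives fully exchangeable samples (no replicate blocks).
    rep_effect_sd: float | None = None

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.n_metab:
            raise ValueError(
                f"class_counts sum {sum(self.class_counts.values())} != n_metab {self.n_metab}"
            )
        if self.k_metab < 2 or self.k_trans < 2:
            raise ValueError("planted cluster counts must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must lie in [0, 1]")
        if self.rep_effect_sd is not None and self.rep_effect_sd < 0:
            raise ValueError("rep_effect_sd must be non-negative")
        if len(self.times) < 2:
            raise ValueError("need at least two time points")


@dataclass
class GroundTruth:
    """What was planted: the key against which recovery is scored."""

    cluster_metab: pd.Series  # feature -> planted cluster (non-null features)
    cluster_trans: pd.Series
    is_null_metab: pd.Series  # feature -> flat-template flag
    is_null_trans: pd.Series
    classes: pd.Series  # metabolite -> chemical class
    enriched_categories: dict[str, int] = field(default_factory=dict)  # cat -> target cluster
    motif_targets: dict[str, int] = field(default_factory=dict)  # motif -> target cluster
    correlation_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def _templates(k: int, times: np.ndarray) -> np.ndarray:
    """k standardized temporal shape templates evaluated at the day values.

    The families mirror the profile types seen across seed fill: steady
    rise/decline, late rise/fall, mid peak/dip, early plateau/decline.
    Each template is standardized to mean 0 / sd 1 over the time points.
    """
    s = (times - times.min()) / (times.max() - times.min())
    families = [
        s,  # steady rise
        -s,  # steady decline
        np.maximum(s - 0.5, 0.0) * 2.0,  # late rise
        1.0 - np.abs(2.0 * s - 1.0),  # mid peak
        np.minimum(2.0 * s, 1.0),  # early plateau
        -np.maximum(s - 0.5, 0.0) * 2.0,  # late fall
        np.abs(2.0 * s - 1.0) - 1.0,  # mid dip
        -np.minimum(2.0 * s, 1.0),  # early decline
    ]
    if k > len(families):  # phase-shifted peaks for any extra clusters
        for j in range(k - len(families)):
            c = (j + 1) / (k - len(families) + 1)
            families.append(1.0 - np.abs(s - c) / max(c, 1 - c))
    out = []
    for f in families[:k]:
        f = np.asarray(f, dtype=float)
        out.append((f - f.mean()) / f.std())
    return np.vstack(out)


def _simulate_platform(
    spec: SimulationSpec,
    rng: np.random.Generator,
    n_features: int,
    n_rep: int,
    k: int,
    prefix: str,
) -> tuple[OmicsMatrix, pd.Series, pd.Series]:
    times = np.asarray(spec.times, dtype=float)
    T = times.size
    templates = _templates(k, times)  # k x T

    ids = [f"{prefix}{i + 1:05d}" for i in range(n_features)]
    n_null = int(round(spec.frac_null * n_features))
    is_null = np.zeros(n_features, dtype=bool)
    if n_null:
        is_null[rng.choice(n_features, size=n_null, replace=False)] = True
    cluster = rng.integers(0, k, size=n_features)
    cluster[is_null] = -1

    baseline = rng.normal(np.log(100.0), 1.0, size=n_features)
    rep_sd = spec.noise_sd / 2.0 if spec.rep_effect_sd is None else spec.rep_effect_sd
    rep_offsets = rng.normal(0.0, rep_sd, size=n_rep) if rep_sd > 0 else np.zeros(n_rep)

    sample_ids, sample_times, sample_reps = [], [], []
    for t in times:
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{prefix}t{int(t)}_r{r}")
            sample_times.append(float(t))
            sample_reps.append(r)
    design = SampleDesign(tuple(sample_ids), tuple(sample_times), tuple(sample_reps))

    tmpl = np.zeros((n_features, T))
    nz = ~is_null
    tmpl[nz] = spec.effect_scale * templates[cluster[nz]]
    ln_mean = baseline[:, None] + tmpl  # features x times

    n_samples = T * n_rep
    noise = rng.normal(0.0, spec.noise_sd, size=(n_features, n_samples))
    ln_vals = np.empty((n_features, n_samples))
    for j, (t, r) in enumerate(zip(sample_times, sample_reps)):
        ti = int(np.searchsorted(times, t))
        ln_vals[:, j] = ln_mean[:, ti] + rep_offsets[r - 1] + noise[:, j]
    values = pd.DataFrame(np.exp(ln_vals), index=ids, columns=sample_ids)
    matrix = OmicsMatrix(values, design, value_scale="raw")
    return (
        matrix,
        pd.Series(cluster, index=ids, name="cluster"),
        pd.Series(is_null, index=ids, name="is_null"),
    )


def simulate_timecourse(
    spec: SimulationSpec,
) -> tuple[OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Generate both platforms and the ground truth.

    With defaults: a 273 x 30 metabolite matrix (6 replicates x 5 times)
    and a 2869 x 10 transcript matrix (2 replicates x 5 times), fully
    reproducible from ``spec.seed``.
    """
    metab, cl_m, null_m = _simulate_platform(
        spec, _rng(spec.seed, "metab"), spec.n_metab, spec.n_rep_metab,
        spec.k_metab, "M",
    )
    trans, cl_t, null_t = _simulate_platform(
        spec, _rng(spec.seed, "trans"), spec.n_trans, spec.n_rep_trans,
        spec.k_trans, "G",
    )
    classes = pd.Series(
        np.repeat(
            [c for c in spec.class_counts],
            [spec.class_counts[c] for c in spec.class_counts],
        ),
        index=metab.feature_ids,
        name="chemical_class",
    )
    truth = GroundTruth(
        cluster_metab=cl_m,
        cluster_trans=cl_t,
        is_null_metab=null_m,
        is_null_trans=null_t,
        classes=classes,
    )
    return metab, trans, truth


def simulate_catalogs(
    truth: GroundTruth,
    n_categories: int,
    enriched_fraction: float,
    seed: int = 0,
    size_range: tuple[int, int] = (8, 15),
    enrichment: float = 0.8,
) -> list[CategoryCatalog]:
    """Catalogs over the transcript features, some cluster-enriched.

    Enriched categories draw >= ``enrichment`` (default 80%) of their
    members from one planted cluster, cycling over clusters; background
    categories sample uniformly. Planted target clusters are recorded in
    ``truth.enriched_categories``.
    """
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    rng = _rng(seed, "catalogs")
    ids = np.asarray(truth.cluster_trans.index, dtype=object)
    clusters = truth.cluster_trans.to_numpy()
    k = int(clusters.max()) + 1
    n_enriched = int(round(enriched_fraction * n_categories))
    out = []
    truth.enriched_categories = {}
    for i in range(n_categories):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if i < n_enriched:
            target = i % k
            in_cluster = ids[clusters == target]
            n_from = min(int(np.ceil(enrichment * size)), in_cluster.size)
            members = list(rng.choice(in_cluster, size=n_from, replace=False))
            rest_pool = ids[clusters != target]
            members += list(rng.choice(rest_pool, size=size - n_from, replace=False))
            cat_id = f"CAT_E{i + 1:03d}"
            truth.enriched_categories[cat_id] = target
        else:
            members = list(rng.choice(ids, size=size, replace=False))
            cat_id = f"CAT_B{i + 1:03d}"
        out.append(CategoryCatalog.build(cat_id, members, measured_ids=list(ids)))
    return out


def _concrete_motif(iupac: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[ch])) for ch in iupac.upper())


def simulate_promoters(
    truth: GroundTruth,
    motifs: list[MotifDef],
    planted_rate: float = 0.5,
    background_rate: float = 0.05,
    length: int = 1000,
    seed: int = 0,
) -> list[PromoterSet]:
    """1000-bp i.i.d. promoters with motif instances planted per cluster.

    Each motif gets a target cluster (cycling over the planted transcript
    clusters, recorded in ``truth.motif_targets``); genes in the target
    cluster receive >= 1 exact planted instance with probability
    ``planted_rate``, all other genes with probability ``background_rate``.
    Chance background matches still occur and must be found by scanning.
    """
    if not (0.0 <= background_rate <= 1.0 and 0.0 <= planted_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if planted_rate <= background_rate:
        raise ValueError("planted_rate must exceed background_rate")
    for m in motifs:
        if len(m.iupac) > length:
            raise ValueError(f"motif {m.motif_name!r} longer than the promoter")
    rng = _rng(seed, "promoters")
    ids = list(truth.cluster_trans.index)
    clusters = truth.cluster_trans
    k = int(clusters.max()) + 1
    truth.motif_targets = {
        m.motif_name: i % k for i, m in enumerate(motifs)
    }
    bases = np.array(list("ACGT"))
    out = []
    for gene_id in ids:
        seq = rng.choice(bases, size=length)
        for m in motifs:
            rate = (
                planted_rate
                if clusters.loc[gene_id] == truth.motif_targets[m.motif_name]
                else background_rate
            )
            if rng.random() < rate:
                inst = _concrete_motif(m.iupac, rng)
                pos = int(rng.integers(0, length - len(inst) + 1))
                seq[pos : pos + len(inst)] = list(inst)
        out.append(PromoterSet(str(gene_id), "".join(seq)))
    return out


def plant_correlation(
    metab: OmicsMatrix,
    trans: OmicsMatrix,
    pairs: list[tuple[str, str, float]],
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> OmicsMatrix:
    """Rewrite chosen transcripts so their ln time-mean profile has a given
    Pearson correlation with a metabolite's ln time-mean profile.

    The new profile is the exact blend r*z_x + sqrt(1-r^2)*z_e with z_e a
    standardized noise direction orthogonal to the metabolite profile, so
    the realized correlation over time-point means equals ``target_r``
    exactly; replicate deviations are constrained to sum to zero within
    each time point so replicate noise cannot shift the means.
    """
    rng = _rng(seed, "correlation")
    new_vals = trans.values.copy()
    design = trans.design
    times = np.asarray(design.times)
    T = times.size
    ln_metab_means = OmicsMatrix(
        pd.DataFrame(
            np.log(metab.values.to_numpy(dtype=float)),
            index=metab.values.index,
            columns=metab.values.columns,
        ),
        metab.design,
        "ln_centered",
    ).time_means()
    groups = design.groups()
    for metab_id, trans_id, target_r in pairs:
        if not -1.0 <= target_r <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")
        x = ln_metab_means.loc[metab_id].to_numpy(dtype=float)
        if x.std() <= 1e-12:
            raise ValueError(f"metabolite {metab_id!r} has a constant profile")
        zx = (x - x.mean()) / x.std()
        # noise direction orthogonal to zx, standardized
        for _ in range(100):
            e = rng.normal(size=T)
            e = e - e.mean()
            e = e - (e @ zx) / (zx @ zx) * zx
            if e.std() > 1e-8:
                break
        ze = (e - e.mean()) / e.std()
        y = target_r * zx + np.sqrt(max(0.0, 1.0 - target_r**2)) * ze
        base = float(np.log(100.0))
        profile = base + y  # ln-scale time means for the transcript
        row = np.empty(design.n_samples)
        for t, idx in groups.items():
            ti = int(np.searchsorted(times, t))
            dev = rng.normal(0.0, 0.05, size=len(idx))
            dev -= dev.mean()  # zero-sum: time means stay exact
            row[idx] = profile[ti] + dev
        new_vals.loc[trans_id] = np.exp(row)
        if truth is not None:
            truth.correlation_pairs.append((str(metab_id), str(trans_id), float(target_r)))
    return OmicsMatrix(new_vals, design, value_scale="raw")
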