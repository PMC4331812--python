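"""Shared data model and readers/writers for the tabular and sequence formats.

The pipeline works on feature-by-sample abundance matrices bound to a sample
design (developmental time point in days after flowering, replicate number),
plus three kinds of side tables: feature annotations (chemical class,
ortholog), category catalogs (pathway / GO membership), and promoter
sequences with an IUPAC motif library.

All tables are TSV with a header row; missing abundance cells are empty and
mean "below detection" (the detection filter itself lives in
:mod:`seedfill.differential`). Promoters are plain FASTA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CHEMICAL_CLASSES",
    "IUPAC_CODES",
    "SampleDesign",
    "OmicsMatrix",
    "FeatureAnnotation",
    "CategoryCatalog",
    "PromoterSet",
    "MotifDef",
    "read_design",
    "write_design",
    "read_matrix",
    "write_matrix",
    "read_catalog",
    "write_catalog",
    "read_promoters",
    "write_promoters",
    "read_motifs",
    "write_motifs",
    "read_annotations",
    "write_annotations",
    "write_json_summary",
]

#: The eight chemical classes used for metabolite annotation: amino acids &
#: amines, aromatics, esterified fatty acids, free fatty acids, organic
#: acids, sugars & derivatives, sterols & tocopherols, unknown.
CHEMICAL_CLASSES = ("AA", "AR", "eFA", "fFA", "OA", "SGD", "ST", "UK")

#: IUPAC degenerate DNA codes and the bases each matches. An ``N`` in a
#: *sequence* is never matched by any code (unknown base != wildcard base).
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

PROMOTER_ALPHABET = frozenset("ACGTN")

VALUE_SCALES = ("raw", "ln_centered")


@dataclass(frozen=True)
class SampleDesign:
    """Sample layout: one entry per sample (time point x replicate)."""

    sample_ids: tuple[str, ...]
    time_points: tuple[float, ...]  # days after flowering
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.time_points) != n or len(self.replicates) != n:
            raise ValueError("design fields must have equal length")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in design")
        if any(r < 1 for r in self.replicates):
            raise ValueError("replicate numbers must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def times(self) -> tuple[float, ...]:
        """Distinct time points in increasing order."""
        return tuple(sorted(set(self.time_points)))

    def groups(self) -> dict[float, list[int]]:
        """Column indices per time point, in increasing time order."""
        out: dict[float, list[int]] = {t: [] for t in self.times}
        for i, t in enumerate(self.time_points):
            out[t].append(i)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time": self.time_points,
                "replicate": self.replicates,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        required = {"sample_id", "time", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        return cls(
            sample_ids=tuple(str(s) for s in df["sample_id"]),
            time_points=tuple(float(t) for t in df["time"]),
            replicates=tuple(int(r) for r in df["replicate"]),
        )


@dataclass
class OmicsMatrix:
    """A features x samples abundance/signal matrix bound to its design.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample, in design order. ``value_scale`` is ``"raw"`` (positive
    abundances, NaN = below detection) or ``"ln_centered"`` (natural log,
    median-centered within each sample).
    """

    values: pd.DataFrame
    design: SampleDesign
    value_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"value_scale must be one of {VALUE_SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups[:5])}")
        if list(self.values.columns) != list(self.design.sample_ids):
            raise ValueError("matrix columns must equal design sample ids, in order")
        if self.value_scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError("raw matrix contains non-positive values")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, feature_ids: Iterable[str]) -> "OmicsMatrix":
        ids = list(feature_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"features not in matrix: {sorted(missing)[:5]}")
        return OmicsMatrix(self.values.loc[ids], self.design, self.value_scale)

    def time_means(self) -> pd.DataFrame:
        """Per-feature means over replicates within each time point.

        Missing (below-detection) cells are excluded from the mean.
        Returns a features x time-points DataFrame (columns sorted by time).
        """
        cols = {}
        for t, idx in self.design.groups().items():
            block = self.values.iloc[:, idx].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                cols[t] = np.nanmean(block, axis=1)
        return pd.DataFrame(cols, index=self.values.index)


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_id: str
    chemical_class: str | None = None
    ortholog_id: str | None = None
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.chemical_class is not None and self.chemical_class not in CHEMICAL_CLASSES:
            raise ValueError(
                f"unknown chemical class {self.chemical_class!r}; "
                f"expected one of {CHEMICAL_CLASSES}"
            )


@dataclass(frozen=True)
class CategoryCatalog:
    """A pathway or GO category with its member feature ids.

    A category is *testable* only when at least two members map to measured
    features; non-testable categories are retained but flagged.
    """

    category_id: str
    category_kind: str = "pathway"
    member_ids: frozenset[str] = field(default_factory=frozenset)
    n_measured: int = 0
    testable: bool = False

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"category {self.category_id!r} has no members")

    @classmethod
    def build(
        cls,
        category_id: str,
        member_ids: Iterable[str],
        measured_ids: Iterable[str] | None = None,
        category_kind: str = "pathway",
    ) -> "CategoryCatalog":
        members = frozenset(str(m) for m in member_ids)
        measured = set(measured_ids) if measured_ids is not None else set(members)
        n = len(members & measured)
        return cls(category_id, category_kind, members, n, n >= 2)


@dataclass(frozen=True)
class PromoterSet:
    """One promoter: up to 1000 nt immediately upstream of the ATG."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - PROMOTER_ALPHABET
        if bad:
            raise ValueError(
                f"promoter {self.gene_id!r} has invalid characters {sorted(bad)}"
            )
        if len(self.sequence) > 1000:
            raise ValueError(f"promoter {self.gene_id!r} longer than 1000 nt")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifDef:
    """A named cis-element as a degenerate IUPAC DNA string."""

    motif_name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.motif_name!r} has empty pattern")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"motif {self.motif_name!r} has non-IUPAC characters {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleDesign.from_frame(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, design_path: str | Path) -> OmicsMatrix:
    """Read a TSV abundance matrix and align its columns to the design.

    The first column holds feature ids, the header row holds sample ids.
    Empty cells are below-detection markers. Sample order in the result is
    the design file's order regardless of column order in the value file.
    """
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate feature ids in {path}: {list(dups[:5])}")
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"samples in design but not in matrix: {missing}")
    extra = [s for s in df.columns if s not in set(design.sample_ids)]
    if extra:
        raise ValueError(f"matrix samples absent from design: {extra}")
    df = df.loc[:, list(design.sample_ids)]
    values = df.apply(pd.to_numeric, errors="raise")
    arr = values.to_numpy(dtype=float)
    n_nonpos = int(np.sum(arr[np.isfinite(arr)] <= 0))
    if n_nonpos:
        warnings.warn(
            f"{n_nonpos} non-positive cells treated as below detection",
            stacklevel=2,
        )
        values = values.where(values > 0)
    return OmicsMatrix(values, design, value_scale="raw")


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_catalog(
    path: str | Path, measured_ids: Iterable[str]
) -> list[CategoryCatalog]:
    """Assemble categories from a (feature_id, category_id[, kind]) TSV.

    Categories are returned sorted by id; membership is a set, so duplicate
    rows collapse and row order never matters.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty catalog file: {path}")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("catalog table needs feature_id and category_id columns")
    feat_col, cat_col = cols[0], cols[1]
    kind_col = cols[2] if len(cols) > 2 else None
    if df[feat_col].isna().any() or df[cat_col].isna().any():
        raise ValueError("malformed catalog row with missing field")
    measured = set(str(m) for m in measured_ids)
    out = []
    for cat_id, grp in df.groupby(cat_col, sort=True):
        kind = "pathway"
        if kind_col is not None:
            kinds = grp[kind_col].dropna().unique()
            if len(kinds) == 1:
                kind = str(kinds[0])
            elif len(kinds) > 1:
                raise ValueError(f"category {cat_id!r} has conflicting kinds {kinds}")
        out.append(
            CategoryCatalog.build(str(cat_id), grp[feat_col], measured, kind)
        )
    return out


def write_catalog(catalogs: Sequence[CategoryCatalog], path: str | Path) -> None:
    rows = [
        {"feature_id": m, "category_id": c.category_id, "category_kind": c.category_kind}
        for c in catalogs
        for m in sorted(c.member_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_promoters(path: str | Path) -> list[PromoterSet]:
    """Read promoter FASTA; upper-case and keep the ATG-proximal 1000 nt.

    Records longer than 1000 nt are truncated to their 3'-most 1000 nt,
    the end adjacent to the translational start.
    """
    out: list[PromoterSet] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id in promoter FASTA: {gene_id!r}")
        seen.add(gene_id)
        seq = str(rec.seq).upper()
        if len(seq) > 1000:
            seq = seq[-1000:]
        out.append(PromoterSet(gene_id, seq))
    return out


def write_promoters(promoters: Sequence[PromoterSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id}\n")
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")


def read_motifs(path: str | Path) -> list[MotifDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"motif_name", "iupac"} <= set(df.columns):
        raise ValueError("motif table needs motif_name and iupac columns")
    motifs = [MotifDef(str(r.motif_name), str(r.iupac).upper()) for r in df.itertuples()]
    names = [m.motif_name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names")
    return motifs


def write_motifs(motifs: Sequence[MotifDef], path: str | Path) -> None:
    pd.DataFrame(
        {"motif_name": [m.motif_name for m in motifs], "iupac": [m.iupac for m in motifs]}
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for r in df.itertuples():
        cc = getattr(r, "chemical_class", None)
        cc = None if (cc is None or pd.isna(cc)) else str(cc)
        ortho = getattr(r, "ortholog_id", None)
        ortho = None if (ortho is None or pd.isna(ortho)) else str(ortho)
        name = getattr(r, "display_name", "")
        name = "" if pd.isna(name) else str(name)
        out.append(FeatureAnnotation(str(r.feature_id), cc, ortho, name))
    return out


def write_annotations(annotations: Sequence[FeatureAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in annotations],
            "chemical_class": [a.chemical_class or "" for a in annotations],
            "ortholog_id": [a.ortholog_id or "" for a in annotations],
            "display_name": [a.display_name for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def write_json_summary(summary: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
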