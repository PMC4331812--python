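"""Promoter cis-element scanning and per-cluster motif enrichment.

Promoters (up to 1000 bp upstream of the translational start) are scanned
for degenerate IUPAC motifs on both strands: a hit is a position where the
motif matches the promoter forward sequence or the promoter's reverse
complement. Overlapping matches all count, and an ``N`` in the *sequence*
matches no motif letter. Enrichment of a motif in a cluster of genes is a
one-sided Fisher exact (hypergeometric) test of motif presence (>= 1 hit)
in the cluster against the genome-wide promoter background.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import IUPAC_CODES, MotifDef, PromoterSet

__all__ = [
    "MotifHit",
    "MotifEnrichmentRecord",
    "reverse_complement",
    "scan_motif",
    "scan_all",
    "motif_cluster_enrichment",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_name: str
    count: int

    @property
    def present(self) -> bool:
        return self.count >= 1


@dataclass
class MotifEnrichmentRecord:
    motif_name: str
    cluster_id: str
    k_in: int  # genes with motif inside the cluster
    n_in: int  # cluster size
    k_bg: int  # genes with motif in the background
    n_bg: int  # background size
    p: float
    significant: bool


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (N stays N)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(iupac: str) -> re.Pattern:
    # lookahead so overlapping occurrences all count; N in the scanned
    # sequence never appears in any character class, so it matches nothing
    parts = []
    for ch in iupac.upper():
        bases = IUPAC_CODES[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(promoter: PromoterSet, motif: MotifDef) -> MotifHit:
    """Count motif occurrences on the promoter and its reverse complement.

    A motif longer than the promoter simply yields count 0.
    """
    pat = _iupac_regex(motif.iupac)
    seq = promoter.sequence
    count = len(pat.findall(seq)) + len(pat.findall(reverse_complement(seq)))
    return MotifHit(promoter.gene_id, motif.motif_name, count)


def scan_all(
    promoters: list[PromoterSet], motifs: list[MotifDef]
) -> pd.DataFrame:
    """Occurrence counts for every (gene, motif) pair.

    Returns a genes x motifs DataFrame of counts; presence is ``counts >= 1``.
    """
    pats = {m.motif_name: _iupac_regex(m.iupac) for m in motifs}
    data = {}
    rc = {p.gene_id: reverse_complement(p.sequence) for p in promoters}
    for name, pat in pats.items():
        data[name] = [
            len(pat.findall(p.sequence)) + len(pat.findall(rc[p.gene_id]))
            for p in promoters
        ]
    return pd.DataFrame(data, index=pd.Index([p.gene_id for p in promoters], name="gene_id"))


def motif_cluster_enrichment(
    counts: pd.DataFrame,
    clusters: pd.Series,
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> list[MotifEnrichmentRecord]:
    """One-sided Fisher exact enrichment of motif presence per cluster.

    ``counts`` is the genes x motifs table from :func:`scan_all`;
    ``clusters`` maps gene id -> cluster id for the clustered genes (a
    subset of the background); ``background`` defaults to all scanned genes.
    Presence (>= 1 hit), not occurrence count, drives the test. Records
    with p < ``alpha`` are flagged significant.
    """
    background = set(background) if background is not None else set(map(str, counts.index))
    if not background <= set(map(str, counts.index)):
        raise ValueError("background contains genes without scanned promoters")
    clusters = clusters.astype(str)
    if not set(map(str, clusters.index)) <= background:
        raise ValueError("clustered genes must be a subset of the background")
    bg_list = sorted(background)
    present = counts.loc[bg_list] >= 1
    n_bg = len(bg_list)
    out = []
    for motif_name in counts.columns:
        pres = present[motif_name]
        k_bg = int(pres.sum())
        for cluster_id in sorted(clusters.unique()):
            genes = [str(g) for g in clusters.index[clusters == cluster_id]]
            n_in = len(genes)
            k_in = int(pres.loc[genes].sum())
            p = float(stats.hypergeom.sf(k_in - 1, n_bg, k_bg, n_in))
            p = min(p, 1.0)
            out.append(
                MotifEnrichmentRecord(
                    motif_name=str(motif_name),
                    cluster_id=cluster_id,
                    k_in=k_in,
                    n_in=n_in,
                    k_bg=k_bg,
                    n_bg=n_bg,
                    p=p,
                    significant=p < alpha,
                )
            )
    return out
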