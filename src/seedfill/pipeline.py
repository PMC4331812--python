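"""End-to-end orchestration of the seed-fill analysis.

Stage order mirrors the analysis flow: simulate (or load) -> detection
filter + normalization -> per-feature differential F-tests with q-values ->
profile clustering with K selection -> category statistics (MRPP, Fisher
over-representation, class-by-cluster tests) -> co-analysis (volcano,
correlation) -> promoter motif enrichment. Every stage writes TSV outputs
and contributes to a JSON run summary; all randomness fans out from the
single configured seed through named substreams, so reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import category_stats, clustering, coanalysis, differential, motifs, simulate
from .io import (
    MotifDef,
    OmicsMatrix,
    write_catalog,
    write_design,
    write_json_summary,
    write_matrix,
    write_motifs,
    write_promoters,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("seedfill")


@dataclass
class RunConfig:
    """Thresholds and sizes for one pipeline run."""

    seed: int = 0
    out_dir: str = "seedfill_out"
    # simulation (used when no input paths are given)
    sim: simulate.SimulationSpec | None = None
    n_categories: int = 20
    enriched_fraction: float = 0.5
    n_motifs: int = 4
    planted_rate: float = 0.5
    background_rate: float = 0.05
    correlation_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    # thresholds
    q_trans: float = 0.01
    q_metab: float = 0.05
    k_range_metab: tuple[int, int] = (2, 8)
    k_range_trans: tuple[int, int] = (2, 11)
    n_restarts: int = 10
    mrpp_B: int = 10_000
    contingency_B: int = 100_000
    r_band: tuple[float, float] = (0.9, 1.0)
    r_p_max: float = 0.05
    volcano_times: tuple[float, float] = (25.0, 50.0)
    pi0_method: str = "lambda_0.5"

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = simulate.SimulationSpec(seed=self.seed)
        for q in (self.q_trans, self.q_metab):
            if not 0.0 <= q <= 1.0:
                raise ValueError("q cutoffs must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim"})
        if sim_raw:
            cfg.sim = simulate.SimulationSpec(**sim_raw)
        return cfg


_MOTIF_LIBRARY = [
    ("TGBOXLIKE", "AACGTG"),
    ("GBOXLIKE", "CACGTG"),
    ("WBOXLIKE", "TTGACY"),
    ("RYLIKE", "CATGCA"),
    ("MYBLIKE", "WAACCA"),
    ("ABRELIKE", "ACGTGKC"),
]


def _default_motifs(n: int) -> list[MotifDef]:
    return [MotifDef(name, pat) for name, pat in _MOTIF_LIBRARY[:n]]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on simulated data and write outputs + summary JSON."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def _stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        # --- simulate -----------------------------------------------------
        _stage("simulate")
        spec = dataclasses.replace(config.sim, seed=config.seed)
        metab, trans, truth = simulate.simulate_timecourse(spec)
        catalogs = simulate.simulate_catalogs(
            truth, config.n_categories, config.enriched_fraction, seed=config.seed
        )
        motif_defs = _default_motifs(config.n_motifs)
        promoters = simulate.simulate_promoters(
            truth,
            motif_defs,
            planted_rate=config.planted_rate,
            background_rate=config.background_rate,
            seed=config.seed,
        )
        pairs = config.correlation_pairs
        if not pairs:  # one planted query pair by default
            nn = truth.is_null_metab.index[~truth.is_null_metab]
            pairs = [(str(nn[0]), str(trans.feature_ids[0]), 0.95)]
        trans = simulate.plant_correlation(metab, trans, pairs, seed=config.seed, truth=truth)

        write_matrix(metab, out / "metabolites.tsv")
        write_matrix(trans, out / "transcripts.tsv")
        write_design(metab.design, out / "design_metab.tsv")
        write_design(trans.design, out / "design_trans.tsv")
        write_catalog(catalogs, out / "catalogs.tsv")
        write_motifs(motif_defs, out / "motifs.tsv")
        write_promoters(promoters, out / "promoters.fasta")
        truth_json = {
            "cluster_metab": truth.cluster_metab.to_dict(),
            "cluster_trans": truth.cluster_trans.to_dict(),
            "enriched_categories": truth.enriched_categories,
            "motif_targets": truth.motif_targets,
            "correlation_pairs": truth.correlation_pairs,
        }
        write_json_summary(truth_json, out / "ground_truth.json")
        summary["stages"]["simulate"] = {
            "n_metab": metab.shape[0],
            "n_trans": trans.shape[0],
            "n_categories": len(catalogs),
            "n_motifs": len(motif_defs),
        }

        # --- differential ---------------------------------------------------
        _stage("differential")
        results = {}
        normalized = {}
        for name, matrix, cutoff in (
            ("metab", metab, config.q_metab),
            ("trans", trans, config.q_trans),
        ):
            res, norm, dropped = differential.differential_analysis(
                matrix, config.pi0_method
            )
            res.index.name = "feature_id"
            res.to_csv(out / f"differential_{name}.tsv", sep="\t")
            results[name] = res
            normalized[name] = norm
            summary["stages"][f"differential_{name}"] = {
                "n_detected": int(res["passed_detection"].sum()),
                "n_dropped": len(dropped),
                "n_significant": int(
                    ((res["q"] < cutoff) & res["passed_detection"]).sum()
                ),
                "q_cutoff": cutoff,
            }

        # --- clustering -----------------------------------------------------
        _stage("clustering")
        chosen = {}
        assignments = {}
        for name, cutoff, k_range in (
            ("metab", config.q_metab, config.k_range_metab),
            ("trans", config.q_trans, config.k_range_trans),
        ):
            res = results[name]
            selected = res.index[(res["q"] < cutoff) & res["passed_detection"]]
            if len(selected) < k_range[1] + 2:
                summary["stages"][f"clustering_{name}"] = {
                    "n_selected": int(len(selected)),
                    "chosen_K": None,
                }
                assignments[name] = pd.Series(dtype=int)
                continue
            profiles, constant = clustering.make_profiles(
                normalized[name], feature_ids=list(selected)
            )
            table, chosen_k, sols = clustering.krzanowski_lai(
                profiles,
                K_range=range(k_range[0], k_range[1] + 1),
                seed=config.seed,
                n_restarts=config.n_restarts,
            )
            sol = sols[chosen_k]
            table.to_csv(out / f"kl_table_{name}.tsv", sep="\t")
            sol.assignment.rename("cluster").to_csv(
                out / f"clusters_{name}.tsv", sep="\t"
            )
            chosen[name] = chosen_k
            assignments[name] = sol.assignment
            summary["stages"][f"clustering_{name}"] = {
                "n_selected": int(len(selected)),
                "n_constant_dropped": len(constant),
                "chosen_K": chosen_k,
                "medoids": sol.medoid_ids,
            }

        # --- category statistics ---------------------------------------------
        _stage("category_stats")
        mrpp_results = []
        for cat in catalogs:
            if not cat.testable:
                continue
            mrpp_results.append(
                category_stats.mrpp_test(
                    normalized["trans"], cat, B=config.mrpp_B, seed=config.seed
                )
            )
        category_stats.category_fdr(mrpp_results, config.pi0_method)
        pd.DataFrame(
            [
                {
                    "category_id": r.category_id,
                    "m": r.m,
                    "delta": r.delta_obs,
                    "A": r.A,
                    "p": r.p,
                    "q": r.q,
                }
                for r in mrpp_results
            ]
        ).to_csv(out / "mrpp.tsv", sep="\t", index=False)

        res_t = results["trans"]
        selected_t = set(
            map(str, res_t.index[(res_t["q"] < config.q_trans) & res_t["passed_detection"]])
        )
        background_t = set(map(str, res_t.index[res_t["passed_detection"]]))
        fisher_results = [
            category_stats.fisher_overrep(selected_t, cat, background_t)
            for cat in catalogs
            if len(cat.member_ids & background_t) >= 2
        ]
        pd.DataFrame(
            [
                {
                    "category_id": r.category_id,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "odds_ratio": r.odds_ratio,
                    "p": r.p,
                }
                for r in sorted(fisher_results, key=lambda x: x.p)
            ]
        ).to_csv(out / "fisher_overrep.tsv", sep="\t", index=False)

        classdist = None
        if len(assignments["metab"]):
            common = assignments["metab"].index
            classdist = category_stats.class_by_cluster_tests(
                assignments["metab"],
                truth.classes.loc[common],
                B=min(config.contingency_B, 20_000),
                seed=config.seed,
            )
            pd.DataFrame(
                [
                    {"family": fam, "label": r.label, "p": r.p, "method": r.method}
                    for fam in ("per_class", "per_cluster")
                    for r in classdist[fam]
                ]
                + [
                    {
                        "family": "overall",
                        "label": classdist["overall"].label,
                        "p": classdist["overall"].p,
                        "method": classdist["overall"].method,
                    }
                ]
            ).to_csv(out / "class_by_cluster.tsv", sep="\t", index=False)

        summary["stages"]["category_stats"] = {
            "n_mrpp": len(mrpp_results),
            "n_mrpp_q05": int(sum(1 for r in mrpp_results if (r.q or 1) < 0.05)),
            "n_fisher": len(fisher_results),
            "n_fisher_p05": int(sum(1 for r in fisher_results if r.p < 0.05)),
            "overall_class_by_cluster_p": (
                classdist["overall"].p if classdist else None
            ),
        }

        # --- co-analysis -----------------------------------------------------
        _stage("coanalysis")
        t1, t2 = config.volcano_times
        vol = coanalysis.volcano(normalized["metab"], t1, t2, config.pi0_method)
        vol.index.name = "feature_id"
        vol.to_csv(out / "volcano.tsv", sep="\t")

        corr_summary = {}
        if truth.correlation_pairs:
            metab_id, trans_id, target_r = truth.correlation_pairs[0]
            query = np.log(
                metab.values.loc[[metab_id]].to_numpy(dtype=float)
            )
            query_means = (
                OmicsMatrix(
                    pd.DataFrame(query, index=[metab_id], columns=metab.values.columns),
                    metab.design,
                    "ln_centered",
                )
                .time_means()
                .iloc[0]
            )
            records = coanalysis.correlate_query(
                query_means,
                OmicsMatrix(
                    pd.DataFrame(
                        np.log(trans.values.to_numpy(dtype=float)),
                        index=trans.values.index,
                        columns=trans.values.columns,
                    ),
                    trans.design,
                    "ln_centered",
                ),
                query_id=metab_id,
            )
            records.to_csv(out / "correlation.tsv", sep="\t")
            ranks = records["r"].abs().rank(ascending=False, method="min")
            corr_summary = {
                "query": metab_id,
                "planted_target": trans_id,
                "planted_r": float(records.loc[trans_id, "r"]),
                "planted_rank": int(ranks.loc[trans_id]),
                "n_targets": int(len(records)),
            }
        summary["stages"]["coanalysis"] = {
            "volcano_n_p05": int((vol["q"] < 0.05).sum()),
            **corr_summary,
        }

        # --- motif enrichment -------------------------------------------------
        _stage("motifs")
        counts = motifs.scan_all(promoters, motif_defs)
        if len(assignments["trans"]):
            cluster_series = assignments["trans"].astype(str)
        else:
            cluster_series = truth.cluster_trans[truth.cluster_trans >= 0].astype(str)
        enr = motifs.motif_cluster_enrichment(counts, cluster_series)
        pd.DataFrame(
            [
                {
                    "motif_name": r.motif_name,
                    "cluster_id": r.cluster_id,
                    "k_in": r.k_in,
                    "n_in": r.n_in,
                    "k_bg": r.k_bg,
                    "n_bg": r.n_bg,
                    "p": r.p,
                    "significant": r.significant,
                }
                for r in enr
            ]
        ).to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        summary["stages"]["motifs"] = {
            "n_tests": len(enr),
            "n_significant": int(sum(1 for r in enr if r.significant)),
        }

    except Exception as exc:  # pragma: no cover - abort diagnostics
        log.error("pipeline aborted: %s", exc)
        raise

    summary["wall_time_s"] = round(time.time() - t0, 2)
    write_json_summary(summary, out / "run_summary.json")
    return summary
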