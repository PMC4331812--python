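# seedfill

Statistical analysis of time-course multi-omics data from developing seeds.

During seed fill, the embryo converts imported sucrose and amino acids into
protein, oil and carbohydrate reserves. Profiling the metabolome (hundreds of
analytes, several replicates) and the transcriptome (tens of thousands of
probes, few replicates) across a handful of developmental time points — e.g.
25–50 days after flowering — raises a recurring set of statistical questions:
which features change at all, which temporal shapes exist and how many, which
pathways or chemical classes move together, which metabolite–transcript pairs
co-accumulate, and which promoter elements mark co-expressed gene clusters.
`seedfill` packages that analysis as a tested, reusable library with a thin
CLI, plus a ground-truthed synthetic data generator so the whole pipeline can
be exercised and validated without any external dataset.

## What it computes

* **Differential screen.** Abundances are ln-transformed and median-centered
  within each sample (chip). Per feature, the fixed-effects linear model
  `y ~ replication + time` (both categorical) is fit and the overall F-test
  for dropping the time term gives a p-value for *any* change in mean level
  across time points; p-values become Storey q-values
  `q(i) = min_{j≥i} π̂₀ m p(j)/j` (with π̂₀ from the λ=0.5 estimator, or
  π̂₀=1 for Benjamini–Hochberg). A detection filter keeps features observed
  in every replicate of at least one time point.
* **Profile clustering.** Standardized per-time-point mean profiles
  (mean 0, sd 1) are clustered by PAM K-medoids (BUILD + SWAP) under
  Euclidean distance; the number of clusters maximizes the Krzanowski–Lai
  criterion `KL(K) = |DIFF(K)| / |DIFF(K+1)|`,
  `DIFF(K) = (K−1)^{2/d} W_{K−1} − K^{2/d} W_K`, with `W_K` the within-cluster
  sum of squared distances to the medoid.
* **Category statistics.** MRPP (multiresponse permutation procedure):
  δ = Σ_g (n_g/N)·(mean within-group pairwise distance), permutation p with
  group sizes fixed — does a category's joint distribution change over time?
  Fisher exact (hypergeometric) over-representation of categories in a
  selected feature list; and class-by-cluster distribution tests (per-class
  uniformity chi-square, per-cluster and overall Monte-Carlo chi-square with
  fixed margins, exact 2×K Fisher available).
* **Co-analysis.** Volcano comparison of two time points (Welch t-test,
  ln fold change) and Pearson correlation of a query profile against all
  features over time-point means, with `t = r·sqrt((n−2)/(1−r²))` p-values.
* **Motif enrichment.** IUPAC motif scanning of ≤1000-bp promoters on both
  strands (overlaps counted, `N` in sequence matches nothing) and one-sided
  Fisher enrichment of motif presence per cluster against the genome-wide
  background.
* **Synthetic data.** Cluster-structured temporal templates with log-normal
  noise, replicate offsets, chemical-class labels, enriched category
  catalogs, promoters with planted motifs, and exactly-planted
  metabolite–transcript correlations — all reproducible from one seed.

## Worked example

```python
import pandas as pd
import seedfill as sf

# Are the 30 sterols/tocopherols spread evenly over 5 metabolite clusters?
assign = pd.Series(
    ["M1"] * 23 + ["M3"] * 4 + ["M4"] * 2 + ["M5"] * 1        # ST members
    + ["M1"] * 57 + ["M2"] * 61 + ["M3"] * 32 + ["M4"] * 33 + ["M5"] * 60,
    index=[f"m{i}" for i in range(273)])
classes = pd.Series(["ST"] * 30 + ["other"] * 243, index=assign.index)
res = sf.class_by_cluster_tests(assign, classes, B=100_000, seed=0)
st = next(r for r in res["per_class"] if r.label == "ST")
print(f"ST uniformity p = {st.p:.3g}")

print(f"two-sided p for r=0.86 over 5 time points: {sf.correlation_pvalue(0.86, 5):.3f}")

cfg = sf.RunConfig(seed=11, out_dir="demo")
cfg.sim = sf.SimulationSpec(seed=11, n_trans=300)   # scaled-down transcriptome
cfg.k_range_trans = (2, 10)
summary = sf.run_pipeline(cfg)
print("metabolite clusters chosen:", summary["stages"]["clustering_metab"]["chosen_K"])
print("transcript clusters chosen:", summary["stages"]["clustering_trans"]["chosen_K"])
```

prints

```
ST uniformity p = 1.29e-12
two-sided p for r=0.86 over 5 time points: 0.062
metabolite clusters chosen: 5
transcript clusters chosen: 8
```

The sterol class is concentrated in the earliest-rising cluster far beyond
an even spread (p ≈ 1.3e-12); a correlation of 0.86 over five time points
sits right at the edge of nominal significance (p ≈ 0.06); and on synthetic
data the Krzanowski–Lai criterion recovers the planted five metabolite and
eight transcript clusters. `run_pipeline` writes every stage's TSV outputs
plus `run_summary.json` and `ground_truth.json` under `out_dir`.

The same stages are available from the shell:

```bash
seedfill simulate --seed 5 --out-dir sim
seedfill diff sim/metabolites.tsv sim/design_metab.tsv --q-cutoff 0.05
seedfill cluster sim/metabolites.tsv sim/design_metab.tsv --k-min 2 --k-max 8
seedfill motifs sim/promoters.fasta sim/motifs.tsv cluster_assignment.tsv
seedfill run --seed 5 --out-dir full_run
```

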