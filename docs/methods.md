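# Methods

This note records the statistical models `seedfill` implements, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Normalization and the differential screen

Raw abundances are assumed strictly positive with missing cells meaning
"below detection". The detection filter keeps a feature iff some time point
has all of its replicates observed — a feature reliably measured at even one
stage is kept, one that never yields a complete time point is not. Values are
then natural-log transformed and median-centered *within each sample*
(column), the analogue of per-chip centering; after centering every sample's
median over features is exactly 0. Remaining missing cells are excluded from
medians and propagated.

Each feature is fit with the fixed-effects linear model
`y ~ replication + time`, both categorical, no interaction: replication is a
block effect and the overall F-test for dropping the time term screens for
any change in mean level across time points. The fit uses a QR projection
shared across all complete features; features with missing cells are re-fit
on their observed samples. Degenerate features (constant values, or zero
residual/numerator degrees of freedom after missingness) are assigned p = 1
and flagged rather than NaN so that downstream set operations stay total.

Storey q-values use the step-down minimum `q(i) = min_{j≥i} π̂₀ m p(j)/j`
clipped to 1. Two π̂₀ estimators are exposed: `fixed_1` (π̂₀ = 1, exactly
Benjamini–Hochberg) and the default `lambda_0.5`
(π̂₀ = #{p > 0.5}/(0.5 m), clipped into [1/m, 1]). The λ = 0.5 point
estimate is the simplest member of the Storey family; the smoother variant
was left out because with a few thousand features the two differ little and
the point estimate is exactly reproducible.

## Profile clustering

Profiles are per-time-point means of the normalized values (replicates
averaged first), standardized to mean 0 / sd 1 across time points, so both
platforms cluster in the same d-dimensional space (d = number of time
points, 5 by default). Means rather than full replicate vectors keep the
metabolite (6-replicate) and transcript (2-replicate) platforms directly
comparable. Constant profiles cannot be standardized and are excluded with a
flag. Profiles are held in lexicographic feature-id order so all tie-breaks
are independent of input row order.

PAM is the classical BUILD (greedy, deterministic, ties to the smallest
index) plus SWAP (best-improvement, vectorized over all candidate swaps)
under Euclidean distance. `n_restarts` (default 10) runs BUILD once and the
remaining starts from seeded random medoid sets, keeping the best solution
by total cost, ties broken by the lexicographically smallest medoid set.

The number of clusters maximizes the Krzanowski–Lai criterion
`KL(K) = |DIFF(K)|/|DIFF(K+1)|` with
`DIFF(K) = (K−1)^{2/d} W_{K−1} − K^{2/d} W_K`. `W_K` is computed as the sum
of *squared* Euclidean distances of members to their **medoid** — staying
inside the K-medoids frame rather than switching to centroids for the
criterion — and W is evaluated one K beyond each end of the requested range
so KL is defined everywhere inside it. Ties in the argmax go to the smaller
K (parsimony).

## Category statistics

**MRPP.** For a category with ≥2 measured members, each sample is the vector
of member values on the normalized ln scale — deliberately *not*
per-feature standardized, since the test targets changes in accumulation
that standardization would erase. The statistic is
δ = Σ_g (n_g/N) · (mean pairwise Euclidean distance within group g), groups
being time points, with the classical n_g/N weights. The null shuffles
sample→group labels with group sizes fixed, Monte-Carlo with
p = (1 + #{δ* ≤ δ})/(B+1) (resolution 1/(B+1), never 0; B defaults to
10,000), or exhaustively over all distinct assignments when requested. The
chance-corrected agreement A = 1 − δ/E[δ*] is reported informationally.

MRPP's permutation null assumes exchangeable samples. Additive per-replicate
offsets (blocked designs) violate that assumption and make the test
miscalibrated in either direction; the calibration study therefore simulates
the exchangeable null (`rep_effect_sd=0`), and each null category is drawn
from its own independent dataset — categories sharing one dataset share its
per-sample normalization shifts and give dependent p-values. On real blocked
data MRPP p-values should be read as approximate.

**Over-representation.** One-sided hypergeometric upper-tail p for the
overlap between a selected list and a category within a background; the odds
ratio uses a 0.5 substitution on zero cells for reporting only.

**Class-by-cluster tests.** Three families for a features × {label,
cluster} pair:

* *per class* (default `chi2_uniform`): chi-square goodness of fit of the
  label's cluster counts against an even spread over the K clusters
  (df = K−1). This is the natural reading of "is this class distributed
  evenly across the clusters", and it is asymptotic; an exact conditional
  Fisher test of the 2×K class-vs-rest table (probability ordering,
  branch-and-bound over margin-preserving tables, exact to enumeration) is
  available as `per_class_method="fisher_exact"`.
* *per cluster*: Monte-Carlo chi-square on the 2×J cluster-vs-rest table.
  Null tables with fixed margins are sampled by the Patefield algorithm;
  extremeness is the Pearson statistic; B defaults to 100,000, matching the
  10⁻⁵ resolution such tables are usually reported at.
* *overall*: the I×J association test, same Monte-Carlo machinery, plus the
  chi-square uniformity test of the cluster sizes themselves.

## Co-analysis

Volcano comparisons use Welch's unequal-variance t-test on replicate values
between two time points (pooled-variance inference is deliberately not the
default: replicate counts are small and variances need not match), with the
fold change as the difference of group means on the ln scale. Correlation
co-analysis computes Pearson r between per-time-point mean profiles and the
exact two-sided p from `t = r·sqrt((n−2)/(1−r²))` on n−2 df; with the
default 5 time points, r = 0.86 gives p ≈ 0.06. Zero-variance profiles are
flagged with undefined r. Correlated sets (r inside a band, p below a
cutoff) feed the same hypergeometric over-representation test against the
all-targets background.

With n = 5 time points the correlation ranking has limited resolution: any
feature sharing the query's temporal shape can reach |r| close to 1 by
chance, so a genuinely co-regulated partner is only identifiable against
candidates with *different* shapes (e.g. an annotated gene family whose
other members follow other profiles). The recovery test mirrors exactly that
scenario; whole-transcriptome top-1 ranking at n = 5 is not a claim this
package makes.

## Motif scanning and enrichment

IUPAC motifs are compiled to overlapping-match regular expressions over
{A,C,G,T}; an `N` in the scanned sequence matches no motif letter (unknown
base ≠ wildcard). A promoter's count is the sum of forward-strand matches on
the sequence and on its reverse complement — cis-elements act from either
strand — and scanning is reverse-complement symmetric by construction.
Enrichment per (motif, cluster) is the one-sided Fisher exact test of motif
*presence* (≥1 hit, not count) in the cluster versus the genome-wide
promoter background, flagged at p < 0.05 by default with no multiplicity
correction (a q column can be added by the caller). Presence and
double-stranded scanning are configurable decisions, not facts about any
particular study.

## Synthetic data

The generator emulates the shape of a seed-fill study: 5 harvests at 25, 30,
35, 45, 50 days after flowering; 273 metabolite analytes in 8 chemical
classes (31/7/12/12/15/41/30/125) with 6 replicates; 2,869 transcript probes
with 2 replicates. Non-null features draw a temporal template from up to 8
standardized shape families (steady rise/decline, late rise/fall, mid
peak/dip, early plateau/decline) evaluated at the day values and scaled by
`effect_scale` (default 1.0 on the ln scale). A feature's value is
`exp(baseline + template + rep_offset + ε)` with ε ~ N(0, `noise_sd`)
(default 0.25, i.e. a 4:1 signal-to-noise ratio on the ln scale) and
per-replicate offsets N(0, `rep_effect_sd`), default `noise_sd/2`, giving
the linear model's replication term something real to absorb (set 0 for
fully exchangeable samples). `frac_null` features get flat templates.
Everything derives from one seed through named substreams, so adding a stage
never perturbs another stage's draws and equal specs give bit-identical
output.

Catalogs plant enrichment by drawing ≥80% of an enriched category's members
from one target cluster. Promoters are 1000 bp of i.i.d. uniform A/C/G/T
with one exact motif instance inserted at a random position with probability
`planted_rate` (target cluster) or `background_rate` (elsewhere); chance
matches in the random background remain and must be found by scanning, which
matters for short motifs — a 6-mer has ≈0.4 probability of a chance hit per
kilobase per strand, so presence contrasts need hundreds of genes per
cluster, the scale the promoter analyses run at. Planted correlations are
constructed exactly: the transcript's ln time-mean profile is set to
`r·z_x + sqrt(1−r²)·z_e` with z_e standardized noise orthogonal to the
metabolite profile, and replicate deviations are constrained to sum to zero
within each time point, so the realized Pearson r over time-point means
equals the target exactly.

What the generator does *not* emulate: probe-level chip artifacts and
cross-hybridization, mass-spectral peak shapes, heteroscedastic or
feature-correlated noise, unbalanced designs, and temporal shapes outside
the template families. Passing recovery tests therefore demonstrate that the
algorithms recover structure of the planted kind at realistic
signal-to-noise, not that any particular biological dataset has that
structure.

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen to make every
stochastic check tight at interactive speed: metabolite-side studies at the
full default 273 × 30; transcript-side recovery at 300–1,000 features
(planted K = 8 stays identifiable from ~300 features, and the acceptance
script's K-selection study uses 600 over three seeds, reporting the mode);
20 seeds for clustering/K-selection/FDR/category recovery; 500 independent
null datasets for MRPP calibration; promoter studies at the full 2,869-gene
scale where presence contrasts dominate chance 6-mer hits. Monte-Carlo
defaults are B = 10,000 (MRPP) and B = 100,000 (contingency tables).

Floating-point and tie-break details: exact-test tie inclusion uses a 1e-7
relative slack on log-probabilities; Monte-Carlo extremeness comparisons use
a 1e-12 absolute slack; PAM accepts a swap only if it improves cost by more
than 1e-12 relative; KL ties choose the smaller K; matrices round-trip
through TSV at full precision (`%.17g`, round-trip float parsing).

## Known limitations

* MRPP with replicate blocks is approximate (see above); a stratified
  permutation variant would be the principled extension.
* The per-class uniformity test is asymptotic chi-square; with very small
  class totals the exact 2×K option should be preferred.
* The q-value implementation exposes only π̂₀ ∈ {1, λ=0.5}; no smoother.
* Volcano and correlation analyses assume the normalized scale is already
  comparable across samples; no additional batch correction is attempted.
* K selection by Krzanowski–Lai inherits its known instability when cluster
  separation is weak; the acceptance study quantifies the selection rate
  rather than asserting determinism.
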