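# Methods

This note records the statistical models, the numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## Site-level differential methylation

Betas are clipped to [10⁻³, 1−10⁻³] and converted to M-values,
M = log₂(β/(1−β)), before modelling; the clip keeps M finite and 10⁻³ is
the conventional guard value (configurable). For each probe we fit by OLS

    M ~ 1 + group + covariates

with group coded case = 1, so the group coefficient is the
case-minus-control difference in M-units. Covariates are ordinary
sample-sheet columns; there is no region-specific hardcoding — which
columns enter (age always; cell-composition fractions only where the
cohort shows composition differences) is a config decision.

Variance moderation follows the standard empirical-Bayes recipe: the
per-probe residual variances s²ᵍ (dₙ degrees of freedom) are modelled as
draws from a scaled inverse-chi-square prior (d₀, s₀²) fitted by method of
moments on log s²ᵍ (the trigamma relation is inverted by Newton
iteration); the posterior variance s̃²ᵍ = (d₀s₀² + dₙs²ᵍ)/(d₀+dₙ) replaces
s²ᵍ in the t statistic, whose null df become dₙ + d₀. When the observed
log-variances are no more dispersed than chi-square sampling noise, d₀ is
infinite and all probes share s₀². Moderation is on by default; plain OLS
(`moderate_var=False`) exists so results can be checked against a
textbook per-probe regression, which the test suite does.

Effect sizes are always reported as Δβ (difference of group mean betas):
it is the interpretable methylation-fraction scale and the unit in which
the region filter below is stated.

Multiple testing uses Benjamini–Hochberg step-up with monotonicity
enforcement, implemented directly (it is a core contract of the package)
and cross-checked in tests against both a literal brute-force definition
and statsmodels.

## Region calling

Per chromosome, t² is smoothed with a Gaussian kernel of bandwidth
λ = 1000 bp (Nadaraya–Watson weights, contributions beyond 4λ truncated).
A probe is *site-significant* if

* its BH-adjusted p ≤ 0.05, **or**
* its smoothed statistic exceeds the pooled (1−0.05) quantile **and** its
  raw p ≤ 0.05 (`site_nominal_p`).

The raw-p gate on the smoothing track is a deliberate refinement: kernel
smoothing spreads a strong locus over ±4λ, so without the gate plainly
null neighbours are flagged, join the region, and dilute its mean Δβ
below the 10% filter — in planted benchmarks that costs essentially all
sensitivity. With the gate, the smoothing track still rescues coordinated
sub-threshold sites (its purpose) while excluding noise.

Significant probes within λ bp merge into candidate regions; candidates
need ≥ 2 CpGs; the region p-value is Fisher's combination of member raw
p-values (χ² with 2k df), BH-adjusted across regions; reported regions
must satisfy FDR < 0.05 and |mean Δβ| ≥ 0.10. The Δβ filter applies to
the **mean** member Δβ (the max is also reported and the threshold is
configurable; which of the two the classic region callers gate on is
ambiguous in practice). Internally regions are 0-based half-open
(BED-compatible); the TSV report uses 1-based inclusive coordinates.

No Satterthwaite df correction is applied to the smoothed statistic; the
two-track rule above replaces the kernel test of the reference region
caller while preserving its merge and threshold semantics, which is what
the planted-recovery benchmark exercises.

## Methylation modules on the PPI graph

Gene statistics aggregate |t| over the probes mapped to each gene (mean
by default, max optional; a promoter-only filter is available because
methylation effects are position-dependent). On the PPI graph, node
weight = gene statistic (0 for genes without probes), edge weight = mean
of its endpoint weights, and a module's *score* is its mean internal edge
weight.

The search is seed-and-grow: seeds are the top-ranked local maxima of the
node weight; growth repeatedly adds the neighbour whose new internal
edges have the highest mean, admitting it while that mean stays within
0.85 of the current module mean (a singleton has mean 0, so growth can
always start); afterwards, members whose mean internal edge weight falls
below 0.85 of the module mean are pruned worst-first (keeping the largest
connected piece). The admission/pruning tolerance keeps modules pure: a
literal "grow while the mean does not decrease" rule cannot leave the
seed, and an untolerated mean is maximised by a single lucky pair.

Significance: the gene statistics are permuted over the graph n_perm
times (default 1000), the full search is re-run, and each observed module
is compared to the permutation distribution of the **maximum** module
statistic, using the size-aware statistic Σw / √(edge count) (a mean-edge
score would again be dominated by pairs). The empirical p uses the
add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm), so it is never 0, and
comparing against the permutation maximum makes "any module with
emp_p < α" a family-wise-calibrated statement: measured over 200 fully
null runs the rate is 0.025–0.04 at α = 0.05.

This greedy procedure replaces the spin-glass optimiser of the original
module-detection package; the contract it is tested on is planted-module
recovery (Jaccard ≥ 0.6 with the truth, emp_p ≤ 0.05) and the calibrated
null above. A module's direction summary is the fraction of members with
positive signed mean Δβ (≥ 0.5 ⇒ predominantly hypermethylated).

## Epigenetic clock

A clock is (intercept, probe weights, adult_age); the linear predictor
x = intercept + Σwᵢβᵢ is mapped to years by the calibration transform

    F(age) = log(age+1) − log(adult+1)   (age ≤ adult)
           = (age − adult)/(adult+1)     (age > adult)

and its exact inverse. F is continuous at adult_age (default 20) and the
pair round-trips to < 10⁻¹⁰ over [0, 120] years. Published coefficient
sets are **not** bundled (licensing and version drift); the model is a
CSV format with an `(Intercept)` row, and the tests use synthetic clocks.

Age acceleration is reported as the difference DNAm − chronological age
and as the residual of one OLS fit of DNAm age on chronological age over
the samples passed to the call (residuals are mean-zero over that cohort
by construction). The residual regression pools cases and controls per
call; per-region analyses are separate calls (CLI `--stratify`). Group
comparisons use Welch's t-test on both AA variants.

## Expression

CPM = count/library-size × 10⁶ with library sizes the column sums. The
low-expression filter keeps a gene when CPM ≥ 0.3 in at least half the
samples of either group. The differential model fits log₂(CPM + 0.5) by
OLS on group + covariates — an intentionally simple, documented stand-in
for a negative-binomial fit with surrogate variables; the integration
stages only consume a DEG list, and an externally produced table (any
TSV with gene, lfc, p, direction) can be substituted for it. The DEG gate
is raw p < 0.01 by default (an adjusted-p gate is a flag); the published
convention this mirrors does not say which, so the default follows the
looser reading.

## Network integration

PPI edges are deduplicated ((a,b) ≡ (b,a), max confidence, self-loops
dropped) and filtered at confidence ≥ 0.7. Nodes are labelled by the
evidence lists containing them (DEG / DMR / FEM; a node may carry several
labels); an edge is retained iff some pairing of endpoint labels is
heterogeneous — equivalently it is dropped only when both endpoints carry
exactly the same single label. The largest connected component is kept
(ties broken by the lexicographically smallest node list).

Centralities: degree (raw), average neighbour degree, closeness
(n−1)/Σd, betweenness with the 2/((n−1)(n−2)) normalisation and local
clustering coefficient via networkx; eigenvector and Katz are computed
with dense linear algebra — the principal eigenvector from a symmetric
eigendecomposition, and Katz as the solution of (I − αA)x = 1 with
α = 0.9/λ_max, β = 1 — both L2-normalised. The dense solves are exact to
machine precision and are verified against independent brute-force
oracles (BFS distance sums, exhaustive shortest-path enumeration, power
iteration on A + I, the Katz series) on random small graphs.

Hubs: per metric, the threshold is the linear-interpolation empirical
95th percentile (nearest-rank available), ties included; the hub set is
the union over the seven metrics with per-metric provenance, and the
per-source breakdown is a reporting view of that one selection. Whether
the percentile should be pooled or per evidence source is ambiguous in
the source convention; pooled is the default.

Enrichment: one-sided hypergeometric upper tail against the supplied
universe, sets intersected with the universe before sizing, sets smaller
than 5 excluded before testing, BH across tested sets, FDR < 0.05.

## TF regulatory networks

DMRs are intersected with TF binding clusters using half-open interval
overlap of ≥ 1 bp (configurable); a chr-prefix mismatch between the two
inputs raises an explicit error with a rename hint. By default all DMRs
are annotated; `--intergenic-only` restricts to DMRs whose member probes
map to no gene (the stricter reading of "regions not located at genes" —
both behaviours ship because the convention is ambiguous). Supported TFs
join to the TF→target table restricted to DEGs; interaction modes are
normalised onto {activation, repression, unknown}; TFs with support but
no DEG target go to a side report.

## Cohort statistics

The summary t-test implements the pooled (Student) and Welch variants
directly from (mean, SD, n); both round the motivating cohort's age row
to the same published value, and Student is the default. Fisher's exact
2×2 sums hypergeometric point probabilities ≤ the observed one (relative
tolerance 1+10⁻⁷). Mann–Whitney enumerates all C(n₁+n₂, n₁) label
assignments exactly for combined n ≤ 20, counting assignments whose U is
at least as far from n₁n₂/2 as observed (midranks under ties); larger
samples use the tie-corrected normal approximation with continuity
correction. The published brain-weight and PMI rows do not reproduce from
their rounded summaries (they were evidently computed on unrounded data);
they are not used as checks.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:
8 cases vs 8 controls, ages ≥ 50 drawn from N(75, 13²) rounded to 0.1 y,
3F/5M per group; 2000 probes over 2 chromosomes with exponential spacing
(mean 500 bp; 200 bp in the region-recovery benchmark); null betas from
the bimodal mixture 0.6·Beta(2,10) + 0.4·Beta(10,2) with N(0, 0.15²)
noise on the M scale; planted shifts of Δβ = 0.2 applied on the beta
scale in cases and clipped to (0.001, 0.999) — planted baselines are
drawn from a range that keeps baseline ± Δβ inside the clip, so the
noiseless planted difference is exact. Detection p-values are ≪ 0.05
with a 10⁻³ failure fraction. Counts are negative-binomial
(variance μ + 0.1μ²) with log-normal base means and library factors and
2^lfc case scaling at planted DEGs (lfc ±1.5). The PPI background is
Erdős–Rényi with edge probability 0.01 (mean degree ≈ 4, matching sparse
high-confidence interactomes), one planted dense module whose genes also
carry methylation signal at their probes (predominantly hypomethylated),
and a denser 0.15 tier among signal-carrying genes, reflecting the
functional clustering of co-regulated genes — without it the cross-source
network of a desk-scale run is nearly empty. The synthetic clock sets
all clock-probe betas equal per sample so the predictor hits F(age)
exactly regardless of how the total weight is split. TF clusters cover a
configurable fraction of planted regions plus decoys placed off-truth.

What the benchmarks show — and do not. Passing planted recovery shows the
callers detect coordinated shifts of the stated size under Gaussian
M-scale noise with honest error control; it does not certify performance
on real arrays, which add probe-type chemistry effects, batch structure,
cell-composition confounding and spatial correlation that the generator
deliberately omits (normalisation and batch correction are assumed done
upstream). All samples are measured in every region per run; per-region
sample overlap is not modelled. One planted module per graph is the
default; multi-module generation is a configuration extension.

## Problem sizes and determinism

The benchmark sizes (2000 probes, 20 replicates, 199–999 permutations,
200 null runs at 99 permutations) were chosen as the smallest at which
the binomial/KS checks are informative; all generators and searches are
pure functions of their inputs including the seed, and a pipeline rerun
with the same config and seed is byte-identical (the run manifest stores
paths relative to the run directory for this reason). Derived seeds stay
below 2³¹.
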