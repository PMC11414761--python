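# Methods

This note documents the statistical procedures the package implements,
the defaults it chooses where the underlying analysis left details open,
what the synthetic-data generator does and does not emulate, and the
numerical conventions that matter for reproducing its output.

## Relative fitness and growth

A competition assay yields one fitness value per replicate,
w_r = ln(D·Nf_m/Ni_m) / ln(D·Nf_a/Ni_a), the ratio of the competitors'
Malthusian parameters over one growth cycle. `D` (dimensionless, default
100) is the net fold-expansion implied by the serial-transfer regime: a
100-fold daily dilution regrown to saturation expands 100-fold. Zero
colony counts are hard errors, never imputed — an uncountable plate is an
uncountable plate. Group summaries pool all assays of a genotype ×
temperature by default; averaging technical replicates within biological
replicates first is available (`pool_technical=False`) because the two
conventions genuinely differ in df and neither is canonical. The
one-sample t against w̄ = 1 uses df = n − 1 with Bonferroni adjustment
across the whole family of genotype × temperature tests. Heterogeneity
among biological replicates is a one-way fixed-effects ANOVA.

Growth curves are fit by sliding every window of ≥ 5 points over
ln(density), scoring each by R², and taking the best positive-slope
window (ties to the earliest window; μ_max in h⁻¹). A constant window is
given R² = 1 and slope exactly 0, so flat cultures report μ_max = 0
rather than floating-point noise. Final yield defaults to the maximum
observed density; the last point of the fitted window is available
because "end of exponential phase" admits both readings. Two-sample
growth comparisons default to Welch's t (unequal variances are the rule
for growth parameters measured years apart).

## Fitness epistasis

ε = w̄_xy − w̄_x·w̄_y, with the expectation's uncertainty propagated by
the exact product-variance identity for independent random variables:
Var(w̄_x·w̄_y) = (Var(w̄_x)+w̄_x²)(Var(w̄_y)+w̄_y²) − w̄_x²w̄_y², and
Var(ε) = Var(w̄_xy) + Var(w̄_x·w̄_y). All variances are variances of
means (s²/n). Independence of the single-mutant estimates is assumed
as-is; no covariance term is added, which can understate Var(ε) if the
assumption fails — it affects significance, not the magnitude of ε.
The per-pair t uses df = n_xy − 1 (the double mutant's replicate count
minus one); the reference leaving the df convention loose, it is
configurable. A degenerate Var(ε) = 0 with ε ≠ 0 reports p = 0 with an
explicit degeneracy flag rather than NaN.

Pooled ε per temperature: one-sample two-tailed t against 0, 95% CI
half-width t₀.₉₇₅,ₙ₋₁ × SE. Cross-environment variation: one-way ANOVA
with temperature as the factor.

Diminishing returns regresses the foreground mutation's fitness effect on
background fitness. The effect is the ratio w̄_xy/w̄_x by default — a
relative gain, which keeps the quantity dimensionless and comparable
across backgrounds — with the difference w̄_xy − w̄_x behind a flag. The
regression runs on the combined allele set and per foreground allele;
a significantly negative slope is the diminishing-returns signature.

## Differential expression layer

Size factors are median-of-ratios: per sample, the median over genes
(with all-positive geometric row means) of count / geometric mean.
Normalized counts are counts divided by the factor.

The built-in DE test is deliberately minimal — a per-gene two-sample t on
log2(normalized + 1) with Benjamini–Hochberg FDR across the genes of a
contrast — and exists so synthetic end-to-end runs need no external
engine; real analyses should ingest DE tables produced by a dedicated
count-model framework (`ingest_de_table`). The t pools the two group
variances by default (df = n₁+n₂−2). At the 2–4 replicates typical of
these designs, a per-gene Welch correction spends most of its information
estimating its own df: in planted-truth simulations at n = 4 it loses
roughly a quarter of strongly perturbed genes (16-fold changes) at the
q < 0.001 gate, while the pooled t recovers them with type-I error still
calibrated under the null (verified by simulation in the test suite).
Welch remains available via `equal_var=False`. The pseudocount is
configurable; genes with all-zero counts in a contrast are dropped with a
logged count. The q < 0.001 and |log2FC| > 2 thresholds are applied by
downstream consumers, never silently here.

Expression variability is the per-gene, per-genotype coefficient of
variation σ/μ of normalized counts (sample SD); genotypes with one
sample are excluded, zero-mean genes flagged undefined.

## Expression epistasis

ε_exp = GE_xy − (GE_x + GE_y) on log2 fold changes against the ancestor
at the stress temperature — additive on the log scale, hence the analogue
of the multiplicative fitness null. Z-scores standardize ε_exp against
the genome-wide mean and sample SD of the same double mutant: one score
per gene per double, as a "standard score" implies; per-gene
replicate-level SDs are not used. Tier A requires q < 0.001 in at least
one of the three mutant-vs-ancestor contrasts (rho single, rpoB single,
double); tier B additionally requires |log2FC| > 2 in such a contrast and
|Z| > 2, both strict inequalities.

Sign balance is a two-sided exact binomial test of positive vs negative
ε_exp at p = ½ (exact zeros count to neither side). Distribution shape
uses Pearson moment measures with population (divisor-n) central moments:
γ₁ = m₃/m₂^1.5 and non-excess γ₂ = m₄/m₂² (normal ⇒ 3; lower bound
γ₂ ≥ γ₁² + 1). Gene-set summaries report, per set and double mutant: the
sign counts and binomial test among flagged genes, a two-sided Wilcoxon
rank-sum of ε_exp in vs out of set (exact for group sizes ≤ 50,
tie-corrected normal approximation otherwise), a two-sided variance-ratio
F-test with df (n₁−1, n₂−1), and the set's tier-A DE fraction.

## Evolutionary-change classification

Three contrasts describe each gene: the ancestor's own stress response
(Anc42 vs Anc37) and the mutant against the ancestor at both temperatures.
With significance meaning q < threshold (default 0.001): restored and
reinforced require both the ancestral response and the mutant-vs-Anc42
contrast significant, in opposite or the same direction respectively;
novel requires no ancestral response but significance in both mutant
contrasts; unrestored requires an ancestral response the mutant does not
counter (mutant-vs-Anc42 non-significant). The four published definitions
are not exhaustive, so a fifth explicit `unclassified` category absorbs
the remaining patterns (e.g. no ancestral response with only one mutant
contrast significant) — the partition is total and mutually exclusive by
construction. Direction-relative definitions are invariant to flipping
every log2FC's sign. A significant contrast with an exactly zero log2FC
(pathological input) falls to `unclassified` with a warning. "Novel" does
not additionally require the two mutant contrasts to agree in direction.

## Coexpression network

Expression is transformed as log2(normalized + 1), zero-variance genes
dropped. This stands in for a variance-stabilizing transform; downstream
statistics are correlations and ranks, which are robust to the
difference, and the simulation-based checks confirm per-gene variance
grows sublinearly with the mean after transformation. Known deviation:
counts from a dedicated VST will differ numerically.

Signed adjacency a_ij = ((1+cor)/2)^β with Pearson correlation and
β = 16 by default; the soft-threshold scan bins connectivity into 10
bins, regresses log10(frequency) on log10(k), signs R² negative when the
slope is positive, and returns the smallest β with signed R² ≥ 0.8 (else
the maximizer; else a configured default with a warning). Topological
overlap is TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
TOM_ii = 1.

Modules are average-linkage clusters of 1 − TOM cut statically at an
absolute height of 0.97 (configurable). The cut is absolute rather than
a fraction of the dendrogram range: on planted block structure (block
correlation 0.8, 20 seeds) within-block merges stay below ≈ 0.955 and
between-block merges above ≈ 0.986 on the 1 − TOM scale, so a fixed 0.97
separates them cleanly, whereas range-relative cuts drift with the
dendrogram's minimum height and merge true blocks on some seeds. Clusters
below 30 genes fall to the unassigned "grey" bin; modules whose
eigengenes correlate above 0.75 merge iteratively (most-correlated pair
first); survivors take the conventional size-ranked color names
(turquoise largest). The full recursive dynamic tree cut is out of scope.

A module eigengene is the first right-singular vector of the module's
gene-standardized expression, oriented so its average correlation with
member genes is positive and scaled to unit sample variance. kME is the
Pearson correlation of a gene with an eigengene, tested with the
correlation t at df = n_samples − 2. Intramodular connectivity k_within
sums a gene's adjacency to co-members (k_total over all genes; the
diagonal is excluded throughout). Hubs require all three: k_within at or
above the module's 90th percentile (linear-interpolation quantile;
modules under 10 genes take the single best-connected gene), kME
strictly > 0.9, and membership p < 0.01; grey genes are never hubs.
Module–trait association is the Pearson correlation of an eigengene with
a per-sample trait (samples inherit their genotype's w̄ per temperature),
flagged undefined for constant traits.

## Network comparisons

PPI edge lists (gene_a, gene_b, confidence) are filtered at confidence
≥ 0.9 by default; a 0–1000 integer dialect is auto-detected, duplicate
edges collapse to the maximum confidence, self-edges are dropped. Degree
is the count of distinct partners; genes in the analysis universe absent
from the edge list count as degree 0 (configurable to exclude, since
whether published degree comparisons included isolated genes is
ambiguous). Epistatic vs non-epistatic connectivity uses the two-sided
Wilcoxon rank-sum; hub enrichment of a gene set is the two-sided Fisher
exact test (summing tables with probability ≤ observed). Gene-name
harmonization goes through an explicit two-column alias table; unmapped
names are reported, never silently dropped.

## Synthetic data

Every generator is a pure function of (config, seed); streams are named
substreams of one master seed, so adding a generator never shifts
another's draws.

*Competition assays.* Initial counts are Poisson around a plating mean of
250 colonies; the ancestor's expected final count equals its initial (a
100-fold expansion plated after 100-fold dilution); the mutant's is
initial × D^(w_eff − 1) with w_eff = w + N(0, 0.10) per assay. The
Gaussian jitter models day-to-day biological variation and brings
per-assay Var(w) to ≈ 0.01–0.02, the scale of published assay-level
variances at the stress temperature; pure plating noise at realistic
colony counts would be several-fold smaller. Default design: 10 assays
per genotype × temperature (the study scale of ~240 double-mutant
assays over 24 genotype × temperature cells). The default fitness truth
plants the published per-pair epistatic deviations on top of plausible
single-mutant fitnesses, so the planted pattern reproduces the study's
diminishing-returns structure (strong negative ε for beneficial rho
alleles at 42.2 °C, weak for near-neutral ones and at lower
temperatures). A noise-free mode makes the estimator exact, which the
tests use as a round-trip check.

*Counts.* Negative binomial with variance μ + αμ², α = 0.05; per-sample
size factors uniform in [0.7, 1.4]; baselines log-normal around 200.
The default design is the 29-library layout (ancestor at both
temperatures, six singles and six doubles at 42.2 °C, two replicates
each, three for the stressed ancestor). Planted effects: an ancestral
stress response in 20% of genes (N(0, 1.5) log2FC), ±4 log2FC in 10% of
genes per single mutant, and ε_exp = ±2 in 5% of genes per double,
planted on genes the rho single already perturbs so that epistatic genes
are differentially expressed somewhere — the study's tier definitions
presuppose exactly that. Double-mutant log2FC is additive plus ε by
construction. What this generator does not emulate: gene–gene correlation
in counts, length/GC biases, and dispersion–mean trends; passing tests
therefore validate the estimators and gates, not count-model robustness
on real libraries.

*Coexpression.* Per block, a latent factor; members are
loading·factor + √(1−loading²)·noise, hubs get the highest loading
(default 0.98 vs 0.9), optional loading spread grades connectivity the
way real modules grade it, optional background genes are pure noise, and
cross-block correlation is configurable. *PPI.* Exact realization of a
planted degree sequence (Havel–Hakimi randomized by degree-preserving
edge swaps; simplified configuration model for non-graphical sequences),
true edges above the confidence cutoff, optional decoys below. *Gene
sets.* Weighted sampling without replacement with configurable enrichment
odds for flagged genes.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the generator at study
scale: 2,000 genes for expression simulations (the genome's ~4,200 coding
regions halved for economy — the statistics under test are
per-gene and insensitive to the cut), 200–400 genes for network recovery,
and 1,000–3,000 replications for Monte-Carlo oracles, chosen so every
check pins its quantity well inside the asserted tolerance. Estimator
calibration checks compare against the estimator's true sampling SD
measured from thousands of independent synthetic experiments rather than
against per-experiment variance estimates, because a ±2σ criterion is
sensitive to both the t-ness of small-sample variance estimates and the
oracle's own Monte-Carlo error. Ties in window selection break toward the
earliest window; quantiles use linear interpolation; p-values of 2×2
tables sum hypergeometric probabilities ≤ the observed table's; BH q
follows the standard step-up with monotonicity enforcement. All RNG is
numpy `default_rng` seeded explicitly; no global state.

## Known limitations

The simple DE layer is not a count model: no dispersion shrinkage, GLM
offsets or independent filtering; at two replicates per genotype its
q < 0.001 calls are very conservative, and real-data users should supply
DE tables from a dedicated engine. Exact module and DEG counts from the
original libraries are not reproducible from this package alone (they
depend on deposited data and unstated filter/cut parameters); the bundled
published tables cover the quantities that are pure arithmetic of printed
numbers. The product-variance propagation assumes independent single
mutants. Network construction is dense (full gene × gene matrices) and
sized for bacterial-genome-scale inputs, not for >20k-gene transcriptomes.
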