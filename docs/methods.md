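# Methods

This note documents the statistical models behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generators emulate (and
do not), and the numerical conventions that make runs reproducible.

## Differential expression on counts

**Model.** Per-gene counts are treated as negative binomial with
Var = μ + αμ². Library depth is removed by median-of-ratios size factors:
the size factor of sample *j* is the median, over genes with a positive
geometric mean across samples, of count_gj divided by that gene's geometric
mean. When no gene is positive in every sample, a `positive_subset` flag
computes geometric means and ratios over positive entries only. Note one
consequence of this estimator: multiplying one sample's counts by a constant
is absorbed into the size factors only up to a single global rescaling of
the normalized matrix (the per-gene geometric means shift by c^(1/n)), so
between-sample ratios — the quantity every downstream statistic uses — are
exactly preserved while absolute normalized values are not.

**Test.** The fold change is (mean_B + 0.5)/(mean_A + 0.5) on normalized
group means; the pseudocount keeps gates meaningful at zero counts. The Wald
statistic divides ln FC by its delta-method standard error
√(v_A/(n_A m_A²) + v_B/(n_B m_B²)) with v = m + αm². Dispersion α is
estimated per gene by the method of moments on the pooled within-group
variance, floored at 10⁻⁸, then shrunk 50/50 (configurable) in log space
toward a log-linear trend of dispersion on mean fitted across genes —
stabilizing the many-gene/few-sample regime without reproducing any
particular tool's machinery. The reference distribution is t with
n_A + n_B − 2 degrees of freedom rather than normal: with moment-estimated
dispersions at n = 5 per group the normal reference is visibly
anti-conservative, while the t reference puts the global-null type-I rate at
α = 0.05 in the 0.034–0.043 range across seeds (slightly conservative, as
expected from NB moment estimation). A Welch t test on log2(normalized + 1)
(`method="welch_log"`) serves log-intensity-like inputs, e.g. the
per-time-point pre-filter of the series data.

**Gates.** Classification is strict on both sides: up ⇔ FC > fc_up and
significance < α; down ⇔ FC < fc_down and significance < α, following the
printed inequality directions (human contrast 1.2 / 0.833 at FDR 0.2;
time-course 2 / 0.5 at p 0.05). Genes with mean normalized count below 1
(configurable) are dropped before testing to avoid degenerate dispersion
estimates.

**BH FDR** is the step-up rule q_(i) = min_{j≥i} p_(j)·m/j, capped at 1,
implemented directly and cross-checked in the tests against both a literal
O(m²) evaluation and statsmodels.

## Short-time-series profile clustering

Model profiles for T ordered time points are all change vectors in
{−c,…,+c}^(T−1) except the all-zero vector; templates are their cumulative
sums anchored at 0. For T = 4, c = 1 there are 3³ − 1 = 26 profiles. Profile
ids are ranks in the lexicographic order of change vectors — a deterministic
convention; published profile numbers from other tools use their internal
order, so ids are comparable only by template shape.

Replicates are averaged per time point (median optional), the series is
anchored by subtracting the first time point, and each gene joins the
template (scaled by `step_size`, default 1.0 log2 unit — an arbitrary scale
absorbed by the distance minimization) with the smallest Euclidean distance;
ties go to the lowest profile id.

Significance of a profile compares its observed membership against a
permutation null in which every gene's time order is shuffled independently
and re-anchored; `expected_n` is the mean membership over permutations, and
p is the one-sided binomial tail P(X ≥ observed) with success probability
expected_n / n_genes. This binomial tail is discrete and therefore mildly
conservative under the null (≈3% of profiles at p < 0.05 instead of 5%);
a `fisher2x2` switch instead tests the observed-vs-rounded-expected 2×2
table with a one-sided Fisher exact test. BH correction runs across
profiles. The p floor is the machine tiny value, keeping p in (0, 1].

## Set statistics

* **Overlap** partitions two gene sets exactly, preserving member order.
* **z-score composite**: each set gene is standardized across samples with
  the population sd (divisor n — a fixed, documented convention); a sample's
  score is the mean standardized value over usable set genes (zero-variance
  genes are excluded with a warning; at least two must remain). Groups are
  compared with the two-sided Mann–Whitney U test, normal approximation with
  tie correction.
* **Term enrichment** uses the one-sided hypergeometric upper tail
  P(X ≥ k | N, K, n) — over-representation being the question asked of
  upregulated pathway membership — with a `two_sided` Fisher 2×2 variant
  available. The universe defaults to all tested genes in the pipeline and
  is always explicit in the API; query genes outside it are dropped with a
  warning. BH runs across terms.
* **ΔΔCT**: ΔCT = CT_target − CT_reference per sample; ΔΔCT subtracts the
  control group's mean ΔCT per target (a group baseline rather than a single
  calibrator sample, matching relative quantification of treatment groups);
  relative expression is 2^(−ΔΔCT), so the control group is centred at 1 on
  the log scale. Adding a constant to every CT of a sample cancels exactly.

## GSEA

Genes are ranked by signal-to-noise (mean_B − mean_A)/(sd_A + sd_B) with
each sd floored at 0.2·|group mean| (the standard convention; a tiny floor
guards the all-zero case), descending, ties broken by gene id. The running
sum adds |metric|^p normalized by the hit total at set members (p = 1
default, the canonical weighting) and subtracts 1/(N − |S|) at non-members;
the enrichment score is the entry of maximal absolute value. With p = 0 the
statistic is the classical two-sample KS distance between hit and miss
positions (up to sign).

Null ES distributions come from phenotype permutation (group labels
reshuffled, ranking recomputed) when each group has at least 7 samples —
label permutations are too few below that, and an explicitly requested
phenotype mode falls back to gene-set sampling (logged) when fewer than 7
samples exist in total — otherwise from random same-size gene sets on the
fixed ranking. NES divides ES by the mean |null ES| of matching sign. The
permutation p is the add-one two-sided-on-magnitude tail
(1 + #{|null| ≥ |ES|})/(n_perm + 1): comparing magnitudes keeps null p
approximately uniform, whereas a sign-conditioned count over all
permutations would compress p into (0, ½). FDR is BH across sets (the
NES-histogram FDR of the original tool is deliberately not reproduced).

## Co-expression network and hubs

Every unordered pair of non-constant genes is tested with the exact
correlation t test (t = r√((n−2)/(1−r²)), two-sided, n − 2 df); BH runs
jointly across all tested pairs (one FDR cut on correlation pairs, not a
per-gene correction) and edges are kept at FDR < 0.05, with an optional |r|
floor that is off by default because the selection criterion is the FDR
alone. Nodes are all tested genes, so isolated genes carry coreness 0.

Coreness is the largest k such that a gene survives iterative removal of all
vertices of degree < k (computed via the standard core-number algorithm and
verified in tests against brute-force peeling). Hubs are ranked by coreness,
then by **correlation strength** (the sum of |r| over incident edges), then
degree, then gene id. Strength rather than raw degree as the first
tie-break is a deliberate design choice: in a dense planted module all
members tie on coreness, and weak spurious edges — which BH at FDR 0.05
admits at a rate of roughly α × (number of true pairs) when strong signals
are present — can hand a member a higher raw degree than the true hub,
whereas the hub's uniformly stronger correlations dominate the strength
ordering. On unweighted graphs strength equals degree, so the familiar
degree tie-break is recovered.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their spec (seed included); RNG
streams are per-generator, so stage order cannot perturb results. Each
generator emits a truth table sufficient to score recovery downstream.

* **Counts**: NB(μ, α) with Var = μ + αμ²; defaults 2 groups × 10 samples,
  baseline mean 100, dispersion 0.1 — a realistic moderately-dispersed bulk
  RNA-seq regime at the scale of a 11-vs-10 human cohort. Planted genes
  multiply the group-B mean by 2^(log2FC). Per-sample library factors
  (log-uniform on [0.7, 1.4] by default, disable with
  `library_factor_range=None`) exercise the normalization.
* **Time course**: log2 values equal to step_size × the planted profile's
  template (flat for unplanted genes) plus Gaussian noise, sd 0.25, over
  4 time points (0 h, 2 h, 24 h, 6 d) with 3 replicates per time point —
  the usual triplicate design of expression time courses. The triplicate
  default matters quantitatively: anchoring subtracts a noisy baseline, so
  with a single replicate the effective per-point noise (√2 × 0.25) puts a
  noticeable fraction of genes closer to a neighbouring template and
  assignment recovery drops from ≈0.99 to ≈0.76.
* **Co-expression**: one latent standard-normal factor; member i is
  loading_i·f + noise_sd·√(1 − loading_i²)·ε, so at the default noise_sd = 1
  the expected correlation between two members is the product of their
  loadings; the hub is distinguished purely by a larger loading (0.95 vs
  0.6). Non-members are independent noise.

Not emulated: batch effects, GC/length biases, dropout, outlier samples,
gene–gene correlation outside the planted module, non-NB overdispersion, and
asymmetric group sizes. Passing recovery tests therefore demonstrates that
the statistics behave correctly under their own model assumptions — not that
the pipeline is robust to real-data artefacts those assumptions exclude.

## Pipeline and reproducibility

The pipeline is driven by one YAML config with a single global seed;
per-stage seeds are derived by stable hashing of stage names (seed·1000003 +
CRC32(stage) mod 2³¹). Stages run in dependency order; enabling a stage
whose prerequisite is neither enabled nor supplied as a file aborts with an
error naming the missing stage. Every result table is TSV with floats at a
declared precision (default 6 significant digits); the run manifest records
a config hash and per-file SHA-256 checksums, and re-running with the same
config reproduces byte-identical result files. INFO logging summarizes the
gene counts surviving each filter, so a run reads as a funnel (tested →
gated DEGs → focus-set overlap → hub).

Default problem sizes for the bundled synthetic run (1000 genes for counts,
300 for the series, 30 for the network; 100–200 permutations) are chosen so
the complete pipeline and its test suite execute in seconds on one CPU while
leaving every Monte-Carlo margin comfortable.

## Known limitations

* The NB Wald test is a desk-scale statistic: no independent filtering,
  no outlier refitting, no exact numerical agreement with any published
  DE tool should be expected.
* Profile ids follow the package's lexicographic convention; cross-tool
  comparisons must go through template shapes.
* The binomial profile-significance tail is conservative for profiles with
  very small expected membership.
* Identifier handling is by opaque case-sensitive strings; no ortholog or
  symbol mapping is attempted, and input matrices must be complete (missing
  values are an error, not imputed).
* GSEA FDR is BH on permutation p-values, which is simpler and more
  conservative than the NES-histogram procedure of the original tool.
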