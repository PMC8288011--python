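# Methods

This note documents the statistical models, numerical choices and known
limitations of each oxmeth component, and what the synthetic cohort does
and does not emulate.

## Channel model and joint MLE (`oxmeth.quant`)

Each CpG carries proportions (p_u, p_m, p_h) of unmodified C, 5mC and
5hmC (summing to 1). Reads are Bernoulli calls with success
probabilities q_bs and q_ox (see README); methylated counts in the two
libraries are independent binomials. The likelihood is maximized over
the simplex as follows:

1. **Moment inversion.** The unconstrained MLE of (q_bs, q_ox) is the
   pair of observed proportions; the map (p_m, p_h) → (q_bs, q_ox) is
   affine and invertible for ox_conv > 0, giving
   p_h = (q̂_bs − q̂_ox)/ox_conv and
   p_m + p_h = (q̂_bs − (1 − bs_conv))/bs_conv. If the inverted triple is
   in the simplex it is the exact MLE (flag `interior`).
2. **Boundary cases.** Otherwise the log-likelihood (concave, being a
   composition of concave binomial log-likelihoods with affine maps) is
   maximized on each active face: p_h = 0 makes the two channels share
   one success probability, so the MLE pools the counts (closed form);
   p_u = 0 fixes q_bs = 1 and leaves a closed-form q_ox problem;
   p_m = 0 is a 1-D concave problem solved by vectorized golden-section
   search (80 iterations, endpoints checked). The best face wins and
   names the boundary flag.

Properties: interior solutions with perfect conversion satisfy
p_m = oxBS beta and p_h = BS beta − oxBS beta exactly; every estimate is
verified against an exhaustive simplex lattice search (step 1e-3) in the
acceptance suite.

**Estimator error and bias.** The per-site error floor is binomial: at
per-channel depth d and success probability q, sd(q̂) = √(q(1−q)/d). At
d = 200 and the cohort's q ≈ 0.77 this is ≈ 0.030, giving a mean
absolute error of ≈ 0.021 for p_m (partially reduced by channel pooling
on the p_h = 0 face) — the estimator sits at the information bound, so
MAE below 0.02 under these conditions is not attainable by any unbiased
method at this depth. Separately, because true 5hmC levels are small
(~0.02) relative to the noise of the channel difference, clipping at the
simplex boundary biases the *mean* 5hmC level upward at modest depth
(visible in example 02 at 30×); the bias shrinks with coverage. Coverage
QC follows the conventional ≥ 5 reads per channel (`pass_qc`); sites
failing it are retained but excluded from region calling.

Conversion rates are pooled ratios over spike-in control cytosines
(unmethylated control → bisulfite rate on the BS channel; fully
hydroxymethylated control → oxidative rate on the oxBS channel), with
defaults 0.9992 and 0.9657. Site-level "positive" calls for the
co-modification summaries use MLE mass > 0 by default; the threshold is
exposed because no canonical call rule exists. Per-sample summaries are
reported (the denominators of pooled alternatives differ; we pick the
per-sample convention and document it here).

## DMR/DhMR calling (`oxmeth.dmr`)

Input is a site × sample matrix of levels (beta or MLE proportions) with
depths and case/control labels. Sites must have ≥ `min_coverage` (5)
reads in at least one sample of each group (strict mode: every sample).

**Segmentation.** The per-site difference of group means is recursively
split at the point maximizing the absolute mean contrast between the two
halves. A segment is emitted as a candidate when its |mean difference|
reaches `diff_threshold` (0.2) and no member site dips below the
`valley_filter` (0.05); if valley sites exist, the segment splits at the
maximal non-valley runs. Flat signal yields no candidates; segments
below `min_cpg` (5) are discarded; `max_seg_len` (2000 CpGs) forces
splitting of pathologically long segments. The valley rule is an
absolute per-site floor — a fixed, documented interpretation, since
upstream tools do not specify theirs.

**Testing.** Each candidate is tested twice. The 2D-KS test embeds each
(site, sample) observation as a (relative position, level) point; the
statistic is the maximum over all data points (both samples) and the
four quadrants each defines (≤/> splits per axis) of the
quadrant-fraction discrepancy — the Fasano–Franceschini two-sample
construction — with the large-sample KS tail and the usual correlation
correction √(1 − r̄²)(0.25 − 0.75/√n_eff). The Mann–Whitney U test runs
on the pooled per-site levels of the two groups (exact null for tie-free
pooled n ≤ 12, tie-corrected normal approximation otherwise; U reported
as min(U₁, U₂)). Regions pass with both raw p < 0.001 and
|mean diff| strictly > 0.2, then receive BH q-values computed across all
retained candidates of one channel and contrast.

Missing (QC-failed) values are dropped per region; label swap provably
flips signs/directions and leaves p-values unchanged (tested).

## Synthetic cohort (`oxmeth.cohort`)

The generator emulates the study design the pipeline targets: stages
healthy, CIN1–3, cervical cancer (CC) and paracancer, two samples per
stage by default, paired BS/oxBS binomial counts at Poisson(10) depth
per channel (matching ~10× study coverage), conversion errors 0.9992 /
0.9657. Default per-stage mean levels are the observed stage averages
(5mC: 76.58 / 78.57 / 79.84 / 72.13 / 68.66%; 5hmC: 1.83 / 1.141 /
0.82 / 3.62 / 0.94%); since two healthy means are reported in the
source data (per-stage list vs overall trend), both are exposed as
presets `stage_list` (default) and `trend`. Paracancer, for which no
numeric mean is printed, is set slightly above CC (0.72 / 0.015),
matching the qualitative description. Site-level noise is
Beta(mean·κ, (1−mean)·κ) with concentration κ = 30; draws exceeding the
simplex are rescaled. Planted DMR/DhMRs shift the target channel's mean
by ± effect over a run of CpGs in the target stages (clipped with a
warning). Coordinates are 0-based half-open and strand-collapsed (the
Watson/Crick strands behave identically in this design, so a single
collapsed track is the default).

The toy genome places CpG islands and genes on jittered grids — spacing
guarantees that shores (±1 kb), shelves (next 2 kb) and gene flanks
(1–5 kb) never self-overlap — and draws CpG positions with geometric
gaps (mean 120 bp background, 12 bp inside islands). Spike-ins are two
dense control contigs (fully unmodified; fully hydroxymethylated),
~800 CpGs each so pooled conversion estimates resolve rates of order
1e-3 at 10–30×. Read-depth tracks are Poisson per 33 kb bin with planted
copy-ratio segments; expression is baseline − slope·(promoter mean 5mC)
+ Gaussian noise; survival times are exponential with log-hazard linear
in a marker, administratively censored at 5 years. The survival stage
operates on a separate validation cohort (default n = 300, emulating the
external array cohort such analyses actually use) because a 12-sample
sequencing cohort cannot support cutpoint/Cox estimation.

**What the generator does not emulate:** bimodal CpG-level methylation
landscapes (background is unimodal Beta around the stage mean),
read-level errors and mapping artifacts, strand asymmetries, correlated
neighboring CpGs beyond the planted regions, and real annotation
geometry. Passing tests therefore demonstrate correctness of the
estimators and callers under the declared model, not performance on
real libraries.

## Enrichment (`oxmeth.enrichment`)

One random region per query (configurable `n_draws`), length-matched,
uniform over all valid start positions genome-wide (chromosome chosen
proportionally to its number of valid starts). Overlap is any-≥1 bp on
half-open intervals via a sorted sweep. The 2×2 construction pools
query and random regions: population N = both sets, successes K = all
regions overlapping the class, draws n = query set, and
p = P(X ≥ n_obs_in) upper-tail hypergeometric;
fold = (query in-rate)/(random in-rate), +inf flagged when the random
rate is 0, NaN when neither set overlaps. Stars: * p<0.05, # p<0.01,
$ p<0.001. Null calibration (uniform queries) is verified at ≤ 8%
rejections at α = 0.05 over 200 seeds.

## Copy number and integration (`oxmeth.integration`)

Bins are a fixed 33 kb half-open tiling (terminal partial bin retained
and flagged). Case/normal per-bin ratios are normalized by the
genome-wide median ratio and segmented on the log2 scale by circular
binary segmentation: the scan maximizes, over all inner windows, the
t-like contrast |mean_in − mean_out|·√(1/(1/n_in + 1/n_out)) — windows
touching a segment end reduce to ordinary splits — and recursion stops
when the best statistic falls below `split_z` (default 6) noise units,
with the per-bin noise scale estimated robustly from successive bin
differences (median|Δ|/(0.6745·√2), floored at 1e-6 so noise-free
constructed inputs still segment). A fixed absolute contrast stop was
rejected: a short plant inside a long chromosome dilutes the first
split's contrast below any fixed threshold, making interior plants
undiscoverable. Segment copy number is 2·2^(mean log2 ratio); calls use
gain ≥ 2.68 and loss ≤ 1.38. Planted copy-4/copy-1 recovery reaches
bin-level F1 ≈ 0.9 at ~30 reads/bin and ≥ 0.95 at 50+ (tested at 50).

M values follow the log2-of-beta convention (not the logit), computed as
log2(max(beta, ε)) with ε = 1e-3 purely as a floor for beta = 0 — M is
exactly log2(beta) for beta ≥ ε. Both z-scores standardize case-minus-
normal differences by the case sample's own per-track SD over bins.
CNV–methylation association is summarized per sample by Spearman
correlation of the z-tracks (pairwise-complete), and per stage by the
Spearman correlation between within-stage pairwise Euclidean distance
vectors of the two data types (≥ 3 samples required). Mutation-type
association with 5hmC runs a per-type Fisher exact test on
[type vs rest] × [5hmC-positive vs not] after normalizing G-strand
variants to the C strand, with Haldane +0.5 odds ratios when a cell is
empty.

Meta-profiles length-normalize peak bodies into 20 bins with fixed-width
±15 kb flanks (15 bins each side); boundary profiles use strand-aware
±150 bp windows in 20 bins around TSS/exon anchors, stratified by
expression class (high/low/no at |fold change| ≥ 2). Bins without CpGs
are missing, never zero-filled.

## Survival (`oxmeth.survival`)

Kaplan–Meier is the product-limit estimator; the log-rank test uses unit
weights (the conventional default; the literature's "weighted" variant
is unspecified, so weights are configurable in principle via the
standardized statistic) with hypergeometric variance and a χ²(1) p.
The optimal cutpoint scans midpoints between consecutive unique marker
values, requiring ≥ `minprop` (0.1) of samples on each side, and
maximizes |standardized log-rank statistic|; ties break toward the lower
cutpoint, and the scan is rank-based, so the grouping is invariant under
strictly monotone marker transforms. **The reported log-rank p at the
chosen cutpoint is not corrected for maximal selection** — it is
anti-conservative under the null (asserted in the test suite) — matching
common practice; `correct="permutation"` provides a calibrated
alternative. The univariate Cox fit is Newton–Raphson on the Breslow
partial likelihood (ties pooled in one denominator; simplest tie rule,
cross-checked against an independent implementation in the tests), with
Wald p, step clipping at ±5 and a 50-iteration convergence flag.

## Pipeline (`oxmeth.pipeline`, CLI `oxmeth`)

Stages simulate → estimate → dmr → enrich → integrate → survival, each
reading only upstream files, writing atomically (temp + rename) and
recording a manifest (stage, seed, parameters, SHA-256 of inputs and
outputs, paths relative to the run directory, no timestamps). All
randomness derives from the single pipeline seed with fixed offsets;
floats are serialized with a fixed %.10g format — two runs with the same
seed are byte-identical. A missing upstream artifact raises an error
naming the stage that produces it. The default cohort (2 × 1 Mb
chromosomes, 12 samples, ~25k CpGs) runs end to end in well under a
minute on one CPU; problem sizes in the test and acceptance suites
(200-CpG power replicates, 1000-bin correlation tracks, 10⁴-site
consistency runs) were chosen to keep full validation in the minutes
range while leaving every statistical conclusion stable across seeds.

## Known limitations

- Only the BS+oxBS two-channel design is supported (no TAB-seq).
- CpG context only; no CHG/CHH estimation.
- The DMR caller has no covariate adjustment, paired testing or
  smoothing; the null calibration holds under the generator's
  independence assumptions.
- Enrichment nulls are size-matched only (no GC or gap masking on the
  synthetic genome; a BED exclusion mask is accepted for real genomes).
- The genome-wide mean 5hmC level is upward-biased at low coverage (see
  estimator section); comparisons between samples at equal depth remain
  valid.
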