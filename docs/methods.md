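# Methods

## Statistical model

Counts are modelled per feature as negative binomial with mean μ and
variance μ + αμ² (α the dispersion; α → 0 recovers Poisson). The mean is
log-linear in the two binary factors and their product,

μ_ij = s_j · q_i · 2^(βm·x_j + βf·y_j + βi·x_j·y_j),

with x (microbes: GF→0, CV→1) and y (meal: none→0, HFM→1). The interaction
coefficient βi is the log2 ratio of ratios (CV+HFM/CV)/(GF+HFM/GF), which
equals (CV+HFM/GF+HFM)/(CV/GF); its sign convention is positive when the
meal response is larger in colonized animals. Coefficients are fitted on
the natural-log scale and reported in log2.

**Size factors** are median-of-ratios: s_j = median over features of
k_ij / (geometric mean of feature i across samples), using features
positive in every sample (with a positive-entries-only fallback), rescaled
to geometric mean 1.

**Dispersion** is estimated in three steps. (1) A per-feature
method-of-moments value from within-condition residuals of normalized
counts, pooled across condition cells weighted by their degrees of freedom
and floored at 1e-8. (2) A mean-dispersion trend α(μ) = a0 + a1/μ fitted by
least squares to per-bin means of the *unfloored* per-feature values across
~20 base-mean quantile bins; averaging raw values before flooring keeps the
trend nearly unbiased despite the strong right skew (and frequent
negativity) of individual moment estimates at 3–12 residual df. (3) The
final value geometrically interpolates the floored feature estimate toward
the trend, α = mom^(1−w)·trend^w. The default weight w = 0.9 shrinks hard
toward the trend: with 2–5 replicates per cell the per-feature estimator is
far too noisy to stand alone, and under-estimated dispersions directly
inflate false-positive rates. With this default the measured null
rejection rate at p < 0.05 is ≈ 0.05–0.06 for both the Wald and the LRT
tests (the tests themselves are computed at the estimated α as in standard
NB-GLM practice; no further small-sample correction is applied).

**Fitting** is iteratively reweighted least squares with log link and fixed
α (weights μ/(1+αμ), convergence at max |Δcoef| < 1e-8 or 100 iterations,
linear predictor clipped at ±50 to survive empty-cell separation, which is
flagged as non-converged). Wald contrasts use the asymptotic normal on
c'β̂ / SE with the full coefficient covariance; the interaction LRT compares
the full fit against the additive fit at the *same* per-feature α (so the
test contrasts nested mean models only) with χ²(1), the statistic floored
at zero. Features with all-zero counts are dropped before fitting. BH
adjustment is applied within each contrast separately. There is no fold
change shrinkage and no independent filtering.

Significance tiers: standard padj < 0.05; lenient gene interaction
p < 0.05 ∧ baseMean > 10; lenient window interaction p < 0.01 ∧
baseMean > 15. All are CLI-configurable.

## Interval conventions

Coordinates are BED: 0-based, half-open. Overlap means ≥ 1 shared bp.
Distances between non-overlapping intervals are the gap in bp; bookended
intervals have distance 0 and are coalesced by merge. Window tiling of a
peak of length L uses full 300-bp windows every 200 bp plus, when the last
regular window stops short of the peak end, one extra end-anchored window
[end−300, end), so peaks are always fully covered; peaks shorter than the
window width become a single whole-peak window. (How the original
window-based analyses handled short peaks and trailing remainders is
generally unstated in the literature; this rule is declared, not inferred.)
Fragment counting is any-overlap, so a fragment spanning two overlapping
windows counts in both — peak-level inference therefore uses the minimum-p
window, never summed window counts. Nearest-gene distance is measured to
the gene body (not the TSS), matching the default of the usual
closest-feature tools; ties go to the first gene in (chrom, start, end,
name) order. Accessible-site (DHS) linkage drops assignments beyond 1 kb.

## Classification

Directional groups are the up/down splits of the four contrasts' significant
features (log2FC exactly 0 cannot be oriented and is excluded with a
warning). Integration classes operate purely on group membership:
red = CV+HFM/CV-up ∧ CV+HFM/GF+HFM-up; blue = GF+HFM/GF-up ∧
CV+HFM/GF+HFM-down; they are provably disjoint because a feature is up or
down, never both, in CV+HFM/GF+HFM. Features significant in ≥1 microbial
and ≥1 meal contrast are dual-responsive; red and blue are subsets of it.
The pairwise group overlap matrix reports raw intersection counts and a
"maximum overlap" normalization |g∩h| / min(|g|,|h|) — the normalization
choice is ours (raw counts are always written alongside) and is 0 by
convention for empty groups.

Accessibility classes partition regions by which cell types' accessible
sets they touch: pan-accessible (all), X-specific (only X), X-restricted
(X plus some but not all others, X ∈ {enterocyte, ISC}), other. A region in
both the enterocyte and ISC sets without being pan-accessible matches both
restricted patterns; the fixed precedence order (pan, then
enterocyte-restricted over ISC-restricted) makes the label deterministic
and unique.

Moving means for ordered site series are forward-looking windows of up to
500 sites advancing 1 site, truncated at the tail, NaNs excluded per
window. Two-sample distribution association uses the two-sided
Kolmogorov–Smirnov test, exact when n·m ≤ 10 000, asymptotic otherwise;
groups under 3 observations get no p value.

## Motif enrichment

PWMs are L×4 probability matrices; scanning adds a 0.001 pseudocount, forms
log2-odds against the background base frequencies, and calls a hit when a
window on either strand reaches the threshold (default 60% of the motif's
maximum achievable score). Windows containing non-ACGT bases are skipped.
Enrichment is ZOOPS (a sequence counts once however many hits it has) with
a hypergeometric upper-tail p for the number of hit-bearing input sequences
drawn from the pooled input+background, and fold = input rate / background
rate. Reciprocal-background runs test each directional group's linked
accessible-site sequences against the opposite direction of the same
contrast; a contrast is skipped when either direction has fewer than 5
linked sequences (both runs need both sets). A small built-in motif set
(two nuclear-receptor DR1-style repeats, a CRE-like palindrome, a GC-rich
control) serves testing; real analyses supply PWM files.

## Ordination

PCA uses log2(normalized count + 1), the 500 most variable features,
per-feature centering, and SVD; the transform is the common count-PCA
default (a variance-stabilizing transform would be a reasonable
alternative; the simple log keeps the pipeline dependency-light and is
what the variance-explained oracle checks). PERMANOVA is one-factor on the
Euclidean distance of that same matrix: pseudo-F from the among/within
partition of squared distances, p = (1+#{F_perm ≥ F_obs})/(1+B) with
seeded label permutations; each factor (microbes, meal) is tested in its
own one-factor run, matching how the separation statistics are usually
reported. Sequential multi-factor partitioning is out of scope. Note the
permutation p is discrete: with very small groups a random permutation can
legitimately redraw the observed partition and tie F exactly, so the
1/(B+1) floor is only reachable when the number of distinct splits is large
relative to B.

## The synthetic-data generator

The generator emulates the study design, not the sequencing process: no
reads, fragments, GC bias, or mappability — count noise enters only through
the NB sampler, and sequences are iid-base background (default GC 0.45)
with planted motif consensus occurrences. Passing tests therefore
demonstrate correctness of the statistics and algebra under the declared
model, not robustness to alignment artefacts or real chromatin covariance
structure (neighboring windows are sampled independently given their
shared effect, whereas real windows are correlated through shared
fragments).

Per feature a class is drawn (defaults: 55% null, 10% each microbe-only /
meal-only / additive, 7.5% each interaction sign) and log2 effect
magnitudes |N(2, 0.5)|. The interaction classes encode the two biological
archetypes: interaction-positive (βi > 0, βm = βf = 0 — meal response only
with microbes; the "red" truth) and interaction-negative (βi < 0 with
βf = −βi — meal response only germ-free plus microbial suppression when
fed; the "blue" truth). Base means are log-uniform on [20, 2000], the
dispersion follows α = 0.02 + 1/μ (a typical bulk-count trend shape;
magnitudes are chosen for test power since real library depths are not
part of the design), and library sizes are log-uniform on [0.7, 1.4].
Replicate defaults mirror the assays emulated: RNA 4/4/4/4, chromatin mark
2/5/2/5, TF binding 3/4/3/4. Windows inherit their parent peak's effects
with ±20% base-mean jitter. Binding-site clusters are planted inside gene
bodies so the nearest-gene truth is exact by construction; one accessible
site per peak sits at the peak center so 1-kb linkage always succeeds. All
randomness flows from one seed through deterministically derived per-stage
child streams, so identical configs give byte-identical fixtures.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
each statistical check has comfortable power: 5000 features for null
calibration, 2000 (50% null) for interaction recovery, 200 random instances
for the interval oracles, 150–200 peaks for end-to-end class recovery, 200
trials for KS/PERMANOVA calibration, 20 seeds for motif ranking. Headline
counts from deep sequencing studies (hundreds of interaction genes,
thousands of windows) are functions of library depth and replication and
are not reproduced by design.

## Known limitations

- Dispersion estimation is moments-plus-trend, not Cox–Reid adjusted
  profile likelihood; with the default heavy trend shrinkage it is
  calibrated under the generator's on-trend dispersions but will flatten
  genuine per-feature dispersion outliers.
- Wald p values use the asymptotic normal; at 2 replicates per cell they
  are mildly anti-conservative for features far off the trend.
- The nearest-gene rule is gene-body distance with first-in-sort-order
  ties; analyses that need TSS-based or multi-gene (regulatory domain)
  assignment should pre-compute their own link table.
- PERMANOVA is one factor at a time; interaction of factors at the
  distance-matrix level is not tested.
- Motif enrichment does not GC-match backgrounds; the reciprocal-direction
  background absorbs composition bias only to the extent the two direction
  groups share it.
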