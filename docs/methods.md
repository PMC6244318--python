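# Methods

This note documents the statistical models and procedures implemented in
`rfinet`, the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Phenotypes and group selection

Animals are ranked by BLUP of additive genetic merit for residual feed
intake; the `n` lowest-BLUP animals form the feed-efficient group and the
`n` highest the feed-inefficient group, with ties broken deterministically
by animal id. Group comparisons use the two-sample Student's t-test with
pooled variance (the test named in the original workflow); Welch's correction
is available behind `equal_variance=False`. Missing phenotype cells are
treated as absent, never as zeros, and are dropped pairwise with the
reported n adjusted. Degenerate inputs (both groups constant) return t = 0,
p = 1 when means agree and the smallest representable p when they differ.

## Count preprocessing

A feature is kept when it has at least one nonzero count and zeros in at
most a `max_zero_fraction` share of samples (default 1/5). The published
description of this filter, read literally, would discard exactly the
best-covered features; the only reading consistent with retaining expressed
miRNAs is "drop features with zeros in **more** than 1/5 of samples", which
is what `filter_counts` implements, with the fraction exposed as a
parameter.

Normalization uses median-of-ratios size factors: reference features are
those with strictly positive counts in every sample, and each sample's
factor is the median of its counts over the reference features' geometric
means. This is the scheme native to the NB differential-expression
framework the workflow is built around; no particular scheme is otherwise
mandated.
Network input is log2(normalized + 1); features with zero variance across
the retained samples are excluded (tolerance 1e-24 on the variance, since
exact float zeros cannot be relied on).

## Differential expression

Counts are modelled as negative binomial with Var = μ + αμ². Per-feature
dispersions are estimated by the method of moments from the pooled
within-group variance, α̂ᵢ = (s²ᵢ − μ̄ᵢ)/μ̄ᵢ², then **moderated**: each raw
estimate is shrunk 50% toward the across-feature median before flooring at
1e-8. With 4–10 samples per group the raw plug-in estimate is noisy, and
because an underestimated dispersion inflates the Wald statistic, the
unmoderated test is measurably anti-conservative (type-I ≈ 0.068 at
p < 0.05 with n = 10/group, α = 0.1); moderation brings it to ≈ 0.055–0.061
while leaving the across-feature median — and hence unbiasedness at scale —
untouched. This mirrors the dispersion information sharing of the DESeq
family. `moderate=0` disables it.

The contrast is a Wald test of log₂((μ̂_eff + c)/(μ̂_ineff + c)) with
pseudocount c = 0.5 guarding all-zero groups, delta-method standard error
from Var(μ̂_g) = (μ̂_g + α̂μ̂_g²)/n_g, normal reference distribution, and
Benjamini–Hochberg step-up adjustment (own implementation, verified against
statsmodels). The feed-efficient group is always the numerator, so negative
log2FC means lower expression in efficient animals. By default the test
runs on the extreme 4-vs-4 BLUP subset, matching the study design of
sharpening the contrast at the cost of power; the subset size is
configurable. Calibration is validated by simulation (type-I error within
[0.03, 0.07] at p < 0.05; sensitivity ≥ 90% at q < 0.10 for planted
log2FC = 2 at mean 500), not by numeric identity to any published table —
the published per-miRNA values depend on the deposited count data.

## Target prediction

Seed sites follow the canonical definitions on the UTR read 5′→3′: the
6mer core is the reverse complement of miRNA positions 2–7; a position-8
complement immediately 5′ of the core upgrades to 7mer-m8; an A immediately
3′ upgrades to 7mer-A1; both give an 8mer. Every core occurrence is
reported once, at its most specific class.

The complementarity alignment is a Gotoh affine-gap local alignment of the
miRNA (3′→5′) against the UTR (5′→3′), scoring Watson–Crick pairs +5, G:U
wobbles +2, mismatches −3, gap open −8, gap extend −2, with pair scores at
miRNA positions 2–8 doubled and a report threshold of 80 (a 22-nt perfect
duplex scores 145). The scoring scheme is this package's own definition —
the study names the tool it used, not its internals — and every parameter
is configurable. All non-overlapping local optima at or above the threshold
are reported, found greedily from the highest-scoring cell. The inner loop
is JIT-compiled with numba.

A gene is a predicted target when it carries at least one seed site AND at
least one alignment hit AND is in the expressed-gene universe
(`mode="intersection"`, the conservative reading of using both tools
jointly; `"union"` preserves the alternative reading). In intersection mode
alignments are only computed for pairs that already have a seed site, which
cannot change the result. Cross-species conservation filtering is out of
scope: it needs multi-species alignments that are neither shipped nor
simulated.

## Co-expression networks

Construction follows WGCNA: Pearson correlation between log-expression
profiles; unsigned soft-threshold adjacency a = |r|^β with β = 6 (the
power used for both data types in the source analysis; `pick_soft_threshold`
implements the scale-free criterion — smallest power whose signed fit
−sign(slope)·R² over 10 connectivity bins reaches 0.90 — for users who want
to re-derive it); TOM similarity
TOMᵢⱼ = (Σᵤ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ); and average-linkage
(UPGMA) clustering of 1 − TOM via scipy.

**Module detection.** The default (`detection="hybrid"`) is a staged
procedure: (1) module *cores* are collected from static cuts at a ladder of
conservative merge-height quantiles (0.1–0.5), claiming each cluster of at
least max(5, min_size/4) mostly-unclaimed features — different modules
finish agglomerating at different heights, so no single cut height captures
all of them; (2) every feature is then iteratively (re)assigned to the
module with its highest **signed** module membership kME, requiring
kME ≥ 0.8, for three rounds (after eigengene orientation true members
correlate positively, so the signed rule halves chance background
recruitment relative to |kME|); (3) modules closer than the merge height
are merged; (4) modules below the minimum size (5 for miRNA, 30 for mRNA)
are dissolved to grey. This plays the role the dynamic hybrid tree cut +
PAM stage plays in the reference implementation. A plain single static
quantile cut is available (`detection="static"`, default quantile 0.99) and
is what `cut_tree_to_modules` itself implements, but on data with modules
embedded in a background it either over-merges or fragments — with 10
samples per group it plateaus around ARI ≈ 0.6 on planted structure at any
quantile — which is why it is not the default.

Eigengenes are the first right singular vector of the z-scored member
matrix (unit norm), oriented so the mean member correlation is nonnegative;
variance explained is σ₁²/Σσ². Merging iterates on the closest eigengene
pair with dissimilarity 1 − cor below 0.25 (the retained default), the
merged module keeping the larger member's label, until a fixed point.
Modules are named by decreasing size along the conventional color sequence
(turquoise, blue, brown, ...); grey is reserved for unassigned features.
With fewer than 15 samples a warning reminds the user that correlation
estimates at this n carry standard errors around 0.3.

## Integration

Module–trait association is the Pearson correlation of each eigengene with
RFI across the group's samples, p from the t transform
t = r√(n−2)/√(1−r²), selection at p < 0.10 (the workflow's exploratory
threshold; configurable). Cross-omics coupling is the full bipartite
miRNA-ME × mRNA-ME correlation table with selection requiring strictly
negative r and p < 0.10 — the canonical repressive direction. Hubs are the
top-5 module members by signed kME toward their own eigengene ("greatest
MM" is read as largest signed value, since orientation makes memberships
predominantly positive; absolute-value ranking is a flag), ties broken by
feature id. For each selected pair, the overlap is the union of the miRNA
module's hub targets intersected with the mRNA module's member genes.

## Over-representation analysis

Exact hypergeometric upper tail P(X ≥ k) with N = universe, K = set within
universe, n = query, k = overlap; BH across tested sets; sets with fewer
than two members in the universe are skipped. The universe is a parameter:
the pipeline uses the expressed genes of the tissue for DE-target
enrichment and the module-assigned genes for module-overlap enrichment —
the appropriate backgrounds for "which expressed genes are targeted" and
"which module genes are enriched" respectively.

## Synthetic data

The generator emulates the study's data shape at desk scale: two groups of
10 animals; ~150 miRNAs with 4 planted modules of 8–16 members; a reduced
mRNA transcriptome (default 1,000 genes; the real tissues express
16,000–18,000) with 6 planted modules of 30–60 genes; NB counts at
dispersion 0.1 with baseline means log-uniform on [50, 1000].

Each module has a latent Gaussian sample signal; member log2-means are
baseline + loading × latent, with the loading calibrated per feature (by a
short internal Monte-Carlo against the realised NB log-scale noise, since
the delta-method variance underestimates it by ~15%) so that the observed
pairwise correlation of member log-expression matches `within_module_cor`
(default 0.8). Hubs — the first two members of each miRNA module — use a
tighter tie (0.95) so their kME ranks highest. Each miRNA module's latent
is coupled to the same-index mRNA module's latent at `coupling_strength`
(default −0.8), encoding hub-miRNA repression at module level. Each hub
regulates five genes of its coupled mRNA module; those genes' UTRs carry a
planted full-complement site (reverse complement of miRNA positions 2..L
followed by A — containing an exact 8mer and supporting a high-scoring
alignment, as a strong site with 3′-supplementary pairing would), while
background genes receive a seed-only decoy at rate 0.05. RFI is a weighted
sum of designated module latents (default: miRNA module 1, effect 1.0)
plus N(0, 0.5) noise; BLUP is a noisier index of the same signal
(correlation with RFI ≈ 0.6), and groups are the BLUP tails, mirroring the
divergent-selection design. Planted DE miRNAs (default 5, log2FC −1, i.e.
down in efficient animals, as in the study) are background miRNAs with a
group shift. All outputs are pure functions of (config, seed); gene sets
are one set per planted mRNA module plus 20 random decoy sets.

What the generator does **not** emulate: batch and library-size structure
beyond size factors, count outliers and heavy-tailed dispersion, correlated
background genes, isoform structure, UTR base composition, conservation,
and any read-level artifacts. Passing recovery tests therefore demonstrate
that the pipeline's logic is correct and well-calibrated under its own
model assumptions — not that the biological conclusions of any particular
dataset would be recovered.

## Problem sizes and numerical choices

Tests and the acceptance script use the desk-scale defaults above
(networks of 150 miRNAs / 1,000 genes on 10 samples, DE calibration with
2,000 features, 5–10 simulation seeds); the whole suite runs in well under
a minute of compute. Tolerances: symmetric matrices enforced at 1e-10;
zero-variance detection at std < 1e-12 (float cancellation makes exact
zeros unreliable); dispersion floor 1e-8; p-values clipped to the smallest
positive float rather than zero. Tie-breaks are deterministic everywhere
(stable sorts, id-ordered), so identical inputs give byte-identical
outputs.

## Known limitations

At n = 10 samples the null distribution of Pearson correlations has
standard deviation ≈ 1/3, so background features can genuinely correlate
with a module latent in-sample; module boundaries and eigengene-based
selections at this n are irreducibly noisy, and occasionally two planted
modules' latents collide (|r| > 0.7 in-sample) and merge. The NB Wald test
remains slightly anti-conservative even after moderation. The alignment
reports greedy non-overlapping local optima, which can differ from the
exhaustive suboptimal-alignment enumeration for heavily self-overlapping
hits. The ORA treats genes as exchangeable (no length or composition bias
correction).
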