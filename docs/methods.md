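# Methods

This note records the models, parameter choices, and numerical decisions
behind `phytoarray`, and what the synthetic-data experiments do and do not
demonstrate about real array data.

## Preprocessing

Probe intensities are floored at 1 and log2-transformed. Probes of a
target are combined by Tukey median polish (an additive probe + array
fit); the summarized level per array is the overall constant plus that
array's column effect, which is robust to a minority of misbehaving
probes. Median polish is order-dependent when a median is a midpoint
(even extents); with the usual 2–4 probes per target the fit is treated
as a robust summary, not a unique estimator. Single-probe targets pass
through as plain log2. Missing probes are excluded from the fit rather
than imputed.

Quantile normalization then maps every array's values onto the mean of
the order statistics across arrays; ties within an array receive the mean
of the reference values their block spans, so the map is well defined and
idempotent on identical columns. Normalization runs at the target level
by default; `normalize_level: probe` applies it to probe-level log2
intensities before summarization (the RMA convention) for users who want
that order. No background subtraction is applied before the log
transform.

Detection calling uses the negative-control probes of each sample, which
travel through the same summarization and normalization: a cell is
detected iff its value strictly exceeds the control mean plus
`detection_k` (default 2) control standard deviations. The exact
detection rule used by array-vendor pipelines is generally unpublished;
this k·SD rule is the package's documented stand-in and is exposed in the
configuration, including a `fixed_threshold` escape hatch for designs
without negative controls.

## Community summaries

Strain presence follows a count rule: ≥ 5 detected targets, or ≥ ⌈n/2⌉
for strains with n < 5 targets ("at least half" is read strictly, so 2 of
3). Transcript sums use linear-scale values of detected cells only;
undetected cells are background and contribute zero. The per-strain
abundance score divides a strain's share of a sample's detected
transcripts by its number of array targets and scales by 1e5, removing
the bias toward strains with more probes. Phylogroup proportions are
per-sample shares (summing to 1) averaged over replicates; whether such
sums should be linear or log2 is a genuine ambiguity and linear is the
documented choice.

## Threshold differential expression

For contrast case-vs-reference, per-gene variances are pooled across the
two groups and shrunk toward a prior fitted across genes by moment
matching on log variances (digamma/trigamma inversion); the moderated
variance has `d0 + d_resid` degrees of freedom. The test statistic
`(|log2FC| − log2 τ)/SE`, τ = 1.2, is referred one-sided to that t
distribution — a threshold test whose null includes all fold changes up
to τ, so `log2FC = 0` gives p ≥ 0.5 and the boundary gives exactly 0.5.
With moderation disabled the test reduces to a plain pooled-variance
two-sample threshold t test (verified against an independent oracle).
Genes undetected in every sample of a contrast are excluded from the test
and from the BH family; BH runs per contrast, since contrasts are
reported separately. With zero replicate variance (degenerate synthetic
input) the p-value is decided by the sign of `|FC| − τ`.

Calibration at the boundary (2,000 genes at |FC| = 1.2, σ = 0.25, 3 vs 3)
rejects at ~5.5% for nominal 5%; power at |log2FC| = 1 under the same
noise is ≥ 90%.

## Ensemble gene-set testing and calibration

Sets are built from the annotation alone: one per (scope, response
label), scope being a phylogroup or a single strain. The four base
statistics are two-sided — |rank-sum deviation|, |mean member t − overall
mean|, a two-sided hypergeometric p on the DE × membership 2×2 table, and
the KS distance between member and non-member t's. The response
*direction* is reported separately as the sign of the set's average fold
change, which is how the up/down calls are drawn.

The four statistics are computed from the same genes and are strongly
dependent, so combining their p-values with Wilkinson's Beta formula
alone would not be calibrated. The implementation therefore uses the
membership permutations (default 10,000 shared draws) as a joint null
reference: each method's p is its permutation tail probability, the
Wilkinson order statistic of those p's is the consensus score, and the
reported combined p is the score's own permutation tail probability
(observed pooled with the permutations, so the floor is 1/(n_perm+1)).
Under a zero-effect simulation the combined p is uniform (KS-checked).
A base method with no information is dropped from the combination for
that set: the hypergeometric when the DE margin is empty or full, and all
rank-based methods degenerate to p = 1 when every score ties. The
Wilkinson order r defaults to 2 ("at least two methods agree") and is
configurable, as is the battery size.

`a_g` and `a_tot` are geometric means: `2^(mean member log2FC)` and
`2^(mean log2FC over all detected targets of the phylogroup)` — the
averaging scale is unstated in the field and geometric is the choice
consistent with log2 analysis; `a_tot` averages detected targets only.
The artifact filter retains an up-call only when `a_g/a_tot > 1` and a
down-call only when `< 1`; filtered sets remain in the output with
`retained = False`. Thick-arrow magnitude means `a_g > 1.2` (up) or
`< 1/1.2` (down). BH runs across all (set, contrast) combined p-values at
α = 0.01.

Because the base tests are competitive, a uniform phylogroup-wide shift
(pure abundance change) leaves members exchangeable with non-members and
produces no signal; the a_g/a_tot filter is the second line of defense
for any chance call. Conversely, a competitive test can legitimately flag
an *unshifted* set inside a phylogroup whose other sets moved (relative
depletion); calibration statements about "null sets" are therefore made
under zero-effect simulations.

## Co-expression modules

Genes detected in ≥ 75% of T24 samples enter the network (correlation
stability; configurable). The soft power is the smallest β in 1..20 whose
binned log-log connectivity fit reaches R² ≥ 0.8 with negative slope,
falling back to the best fit with a warning. TOM follows
`(Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with unit diagonal.
Modules come from average-linkage clustering of 1 − TOM with a *static*
cut — deliberately simpler than dynamic tree cutting — at a configurable
fraction of the maximum merge height; clusters below `min_module_size`
(10) are unassigned. The default fraction 0.92 was set by scanning block
fixtures (three r = 0.9 blocks of 15 genes; the default community
fixture) where 0.90–0.94 keeps implanted blocks intact while shedding
chance-correlated noise genes; much lower cuts produce no modules at all
because TOM dissimilarities concentrate near 1 at realistic soft powers.
Eigengenes are the first right singular vector of the standardized member
submatrix, unit-norm, sign-fixed positive against the module mean
profile.

## Ordination

Distances are Euclidean over log2 levels of targets detected in at least
one sample; undetected cells enter at their normalized background values
rather than being masked, since the distance universe is defined by
detection anywhere, not per sample. NMDS alternates isotonic regression
of embedded distances on the dissimilarity rank order (primary tie
handling: ties broken by current embedded distance, hence unconstrained
within blocks) with a Guttman/SMACOF majorization step; disparities are
rescaled to the embedded sum of squares each iteration and stress-1 is
reported. Iteration stops when stress improves by < 1e-6 or at 500
iterations; the best of 20 seeded random starts plus one
classical-scaling start wins. Group summaries are medians over all
(treatment sample, reference sample) pairs, excluding zero self-pairs
within the reference.

## Synthetic communities

The generator draws a design of `n_phylogroups × strains_per_group`
strains with 10–16 targets each (2–4 probes per target, ≥ 32 negative
controls) and simulates `log2 intensity = μ_i + δ_{i,t} + a_j + ε` with
target baselines μ ~ N(10, 1.5²), probe affinities a ~ N(0, 0.3²), and
residual noise σ = 0.25 on the log2 scale (lognormal linear intensities).
Cells of absent strains and cells whose expected level falls below the
background floor are replaced by background draws N(4, 0.5²) —
censored-at-background, so detection truth is binary and recorded. The
floor sits ~6 log2 units (64×) below typical signal, the separation real
arrays show between background and hybridized spots; absence is a
community property (10% of strains, drawn once per simulation) because
replicate bottles share one water mass, with an optional per-sample
dropout knob (default 0) for compositional variability. The replicate
plan is 7 conditions × 3 plus a T0 control, with 2 replicates for NH4
(23 arrays).

The default implanted-response table mirrors the qualitative pattern of a
late-summer N-limited community: HL *Prochlorococcus* N stress down and
RuBisCO up after NH4/urea, photosynthetic-eukaryote RuBisCO up most
strongly after NO3, *Synechococcus* RuBisCO up across N additions,
picocyanobacterial *urtA* up across strains in deep water (a correlated
cross-strain block exercising module recovery), and one pure abundance
shift (all *Pelagibacter* targets up equally under Fe) exercising the
artifact filter. No field study reports effect magnitudes at this
resolution; the defaults of 0.6–1.0 log2 are documented placeholders.
Gene-level effects override set-level effects for their targets.

What passing recovery tests shows — and does not. The generator captures
the analysis-relevant structure: multi-probe targets, lognormal noise, a
detection floor, closed-sum normalization artifacts (quantile
normalization visibly compresses implanted effects in all-up contrasts,
which is exactly the artifact the a_g/a_tot filter addresses), small and
unbalanced replicate groups. It does not simulate sequence-level
cross-hybridization, dye or spatial artifacts, amplification bias, or
community dynamics, so recovery rates here bound what the pipeline can do
under its own model assumptions, not under every failure mode of real
hybridization data.

## Problem sizes and runtime

Desk-scale defaults keep everything in minutes on one CPU: the default
community is 40 strains / ~530 targets / ~1,600 probes / 23 arrays;
calibration studies use a compact 3-phylogroup × 6-strain design, 20
replicate simulations for the null false-positive study, 200 member sets
for the uniformity study, and 2,000–10,000 membership permutations
depending on the precision the downstream threshold requires. These sizes
are the package's chosen defaults for its own validation suite;
full-scale deposited series (hundreds of strains, ~10⁴ detected genes)
run through the same code paths via the series-matrix reader.
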