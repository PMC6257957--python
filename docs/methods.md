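# Methods

This note documents the models and numerical choices behind each stage of
the pipeline, the design of the synthetic data, and the limits of what
passing tests establish.

## Synthetic data model

The generator produces intrachromosomal binned contact maps for two
conditions on a desk-scale genome (default 2 chromosomes × 30 Mb; 600
bins at the 100-kb analysis resolution). The expected count for bin pair
(i, j) at separation d bins is

    mu_ij ∝ (d + 1)^(−α) · κ^[same compartment] · τ^[same TAD] · b_i b_j
            · δ^[constricted ∧ both B ∧ separation < 1 Mb]

normalized so the upper-triangle sum equals the requested read total, with
independent Poisson counts (optionally a single multinomial draw when an
exactly conserved total is wanted). Defaults: α = 1 (the canonical Hi-C
decay exponent at sub-10-Mb separations), κ = 1.5, τ = 1.8, δ = 0.6,
log-normal bias with σ = 0.3, and 3 × 10⁶ reads per condition (2.8 × 10⁶
for the constricted library, so depth matching by hypergeometric
downsampling is exercised). These depths are the desk-scale analog of a
pooled sequencing experiment: large enough that compartment and TAD
recovery are reliable, small enough that every stage runs in seconds.

Compartments are alternating A/B blocks with uniform random lengths of
5–15 bins (0.5–1.5 Mb). TAD boundaries combine uniform random domain
lengths (8–24 bins of 50 kb) with every compartment block edge: in real
genomes compartment transitions coincide with domain boundaries, and the
κ checkerboard makes block edges genuine contact discontinuities, so
leaving them out of the planted boundary set would misrepresent the
map's true structure.

The constricted condition derives from the baseline by three
perturbations. (1) 5% of 100-kb bins flip compartment, 90% of them drawn
from B — concentrated but not exclusive, mirroring the observation that
both compartments switch, B far more often; an all-B perturbation would
also make the downstream logistic regression separable and its Wald
test meaningless. (2) 20% of TAD boundaries are deleted, 90% drawn from
B-flanked boundaries. (3) B–B contacts closer than 1 Mb are scaled by
δ = 0.6 before normalization, so the perturbation changes contact
composition at fixed sequencing depth; δ has no measured counterpart and
was chosen once for detectability at desk depth.

Genes (default 15,000) are placed inside single 100-kb bins. Each bin is
assigned a transcriptional-activity flag (probability 0.9 in A, 0.4 in
B); expressed genes exist only in active bins, and every active bin with
genes holds at least one, so "contains an expressed gene" reproduces the
planted activity exactly. Differential-expression tables plant three gene
sets (defaults 420/1443/199) whose log2 fold changes across the two
migration contrasts are bivariate normal with correlations 0.92/0.82/0.32;
FDR columns are planted strictly below/above the 0.05 threshold so the
set classifier recovers membership by construction, leaving the R²
recovery as the statistical check.

## Matrix processing

**ICE balancing** iterates b_i ← b_i · m_i / mean(m) on the balanced
marginals m until their coefficient of variation drops below 1e-5 (max
200 iterations), after masking bins with zero (or below a configurable
floor) raw marginal. Balanced values are count/(b_i b_j). Non-convergence
is flagged, never raised; an all-zero chromosome is fully masked.

**Depth matching** thins every map to the minimum total by a single
multivariate-hypergeometric draw over the concatenated entries — exact
totals, no created counts.

**Distance decay** uses log-spaced strata (factor √2) from one bin to the
chromosome length; stratum means are per-chromosome over all unmasked
pairs (zeros included), then averaged across chromosomes. The KS
comparison between conditions weights each pairwise separation by its
balanced frequency, realized as a deterministic 10⁵-point weighted
quantile expansion (accurate to 2 × 10⁻⁵ in CDF) fed to the standard
two-sample test. What distributions entered the original analysis is not
derivable from the test statistic alone; this weighted-separation reading
is recorded in the result's method string.

## Compartments

PC1 comes from an SVD of the column-centered Pearson correlation matrix
of the per-chromosome O/E map; the sign is fixed so PC1 correlates
non-negatively with the activity track, with an ambiguity flag below
|r| = 0.1 and a degeneracy flag for (near-)tied leading singular values.
Chromosomes whose PC1 tracks the chromosome arms (|correlation| > 0.7
with a ±1 arm indicator around a supplied centromere) are excluded from
switching analysis automatically rather than via a hard-coded list.

Switching requires both an opposite PC1 sign and a per-bin
interaction-pattern correlation (rows of the two correlation matrices,
diagonal excluded) strictly below 0.6. Bins meeting exactly one criterion
are conservatively labeled stable and counted separately
(`attrs["partial"]`). Stability percentages are reported against two
denominators (unmasked bins of the source compartment; all bins) because
the choice is not fixed a priori.

The compartment bias of switching is tested twice: logistic regression of
switched on source compartment (Wald p; separation detected and flagged,
with a regularized fallback) and a 10,000-rep bootstrap of per-compartment
switch rates with percentile CIs — the bootstrap is authoritative when
the regression is separable.

## TADs

The boundary signal is the mean balanced frequency in the w × w diamond
straddling each bin (w = 5 at 50 kb), truncated at chromosome ends.
Candidate boundaries are strict local minima of the signal after local
linear detrending over ±w bins. Every interior bin is scored by a
one-sided Mann–Whitney test of its diamond entries against the flanking
within-domain entries, computed on distance-normalized (O/E) values —
on raw values the diamond's larger separations make the test wildly
anticonservative under pure decay. BH correction runs across **all**
scored bins genome-wide, not only the minima, so minimum-selection cannot
shrink the correction family; boundaries are minima with adjusted
p < 0.05. On flat-noise matrices at study scale this retains no boundary
in ≥ 95% of simulations while recovering planted boundaries at ≥ 0.9
recall / ≥ 0.8 precision (±1 bin).

Conservation uses reciprocal overlap with the **larger** domain as
denominator, boundary inclusive at the 0.8 threshold. Boundaries whose
two flanks both fall in the lowest coverage decile carry a power-loss
flag, since apparent boundary loss can reflect depth rather than
structure. The within/between contact summary is reported
distance-stratified as well as overall, because raw within-vs-between
means are confounded by decay (within pairs are shorter-range); the
stratified ratio is the one that recovers τ.

## Contacts

Window counts place 100-kb windows every 40 kb (fully contained source
bins of the 20-kb base map). The background for significance is
E_ij = T·p(d)·c_i·c_j/Z — genome-wide lattice decay profile times window
coverage shares, normalized to the map total. Pairs more than 100 kb
apart with observed > expected get Poisson upper-tail p-values, BH across
all tested pairs; calls are de-duplicated by non-maximum suppression on
the lattice (of two calls with both anchors within 100 kb, the more
significant survives).

Two design points deserve emphasis:

- **The contact universe is selected on pooled counts** (sum of the two
  conditions), not on one condition. The differential test conditions on
  a + b; when selection depends only on a + b, the null split a | a + b
  remains exactly Binomial, so pooling eliminates the winner's-curse bias
  that a single-condition universe injects into differential calls
  (selected upward fluctuations regress to the mean and masquerade as
  losses). A baseline-only universe remains available via configuration.
- **The binomial null is the decay-profile share** q = p_a(d)/(p_a+p_b)
  rather than 1/2. Depleting one stratum at fixed depth necessarily
  inflates all others in relative terms; normalizing each condition by
  its own distance profile absorbs that compositional shift (long-range
  calls stay balanced under a planted short-range-only depletion), while
  per-bin coverage biases, shared between conditions, cancel in the
  paired counts without modeling. When the profiles agree q = 1/2 and
  the textbook test is recovered. The reported logFC is the raw count
  ratio log2((a+0.5)/(b+0.5)); `logfc_norm` subtracts the null share and
  determines direction.

Range tests are Yates-corrected chi-squared of decreased vs increased
counts against 50:50 within each range class. The bootstrap enrichment
table resamples, per distance bin (uneven default edges 0.1–0.25–0.5–1–
2–5–10 Mb), disrupted-set-sized draws with replacement from the
significant-contact pool; resampling a binary compartment label with
replacement is realized as the mathematically identical binomial draw.
The resample size per bin equals the disrupted count in that bin; CIs are
percentile at 99%. Activity differences (disrupted vs total, per
compartment and range class; a contact is active when either anchor's bin
holds an expressed gene) use the continuity-corrected two-sample
proportion test with a Wald ± continuity CI for the difference —
hand-rolled because statsmodels does not expose the continuity-corrected
form, and oracle-checked against hand calculations. Because the disrupted
set is a subset of the total pool, this test is mildly conservative.

## Expression

Set classification follows the three-contrast significance pattern:
set1 = significant in both migration-vs-control contrasts; set3 =
significant in the constricted-vs-control **and** constricted-vs-baseline
contrasts, taking precedence over set1 when both match; set2 =
significant only vs control. Because the published set boundaries are not
fully specified by any single rule, the classifier also emits all seven
Venn regions and the set1/set3 overlap count, so any alternative
partition can be reconstructed from the output. Per-set R² is the
ordinary-least-squares R² (symmetric in the two fold-change axes).
The expression-vs-switching test is a one-way ANOVA (Tukey-adjusted) of
constriction-contrast logFC across bin switch-status categories, with
sub-2-gene categories dropped with a warning.

## Pipeline and reproducibility

A single global seed fans out to every stochastic stage through fixed
per-stage spawn keys (an append-only table), so adding a stage never
reshuffles downstream randomness, and rerunning a stage prefix reproduces
it bit for bit — the CLI subcommands exploit this by recomputing cheap
prefixes rather than passing state through files. Summary JSON is written
with sorted keys; two runs with the same config and seed are
byte-identical.

## Scope and limitations

Passing the test suite establishes that each method recovers the planted
generative structure under Poisson noise at desk-scale depth. It does not
establish performance on real Hi-C: the simulator has no ligation
artifacts, no interchromosomal contacts, no restriction-fragment
structure, no replicate variability, Poisson rather than overdispersed
counts (a deliberate choice that keeps closed-form oracles exact), sharp
rather than graded compartment boundaries, and a gene model without
overlapping isoforms. The KS reading of the decay comparison and the
exact bootstrap resample-size convention are interpretation choices
recorded in output metadata. Thresholds (R = 0.6, 80% reciprocal overlap,
FDR 0.05/0.1, 1 Mb range cut, w = 5, 10,000 bootstraps, 99% CI) are the
analysis's fixed operating points, exposed in `RunConfig` but not tuned.
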