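# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
package's known limitations.

## Coordinates and formats

All intervals are 0-based half-open internally (BED-native); 1-based
closed coordinates, the convention of printed genome-browser ranges, are
converted only at the boundary (`closed1_to_halfopen0`), so a printed
range `start–end` has length `end − start + 1`. Chromosome names are
matched literally and case-sensitively; a `strip_chr` normalizer is
available for mixed inputs. Genome builds are opaque labels — no liftover.
Duplicate Hi-C triplets are summed on read (matrix dumpers disagree about
mirrored records; summing is lossless). Strand is carried for genes only;
ATAC peaks are unstranded.

## Synthetic study

The generator emulates a donor-paired drug-perturbation design: 6 donors ×
{NS, NT, TNFi, JAKi1–3} × {24 h, 7 d} on a toy genome (2 × 10 Mb, 300
genes, 1,500 candidate elements, 5 kb Hi-C bins). Key structure:

* **Genome and truth.** TSSs are uniform (inside a 200 kb edge margin).
  Every gene gets one *anchored* active enhancer 10–30 kb away; the
  remaining elements are background peaks placed so ~60% of all elements
  lie within 100 kb of a TSS. Elements are disjoint and avoid Hi-C bins
  containing TSSs. The planted regulatory truth is *dense*: every
  (active enhancer, gene) pair within 100 kb is a true link, and all true
  links receive Hi-C loops. This is the regime in which an
  activity-by-contact criterion is the right decoder — active, looped
  elements regulate their spatial neighborhood — and it makes planted-link
  recovery a sharp test: non-enhancer elements have ~50-fold lower
  activity and must never be called, enhancers of distant genes must fall
  below the per-gene score threshold.
* **Counts.** Negative binomial with fixed dispersion 0.1
  (variance μ + 0.1 μ²) for all modalities; no per-feature dispersion.
  log2 expected ATAC count = baseline + stimulation opening (+2, on the
  600 responsive elements) + drug closing (−1, on each drug's closed set,
  applied at 24 h and persisting at 7 d) + a per-(feature, donor) Gaussian
  intercept (sd 0.3). H3K27ac has one profile per condition (no donor
  axis), mirroring designs where the histone mark comes from a separate
  reference experiment. Anchored enhancers have 25-fold higher ATAC and
  200-fold higher H3K27ac baselines than background peaks — the activity
  contrast that separates marked enhancers from mere open chromatin.
* **Drug-closing classes.** Of the responsive elements, disjoint sets
  close under the TNFi only, under all three JAKis, or under all four
  drugs; a handful of "decoupled" genes are repressed by the TNFi while
  their enhancer stays open, exercising direction-consistency logic.
* **Expression.** Eight modules with condition profiles orthogonalized
  against the constant, the stimulation axis and each other (the first is
  a designed TNFi-preferential repression contrast); genes load
  positively on their module's profile (amplitude 1.0) and inherit a
  drug's effect when their anchored enhancer is closed by it. A global
  activation signature (+2.5 log2 × gene weight) is carried by 60% of
  genes: depth normalization removes any shift common to *all* genes, so
  the activation program must be heterogeneous to be visible in
  normalized data, and its total variance is kept above any single
  module's so the first principal component is the activation axis — the
  dominant structure such designs show in practice. Orthogonalized
  profiles keep between-module correlations at noise level, so module
  recovery measures the network pipeline rather than luck in profile
  collisions.
* **Hi-C.** Expected count c₀·(d + d₀)^(−γ) with d₀ = bin size (finite at
  d = 0), γ = 1, Poisson noise, loops boosted 8-fold; emitted sparsely up
  to 1 Mb. c₀ = 2×10⁵ gives ~20 counts in adjacent bins.
* **GWAS panel.** 120 variants in 30 LD blocks of 4 (within-block r² ~
  U(0.9, 1), cross-block 0): 15 blocks anchored inside drug-closed active
  enhancers (the causal variants), 10 inside background open chromatin,
  5 outside any element. The three classes make the two regression
  annotations ("drug_closed", "all_elements") separable on the panel —
  with fewer background-element blocks the coefficients are barely
  identified. Per-study χ² = z², z ~ N(0, √(1 + N Σ_c τ_c ℓ(j,c))) with
  N = 50,000, τ_drug_closed = 10⁻⁵, τ_all = 2×10⁻⁶ and LD scores computed
  on the same panel. With `causal_in_enhancers=False` the panel is placed
  fully uniformly — independent of the element landscape — which is the
  exchangeability null of the rotation enrichment test.

What the generator does **not** emulate: realistic LD (blocks are ideal
and rectangular), genome-scale peak/gene counts, per-feature dispersions,
batch or library-composition effects, trans contacts, allelic effects, or
real effect-size distributions. Tests passing on this data show the
algorithms decode their own generative assumptions correctly — not that
those assumptions hold in any real tissue.

## Differential analysis

With exactly one sample per donor per arm, a donor-random-intercept model
is exactly equivalent to the paired t test on per-donor log-CPM
differences; that test is used (statistic with n_donors − 1 df, here 5).
log-CPM = log2((count + 0.5)/library × 10⁶). Zero-variance difference
vectors get p = 1 by convention. Benjamini–Hochberg correction is applied
within each contrast (each contrast is its own figure-level family).
Donors missing an arm are dropped with a warning; fewer than 3 complete
donors refuses the contrast. The paired design cancels donor intercepts
exactly, and the test is calibrated on null data (measured 4.4–4.8% of
features at p < 0.05). Known limitation: with 5 df and count-level noise
floored by dispersion 0.1, per-feature power after FDR correction is
modest for 2-fold effects — a full mixed/moderated model (e.g.
empirical-Bayes variance pooling) would be the upgrade path, and the
module boundary permits swapping one in.

## Co-expression modules

Unsigned adjacency |cor|^β with β = 6, the conventional default for
unsigned networks. A scale-free power picker is available
(`power="auto"`): the smallest β in 1..20 whose connectivity distribution
reaches a signed scale-free fit index ≥ 0.8 (R² of log p(k) vs log k,
negated when the slope is positive), else the argmax. The picker is not
the default because on data with several comparably sized modules the
connectivity distribution is narrow and the criterion is unstable —
neighboring seeds can flip it between extreme powers.
Topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij), TOM_ii = 1. Average-linkage clustering of 1 − TOM with a *static*
cut: the tree is cut at `cut_height_quantile × max merge height`
(default 0.99). The cut is deliberately a fraction of the maximum height
rather than an empirical quantile of the height distribution: with
well-separated modules the between-module merge heights concentrate within
~10⁻³ of the dissimilarity ceiling, so an empirical 0.99-quantile lands
*inside* that block and splits an arbitrary subset of modules, whereas a
fraction of the maximum reliably undercuts all of them. Clusters below
`min_module_size` (30) go to module 0. Eigengene = first right singular
vector of the standardized module expression, sign-aligned with the module
mean profile. Genes are processed in sorted-id order, making the partition
independent of input order. Module–treatment coefficients reuse the paired
donor contrast on eigengenes; module enrichment in gene sets is a two-sided
Fisher exact test over the analyzed universe with a Bonferroni line at
0.05 / modules tested (infinite odds ratios are capped at 10⁶).

## ABC enhancer–gene map

Activity = geometric mean of ATAC CPM (averaged over a condition's
samples) and the condition's H3K27ac CPM; `use_h3k27ac=False` falls back
to ATAC alone. Contact = observed count between element and TSS bins plus
a pseudocount equal to the fitted power-law value at 1 Mb (configurable
fraction); same-bin pairs use the fitted value at one bin size; trans
pairs are zero. The decay is fitted by least squares on log mean count vs
log distance over 10–1 Mb, with absent pairs counted as zeros. Candidate
set = elements with midpoint within 5 Mb of the TSS on the same
chromosome; scores are normalized within the candidate set (so they sum to
one per gene) and pairs ≥ 0.02 are called. An element overlapping the TSS
± 500 bp is treated as the gene's promoter: it stays in the denominator
but is never reported as an enhancer pair. Genes with zero-activity
candidates get all-zero scores without error. The Hi-C matrix is used as
supplied — no matrix balancing is performed; real-data users should
provide pre-normalized contacts. The 5 Mb window / 0.02 threshold /
combined-activity defaults follow the standard published defaults of the
activity-by-contact method and are config-exposed.

## Risk-variant overlap and enrichment

LD expansion annotates each top variant with all panel variants at
r² > 0.8 (itself included at r² = 1; absent-from-panel variants keep only
themselves, with a warning). Locus pruning is greedy and p-ordered (the
clumping convention): the best remaining variant leads a locus and
absorbs everything at r² > 0.1 to it; ties break by chromosome then
position; the output partitions the input. Overlap is at single-base
resolution against half-open enhancer intervals; loci whose lead sits in
the configured MHC interval are dropped first (the interval is a config
value, not hard-coded, because it is build-dependent).

Enrichment uses a circular-rotation null: each condition's called-enhancer
set is rotated within each chromosome by a uniform offset, preserving
enhancer number, lengths and spacing — properties a matched-set sampler
would not preserve. Empirical p = (1 + #{rotations ≥ observed})/(1 +
n_perm), so p is never exactly zero; B-H across conditions. This null is
an interpretation choice — the statistic (count of overlapping loci) and
the rotation scheme are stated here precisely because no standard is
universal. Calibration was measured on 500 uniform-panel replicates × 100
rotations using a 600-variant panel and 2 kb elements (a smooth enough
count statistic for a 100-permutation test): type-I error 0.048 at
α = 0.05. Chromosomes shorter than the longest enhancer are left
unrotated with a warning.

## Drug-target calls

A call is (treatment, element, gene, locus) where the gene passes q ≤ 0.05
in the treatment-vs-NT expression contrast and the element overlaps a risk
locus in that treatment's map. Direction consistency — the "closing
direction" — additionally requires negative accessibility log2FC with
q ≤ 0.05; calls lacking an accessibility contrast are emitted with those
fields absent and consistency undetermined. Significance is required on
accessibility only for the consistency flag, not for emitting the call,
because direction is reported for all risk enhancers while closing
significance is treated as corroborating evidence. Class summaries (TNFi
vs JAKi) use a unanimity rule — a pair is class-called only if called
under every member — the conservative choice among pooling rules, config
-exposed. Expression significance alone does not separate drug classes
when co-expression programs respond to several treatments; class
distinctiveness should be read from direction-consistent calls.

## Heritability partitioning (S-LDSC-lite)

Annotations are region sets; the per-treatment annotation is the top-k
most down-regulated open-chromatin regions (ranked by accessibility log2FC
ascending, ties by p then id; k = 15,000 in the method's real-data
convention, 150 — 10% of peaks — in the bundled synthetic pipeline so the
annotation stays a strict subset of accessible chromatin). LD scores
ℓ(j,c) = Σ_k r²(j,k)·member_c(k) include the self-term, so ℓ ≥ membership.
The fit is OLS of (χ² − 1) on {N·ℓ_c} plus an estimated constant; the
large external baseline-annotation set of full stratified LD-score
regression is replaced by a single all-accessible-peaks adjustment, which
preserves the inferential claim (signal beyond accessible chromatin at
large) at synthetic scale. τ*_c = τ_c · M · sd(member_c)/ĥ², with ĥ² =
Σ_c τ_c · M · mean(member_c). Standard errors come from a delete-one
jackknife over 20 contiguous position-ordered variant blocks (200 blocks
is depth-inappropriate for a 120-variant panel); the one-sided p tests
coefficient positivity. Both τ and τ* are reported, and the meta-analysis
combines per-study τ* by inverse-variance weighting. Near-null ĥ² makes
τ* an unstable ratio; the jackknife tracks that instability, yielding
conservative (wide) intervals rather than false positives — measured null
coverage of ±2 se was 97–100%. Unweighted OLS (rather than LDSC's
heteroskedasticity weights) is a deliberate simplification at toy panel
sizes; it costs efficiency, not unbiasedness (measured mean τ recovery
ratio 1.00 ± 0.04 over 200 replicates).

## Pipeline

`run_all` executes simulate → differential → modules → ABC → risk overlap
→ drug targets → heritability, communicating only through documented file
formats in the run directory; the YAML config is echoed verbatim, unknown
keys are rejected before any computation, and a manifest of SHA-256
artifact hashes is written. All randomness flows through per-stage
generators spawned from the master seed, so stages are individually
reproducible and reruns reproduce hashes exactly. The bundled default
configuration finishes in well under a minute on one CPU.

## Problem sizes

The bundled analyses run at deliberately small scale — 300 genes, 1,500
elements, 20 Mb genome, 120-variant panel, 500 calibration replicates ×
100 rotations, 200 recovery replicates — chosen so the full suite and the
reproduction script each complete in minutes on a single CPU while keeping
every statistical check non-degenerate (smooth permutation statistics,
identified regressions, non-trivial multiple-testing burden).
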