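# Methods

This note documents the models implemented in `dcisatlas`, their
assumptions, the parameter defaults and why they were chosen, the
numerical choices that affect results, what the synthetic generators do
and do not emulate, and the known limitations.

## Cohort table

The cohort fixture is a tab-delimited table with one row per tissue
block: patient identity, block identity, age at index diagnosis, lesion
size (cm), laterality, nuclear grade (Low / Inter. / High), dominant
architecture (Cribriform / Solid / Micropapillary / Mixed / ADH), ER and
HER2 status (`+`, `-`, `equ` for equivocal, `NA`), number of profiled
regions, and diagnostic timeline (Index, Recurrence with month offset,
Synchronous).  Conventions that matter for the counts:

* **Samples, not patients, are the counting unit** in every stratified
  summary — a patient can contribute an index block and a recurrence.
* **Sample identity is the (patient, block) pair.**  Block identifiers
  are only unique within a patient (different institutions reuse block
  numbering), so duplicates are detected on the pair.
* **Grade grouping**: intermediate and high grade pool to HG-DCIS;
  low-grade lesions are LG-DCIS unless their architecture is ADH.
* **Size threshold is inclusive** (≥): the "extended lesion" count uses
  ≥ 4 cm; blocks without a recorded size are excluded from the count,
  never treated as zero.
* **HER2 equivocal blocks are evaluable but not positive** — they stay
  in the denominator of positivity fractions.

## Copy-number analysis

**Input model.**  Each region contributes bin-level log2 copy ratios
(tumor/normal depth ratio per targeted bin) on a bin grid identical
across the regions of a sample.  Coordinates are 0-based half-open in
memory and 1-based inclusive on SEG read/write.

**Winsorization.**  Outlier bins are clipped per chromosome to
median ± k·MAD with the MAD scaled by 1.4826 (normal-consistent) and
k = 2.5.  The method is standard; the constants are package defaults
chosen to clip only clear single-bin outliers, and the operation is
idempotent.

**Joint segmentation.**  All regions are segmented on *shared*
breakpoints by exactly minimizing

    Σ_regions Σ_bins (value − segment mean)² + γ · (number of breakpoints)

per chromosome with an O(n²)-time, O(n)-memory dynamic program over
changepoints (the multi-sample analogue of penalized piecewise-constant
fitting).  Segment means are per-region within-segment averages of the
input values — divergence and discretization therefore operate on the
fitted means, not on re-winsorized data.  The penalty default is γ = 40.
With a single region the program reduces to ordinary penalized PCF.
Chromosomes beyond 50,000 bins (never reached by exome grids) are
segmented in overlapping chunks and the breakpoints merged; this is an
approximation and is flagged here for completeness.

**Burden.**  Fraction of covered base pairs in segments called gain
(log2 > 0.3) or loss (log2 < −0.4).  The cutoffs are the complement of
the neutral band used for character coding, keeping the two operations
consistent; both are configurable.  The denominator is the span covered
by segments, because targeted capture covers only part of the genome —
burden is therefore relative to the assayed footprint, not a nominal
genome length.

**Divergence.**  For two regions on one segmentation,
D(a,b) = Σ_k |a_k − b_k| · bins_k / total_bins.  The bin weight corrects
for unequal segment support.  On a fixed segmentation this is a weighted
L1 metric (symmetric, zero iff equal means, triangle inequality); a
sample with more than two regions is summarized by its maximal pair,
which makes the statistic insensitive to duplicated regions but
sensitive to a single outlier region — a deliberate "worst pair" view of
intra-sample heterogeneity.

**Character coding.**  Segment means map to −1 (loss) below −0.6, 0
(neutral) in [−0.4, 0.3], and undetermined otherwise; segments with
fewer than 12 bins are dropped.  Values in the guard bands (−0.6, −0.4)
and (0.3, gain threshold] are deliberately *missing*, not forced into a
state.  Gains (+1 above 0.6) are off by default: the loss/neutral
alphabet is the conservative core, and gain characters are an option
because tree figures in this field do annotate gains; enabling them adds
resolution on synthetic data and is what the planted-truth tests use.

## Maximum-parsimony phylogeny

The tree model is a rooted binary topology over regions beneath an
inferred normal diploid ancestor (all-neutral state vector) connected by
a trunk branch, so alterations shared by every region land on the trunk.

* **Scoring** is exact small parsimony by the unit-cost Sankoff
  recursion per character, with the ancestor fixed at neutral.
  Undetermined characters are wildcards (any state, no cost), *not* a
  fourth state: undetermined means unknown.  Set-based Fitch counting
  was rejected because it can undercount changes when leaves are
  ambiguous; the dynamic program is exact for any pattern of missing
  data (the test suite checks it against independent exhaustive
  enumeration).
* **Search** enumerates all (2n−3)!! rooted topologies, exact for the
  2–8 regions a microdissection study yields; beyond 8 the builder
  refuses rather than silently switching to a heuristic.  Ties are
  broken by the lexicographically smallest canonical newick string and
  the number of co-optimal topologies is always reported, so topological
  ambiguity is visible instead of hidden by an arbitrary pick.
* **Ancestral states** are fixed root-to-tip by choosing, at each node,
  a state realizing the parent's minimum — keeping the parent's state
  when optimal and preferring neutral on ties, which biases events later
  (the conservative reading of a normal ancestor).  Branch lengths are
  Hamming distances between endpoint state vectors, skipping positions
  where a leaf's observation is missing; with no missing data the total
  tree length equals the parsimony score.
* **Event placement.**  Each character is recorded on every branch where
  its assigned state changes.  A mutation from the multi-region presence
  matrix is placed on the branch above the most recent common ancestor
  of its present regions (trunk when present everywhere); if that clade
  contains a region where the mutation is absent, the pattern is
  homoplastic and the mutation is flagged `unplaced` rather than dropped.

## Tumor-only variant filtering

Filters are independent predicates that *label* records; nothing is
dropped, the final `somatic_pass` verdict is a pure function of the
labels, and the outcome is invariant to filter order.  Thresholds follow
their printed senses exactly (e.g. mapping quality strictly greater than
45, depth at least 5):

| filter | rule (defaults) |
| --- | --- |
| `quality_fail` | depth ≥ 5, MQ > 45, mean read position > 15, mean mismatches < 2.5, microsatellite length < 5, tumor LOD > 10, strand-bias Phred < 10, VAF > 0.1 |
| `common_germline` | population AF > 1e-3 or > 9 carriers (maximum over databases when several are annotated), unless CGC tier-1 gene and in COSMIC or ClinVar |
| `vaf_germline` | VAF ≥ 0.9 outside every LOH interval (inside LOH the retained allele legitimately reaches high VAF) |
| `pon` | > 2 pool-of-normal patients |
| `rescued_hotspot` | COSMIC count ≥ 15 and gene in the breast-cancer driver list; survives `common_germline` |

Missing quality fields do not fail a record — upstream callers do not
all emit every metric — unless `strict` mode is enabled.

**Presence calling.**  For alt count k of depth n in one region, the
Bayes factor compares a real-variant model with allele fraction
integrated uniformly over (f_min, 1) against a sequencing-noise binomial
at error rate e:

    BF = [∫_{f_min}^{1} Binom(k; n, f) df] / Binom(k; n, e)

with the closed form (1 − I_{f_min}(k+1, n−k+1))/(n+1) for the
numerator.  Defaults: e = 0.02, f_min = 0.05, present above BF = 10,
absent below BF = 0.1, unknown between or at depth 0.  This replaces a
full tree-aware Bayesian multi-region caller with a desk-scale,
dependency-free test per cell that is monotone in k and sufficient to
feed event placement; it does not learn error rates from the data or
share information across regions.

## Immune micro-environment states

Inputs are phenotyped cells (T-cell, B-cell, T-reg, epithelial, other;
Ki67 status; epithelium vs stroma compartment) and compartment areas per
region.  The 18 features are {BC, TC, TREG} × {Ki67+, Ki67−, total} ×
{Epi, Str} densities in cells/mm²; absent populations are explicit
zeros, and totals are sums of the Ki67 components by construction.
Epithelial (PanCK) counts define compartments but are not features, and
T-reg counts are disjoint from the T-cell feature by default so the
features stay non-redundant (both choices configurable).

Densities are mapped per feature to decile scores ceil(10·rank/n)
(average ranks on ties; a constant feature collapses to one decile),
computed jointly over all regions — normal and pre-invasive — so scores
are comparable across region classes.  The score matrix is factorized by
rank-4 NMF (Frobenius loss, multiplicative updates, best of 10 seeded
restarts, deterministic given the seed); W columns are normalized to
unit maximum with compensating scaling of H.  Because NMF factor order
is arbitrary, factors are relabeled canonically — MM2 is the factor with
the largest T-cell loading, MM4 the remaining factor with the largest
stroma-minus-epithelium skew, MM1 the remaining factor with the largest
Ki67+ share, MM3 the leftover — so the meta-marker indices carry their
conventional meaning.  Multiplicative updates converge slowly near the
boundary of the non-negative cone; the default 2,000 iterations suffice
for classification, and factor-recovery experiments use more.

Regions are clustered on their H columns by Ward linkage on Euclidean
distance, cut at k = 3 (the linkage/distance pair is a package choice
where only "hierarchical clustering" is conventional, and both are
configurable).  Naming: the cluster with maximal mean MM4 is
**Excluded**, of the remainder the cluster with maximal mean MM2 is
**Active**, and the last is **Suppressed**.  The stroma/epithelium ratio
summary reports Str_t/Epi_t per cell type (unbounded when the epithelium
is empty but the stroma populated), with a high/low/none category: none
when both compartments are empty, otherwise split at the per-cell-type
median of nonzero epithelial densities — a reimplementation choice where
no threshold is conventional.

## Statistics

* **Odds ratio** for a 2×2 table is the conditional MLE under Fisher's
  noncentral hypergeometric distribution: ψ̂ solves E[a | ψ, margins] = a,
  found by bisection on log ψ to 1e-8 and returning 0/∞ on the support
  boundary.  This is deliberately *not* the sample cross-product ratio:
  for the table (5, 3; 4, 20) the cross-product ratio is ≈ 8.3 while the
  conditional MLE is 7.6, matching the convention of classical
  Fisher-test software.  The two-sided p-value is the standard sum of
  point probabilities no larger than the observed one (no mid-p).
* **Mann–Whitney U** is exact by full enumeration of group assignments
  when the pooled size is ≤ 12 (with the 0.5 tie convention), otherwise
  the tie-corrected normal approximation with continuity correction.
* **OLS** reports slope, intercept, R² = 1 − SS_res/SS_tot, and the
  slope's t-test p-value; a constant response returns the zero-slope fit
  with R² = 0.

## Synthetic data: what passing tests show

The generators are pure functions of their spec (seed included).

* **Clonal copy number** plants a rooted event tree whose branches carry
  interval events; a region's noise-free bin value is the sum of log2
  shifts on its root-to-leaf path plus N(0, σ²) bin noise.  The default
  history has 4 regions ((A,B),(C,D)) on two 1,400-bin chromosomes with
  events in 200-bin slots, three events on the trunk and on each internal
  branch, one private event per region, magnitude ±0.8 and σ = 0.1.  The
  slot width is matched to the segmentation penalty: a 200-bin, 0.8-shift
  event in a *single* region changes the fit error by about
  (200·200/400)·0.8² = 64 per breakpoint, safely above γ = 40, so even
  private events are recoverable; magnitude 0.8 clears the ±0.6/±0.4
  character thresholds with room for noise.  What this does **not**
  emulate: overlapping events on one lineage (compound amplifications),
  focal events below the probe filter, wavy GC bias, purity dilution, or
  subclonal mixtures within one region — recovery rates on this
  generator are upper bounds for real microdissections.
* **Variant tables** plant germline records (VAF near 0.5 or 1.0,
  population AF sampled above the common-variant cutoff), somatic
  records (VAF uniform 0.1–0.4, clean metrics, unannotated) and
  artifacts (VAF below 0.1 plus one to three degraded quality metrics),
  defaulting to 120/40/40 per table — a germline-dominated candidate
  list, as tumor-only exomes produce.  Rare germline variants absent
  from population databases are *not* planted; the cascade cannot remove
  those by design (that residue is a known limitation of tumor-only
  filtering), so the removal rates measured here apply to the common-
  variant fraction.
* **Immune cohorts** draw the 18 features from three state archetypes
  (10 regions each) with independent multiplicative log-normal noise
  (σ = 0.3) on the Ki67+ and Ki67− components.  Archetypes encode the
  state definitions — Active: high T-cells in both compartments;
  Suppressed: low T-cells, elevated B/T-reg; Excluded: stroma-restricted
  lymphocytes — at magnitudes typical of compartmentalized DCIS
  immunoprofiling (epithelial T-cells ~120/mm² in Active regions).
  Spatial correlation between neighboring regions and the continuum
  between states are not modeled, so planted-state recovery quantifies
  the pipeline's behavior under clean state separation.

## Known limitations

* Exhaustive tree search is exact but factorial: 8 regions is the hard
  ceiling; no heuristic search or bootstrap support is provided.
* Divergence and characters require a *shared* segmentation; profiles
  segmented independently must be re-segmented jointly first.
* The presence caller treats regions independently; it does not exploit
  the tree or learn error rates.
* Allele-specific copy number, purity/ploidy fitting and whole-genome-
  doubling detection are out of scope, as are read alignment, raw
  variant calling, expression subtyping and image analysis.
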