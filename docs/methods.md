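# Methods

## Scope and model

The package implements the downstream analysis of an ECM-enriched
(decellularized-tissue) TMT proteomics study design: a protein × channel
intensity matrix from several isobaric plexes, each plex carrying tissue
samples plus two channels of a pooled common control (equal amounts of every
sample), is normalized, profiled against the matrisome, tested for
differential matrisome proteins between tissue groups and histologic
subtypes, and integrated with single-cell expression and bulk survival
cohorts. Raw spectra, peptide-spectrum matching and protein roll-up are out
of scope: the protein-level quantitation matrix is the entry point.

## Normalization

Stage 1 (median centering): for channel *j* with log2-median *m_j*, every
value becomes `2^(log2 x − m_j + mean_k m_k)`. Adding back the mean of the
medians preserves the overall intensity scale while giving every channel a
common log2 median; the stage is idempotent. The direction of centering is
value − median, the only direction that produces a common (zero-centered)
median. The stage operates on the protein matrix — the only matrix the
package ingests — although median centering is equally well defined at the
peptide level.

Stage 2 (reference scaling): the second reference channel (R2) carries the
same pooled control in every plex, so the ratio `x[i,j]/x[i,R2_p]` is
comparable across plexes. Rescaling by `a_i = mean_p x[i,R2_p]` (the
arithmetic mean on the linear scale, per protein) restores interpretable
intensity units and makes each protein's R2 values identical across plexes
— R2 acts as a cross-plex bridge. An alternative reading of the rescaling
constant (a grand mean over proteins) would not make R2 flat across plexes
and is not used. The first reference channel (R1) is not used in the
computation; it is retained for QC (R1/R2 agreement). Proteins whose R2
intensity is missing or non-positive in any plex cannot be bridged and are
excluded with a count in the QC report. Matrices stay on the linear scale
between stages; within-plex sample ratios are exactly preserved by stage 2,
and on a noise-free cohort the per-plex batch factor cancels exactly.

## Matrisome profiling

RPC uses all detected proteins in the denominator (the matrisome share of
total intensity then falls out of the same table); a matrisome-only
denominator is available. Category composition sums member-protein RPC per
sample; group comparisons use Welch's *t* (two-sided). The
cumulative-coverage count is the smallest *k* whose top-*k* mean-RPC sum
reaches the threshold (default 90%). Hierarchical clustering z-scores each
protein across samples (constant rows dropped) and clusters samples on
Euclidean distance; the linkage method is selectable with average linkage
as default, a conventional heatmap choice. PCA runs on log2 intensities by
default (variance stabilization; a linear-scale option exists), components
ordered by explained variance with the sign fixed so the largest-magnitude
loading is positive.

## Differential calling

Fold change is the ratio of linear-scale group means; the Welch statistic
and two-sided p-value are computed on log2 intensities with
Welch–Satterthwaite degrees of freedom. The two scales are deliberately
different: linear means match the field's fold-change convention, log2
stabilizes the test. The DEP rule is |log2FC| > 0.5 (FC > √2) **and**
p < 0.05 with no multiple-testing correction — raw p plus the fold-change
filter is the convention this analysis follows; a Benjamini–Hochberg mode
exists but is off by default. Zeros are treated as missing for the log test;
proteins with fewer than two observations in a group are excluded. Only
matrisome rows are tested by default (the contrast of interest is the
matrisome volcano); `matrisome_only=False` tests everything. PEMs are the
A-enriched DEPs of the PCC-NOS vs non-PCC-NOS tumor contrast.

## Cellular origins and fibroblast subclustering

Marker detection is a one-vs-rest two-sided Wilcoxon rank-sum on the
depth-normalized log1p layer (counts scaled to 1e4 per cell), BH-adjusted
across genes within each cell type; a gene is type-specific at adjusted
p < 0.01 with positive one-vs-rest log2 fold change. Origin assignment
requires specificity somewhere and then takes the cell type with the highest
mean normalized expression. Fibroblast subclustering z-scores the matrisome
feature genes, takes 20 principal components, builds a 20-nearest-neighbor
graph and runs Leiden community detection at resolution 0.5, all
seed-fixed. The 20/0.5/20 parameters are the study's stated clustering
settings and the package defaults.

## Single-sample gene-set scoring

One scorer serves cells and bulk. Genes are ranked within a sample
(ascending, average ranks for ties); walking the ranking from the
highest-expressed gene down, set genes accumulate weight `rank^α`
(normalized to 1 over the set, α = 0.25) and non-set genes accumulate
uniform weight over the complement; the score is `Σ_i (P_in(i) − P_out(i))`
over all positions. Ties in the walk order are broken by gene symbol, making
the scorer deterministic under permutations of the input rows. Because only
within-sample ranks enter, the score is invariant to any strictly monotone
per-sample transformation (e.g. TPM vs log-TPM). No cross-sample rescaling
is applied: the score is used for within-cohort ranking and mean-split
dichotomization, which rescaling would not change. Score–gene correlations
use raw TPM by default (log option available); "proportion of positive
cells" is the fraction with nonzero raw count.

## Survival

Patients are dichotomized at the mean score (median optional); a value equal
to the cutpoint goes to the high group. The survival comparison uses the
Kaplan–Meier product-limit estimator and the k-group log-rank test
(observed − expected under the hypergeometric at each event time, k−1 df,
simultaneous risk sets at tied times), via lifelines. Tests in the suite
check both against hand-computed product-limit and O/E tables.

## Synthetic data: what it emulates, what it does not

`generate_cohort` draws log2 baselines per protein (Normal(21.2, 1.5) for
matrisome, Normal(17.0, 1.5) otherwise — chosen so matrisome proteins carry
roughly 60% of total intensity, as expected after ECM enrichment), adds
planted log2 effects to TUM channels (tumor contrast) and PCC-NOS TUM
channels (subtype contrast), a per-plex batch factor (log2 sd 0.5, a
realistic between-plex scale for TMT), and residual noise (log2 sd 0.3, a
typical protein-level residual). Reference channels are the linear pooled
mean of all pre-noise sample values with independent noise draws, matching
physically distinct aliquots of one pooled control. Intensities are
log-normal — the conventional model for MS intensities. Matrices are
complete by default; a missing-at-random knob exists. Tissue classes are
spread across plexes by a seeded permutation so no plex is a pure group.

`generate_sc_data` produces Poisson counts around log-normal gene means with
planted cell-type-specific elevation (default 8-fold) and a PCC-NOS-like
fibroblast subpopulation (default 30% of fibroblasts) over-expressing the
PEM genes 4-fold. `generate_bulk_survival` shifts the log2 mean of gene-set
genes by a standard-normal latent score z and draws exponential event times
with log-hazard proportional to z (baseline hazard 1/60 per month ≈ 5-year
median survival), uniformly censored over 10 years; TPM columns sum to 1e6.

Not emulated: peptide-level structure, isotope-impurity cross-talk between
TMT channels, intensity-dependent missingness, zero-inflation beyond
Poisson sampling, doublets/ambient RNA, or batch structure in the
single-cell and bulk cohorts. Passing tests therefore demonstrate the
correctness of the computations and their recovery behavior under the
assumed generative model, not robustness to these real-data artifacts.

## Problem sizes and numerical choices

The default pipeline run uses 1000 proteins (the study-scale 4838 with 376
matrisome is the generator default and remains available), 120 cells per
type and 375 bulk patients — sizes chosen so a full run completes in tens of
seconds while every group comparison retains the study's group counts.
Normalization invariants hold to better than 1e-9 and are tested at that
tolerance. Degenerate inputs raise informative errors (all-missing channel,
zero-total RPC sample, single-group log-rank, degenerate dichotomization);
warnings are used where the analysis can proceed (short top-N lists, skipped
small groups). Ranking ties anywhere (top lists, marker selection, scorer
walk) break lexicographically by gene symbol.

## Known limitations

No moderated (limma-style) test statistics; no imputation; no Cox
regression or optimal-cutpoint scanning; no GO/pathway enrichment. The
Leiden clustering depends on graph construction details, so cluster counts
on weakly separated data are not a stable output — tests assert recovery
only under strong planted separation, plus determinism under a fixed seed.
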