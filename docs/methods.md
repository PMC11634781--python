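# Methods

## Study design being emulated

The pipeline targets diet-switch designs in mouse epididymal adipose
tissue. Conditions form a ladder: chow controls of increasing age (C, CC,
CCC), high-fat-diet obesity after a short or long exposure (H, HH), weight
loss by switching back to chow (HC, HHC), and a rebound arm in which
weight-loss mice and their controls are re-exposed to high-fat diet (HCH,
CCH). Every experimental condition is compared against its age-matched
control: H vs C, HH vs CC, HC vs CC, HHC vs CCC, HCH vs CCH.

Two data layers are modelled. Single-nucleus RNA counts (genes × cells,
with condition, cell-type and donor labels) drive the transcriptional
analyses; replicate-level region counts (regions × samples, 3 replicates
per condition by default, mirroring the 2–3 used in such designs) for
H3K4me3, H3K27me3, H3K27ac, H3K4me1 and ATAC drive the epigenetic analyses,
alongside binary 200-bp binned mark tracks used for rule-based enhancer
calling.

## Statistical models and procedures

### Single-nucleus DEG calling

Cells pass QC when 500 ≤ detected features ≤ 3,000 and total UMI ≤ 40,000
(boundaries inclusive; the thresholds are configuration fields and the
stated defaults are the mouse single-nucleus values). Counts are
normalized as log(1 + c·10⁴/total) per cell. Published analyses of such
designs use a variance-stabilizing transform; we use counts-per-10k
log1p deliberately, because the rank-sum statistic is invariant to any
monotone per-cell transform applied with a common scaling policy, so DEG
calls differ only through the fold-change estimate.

Per gene, a two-sided Wilcoxon rank-sum test compares the two cell groups.
When both groups have ≤ 8 cells the p-value is computed by exhaustive
enumeration of all C(n, n₁) assignments of the pooled midranks (ties exact
by construction); otherwise by the normal approximation with tie-corrected
variance n₁n₂/12·[(n+1) − Σ(t³−t)/(n(n−1))] and a 0.5 continuity
correction. The switch point balances enumeration cost (C(16,8) = 12,870)
against approximation error; without ties the two paths agree to within
0.01 for groups of 8–12.

log2FC = log2((mean de-logged expression A + 1)/(mean B + 1)); the
pseudocount of 1 (on the counts-per-10k scale) avoids division by zero and
is configurable. The conventional calls use |log2FC| ≥ 0.5 and Bonferroni-
adjusted P < 0.01 (a preset with adjusted P < 0.05 matches the
mouse-adipocyte pattern analysis). Fold-change thresholds are applied
inclusively (≥); since the statistic is continuous, boundary behaviour is
immaterial in practice.

### Replicate-level NB exact test

Region counts are modelled as negative binomial with Var = μ + φμ² and a
single common dispersion φ per modality. φ is estimated by method of
moments: after median-of-ratios size-factor normalization, least squares of
(s² − m) on m² pooled over all feature × condition groups with ≥ 2
samples, clipped at 0. This deliberately replaces the tagwise-shrinkage
machinery of GLM frameworks: it is well-specified, fast, and directly
testable by simulation (Poisson data drives the estimate to 0; φ = 0.2 data
with 2,000 features is recovered within [0.1, 0.3]).

The test itself conditions on each feature's total pseudo-count across the
two groups. Counts are divided by their size factors and rounded ("equal-
library-size pseudo-counts"); group totals then follow NB(n_g·μ, φ/n_g)
under H0, and the group-A total conditional on the feature total t has
kernel C(a + r_a − 1, a)·C(t − a + r_b − 1, t − a) with r_g = n_g/φ. The
two-sided p-value sums the probabilities of all outcomes no more likely
than the observed one (minimum-likelihood rule, with the same (1 + 10⁻⁷)
float-tie guard as the standard exact binomial implementation). At φ = 0
the kernel degenerates to Binomial(t, n_a/(n_a+n_b)) and the test equals
the exact binomial test. Promoter-level contrasts are called at nominal
P < 0.01 and |log2FC| > 1; enhancer-level contrasts at BH-FDR < 0.05 and
|log2FC| > 1; bulk translatome-style contrasts use |log2FC| ≥ 1 and nominal
P < 0.01. Null calibration: at the true dispersion the empirical type-I
error at α = 0.05 is ≈ 0.047 over 10,000 simulated features.

### Retention, patterns, trajectories

Retention overlays two DiffResult tables gene-wise. Obese DEG + WL ns →
restored; same direction → memory; opposite direction → sign_flip (kept
apart so direction reversals cannot inflate retention — the source analyses
do not address reversals); WL-only DEGs are reported but excluded from the
retention denominator, which is the obese-time-point DEG set:
proportion = memory/(memory + restored). Cell types with fewer than 30
cells per donor group can be excluded when per-donor counts are supplied.

Cross-arm patterns classify genes deregulated in both H and HH:
(memory, memory) → not_restored_both, (restored, memory) →
restored_HC_only, (restored, restored) → restored_both,
(memory, restored) → restored_HHC_only, anything involving a sign flip →
other. Region trajectories map the (obese, WL) call pair through the fixed
3×3 rule table; reversals are flagged, not forced into a class.

### Enhancers, linkage, fold enrichment

An enhancer bin is marked by H3K4me1 and H3K27ac, open by ATAC, lacks
H3K4me3, and lies outside every ±2-kb promoter window (strand-aware TSS:
gene start on +, end − 1 on −; windows are half-open [tss−2000, tss+2000)
clipped to the chromosome). The rule is applied directly to 200-bp bins —
the chromatin-state HMM used upstream in the original analysis is an
external tool, and the selection criterion it feeds is exactly this mark
combination, so the rule is implemented as stated. Qualifying bins merge
when adjacent (merge_gap = 0 by default; configurable), and merged
intervals overlapping a promoter window by ≥ 1 bp are removed, so called
enhancers never overlap promoters.

Enhancers link to the closest gene within 20,000 bp, distance 0 when
overlapping the gene body, else the smaller edge-to-edge gap to gene body
or TSS (the TSS lies inside the body, so the body gap dominates; both are
computed for fidelity to the stated rule). Whether the 20-kb radius is
measured edge-to-edge or from the midpoint is not specified upstream;
edge-to-edge is used, and ties break to the lexicographically smaller gene
id for determinism. Fold enrichment of peaks against a genomic feature is
Σ(bp overlap)·genome_size/(Σ(bp peaks)·Σ(bp feature)); > 1 means more
overlap than random placement would give. All coordinates are 0-based
half-open BED throughout; blacklist filtering removes peaks with ≥ 1 bp
overlap (the strictest reading of "overlapping").

### Epigenetic explanation

A persistent entry at a gene is a promoter or linked-enhancer contrast pair
that is significant in the same direction in both the obese and WL
contrasts (persistence = obese_and_wl), or significant in the WL contrast
(persistence = wl_only, the default for the rebound analysis, which asks
whether regions are still differentially marked at the weight-loss time
point). "Explained by one or more epigenetic modality" is not defined
operationally in the source analyses, so two modes are implemented and
always labelled: any_modality (any persistent entry; closest to the figure-
legend wording; the default) and direction_consistent (gains of activating
marks or losses of H3K27me3 explain up-regulation; mirrored for down).
The direction-consistent explained set is a subset of the any-modality set
by construction. Rebound DEGs carry three non-exclusive flags: prior
same-direction DEG status at weight loss, transcriptional memory at weight
loss, and epigenetic marking; fractions are reported per source and
direction, mirroring stacked proportional bars. ATAC participates as a
modality on equal footing; it can be excluded via the modality filter.

## Synthetic data generator

The generator emulates the statistical structure of the study, not its
sequences: no reads, fragments, doublets or ambient RNA.

* **Genes**: placed in regularly spaced slots with jittered starts on
  synthetic chromosomes (default 2,000 genes on 4 × 30 Mb), lengths 2–10 kb,
  random strand; each slot reserves room for the promoter window and a
  distal enhancer region so neighbouring genes' regulatory intervals never
  collide. Infeasible configurations (slots < 20 kb) raise.
* **Counts**: negative binomial with Var = μ + φμ², log-normal library-size
  factors with mean 1 and configured CV (0.3 default) — realistic depth
  variation that exercises the normalization. Gene baseline means are
  log-uniform on [0.5, 8] counts/cell (single-nucleus scale); region
  baselines log-uniform on [30, 80] counts/replicate. Dispersions: 0.3 for
  cells, 0.1 for replicate-level regions.
* **Planted gene classes**: memory genes are shifted by ±effect (default
  |log2FC| = 1.5) in obese, weight-loss *and* rebound conditions; restored
  genes in obese and rebound conditions only; optional sign-flip classes
  reverse direction after weight loss; everything else is null. Same sign
  and magnitude in obese and WL conditions makes the retention truth
  unambiguous.
* **Planted region classes** per modality: gain_maintained/gain_lost/
  loss_maintained/loss_regained/wl_only/stable as mean shifts (default
  |log2FC| = 2) in the designated conditions.
* **Explanation links**: 70% of memory genes (default) receive a persistent
  direction-consistent region — alternating promoter route (H3K27ac gain for
  up, H3K4me3 loss for down) and enhancer route (H3K4me1 on a distal region
  3 kb downstream of the gene). Link counts are allocated so the total
  equals round(fraction × n_memory) exactly, making the noiseless recovery
  exact. Memory/restored genes not chosen for a link keep fully stable
  regions, so false explanations require double type-I errors and the
  planted fraction is identifiable. A separate fraction (60%) of restored
  genes receives the same treatment for the rebound analysis, recorded in a
  separate truth field.
* **Binned tracks**: planted enhancer runs (1–3 bins), decoys violating
  exactly one clause (extra H3K4me3; partial mark combinations; full
  combination inside promoters), and a sparse random background per mark.
  The truth set is computed from the final binary track with the enhancer
  rule itself, so the caller's recovery is a consistency check of selection,
  merging and promoter exclusion rather than of noise robustness. Tracks
  are binary because the defining rule is stated on mark presence;
  thresholding continuous enrichment is out of scope.

All randomness flows from a single seed through named substreams, so each
stage is independently reproducible and a fixed seed yields byte-identical
fixture bundles and pipeline outputs.

### What passing tests do and do not show

Planted effects are condition-homogeneous mean shifts with a common
dispersion; real data have correlated genes, per-donor effects, batch
structure, zero inflation beyond NB, and epigenetic effect sizes that vary
continuously rather than by class. Recovery results (retention sensitivity/
FDR, explained-fraction recovery) therefore validate the *rules and
statistics*, not performance on any real dataset; the headline percentages
printed by real studies depend on their sequencing data and are not
reproducible at this scale.

## Numerical and design choices

* Exact/normal Wilcoxon switch at group size 8; permutation mean used for
  two-sidedness; deviation comparisons use a 10⁻⁹ guard on midrank floats.
* Minimum-likelihood two-sided rule for all exact tests, with relative
  float-tie tolerance 1 + 10⁻⁷.
* BH step-up enforces monotonicity by a reverse cumulative minimum.
* Median-of-ratios size factors fall back to library-size ratios when no
  feature is positive in all samples; constant matrices give φ = 0.
* Degenerate inputs raise explicitly (empty interval sets in fold
  enrichment, zero-total cells, < 2 samples per group, zero-variance
  profiles in correlation); all-cells-removed QC warns and returns an empty
  selection rather than raising.
* The pipeline's problem sizes (2,000 genes, 300 cells/condition, 3
  replicates, 5 modalities) are the package's default study scale; the
  oracle checks run at 10⁵-bp genomes and 10⁴ simulated features, sizes at
  which the exhaustive references are exact and fast.

## Known limitations

Single common dispersion per modality (no tagwise shrinkage, no
covariates); no clustering/integration (cell types are taken as labels);
rank-sum DEG calling only (no mixed models or pseudobulk); enhancer calling
ignores signal strength; linkage is distance-based (no 3D contacts); the
explanation logic is associative, not causal.
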