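# adipomem

Obesogenic-memory analysis of adipose-tissue multi-omic data.

Adipose tissue retains molecular traces of past obesity after substantial
weight loss: a subset of genes deregulated in the obese state stay
deregulated in adipocytes after weight normalization ("memory" genes), and
this transcriptional persistence is mirrored by persistent histone-mark and
chromatin-accessibility changes at promoters and enhancers. `adipomem`
implements that analysis as a tested, reusable pipeline for mouse-style
diet-switch designs (conditions C/CC/CCC controls, H/HH high-fat diet,
HC/HHC weight loss, HCH/CCH high-fat rebound), together with a synthetic
data generator that plants known ground truth, so every stage can be
validated without any sequencing data.

## What it computes

* **DEG calling** per contrast on single-nucleus counts: counts-per-10k
  log1p normalization, two-sided Wilcoxon rank-sum test (exact enumeration
  for groups of ≤ 8 cells, tie- and continuity-corrected normal
  approximation otherwise), Bonferroni or Benjamini–Hochberg adjustment, and
  calls at |log2FC| > 0.5 with adjusted *P* < 0.01. Cell QC discards nuclei
  with < 500 or > 3,000 detected features or > 40,000 UMIs.
* **Transcriptional retention**: overlaying the obese-vs-control and
  WL-vs-control DEG calls classifies each obese DEG as *restored* (no longer
  deregulated after weight loss), *memory* (same-direction DEG in both), or
  *sign_flip*; retention proportion = memory / (memory + restored) per cell
  type and direction. Cross-arm patterns (restored in neither, only HC,
  both, only HHC) for genes deregulated in both obesity arms.
* **Region differential statistics** on replicate-level histone-PTM
  (H3K4me3, H3K27me3, H3K27ac, H3K4me1) and ATAC counts: median-of-ratios
  size factors, method-of-moments common NB dispersion φ (Var = μ + φμ²),
  and an exact-conditional NB test per region (conditioning on the region's
  total normalized count across both groups; at φ = 0 it reduces to the
  exact binomial test). Promoter-level calls at nominal *P* < 0.01 and
  |log2FC| > 1, enhancer-level calls at FDR < 0.05 and |log2FC| > 1.
* **Enhancer definition and dynamics**: rule-based enhancer calling on
  200-bp binned tracks (H3K4me1 + H3K27ac + open ATAC, no H3K4me3, not
  within a ±2-kb promoter window), trajectory classes across
  obesity → weight loss (gained_maintained = "new enhancer", gained_lost,
  lost_maintained, …), per-condition H3K27ac activity overlay, and linkage
  of each enhancer to its closest gene (TSS or gene body) within 20 kb.
* **Interval utilities**: BED I/O, union/merge, blacklist filtering, and
  peak fold enrichment
  Σ(bp overlap) × genome_size / (Σ(bp peaks) × Σ(bp feature)).
* **Epigenetic explanation**: a memory DEG is *explained* when a persistent
  differential mark sits at its promoter or a linked enhancer (either any
  modality, or direction-consistent: activating-mark gains / H3K27me3 losses
  for up-regulation and the mirror image for down-regulation). Rebound DEGs
  (HCH vs CCH) are attributed to prior DEG status, transcriptional memory
  and/or epigenetic marks as three non-exclusive sources.

## Worked example

```python
import adipomem as am

cfg = am.SimConfig(seed=1)       # 2,000 genes, 9 conditions, planted truth
res = am.run_pipeline(cfg)

print(res["proportions_HC"])
print(res["explained_fractions_any_modality"])
```

Output:

```
cell_type direction  n_memory  n_restored  proportion
adipocyte      down        73          74    0.496599
adipocyte        up        75          75    0.500000

deg_direction  n_explained  n_total  fraction
         down           48       73  0.657534
           up           54       75  0.720000
```

The default configuration plants 75 memory and 75 restored genes per
direction; the retention classifier recovers essentially all of them (the
proportion of retained changes is ≈ 0.50 by construction), and with 70% of
memory genes carrying a planted persistent promoter/enhancer alteration the
explanation stage recovers fractions close to 0.7 per direction. The rebound
analysis on the same run attributes 63–68% of HCH DEGs to an epigenetic
source versus ~50% to prior DEG status — planted as the generator's rebound
structure, where re-exposure reactivates both memory and restored genes but
only a configured fraction carries persistent marks.

A thin CLI mirrors the stages:

```sh
adipomem simulate bundle/ --seed 1          # write MTX/TSV/BED fixtures
adipomem deg bundle/ H C deg_H.tsv          # Wilcoxon DEG table
adipomem retention deg_H.tsv deg_HC.tsv calls.tsv
adipomem run out/ --seed 1                  # full pipeline
```

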