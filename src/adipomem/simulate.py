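"""Synthetic multi-omic adipose-tissue data with planted ground truth.

The generator emulates the statistical structure of a diet-switch study in
mouse epididymal adipose tissue: single-nucleus RNA counts and replicate-level
histone-mark/accessibility region counts across the condition ladder

    C, CC, CCC      chow controls of increasing age
    H, HH           high-fat-diet obesity (12 / 25 weeks)
    HC, HHC         weight loss (chow after HFD)
    HCH, CCH        rebound: HFD re-exposure of weight-loss mice / controls

Counts are negative binomial with Var = mu + phi*mu^2 and log-normal per-cell
(or per-replicate) library-size factors. Ground truth is planted as condition-
dependent mean shifts:

* gene classes: ``memory_up/down`` (shifted in obese, weight-loss and rebound
  conditions), ``restored_up/down`` (shifted in obese and rebound conditions
  only), optional ``sign_flip_up/down``, and ``null``;
* region trajectory classes per modality: ``gain_maintained``, ``gain_lost``,
  ``loss_maintained``, ``loss_regained``, ``wl_only`` and ``stable``;
* explanation links: a configured fraction of memory genes carries a
  persistent differential region (its promoter, or a distal enhancer within
  linkage range) in a direction-consistent modality; a configured fraction of
  restored genes carries the same for the rebound analysis;
* 200-bp binned binary mark tracks whose enhancer-rule-satisfying bins are
  recorded exactly.

Every operation is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .regions import RegionSet, make_gene_table, make_promoters, write_bed, read_bed

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "MODALITIES",
    "OBESE_CONDITIONS",
    "WL_CONDITIONS",
    "REBOUND_CONDITIONS",
    "CONTROL_OF",
    "simulate_gene_annotation",
    "simulate_sn_counts",
    "simulate_region_counts",
    "simulate_binned_tracks",
    "simulate_all",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

MODALITIES = ("H3K4me3", "H3K27me3", "H3K27ac", "H3K4me1", "ATAC")

OBESE_CONDITIONS = frozenset({"H", "HH"})
WL_CONDITIONS = frozenset({"HC", "HHC"})
REBOUND_CONDITIONS = frozenset({"HCH"})
CONTROL_CONDITIONS = frozenset({"C", "CC", "CCC", "CCH"})
#: obese/WL/rebound condition -> its age-matched control
CONTROL_OF = {"H": "C", "HH": "CC", "HC": "CC", "HHC": "CCC", "HCH": "CCH"}

GENE_CLASSES = ("memory_up", "memory_down", "restored_up", "restored_down",
                "sign_flip_up", "sign_flip_down", "null")
REGION_CLASSES = ("gain_maintained", "gain_lost", "loss_maintained",
                  "loss_regained", "wl_only", "stable")

_ALL_CONDITIONS = ("C", "CC", "CCC", "H", "HC", "HH", "HHC", "HCH", "CCH")

# activating marks gain with up-regulation; H3K27me3 is repressive
ACTIVATING_MARKS = frozenset({"H3K4me3", "H3K27ac", "H3K4me1", "ATAC"})


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic dataset.

    Defaults describe the emulated study scale: 2,000 genes on 4 chromosomes,
    300 nuclei per condition, 3 replicates per condition for the five region
    modalities, gene effects of |log2FC| = 1.5 and region effects of
    |log2FC| = 2 on negative-binomial counts.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    chrom_length: int = 30_000_000
    n_cells_per_condition: int = 300
    cell_types: dict = field(default_factory=lambda: {"adipocyte": 1.0})
    conditions: tuple = _ALL_CONDITIONS
    n_replicates_per_condition: int = 3
    gene_counts: dict = field(default_factory=lambda: {
        "memory_up": 75, "memory_down": 75,
        "restored_up": 75, "restored_down": 75,
        "sign_flip_up": 0, "sign_flip_down": 0,
    })
    region_counts: dict = field(default_factory=lambda: {
        "gain_maintained": 60, "gain_lost": 60, "loss_maintained": 60,
        "loss_regained": 60, "wl_only": 60,
    })
    effect_size_log2fc: float = 1.5
    region_effect_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    region_nb_dispersion: float = 0.1
    baseline_mean_range: tuple = (0.5, 8.0)
    region_baseline_mean_range: tuple = (30.0, 80.0)
    library_size_cv: float = 0.3
    explained_fraction: float = 0.7
    rebound_marked_fraction: float = 0.6
    n_distal_regions: int = 600
    bin_size: int = 200
    mark_density: float = 0.002
    n_enhancer_runs: int = 300
    qc_min_features: int = 500
    qc_max_features: int = 3000
    qc_max_umi: int = 40000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("need >= 1 chromosome of positive length")
        if not 0.0 <= self.explained_fraction <= 1.0:
            raise ValueError("explained_fraction must lie in [0, 1]")
        if not 0.0 <= self.rebound_marked_fraction <= 1.0:
            raise ValueError("rebound_marked_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.region_nb_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if self.effect_size_log2fc < 0 or self.region_effect_log2fc < 0:
            raise ValueError("effect sizes must be >= 0")
        unknown = set(self.conditions) - set(_ALL_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        if sum(self.gene_counts.values()) > self.n_genes:
            raise ValueError("planted gene class counts exceed n_genes")
        bad = set(self.gene_counts) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        bad = set(self.region_counts) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")
        if self.chrom_length % self.bin_size != 0:
            raise ValueError("bin_size must divide chrom_length")
        props = np.array(list(self.cell_types.values()), dtype=float)
        if len(props) == 0 or not np.isclose(props.sum(), 1.0):
            raise ValueError("cell_type proportions must sum to 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        d["baseline_mean_range"] = list(d["baseline_mean_range"])
        d["region_baseline_mean_range"] = list(d["region_baseline_mean_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("conditions", "baseline_mean_range", "region_baseline_mean_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    gene_class : Series gene_id -> class label
    region_class : DataFrame (modality, region_id) -> class (one row each)
    explanation_link : dict gene_id -> set of (modality, region_id) persistent
        links planted for memory genes
    rebound_link : same, planted for restored genes (rebound analysis)
    enhancer_bins : set of (chrom, bin_start) satisfying the enhancer rule
    """

    gene_class: pd.Series | None = None
    region_class: pd.DataFrame | None = None
    explanation_link: dict | None = None
    rebound_link: dict | None = None
    enhancer_bins: set | None = None

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        out = PlantedTruth()
        for f in dataclasses.fields(PlantedTruth):
            a, b = getattr(self, f.name), getattr(other, f.name)
            setattr(out, f.name, b if b is not None else a)
        return out


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Named deterministic sub-stream of the config seed."""
    return np.random.default_rng([config.seed, stream])


def _nb_draw(rng, mu, phi):
    """NB draws with Var = mu + phi*mu^2 (Poisson when phi == 0)."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def _library_factors(rng, n, cv):
    """Log-normal depth factors with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# gene annotation

def simulate_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Place non-overlapping genes on the synthetic genome.

    Genes sit in regularly spaced slots with jittered starts; each slot
    reserves room for the promoter window upstream and a distal enhancer
    region downstream, so promoter and enhancer intervals of neighbouring
    genes never collide. Raises when the genome is too short to place
    ``n_genes`` this way.
    """
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    rng = _rng(config, 1)
    chroms, starts, ends, strands = [], [], [], []
    for ci, k in enumerate(per_chrom):
        if k == 0:
            continue
        slot = config.chrom_length // k
        if slot < 20000:
            raise ValueError(
                f"cannot place {k} genes on a {config.chrom_length}-bp "
                f"chromosome: need >= 20 kb per gene slot")
        max_len = min(10000, slot - 9000)
        for j in range(k):
            length = int(rng.integers(2000, max_len + 1))
            lo = j * slot + 2000
            hi = (j + 1) * slot - length - 6000
            start = int(rng.integers(lo, hi + 1))
            chroms.append(f"chr{ci + 1}")
            starts.append(start)
            ends.append(start + length)
            strands.append("+" if rng.random() < 0.5 else "-")
    genes = make_gene_table(
        gene_id=[f"g{i:05d}" for i in range(len(chroms))],
        chrom=chroms, start=starts, end=ends, strand=strands)
    genes["gene_id"] = [f"g{i:05d}" for i in range(len(genes))]
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return genes


def plant_gene_classes(config: SimConfig, genes: pd.DataFrame) -> pd.Series:
    """Deterministic assignment of gene ids to planted classes (rest: null)."""
    rng = _rng(config, 17)
    order = rng.permutation(len(genes))
    labels = pd.Series("null", index=genes["gene_id"].to_numpy(), name="gene_class")
    pos = 0
    for cls in GENE_CLASSES:
        n = int(config.gene_counts.get(cls, 0))
        labels.iloc[order[pos:pos + n]] = cls
        pos += n
    return labels


def _gene_condition_log2fc(cls: str, cond: str, eff: float) -> float:
    shifted_up = {
        "memory_up": OBESE_CONDITIONS | WL_CONDITIONS | REBOUND_CONDITIONS,
        "restored_up": OBESE_CONDITIONS | REBOUND_CONDITIONS,
        "sign_flip_up": OBESE_CONDITIONS,
    }
    if cls == "null":
        return 0.0
    base = cls.replace("_down", "_up")
    sign = 1.0 if cls.endswith("_up") else -1.0
    if cond in shifted_up[base]:
        return sign * eff
    if base.startswith("sign_flip") and cond in WL_CONDITIONS:
        return -sign * eff
    return 0.0


# ---------------------------------------------------------------------------
# single-nucleus counts

def simulate_sn_counts(config: SimConfig, genes: pd.DataFrame):
    """Negative-binomial single-nucleus counts with planted DEG classes.

    Returns ``(counts, cells, truth)``: a sparse genes x cells matrix, a cell
    metadata DataFrame (barcode, condition, cell_type, donor) and the
    PlantedTruth with gene classes.
    """
    if not any(c in CONTROL_CONDITIONS for c in config.conditions):
        raise ValueError("conditions must include at least one control")
    if not any(c in OBESE_CONDITIONS for c in config.conditions):
        raise ValueError("conditions must include at least one obese condition")
    rng = _rng(config, 2)
    classes = plant_gene_classes(config, genes)
    lo, hi = config.baseline_mean_range
    base_mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    ct_labels = list(config.cell_types)
    ct_props = np.array([config.cell_types[c] for c in ct_labels], dtype=float)

    blocks, meta = [], []
    for cond in config.conditions:
        n = config.n_cells_per_condition
        lib = _library_factors(rng, n, config.library_size_cv)
        cts = rng.choice(len(ct_labels), size=n, p=ct_props)
        shift = np.array([
            2.0 ** _gene_condition_log2fc(classes.loc[g], cond,
                                          config.effect_size_log2fc)
            for g in genes["gene_id"]])
        mu = np.outer(base_mu * shift, lib)
        blocks.append(sparse.csr_matrix(_nb_draw(rng, mu, config.nb_dispersion)))
        for i in range(n):
            meta.append((f"{cond}_c{i:04d}", cond, ct_labels[cts[i]],
                         f"{cond}_d{i % 2 + 1}"))
    counts = sparse.hstack(blocks, format="csr")
    cells = pd.DataFrame(meta, columns=["barcode", "condition", "cell_type", "donor"])
    return counts, cells, PlantedTruth(gene_class=classes)


# ---------------------------------------------------------------------------
# region counts

def _region_condition_log2fc(cls: str, cond: str, eff: float) -> float:
    if cls == "gain_maintained" and cond in OBESE_CONDITIONS | WL_CONDITIONS:
        return eff
    if cls == "gain_lost" and cond in OBESE_CONDITIONS:
        return eff
    if cls == "loss_maintained" and cond in OBESE_CONDITIONS | WL_CONDITIONS:
        return -eff
    if cls == "loss_regained" and cond in OBESE_CONDITIONS:
        return -eff
    if cls == "wl_only" and cond in WL_CONDITIONS:
        return eff
    return 0.0


def build_region_table(config: SimConfig, genes: pd.DataFrame,
                       classes: pd.Series) -> pd.DataFrame:
    """Region universe: one promoter-proximal region per gene plus distal
    regions placed 3 kb downstream of a deterministic subset of genes.

    Distal hosts are the memory and restored genes (candidates for planted
    enhancer links) topped up with null genes to ``n_distal_regions``.
    """
    prom = pd.DataFrame({
        "region_id": "pr_" + genes["gene_id"],
        "chrom": genes["chrom"],
        "start": np.maximum(genes["tss"] - 1000, 0),
        "end": genes["tss"] + 1000,
        "gene_id": genes["gene_id"],
        "kind": "promoter",
    })
    rng = _rng(config, 18)
    planted = genes["gene_id"][classes.loc[genes["gene_id"]].ne("null").to_numpy()]
    nulls = genes["gene_id"][classes.loc[genes["gene_id"]].eq("null").to_numpy()]
    n_fill = max(0, config.n_distal_regions - len(planted))
    fill = nulls.iloc[np.sort(rng.permutation(len(nulls))[:n_fill])]
    hosts = pd.concat([planted, fill]).sort_index()
    g = genes.set_index("gene_id")
    dist = pd.DataFrame({
        "region_id": "en_" + hosts,
        "chrom": g.loc[hosts, "chrom"].to_numpy(),
        "start": g.loc[hosts, "end"].to_numpy() + 3000,
        "end": g.loc[hosts, "end"].to_numpy() + 4000,
        "gene_id": hosts.to_numpy(),
        "kind": "distal",
    })
    return pd.concat([prom, dist], ignore_index=True)


def _plant_region_classes(config: SimConfig, regions: pd.DataFrame,
                          gene_classes: pd.Series):
    """Assign per-modality trajectory classes, explanation links and rebound
    links. Regions of memory/restored genes that are not selected for a link
    stay 'stable' in every modality so planted links are unambiguous."""
    rng = _rng(config, 19)
    cls_map = {(m, r): "stable" for m in MODALITIES for r in regions["region_id"]}
    explanation, rebound = {}, {}
    by_gene = regions.set_index("region_id")

    def pick(gene_ids, k):
        ids = np.asarray(gene_ids)
        return set(ids[np.sort(rng.permutation(len(ids))[:k])])

    mem_up = gene_classes.index[gene_classes == "memory_up"]
    mem_dn = gene_classes.index[gene_classes == "memory_down"]
    res_up = gene_classes.index[gene_classes == "restored_up"]
    res_dn = gene_classes.index[gene_classes == "restored_down"]

    def plant_links(up_genes, dn_genes, fraction, store):
        # allocate so the total linked count equals round(fraction * n) exactly
        n_up, n_dn = len(up_genes), len(dn_genes)
        k_tot = int(round(fraction * (n_up + n_dn)))
        k_up = min(n_up, int(np.floor(fraction * n_up + 0.5)))
        k_dn = min(n_dn, k_tot - k_up)
        chosen_up = pick(up_genes, k_up)
        chosen_dn = pick(dn_genes, k_dn)
        for i, gset, up in ((0, chosen_up, True), (1, chosen_dn, False)):
            for j, gene in enumerate(sorted(gset)):
                # alternate promoter-route and enhancer-route links
                if j % 2 == 0 or f"en_{gene}" not in by_gene.index:
                    rid = f"pr_{gene}"
                    modality = "H3K27ac" if up else "H3K4me3"
                else:
                    rid = f"en_{gene}"
                    modality = "H3K4me1"
                cls_map[(modality, rid)] = "gain_maintained" if up else "loss_maintained"
                store.setdefault(gene, set()).add((modality, rid))
        return chosen_up | chosen_dn

    plant_links(mem_up, mem_dn, config.explained_fraction, explanation)
    plant_links(res_up, res_dn, config.rebound_marked_fraction, rebound)

    # generic trajectory classes live on regions of null genes only
    reserved_genes = set(gene_classes.index[gene_classes != "null"])
    pool = [r for r in regions["region_id"]
            if by_gene.loc[r, "gene_id"] not in reserved_genes]
    for mi, m in enumerate(MODALITIES):
        free = list(pool)
        order = rng.permutation(len(free))
        pos = 0
        for cls in REGION_CLASSES:
            if cls == "stable":
                continue
            n = int(config.region_counts.get(cls, 0))
            if pos + n > len(free):
                raise ValueError("planted region class counts exceed free regions")
            for k in order[pos:pos + n]:
                cls_map[(m, free[k])] = cls
            pos += n
    region_class = pd.DataFrame(
        [(m, r, c) for (m, r), c in cls_map.items()],
        columns=["modality", "region_id", "class"],
    ).sort_values(["modality", "region_id"], kind="mergesort").reset_index(drop=True)
    return region_class, explanation, rebound


def simulate_region_counts(config: SimConfig, genes: pd.DataFrame):
    """Per-modality replicate-level NB region counts with planted trajectories.

    Returns ``(counts_by_modality, regions, samples, truth)`` where
    counts_by_modality maps modality -> DataFrame (regions x samples),
    ``samples`` carries the per-sample condition labels, and ``truth`` holds
    region classes plus explanation/rebound links.
    """
    if config.n_replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    gene_classes = plant_gene_classes(config, genes)
    regions = build_region_table(config, genes, gene_classes)
    region_class, explanation, rebound = _plant_region_classes(
        config, regions, gene_classes)
    cls_lookup = region_class.set_index(["modality", "region_id"])["class"]

    sample_ids, sample_cond = [], []
    for cond in config.conditions:
        for r in range(config.n_replicates_per_condition):
            sample_ids.append(f"{cond}_r{r + 1}")
            sample_cond.append(cond)
    samples = pd.DataFrame({"sample": sample_ids, "condition": sample_cond})

    rng = _rng(config, 3)
    lo, hi = config.region_baseline_mean_range
    counts_by_modality = {}
    for m in MODALITIES:
        base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(regions)))
        lib = _library_factors(rng, len(sample_ids), config.library_size_cv)
        shift = np.empty((len(regions), len(sample_ids)))
        cls_vec = cls_lookup.loc[m].loc[regions["region_id"]].to_numpy()
        for j, cond in enumerate(sample_cond):
            lfc = np.array([_region_condition_log2fc(c, cond,
                                                     config.region_effect_log2fc)
                            for c in cls_vec])
            shift[:, j] = 2.0 ** lfc
        mu = base[:, None] * shift * lib[None, :]
        mat = _nb_draw(rng, mu, config.region_nb_dispersion)
        counts_by_modality[m] = pd.DataFrame(
            mat, index=regions["region_id"].to_numpy(), columns=sample_ids)
    truth = PlantedTruth(gene_class=gene_classes, region_class=region_class,
                         explanation_link=explanation, rebound_link=rebound)
    return counts_by_modality, regions, samples, truth


def truth_memory_calls(truth: PlantedTruth) -> pd.DataFrame:
    """Noiseless retention table implied by the planted gene classes."""
    rows = []
    for gene, cls in truth.gene_class.items():
        if cls.startswith("memory"):
            rows.append((gene, cls.rsplit("_", 1)[1], "memory"))
        elif cls.startswith("restored"):
            rows.append((gene, cls.rsplit("_", 1)[1], "restored"))
    return pd.DataFrame(rows, columns=["gene", "direction", "status"])


def truth_epigenome_map(truth: PlantedTruth) -> dict:
    """Noiseless gene epigenome map implied by the planted links."""
    cls = truth.region_class.set_index(["modality", "region_id"])["class"]
    gmap = {}
    for gene, links in (truth.explanation_link or {}).items():
        for modality, rid in links:
            locus = "promoter" if rid.startswith("pr_") else "enhancer"
            direction = "gain" if cls.loc[(modality, rid)].startswith("gain") else "loss"
            gmap.setdefault(gene, set()).add((modality, locus, direction))
    return gmap


# ---------------------------------------------------------------------------
# binned mark tracks

def simulate_binned_tracks(config: SimConfig, promoters: RegionSet):
    """Binary 200-bp-binned mark states with known enhancer bins.

    Plants enhancer runs (H3K4me1 + H3K27ac + ATAC, no H3K4me3, outside
    promoters), decoy runs that violate exactly one clause of the rule, and a
    sparse random background per mark. The returned truth set contains exactly
    the bins that satisfy the full conjunction, computed from the final track.

    Returns ``(bins, enhancer_bins)``: a sparse bin table (chrom, start, one
    0/1 column per modality; bins with no mark are omitted) and the truth set
    of (chrom, bin_start) pairs.
    """
    if config.chrom_length % config.bin_size != 0:
        raise ValueError("bin_size must divide chrom_length")
    rng = _rng(config, 4)
    bs = config.bin_size
    nb_per_chrom = config.chrom_length // bs
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    total_bins = nb_per_chrom * config.n_chroms

    marks = {m: set() for m in MODALITIES}

    def set_run(global_bin, length, mods):
        for k in range(length):
            b = global_bin + k
            if b >= total_bins:
                break
            for m in mods:
                marks[m].add(b)

    n = config.n_enhancer_runs
    starts = rng.integers(0, total_bins, size=n)
    lengths = rng.integers(1, 4, size=n)
    for s, L in zip(starts, lengths):
        set_run(int(s), int(L), ("H3K4me1", "H3K27ac", "ATAC"))
    # decoys: same combination plus H3K4me3 (disqualified)
    for s, L in zip(rng.integers(0, total_bins, size=n // 3),
                    rng.integers(1, 4, size=n // 3)):
        set_run(int(s), int(L), ("H3K4me1", "H3K27ac", "ATAC", "H3K4me3"))
    # decoys: partial combinations
    for s in rng.integers(0, total_bins, size=n):
        set_run(int(s), 1, ("H3K4me1", "H3K27ac"))
    # decoys inside promoter windows: full enhancer combination
    pdf = promoters.df
    if len(pdf):
        for _ in range(n // 3):
            row = pdf.iloc[int(rng.integers(0, len(pdf)))]
            ci = chrom_names.index(row["chrom"])
            b = ci * nb_per_chrom + int(row["start"] + bs) // bs
            set_run(b, 1, ("H3K4me1", "H3K27ac", "ATAC"))
    # sparse independent background per mark
    for m in MODALITIES:
        k = int(config.mark_density * total_bins)
        marks[m].update(int(b) for b in rng.integers(0, total_bins, size=k))

    used = sorted(set().union(*marks.values()))
    chrom_col = [chrom_names[b // nb_per_chrom] for b in used]
    start_col = [(b % nb_per_chrom) * bs for b in used]
    bins = pd.DataFrame({"chrom": chrom_col, "start": start_col})
    for m in MODALITIES:
        bins[m] = [1 if b in marks[m] else 0 for b in used]

    # promoter overlap per bin (>= 1 bp with any promoter window)
    in_promoter = np.zeros(len(bins), dtype=bool)
    prom_by_chrom = {c: sub for c, sub in pdf.groupby("chrom")} if len(pdf) else {}
    for i, (c, s) in enumerate(zip(bins["chrom"], bins["start"])):
        sub = prom_by_chrom.get(c)
        if sub is None:
            continue
        if np.any((sub["start"].to_numpy() < s + bs) & (sub["end"].to_numpy() > s)):
            in_promoter[i] = True

    ok = ((bins["H3K4me1"] == 1) & (bins["H3K27ac"] == 1) & (bins["ATAC"] == 1)
          & (bins["H3K4me3"] == 0) & ~in_promoter)
    enhancer_bins = set(zip(bins.loc[ok, "chrom"], bins.loc[ok, "start"]))
    return bins, enhancer_bins


# ---------------------------------------------------------------------------
# orchestration and fixture I/O

@dataclass
class SimBundle:
    """Everything one simulated study produces."""

    config: SimConfig
    genes: pd.DataFrame
    sn_counts: sparse.csr_matrix
    cells: pd.DataFrame
    region_counts: dict
    regions: pd.DataFrame
    samples: pd.DataFrame
    bins: pd.DataFrame
    truth: PlantedTruth
    promoters: RegionSet
    blacklist: RegionSet


def _simulate_blacklist(config: SimConfig, genes: pd.DataFrame) -> RegionSet:
    """A handful of intergenic problem regions (repeat-like artefacts)."""
    rng = _rng(config, 5)
    rows = []
    for _ in range(20):
        ci = int(rng.integers(0, config.n_chroms))
        start = int(rng.integers(0, config.chrom_length - 5000))
        rows.append((f"chr{ci + 1}", start, start + int(rng.integers(500, 5001))))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                     genome_size=config.n_chroms * config.chrom_length)


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator stage in a fixed order."""
    genes = simulate_gene_annotation(config)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    promoters = make_promoters(genes, flank=2000, chrom_sizes=chrom_sizes)
    sn_counts, cells, truth_g = simulate_sn_counts(config, genes)
    region_counts, regions, samples, truth_r = simulate_region_counts(config, genes)
    bins, enhancer_bins = simulate_binned_tracks(config, promoters)
    truth = truth_g.merge(truth_r)
    truth.enhancer_bins = enhancer_bins
    return SimBundle(config=config, genes=genes, sn_counts=sn_counts, cells=cells,
                     region_counts=region_counts, regions=regions, samples=samples,
                     bins=bins, truth=truth, promoters=promoters,
                     blacklist=_simulate_blacklist(config, genes))


def write_fixture_bundle(bundle: SimBundle, directory) -> None:
    """Write the bundle as plain-text fixtures (MTX/TSV/BED/YAML)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(d / "config.yaml")
    bundle.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    spio.mmwrite(d / "sn_counts.mtx", bundle.sn_counts.astype(np.int64))
    bundle.cells.to_csv(d / "cells.tsv", sep="\t", index=False)
    bundle.regions.to_csv(d / "regions.tsv", sep="\t", index=False)
    bundle.samples.to_csv(d / "samples.tsv", sep="\t", index=False)
    for m, df in bundle.region_counts.items():
        df.to_csv(d / f"region_counts_{m}.tsv", sep="\t")
    bundle.bins.to_csv(d / "binned_tracks.tsv", sep="\t", index=False)
    write_bed(bundle.promoters, d / "promoters.bed")
    write_bed(bundle.blacklist, d / "blacklist.bed")
    t = bundle.truth
    t.gene_class.rename_axis("gene_id").reset_index().to_csv(
        d / "truth_genes.tsv", sep="\t", index=False)
    t.region_class.to_csv(d / "truth_regions.tsv", sep="\t", index=False)
    for name, links in (("explanation", t.explanation_link),
                        ("rebound", t.rebound_link)):
        rows = [(g, m, r) for g in sorted(links or {})
                for (m, r) in sorted(links[g])]
        pd.DataFrame(rows, columns=["gene_id", "modality", "region_id"]).to_csv(
            d / f"truth_{name}_links.tsv", sep="\t", index=False)
    rows = sorted(t.enhancer_bins or set())
    pd.DataFrame(
        {"chrom": [r[0] for r in rows],
         "start": [r[1] for r in rows],
         "end": [r[1] + bundle.config.bin_size for r in rows]}
    ).to_csv(d / "truth_enhancer_bins.bed", sep="\t", header=False, index=False)


def read_fixture_bundle(directory) -> SimBundle:
    """Read back a fixture bundle written by :func:`write_fixture_bundle`."""
    d = Path(directory)
    config = SimConfig.from_yaml(d / "config.yaml")
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    sn_counts = sparse.csr_matrix(spio.mmread(d / "sn_counts.mtx")).astype(np.int64)
    cells = pd.read_csv(d / "cells.tsv", sep="\t")
    regions = pd.read_csv(d / "regions.tsv", sep="\t")
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    region_counts = {m: pd.read_csv(d / f"region_counts_{m}.tsv", sep="\t",
                                    index_col=0)
                     for m in MODALITIES}
    bins = pd.read_csv(d / "binned_tracks.tsv", sep="\t")
    promoters = read_bed(d / "promoters.bed")
    blacklist = read_bed(d / "blacklist.bed")
    gene_class = pd.read_csv(d / "truth_genes.tsv", sep="\t",
                             keep_default_na=False).set_index(
        "gene_id")["gene_class"]
    region_class = pd.read_csv(d / "truth_regions.tsv", sep="\t")
    links = {}
    for name in ("explanation", "rebound"):
        df = pd.read_csv(d / f"truth_{name}_links.tsv", sep="\t")
        links[name] = {}
        for g, m, r in df.itertuples(index=False):
            links[name].setdefault(g, set()).add((m, r))
    eb = pd.read_csv(d / "truth_enhancer_bins.bed", sep="\t", header=None,
                     names=["chrom", "start", "end"])
    truth = PlantedTruth(gene_class=gene_class, region_class=region_class,
                         explanation_link=links["explanation"],
                         rebound_link=links["rebound"],
                         enhancer_bins=set(zip(eb["chrom"], eb["start"])))
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chroms)}
    del chrom_sizes
    return SimBundle(config=config, genes=genes, sn_counts=sn_counts, cells=cells,
                     region_counts=region_counts, regions=regions, samples=samples,
                     bins=bins, truth=truth, promoters=promoters,
                     blacklist=blacklist)
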