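"""Genomic interval arithmetic: promoters, overlaps, blacklist filtering,
fold enrichment and region-to-gene linkage.

All coordinates are 0-based, half-open (BED convention). A gene's TSS is
``start`` on the + strand and ``end - 1`` on the - strand, so the TSS is
always a base inside the gene body. Interval sets are held as sorted pandas
DataFrames wrapped by :class:`RegionSet`; set operations (merge, intersect,
subtract-by-overlap) run on numpy arrays with a per-chromosome sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "make_gene_table",
    "make_promoters",
    "overlap_bp",
    "fold_enrichment",
    "filter_blacklist",
    "union_regions",
    "link_regions_to_genes",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class RegionSet:
    """An ordered collection of genomic intervals on one genome.

    Parameters
    ----------
    df : DataFrame with at least ``chrom``, ``start``, ``end`` columns
        (optionally ``name``, ``score``, ``strand``).
    genome_size : total genome length in bp, if known; required only by
        :func:`fold_enrichment` when not passed explicitly.
    """

    df: pd.DataFrame
    genome_size: int | None = field(default=None)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df).copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"RegionSet requires a '{col}' column")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative interval start")
            if (df["start"] >= df["end"]).any():
                raise ValueError("interval with start >= end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    @classmethod
    def from_arrays(cls, chrom, start, end, genome_size=None, **extra) -> "RegionSet":
        data = {"chrom": chrom, "start": start, "end": end, **extra}
        return cls(pd.DataFrame(data), genome_size=genome_size)

    def total_bp(self) -> int:
        """Total covered bp, counting overlapping bases once."""
        m = self.merged()
        return int((m.df["end"] - m.df["start"]).sum())

    def merged(self, gap: int = 0) -> "RegionSet":
        """Merge intervals that overlap or lie within ``gap`` bp of each other.

        With ``gap=0`` abutting intervals are merged too, so output intervals
        neither overlap nor abut.
        """
        if not len(self.df):
            return RegionSet(self.df.iloc[:0][["chrom", "start", "end"]],
                             genome_size=self.genome_size)
        out_c, out_s, out_e = [], [], []
        for chrom, sub in self.df.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e + gap:
                    cur_e = max(cur_e, e)
                else:
                    out_c.append(chrom)
                    out_s.append(cur_s)
                    out_e.append(cur_e)
                    cur_s, cur_e = s, e
            out_c.append(chrom)
            out_s.append(cur_s)
            out_e.append(cur_e)
        return RegionSet.from_arrays(out_c, out_s, out_e, genome_size=self.genome_size)


def make_gene_table(gene_id, chrom, start, end, strand) -> pd.DataFrame:
    """Build a gene-model table with a strand-aware TSS column.

    TSS = ``start`` for + strand genes, ``end - 1`` for - strand genes, so
    the TSS always lies within ``[start, end)``.
    """
    df = pd.DataFrame({
        "gene_id": gene_id,
        "chrom": chrom,
        "start": np.asarray(start, dtype=np.int64),
        "end": np.asarray(end, dtype=np.int64),
        "strand": strand,
    })
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene with start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def make_promoters(genes: pd.DataFrame, flank: int = 2000,
                   chrom_sizes: dict[str, int] | None = None) -> RegionSet:
    """Promoter windows: ``[tss - flank, tss + flank)`` per gene, clipped to
    chromosome bounds.

    The default ``flank=2000`` gives the conventional +/-2 kb TSS window.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = np.maximum(genes["tss"].to_numpy() - flank, 0)
    end = genes["tss"].to_numpy() + flank
    if chrom_sizes is not None:
        limits = genes["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    return RegionSet.from_arrays(genes["chrom"], start, end,
                                 name=genes["gene_id"].to_numpy(),
                                 strand=genes["strand"].to_numpy())


def _intersections(a: RegionSet, b: RegionSet) -> pd.DataFrame:
    """Per-pair overlap table between raw (unmerged) interval lists."""
    rows = []
    b_by_chrom = {c: sub for c, sub in b.df.groupby("chrom")}
    for c, sub_a in a.df.groupby("chrom"):
        sub_b = b_by_chrom.get(c)
        if sub_b is None:
            continue
        as_, ae = sub_a["start"].to_numpy(), sub_a["end"].to_numpy()
        bs, be = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        for ia, (s1, e1) in zip(sub_a.index, zip(as_, ae)):
            lo = np.maximum(bs, s1)
            hi = np.minimum(be, e1)
            hit = lo < hi
            for ib, bp in zip(sub_b.index[hit], (hi - lo)[hit]):
                rows.append((ia, ib, int(bp)))
    return pd.DataFrame(rows, columns=["index_a", "index_b", "bp"])


def overlap_bp(a: RegionSet, b: RegionSet) -> tuple[int, pd.DataFrame]:
    """Total overlapping bp between two interval sets, plus a per-pair table.

    The total is computed on the merged sets, so bases covered by several
    intervals in either set are counted once; the operation is symmetric.
    """
    am, bm = a.merged(), b.merged()
    total = 0
    b_by_chrom = {c: sub for c, sub in bm.df.groupby("chrom")}
    for c, sub_a in am.df.groupby("chrom"):
        sub_b = b_by_chrom.get(c)
        if sub_b is None:
            continue
        bs, be = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        for s1, e1 in zip(sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            lo = np.maximum(bs, s1)
            hi = np.minimum(be, e1)
            total += int(np.maximum(hi - lo, 0).sum())
    return total, _intersections(a, b)


def fold_enrichment(peaks: RegionSet, feature: RegionSet,
                    genome_size: int | None = None) -> float:
    """Fold enrichment of peak/feature overlap over random expectation:

        sum(bp overlap) * genome_size / (sum(bp peaks) * sum(bp feature))

    A value > 1 means the two sets overlap more than expected if both were
    placed uniformly at random on the genome. Symmetric in its arguments.
    """
    if genome_size is None:
        genome_size = peaks.genome_size or feature.genome_size
    if genome_size is None:
        raise ValueError("genome_size is required")
    bp_peaks = peaks.total_bp()
    bp_feature = feature.total_bp()
    if bp_peaks == 0 or bp_feature == 0:
        raise ValueError("fold enrichment undefined for an empty interval set")
    ov, _ = overlap_bp(peaks, feature)
    return ov * genome_size / (bp_peaks * bp_feature)


def filter_blacklist(peaks: RegionSet, blacklist: RegionSet) -> RegionSet:
    """Drop every peak overlapping a blacklist interval by >= 1 bp."""
    if not len(blacklist) or not len(peaks):
        return RegionSet(peaks.df, genome_size=peaks.genome_size)
    bl = blacklist.merged()
    keep = np.ones(len(peaks.df), dtype=bool)
    bl_by_chrom = {c: sub for c, sub in bl.df.groupby("chrom")}
    for c, sub in peaks.df.groupby("chrom"):
        sub_b = bl_by_chrom.get(c)
        if sub_b is None:
            continue
        bs, be = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        for i, s1, e1 in zip(sub.index, sub["start"].to_numpy(), sub["end"].to_numpy()):
            if np.any((np.maximum(bs, s1) < np.minimum(be, e1))):
                keep[i] = False
    return RegionSet(peaks.df[keep], genome_size=peaks.genome_size)


def union_regions(sets: list[RegionSet]) -> RegionSet:
    """Union of several interval sets as a merged, non-overlapping list."""
    frames = [s.df[["chrom", "start", "end"]] for s in sets if len(s)]
    genome_size = next((s.genome_size for s in sets if s.genome_size), None)
    if not frames:
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        return RegionSet(empty, genome_size=genome_size)
    cat = pd.concat(frames, ignore_index=True)
    return RegionSet(cat, genome_size=genome_size).merged()


def _interval_gap(r_start, r_end, g_start, g_end):
    """Gap in bp between half-open intervals; 0 if they overlap or abut."""
    return np.maximum(0, np.maximum(g_start - r_end, r_start - g_end))


def link_regions_to_genes(regions: RegionSet, genes: pd.DataFrame,
                          max_dist: int = 20000) -> pd.DataFrame:
    """Assign each region to its closest gene within ``max_dist`` bp.

    Distance to a gene is 0 when the region overlaps the gene body, else the
    smaller of the edge-to-edge gaps to the gene body and to the TSS. Regions
    farther than ``max_dist`` from every gene are left out of the table. Ties
    are broken by the lexicographically smaller gene_id.

    Returns a DataFrame with columns region_index (row index into
    ``regions.df``), region_id (the interval's name when present), chrom,
    start, end, gene_id, distance.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    has_name = "name" in regions.df.columns
    rows = []
    genes_by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for c, sub in regions.df.groupby("chrom"):
        g = genes_by_chrom.get(c)
        if g is None:
            continue
        gs, ge = g["start"].to_numpy(), g["end"].to_numpy()
        tss = g["tss"].to_numpy()
        gid = g["gene_id"].to_numpy()
        for i, s, e in zip(sub.index, sub["start"].to_numpy(), sub["end"].to_numpy()):
            d_body = _interval_gap(s, e, gs, ge)
            d_tss = _interval_gap(s, e, tss, tss + 1)
            d = np.minimum(d_body, d_tss)
            dmin = d.min()
            if dmin > max_dist:
                continue
            cands = gid[d == dmin]
            rid = regions.df.loc[i, "name"] if has_name else i
            rows.append((i, rid, c, int(s), int(e), sorted(cands)[0], int(dmin)))
    return pd.DataFrame(
        rows, columns=["region_index", "region_id", "chrom", "start", "end",
                       "gene_id", "distance"]
    )


def read_bed(path) -> RegionSet:
    """Read a BED3/BED6 file (0-based, half-open).

    Header/``track``/``browser``/comment lines are skipped with a warning.
    Malformed lines raise with the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                warnings.warn(f"{path}:{lineno}: skipping header/track line")
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=_BED_COLS)
    return RegionSet(df)


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED (BED6 when name/score/strand are present)."""
    df = regions.df
    cols = ["chrom", "start", "end"]
    if any(c in df.columns for c in ("name", "score", "strand")):
        df = df.copy()
        for c, default in (("name", "."), ("score", "."), ("strand", ".")):
            if c not in df.columns:
                df[c] = default
        cols = _BED_COLS
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom-sizes TSV -> {chrom: length}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))
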