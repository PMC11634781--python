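"""Region-level memory: rule-based enhancer calling and trajectory classes.

An enhancer is a non-promoter region marked by H3K4me1 and H3K27ac and open
by ATAC, without H3K4me3 — the mark-combination rule applied directly to
200-bp genome bins. Trajectory classes describe how a region's differential
status evolves from the obese contrast to the weight-loss contrast; a region
that gained H3K4me1 in obesity and kept it after weight loss is a "new
enhancer".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regions import RegionSet, filter_blacklist

__all__ = [
    "call_enhancers_by_rule",
    "classify_trajectory",
    "acetylation_status",
    "TRAJECTORY_CLASSES",
]

TRAJECTORY_CLASSES = ("gained_maintained", "gained_lost", "lost_maintained",
                      "lost_regained", "wl_only_gain", "wl_only_loss", "stable")

_RULE = {
    ("up", "up"): "gained_maintained",
    ("up", "ns"): "gained_lost",
    ("down", "down"): "lost_maintained",
    ("down", "ns"): "lost_regained",
    ("ns", "up"): "wl_only_gain",
    ("ns", "down"): "wl_only_loss",
    ("ns", "ns"): "stable",
    ("up", "down"): "reversal",
    ("down", "up"): "reversal",
}


def call_enhancers_by_rule(bins: pd.DataFrame, promoters: RegionSet,
                           merge_gap: int = 0, bin_size: int = 200) -> RegionSet:
    """Select enhancer bins by the mark-combination rule and merge them.

    ``bins`` is a (possibly sparse) bin table with columns chrom, start and
    one 0/1 column per modality; bins absent from the table carry no mark.
    Qualifying bins (H3K4me1=1, H3K27ac=1, ATAC=1, H3K4me3=0) are merged when
    separated by at most ``merge_gap`` unqualified bins, and any merged
    interval overlapping a promoter window by >= 1 bp is removed.
    """
    ok = ((bins["H3K4me1"] == 1) & (bins["H3K27ac"] == 1)
          & (bins["ATAC"] == 1) & (bins["H3K4me3"] == 0))
    sel = bins.loc[ok, ["chrom", "start"]].copy()
    sel["end"] = sel["start"] + bin_size
    cand = RegionSet(sel).merged(gap=merge_gap * bin_size)
    return filter_blacklist(cand, promoters)


def classify_trajectory(diff_obese: pd.DataFrame,
                        diff_wl: pd.DataFrame) -> pd.DataFrame:
    """Map each region's (obese-vs-control, WL-vs-control) call pair to a
    trajectory class.

    (up, up) gained_maintained; (up, ns) gained_lost; (down, down)
    lost_maintained; (down, ns) lost_regained; (ns, up/down) wl_only_gain/
    loss; (ns, ns) stable. Direction reversals are flagged separately rather
    than forced into a class.
    """
    if set(diff_obese["feature"]) != set(diff_wl["feature"]):
        raise ValueError("diff tables cover different region universes")
    wl = diff_wl.set_index("feature")["call"]
    rows = []
    for feat, ob in zip(diff_obese["feature"], diff_obese["call"]):
        cls = _RULE[(ob, wl.loc[feat])]
        rows.append((feat, ob, wl.loc[feat], cls, cls == "reversal"))
    return pd.DataFrame(rows, columns=["region", "obese_call", "wl_call",
                                       "class", "reversal"])


def acetylation_status(enhancers: RegionSet,
                       h3k27ac_peaks: dict[str, RegionSet]) -> pd.DataFrame:
    """Per-enhancer, per-condition activity: an enhancer is active in a
    condition iff it overlaps (>= 1 bp) an H3K27ac peak of that condition."""
    out = enhancers.df[["chrom", "start", "end"]].copy()
    for cond, peaks in h3k27ac_peaks.items():
        active = np.zeros(len(out), dtype=bool)
        by_chrom = {c: sub for c, sub in peaks.df.groupby("chrom")}
        for i, (c, s, e) in enumerate(zip(out["chrom"], out["start"], out["end"])):
            sub = by_chrom.get(c)
            if sub is None:
                continue
            ps, pe = sub["start"].to_numpy(), sub["end"].to_numpy()
            active[i] = bool(np.any((np.maximum(ps, s) < np.minimum(pe, e))))
        out[cond] = active
    return out
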