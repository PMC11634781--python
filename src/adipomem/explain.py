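"""Multi-modality epigenetic explanation of persistent and rebound DEGs.

Persistent promoter or enhancer alterations are collected per gene into a
GeneEpigenomeMap; a memory DEG is *explained* when at least one persistent
entry exists at its promoter or at an enhancer linked to it (``any_modality``
mode) or when an entry's direction is consistent with the expression change
(``direction_consistent`` mode: gains of activating marks / losses of
H3K27me3 explain up-regulation, and the mirror image explains
down-regulation). Rebound DEGs after renewed high-fat exposure are
additionally attributed to their prior DEG status and to transcriptional
memory; the three sources are non-exclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .memory import STATUS_MEMORY

__all__ = [
    "build_gene_epigenome_map",
    "explain_memory_degs",
    "explain_rebound_degs",
]

REPRESSIVE_MARKS = frozenset({"H3K27me3"})


def _persistent_direction(obese_call: str, wl_call: str, persistence: str):
    """Direction ('gain'/'loss') of a persistent entry, or None."""
    if persistence == "obese_and_wl":
        if obese_call != "ns" and obese_call == wl_call:
            return "gain" if obese_call == "up" else "loss"
        return None
    if persistence == "wl_only":
        if wl_call != "ns":
            return "gain" if wl_call == "up" else "loss"
        return None
    raise ValueError(f"unknown persistence mode {persistence!r}")


def build_gene_epigenome_map(promoter_diffs: dict, enhancer_diffs: dict,
                             linkage: pd.DataFrame,
                             persistence: str = "obese_and_wl",
                             modalities=None) -> dict:
    """Collect persistent differential entries per gene.

    Parameters
    ----------
    promoter_diffs : modality -> (diff_obese, diff_wl) DiffResult pair whose
        features are gene ids (promoter counts aggregated at gene level).
    enhancer_diffs : modality -> (diff_obese, diff_wl) pair whose features
        are enhancer region ids.
    linkage : DataFrame with columns region_id and gene_id assigning each
        enhancer to at most one gene.
    persistence : 'obese_and_wl' requires the same significant direction in
        both contrasts; 'wl_only' requires significance in the WL contrast.

    Returns {gene: {(modality, locus_type, direction), ...}}.
    """
    if modalities is not None:
        missing = set(modalities) - set(promoter_diffs)
        if missing:
            raise ValueError(f"missing promoter diff tables: {sorted(missing)}")
        missing = set(modalities) - set(enhancer_diffs)
        if missing:
            raise ValueError(f"missing enhancer diff tables: {sorted(missing)}")
        promoter_diffs = {m: promoter_diffs[m] for m in modalities}
        enhancer_diffs = {m: enhancer_diffs[m] for m in modalities}
    gmap: dict = {}
    for modality, (d_ob, d_wl) in promoter_diffs.items():
        wl = d_wl.set_index("feature")["call"]
        for gene, ob_call in zip(d_ob["feature"], d_ob["call"]):
            direction = _persistent_direction(ob_call, wl.loc[gene], persistence)
            if direction is not None:
                gmap.setdefault(gene, set()).add((modality, "promoter", direction))
    region_gene = linkage.set_index("region_id")["gene_id"]
    for modality, (d_ob, d_wl) in enhancer_diffs.items():
        wl = d_wl.set_index("feature")["call"]
        for rid, ob_call in zip(d_ob["feature"], d_ob["call"]):
            if rid not in region_gene.index:
                continue  # unlinked enhancers explain nothing
            direction = _persistent_direction(ob_call, wl.loc[rid], persistence)
            if direction is not None:
                gmap.setdefault(region_gene.loc[rid], set()).add(
                    (modality, "enhancer", direction))
    return gmap


def _entry_supports(entry, deg_direction: str) -> bool:
    modality, _locus, direction = entry
    if deg_direction == "up":
        return direction == ("loss" if modality in REPRESSIVE_MARKS else "gain")
    return direction == ("gain" if modality in REPRESSIVE_MARKS else "loss")


def _supporting(entries, deg_direction: str, mode: str):
    if mode == "any_modality":
        return set(entries)
    if mode == "direction_consistent":
        return {e for e in entries if _entry_supports(e, deg_direction)}
    raise ValueError(f"unknown mode {mode!r}")


def _fractions(records: pd.DataFrame, flag: str) -> pd.DataFrame:
    rows = []
    for direction, sub in records.groupby("deg_direction", sort=True):
        n = len(sub)
        k = int(sub[flag].sum())
        rows.append((direction, k, n, k / n if n else np.nan))
    return pd.DataFrame(rows, columns=["deg_direction", "n_explained",
                                       "n_total", "fraction"])


def explain_memory_degs(memory_calls: pd.DataFrame, gmap: dict,
                        mode: str = "any_modality"):
    """Which memory DEGs carry a persistent epigenetic alteration?

    ``memory_calls`` is a retention table; only rows with status 'memory'
    are considered. Returns (records, fractions): per-gene ExplanationRecords
    with their supporting entries, and the explained fraction per direction.
    """
    mem = memory_calls[memory_calls["status"] == STATUS_MEMORY]
    rows = []
    for gene, direction in zip(mem["gene"], mem["direction"]):
        support = _supporting(gmap.get(gene, set()), direction, mode)
        rows.append((gene, direction, len(support) > 0,
                     ";".join(sorted("|".join(e) for e in support))))
    records = pd.DataFrame(rows, columns=["gene", "deg_direction", "explained",
                                          "support"])
    return records, _fractions(records, "explained")


def explain_rebound_degs(hch_degs: pd.DataFrame, hc_degs: pd.DataFrame,
                         memory_calls: pd.DataFrame, gmap: dict,
                         mode: str = "any_modality"):
    """Attribute rebound DEGs (renewed HFD exposure vs its control) to three
    non-exclusive sources.

    Per rebound DEG: ``prior_deg_status`` — same-direction DEG at the
    weight-loss time point; ``transcriptional_memory`` — classified memory at
    weight loss; ``epigenetic`` — persistent differential mark at the
    promoter or a linked enhancer (per ``gmap``/``mode``). Returns
    (records, fractions) with one fraction table row per source x direction.
    """
    for name, df in (("hch_degs", hch_degs), ("hc_degs", hc_degs)):
        if df is None or not len(df):
            raise ValueError(f"{name} is required")
    hc = hc_degs.set_index("feature")["call"]
    mem_status = memory_calls.set_index("gene")["status"] if len(memory_calls) else pd.Series(dtype=object)
    rows = []
    for gene, call in zip(hch_degs["feature"], hch_degs["call"]):
        if call == "ns":
            continue
        prior = gene in hc.index and hc.loc[gene] == call
        memory = gene in mem_status.index and mem_status.loc[gene] == STATUS_MEMORY
        support = _supporting(gmap.get(gene, set()), call, mode)
        rows.append((gene, call, bool(prior), bool(memory), len(support) > 0,
                     ";".join(sorted("|".join(e) for e in support))))
    records = pd.DataFrame(rows, columns=["gene", "deg_direction",
                                          "prior_deg_status",
                                          "transcriptional_memory",
                                          "epigenetic", "support"])
    fracs = []
    for source in ("prior_deg_status", "transcriptional_memory", "epigenetic"):
        f = _fractions(records, source)
        f.insert(0, "source", source)
        fracs.append(f)
    return records, pd.concat(fracs, ignore_index=True)
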