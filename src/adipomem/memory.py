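"""Transcriptional-retention classification.

A gene that is differentially expressed in the obese state is *restored* when
it is no longer deregulated after weight loss (versus the age-matched
control), and part of a *transcriptional memory* when it stays deregulated in
the same direction. Direction reversals are kept apart as ``sign_flip`` so
they cannot inflate retention; genes deregulated only after weight loss are
reported as ``wl_only`` and excluded from retention denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "classify_retention",
    "retention_proportions",
    "classify_patterns",
    "STATUS_MEMORY",
    "STATUS_RESTORED",
    "STATUS_SIGN_FLIP",
    "STATUS_WL_ONLY",
]

STATUS_MEMORY = "memory"
STATUS_RESTORED = "restored"
STATUS_SIGN_FLIP = "sign_flip"
STATUS_WL_ONLY = "wl_only"


def _check_universe(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if set(a["feature"]) != set(b["feature"]):
        raise ValueError("DEG tables cover different feature universes")


def classify_retention(deg_obese: pd.DataFrame, deg_wl: pd.DataFrame,
                       cell_type: str | None = None) -> pd.DataFrame:
    """Overlay obese-vs-control and WL-vs-control DEG calls per gene.

    Both inputs are DiffResult tables (columns feature, log2fc, p, p_adj,
    call) over the same feature universe. For each obese DEG the WL call
    decides the status: ns -> restored, same direction -> memory, opposite
    direction -> sign_flip. Genes that are DEGs only in the WL contrast get
    status wl_only (direction taken from the WL call).
    """
    _check_universe(deg_obese, deg_wl)
    wl = deg_wl.set_index("feature")["call"]
    rows = []
    for feat, ob_call in zip(deg_obese["feature"], deg_obese["call"]):
        wl_call = wl.loc[feat]
        if ob_call == "ns":
            if wl_call != "ns":
                rows.append((feat, wl_call, STATUS_WL_ONLY, ob_call, wl_call))
            continue
        if wl_call == "ns":
            status = STATUS_RESTORED
        elif wl_call == ob_call:
            status = STATUS_MEMORY
        else:
            status = STATUS_SIGN_FLIP
        rows.append((feat, ob_call, status, ob_call, wl_call))
    out = pd.DataFrame(rows, columns=["gene", "direction", "status",
                                      "obese_call", "wl_call"])
    if cell_type is not None:
        out.insert(1, "cell_type", cell_type)
    return out


def retention_proportions(calls: pd.DataFrame, cell_counts: dict | None = None,
                          min_cells_per_group: int = 30) -> pd.DataFrame:
    """Proportion of retained (memory) changes per cell type and direction.

    proportion = n_memory / (n_memory + n_restored); sign_flip and wl_only
    calls are excluded from the denominator. Cell types with fewer than
    ``min_cells_per_group`` cells in any donor group (per ``cell_counts``,
    a mapping cell_type -> minimum per-donor cell count) are dropped.
    A cell type/direction with no obese DEGs gets a missing proportion.
    """
    df = calls.copy()
    if "cell_type" not in df.columns:
        df["cell_type"] = "all"
    if cell_counts is not None:
        ok = {ct for ct, n in cell_counts.items() if n >= min_cells_per_group}
        df = df[df["cell_type"].isin(ok)]
    rows = []
    for (ct, direction), sub in df.groupby(["cell_type", "direction"], sort=True):
        n_mem = int((sub["status"] == STATUS_MEMORY).sum())
        n_res = int((sub["status"] == STATUS_RESTORED).sum())
        denom = n_mem + n_res
        prop = n_mem / denom if denom else np.nan
        rows.append((ct, direction, n_mem, n_res, prop))
    return pd.DataFrame(rows, columns=["cell_type", "direction", "n_memory",
                                       "n_restored", "proportion"])


_PATTERNS = {
    (STATUS_MEMORY, STATUS_MEMORY): "not_restored_both",
    (STATUS_RESTORED, STATUS_MEMORY): "restored_HC_only",
    (STATUS_RESTORED, STATUS_RESTORED): "restored_both",
    (STATUS_MEMORY, STATUS_RESTORED): "restored_HHC_only",
}


def classify_patterns(deg_h: pd.DataFrame, deg_hc: pd.DataFrame,
                      deg_hh: pd.DataFrame, deg_hhc: pd.DataFrame) -> pd.DataFrame:
    """Cross-arm restoration patterns for genes deregulated in both obesity
    arms (short H and long HH exposure).

    Per arm the WL status follows the retention rule; the pattern combines
    the two arms: not restored in either, restored only after the short
    exposure, restored in both, restored only after the long exposure, or
    'other' (any direction reversal).
    """
    for d in (deg_hc, deg_hh, deg_hhc):
        _check_universe(deg_h, d)
    arm1 = classify_retention(deg_h, deg_hc).set_index("gene")
    arm2 = classify_retention(deg_hh, deg_hhc).set_index("gene")
    genes = sorted(
        set(arm1.index[arm1["status"] != STATUS_WL_ONLY])
        & set(arm2.index[arm2["status"] != STATUS_WL_ONLY]))
    rows = []
    for g in genes:
        s1, s2 = arm1.loc[g, "status"], arm2.loc[g, "status"]
        rows.append((g, _PATTERNS.get((s1, s2), "other"), s1, s2))
    return pd.DataFrame(rows, columns=["gene", "pattern", "status_HC", "status_HHC"])
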