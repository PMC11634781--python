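"""Differential statistics implemented from first principles.

Covers the contrasts used throughout the pipeline:

* single-nucleus DEG calling: counts-per-10k log normalization, two-sided
  Wilcoxon rank-sum test (exact enumeration for small groups, tie- and
  continuity-corrected normal approximation otherwise), Bonferroni/BH
  adjustment, and |log2FC| + adjusted-P calls;
* replicate-level region/bulk counts: median-of-ratios size factors, a
  method-of-moments common negative-binomial dispersion, and an
  exact-conditional NB test (conditioning each feature on its total
  normalized count across both groups);
* Pearson correlation of a sample against an averaged healthy control.

Matrices are features x samples (genes x cells, regions x replicates)
throughout this module.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln
from scipy.stats import norm, rankdata

__all__ = [
    "qc_filter_cells",
    "lognormalize",
    "log2fc",
    "wilcoxon_rank_sum",
    "wilcoxon_deg",
    "adjust_pvalues",
    "size_factors_median_of_ratios",
    "estimate_common_dispersion",
    "nb_exact_test",
    "correlation_to_reference",
    "make_calls",
]

CALL_UP, CALL_DOWN, CALL_NS = "up", "down", "ns"


# ---------------------------------------------------------------------------
# single-cell QC and normalization

def qc_filter_cells(counts, min_features: int = 500, max_features: int = 3000,
                    max_umi: int = 40000):
    """Filter cells of a genes x cells count matrix on QC thresholds.

    Keeps cells with ``min_features <= detected genes <= max_features`` and
    total UMI ``<= max_umi`` (boundaries inclusive: only cells strictly below
    / above the stated limits are discarded).

    Returns ``(kept_mask, report)`` where report counts removals per rule.
    """
    if not (0 < min_features < max_features):
        raise ValueError("need 0 < min_features < max_features")
    if max_umi <= 0:
        raise ValueError("max_umi must be positive")
    X = counts
    if sparse.issparse(X):
        n_feat = np.asarray((X > 0).sum(axis=0)).ravel()
        umi = np.asarray(X.sum(axis=0)).ravel()
    else:
        X = np.asarray(X)
        n_feat = (X > 0).sum(axis=0)
        umi = X.sum(axis=0)
    low = n_feat < min_features
    high = n_feat > max_features
    deep = umi > max_umi
    keep = ~(low | high | deep)
    report = {
        "n_input": int(X.shape[1]),
        "n_kept": int(keep.sum()),
        "removed_low_features": int(low.sum()),
        "removed_high_features": int(high.sum()),
        "removed_high_umi": int(deep.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("QC filtering removed every cell")
    return keep, report


def lognormalize(counts, scale: float = 10000.0) -> np.ndarray:
    """Counts-per-``scale`` log1p normalization (natural log).

    value = log(1 + count * scale / cell_total). Cells with zero total are
    an error (they carry no information and would divide by zero).
    """
    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cell with zero total count; run QC filtering first")
    return np.log1p(X * (scale / totals))


def log2fc(norm, cells_a, cells_b, pseudocount: float = 1.0) -> np.ndarray:
    """Per-feature log2 fold change on de-logged normalized expression.

    log2((mean expm1(norm) over A + pseudocount) / (mean over B + pseudocount)).
    """
    A = np.expm1(norm[:, cells_a])
    B = np.expm1(norm[:, cells_b])
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    return np.log2((A.mean(axis=1) + pseudocount) / (B.mean(axis=1) + pseudocount))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def wilcoxon_rank_sum(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two samples.

    method='exact' enumerates all C(n, n_x) assignments of the pooled values
    to group x and reports the fraction whose rank sum deviates from its
    permutation mean at least as much as observed (ties handled naturally
    through midranks). method='normal' uses the tie-corrected normal
    approximation with a 0.5 continuity correction. 'auto' switches to exact
    when both groups have <= 8 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    if method == "auto":
        method = "exact" if max(n1, n2) <= 8 else "normal"
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = n1 + n2
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    if method == "exact":
        dev_obs = abs(w_obs - mu)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev_obs - 1e-9:
                hits += 1
        return hits / total
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def _wilcoxon_normal_matrix(X: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation p for each row of X,
    comparing columns [:n1] against [n1:]."""
    G, n = X.shape
    n2 = n - n1
    ranks = rankdata(X, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie = np.fromiter((_tie_term(X[g]) for g in range(G)), dtype=float, count=G)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros(G)
    ok = var > 0
    z[ok] = np.maximum(np.abs(w[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    p = 2.0 * norm.sf(z)
    p[~ok] = 1.0
    return np.minimum(p, 1.0)


def wilcoxon_deg(norm, cells_a, cells_b, features=None, lfc_threshold: float = 0.5,
                 alpha: float = 0.01, correction: str = "bonferroni",
                 method: str = "auto", pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum DEG table for group A vs group B.

    Returns a DataFrame (feature, log2fc, p, p_adj, call); call is 'up'/'down'
    when ``|log2fc| >= lfc_threshold`` and the adjusted p is below ``alpha``.
    """
    A = norm[:, cells_a]
    B = norm[:, cells_b]
    n1, n2 = A.shape[1], B.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 cells")
    X = np.concatenate([A, B], axis=1)
    if method == "auto":
        method = "exact" if max(n1, n2) <= 8 else "normal"
    if method == "exact":
        p = np.array([wilcoxon_rank_sum(X[g, :n1], X[g, n1:], method="exact")
                      for g in range(X.shape[0])])
    else:
        p = _wilcoxon_normal_matrix(X, n1)
    lfc = log2fc(norm, cells_a, cells_b, pseudocount=pseudocount)
    p_adj = adjust_pvalues(p, method=correction)
    call = make_calls(lfc, p_adj, lfc_threshold, alpha)
    feats = np.arange(X.shape[0]) if features is None else np.asarray(features)
    return pd.DataFrame({"feature": feats, "log2fc": lfc, "p": p,
                         "p_adj": p_adj, "call": call})


def make_calls(lfc: np.ndarray, p: np.ndarray, lfc_threshold: float,
               alpha: float) -> np.ndarray:
    """up/down/ns calls from fold changes and (adjusted) p-values."""
    call = np.full(len(lfc), CALL_NS, dtype=object)
    sig = p < alpha
    call[sig & (lfc >= lfc_threshold)] = CALL_UP
    call[sig & (lfc <= -lfc_threshold)] = CALL_DOWN
    return call


def adjust_pvalues(pvals, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (min(1, m*p)) or
    Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}")


# ---------------------------------------------------------------------------
# replicate-level NB machinery

def size_factors_median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (features x samples), scaled to
    geometric mean 1. Falls back to library-size ratios when no feature is
    positive in every sample."""
    X = np.asarray(counts, dtype=float)
    pos = (X > 0).all(axis=1)
    if pos.sum() == 0:
        lib = X.sum(axis=0)
        if np.any(lib <= 0):
            raise ValueError("sample with zero total count")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return sf
    logref = np.log(X[pos]).mean(axis=1)
    ratios = np.log(X[pos]) - logref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def estimate_common_dispersion(counts, groups) -> float:
    """Single common NB dispersion phi (Var = mu + phi*mu^2) by method of
    moments on size-factor-normalized counts, pooling (variance - mean)
    residuals across features within each condition group.

    Least-squares in phi of (s^2 - m) ~ phi * m^2 over all feature/group
    pairs with >= 2 samples; clipped at 0.
    """
    X = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    sf = size_factors_median_of_ratios(X)
    Xn = X / sf
    num = 0.0
    den = 0.0
    n_used = 0
    for g in np.unique(groups):
        cols = Xn[:, groups == g]
        if cols.shape[1] < 2:
            continue
        n_used += 1
        m = cols.mean(axis=1)
        v = cols.var(axis=1, ddof=1)
        num += float(((v - m) * m ** 2).sum())
        den += float((m ** 4).sum())
    if n_used == 0:
        raise ValueError("need >= 2 samples in at least one group")
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _nb_conditional_pvalue(ya: int, t: int, r_a: float, r_b: float) -> float:
    """Two-sided exact-conditional NB p-value.

    Under H0 (equal means, equal per-sample library sizes) the group-A total
    given the feature total t follows
    P(A = a | t) ∝ C(a + r_a - 1, a) * C(t - a + r_b - 1, t - a),
    where r_g = n_g / phi is the group NB size. The p-value sums the
    probabilities of all outcomes no more likely than the observed one
    (minimum-likelihood two-sided rule, as in the exact binomial test).
    At phi = 0 the kernel degenerates to Binomial(t, n_a/(n_a+n_b)).
    """
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if np.isinf(r_a):  # Poisson limit: binomial kernel with p = n_a/(n_a+n_b)
        raise ValueError("pass binomial kernel explicitly")
    logw = (gammaln(a + r_a) - gammaln(a + 1.0) - gammaln(r_a)
            + gammaln(t - a + r_b) - gammaln(t - a + 1.0) - gammaln(r_b))
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return float(min(1.0, w[w <= w[ya] * (1.0 + 1e-7)].sum()))


def _binomial_pvalue(ya: int, t: int, frac_a: float) -> float:
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    logw = (gammaln(t + 1.0) - gammaln(a + 1.0) - gammaln(t - a + 1.0)
            + a * np.log(frac_a) + (t - a) * np.log1p(-frac_a))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return float(min(1.0, w[w <= w[ya] * (1.0 + 1e-7)].sum()))


def nb_exact_test(counts, conditions, cond_a, cond_b, dispersion: float,
                  features=None, lfc_threshold: float = 1.0, alpha: float = 0.01,
                  alpha_on: str = "p", pseudocount: float = 1.0) -> pd.DataFrame:
    """Exact-conditional NB differential test between two conditions.

    ``counts`` is features x samples; ``conditions`` labels each column.
    Counts are brought to equal library sizes with median-of-ratios size
    factors, rounded to pseudo-counts, and each feature is tested conditional
    on its pseudo-count total across both groups (see
    :func:`_nb_conditional_pvalue`). log2fc is computed on normalized group
    means with ``pseudocount``. ``alpha_on`` selects whether the significance
    cut applies to the nominal p ('p') or the BH FDR ('fdr').
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if alpha_on not in ("p", "fdr"):
        raise ValueError("alpha_on must be 'p' or 'fdr'")
    X = np.asarray(counts, dtype=float)
    conditions = np.asarray(conditions)
    ia = np.flatnonzero(conditions == cond_a)
    ib = np.flatnonzero(conditions == cond_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"no samples for contrast {cond_a} vs {cond_b}")
    sub = X[:, np.concatenate([ia, ib])]
    sf = size_factors_median_of_ratios(sub)
    pseudo = np.rint(sub / sf).astype(np.int64)
    n_a, n_b = len(ia), len(ib)
    ya = pseudo[:, :n_a].sum(axis=1)
    yb = pseudo[:, n_a:].sum(axis=1)
    t = ya + yb
    p = np.ones(len(t))
    if dispersion == 0:
        frac_a = n_a / (n_a + n_b)
        for i in range(len(t)):
            p[i] = _binomial_pvalue(int(ya[i]), int(t[i]), frac_a)
    else:
        r_a, r_b = n_a / dispersion, n_b / dispersion
        for i in range(len(t)):
            p[i] = _nb_conditional_pvalue(int(ya[i]), int(t[i]), r_a, r_b)
    mean_a = (sub[:, :n_a] / sf[:n_a]).mean(axis=1)
    mean_b = (sub[:, n_a:] / sf[n_a:]).mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    p_adj = adjust_pvalues(p, method="bh")
    call = make_calls(lfc, p_adj if alpha_on == "fdr" else p, lfc_threshold, alpha)
    feats = np.arange(X.shape[0]) if features is None else np.asarray(features)
    return pd.DataFrame({"feature": feats, "log2fc": lfc, "p": p,
                         "p_adj": p_adj, "call": call})


# ---------------------------------------------------------------------------
# correlation against an aggregated control

def correlation_to_reference(matrix, control_samples, query_sample,
                             scale: float = 10000.0, lognorm: bool = True) -> float:
    """Pearson r between one sample and the mean log-normalized profile of a
    set of control samples (the 'hypothetical healthy control').

    With ``lognorm=False`` the matrix is taken as already normalized.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 features")
    control_samples = np.atleast_1d(control_samples)
    if len(control_samples) == 0:
        raise ValueError("control_samples must be non-empty")
    sub = X[:, np.concatenate([control_samples, [query_sample]])]
    ln = lognormalize(sub, scale=scale) if lognorm else sub
    ref = ln[:, :-1].mean(axis=1)
    q = ln[:, -1]
    tol = 1e-12 * max(1.0, float(np.abs(ln).max()))
    if np.std(ref) <= tol or np.std(q) <= tol:
        raise ValueError("zero-variance profile; correlation undefined")
    return float(np.corrcoef(ref, q)[0, 1])
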