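"""Shared statistical primitives: composition tests, rank-sum DEG calling,
and Kruskal-Wallis with Dunn's all-pairs post hoc comparison.

Conventions: Fisher's exact test is two-sided by summing tables with
probability at most that of the observed table; Dunn's z uses the pooled
mid-rank formulation with tie correction; p-value adjustment is Bonferroni
where a figure legend names it and Benjamini-Hochberg otherwise, always a
per-call parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

_ADJUST_METHODS = {"BH": "fdr_bh", "bonferroni": "bonferroni"}


def adjust_pvalues(pvals, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}; use 'BH' or 'bonferroni'")
    return multipletests(pvals, method=_ADJUST_METHODS[method])[1]


# ---------------------------------------------------------------------------
# Composition: chi-square with post hoc pairwise Fisher


@dataclass
class ChisqPosthocResult:
    global_p: float
    global_stat: float
    pairwise: pd.DataFrame  # group_a, group_b, category, odds_ratio, p, p_adj


def chisq_posthoc(
    table: pd.DataFrame | np.ndarray,
    adjust: str = "BH",
) -> ChisqPosthocResult:
    """Pearson chi-square over a groups x categories count table, followed by
    pairwise Fisher exact tests on 2x2 collapses (group i vs j, category k
    vs rest) with multiplicity adjustment across all collapses.
    """
    df = pd.DataFrame(table)
    counts = df.to_numpy(dtype=np.int64)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 categories")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero margin")

    stat, p_global, _, _ = st.chi2_contingency(counts)
    rows = []
    groups = list(df.index)
    cats = list(df.columns)
    for (i, j) in combinations(range(len(groups)), 2):
        for k in range(len(cats)):
            sub = np.array([
                [counts[i, k], counts[i].sum() - counts[i, k]],
                [counts[j, k], counts[j].sum() - counts[j, k]],
            ])
            odds, p = st.fisher_exact(sub, alternative="two-sided")
            rows.append({
                "group_a": groups[i], "group_b": groups[j], "category": cats[k],
                "odds_ratio": odds, "p": p,
            })
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = adjust_pvalues(pairwise["p"].to_numpy(), adjust)
    return ChisqPosthocResult(global_p=float(p_global), global_stat=float(stat),
                              pairwise=pairwise)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum DEG calling


def wilcoxon_deg_matrix(
    values_a: np.ndarray | sp.spmatrix,
    values_b: np.ndarray | sp.spmatrix,
    genes: list[str],
    lfc_thresh: float = 0.25,
    alpha: float = 0.05,
    adjust: str = "BH",
    pseudocount: float = 1.0,
    filter_significant: bool = True,
) -> pd.DataFrame:
    """Two-sided rank-sum test per gene on normalized log counts.

    `values_a` / `values_b` are genes x cells arrays of log-normalized
    expression.  avg log2FC follows the single-cell convention
    log2(mean(expm1(x_A)) + 1) - log2(mean(expm1(x_B)) + 1).  Genes pass
    with |avg_log2FC| > lfc_thresh AND adjusted p < alpha; output is sorted
    by adjusted p.
    """
    A = np.asarray(values_a.todense() if sp.issparse(values_a) else values_a, dtype=float)
    B = np.asarray(values_b.todense() if sp.issparse(values_b) else values_b, dtype=float)
    if A.shape[1] < 3 or B.shape[1] < 3:
        raise ValueError("each group needs at least 3 cells")
    if A.shape[0] != len(genes) or B.shape[0] != len(genes):
        raise ValueError("gene list length does not match value rows")

    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    lfc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    pvals = np.ones(len(genes))
    for gi in range(len(genes)):
        a, b = A[gi], B[gi]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue  # constant gene, no evidence
        pvals[gi] = st.mannwhitneyu(a, b, alternative="two-sided").pvalue
    padj = adjust_pvalues(pvals, adjust)
    out = pd.DataFrame({
        "gene": genes, "avg_log2FC": lfc, "p": pvals, "p_adj": padj,
        "direction": np.where(lfc > 0, "up", "down"),
    })
    if filter_significant:
        out = out[(out["p_adj"] < alpha) & (out["avg_log2FC"].abs() > lfc_thresh)]
    return out.sort_values("p_adj", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


@dataclass
class KruskalDunnResult:
    global_p: float
    global_stat: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p, p_adj


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's all-pairs z comparison on pooled mid-ranks with tie correction."""
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = st.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for name, v in zip(names, values):
        r = ranks[offset:offset + len(v)]
        mean_ranks[name] = r.mean()
        sizes[name] = len(v)
        offset += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * st.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), adjust)
    return out


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    adjust: str = "bonferroni",
) -> KruskalDunnResult:
    """Global Kruskal-Wallis H test plus Dunn's all-pairs post hoc comparison."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(np.asarray(v)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    try:
        stat, p = st.kruskal(*arrays)
    except ValueError:  # every pooled value identical => no evidence
        stat, p = 0.0, 1.0
    pairwise = dunn_test(groups, adjust)
    return KruskalDunnResult(global_p=float(p), global_stat=float(stat), pairwise=pairwise)
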