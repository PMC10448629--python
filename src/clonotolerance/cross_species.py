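"""Ortholog-mapped integration bookkeeping and human-vs-mouse subset
similarity by Spearman correlation over subset-specific genes."""

from __future__ import annotations

import importlib.resources
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

from .core_io import ExpressionMatrix


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column TSV (source_symbol, target_symbol), human -> mouse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["source_symbol", "target_symbol"][: len(df.columns)]
    if df.isna().any().any() or (df == "").any().any():
        raise ValueError("ortholog map contains empty symbols")
    return df


def bundled_ortholog_map() -> pd.DataFrame:
    """Fixture human->mouse map covering the synthetic gene panel."""
    ref = importlib.resources.files("clonotolerance.data").joinpath("ortholog_map.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def map_orthologs(matrix: ExpressionMatrix, mapping: pd.DataFrame) -> ExpressionMatrix:
    """Rename genes to mapped targets; drop unmapped genes; sum many-to-one
    collisions so total mapped counts are conserved."""
    if mapping.empty:
        raise ValueError("ortholog mapping is empty")
    lut = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    keep = np.array([g in lut for g in matrix.genes])
    sub = matrix.subset_genes(keep)
    renamed = [lut[g] for g in sub.genes]
    # ExpressionMatrix sums duplicate symbols on construction
    return ExpressionMatrix(renamed, sub.barcodes, sub.counts)


def subset_specific_genes(
    profiles: pd.DataFrame,
    subset: str,
    top_n: int = 50,
    mode: str = "specific",
) -> list[str]:
    """Top-n genes for one subset from a genes x subsets mean-profile frame.

    mode="specific" ranks by log2 fold change of the subset's mean over
    the mean of the remaining subsets' profiles (one-vs-rest);
    mode="highest" ranks by the subset's own mean expression.
    """
    if mode == "highest":
        score = profiles[subset]
    elif mode == "specific":
        others = profiles.drop(columns=[subset])
        score = np.log2(profiles[subset] + 1.0) - np.log2(others.mean(axis=1) + 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(score.sort_values(ascending=False, kind="mergesort").index[:top_n])


def subset_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    top_n: int = 50,
    mode: str = "specific",
) -> pd.DataFrame:
    """Spearman correlation between every subset of `a` (rows of the result)
    and every subset of `b` (columns), over the union of each pair's top-n
    subset-specific genes.  Inputs are genes x subsets mean-expression
    frames on a shared (post-ortholog-mapping) gene namespace.
    """
    shared = a.index.intersection(b.index)
    a = a.loc[shared]
    b = b.loc[shared]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    top_a = {s: subset_specific_genes(a, s, top_n, mode) for s in a.columns}
    top_b = {s: subset_specific_genes(b, s, top_n, mode) for s in b.columns}
    for sa in a.columns:
        for sb in b.columns:
            genes = sorted(set(top_a[sa]) | set(top_b[sb]))
            if len(genes) < 3:
                warnings.warn(f"fewer than 3 shared genes for {sa} vs {sb}; NA")
                out.loc[sa, sb] = np.nan
                continue
            rho = st.spearmanr(a.loc[genes, sa], b.loc[genes, sb]).statistic
            out.loc[sa, sb] = rho
    return out


def mean_profiles(
    matrix: ExpressionMatrix,
    labels: dict[str, str],
    normalized_values=None,
) -> pd.DataFrame:
    """Genes x subsets frame of per-subset mean expression."""
    values = normalized_values if normalized_values is not None else matrix.counts
    pos_of = {bc: i for i, bc in enumerate(matrix.barcodes)}
    cols: dict[str, list[int]] = {}
    for bc, label in labels.items():
        if bc in pos_of:
            cols.setdefault(label, []).append(pos_of[bc])
    data = {}
    for subset in sorted(cols):
        sub = values[:, cols[subset]]
        data[subset] = np.asarray(sub.mean(axis=1)).ravel()
    return pd.DataFrame(data, index=matrix.genes)
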