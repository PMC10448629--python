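"""Marker-rule subset annotation, the marker-consistency correction rule for
clonally expanded cells, parent-group assignment, Treg-TH17 conversion
statistics, tolerance-panel scoring, APC normalized expression, and the
shared-clone plaque-inducible differential-expression signature.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .clonotype import ClonotypeTable
from .core_io import CohortDataset, ExpressionMatrix, Tissue
from .qc import lognormalize
from .stats_util import wilcoxon_deg_matrix

SUBSET_LABELS = [
    "eTreg", "CD4_Tem", "CD8_Tem", "CD8_naive", "CD8_Tcm",
    "NKT_CD8_Tcm", "CD4_naive", "cTreg", "gdT", "CD4_Tcm",
]

#: ten subsets grouped into five parent subtypes by function and
#: antigen experience
PARENT_GROUPS = {
    "CD4_Tem": "I", "CD4_Tcm": "I",
    "eTreg": "II", "cTreg": "II",
    "CD8_Tem": "III", "CD8_Tcm": "III", "NKT_CD8_Tcm": "III",
    "CD4_naive": "IV", "CD8_naive": "IV",
    "gdT": "V",
}

TREG_SUBSETS = {"eTreg", "cTreg"}

DEFAULT_CONVERSION_PAIRS = [("Foxp3", "Rorc"), ("Nrp1", "Rorc"), ("Il2ra", "Rorc")]


class MarkerConfigError(ValueError):
    pass


def _load_data_yaml(name: str) -> dict:
    ref = importlib.resources.files("clonotolerance.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Subset decision table


@dataclass(frozen=True)
class SubsetRule:
    label: str
    positive: tuple[str, ...]
    zero: tuple[str, ...]
    ccr7_levels: tuple[str, ...] = ()


@dataclass
class SubsetDecisionTable:
    """Ordered first-match marker rules over raw-count positivity.

    Ccr7 low/int/high levels come from tertiles of normalized Ccr7 among
    Ccr7-positive cells; by default they are reported but not used for
    discrimination (each pair of subsets already differs in a binary
    marker), ``strict_ccr7`` enforces them.
    """

    rules: list[SubsetRule]
    default: str = "unassigned"
    positivity_threshold: int = 0
    strict_ccr7: bool = False

    @classmethod
    def published(cls, **kw) -> "SubsetDecisionTable":
        raw = _load_data_yaml("subset_rules.yaml")
        rules = [
            SubsetRule(
                label=r["label"],
                positive=tuple(r.get("positive", [])),
                zero=tuple(r.get("zero", [])),
                ccr7_levels=tuple(r.get("ccr7", [])),
            )
            for r in raw["rules"]
        ]
        return cls(rules=rules, default=raw.get("default", "unassigned"), **kw)

    def marker_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            for g in r.positive + r.zero:
                seen.setdefault(g, None)
        if self.strict_ccr7:
            seen.setdefault("Ccr7", None)
        return list(seen)


def ccr7_levels(matrix: ExpressionMatrix, target_sum: float = 1e4) -> dict[str, str]:
    """Per-cell Ccr7 level: zero count => low; positive cells split into
    low/int/high by tertiles of normalized log expression."""
    raw = matrix.gene_row("Ccr7")
    norm = np.log1p(raw / np.maximum(matrix.counts_per_cell(), 1) * target_sum)
    levels = {}
    pos = norm[raw > 0]
    if len(pos) >= 3:
        t1, t2 = np.quantile(pos, [1 / 3, 2 / 3])
    else:
        t1 = t2 = np.inf
    for bc, r, v in zip(matrix.barcodes, raw, norm):
        if r == 0 or v <= t1:
            levels[bc] = "low"
        elif v <= t2:
            levels[bc] = "int"
        else:
            levels[bc] = "high"
    return levels


def classify_subsets(
    dataset: CohortDataset,
    table: SubsetDecisionTable | None = None,
) -> dict[str, str]:
    """Label every cell by the first matching marker rule."""
    table = table or SubsetDecisionTable.published()
    matrix = dataset.matrix
    for g in table.marker_genes():
        if g not in matrix.genes:
            raise MarkerConfigError(f"marker gene {g!r} missing from expression matrix")
    thr = table.positivity_threshold
    rows = {g: matrix.gene_row(g) for g in table.marker_genes()}
    levels = ccr7_levels(matrix) if table.strict_ccr7 else None

    labels: dict[str, str] = {}
    for ci, bc in enumerate(matrix.barcodes):
        label = table.default
        for rule in table.rules:
            if all(rows[g][ci] > thr for g in rule.positive) and \
                    all(rows[g][ci] <= thr for g in rule.zero):
                if levels is not None and rule.ccr7_levels and \
                        levels[bc] not in rule.ccr7_levels:
                    continue
                label = rule.label
                break
        labels[bc] = label
    return labels


def assign_parent_groups(labels: dict[str, str]) -> dict[str, str]:
    """Map ten-subset labels to parent groups I..V; unassigned cells are
    omitted with a warning."""
    out = {}
    n_skipped = 0
    for bc, label in labels.items():
        group = PARENT_GROUPS.get(label)
        if group is None:
            n_skipped += 1
            continue
        out[bc] = group
    if n_skipped:
        warnings.warn(f"{n_skipped} cells with unassigned subset omitted from parent groups")
    return out


# ---------------------------------------------------------------------------
# Correction rule for clonally expanded cells

CORRECTION_MARKERS = ("Cd4", "Cd8a", "Cd44", "Sell", "Ccr7", "Gzmk")


@dataclass
class CorrectionRule:
    """Marker-consistency check applied to clonally expanded cells.

    Lineage: CD4 if Cd4+ and Cd8a-; CD8 if Cd8a+ and Cd4-; otherwise the
    original lineage is kept.  State: Tem if Sell- and Ccr7- and (Cd44+ or
    Gzmk+); Tcm if Sell+ and Ccr7+ and (Cd44+ or Gzmk+); naive if Sell+
    and Ccr7+ and Cd44- and Gzmk-; otherwise the original state is kept.
    Positivity is raw count above ``threshold`` (default 0).  Idempotent:
    correcting a corrected label changes nothing.
    """

    threshold: int = 0

    def correct(self, label: str, counts: dict[str, int]) -> str:
        parsed = _parse_lineage_state(label)
        if parsed is None:
            return label  # rule covers only lineage-state labels
        lineage, state = parsed
        pos = {g: counts.get(g, 0) > self.threshold for g in CORRECTION_MARKERS}

        if pos["Cd4"] and not pos["Cd8a"]:
            lineage = "CD4"
        elif pos["Cd8a"] and not pos["Cd4"]:
            lineage = "CD8"

        memory = pos["Cd44"] or pos["Gzmk"]
        if not pos["Sell"] and not pos["Ccr7"] and memory:
            state = "Tem"
        elif pos["Sell"] and pos["Ccr7"] and memory:
            state = "Tcm"
        elif pos["Sell"] and pos["Ccr7"] and not pos["Cd44"] and not pos["Gzmk"]:
            state = "naive"
        return f"{lineage}_{state}"


def _parse_lineage_state(label: str):
    parts = label.split("_")
    if len(parts) == 2 and parts[0] in ("CD4", "CD8") and \
            parts[1] in ("Tem", "Tcm", "naive"):
        return parts[0], parts[1]
    return None


def pairing_accuracy(n_expanded: int, n_corrected: int) -> tuple[float, float]:
    """(accuracy %, discordance %) of the pairing algorithm, to three decimals:
    accuracy = (1 - corrected/expanded) x 100."""
    if n_expanded <= 0:
        raise ValueError("n_expanded must be positive")
    disc = round(100.0 * n_corrected / n_expanded, 3)
    return round(100.0 - 100.0 * n_corrected / n_expanded, 3), disc


@dataclass
class CorrectionReport:
    rows: pd.DataFrame       # barcode, original, corrected, changed
    n_expanded: int
    n_corrected: int
    accuracy_pct: float
    discordance_pct: float


def verify_expanded_subsets(
    labels: dict[str, str],
    dataset: CohortDataset,
    expanded_barcodes: set[str],
    rule: CorrectionRule | None = None,
) -> CorrectionReport:
    """Re-derive lineage and memory state of every expanded cell from raw
    marker counts; emit corrected labels where discordant and the pairing
    accuracy (1 - corrected/expanded) x 100."""
    rule = rule or CorrectionRule()
    missing = expanded_barcodes - set(labels)
    if missing:
        raise ValueError(f"expanded barcodes without labels, e.g. {sorted(missing)[:3]}")
    marker_rows = {g: dataset.matrix.gene_row(g) for g in CORRECTION_MARKERS
                   if g in dataset.matrix.genes}
    pos_of = {bc: i for i, bc in enumerate(dataset.matrix.barcodes)}
    recs = []
    for bc in sorted(expanded_barcodes):
        ci = pos_of[bc]
        counts = {g: int(marker_rows[g][ci]) for g in marker_rows}
        original = labels[bc]
        corrected = rule.correct(original, counts)
        recs.append({"barcode": bc, "original": original,
                     "corrected": corrected, "changed": corrected != original})
    rows = pd.DataFrame(recs, columns=["barcode", "original", "corrected", "changed"])
    n_exp = len(rows)
    n_corr = int(rows["changed"].sum()) if n_exp else 0
    acc = 100.0 * (1 - n_corr / n_exp) if n_exp else 100.0
    return CorrectionReport(rows=rows, n_expanded=n_exp, n_corrected=n_corr,
                            accuracy_pct=acc, discordance_pct=100.0 - acc)


# ---------------------------------------------------------------------------
# Treg-TH17 conversion


@dataclass
class ConversionReport:
    table: pd.DataFrame  # tissue, pair, n_treg, n_double_positive, pct


def treg_th17_conversion(
    dataset: CohortDataset,
    labels: dict[str, str],
    pairs: list[tuple[str, str]] | None = None,
) -> ConversionReport:
    """Double-positive counts and percentages among Treg cells per tissue.

    Treg = parent group II (eTreg plus cTreg).  A cell is double positive
    for a pair when both raw counts are above zero.  Percentages are
    reported to two decimals; tissues without Treg cells yield NA rows.
    """
    pairs = pairs or DEFAULT_CONVERSION_PAIRS
    tissue_of = {m.barcode: m.tissue for m in dataset.meta}
    rows_by_gene = {}
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in rows_by_gene:
                rows_by_gene[g] = dataset.matrix.gene_row(g)
    pos_of = {bc: i for i, bc in enumerate(dataset.matrix.barcodes)}

    treg_by_tissue: dict[Tissue, list[str]] = {t: [] for t in
                                               {tissue_of[bc] for bc in pos_of}}
    for bc, label in labels.items():
        if label in TREG_SUBSETS and bc in pos_of:
            treg_by_tissue[tissue_of[bc]].append(bc)

    recs = []
    for tissue in sorted(treg_by_tissue, key=lambda t: t.value):
        tregs = treg_by_tissue[tissue]
        for g1, g2 in pairs:
            if not tregs:
                recs.append({"tissue": tissue.value, "pair": f"{g1}+{g2}",
                             "n_treg": 0, "n_double_positive": pd.NA, "pct": pd.NA})
                continue
            dp = sum(
                1 for bc in tregs
                if rows_by_gene[g1][pos_of[bc]] > 0 and rows_by_gene[g2][pos_of[bc]] > 0
            )
            recs.append({"tissue": tissue.value, "pair": f"{g1}+{g2}",
                         "n_treg": len(tregs), "n_double_positive": dp,
                         "pct": round(100.0 * dp / len(tregs), 2)})
    return ConversionReport(table=pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# Panel scoring


@dataclass
class PanelDefinition:
    name: str
    genes: list[str]
    direction: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name}: duplicate genes")


def load_panels() -> dict[str, PanelDefinition]:
    raw = _load_data_yaml("panels.yaml")
    return {
        name: PanelDefinition(name=name, genes=list(spec["genes"]),
                              direction=spec.get("direction", {}))
        for name, spec in raw["panels"].items()
    }


def panel_score(
    dataset: CohortDataset,
    labels: dict[str, str],
    panel: PanelDefinition,
    normalized: bool = True,
) -> pd.DataFrame:
    """Mean expression and percent-expressing per (subset, gene) — the data
    behind a dot plot.  ``normalized`` uses log-normalized counts, else raw."""
    matrix = dataset.matrix
    for g in panel.genes:
        if g not in matrix.genes:
            raise MarkerConfigError(f"panel gene {g!r} missing from expression matrix")
    values = lognormalize(matrix) if normalized else matrix.counts
    gene_idx = {g: matrix.genes.index(g) for g in panel.genes}
    cells_by_subset: dict[str, list[int]] = {}
    pos_of = {bc: i for i, bc in enumerate(matrix.barcodes)}
    for bc, label in labels.items():
        if bc in pos_of:
            cells_by_subset.setdefault(label, []).append(pos_of[bc])

    recs = []
    for subset in sorted(cells_by_subset):
        cols = cells_by_subset[subset]
        for g in panel.genes:
            sub = values[gene_idx[g]][:, cols]
            dense = np.asarray(sub.todense()).ravel()
            if len(cols) == 0:
                recs.append({"subset": subset, "gene": g,
                             "mean": pd.NA, "pct_expressing": pd.NA, "n_cells": 0})
            else:
                recs.append({
                    "subset": subset, "gene": g,
                    "mean": float(dense.mean()),
                    "pct_expressing": 100.0 * float((dense > 0).mean()),
                    "n_cells": len(cols),
                })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# APC normalized expression


def apc_normalized_expression(
    dataset: CohortDataset,
    cell_type_labels: dict[str, str],
    genes: list[str],
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(tissue, gene) normalized score:
    sum over cell types of (average raw expression per cell type) x
    (cell-type fraction of all leukocytes in the tissue).

    ``cell_type_labels`` maps barcodes to myeloid cell types; unlabeled
    cells count in the leukocyte denominator only.  Doubling every cell's
    counts doubles the score (linearity in the raw mean).
    """
    matrix = dataset.matrix
    tissue_of = {m.barcode: m.tissue for m in dataset.meta}
    pos_of = {bc: i for i, bc in enumerate(matrix.barcodes)}
    rows = {g: matrix.gene_row(g) for g in genes}

    tissues = sorted({tissue_of[bc] for bc in matrix.barcodes}, key=lambda t: t.value)
    recs = []
    for tissue in tissues:
        all_cells = [bc for bc in matrix.barcodes if tissue_of[bc] == tissue]
        total = len(all_cells)
        by_type: dict[str, list[str]] = {}
        for bc in all_cells:
            ct = cell_type_labels.get(bc)
            if ct is not None and (cell_types is None or ct in cell_types):
                by_type.setdefault(ct, []).append(bc)
        for g in genes:
            score = 0.0
            for ct, members in by_type.items():
                idx = [pos_of[bc] for bc in members]
                mean = float(rows[g][idx].mean())
                score += mean * (len(members) / total)
            recs.append({"tissue": tissue.value, "gene": g, "score": score})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Plaque-inducible signature of shared clones


@dataclass
class SignatureReport:
    degs: pd.DataFrame        # gene, avg_log2FC, p, p_adj, direction
    n_focal_cells: int
    n_reference_cells: int
    n_shared_clonotypes: int
    per_clone: pd.DataFrame | None = None


def plaque_inducible_signature(
    dataset: CohortDataset,
    clonotypes: ClonotypeTable,
    focal_tissue: Tissue = Tissue.PLAQUE,
    reference_tissues: tuple[Tissue, ...] = (Tissue.ATLO, Tissue.APOE_RLN),
    lfc_thresh: float = 0.25,
    alpha: float = 0.05,
    adjust: str = "BH",
    per_clone: bool = False,
) -> SignatureReport:
    """Differential expression of shared-clone cells in the focal tissue
    versus their clone mates pooled across reference tissues.

    Only cells of clonotypes present in the focal tissue AND in at least
    one reference tissue enter.  Two-sided Wilcoxon rank-sum on normalized
    log counts; significant genes need adjusted p < alpha and
    |avg_log2FC| > lfc_thresh.  ``per_clone`` adds a per-clonotype
    fold-change recomputation for the consistency check that the signature
    is independent of the specific TCR.
    """
    if clonotypes.scope != "global":
        raise ValueError("signature requires a clonotype table with scope='global'")
    shared_rows = [
        r for r in clonotypes.rows
        if r.size_by_tissue.get(focal_tissue, 0) >= 1
        and any(r.size_by_tissue.get(t, 0) >= 1 for t in reference_tissues)
    ]
    if not shared_rows:
        empty = pd.DataFrame(columns=["gene", "avg_log2FC", "p", "p_adj", "direction"])
        return SignatureReport(degs=empty, n_focal_cells=0, n_reference_cells=0,
                               n_shared_clonotypes=0)

    tissue_of = clonotypes.tissue_of
    focal_cells, ref_cells = [], []
    for r in shared_rows:
        for bc in sorted(r.barcodes):
            if tissue_of[bc] == focal_tissue:
                focal_cells.append(bc)
            elif tissue_of[bc] in reference_tissues:
                ref_cells.append(bc)

    norm = lognormalize(dataset.matrix)
    pos_of = {bc: i for i, bc in enumerate(dataset.matrix.barcodes)}
    A = norm[:, [pos_of[bc] for bc in focal_cells]]
    B = norm[:, [pos_of[bc] for bc in ref_cells]]
    degs = wilcoxon_deg_matrix(A, B, dataset.matrix.genes,
                               lfc_thresh=lfc_thresh, alpha=alpha, adjust=adjust)

    per_clone_df = None
    if per_clone:
        recs = []
        sig_genes = list(degs["gene"])
        gidx = [dataset.matrix.genes.index(g) for g in sig_genes]
        for r in shared_rows:
            f = [pos_of[bc] for bc in sorted(r.barcodes) if tissue_of[bc] == focal_tissue]
            b = [pos_of[bc] for bc in sorted(r.barcodes) if tissue_of[bc] in reference_tissues]
            if not f or not b:
                continue
            fa = np.asarray(norm[gidx][:, f].todense())
            fb = np.asarray(norm[gidx][:, b].todense())
            lfc = np.log2(np.expm1(fa).mean(axis=1) + 1) - \
                np.log2(np.expm1(fb).mean(axis=1) + 1)
            clone_name = f"{r.key.tra_cdr3_aa}/{r.key.trb_cdr3_aa}"
            for g, v in zip(sig_genes, lfc):
                recs.append({"clone": clone_name, "gene": g, "avg_log2FC": float(v)})
        per_clone_df = pd.DataFrame(recs)

    return SignatureReport(
        degs=degs, n_focal_cells=len(focal_cells), n_reference_cells=len(ref_cells),
        n_shared_clonotypes=len(shared_rows), per_clone=per_clone_df,
    )


# ---------------------------------------------------------------------------
# Printed Table-1-style correction inputs shipped as data


def load_published_corrections() -> pd.DataFrame:
    """The ten printed expanded-cell marker-count rows with algorithm and
    corrected subset labels, for validating the correction rule."""
    ref = importlib.resources.files("clonotolerance.data").joinpath(
        "expanded_cell_corrections.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")
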