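"""Per-tissue cell and gene quality filters, plus log-normalization.

Cells with fewer than 200 detected genes are removed everywhere.  Upper
gene-count caps (a doublet proxy) and mitochondrial-percentage caps are
tissue specific: blood >3,000 genes or >10% mito; lymph node and ATLO
>4,000 genes or >8% mito; plaque >5,000 genes or >8% mito.  Removal is
strictly ">" at every boundary.  The gene filter (detected in fewer than
three cells) runs after the cell filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CellMeta, ExpressionMatrix, Tissue


class QCConfigError(ValueError):
    pass


def _default_max_genes() -> dict[Tissue, int]:
    return {
        Tissue.WT_BLOOD: 3000, Tissue.APOE_BLOOD: 3000,
        Tissue.WT_RLN: 4000, Tissue.APOE_RLN: 4000, Tissue.ATLO: 4000,
        Tissue.PLAQUE: 5000,
    }


def _default_max_mito() -> dict[Tissue, float]:
    return {
        Tissue.WT_BLOOD: 10.0, Tissue.APOE_BLOOD: 10.0,
        Tissue.WT_RLN: 8.0, Tissue.APOE_RLN: 8.0, Tissue.ATLO: 8.0,
        Tissue.PLAQUE: 8.0,
    }


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 200
    max_genes_per_cell: dict[Tissue, int] = field(default_factory=_default_max_genes)
    max_mito_pct: dict[Tissue, float] = field(default_factory=_default_max_mito)
    min_cells_per_gene: int = 3
    mito_prefix: str = "mt-"

    def validate_for(self, tissues: set[Tissue]) -> None:
        for t in tissues:
            if t not in self.max_genes_per_cell:
                raise QCConfigError(f"no max_genes_per_cell threshold for tissue {t.value}")
            if t not in self.max_mito_pct:
                raise QCConfigError(f"no max_mito_pct threshold for tissue {t.value}")
            if self.max_genes_per_cell[t] <= self.min_genes_per_cell:
                raise QCConfigError(f"max_genes must exceed min_genes for {t.value}")
            if not 0 < self.max_mito_pct[t] <= 100:
                raise QCConfigError(f"max_mito_pct for {t.value} must be in (0, 100]")


@dataclass
class QCReport:
    """Removal counts per rule per tissue plus totals."""

    removed_low_genes: dict[Tissue, int]
    removed_high_genes: dict[Tissue, int]
    removed_high_mito: dict[Tissue, int]
    genes_removed: int
    cells_in: int
    cells_out: int

    def to_frame(self) -> pd.DataFrame:
        tissues = sorted(set(self.removed_low_genes), key=lambda t: t.value)
        return pd.DataFrame({
            "tissue": [t.value for t in tissues],
            "removed_low_genes": [self.removed_low_genes[t] for t in tissues],
            "removed_high_genes": [self.removed_high_genes[t] for t in tissues],
            "removed_high_mito": [self.removed_high_mito[t] for t in tissues],
        })


def mito_percent(matrix: ExpressionMatrix, prefix: str = "mt-") -> np.ndarray:
    """Mitochondrial counts / total counts x 100 per cell (case-sensitive prefix)."""
    mask = np.array([g.startswith(prefix) for g in matrix.genes])
    total = matrix.counts_per_cell().astype(float)
    if not mask.any():
        return np.zeros(len(matrix.barcodes))
    mito = np.asarray(matrix.counts[np.flatnonzero(mask)].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return pct


def apply_qc(
    matrix: ExpressionMatrix,
    meta: list[CellMeta],
    thresholds: QCThresholds | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply cell filters then the gene filter; returns filtered matrix + report.

    A cell failing ANY rule is removed.  Boundary semantics are strict:
    a blood cell with exactly 3,000 detected genes or exactly 10% mito
    is retained.
    """
    thresholds = thresholds or QCThresholds()
    tissue_by_bc = {m.barcode: m.tissue for m in meta}
    tissues = {tissue_by_bc[bc] for bc in matrix.barcodes if bc in tissue_by_bc}
    missing = [bc for bc in matrix.barcodes if bc not in tissue_by_bc]
    if missing:
        raise QCConfigError(f"cells without tissue label, e.g. {missing[:3]}")
    thresholds.validate_for(tissues)

    n_genes = matrix.genes_per_cell()
    mito = mito_percent(matrix, thresholds.mito_prefix)
    cell_tissues = [tissue_by_bc[bc] for bc in matrix.barcodes]
    max_genes = np.array([thresholds.max_genes_per_cell[t] for t in cell_tissues])
    max_mito = np.array([thresholds.max_mito_pct[t] for t in cell_tissues])

    low = n_genes < thresholds.min_genes_per_cell
    high = n_genes > max_genes
    hi_mito = mito > max_mito
    keep = ~(low | high | hi_mito)

    removed_low = {t: 0 for t in tissues}
    removed_high = {t: 0 for t in tissues}
    removed_mito = {t: 0 for t in tissues}
    for i, t in enumerate(cell_tissues):
        if low[i]:
            removed_low[t] += 1
        if high[i]:
            removed_high[t] += 1
        if hi_mito[i]:
            removed_mito[t] += 1

    filtered = matrix.subset_cells(keep)
    gene_keep = filtered.cells_per_gene() >= thresholds.min_cells_per_gene
    out = filtered.subset_genes(gene_keep)
    report = QCReport(
        removed_low_genes=removed_low,
        removed_high_genes=removed_high,
        removed_high_mito=removed_mito,
        genes_removed=int((~gene_keep).sum()),
        cells_in=len(matrix.barcodes),
        cells_out=len(out.barcodes),
    )
    return out, report


def lognormalize(matrix: ExpressionMatrix, target_sum: float = 1e4) -> sp.csr_matrix:
    """Library-size scaling to `target_sum` per cell followed by log1p.

    Returns a genes-by-cells sparse matrix of normalized log counts.
    """
    totals = matrix.counts_per_cell().astype(float)
    totals[totals == 0] = 1.0
    scale = sp.diags(target_sum / totals)
    norm = matrix.counts.astype(float) @ scale
    norm.data = np.log1p(norm.data)
    return sp.csr_matrix(norm)
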