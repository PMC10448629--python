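"""Data model and readers/writers for paired scRNA-seq + scTCR-seq cohorts.

The hub object is :class:`CohortDataset`: a sparse gene-by-cell count matrix,
per-cell metadata (tissue, genotype), and a table of paired TCR alpha/beta
chains keyed by cell barcode.  V(D)J contigs arrive as 10x-Genomics-style
``filtered_contig_annotations.csv`` tables; expression arrives as
MatrixMarket MTX plus barcodes/features TSV.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class Chain(str, Enum):
    TRA = "TRA"
    TRB = "TRB"
    OTHER = "other"


class Tissue(str, Enum):
    WT_RLN = "WT_RLN"
    APOE_RLN = "APOE_RLN"
    ATLO = "ATLO"
    PLAQUE = "PLAQUE"
    WT_BLOOD = "WT_BLOOD"
    APOE_BLOOD = "APOE_BLOOD"


class Genotype(str, Enum):
    WT = "WT"
    APOE = "APOE"


#: tissues that only exist in the atherosclerotic (Apoe-deficient) genotype
TISSUE_GENOTYPE = {
    Tissue.WT_RLN: Genotype.WT,
    Tissue.WT_BLOOD: Genotype.WT,
    Tissue.APOE_RLN: Genotype.APOE,
    Tissue.APOE_BLOOD: Genotype.APOE,
    Tissue.ATLO: Genotype.APOE,
    Tissue.PLAQUE: Genotype.APOE,
}


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


@dataclass(frozen=True)
class ContigRecord:
    """One reconstructed V(D)J contig for one cell barcode."""

    barcode: str
    chain: Chain
    v_gene: str
    d_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    productive: bool
    umis: int

    def __post_init__(self):
        if self.umis < 0:
            raise ValueError(f"umis must be non-negative, got {self.umis}")
        if self.productive and not self.cdr3_aa:
            raise ValueError(f"productive contig for {self.barcode} has empty cdr3_aa")


@dataclass(frozen=True)
class PairedTCR:
    """One productive TCRalpha + TCRbeta pair for one cell."""

    barcode: str
    tra_v_family: str
    tra_cdr3_aa: str
    trb_v_family: str
    trb_cdr3_aa: str


@dataclass(frozen=True)
class CellMeta:
    barcode: str
    tissue: Tissue
    genotype: Genotype
    subset: str | None = None
    parent_group: str | None = None

    def __post_init__(self):
        expected = TISSUE_GENOTYPE[self.tissue]
        if self.genotype != expected:
            raise ValueError(
                f"tissue {self.tissue.value} implies genotype {expected.value}, "
                f"got {self.genotype.value} for barcode {self.barcode}"
            )


def meta_for_tissue(barcode: str, tissue: Tissue, **kw) -> CellMeta:
    """Build a CellMeta with the genotype implied by the tissue."""
    return CellMeta(barcode=barcode, tissue=tissue, genotype=TISSUE_GENOTYPE[tissue], **kw)


class ExpressionMatrix:
    """Sparse non-negative integer gene-by-cell count matrix with name lists."""

    def __init__(self, genes: Sequence[str], barcodes: Sequence[str], counts):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        if len(set(genes)) != len(genes):
            genes, counts = _sum_duplicate_genes(list(genes), counts)
        self.genes: list[str] = list(genes)
        self.barcodes: list[str] = list(barcodes)
        self.counts: sp.csr_matrix = counts
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._barcode_index = {b: i for i, b in enumerate(self.barcodes)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_row(self, gene: str) -> np.ndarray:
        """Dense 1-d count vector across cells for one gene."""
        try:
            i = self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return np.asarray(self.counts[i].todense()).ravel()

    def barcode_positions(self, barcodes: Iterable[str]) -> np.ndarray:
        return np.array([self._barcode_index[b] for b in barcodes], dtype=int)

    def subset_cells(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the given barcodes (order preserved) or boolean mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
            barcodes = [self.barcodes[i] for i in idx]
        else:
            barcodes = list(keep)
            idx = self.barcode_positions(barcodes)
        return ExpressionMatrix(self.genes, barcodes, self.counts[:, idx])

    def subset_genes(self, keep_mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.flatnonzero(keep_mask)
        return ExpressionMatrix([self.genes[i] for i in idx], self.barcodes, self.counts[idx])

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()


def _sum_duplicate_genes(genes: list[str], counts: sp.spmatrix):
    """Aggregate rows with identical gene symbols by summation (first-seen order)."""
    order: dict[str, int] = {}
    for g in genes:
        order.setdefault(g, len(order))
    n_unique = len(order)
    rows = np.array([order[g] for g in genes])
    agg = sp.csr_matrix(
        (np.ones(len(genes)), (rows, np.arange(len(genes)))),
        shape=(n_unique, len(genes)),
    )
    out_genes = [None] * n_unique
    for g, i in order.items():
        out_genes[i] = g
    return out_genes, sp.csr_matrix(agg @ counts)


@dataclass
class CohortDataset:
    """Paired cohort: expression matrix + per-cell metadata + paired TCR table."""

    matrix: ExpressionMatrix
    meta: list[CellMeta]
    tcr: list[PairedTCR] = field(default_factory=list)

    def __post_init__(self):
        bcs = set(self.matrix.barcodes)
        meta_bcs = {m.barcode for m in self.meta}
        if not bcs <= meta_bcs:
            missing = sorted(bcs - meta_bcs)[:3]
            raise ValueError(f"metadata missing for matrix barcodes, e.g. {missing}")
        for t in self.tcr:
            if t.barcode not in bcs:
                raise ValueError(f"tcr barcode {t.barcode} not in expression matrix")

    @property
    def meta_by_barcode(self) -> dict[str, CellMeta]:
        return {m.barcode: m for m in self.meta}

    def tissue_of(self) -> dict[str, Tissue]:
        return {m.barcode: m.tissue for m in self.meta}

    def subset_cells(self, barcodes: Sequence[str]) -> "CohortDataset":
        keep = set(barcodes)
        return CohortDataset(
            matrix=self.matrix.subset_cells(list(barcodes)),
            meta=[m for m in self.meta if m.barcode in keep],
            tcr=[t for t in self.tcr if t.barcode in keep],
        )

    def with_subsets(self, labels: dict[str, str]) -> "CohortDataset":
        """Copy with per-cell subset labels filled into metadata."""
        new_meta = [
            replace(m, subset=labels.get(m.barcode, m.subset)) for m in self.meta
        ]
        return CohortDataset(matrix=self.matrix, meta=new_meta, tcr=self.tcr)


# ---------------------------------------------------------------------------
# V gene canonicalization


def canonical_v(v_gene: str, granularity: str = "gene") -> str:
    """Canonical V-segment name.

    granularity="gene"   -> allele stripped: "TRBV13-3*01" -> "TRBV13-3"
    granularity="family" -> gene member also stripped:      -> "TRBV13"

    The clonotype definition requires identical V segments; whether that
    means the family (TRBV13) or the gene (TRBV13-3) is configurable, with
    full gene (allele-free) as the default.
    """
    name = v_gene.split("*")[0].strip()
    if granularity == "gene":
        return name
    if granularity == "family":
        return name.split("-")[0].split("/")[0]
    raise ValueError(f"unknown granularity {granularity!r}")


# ---------------------------------------------------------------------------
# Contig table IO

_CONTIG_COLUMNS = {
    "barcode": ("barcode",),
    "chain": ("chain",),
    "v_gene": ("v_gene",),
    "d_gene": ("d_gene",),
    "j_gene": ("j_gene",),
    "cdr3_aa": ("cdr3_aa", "cdr3"),
    "cdr3_nt": ("cdr3_nt",),
    "productive": ("productive",),
    "umis": ("umis", "umi_count"),
}
_OPTIONAL = {"d_gene", "cdr3_nt"}

_TRUTHY = {"true", "t", "1", "yes"}
_FALSY = {"false", "f", "0", "no", "none", ""}


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise FormatError(f"cannot parse productive flag {value!r}")


def read_contig_table(path: str | Path) -> list[ContigRecord]:
    """Read a 10x-style contig annotation CSV into ContigRecords.

    10x column names (``cdr3``, ``umis``/``umi_count``) are accepted as
    aliases.  Chain values other than TRA/TRB map to ``other``.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        colmap: dict[str, str] = {}
        for canon, aliases in _CONTIG_COLUMNS.items():
            found = next((a for a in aliases if a in header), None)
            if found is None and canon not in _OPTIONAL:
                raise FormatError(f"contig table {path} missing mandatory column {canon!r}")
            if found is not None:
                colmap[canon] = found
        records = []
        for row in reader:
            chain_raw = row[colmap["chain"]].strip()
            try:
                chain = Chain(chain_raw)
            except ValueError:
                chain = Chain.OTHER
            records.append(
                ContigRecord(
                    barcode=row[colmap["barcode"]].strip(),
                    chain=chain,
                    v_gene=row[colmap["v_gene"]].strip(),
                    d_gene=row.get(colmap.get("d_gene", ""), "") or "",
                    j_gene=row[colmap["j_gene"]].strip(),
                    cdr3_aa=row[colmap["cdr3_aa"]].strip(),
                    cdr3_nt=row.get(colmap.get("cdr3_nt", ""), "") or "",
                    productive=_parse_bool(row[colmap["productive"]]),
                    umis=int(row[colmap["umis"]]),
                )
            )
    return records


def write_contig_table(records: Iterable[ContigRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["barcode", "chain", "v_gene", "d_gene", "j_gene",
             "cdr3_aa", "cdr3_nt", "productive", "umis"]
        )
        for r in records:
            writer.writerow(
                [r.barcode, r.chain.value, r.v_gene, r.d_gene, r.j_gene,
                 r.cdr3_aa, r.cdr3_nt, "True" if r.productive else "False", r.umis]
            )


# ---------------------------------------------------------------------------
# Expression matrix IO (MatrixMarket + barcodes.tsv + features.tsv)


def read_expression(directory: str | Path) -> ExpressionMatrix:
    """Read matrix.mtx + barcodes.tsv + features.tsv from a directory.

    ``features.tsv`` may have one column (symbol) or the 10x three-column
    layout (id, symbol, type); the symbol column is used.  Duplicate gene
    symbols are summed.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (directory / name).exists():
            raise FormatError(f"missing {name} in {directory}")
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    barcodes = _read_single_column(directory / "barcodes.tsv")
    feat = pd.read_csv(directory / "features.tsv", sep="\t", header=None, dtype=str)
    genes = list(feat[1] if feat.shape[1] >= 2 else feat[0])
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX dimensions {counts.shape} do not match features x barcodes "
            f"({len(genes)}, {len(barcodes)})"
        )
    return ExpressionMatrix(genes, barcodes, counts)


def _read_single_column(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_expression(matrix: ExpressionMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(matrix.counts))
    with open(directory / "barcodes.tsv", "w", encoding="utf-8") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)
    with open(directory / "features.tsv", "w", encoding="utf-8") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes)


# ---------------------------------------------------------------------------
# Metadata IO


def read_metadata(path: str | Path) -> list[CellMeta]:
    df = pd.read_csv(path, dtype=str)
    for col in ("barcode", "tissue"):
        if col not in df.columns:
            raise FormatError(f"metadata {path} missing mandatory column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        tissue = Tissue(row.tissue)
        out.append(
            CellMeta(
                barcode=row.barcode,
                tissue=tissue,
                genotype=TISSUE_GENOTYPE[tissue],
                subset=getattr(row, "subset", None) or None,
            )
        )
    return out


def write_metadata(meta: Iterable[CellMeta], path: str | Path) -> None:
    rows = [
        {
            "barcode": m.barcode,
            "tissue": m.tissue.value,
            "genotype": m.genotype.value,
            "subset": m.subset or "",
            "parent_group": m.parent_group or "",
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Barcode-level pairing of TCR with expression


def pair_cells(
    contigs: Iterable[ContigRecord],
    matrix: ExpressionMatrix,
    meta: list[CellMeta],
    v_granularity: str = "gene",
) -> CohortDataset:
    """Pair TCR contigs with the expression matrix by cell barcode.

    A cell enters the paired TCR table only if it has at least one
    productive TRA contig AND at least one productive TRB contig AND its
    barcode is present in the expression matrix.  When a barcode carries
    several productive contigs of one chain (double-alpha cells are common
    in 10x data), the highest-UMI contig represents the chain; UMI ties
    break by lexicographic CDR3 aa, then V gene, so the result does not
    depend on input row order.  Cells without a paired TCR stay in the
    matrix and metadata.
    """
    present = set(matrix.barcodes)
    per_cell: dict[str, dict[Chain, list[ContigRecord]]] = {}
    for c in contigs:
        if not c.productive or c.chain is Chain.OTHER or c.barcode not in present:
            continue
        per_cell.setdefault(c.barcode, {}).setdefault(c.chain, []).append(c)

    def best(contig_list: list[ContigRecord]) -> ContigRecord:
        return min(contig_list, key=lambda c: (-c.umis, c.cdr3_aa, c.v_gene))

    tcr = []
    for barcode in matrix.barcodes:  # matrix order => deterministic output order
        chains = per_cell.get(barcode)
        if not chains or Chain.TRA not in chains or Chain.TRB not in chains:
            continue
        tra = best(chains[Chain.TRA])
        trb = best(chains[Chain.TRB])
        tcr.append(
            PairedTCR(
                barcode=barcode,
                tra_v_family=canonical_v(tra.v_gene, v_granularity),
                tra_cdr3_aa=tra.cdr3_aa,
                trb_v_family=canonical_v(trb.v_gene, v_granularity),
                trb_cdr3_aa=trb.cdr3_aa,
            )
        )
    return CohortDataset(matrix=matrix, meta=meta, tcr=tcr)
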