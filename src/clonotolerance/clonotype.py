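"""Clonotype construction, expansion calling, V-usage, cross-tissue sharing,
and twin-cell discovery.

A clonotype is the set of cells sharing an identical paired key
(TRA V segment, TRA CDR3 aa, TRB V segment, TRB CDR3 aa); clones of at
least ``min_clone_size`` cells (default 2) are called expanded.  Expansion
percentages are computed per tissue: a 1+1 cross-tissue twin does not make
either tissue's cell expanded.  Global scope serves twin discovery and
cross-tissue sharing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .core_io import CohortDataset, PairedTCR, Tissue


@dataclass(frozen=True)
class ClonotypeKey:
    tra_v: str
    tra_cdr3_aa: str
    trb_v: str
    trb_cdr3_aa: str

    @classmethod
    def of(cls, t: PairedTCR) -> "ClonotypeKey":
        return cls(t.tra_v_family, t.tra_cdr3_aa, t.trb_v_family, t.trb_cdr3_aa)


@dataclass(frozen=True)
class ClonotypeRow:
    key: ClonotypeKey
    barcodes: frozenset[str]
    size_by_tissue: dict[Tissue, int]
    total_size: int
    expanded: bool = False


@dataclass
class ClonotypeTable:
    rows: list[ClonotypeRow]
    scope: str
    tissue_of: dict[str, Tissue]
    min_clone_size: int | None = None

    def n_paired_cells(self) -> int:
        return sum(r.total_size for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "tra_v": r.key.tra_v, "tra_cdr3_aa": r.key.tra_cdr3_aa,
                "trb_v": r.key.trb_v, "trb_cdr3_aa": r.key.trb_cdr3_aa,
                "total_size": r.total_size, "expanded": r.expanded,
            }
            for t, n in sorted(r.size_by_tissue.items(), key=lambda kv: kv[0].value):
                rec[f"n_{t.value}"] = n
            recs.append(rec)
        return pd.DataFrame(recs).fillna(0)


def build_clonotypes(dataset: CohortDataset, scope: str = "per_tissue") -> ClonotypeTable:
    """Group paired cells into clonotype rows.

    scope="per_tissue": one row per (key, tissue) — sizes never span tissues.
    scope="per_genotype": one row per (key, genotype).
    scope="global": one row per key across all cells.
    Every paired cell lands in exactly one row.
    """
    if not dataset.tcr:
        raise ValueError("dataset has no paired TCR cells")
    tissue_of = {m.barcode: m.tissue for m in dataset.meta}
    groups: dict[tuple, list[str]] = {}
    for t in dataset.tcr:
        key = ClonotypeKey.of(t)
        tissue = tissue_of[t.barcode]
        if scope == "per_tissue":
            gk = (key, tissue)
        elif scope == "per_genotype":
            gk = (key, _genotype(tissue))
        elif scope == "global":
            gk = (key,)
        else:
            raise ValueError(f"unknown scope {scope!r}")
        groups.setdefault(gk, []).append(t.barcode)

    rows = []
    for gk in sorted(groups, key=_group_sort_key):
        barcodes = groups[gk]
        by_tissue: dict[Tissue, int] = {}
        for bc in barcodes:
            by_tissue[tissue_of[bc]] = by_tissue.get(tissue_of[bc], 0) + 1
        rows.append(ClonotypeRow(
            key=gk[0], barcodes=frozenset(barcodes),
            size_by_tissue=by_tissue, total_size=len(barcodes),
        ))
    return ClonotypeTable(rows=rows, scope=scope, tissue_of=tissue_of)


def _genotype(tissue: Tissue) -> str:
    return "WT" if tissue in (Tissue.WT_RLN, Tissue.WT_BLOOD) else "APOE"


def _group_sort_key(gk):
    key = gk[0]
    rest = tuple(getattr(x, "value", str(x)) for x in gk[1:])
    return (key.tra_v, key.tra_cdr3_aa, key.trb_v, key.trb_cdr3_aa) + rest


@dataclass
class ExpansionSummary:
    per_tissue: pd.DataFrame            # tissue, paired_cells, expanded_cells, pct
    per_group: pd.DataFrame | None = None  # tissue, parent_group, ... when labels given


def call_expanded(
    table: ClonotypeTable,
    min_clone_size: int = 2,
    parent_groups: dict[str, str] | None = None,
) -> tuple[ClonotypeTable, ExpansionSummary]:
    """Flag clones with >= min_clone_size cells within the table's scope and
    summarize expanded-cell percentages per tissue (and per parent group
    when per-cell parent-group labels are supplied)."""
    if min_clone_size < 2:
        raise ValueError("min_clone_size must be >= 2")
    rows = [replace(r, expanded=r.total_size >= min_clone_size) for r in table.rows]
    flagged = ClonotypeTable(rows=rows, scope=table.scope,
                             tissue_of=table.tissue_of, min_clone_size=min_clone_size)

    paired: dict[Tissue, int] = {}
    expanded: dict[Tissue, int] = {}
    grp_paired: dict[tuple[Tissue, str], int] = {}
    grp_expanded: dict[tuple[Tissue, str], int] = {}
    for r in rows:
        for bc in r.barcodes:
            t = table.tissue_of[bc]
            paired[t] = paired.get(t, 0) + 1
            # per-tissue expansion: the clone must reach the threshold
            # within the cell's own tissue
            is_exp = r.size_by_tissue.get(t, 0) >= min_clone_size \
                if table.scope != "per_tissue" else r.expanded
            if is_exp:
                expanded[t] = expanded.get(t, 0) + 1
            if parent_groups is not None and bc in parent_groups:
                gk = (t, parent_groups[bc])
                grp_paired[gk] = grp_paired.get(gk, 0) + 1
                if is_exp:
                    grp_expanded[gk] = grp_expanded.get(gk, 0) + 1

    tissues = sorted(paired, key=lambda t: t.value)
    per_tissue = pd.DataFrame({
        "tissue": [t.value for t in tissues],
        "paired_cells": [paired[t] for t in tissues],
        "expanded_cells": [expanded.get(t, 0) for t in tissues],
    })
    per_tissue["pct_expanded"] = 100.0 * per_tissue["expanded_cells"] / per_tissue["paired_cells"]

    per_group = None
    if parent_groups is not None:
        keys = sorted(grp_paired, key=lambda k: (k[0].value, k[1]))
        per_group = pd.DataFrame({
            "tissue": [k[0].value for k in keys],
            "parent_group": [k[1] for k in keys],
            "paired_cells": [grp_paired[k] for k in keys],
            "expanded_cells": [grp_expanded.get(k, 0) for k in keys],
        })
        per_group["pct_expanded"] = (
            100.0 * per_group["expanded_cells"] / per_group["paired_cells"])
    return flagged, ExpansionSummary(per_tissue=per_tissue, per_group=per_group)


# ---------------------------------------------------------------------------
# V usage


def v_usage(
    dataset: CohortDataset,
    chain: str = "TRB",
    contigs=None,
) -> pd.DataFrame:
    """Per-tissue V-segment usage percentages among paired cells.

    Percentage = individual V count / total V count in the tissue x 100;
    rows sum to 100 per tissue.  When the original contig records are
    supplied, V-J pair counts are attached for circos-style output (the
    paired table itself does not retain J segments).
    """
    if chain not in ("TRA", "TRB"):
        raise ValueError("chain must be 'TRA' or 'TRB'")
    tissue_of = {m.barcode: m.tissue for m in dataset.meta}
    counts: dict[Tissue, dict[str, int]] = {}
    for t in dataset.tcr:
        v = t.trb_v_family if chain == "TRB" else t.tra_v_family
        tissue = tissue_of[t.barcode]
        counts.setdefault(tissue, {})
        counts[tissue][v] = counts[tissue].get(v, 0) + 1

    rows = []
    for tissue in sorted(counts, key=lambda t: t.value):
        total = sum(counts[tissue].values())
        if total == 0:
            warnings.warn(f"no paired cells in tissue {tissue.value}; row omitted")
            continue
        for v, n in sorted(counts[tissue].items()):
            rows.append({"tissue": tissue.value, "v": v, "count": n,
                         "pct": 100.0 * n / total})
    return pd.DataFrame(rows)


def vj_pairs(dataset: CohortDataset, contigs, chain: str = "TRB") -> pd.DataFrame:
    """V-J pair counts per tissue from productive contigs of paired cells."""
    paired = {t.barcode for t in dataset.tcr}
    tissue_of = {m.barcode: m.tissue for m in dataset.meta}
    counts: dict[tuple[str, str, str], int] = {}
    for c in contigs:
        if not c.productive or c.chain.value != chain or c.barcode not in paired:
            continue
        key = (tissue_of[c.barcode].value, c.v_gene.split("*")[0], c.j_gene)
        counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [{"tissue": t, "v": v, "j": j, "count": n}
         for (t, v, j), n in sorted(counts.items())]
    )


# ---------------------------------------------------------------------------
# Cross-tissue sharing


@dataclass
class SharedFractionReport:
    source: Tissue
    targets: tuple[Tissue, ...]
    level: str
    n_source_cells: int
    n_shared_cells: int
    fraction_pct: float | None
    shared_sequences: list


def sharing_fraction(
    table: ClonotypeTable,
    source: Tissue,
    targets: Iterable[Tissue],
    level: str = "paired",
    expanded_only: bool = False,
    parent_groups: dict[str, str] | None = None,
    subset_filter: str | None = None,
    min_clone_size: int = 2,
) -> SharedFractionReport:
    """Fraction of filtered source-tissue cells whose CDR3 (at the chosen
    chain level) occurs in the corresponding filtered target-tissue cell set.

    level="alpha" compares TRA CDR3 aa sets, "beta" TRB, "paired" the full
    clonotype key.  ``expanded_only`` restricts both source and target cells
    to members of clones expanded within their own tissue;
    ``subset_filter`` restricts both to a parent group (requires
    ``parent_groups`` labels).  The denominator is cells, not clonotypes.
    """
    targets = tuple(targets)
    if source in targets:
        raise ValueError("source tissue must not be among targets")
    if level not in ("alpha", "beta", "paired"):
        raise ValueError(f"unknown level {level!r}")
    if subset_filter is not None and parent_groups is None:
        raise ValueError("subset_filter requires parent_groups labels")

    def seq_of(key: ClonotypeKey):
        if level == "alpha":
            return key.tra_cdr3_aa
        if level == "beta":
            return key.trb_cdr3_aa
        return (key.tra_v, key.tra_cdr3_aa, key.trb_v, key.trb_cdr3_aa)

    def cell_passes(row: ClonotypeRow, bc: str, tissue: Tissue) -> bool:
        if expanded_only and row.size_by_tissue.get(tissue, 0) < min_clone_size:
            return False
        if subset_filter is not None and parent_groups.get(bc) != subset_filter:
            return False
        return True

    target_seqs = set()
    source_cells: list[tuple[ClonotypeRow, str]] = []
    for row in table.rows:
        for bc in row.barcodes:
            t = table.tissue_of[bc]
            if t == source and cell_passes(row, bc, t):
                source_cells.append((row, bc))
            elif t in targets and cell_passes(row, bc, t):
                target_seqs.add(seq_of(row.key))

    if not source_cells:
        return SharedFractionReport(source, targets, level, 0, 0, None, [])
    shared = [(row, bc) for row, bc in source_cells if seq_of(row.key) in target_seqs]
    shared_seqs = sorted({seq_of(row.key) for row, _ in shared})
    return SharedFractionReport(
        source=source, targets=targets, level=level,
        n_source_cells=len(source_cells), n_shared_cells=len(shared),
        fraction_pct=100.0 * len(shared) / len(source_cells),
        shared_sequences=shared_seqs,
    )


# ---------------------------------------------------------------------------
# Twin-like cells


@dataclass(frozen=True)
class TwinRecord:
    key: ClonotypeKey
    barcodes_by_tissue: tuple[tuple[Tissue, tuple[str, ...]], ...]


def find_twins(table: ClonotypeTable) -> list[TwinRecord]:
    """Clonotypes occurring in at least two distinct tissues, with member
    barcodes per tissue.  Requires a table built with scope='global'."""
    if table.scope != "global":
        raise ValueError("find_twins requires a table built with scope='global'")
    out = []
    for row in table.rows:
        tissues = {t for t in row.size_by_tissue if row.size_by_tissue[t] > 0}
        if len(tissues) < 2:
            continue
        per_tissue: dict[Tissue, list[str]] = {}
        for bc in sorted(row.barcodes):
            per_tissue.setdefault(table.tissue_of[bc], []).append(bc)
        out.append(TwinRecord(
            key=row.key,
            barcodes_by_tissue=tuple(
                (t, tuple(per_tissue[t]))
                for t in sorted(per_tissue, key=lambda t: t.value)
            ),
        ))
    return out
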