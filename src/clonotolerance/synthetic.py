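"""Synthetic paired scRNA/scTCR cohorts with known ground truth.

The generator emulates the structure of an aged-atherosclerosis T cell
atlas: four tissues (wild-type renal lymph node, Apoe-deficient renal
lymph node, artery tertiary lymphoid organ, plaque), ten T cell subsets
with marker-gene structure, tissue-specific clone-size skew, cross-tissue
clonotype sharing, planted Treg-to-TH17 double-positive cells, planted
cross-tissue twin clones, and plaque-inducible expression shifts.  Counts
are negative binomial; every planted event is recorded in
:class:`SyntheticTruth` so downstream stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_io import (
    CellMeta,
    Chain,
    CohortDataset,
    ContigRecord,
    ExpressionMatrix,
    Tissue,
    meta_for_tissue,
    pair_cells,
)

SUBSETS = [
    "eTreg", "CD4_Tem", "CD8_Tem", "CD8_naive", "CD8_Tcm",
    "NKT_CD8_Tcm", "CD4_naive", "cTreg", "gdT", "CD4_Tcm",
]

TREG_SUBSETS = {"eTreg", "cTreg"}

#: concentrations at or above this are treated as the all-distinct limit
INFINITE_CONCENTRATION = 1e6

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# Gene universe: classifier markers, tolerance panels, mitochondrial decoys,
# housekeeping filler.  Roughly 120 genes; enough for every pipeline stage.

CLASSIFIER_MARKERS = [
    "Cd4", "Cd8a", "Foxp3", "Cd44", "Sell", "Ccr7",
    "Klrb1c", "Tcrg-C1", "Trdc", "Ly6c1", "Gzmk",
]

PANEL_GENES = [
    # egress / residency
    "S1pr1",
    # activation / migration
    "Cxcr6", "Ccr5", "Slamf7", "Adgre5", "S100a4", "S100a6", "Ctsw",
    "Lgals1", "Reep5", "H2-D1", "Cd8b1",
    # cytotoxicity / cytokines
    "Cst7", "Gzmb", "Gzmm", "Ifng", "Nkg7", "Prf1", "Efhd2", "Ccl5", "Ccl4",
    # exhaustion receptors / signaling / transcription factors
    "Pdcd1", "Tigit", "Lag3", "Havcr2", "Ctla4",
    "Ptpn6", "Ptpn11", "Ptpn2",
    "Irf4", "Nr4a1", "Gata3", "Tox", "Batf", "Prdm1", "Eomes",
    # Treg maintenance / suppression
    "Il2ra", "Stat5a", "Il10", "Nrp1", "Cd83",
    # TH17
    "Rorc", "Rora", "Il17a",
    # tissue-resident memory
    "Itga1", "Itgae", "Cd101", "Cd69", "Klf2", "Klf3", "S1pr5",
    # APC costimulation / checkpoint
    "Cd80", "Cd86", "Cd40", "Cd274", "Pdcd1lg2", "Fas", "Icosl",
    "Lgals3", "Cd200",
]

MITO_GENES = ["mt-Co1", "mt-Co3", "mt-Atp8", "mt-Nd1", "mt-Cytb"]

HOUSEKEEPING = [
    "Actb", "B2m", "Gapdh", "Pgk1", "Tbp",
] + [f"Rpl{i}" for i in range(3, 23)] + [f"Rps{i}" for i in range(2, 22)]

GENE_UNIVERSE = CLASSIFIER_MARKERS + PANEL_GENES + MITO_GENES + HOUSEKEEPING


def _base_means() -> dict[str, float]:
    means = {g: 0.02 for g in CLASSIFIER_MARKERS + PANEL_GENES}
    means.update({g: 0.5 for g in MITO_GENES})
    means.update({g: 1.5 for g in HOUSEKEEPING})
    # broadly expressed activation/structural transcripts carry a moderate
    # baseline so tissue-level fold changes act on a detectable floor
    means.update({"Cxcr6": 0.8, "Lgals1": 1.2, "S100a6": 1.0, "S100a4": 0.8,
                  "Reep5": 1.0, "H2-D1": 1.0})
    # planted-signal genes kept silent unless a subset or event turns them on
    means["Rorc"] = 0.0
    means["Il17a"] = 0.0
    return means


ON = 10.0   # mean for a defining positive marker
MID = 2.5   # mean for a moderately expressed gene

#: per-subset overrides on top of the baseline means
SUBSET_MARKER_MEANS: dict[str, dict[str, float]] = {
    "eTreg":       {"Cd4": ON, "Foxp3": ON, "Cd44": ON, "Sell": 0.0, "Ccr7": 0.2,
                    "Il2ra": ON, "Nrp1": ON, "Ctla4": MID, "Il10": MID,
                    "Stat5a": MID, "Cd83": MID},
    "cTreg":       {"Cd4": ON, "Foxp3": ON, "Cd44": 0.02, "Sell": MID, "Ccr7": 0.3,
                    "Il2ra": ON, "Nrp1": ON, "Stat5a": MID},
    "CD4_Tem":     {"Cd4": ON, "Cd44": ON, "Sell": 0.0, "Ccr7": 0.2,
                    "S100a6": MID, "Cxcr6": MID, "Ctla4": 1.0},
    "CD4_Tcm":     {"Cd4": ON, "Cd44": ON, "Sell": MID, "Ccr7": 4.0, "Ly6c1": ON},
    "CD4_naive":   {"Cd4": ON, "Cd44": 0.0, "Sell": ON, "Ccr7": 6.0,
                    "Klf2": MID, "S1pr1": MID},
    "CD8_Tem":     {"Cd8a": ON, "Cd8b1": MID, "Cd44": ON, "Sell": 0.0, "Ccr7": 0.2,
                    "Gzmk": MID, "Ccl5": MID, "Nkg7": MID, "Pdcd1": 1.0},
    "CD8_Tcm":     {"Cd8a": ON, "Cd8b1": MID, "Cd44": ON, "Sell": MID, "Ccr7": 2.0},
    "NKT_CD8_Tcm": {"Cd8a": ON, "Cd8b1": MID, "Cd44": ON, "Sell": MID, "Ccr7": 2.0,
                    "Klrb1c": ON},
    "CD8_naive":   {"Cd8a": ON, "Cd8b1": MID, "Cd44": 0.0, "Sell": ON, "Ccr7": 6.0,
                    "Klf2": MID, "S1pr1": MID},
    "gdT":         {"Cd4": 0.0, "Cd8a": 0.0, "Tcrg-C1": ON, "Trdc": ON, "Cd44": MID},
}

#: per-tissue subset composition (order follows SUBSETS), emulating a
#: naive-cell-rich lymph node versus an effector/gdT-rich plaque
DEFAULT_SUBSET_FRACTIONS: dict[Tissue, list[float]] = {
    Tissue.WT_RLN:   [.06, .08, .03, .20, .08, .03, .30, .06, .02, .14],
    Tissue.APOE_RLN: [.07, .12, .08, .16, .08, .03, .24, .06, .03, .13],
    Tissue.ATLO:     [.10, .15, .14, .08, .10, .04, .14, .07, .08, .10],
    Tissue.PLAQUE:   [.04, .15, .25, .03, .15, .06, .05, .02, .15, .10],
}

#: default cohort sizes approximating a 13,800-cell four-tissue atlas
DEFAULT_CELLS_PER_TISSUE: dict[Tissue, int] = {
    Tissue.WT_RLN: 5000,
    Tissue.APOE_RLN: 5100,
    Tissue.ATLO: 2400,
    Tissue.PLAQUE: 1300,
}

#: clone-size concentration per tissue (Chinese-restaurant-process alpha);
#: smaller alpha => more clonal expansion.  Defaults calibrated so realized
#: expansion follows the published per-tissue gradient (~4/7/11/21%).
DEFAULT_CLONE_CONCENTRATION: dict[Tissue, float] = {
    Tissue.WT_RLN: 120000.0,
    Tissue.APOE_RLN: 70000.0,
    Tissue.ATLO: 18000.0,
    Tissue.PLAQUE: 4000.0,
}

#: fraction of Treg cells planted as TH17 double positives, following the
#: published Foxp3+Rorc+ rates per tissue
DEFAULT_CONVERSION_RATE: dict[Tissue, float] = {
    Tissue.WT_RLN: 0.0037,
    Tissue.APOE_RLN: 0.0044,
    Tissue.ATLO: 0.0117,
    Tissue.PLAQUE: 0.0274,
}

#: V-segment sampling weights per tissue; the plaque table is skewed toward
#: TRBV31/TRBV5, the Apoe-deficient node toward TRBV13-3, the ATLO toward
#: TRBV19/TRBV16, mirroring the published usage skews
_TRBV_POOL = ["TRBV1", "TRBV2", "TRBV5", "TRBV12-1", "TRBV13-1", "TRBV13-2",
              "TRBV13-3", "TRBV16", "TRBV19", "TRBV29", "TRBV31"]
_TRAV_POOL = ["TRAV3-3", "TRAV6-5", "TRAV7-2", "TRAV9-4", "TRAV12-1",
              "TRAV14-1", "TRAV16", "TRAV19", "TRAV21"]


def _uniform_weights(pool):
    return {g: 1.0 for g in pool}


def default_v_frequencies() -> dict[Tissue, dict[str, float]]:
    freqs = {}
    for t in DEFAULT_CELLS_PER_TISSUE:
        w = _uniform_weights(_TRBV_POOL)
        if t is Tissue.APOE_RLN:
            w["TRBV13-3"] = 4.0
        elif t is Tissue.ATLO:
            w["TRBV19"] = 3.0
            w["TRBV16"] = 3.0
        elif t is Tissue.PLAQUE:
            w["TRBV31"] = 4.0
            w["TRBV5"] = 3.0
        freqs[t] = w
    return freqs


class ConfigError(ValueError):
    """Raised when a synthetic configuration is inconsistent."""


@dataclass
class SyntheticConfig:
    seed: int = 0
    cells_per_tissue: dict[Tissue, int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS_PER_TISSUE))
    subset_fractions: dict[Tissue, list[float]] = field(
        default_factory=lambda: {t: list(v) for t, v in DEFAULT_SUBSET_FRACTIONS.items()})
    clone_concentration: dict[Tissue, float] = field(
        default_factory=lambda: dict(DEFAULT_CLONE_CONCENTRATION))
    sharing_prob: float = 0.3
    conversion_rate: dict[Tissue, float] = field(
        default_factory=lambda: dict(DEFAULT_CONVERSION_RATE))
    twin_count: int = 5
    nb_dispersion: float = 5.0
    marker_means: dict[tuple[str, str], float] = field(default_factory=dict)
    plaque_inducible: dict[str, float] = field(
        default_factory=lambda: {"Cxcr6": 3.0, "Lgals1": 3.0,
                                 "S100a6": 3.0, "Reep5": 3.0})
    v_frequencies: dict[Tissue, dict[str, float]] = field(
        default_factory=default_v_frequencies)

    def validate(self) -> None:
        for t, fr in self.subset_fractions.items():
            if len(fr) != len(SUBSETS):
                raise ConfigError(f"{t.value}: need {len(SUBSETS)} subset fractions")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ConfigError(f"{t.value}: subset fractions sum to {sum(fr)}, not 1")
            if any(f < 0 for f in fr):
                raise ConfigError(f"{t.value}: negative subset fraction")
        if not 0 <= self.sharing_prob <= 1:
            raise ConfigError("sharing_prob must be in [0, 1]")
        for t, r in self.conversion_rate.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"conversion_rate[{t.value}] must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for t in self.cells_per_tissue:
            if t not in self.subset_fractions:
                raise ConfigError(f"no subset fractions for tissue {t.value}")
            if t not in self.clone_concentration:
                raise ConfigError(f"no clone concentration for tissue {t.value}")


@dataclass
class SyntheticTruth:
    subset_labels: dict[str, str]
    clone_ids: dict[str, str]
    double_positive_barcodes: set[str]
    twin_clonotypes: list[tuple[str, str, str, str]]
    realized_expansion: dict[Tissue, float]
    plaque_inducible_genes: dict[str, float]
    contigs: list[ContigRecord]


@dataclass(frozen=True)
class _Clone:
    clone_id: str
    tra_v: str
    tra_cdr3: str
    trb_v: str
    trb_cdr3: str


def _random_cdr3(rng: np.random.Generator) -> str:
    """CDR3 amino-acid string with the canonical C...F motif, length 10-18."""
    middle = rng.integers(8, 17)
    body = "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), middle))
    return "C" + body + "F"


def _random_nt(rng: np.random.Generator, aa_len: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 3 * aa_len))


def _sample_v(rng, weights: Mapping[str, float]) -> str:
    genes = sorted(weights)
    p = np.array([weights[g] for g in genes], dtype=float)
    return genes[rng.choice(len(genes), p=p / p.sum())]


def _crp_assign(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Chinese-restaurant-process clone assignment: small alpha => big clones.

    Concentrations >= INFINITE_CONCENTRATION are the all-distinct limit:
    every cell its own clone, realized expansion exactly zero.
    """
    labels = np.empty(n, dtype=int)
    if alpha >= INFINITE_CONCENTRATION:
        labels[:] = np.arange(n)
        return labels
    counts: list[int] = []
    for i in range(n):
        total = i
        p_new = alpha / (alpha + total)
        if rng.random() < p_new or not counts:
            counts.append(1)
            labels[i] = len(counts) - 1
        else:
            probs = np.array(counts, dtype=float) / total
            k = rng.choice(len(counts), p=probs)
            counts[k] += 1
            labels[i] = k
    return labels


def _nb_draw(rng, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean `mean` and dispersion theta (var = m + m^2/theta)."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        m = mean[pos]
        p = theta / (theta + m)
        out[pos] = rng.negative_binomial(theta, p)
    return out


_TISSUE_CODE = {
    Tissue.WT_RLN: "WRL", Tissue.APOE_RLN: "ARL", Tissue.ATLO: "ATL",
    Tissue.PLAQUE: "PLQ", Tissue.WT_BLOOD: "WBL", Tissue.APOE_BLOOD: "ABL",
}


def generate_cohort(config: SyntheticConfig) -> tuple[CohortDataset, SyntheticTruth]:
    """Generate a cohort plus its ground truth.  Same config+seed => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = sorted(config.cells_per_tissue, key=lambda t: t.value)

    base = _base_means()
    mean_table = np.zeros((len(SUBSETS), len(GENE_UNIVERSE)))
    for si, subset in enumerate(SUBSETS):
        for gi, gene in enumerate(GENE_UNIVERSE):
            mean = SUBSET_MARKER_MEANS[subset].get(gene, base[gene])
            mean = config.marker_means.get((subset, gene), mean)
            mean_table[si, gi] = mean

    barcodes: list[str] = []
    meta: list[CellMeta] = []
    subset_labels: dict[str, str] = {}
    tissue_cells: dict[Tissue, list[str]] = {}
    cell_subset_idx: dict[str, int] = {}

    for tissue in tissues:
        n = config.cells_per_tissue[tissue]
        fr = np.array(config.subset_fractions[tissue], dtype=float)
        subset_idx = rng.choice(len(SUBSETS), size=n, p=fr / fr.sum())
        cells = []
        for i in range(n):
            bc = f"{_TISSUE_CODE[tissue]}-{i:05d}"
            barcodes.append(bc)
            meta.append(meta_for_tissue(bc, tissue))
            subset_labels[bc] = SUBSETS[subset_idx[i]]
            cell_subset_idx[bc] = int(subset_idx[i])
            cells.append(bc)
        tissue_cells[tissue] = cells

    # ---- expression counts -------------------------------------------------
    gene_idx = {g: i for i, g in enumerate(GENE_UNIVERSE)}
    counts = np.zeros((len(GENE_UNIVERSE), len(barcodes)), dtype=np.int64)
    plaque_fold = np.ones(len(GENE_UNIVERSE))
    for g, fold in config.plaque_inducible.items():
        plaque_fold[gene_idx[g]] = fold
    for ci, bc in enumerate(barcodes):
        mean = mean_table[cell_subset_idx[bc]].copy()
        if meta[ci].tissue is Tissue.PLAQUE:
            mean = mean * plaque_fold
        counts[:, ci] = _nb_draw(rng, mean, config.nb_dispersion)

    # ---- planted Treg->TH17 double positives ------------------------------
    dp_barcodes: set[str] = set()
    force_idx = [gene_idx[g] for g in ("Rorc", "Foxp3", "Nrp1", "Il2ra")]
    for tissue in tissues:
        rate = config.conversion_rate.get(tissue, 0.0)
        if rate <= 0:
            continue
        for bc in tissue_cells[tissue]:
            if subset_labels[bc] in TREG_SUBSETS and rng.random() < rate:
                dp_barcodes.add(bc)
    pos = {bc: i for i, bc in enumerate(barcodes)}
    for bc in sorted(dp_barcodes):
        ci = pos[bc]
        for gi in force_idx:
            counts[gi, ci] = max(counts[gi, ci], 1 + rng.poisson(1.0))

    matrix = ExpressionMatrix(GENE_UNIVERSE, barcodes, counts)

    # ---- clonotypes --------------------------------------------------------
    clone_of: dict[str, _Clone] = {}
    clone_counter = 0
    tissue_clones: dict[Tissue, list[_Clone]] = {}

    def new_clone(tissue: Tissue) -> _Clone:
        nonlocal clone_counter
        clone_counter += 1
        vfreq = config.v_frequencies.get(tissue, _uniform_weights(_TRBV_POOL))
        return _Clone(
            clone_id=f"clone{clone_counter:06d}",
            tra_v=_sample_v(rng, _uniform_weights(_TRAV_POOL)),
            tra_cdr3=_random_cdr3(rng),
            trb_v=_sample_v(rng, vfreq),
            trb_cdr3=_random_cdr3(rng),
        )

    for tissue in tissues:
        ab_cells = [bc for bc in tissue_cells[tissue] if subset_labels[bc] != "gdT"]
        labels = _crp_assign(rng, len(ab_cells), config.clone_concentration[tissue])
        clones = [new_clone(tissue) for _ in range(int(labels.max()) + 1 if len(ab_cells) else 0)]
        tissue_clones[tissue] = clones
        for bc, k in zip(ab_cells, labels):
            clone_of[bc] = clones[k]

    # ---- cross-tissue sharing: re-use plaque clonotypes in ATLO / ApoE RLN -
    share_targets = [t for t in (Tissue.ATLO, Tissue.APOE_RLN) if t in tissue_cells]
    if config.sharing_prob > 0 and Tissue.PLAQUE in tissue_cells and share_targets:
        for clone in tissue_clones[Tissue.PLAQUE]:
            if rng.random() >= config.sharing_prob:
                continue
            target = share_targets[rng.integers(0, len(share_targets))]
            candidates = [bc for bc in tissue_cells[target] if bc in clone_of]
            # replace the clonotype of one target-tissue clone with the
            # plaque one; expanded target clones are preferred so that
            # sharing concentrates among expanded cells on both sides, as
            # observed for plaque/ATLO/RLN repertoires
            sizes: dict[str, int] = {}
            for bc in candidates:
                sizes[clone_of[bc].clone_id] = sizes.get(clone_of[bc].clone_id, 0) + 1
            expanded_ids = sorted(cid for cid, n in sizes.items() if n >= 2)
            pool = expanded_ids if expanded_ids else sorted(sizes)
            if not pool:
                continue
            victim_id = pool[rng.integers(0, len(pool))]
            for bc in candidates:
                if clone_of[bc].clone_id == victim_id:
                    clone_of[bc] = clone

    # ---- planted twins: singleton pairs across two tissues -----------------
    twin_keys: list[tuple[str, str, str, str]] = []
    twin_pair = [t for t in (Tissue.APOE_RLN, Tissue.PLAQUE) if t in tissue_cells]
    if config.twin_count > 0 and len(twin_pair) == 2:
        twin_used: set[str] = set()
        for _ in range(config.twin_count):
            twin = new_clone(twin_pair[1])
            for tissue in twin_pair:
                # pick a current singleton so the twin stays a 1+1 pair;
                # never reuse a cell already given to an earlier twin
                sizes: dict[str, list[str]] = {}
                for bc in tissue_cells[tissue]:
                    if bc in clone_of:
                        sizes.setdefault(clone_of[bc].clone_id, []).append(bc)
                singles = sorted(bcs[0] for cid, bcs in sizes.items()
                                 if len(bcs) == 1 and bcs[0] not in twin_used)
                bc = singles[rng.integers(0, len(singles))]
                clone_of[bc] = twin
                twin_used.add(bc)
            twin_keys.append((twin.tra_v, twin.tra_cdr3, twin.trb_v, twin.trb_cdr3))

    # ---- realized expansion per tissue (clone sizes within tissue) ---------
    realized: dict[Tissue, float] = {}
    for tissue in tissues:
        sizes: dict[str, int] = {}
        members = [bc for bc in tissue_cells[tissue] if bc in clone_of]
        for bc in members:
            sizes[clone_of[bc].clone_id] = sizes.get(clone_of[bc].clone_id, 0) + 1
        expanded = sum(n for n in sizes.values() if n >= 2)
        realized[tissue] = 100.0 * expanded / len(members) if members else 0.0

    # ---- contig records -----------------------------------------------------
    contigs: list[ContigRecord] = []
    for bc in barcodes:
        clone = clone_of.get(bc)
        if clone is None:
            continue
        umis_a, umis_b = rng.integers(2, 60, size=2)
        contigs.append(ContigRecord(
            barcode=bc, chain=Chain.TRA, v_gene=clone.tra_v + "*01", d_gene="",
            j_gene="TRAJ33", cdr3_aa=clone.tra_cdr3,
            cdr3_nt=_random_nt(rng, len(clone.tra_cdr3)),
            productive=True, umis=int(umis_a)))
        contigs.append(ContigRecord(
            barcode=bc, chain=Chain.TRB, v_gene=clone.trb_v + "*01", d_gene="TRBD1",
            j_gene="TRBJ2-1", cdr3_aa=clone.trb_cdr3,
            cdr3_nt=_random_nt(rng, len(clone.trb_cdr3)),
            productive=True, umis=int(umis_b)))

    dataset = pair_cells(contigs, matrix, meta)
    truth = SyntheticTruth(
        subset_labels=subset_labels,
        clone_ids={bc: c.clone_id for bc, c in clone_of.items()},
        double_positive_barcodes=dp_barcodes,
        twin_clonotypes=twin_keys,
        realized_expansion=realized,
        plaque_inducible_genes=dict(config.plaque_inducible),
        contigs=contigs,
    )
    return dataset, truth
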