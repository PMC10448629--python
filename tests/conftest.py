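import numpy as np
import pytest

from clonotolerance.core_io import (
    CohortDataset,
    ExpressionMatrix,
    PairedTCR,
    Tissue,
    meta_for_tissue,
)
from clonotolerance.synthetic import SyntheticConfig, generate_cohort


def make_matrix(genes, barcodes, dense):
    return ExpressionMatrix(genes, barcodes, np.asarray(dense))


def make_dataset(genes, cells, tcr=None):
    """cells: list of (barcode, tissue, counts-vector)."""
    barcodes = [c[0] for c in cells]
    dense = np.column_stack([np.asarray(c[2]) for c in cells])
    matrix = ExpressionMatrix(genes, barcodes, dense)
    meta = [meta_for_tissue(c[0], c[1]) for c in cells]
    return CohortDataset(matrix=matrix, meta=meta, tcr=tcr or [])


def make_tcr(barcode, tra_cdr3="CAAAF", trb_cdr3="CBBBF",
             tra_v="TRAV1", trb_v="TRBV1"):
    return PairedTCR(barcode=barcode, tra_v_family=tra_v, tra_cdr3_aa=tra_cdr3,
                     trb_v_family=trb_v, trb_cdr3_aa=trb_cdr3)


@pytest.fixture(scope="session")
def small_cohort():
    """~1,900-cell four-tissue cohort with default structure, shared seed."""
    config = SyntheticConfig(
        seed=11,
        cells_per_tissue={Tissue.WT_RLN: 600, Tissue.APOE_RLN: 600,
                          Tissue.ATLO: 400, Tissue.PLAQUE: 300},
        clone_concentration={Tissue.WT_RLN: 12000.0, Tissue.APOE_RLN: 7000.0,
                             Tissue.ATLO: 2000.0, Tissue.PLAQUE: 500.0},
    )
    return generate_cohort(config)
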