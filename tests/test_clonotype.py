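import pytest

from clonotolerance.clonotype import (
    build_clonotypes,
    call_expanded,
    find_twins,
    sharing_fraction,
    v_usage,
)
from clonotolerance.core_io import Tissue
from conftest import make_dataset, make_tcr


def toy_dataset(clone_sizes, tissue=Tissue.PLAQUE):
    """One tissue; clone i has clone_sizes[i] cells with a unique key."""
    cells, tcr = [], []
    k = 0
    for i, size in enumerate(clone_sizes):
        for _ in range(size):
            bc = f"c{k}"
            cells.append((bc, tissue, [1]))
            tcr.append(make_tcr(bc, tra_cdr3=f"CA{i}F", trb_cdr3=f"CB{i}F"))
            k += 1
    return make_dataset(["g"], cells, tcr)


class TestBuildAndExpand:
    def test_identical_keys_merge(self):
        ds = toy_dataset([2])
        table = build_clonotypes(ds, scope="per_tissue")
        assert len(table.rows) == 1 and table.rows[0].total_size == 2

    def test_beta_cdr3_difference_splits(self):
        cells = [("c0", Tissue.PLAQUE, [1]), ("c1", Tissue.PLAQUE, [1])]
        tcr = [make_tcr("c0", trb_cdr3="CXF"), make_tcr("c1", trb_cdr3="CYF")]
        ds = make_dataset(["g"], cells, tcr)
        assert len(build_clonotypes(ds).rows) == 2

    def test_toy_size_spectrum(self):
        ds = toy_dataset([3, 2, 1, 1, 1, 1, 1])
        table = build_clonotypes(ds)
        assert len(table.rows) == 7
        assert sorted(r.total_size for r in table.rows) == [1, 1, 1, 1, 1, 2, 3]

    def test_partition_property(self, small_cohort):
        ds, _ = small_cohort
        table = build_clonotypes(ds, scope="global")
        assert table.n_paired_cells() == len(ds.tcr)
        all_bcs = [bc for r in table.rows for bc in r.barcodes]
        assert len(all_bcs) == len(set(all_bcs))

    def test_two_cell_clone_is_expanded(self):
        table, summary = call_expanded(build_clonotypes(toy_dataset([2])), 2)
        assert table.rows[0].expanded

    def test_all_singletons_zero_percent(self):
        _, summary = call_expanded(build_clonotypes(toy_dataset([1, 1, 1])), 2)
        assert summary.per_tissue["pct_expanded"].tolist() == [0.0]

    def test_toy_expansion_is_half(self):
        _, summary = call_expanded(build_clonotypes(toy_dataset([3, 2, 1, 1, 1, 1, 1])), 2)
        assert summary.per_tissue["pct_expanded"].tolist() == [50.0]

    def test_min_clone_size_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            call_expanded(build_clonotypes(toy_dataset([2])), 1)

    def test_summary_invariant_to_row_order(self):
        ds = toy_dataset([3, 2, 1, 1])
        shuffled = make_dataset(
            ["g"],
            [(t.barcode, Tissue.PLAQUE, [1]) for t in reversed(ds.tcr)],
            list(reversed(ds.tcr)),
        )
        _, a = call_expanded(build_clonotypes(ds), 2)
        _, b = call_expanded(build_clonotypes(shuffled), 2)
        assert a.per_tissue.equals(b.per_tissue)


class TestVUsage:
    def test_single_family_is_100(self):
        ds = toy_dataset([1, 1])
        out = v_usage(ds, "TRB")
        assert out["pct"].tolist() == [100.0]

    def test_even_split(self):
        cells = [(f"c{i}", Tissue.PLAQUE, [1]) for i in range(4)]
        tcr = [make_tcr(f"c{i}", trb_cdr3=f"C{i}F",
                        trb_v="TRBV31" if i < 2 else "TRBV5") for i in range(4)]
        out = v_usage(make_dataset(["g"], cells, tcr), "TRB")
        assert sorted(out["pct"]) == [50.0, 50.0]
        assert out.groupby("tissue")["pct"].sum().tolist() == pytest.approx([100.0])

    def test_planted_plaque_skew_dominates(self, small_cohort):
        ds, _ = small_cohort
        out = v_usage(ds, "TRB")
        plaque = out[out["tissue"] == "PLAQUE"]
        assert plaque.loc[plaque["pct"].idxmax(), "v"] == "TRBV31"


class TestSharing:
    def two_tissue_dataset(self, source_cdr3s, target_cdr3s):
        cells, tcr = [], []
        for i, c in enumerate(source_cdr3s):
            bc = f"s{i}"
            cells.append((bc, Tissue.PLAQUE, [1]))
            tcr.append(make_tcr(bc, tra_cdr3=c, trb_cdr3=f"CS{i}F"))
        for i, c in enumerate(target_cdr3s):
            bc = f"t{i}"
            cells.append((bc, Tissue.ATLO, [1]))
            tcr.append(make_tcr(bc, tra_cdr3=c, trb_cdr3=f"CT{i}F"))
        return make_dataset(["g"], cells, tcr)

    def test_disjoint_sets_zero(self):
        ds = self.two_tissue_dataset(["CAF", "CBF"], ["CXF", "CYF"])
        table = build_clonotypes(ds, scope="global")
        rep = sharing_fraction(table, Tissue.PLAQUE, [Tissue.ATLO], level="alpha")
        assert rep.fraction_pct == 0.0

    def test_two_of_three_shared(self):
        ds = self.two_tissue_dataset(["CAF", "CBF", "CCF"], ["CAF", "CBF"])
        table = build_clonotypes(ds, scope="global")
        rep = sharing_fraction(table, Tissue.PLAQUE, [Tissue.ATLO], level="alpha")
        assert rep.fraction_pct == pytest.approx(66.6667, abs=1e-3)
        assert rep.shared_sequences == ["CAF", "CBF"]

    def test_zero_denominator_explicit_empty(self):
        ds = self.two_tissue_dataset(["CAF"], ["CAF"])
        table = build_clonotypes(ds, scope="global")
        rep = sharing_fraction(table, Tissue.PLAQUE, [Tissue.ATLO],
                               level="alpha", expanded_only=True)
        assert rep.fraction_pct is None and rep.n_source_cells == 0

    def test_source_in_targets_rejected(self):
        ds = self.two_tissue_dataset(["CAF"], ["CAF"])
        table = build_clonotypes(ds, scope="global")
        with pytest.raises(ValueError):
            sharing_fraction(table, Tissue.PLAQUE, [Tissue.PLAQUE, Tissue.ATLO])

    def test_monotone_in_target_set(self, small_cohort):
        ds, _ = small_cohort
        table = build_clonotypes(ds, scope="global")
        f = lambda targets: sharing_fraction(
            table, Tissue.PLAQUE, targets, level="alpha").fraction_pct
        union = f([Tissue.ATLO, Tissue.APOE_RLN])
        assert union >= max(f([Tissue.ATLO]), f([Tissue.APOE_RLN]))


class TestTwins:
    def test_cross_tissue_pair_found(self):
        cells = [("a", Tissue.APOE_RLN, [1]), ("b", Tissue.PLAQUE, [1])]
        tcr = [make_tcr("a"), make_tcr("b")]
        table = build_clonotypes(make_dataset(["g"], cells, tcr), scope="global")
        twins = find_twins(table)
        assert len(twins) == 1
        tissues = dict(twins[0].barcodes_by_tissue)
        assert tissues[Tissue.APOE_RLN] == ("a",) and tissues[Tissue.PLAQUE] == ("b",)

    def test_no_cross_tissue_clones_empty(self):
        twins = find_twins(build_clonotypes(toy_dataset([2, 1]), scope="global"))
        assert twins == []

    def test_requires_global_scope(self):
        with pytest.raises(ValueError):
            find_twins(build_clonotypes(toy_dataset([2]), scope="per_tissue"))

    def test_planted_twins_recovered_exactly(self):
        from clonotolerance.synthetic import SyntheticConfig, generate_cohort
        cfg = SyntheticConfig(
            seed=9,
            cells_per_tissue={Tissue.APOE_RLN: 300, Tissue.PLAQUE: 200},
            clone_concentration={Tissue.APOE_RLN: 1e6, Tissue.PLAQUE: 1e6},
            sharing_prob=0.0, twin_count=5,
        )
        ds, truth = generate_cohort(cfg)
        twins = find_twins(build_clonotypes(ds, scope="global"))
        assert len(twins) == 5
        found = {(t.key.tra_v, t.key.tra_cdr3_aa, t.key.trb_v, t.key.trb_cdr3_aa)
                 for t in twins}
        assert found == set(truth.twin_clonotypes)
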