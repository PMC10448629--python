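import numpy as np
import pytest

from clonotolerance.clonotype import build_clonotypes
from clonotolerance.core_io import Tissue
from clonotolerance.phenotype import (
    CorrectionRule,
    MarkerConfigError,
    SubsetDecisionTable,
    apc_normalized_expression,
    assign_parent_groups,
    classify_subsets,
    load_panels,
    load_published_corrections,
    pairing_accuracy,
    panel_score,
    plaque_inducible_signature,
    treg_th17_conversion,
    verify_expanded_subsets,
)
from conftest import make_dataset, make_tcr

MARKERS = ["Cd4", "Cd8a", "Foxp3", "Cd44", "Sell", "Ccr7",
           "Klrb1c", "Tcrg-C1", "Trdc", "Ly6c1", "Gzmk"]


def marker_cell(**counts):
    return [counts.get(g, 0) for g in MARKERS]


class TestClassifier:
    def dataset(self, cells):
        return make_dataset(MARKERS, cells)

    def test_etreg_combination(self):
        ds = self.dataset([("c0", Tissue.PLAQUE,
                            marker_cell(Cd4=3, Foxp3=2, Cd44=4))])
        assert classify_subsets(ds)["c0"] == "eTreg"

    def test_gdt_combination(self):
        ds = self.dataset([("c0", Tissue.PLAQUE, marker_cell(**{"Tcrg-C1": 2, "Trdc": 1}))])
        assert classify_subsets(ds)["c0"] == "gdT"

    def test_all_zero_unassigned(self):
        ds = self.dataset([("c0", Tissue.PLAQUE, marker_cell())])
        assert classify_subsets(ds)["c0"] == "unassigned"

    def test_missing_marker_gene_errors_with_name(self):
        ds = make_dataset(["Cd4", "Cd8a"], [("c0", Tissue.PLAQUE, [1, 0])])
        with pytest.raises(MarkerConfigError, match="missing from expression matrix"):
            classify_subsets(ds)

    @pytest.mark.parametrize("counts,label", [
        (dict(Cd8a=2, Cd44=1), "CD8_Tem"),
        (dict(Cd8a=2, Sell=3, Ccr7=4), "CD8_naive"),
        (dict(Cd8a=2, Cd44=1, Sell=1, Klrb1c=2), "NKT_CD8_Tcm"),
        (dict(Cd4=1, Cd44=2, Sell=1, Ly6c1=3), "CD4_Tcm"),
        (dict(Cd4=1, Sell=2, Ccr7=5), "CD4_naive"),
        (dict(Cd4=1, Foxp3=1), "cTreg"),
    ])
    def test_first_match_rules(self, counts, label):
        ds = self.dataset([("c0", Tissue.PLAQUE, marker_cell(**counts))])
        assert classify_subsets(ds)["c0"] == label


class TestParentGroups:
    @pytest.mark.parametrize("subset,group", [
        ("CD4_Tcm", "I"), ("cTreg", "II"), ("NKT_CD8_Tcm", "III"),
        ("CD8_naive", "IV"), ("gdT", "V"),
    ])
    def test_mapping(self, subset, group):
        assert assign_parent_groups({"c": subset})["c"] == group

    def test_unassigned_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="omitted"):
            out = assign_parent_groups({"a": "unassigned", "b": "gdT"})
        assert out == {"b": "V"}


class TestCorrectionRule:
    def test_reproduces_all_published_rows(self):
        rule = CorrectionRule()
        table = load_published_corrections()
        for row in table.itertuples(index=False):
            counts = {g: getattr(row, g) for g in
                      ("Cd4", "Cd8a", "Cd44", "Sell", "Ccr7", "Gzmk")}
            assert rule.correct(row.algorithm_label, counts) == row.corrected_label, \
                f"row {row.row}"

    def test_idempotent_on_published_rows(self):
        rule = CorrectionRule()
        table = load_published_corrections()
        for row in table.itertuples(index=False):
            counts = {g: getattr(row, g) for g in
                      ("Cd4", "Cd8a", "Cd44", "Sell", "Ccr7", "Gzmk")}
            once = rule.correct(row.algorithm_label, counts)
            assert rule.correct(once, counts) == once

    def test_concordant_cell_unchanged(self):
        rule = CorrectionRule()
        counts = dict(Cd4=0, Cd8a=2, Cd44=3, Sell=0, Ccr7=0, Gzmk=0)
        assert rule.correct("CD8_Tem", counts) == "CD8_Tem"

    def test_non_lineage_state_labels_untouched(self):
        rule = CorrectionRule()
        assert rule.correct("eTreg", dict(Cd4=3, Cd8a=0, Cd44=1)) == "eTreg"

    def test_accuracy_arithmetic(self):
        acc, disc = pairing_accuracy(547, 10)
        assert acc == 98.172 and disc == 1.828

    def test_verify_reports_corrections(self):
        genes = ["Cd4", "Cd8a", "Cd44", "Sell", "Ccr7", "Gzmk"]
        cells = [("c0", Tissue.PLAQUE, [0, 4, 5, 0, 0, 2]),   # printed row 1
                 ("c1", Tissue.PLAQUE, [0, 2, 3, 0, 0, 0])]   # concordant CD8_Tem
        ds = make_dataset(genes, cells)
        report = verify_expanded_subsets(
            {"c0": "CD8_naive", "c1": "CD8_Tem"}, ds, {"c0", "c1"})
        assert report.n_corrected == 1
        assert report.rows.set_index("barcode").loc["c0", "corrected"] == "CD8_Tem"
        assert report.accuracy_pct == pytest.approx(50.0)


class TestConversion:
    def test_published_plaque_percentages(self):
        # 73 plaque Tregs: 2 Foxp3+Rorc+, 8 Nrp1+Rorc+, 6 Il2ra+Rorc+
        genes = ["Foxp3", "Rorc", "Nrp1", "Il2ra"]
        cells, labels = [], {}
        for i in range(73):
            bc = f"p{i}"
            foxp3 = 1 if i < 2 else 0
            nrp1 = 1 if i < 8 else 0
            il2ra = 1 if i < 6 else 0
            rorc = 1 if i < 8 else 0
            cells.append((bc, Tissue.PLAQUE, [foxp3, rorc, nrp1, il2ra]))
            labels[bc] = "eTreg"
        ds = make_dataset(genes, cells)
        table = treg_th17_conversion(ds, labels).table.set_index("pair")
        assert table.loc["Foxp3+Rorc", "pct"] == 2.74
        assert table.loc["Nrp1+Rorc", "pct"] == 10.96
        assert table.loc["Il2ra+Rorc", "pct"] == 8.22

    def test_atlo_nrp1_percentage(self):
        genes = ["Foxp3", "Rorc", "Nrp1", "Il2ra"]
        cells, labels = [], {}
        for i in range(429):
            bc = f"a{i}"
            cells.append((bc, Tissue.ATLO, [0, 1 if i < 11 else 0,
                                            1 if i < 11 else 0, 0]))
            labels[bc] = "cTreg"
        ds = make_dataset(genes, cells)
        table = treg_th17_conversion(ds, labels).table.set_index("pair")
        assert table.loc["Nrp1+Rorc", "pct"] == 2.56

    def test_zero_dp_and_na_rows(self):
        genes = ["Foxp3", "Rorc", "Nrp1", "Il2ra"]
        cells = [("t0", Tissue.ATLO, [1, 0, 0, 0]),
                 ("p0", Tissue.PLAQUE, [0, 0, 0, 0])]
        labels = {"t0": "eTreg", "p0": "CD8_Tem"}  # no plaque Tregs
        table = treg_th17_conversion(make_dataset(genes, cells), labels).table
        atlo = table[(table.tissue == "ATLO") & (table.pair == "Foxp3+Rorc")]
        assert atlo["pct"].iloc[0] == 0.0
        plaque = table[table.tissue == "PLAQUE"]
        assert plaque["pct"].isna().all()

    def test_dp_bounded_by_single_positives(self, small_cohort):
        ds, truth = small_cohort
        table = treg_th17_conversion(ds, truth.subset_labels).table
        valid = table.dropna(subset=["n_double_positive"])
        assert (valid["n_double_positive"] <= valid["n_treg"]).all()


class TestPanels:
    def test_bundled_panels_load_and_are_unique(self):
        panels = load_panels()
        assert "plaque_inducible" in panels and "trm" in panels
        for p in panels.values():
            assert len(set(p.genes)) == len(p.genes)

    def test_single_cell_raw_mode(self):
        panels = load_panels()
        egress = panels["egress_residency"]
        ds = make_dataset(["Ccr7", "S1pr1", "Sell"],
                          [("c0", Tissue.PLAQUE, [4, 0, 1])])
        out = panel_score(ds, {"c0": "CD8_Tem"}, egress, normalized=False)
        row = out.set_index("gene").loc["Ccr7"]
        assert row["mean"] == 4.0 and row["pct_expressing"] == 100.0
        assert out.set_index("gene").loc["S1pr1", "mean"] == 0.0

    def test_planted_marker_highest_in_own_subset(self, small_cohort):
        ds, truth = small_cohort
        panels = load_panels()
        out = panel_score(ds, truth.subset_labels, panels["treg_maintenance"])
        foxp3 = out[out.gene == "Foxp3"].set_index("subset")["mean"]
        assert foxp3[["eTreg", "cTreg"]].min() > foxp3.drop(["eTreg", "cTreg"]).max()


class TestAPCScore:
    def test_formula_and_zero_fraction(self):
        ds = make_dataset(["Cd274"], [("c0", Tissue.PLAQUE, [2]),
                                      ("c1", Tissue.PLAQUE, [2]),
                                      ("c2", Tissue.PLAQUE, [0]),
                                      ("c3", Tissue.PLAQUE, [0])])
        # two labeled macrophages with mean 2.0 and fraction 0.5 -> 1.0
        out = apc_normalized_expression(ds, {"c0": "mac", "c1": "mac"}, ["Cd274"])
        assert out["score"].iloc[0] == pytest.approx(1.0)
        out2 = apc_normalized_expression(ds, {}, ["Cd274"])
        assert out2["score"].iloc[0] == 0.0

    def test_linearity_in_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(3, 6))
        cells = [(f"c{i}", Tissue.ATLO, counts[:, i]) for i in range(6)]
        ds = make_dataset(["g1", "g2", "g3"], cells)
        doubled = make_dataset(["g1", "g2", "g3"],
                               [(f"c{i}", Tissue.ATLO, 2 * counts[:, i]) for i in range(6)])
        labels = {"c0": "mac", "c1": "mac", "c2": "dc"}
        a = apc_normalized_expression(ds, labels, ["g1", "g2", "g3"])
        b = apc_normalized_expression(doubled, labels, ["g1", "g2", "g3"])
        assert np.allclose(2 * a["score"], b["score"])


class TestSignature:
    def shared_clone_dataset(self, focal_boost=None):
        """Two tissues, two shared clones, six cells each side."""
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        cells, tcr = [], []
        for i in range(6):
            for tissue, prefix in ((Tissue.PLAQUE, "p"), (Tissue.ATLO, "a")):
                bc = f"{prefix}{i}"
                counts = rng.poisson(3.0, len(genes))
                if focal_boost and tissue is Tissue.PLAQUE:
                    for g, fold in focal_boost.items():
                        counts[genes.index(g)] = rng.poisson(3.0 * fold)
                cells.append((bc, tissue, counts))
                tcr.append(make_tcr(bc, tra_cdr3=f"CA{i % 2}F", trb_cdr3=f"CB{i % 2}F"))
        return make_dataset(genes, cells, tcr)

    def test_identical_distributions_empty(self):
        ds = self.shared_clone_dataset()
        table = build_clonotypes(ds, scope="global")
        rep = plaque_inducible_signature(ds, table, Tissue.PLAQUE, (Tissue.ATLO,))
        assert rep.degs.empty and rep.n_shared_clonotypes == 2

    def test_no_shared_clonotypes_explicit_empty(self):
        cells = [("p0", Tissue.PLAQUE, [1]), ("a0", Tissue.ATLO, [1])]
        tcr = [make_tcr("p0", tra_cdr3="CXF"), make_tcr("a0", tra_cdr3="CYF")]
        ds = make_dataset(["g"], cells, tcr)
        table = build_clonotypes(ds, scope="global")
        rep = plaque_inducible_signature(ds, table, Tissue.PLAQUE, (Tissue.ATLO,))
        assert rep.degs.empty and rep.n_shared_clonotypes == 0

    def test_label_swap_negates_fold_changes(self):
        ds = self.shared_clone_dataset(focal_boost={"g3": 5.0})
        table = build_clonotypes(ds, scope="global")
        fwd = plaque_inducible_signature(ds, table, Tissue.PLAQUE, (Tissue.ATLO,),
                                         alpha=1.1, lfc_thresh=-1.0)
        rev = plaque_inducible_signature(ds, table, Tissue.ATLO, (Tissue.PLAQUE,),
                                         alpha=1.1, lfc_thresh=-1.0)
        a = fwd.degs.set_index("gene")["avg_log2FC"]
        b = rev.degs.set_index("gene")["avg_log2FC"]
        assert np.allclose(a, -b[a.index])

    def test_small_fold_change_excluded(self):
        """A gene with tiny fold change stays out regardless of p value."""
        rng = np.random.default_rng(8)
        genes = ["flat", "shifted"]
        cells, tcr = [], []
        for i in range(40):
            for tissue, prefix in ((Tissue.PLAQUE, "p"), (Tissue.ATLO, "a")):
                bc = f"{prefix}{i}"
                flat = 100 + (1 if tissue is Tissue.PLAQUE else 0)  # tiny LFC, huge p-signal
                shifted = rng.poisson(8.0 if tissue is Tissue.PLAQUE else 1.0)
                cells.append((bc, tissue, [flat, shifted]))
                tcr.append(make_tcr(bc, tra_cdr3="CAF", trb_cdr3="CBF"))
        ds = make_dataset(genes, cells, tcr)
        table = build_clonotypes(ds, scope="global")
        rep = plaque_inducible_signature(ds, table, Tissue.PLAQUE, (Tissue.ATLO,))
        assert "flat" not in set(rep.degs["gene"])
        assert "shifted" in set(rep.degs["gene"])
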