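from math import comb

import pytest

from orgflux.changes import ChangeEvent
from orgflux.duplication import (
    DupNodeRecord,
    DupTestError,
    classify_duplication_origin,
    classify_origins,
    duplication_change_test,
    find_fossil_duplicate_branches,
    flag_child_changes,
    fossil_change_frequency,
    select_high_confidence_nodes,
)
from orgflux.reconcile import lca_reconcile
from orgflux.trees import GeneSpeciesMap, SpeciesAnnotation, read_newick

SPECIES = "((A:1,B:1)AB:1,C:2)ABC;"


def _recon(gtree_text, **gsmap):
    stree = read_newick(SPECIES)
    gtree = read_newick(gtree_text)
    return lca_reconcile(gtree, stree, GeneSpeciesMap(gsmap)), gtree, stree


class TestHighConfidenceSelection:
    def test_full_retention_duplication_qualifies(self):
        recon, gtree, _ = _recon(
            "((a1:1,b1:1):1,(a2:1,b2:1):1)r;", a1="A", b1="B", a2="A", b2="B"
        )
        records = select_high_confidence_nodes("OG", recon)
        dups = [r for r in records if r.node_class == "duplication"]
        assert len(dups) == 1 and dups[0].species_node == "AB"
        assert dups[0].informative

    def test_partial_retention_duplication_fails(self):
        # second copy lost in B: right child clade lacks B
        recon, gtree, _ = _recon(
            "((a1:1,b1:1):1,a2:2)r;", a1="A", b1="B", a2="A"
        )
        records = select_high_confidence_nodes("OG", recon)
        assert not [r for r in records if r.node_class == "duplication"]

    def test_terminal_duplication_uninformative(self):
        recon, gtree, _ = _recon("((a1:1,a2:1):1,b1:2)r;", a1="A", a2="A", b1="B")
        records = select_high_confidence_nodes("OG", recon)
        dups = [r for r in records if r.node_class == "duplication"]
        assert len(dups) == 1
        assert not dups[0].informative  # both children terminal, no scoreable change

    def test_speciation_with_gene_loss_fails(self):
        # root maps to ABC but C is absent below it
        recon, gtree, _ = _recon("(a1:1,b1:1)r;", a1="A", b1="B")
        records = select_high_confidence_nodes("OG", recon)
        names = {(r.node_class, r.gene_node) for r in records}
        assert ("speciation", "r") in names  # maps to AB, full coverage
        recon2, gtree2, _ = _recon("(a1:1,c1:1)r;", a1="A", c1="C")
        records2 = select_high_confidence_nodes("OG", recon2)
        assert not records2  # root maps to ABC, B missing

    def test_speciation_below_duplication_subtree_scope(self):
        text = "(((a1:1,b1:1)s1:1,(a2:1,b2:1)s2:1)dup:1,c1:2)r;"
        recon, gtree, _ = _recon(text, a1="A", b1="B", a2="A", b2="B", c1="C")
        subtree = select_high_confidence_nodes("OG", recon, "subtree")
        spec_names = {r.gene_node for r in subtree if r.node_class == "speciation"}
        assert spec_names == {"s1", "s2"}  # r excluded: dup in its subtree
        local = select_high_confidence_nodes("OG", recon, "local")
        spec_local = {r.gene_node for r in local if r.node_class == "speciation"}
        assert "r" in spec_local


class TestChangeFlag:
    def test_only_immediate_children_count(self):
        recon, gtree, _ = _recon(
            "((a1:1,b1:1)ab:1,(a2:1,b2:1)ab2:1)r;", a1="A", b1="B", a2="A", b2="B"
        )
        records = select_high_confidence_nodes("OG", recon)
        ev = ChangeEvent("OG", "chloroplast", "gain", parent_node="r", child_node="ab")
        flag_child_changes(records, [ev], gtree)
        by_name = {r.gene_node: r for r in records}
        assert by_name["r"].child_change
        assert not by_name["ab"].child_change


class TestTest:
    def _records(self, dup_changed, dup_total, spec_changed, spec_total):
        recs = []
        for i in range(dup_total):
            recs.append(
                DupNodeRecord("OG", f"d{i}", "duplication", "AB", child_change=i < dup_changed)
            )
        for i in range(spec_total):
            recs.append(
                DupNodeRecord("OG", f"s{i}", "speciation", "AB", child_change=i < spec_changed)
            )
        return recs

    def test_no_enrichment_case(self):
        res = duplication_change_test(self._records(5, 10, 50, 100), seed=1)
        assert res["freq_dup"] == 0.5 and res["freq_spec"] == 0.5
        # exact upper tail of the 2x2 by direct combinatorics
        expected = sum(
            comb(55, k) * comb(55, 10 - k) for k in range(5, 11)
        ) / comb(110, 10)
        assert res["hypergeom_p"] == pytest.approx(expected, rel=1e-10)

    def test_extreme_tail_closed_form(self):
        res = duplication_change_test(self._records(10, 10, 0, 100), seed=1)
        assert res["hypergeom_p"] == pytest.approx(1 / comb(110, 10))
        assert res["mc_p"] == pytest.approx(1 / 1001)

    def test_zero_variance_warns(self, caplog):
        with caplog.at_level("WARNING", logger="orgflux"):
            res = duplication_change_test(self._records(0, 10, 0, 100), seed=1)
        assert res["hypergeom_p"] == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(DupTestError):
            duplication_change_test(self._records(0, 10, 0, 0), seed=1)

    def test_printed_results_scale_frequency(self):
        # dataset-scale sanity: 1,072 changed of 19,353 duplications is 5.5%
        res = duplication_change_test(
            self._records(1072, 19353, 220, 10000), n_resamples=10, seed=1
        )
        assert round(100 * res["freq_dup"], 1) == 5.5


class TestOrigin:
    def test_wgd_flag_classification(self):
        ann = SpeciesAnnotation(wgd_branches={"AB"})
        rec = DupNodeRecord("OG", "d", "duplication", "AB")
        assert classify_duplication_origin(rec, ann) == "WGD"
        rec2 = DupNodeRecord("OG", "d", "duplication", "A")
        assert classify_duplication_origin(rec2, ann) == "single-gene"

    def test_speciation_is_na_and_partition_is_exact(self):
        recon, gtree, _ = _recon(
            "((a1:1,b1:1):1,(a2:1,b2:1):1)r;", a1="A", b1="B", a2="A", b2="B"
        )
        records = select_high_confidence_nodes("OG", recon)
        classify_origins(records, recon, SpeciesAnnotation(wgd_branches={"AB"}))
        for r in records:
            if r.node_class == "duplication":
                assert r.origin in ("WGD", "single-gene")
            else:
                assert r.origin == "n/a"

    def test_root_mapped_duplication_single_gene(self, caplog):
        recon, gtree, _ = _recon(
            "(((a1:1,b1:1):1,c1:1):1,((a2:1,b2:1):1,c2:1):1)r;",
            a1="A", b1="B", c1="C", a2="A", b2="B", c2="C",
        )
        records = select_high_confidence_nodes("OG", recon)
        with caplog.at_level("WARNING", logger="orgflux"):
            classify_origins(records, recon, SpeciesAnnotation(wgd_branches=set()))
        dup = [r for r in records if r.node_class == "duplication"]
        assert dup and all(r.origin == "single-gene" for r in dup)


class TestFossils:
    def test_single_copy_lineage_through_wgd(self):
        recon, gtree, _ = _recon("((a1:1,b1:1)ab:1,c1:2)r;", a1="A", b1="B", c1="C")
        ann = SpeciesAnnotation(wgd_branches={"AB"})
        fossils = find_fossil_duplicate_branches(recon, ann)
        assert {n.name for n in fossils} == {"ab"}

    def test_retained_duplicate_not_fossil(self):
        recon, gtree, _ = _recon(
            "(((a1:1,b1:1):1,(a2:1,b2:1):1)dup:1,c1:2)r;",
            a1="A", b1="B", a2="A", b2="B", c1="C",
        )
        ann = SpeciesAnnotation(wgd_branches={"AB"})
        fossils = find_fossil_duplicate_branches(recon, ann)
        assert "dup" not in {n.name for n in fossils}

    def test_no_flags_no_fossils(self):
        recon, gtree, _ = _recon("((a1:1,b1:1)ab:1,c1:2)r;", a1="A", b1="B", c1="C")
        assert find_fossil_duplicate_branches(recon, SpeciesAnnotation()) == []

    def test_fossil_change_frequency(self):
        recon, gtree, _ = _recon("((a1:1,b1:1)ab:1,c1:2)r;", a1="A", b1="B", c1="C")
        ann = SpeciesAnnotation(wgd_branches={"AB"})
        fossils = find_fossil_duplicate_branches(recon, ann)
        ev = ChangeEvent("OG", "chloroplast", "gain", parent_node="r", child_node="ab")
        res = fossil_change_frequency(fossils, [ev])
        assert res == {"n_fossil": 1, "k_fossil": 1, "freq_fossil": 1.0}
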