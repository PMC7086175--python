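from fractions import Fraction

import pytest

from orgflux.changes import (
    binarize,
    call_changes,
    candidate_transitions,
    map_to_species_branches,
    retention_filter,
    tally_changes,
)
from orgflux.reconcile import lca_reconcile
from orgflux.trees import GeneSpeciesMap, read_newick
from oracle_utils import caterpillar_tree

SPECIES = "((A:1,B:1)AB:1,C:2)ABC;"


class TestBinarize:
    def test_tie_goes_to_targeted(self):
        assert binarize({0: 0.5}) == {0: 1}

    def test_below_threshold_untargeted(self):
        assert binarize({0: 0.4999}) == {0: 0}

    def test_all_targeted_no_candidates(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        probs = {n.index: 0.9 for n in tree.postorder}
        states = binarize(probs)
        assert candidate_transitions(tree, states) == []


class TestCandidates:
    def test_directions(self):
        tree = read_newick("((A:1,B:1)ab:1,C:2)r;")
        states = {n.index: 0 for n in tree.postorder}
        ab = tree.node_by_name("ab")
        states[ab.index] = 1  # gain on the branch to ab ...
        states[tree.leaf("A").index] = 1
        states[tree.leaf("B").index] = 0  # ... loss on the branch to B
        cands = {(n.name, d) for n, d in candidate_transitions(tree, states)}
        assert cands == {("ab", "gain"), ("B", "loss")}

    def test_root_never_a_candidate(self):
        tree = read_newick("(A:1,B:1);")
        states = {tree.root.index: 1}
        states[tree.leaf("A").index] = 1
        states[tree.leaf("B").index] = 0
        names = [n.name for n, _ in candidate_transitions(tree, states)]
        assert names == ["B"]


class TestRetentionFilter:
    def _run(self, n_x, k_changed, n_species_x, n_y, k_ancestral):
        tree, gsmap, x_labels, y_labels, x_root = caterpillar_tree(
            n_x, n_y, [f"Xsp{i}" for i in range(n_species_x)]
        )
        tips = {}
        for i, lb in enumerate(x_labels):
            tips[lb] = 1 if i < k_changed else 0  # changed state = 1 (gain)
        for i, lb in enumerate(y_labels):
            tips[lb] = 0 if i < k_ancestral else 1
        return retention_filter((x_root, "gain"), tree, tips, gsmap)

    def test_spec_example_retained(self):
        # X: 4/5 changed (80%), Y: 3/3 ancestral, X spans 2 species
        assert self._run(5, 4, 2, 3, 3)

    def test_exact_75_percent_rejected(self):
        assert not self._run(4, 3, 2, 3, 3)

    def test_single_species_clade_rejected(self):
        assert not self._run(2, 2, 1, 3, 3)

    def test_sister_criterion_enforced(self):
        # sister keeps only 2/4 = 50% ancestral
        assert not self._run(5, 5, 2, 4, 2)

    def test_minimum_support_is_three_genes(self):
        # smallest passing configuration: 2 changed X genes from 2 species
        # plus a single ancestral sister gene
        assert self._run(2, 2, 2, 1, 1)


class TestMapping:
    def _recon(self):
        stree = read_newick(SPECIES)
        gtree = read_newick("(a1:1,c1:1);")  # branch to a1 spans AB then A
        gsmap = GeneSpeciesMap(a1="A", c1="C")
        return lca_reconcile(gtree, stree, gsmap), gtree

    def test_mrca_takes_most_recent(self):
        recon, gtree = self._recon()
        out = map_to_species_branches(gtree.leaf("a1"), recon, "mrca")
        assert out == [("A", Fraction(1))]

    def test_split_distributes_equally(self):
        recon, gtree = self._recon()
        out = map_to_species_branches(gtree.leaf("a1"), recon, "split")
        assert out == [("AB", Fraction(1, 2)), ("A", Fraction(1, 2))]

    def test_single_branch_span_identical_modes(self):
        recon, gtree = self._recon()
        c1 = gtree.leaf("c1")
        assert map_to_species_branches(c1, recon, "mrca") == map_to_species_branches(
            c1, recon, "split"
        )

    def test_empty_span_for_within_species_branch(self):
        stree = read_newick(SPECIES)
        gtree = read_newick("((a1:1,a2:1):1,b1:2);")
        recon = lca_reconcile(gtree, stree, GeneSpeciesMap(a1="A", a2="A", b1="B"))
        assert map_to_species_branches(gtree.leaf("a1"), recon, "mrca") == []


class TestEndToEnd:
    def test_gain_called_and_mapped(self):
        stree = read_newick("((A:1,B:1)AB:1,(C:1,D:1)CD:1)r;")
        gtree = read_newick("((a1:1,b1:1)ab:1,(c1:1,d1:1)cd:1)g;")
        gsmap = GeneSpeciesMap(a1="A", b1="B", c1="C", d1="D")
        recon = lca_reconcile(gtree, stree, gsmap)
        tips = {"a1": 1, "b1": 1, "c1": 0, "d1": 0}
        probs = {gtree.node_by_name(n).index: p for n, p in
                 [("g", 0.1), ("ab", 0.9), ("cd", 0.05)]}
        for lf in gtree.leaves:
            probs[lf.index] = float(tips[lf.label])
        events = call_changes("OG1", "chloroplast", gtree, tips, probs, recon, gsmap)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "gain" and ev.child_node == "ab"
        assert ev.assignments == [("AB", Fraction(1))]
        assert ev.n_support_genes == 4

    def test_conservation_across_modes(self, reference_dataset):
        from orgflux.ancestral import fit_mk

        totals = {}
        for mode in ("mrca", "split"):
            events = []
            for og in reference_dataset.orthogroups:
                recon = lca_reconcile(
                    og.tree, reference_dataset.species_tree, og.gsmap
                )
                fit = fit_mk(og.tree, og.tip_states)
                events.extend(
                    call_changes(
                        og.og_id,
                        "chloroplast",
                        og.tree,
                        og.tip_states,
                        fit.marginal,
                        recon,
                        og.gsmap,
                        mode=mode,
                    )
                )
            weight = sum(
                (w for e in events for _, w in e.assignments), Fraction(0)
            )
            n_mapped = sum(1 for e in events if e.assignments)
            totals[mode] = (len(events), n_mapped, weight)
        assert totals["mrca"] == totals["split"]
        # every mapped event contributes exactly total weight 1
        assert totals["mrca"][2] == totals["mrca"][1]


class TestTally:
    def test_weighted_sums_and_zero_case(self):
        stree = read_newick(SPECIES)
        from orgflux.changes import ChangeEvent

        events = [
            ChangeEvent("OG1", "chloroplast", "gain", "p", "c", [("AB", Fraction(1))]),
            ChangeEvent("OG2", "chloroplast", "gain", "p", "c", [("AB", Fraction(1))]),
            ChangeEvent(
                "OG3",
                "mitochondrion",
                "loss",
                "p",
                "c",
                [("AB", Fraction(1, 2)), ("A", Fraction(1, 2))],
            ),
        ]
        df = tally_changes(events, stree, include_terminal=True)
        gains = df[(df.species_branch == "AB") & (df.direction == "gain")]
        assert gains["count"].iloc[0] == 2.0
        mito = df[df.organelle == "mitochondrion"]
        assert mito["count"].sum() == 1.0
        assert tally_changes([], stree).empty

    def test_terminal_branches_excluded_from_headline(self):
        from orgflux.changes import ChangeEvent

        stree = read_newick(SPECIES)
        events = [
            ChangeEvent("OG1", "peroxisome", "loss", "p", "c", [("A", Fraction(1))])
        ]
        assert tally_changes(events, stree).empty
        assert not tally_changes(events, stree, include_terminal=True).empty
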