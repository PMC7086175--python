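"""Gene-tree / species-tree reconciliation by last-common-ancestor mapping.

Each gene-tree node is mapped to the species-tree LCA of its descendant
species.  A node is a duplication when its mapping coincides with that of
at least one child; otherwise it is a speciation (internal) or leaf.  A
gene-tree branch spans the ordered path of species-tree branches between
the mappings of its endpoints — gene loss can make a single gene branch
span several consecutive species branches.

Externally reconciled trees (e.g. produced by a joint gene-tree/species-
tree method) can be ingested from a sidecar table instead of recomputing
the LCA mapping; downstream stages are agnostic to the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import GeneSpeciesMap, OrgfluxError, PhyloNode, PhyloTree


class ReconciliationError(OrgfluxError):
    pass


@dataclass
class ReconciliationMap:
    gene_tree: PhyloTree
    species_tree: PhyloTree
    species_of: dict = field(default_factory=dict)  # gene node index -> species PhyloNode
    event: dict = field(default_factory=dict)  # gene node index -> leaf|duplication|speciation
    _span_cache: dict = field(default_factory=dict, repr=False)

    def is_duplication(self, node: PhyloNode) -> bool:
        return self.event[node.index] == "duplication"

    def span(self, gene_child: PhyloNode) -> list[PhyloNode]:
        """Ordered (rootward first) species branches spanned by the gene
        branch above ``gene_child``; branches are identified by the species
        node below them.  Empty for within-species (self-mapping) branches.
        """
        if gene_child.parent is None:
            raise ReconciliationError("the root has no branch above it")
        key = gene_child.index
        if key not in self._span_cache:
            top = self.species_of[gene_child.parent.index]
            bottom = self.species_of[key]
            path = []
            node = bottom
            while node is not top:
                if node is None:
                    raise ReconciliationError(
                        "child mapping is not descendant of parent mapping"
                    )
                path.append(node)
                node = node.parent
            path.reverse()
            self._span_cache[key] = path
        return self._span_cache[key]


def _species_lca(a: PhyloNode, b: PhyloNode, depth: dict) -> PhyloNode:
    while depth[a.index] > depth[b.index]:
        a = a.parent
    while depth[b.index] > depth[a.index]:
        b = b.parent
    while a is not b:
        a = a.parent
        b = b.parent
    return a


def lca_reconcile(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    gsmap: GeneSpeciesMap,
) -> ReconciliationMap:
    """Reconcile a binary rooted gene tree against the species tree.

    Raises for nonbinary gene trees (upstream pipelines produce binary
    trees; polytomies would make duplication labelling ambiguous) and for
    genes missing from the map.
    """
    if not gene_tree.is_binary():
        raise ReconciliationError("gene tree is not binary")
    depth = species_tree.depths()
    sp_leaf = {lf.label: lf for lf in species_tree.leaves}

    recon = ReconciliationMap(gene_tree, species_tree)
    for node in gene_tree.postorder:
        if node.is_leaf:
            species = gsmap.get(node.label)
            if species is None:
                raise ReconciliationError(f"gene {node.label!r} has no species mapping")
            if species not in sp_leaf:
                raise ReconciliationError(
                    f"gene {node.label!r} maps to unknown species {species!r}"
                )
            recon.species_of[node.index] = sp_leaf[species]
            recon.event[node.index] = "leaf"
        else:
            left, right = (recon.species_of[c.index] for c in node.children)
            lca = _species_lca(left, right, depth)
            recon.species_of[node.index] = lca
            dup = any(recon.species_of[c.index] is lca for c in node.children)
            recon.event[node.index] = "duplication" if dup else "speciation"
    return recon


def reconciliation_from_table(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    rows,
) -> ReconciliationMap:
    """Ingest a precomputed reconciliation.

    ``rows`` is an iterable of ``(gene_node_name, species_node_name,
    event)`` covering every gene-tree node; events are validated but taken
    verbatim (PHYLDOG-style external reconciliations).
    """
    by_name = {}
    for gname, sname, event in rows:
        by_name[gname] = (sname, event)
    sp_by_name = {n.name: n for n in species_tree.postorder}
    recon = ReconciliationMap(gene_tree, species_tree)
    for node in gene_tree.postorder:
        if node.name not in by_name:
            raise ReconciliationError(f"gene node {node.name!r} absent from table")
        sname, event = by_name[node.name]
        if sname not in sp_by_name:
            raise ReconciliationError(f"unknown species node {sname!r}")
        if event not in ("leaf", "duplication", "speciation"):
            raise ReconciliationError(f"unknown event {event!r}")
        recon.species_of[node.index] = sp_by_name[sname]
        recon.event[node.index] = event
    return recon


def species_branch_span(
    gene_branch_child: PhyloNode, recon: ReconciliationMap
) -> list[PhyloNode]:
    """Convenience wrapper: span of the branch above ``gene_branch_child``."""
    return recon.span(gene_branch_child)


def duplication_count(recon: ReconciliationMap) -> int:
    return sum(1 for ev in recon.event.values() if ev == "duplication")
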