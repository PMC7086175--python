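"""Core tree and table data model.

All downstream stages operate on :class:`PhyloTree` and the small record
types defined here; no stage reads files directly.  Newick parsing and
serialisation are delegated to :mod:`dendropy`; the in-memory tree is a
lightweight indexed structure suited to the traversal-heavy algorithms
(pruning likelihoods, reconciliation, simulation) used throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd

logger = logging.getLogger("orgflux")

COMPARTMENTS = ("chloroplast", "mitochondrion", "secretory", "peroxisome", "none")


class OrgfluxError(Exception):
    """Base class for package errors."""


class NewickError(OrgfluxError):
    """Malformed or unusable newick input."""


class TableError(OrgfluxError):
    """Malformed tabular input."""


class PhyloNode:
    """A node of a rooted tree.

    ``length`` is the length of the branch above the node (substitutions
    per site) or ``None`` when absent; the root's length is ignored by all
    analyses.
    """

    __slots__ = ("index", "label", "length", "parent", "children")

    def __init__(self, label=None, length=None):
        self.index = -1
        self.label = label
        self.length = length
        self.parent: PhyloNode | None = None
        self.children: list[PhyloNode] = []

    @property
    def name(self) -> str:
        """Label if present, else a stable postorder-derived identifier."""
        return self.label if self.label is not None else f"n{self.index}"

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "PhyloNode") -> "PhyloNode":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<PhyloNode {self.name}>"


class PhyloTree:
    """Rooted tree with indexed postorder access.

    Invariants enforced on construction: single root, acyclic parent/child
    links, unique leaf labels.  Node indices are assigned in postorder and
    are stable for the lifetime of the tree.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        self.postorder: list[PhyloNode] = []
        self._index()
        labels = [lf.label for lf in self.leaves]
        if any(lb is None for lb in labels):
            raise NewickError("every leaf must carry a label")
        dup = {lb for lb in labels if labels.count(lb) > 1}
        if dup:
            raise NewickError(f"duplicate leaf labels: {sorted(dup)}")
        self._leaf_by_label = {lf.label: lf for lf in self.leaves}

    def _index(self) -> None:
        order: list[PhyloNode] = []
        stack = [(self.root, False)]
        seen = set()
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                raise NewickError("cycle detected in tree")
            seen.add(id(node))
            stack.append((node, True))
            for child in reversed(node.children):
                if child.parent is not node:
                    raise NewickError("inconsistent parent link")
                stack.append((child, False))
        for i, node in enumerate(order):
            node.index = i
        self.postorder = order

    # -- traversal helpers -------------------------------------------------
    @property
    def preorder(self) -> list[PhyloNode]:
        return list(reversed(self.postorder))

    @property
    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.postorder if n.is_leaf]

    @property
    def internal_nodes(self) -> list[PhyloNode]:
        return [n for n in self.postorder if not n.is_leaf]

    def __len__(self) -> int:
        return len(self.postorder)

    def leaf(self, label: str) -> PhyloNode:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r}") from None

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves]

    def node_by_name(self, name: str) -> PhyloNode:
        for n in self.postorder:
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes)

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.postorder if n is not self.root)

    def leaves_under(self, node: PhyloNode) -> list[PhyloNode]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def depths(self) -> dict[int, int]:
        """Topological depth (edge count from root) per node index."""
        depth = {self.root.index: 0}
        for node in self.preorder:
            for child in node.children:
                depth[child.index] = depth[node.index] + 1
        return depth

    def copy(self) -> "PhyloTree":
        mapping: dict[int, PhyloNode] = {}
        for node in self.postorder:
            clone = PhyloNode(node.label, node.length)
            for child in node.children:
                clone.add_child(mapping[child.index])
            mapping[node.index] = clone
        return PhyloTree(mapping[self.root.index])

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree {len(self.leaves)} leaves>"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> PhyloNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            label = dnode.label
        node = PhyloNode(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node))


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: PhyloNode, dnode) -> None:
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = taxa.new_taxon(node.label)
        else:
            dnode.label = node.label
            for child in node.children:
                convert(child, dnode.new_child())

    convert(tree.root, dtree.seed_node)
    return dtree


def read_newick(source: str) -> PhyloTree:
    """Parse a newick string (or path ending in ``.nwk``/``.tre``/``.newick``).

    Branch lengths and internal labels are optional and preserved.
    Duplicate leaf labels or malformed syntax raise :class:`NewickError`.
    """
    text = source
    if not source.lstrip().startswith("(") and source.endswith((".nwk", ".tre", ".newick", ".txt")):
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree) -> str:
    dtree = _to_dendropy(tree)
    return dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalizationCall:
    """Predicted subcellular compartment for one gene.

    ``dual_peroxisomal`` marks genes carrying a peroxisomal targeting
    signal on top of a positive chloroplast/mitochondrion/secretory
    prediction.
    """

    gene_id: str
    compartment: str
    dual_peroxisomal: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise TableError(
                f"unknown compartment {self.compartment!r} for {self.gene_id}; "
                f"allowed: {', '.join(COMPARTMENTS)}"
            )
        if self.dual_peroxisomal and self.compartment == "none":
            raise TableError(f"{self.gene_id}: dual-peroxisomal requires a compartment")


@dataclass
class SpeciesAnnotation:
    """Auxiliary species-tree data: WGD-flagged branches and node ages.

    Branches are identified by the name of the node below them.  Ages are
    in million years, decreasing root to tips; the root age default (450)
    corresponds to the origin of land plants.
    """

    wgd_branches: set = field(default_factory=set)
    node_ages: dict = field(default_factory=dict)
    root_age: float = 450.0

    def validate(self, species_tree: PhyloTree) -> None:
        names = {n.name for n in species_tree.postorder}
        missing = self.wgd_branches - names
        if missing:
            raise TableError(f"WGD flags on unknown branches: {sorted(missing)}")
        if species_tree.root.name in self.wgd_branches:
            raise TableError("the root has no branch above it to flag as WGD")
        for name, age in self.node_ages.items():
            if name not in names:
                raise TableError(f"dated node {name!r} not in species tree")
            if age < 0:
                raise TableError(f"negative age for node {name!r}")
        for node in species_tree.postorder:
            if node.name in self.node_ages and node.parent is not None:
                panc = node.parent.name
                if panc in self.node_ages and self.node_ages[panc] < self.node_ages[node.name]:
                    raise TableError(f"node {node.name!r} older than its parent")


class GeneSpeciesMap(dict):
    """gene_id -> species_id mapping."""

    def validate(self, gene_tree: PhyloTree, species_tree: PhyloTree) -> None:
        species = set(species_tree.leaf_labels)
        for gene in gene_tree.leaf_labels:
            if gene not in self:
                raise TableError(f"gene {gene!r} missing from gene-species map")
            if self[gene] not in species:
                raise TableError(
                    f"gene {gene!r} maps to unknown species {self[gene]!r}"
                )


# ---------------------------------------------------------------------------
# Tabular readers (TSV, tab-separated, header row, '#' comments)
# ---------------------------------------------------------------------------


def _read_tsv(source) -> pd.DataFrame:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep="\t", comment="#", dtype=str)


def read_localization_table(source) -> dict[str, LocalizationCall]:
    """Read a localization TSV (columns ``gene_id``, ``compartment``,
    optional ``dual_peroxisomal``) into calls keyed by gene.

    Stands in for TargetP/PredAlgo output.  Duplicated gene ids are an
    error; an empty table is allowed with a warning.
    """
    df = _read_tsv(source)
    for col in ("gene_id", "compartment"):
        if col not in df.columns:
            raise TableError(f"localization table lacks column {col!r}")
    if df.empty:
        logger.warning("localization table is empty")
        return {}
    dups = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dups:
        raise TableError(f"duplicate gene ids in localization table: {sorted(set(dups))}")
    calls = {}
    for row in df.itertuples(index=False):
        dual = False
        if hasattr(row, "dual_peroxisomal") and isinstance(row.dual_peroxisomal, str):
            dual = row.dual_peroxisomal.strip().lower() in ("1", "true", "yes")
        calls[row.gene_id] = LocalizationCall(row.gene_id, row.compartment, dual)
    return calls


def read_gene_species_map(source) -> GeneSpeciesMap:
    df = _read_tsv(source)
    for col in ("gene_id", "species_id"):
        if col not in df.columns:
            raise TableError(f"gene-species map lacks column {col!r}")
    if df["gene_id"].duplicated().any():
        raise TableError("duplicate gene ids in gene-species map")
    return GeneSpeciesMap(zip(df["gene_id"], df["species_id"]))


def read_term_table(source) -> dict[str, set]:
    """Read gene->terms from a TSV with columns ``gene_id``, ``term``."""
    df = _read_tsv(source)
    for col in ("gene_id", "term"):
        if col not in df.columns:
            raise TableError(f"term table lacks column {col!r}")
    terms: dict[str, set] = {}
    for row in df.itertuples(index=False):
        terms.setdefault(row.gene_id, set()).add(row.term)
    return terms


def read_species_annotation(wgd_source=None, ages_source=None, root_age=450.0) -> SpeciesAnnotation:
    """WGD TSV has column ``branch``; ages TSV has ``node``, ``age_my``."""
    ann = SpeciesAnnotation(root_age=root_age)
    if wgd_source is not None:
        df = _read_tsv(wgd_source)
        if "branch" not in df.columns:
            raise TableError("WGD table lacks column 'branch'")
        ann.wgd_branches = set(df["branch"])
    if ages_source is not None:
        df = _read_tsv(ages_source)
        for col in ("node", "age_my"):
            if col not in df.columns:
                raise TableError(f"node-age table lacks column {col!r}")
        ann.node_ages = {r.node: float(r.age_my) for r in df.itertuples(index=False)}
    return ann


def trait_states(
    calls: dict[str, LocalizationCall],
    organelle: str,
    genes,
) -> dict[str, int]:
    """Binary presence/absence of targeting to ``organelle`` per gene.

    Genes absent from the localization table are treated as untargeted
    ("none") with a warning.  Dual-peroxisomal genes count as targeted for
    both the peroxisome trait and their external-compartment trait.
    """
    if organelle not in COMPARTMENTS or organelle == "none":
        raise ValueError(f"invalid organelle {organelle!r}")
    states = {}
    missing = []
    for gene in genes:
        call = calls.get(gene)
        if call is None:
            missing.append(gene)
            states[gene] = 0
            continue
        hit = call.compartment == organelle
        if organelle == "peroxisome" and call.dual_peroxisomal:
            hit = True
        states[gene] = int(hit)
    if missing:
        logger.warning(
            "%d genes absent from the localization table; treated as untargeted",
            len(missing),
        )
    return states
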