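"""Association between gene duplication and targeting change.

High-confidence duplication nodes retain the duplication in every
descendant species of both child clades; high-confidence speciation nodes
have no duplication anywhere in their subtree and no gene loss in any
descendant species.  Both definitions imply complete gene retention, so
the two node sets are comparable and their child branches unambiguously
placed in the species tree.  For each such node we score whether a
retained targeting change lies on either of its two immediate child
branches, then compare the change frequencies between classes with an
upper-tail hypergeometric test and a matched Monte Carlo resampling that
equalises the species-node distribution of the two classes.

Duplications are stratified by origin: those mapped under a species
branch carrying a whole-genome duplication (or triplication) flag versus
single-gene duplications.  "Fossil duplicates" — single-copy lineages
whose branch passes through a WGD species branch, implying a duplicate
that was created and lost again — are identified from the reconciliation
spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .reconcile import ReconciliationMap
from .trees import OrgfluxError, PhyloNode, SpeciesAnnotation

logger = logging.getLogger("orgflux")


class DupTestError(OrgfluxError):
    pass


@dataclass
class DupNodeRecord:
    orthogroup: str
    gene_node: str
    node_class: str  # duplication | speciation
    species_node: str
    origin: str = "n/a"  # WGD | single-gene | n/a
    child_change: bool = False
    #: both child branches subtend >= 2 species, so a retained change is
    #: callable on either; only informative records enter the association
    #: test, keeping the two node classes comparable (a change can never
    #: pass the >=2-species filter below a terminal branch, and informative
    #: duplication nodes always have two callable children)
    informative: bool = True


def _species_leafsets(recon: ReconciliationMap) -> dict[int, frozenset]:
    sets: dict[int, frozenset] = {}
    for node in recon.species_tree.postorder:
        if node.is_leaf:
            sets[node.index] = frozenset([node.label])
        else:
            sets[node.index] = frozenset().union(
                *(sets[c.index] for c in node.children)
            )
    return sets


def select_high_confidence_nodes(
    orthogroup: str,
    recon: ReconciliationMap,
    speciation_scope: str = "local",
) -> list[DupNodeRecord]:
    """Apply the stringent node filters to one reconciled gene tree.

    A speciation node qualifies when the node itself is a speciation and
    there is no evidence of gene loss anywhere in its subtree.  Under
    ``speciation_scope='local'`` (default) duplications below the node are
    tolerated provided they are fully retained (both duplicate copies
    present in every descendant species), so complete retention of all
    genes in all descendant species holds for both node classes; the
    stricter ``'subtree'`` variant additionally demands no duplication at
    all below the node, shrinking the comparison set to families that
    stayed single-copy.
    """
    if speciation_scope not in ("subtree", "local"):
        raise ValueError("speciation_scope must be 'subtree' or 'local'")
    gene_tree = recon.gene_tree
    sp_leafsets = _species_leafsets(recon)

    gene_species: dict[int, frozenset] = {}
    has_dup_below: dict[int, bool] = {}
    retained: dict[int, bool] = {}  # no evidence of gene loss in the subtree
    for node in gene_tree.postorder:
        i = node.index
        if node.is_leaf:
            gene_species[i] = frozenset([recon.species_of[i].label])
            has_dup_below[i] = False
            retained[i] = True
            continue
        gene_species[i] = frozenset().union(
            *(gene_species[c.index] for c in node.children)
        )
        has_dup_below[i] = recon.is_duplication(node) or any(
            has_dup_below[c.index] for c in node.children
        )
        kids_ok = all(retained[c.index] for c in node.children)
        required = sp_leafsets[recon.species_of[i].index]
        if recon.is_duplication(node):
            # a retained duplication keeps both copies in every species
            retained[i] = kids_ok and all(
                required <= gene_species[c.index] for c in node.children
            )
        else:
            retained[i] = kids_ok and gene_species[i] == required

    records = []
    for node in gene_tree.internal_nodes:
        sp_node = recon.species_of[node.index]
        required = sp_leafsets[sp_node.index]
        event = recon.event[node.index]
        if event == "duplication":
            if all(required <= gene_species[c.index] for c in node.children):
                records.append(
                    DupNodeRecord(
                        orthogroup=orthogroup,
                        gene_node=node.name,
                        node_class="duplication",
                        species_node=sp_node.name,
                        informative=_informative(node, gene_species),
                    )
                )
        elif event == "speciation":
            no_dup = (
                not has_dup_below[node.index]
                if speciation_scope == "subtree"
                else True
            )
            if no_dup and retained[node.index]:
                records.append(
                    DupNodeRecord(
                        orthogroup=orthogroup,
                        gene_node=node.name,
                        node_class="speciation",
                        species_node=sp_node.name,
                        informative=_informative(node, gene_species),
                    )
                )
    return records


def _informative(node: PhyloNode, gene_species: dict) -> bool:
    return all(len(gene_species[c.index]) >= 2 for c in node.children)


def flag_child_changes(records: list[DupNodeRecord], recon_events, gene_tree) -> None:
    """Set ``child_change`` from retained events of any organelle.

    ``recon_events`` is an iterable of ChangeEvents for this orthogroup;
    a record scores when an event's gene branch hangs directly below the
    record's node.
    """
    changed_parents = {ev.parent_node for ev in recon_events}
    for rec in records:
        rec.child_change = rec.gene_node in changed_parents


def duplication_change_test(
    records: list[DupNodeRecord],
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Compare child-change frequencies of duplication vs speciation nodes.

    Only informative records (both child branches subtending >= 2 species,
    so a retained change is callable on either) enter the 2x2.  The hypergeometric p is
    upper-tailed on duplication-class changes.  The matched Monte Carlo
    draws speciation nodes to mirror the duplication set's size and
    species-node distribution and compares change frequencies, with the
    add-one estimator.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dup = [r for r in records if r.informative and r.node_class == "duplication"]
    spec = [r for r in records if r.informative and r.node_class == "speciation"]
    if not dup or not spec:
        raise DupTestError("both duplication and speciation classes must be nonempty")
    k_dup = sum(r.child_change for r in dup)
    k_spec = sum(r.child_change for r in spec)
    n_dup, n_spec = len(dup), len(spec)
    N = n_dup + n_spec
    K = k_dup + k_spec
    result = {
        "n_dup": n_dup,
        "n_spec": n_spec,
        "k_dup": k_dup,
        "k_spec": k_spec,
        "freq_dup": k_dup / n_dup,
        "freq_spec": k_spec / n_spec,
    }
    if K == 0 or K == N:
        logger.warning("no variance in child-change flags; tests uninformative")
        result.update({"hypergeom_p": 1.0, "mc_p": 1.0})
        return result
    result["hypergeom_p"] = float(hypergeom.sf(k_dup - 1, N, K, n_dup))

    by_node: dict[str, np.ndarray] = {}
    for r in spec:
        by_node.setdefault(r.species_node, []).append(r.child_change)
    pools = {k: np.array(v, dtype=float) for k, v in by_node.items()}
    strata: dict[str, int] = {}
    for r in dup:
        strata[r.species_node] = strata.get(r.species_node, 0) + 1
    all_spec = np.array([r.child_change for r in spec], dtype=float)
    sums = np.zeros(n_resamples)
    for node, count in strata.items():
        pool = pools.get(node)
        if pool is None:
            logger.warning(
                "no speciation nodes mapped to %s; matching from the pooled set",
                node,
            )
            pool = all_spec
        sums += rng.choice(pool, size=(n_resamples, count), replace=True).sum(axis=1)
    freqs = sums / n_dup
    result["mc_p"] = (1 + int(np.sum(freqs >= result["freq_dup"]))) / (1 + n_resamples)
    result["n_resamples"] = n_resamples
    return result


def classify_duplication_origin(
    record: DupNodeRecord, annotation: SpeciesAnnotation
) -> str:
    """WGD iff the species branch above the record's mapped node is flagged.

    Speciation records get ``n/a``; a duplication mapped to the species
    root (no branch above) is classed single-gene with a warning.
    """
    if record.node_class != "duplication":
        return "n/a"
    return "WGD" if record.species_node in annotation.wgd_branches else "single-gene"


def classify_origins(
    records: list[DupNodeRecord],
    recon: ReconciliationMap,
    annotation: SpeciesAnnotation,
) -> None:
    root_name = recon.species_tree.root.name
    for rec in records:
        if rec.node_class != "duplication":
            rec.origin = "n/a"
            continue
        if rec.species_node == root_name:
            logger.warning(
                "duplication %s maps to the species root; classed single-gene",
                rec.gene_node,
            )
            rec.origin = "single-gene"
        else:
            rec.origin = classify_duplication_origin(rec, annotation)


def find_fossil_duplicate_branches(
    recon: ReconciliationMap,
    annotation: SpeciesAnnotation,
) -> list[PhyloNode]:
    """Gene branches that crossed a WGD species branch in single copy.

    A branch qualifies when its reconciliation span includes a WGD-flagged
    species branch and its lower endpoint is not a duplication mapped to
    the node below that branch (which would be the retained WGD
    duplicate).  Such lineages must have duplicated at the WGD and lost
    one copy again before the next speciation.
    """
    if not annotation.wgd_branches:
        return []
    out = []
    for node in recon.gene_tree.postorder:
        if node.parent is None:
            continue
        span = recon.span(node)
        for sp in span:
            if sp.name not in annotation.wgd_branches:
                continue
            retained = (
                not node.is_leaf
                and recon.is_duplication(node)
                and recon.species_of[node.index] is sp
            )
            if not retained:
                out.append(node)
                break
    return out


def fossil_change_frequency(
    fossil_branches: list[PhyloNode], events
) -> dict:
    """Fraction of fossil-duplicate branches carrying a retained change."""
    changed = {ev.child_node for ev in events}
    n = len(fossil_branches)
    k = sum(1 for b in fossil_branches if b.name in changed)
    return {"n_fossil": n, "k_fossil": k, "freq_fossil": k / n if n else float("nan")}
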