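"""Calling retained gains and losses of organellar targeting.

Marginal ancestral probabilities are binarized winner-takes-all (targeted
when P >= 0.5).  A candidate change is any gene-tree branch whose parent
and child states differ.  Candidates survive a stringent retention filter:
strictly more than 75% of the extant genes descending from the change
branch must show the changed state, strictly more than 75% of genes under
the sister branch must keep the ancestral state, and the change branch
must subtend genes from at least two species.  Descendant states are the
*observed* tip localizations, so every retained call is informed by at
least three extant genes.

Retained events are mapped onto species-tree branches through the
reconciliation span: either wholly to the most recent spanned branch
(``mrca``, the primary analysis) or split equally across all spanned
branches (``split``, the sensitivity analysis).  Weights are exact
rationals so tallies conserve event counts under both modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .reconcile import ReconciliationMap
from .trees import GeneSpeciesMap, PhyloNode, PhyloTree

logger = logging.getLogger("orgflux")

RETENTION_FRACTION = 0.75
MIN_SPECIES = 2


@dataclass
class ChangeEvent:
    orthogroup: str
    organelle: str
    direction: str  # gain | loss
    parent_node: str
    child_node: str
    #: (species branch id = name of the node below the branch, weight)
    assignments: list = field(default_factory=list)
    within_species: bool = False
    n_support_genes: int = 0

    @property
    def span_length(self) -> int:
        return len(self.assignments)


def binarize(probabilities: dict, threshold: float = 0.5) -> dict:
    """Winner-takes-all state per node: 1 iff P(targeted) >= threshold."""
    return {k: int(p >= threshold) for k, p in probabilities.items()}


def candidate_transitions(tree: PhyloTree, states: dict) -> list[tuple[PhyloNode, str]]:
    """Branches whose endpoint states differ.

    ``states`` maps node index -> 0/1 for every node (leaves included).
    Returns ``(child_node, direction)`` per candidate; the root has no
    branch above it and never appears.
    """
    out = []
    for node in tree.postorder:
        if node.parent is None:
            continue
        parent_state = states[node.parent.index]
        child_state = states[node.index]
        if parent_state != child_state:
            out.append((node, "gain" if child_state == 1 else "loss"))
    return out


def retention_filter(
    candidate: tuple[PhyloNode, str],
    tree: PhyloTree,
    tip_states: dict,
    gsmap: GeneSpeciesMap,
    fraction: float = RETENTION_FRACTION,
    min_species: int = MIN_SPECIES,
) -> bool:
    """Decide whether a candidate change is retained.

    Both descendant-retention criteria are strict inequalities; exactly
    75% fails.  Tip states are the observed localizations of extant
    genes.
    """
    node, direction = candidate
    parent = node.parent
    if parent is None:
        return False
    siblings = [c for c in parent.children if c is not node]
    if len(siblings) != 1:
        logger.warning(
            "candidate on %s rejected: nonbinary bipartition", node.name
        )
        return False
    sister = siblings[0]
    changed_state = 1 if direction == "gain" else 0
    ancestral_state = 1 - changed_state

    x_leaves = tree.leaves_under(node)
    y_leaves = tree.leaves_under(sister)
    if len({gsmap[lf.label] for lf in x_leaves}) < min_species:
        return False
    frac_changed = sum(
        1 for lf in x_leaves if tip_states[lf.label] == changed_state
    ) / len(x_leaves)
    frac_ancestral = sum(
        1 for lf in y_leaves if tip_states[lf.label] == ancestral_state
    ) / len(y_leaves)
    return frac_changed > fraction and frac_ancestral > fraction


def map_to_species_branches(
    child_node: PhyloNode,
    recon: ReconciliationMap,
    mode: str = "mrca",
) -> list[tuple[str, Fraction]]:
    """Weighted species-branch assignment for the branch above ``child_node``.

    ``mrca`` puts weight 1 on the most recent (tipward) spanned branch;
    ``split`` spreads weight 1/k over all k spanned branches.  An empty
    span (within-species branch under a duplication) yields no
    assignment.
    """
    if mode not in ("mrca", "split"):
        raise ValueError("mode must be 'mrca' or 'split'")
    span = recon.span(child_node)
    if not span:
        return []
    if mode == "mrca":
        return [(span[-1].name, Fraction(1))]
    k = len(span)
    return [(sp.name, Fraction(1, k)) for sp in span]


def call_changes(
    orthogroup: str,
    organelle: str,
    tree: PhyloTree,
    tip_states: dict,
    node_probabilities: dict,
    recon: ReconciliationMap,
    gsmap: GeneSpeciesMap,
    mode: str = "mrca",
    threshold: float = 0.5,
) -> list[ChangeEvent]:
    """Full calling stage for one orthogroup and one organelle trait.

    ``node_probabilities`` maps node index -> P(targeted) from ancestral
    estimation; leaf entries are overridden by the observed tip states so
    that candidates at the tips reflect the data, as the marginals do.
    Overlapping candidates on nested branches are filtered independently.
    """
    states = binarize(node_probabilities, threshold)
    for lf in tree.leaves:
        states[lf.index] = int(tip_states[lf.label])
    events = []
    for candidate in candidate_transitions(tree, states):
        if not retention_filter(candidate, tree, tip_states, gsmap):
            continue
        node, direction = candidate
        assignments = map_to_species_branches(node, recon, mode)
        sister = [c for c in node.parent.children if c is not node][0]
        support = len(tree.leaves_under(node)) + len(tree.leaves_under(sister))
        events.append(
            ChangeEvent(
                orthogroup=orthogroup,
                organelle=organelle,
                direction=direction,
                parent_node=node.parent.name,
                child_node=node.name,
                assignments=assignments,
                within_species=not assignments,
                n_support_genes=support,
            )
        )
    return events


def tally_changes(
    events, species_tree: PhyloTree, include_terminal: bool = False
) -> pd.DataFrame:
    """Weighted gain/loss totals per species branch and organelle.

    Nonterminal branches form the headline table; terminal branches are
    returned too when ``include_terminal`` (the sidecar).  Within-species
    events carry no species-branch assignment and are excluded.
    """
    terminal = {n.name for n in species_tree.leaves}
    totals: dict[tuple[str, str, str], Fraction] = {}
    for ev in events:
        for branch, weight in ev.assignments:
            if branch in terminal and not include_terminal:
                continue
            key = (branch, ev.organelle, ev.direction)
            totals[key] = totals.get(key, Fraction(0)) + weight
    rows = [
        {
            "species_branch": b,
            "organelle": org,
            "direction": d,
            "count": float(w),
        }
        for (b, org, d), w in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["species_branch", "organelle", "direction", "count"])
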