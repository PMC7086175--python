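"""Independent oracles used across the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
formulas) and shares no code with the implementation paths it checks.
"""

import itertools
import math

from orgflux.ancestral import MkModel, transition_matrix


def enumeration_log_likelihood(tree, tip_states, model: MkModel, prior=(0.5, 0.5)):
    """Brute-force likelihood: sum over all internal state assignments."""
    internal = [n for n in tree.postorder if not n.is_leaf]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = {n.index: s for n, s in zip(internal, assign)}
        for lf in tree.leaves:
            states[lf.index] = tip_states[lf.label]
        p = prior[states[tree.root.index]]
        for n in tree.postorder:
            if n.parent is None:
                continue
            P = transition_matrix(model, max(n.length, 1e-9))
            p *= P[states[n.parent.index], states[n.index]]
        total += p
    return math.log(total)


def enumeration_marginals(tree, tip_states, model: MkModel, prior=(0.5, 0.5)):
    """Brute-force marginal P(state 1) per node index."""
    internal = [n for n in tree.postorder if not n.is_leaf]
    total = 0.0
    marg = {n.index: 0.0 for n in tree.postorder}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = {n.index: s for n, s in zip(internal, assign)}
        for lf in tree.leaves:
            states[lf.index] = tip_states[lf.label]
        p = prior[states[tree.root.index]]
        for n in tree.postorder:
            if n.parent is None:
                continue
            P = transition_matrix(model, max(n.length, 1e-9))
            p *= P[states[n.parent.index], states[n.index]]
        total += p
        for i, s in states.items():
            if s == 1:
                marg[i] += p
    return {i: m / total for i, m in marg.items()}


def bh_stepup(pvalues):
    """Benjamini-Hochberg q-values by the step-up formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[idx] * m / rank)
        q[idx] = prev
    return q


def caterpillar_tree(n_x, n_y, species_x, length=0.5):
    """Binary tree with a bipartition into clades X (n_x leaves) and Y
    (n_y leaves) hanging off one internal node; X leaves are assigned the
    species labels in ``species_x`` cyclically, Y leaves one species each.

    Returns (tree, gsmap, x_labels, y_labels, change_child_node).
    """
    from orgflux.trees import GeneSpeciesMap, PhyloNode, PhyloTree

    def clade(labels):
        nodes = [PhyloNode(label=lb, length=length) for lb in labels]
        while len(nodes) > 1:
            a = nodes.pop()
            b = nodes.pop()
            parent = PhyloNode(length=length)
            parent.add_child(a)
            parent.add_child(b)
            nodes.append(parent)
        return nodes[0]

    x_labels = [f"x{i}" for i in range(n_x)]
    y_labels = [f"y{i}" for i in range(n_y)]
    top = PhyloNode()
    x_root = clade(x_labels)
    y_root = clade(y_labels)
    top.add_child(x_root)
    top.add_child(y_root)
    tree = PhyloTree(top)
    gsmap = GeneSpeciesMap()
    for i, lb in enumerate(x_labels):
        gsmap[lb] = species_x[i % len(species_x)]
    for i, lb in enumerate(y_labels):
        gsmap[lb] = f"Ysp{i}"
    return tree, gsmap, x_labels, y_labels, x_root
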