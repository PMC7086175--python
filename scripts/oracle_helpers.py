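"""Small tree constructors used by the acceptance script."""

from orgflux.trees import GeneSpeciesMap, PhyloNode, PhyloTree


def caterpillar(n_x: int, n_y: int, n_species_x: int, length: float = 0.5):
    """Binary tree with clades X (n_x leaves) and Y (n_y leaves) under one
    bipartition; X leaves cycle over ``n_species_x`` species labels, Y
    leaves get one species each."""

    def clade(labels):
        nodes = [PhyloNode(label=lb, length=length) for lb in labels]
        while len(nodes) > 1:
            a, b = nodes.pop(), nodes.pop()
            parent = PhyloNode(length=length)
            parent.add_child(a)
            parent.add_child(b)
            nodes.append(parent)
        return nodes[0]

    x_labels = [f"x{i}" for i in range(n_x)]
    y_labels = [f"y{i}" for i in range(n_y)]
    top = PhyloNode()
    x_root = clade(x_labels)
    top.add_child(x_root)
    top.add_child(clade(y_labels))
    tree = PhyloTree(top)
    gsmap = GeneSpeciesMap()
    for i, lb in enumerate(x_labels):
        gsmap[lb] = f"Xsp{i % n_species_x}"
    for i, lb in enumerate(y_labels):
        gsmap[lb] = f"Ysp{i}"
    return tree, gsmap, x_labels, y_labels, x_root
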