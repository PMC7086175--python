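"""Synthetic data with full ground truth for every pipeline stage.

The generator emulates the data a comparative study of organellar
targeting consumes: a Yule species tree with node ages; duplication-loss
gene trees evolved along it (Poisson duplication and loss per unit branch
length, plus optional whole-genome-duplication branches where every
lineage duplicates with a fixed probability at the branch midpoint); a
binary targeting trait evolved under a two-rate Markov process whose gain
and loss rates are multiplied by kappa on the two branches immediately
following each duplication; molecular branch lengths equal to the
species-path length times lognormal rate jitter, times rho on branches
where the trait actually changed; protein sequences with planted
peroxisomal targeting motifs; and term annotations with planted
enrichment.  kappa = 1 and rho = 1 recover the null model exactly.

Every stochastic choice flows from a single numpy ``SeedSequence`` so a
dataset is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import GeneSpeciesMap, OrgfluxError, PhyloNode, PhyloTree, SpeciesAnnotation

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(OrgfluxError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults define the reference study conditions.

    Rates are per unit of species-tree branch length.  ``kappa`` scales
    both trait rates on post-duplication branches; ``rho`` scales the
    molecular length of branches on which the trait changed.
    """

    n_species: int = 20
    n_orthogroups: int = 50
    birth_rate: float = 1.0
    dup_rate: float = 0.7
    loss_rate: float = 0.02
    alpha: float = 0.04  # trait gain rate
    beta: float = 0.08  # trait loss rate
    kappa: float = 1.0  # post-duplication trait-rate multiplier
    rho: float = 1.0  # molecular-rate multiplier on change branches
    #: lognormal sd of the per-family molecular-rate factor (gene-level
    #: rate variation, the dominant component in real gene families)
    family_rate_sigma: float = 0.25
    #: lognormal sd of the residual per-branch rate wiggle
    rate_jitter_sigma: float = 0.05
    n_wgd_branches: int = 0
    wgd_probability: float = 0.8
    root_age: float = 450.0
    organelle: str = "chloroplast"
    min_genes: int = 4
    min_species: int = 2
    max_retries: int = 500

    def __post_init__(self):
        for name in ("birth_rate", "dup_rate", "loss_rate", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be nonnegative")
        if self.kappa < 1 or self.rho <= 0:
            raise SimulationError("kappa must be >= 1 and rho > 0")


@dataclass
class OrthogroupTruth:
    """Ground truth for one simulated gene family."""

    dup_nodes: set = field(default_factory=set)  # names of surviving dup nodes
    wgd_dup_nodes: set = field(default_factory=set)
    post_dup_branches: set = field(default_factory=set)  # child-node names
    events: list = field(default_factory=list)  # (child_node, direction, species_branch)
    change_branches: set = field(default_factory=set)
    node_states: dict = field(default_factory=dict)  # node name -> 0/1


@dataclass
class SimOrthogroup:
    og_id: str
    tree: PhyloTree
    gsmap: GeneSpeciesMap
    tip_states: dict
    truth: OrthogroupTruth


@dataclass
class SimulatedDataset:
    config: SimConfig
    species_tree: PhyloTree
    annotation: SpeciesAnnotation
    orthogroups: list


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    root_age: float = 450.0,
) -> tuple[PhyloTree, SpeciesAnnotation]:
    """Ultrametric Yule tree; internal-node ages scaled to ``root_age`` My."""
    if n_species < 2:
        raise SimulationError("need at least two species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = PhyloNode()
    active = []  # (node, birth_time)
    t = 0.0
    for _ in range(2):
        child = root.add_child(PhyloNode())
        active.append((child, t))
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, birth = active.pop(int(i))
        node.length = t - birth
        for _ in range(2):
            active.append((node.add_child(PhyloNode()), t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    for k, (node, birth) in enumerate(active):
        node.length = t_end - birth
    # stable left-to-right leaf naming
    counter = [0]

    def name_leaves(node: PhyloNode):
        if node.is_leaf:
            counter[0] += 1
            node.label = f"S{counter[0]:02d}"
        for c in node.children:
            name_leaves(c)

    name_leaves(root)
    tree = PhyloTree(root)
    ann = SpeciesAnnotation(root_age=root_age)
    depth = {tree.root.index: 0.0}
    for node in tree.preorder:
        for c in node.children:
            depth[c.index] = depth[node.index] + c.length
    for node in tree.internal_nodes:
        if node is tree.root:
            continue  # the root's age is the root_age field itself
        ann.node_ages[node.name] = root_age * (t_end - depth[node.index]) / t_end
    return tree, ann


# ---------------------------------------------------------------------------
# Gene trees (duplication-loss along the species tree)
# ---------------------------------------------------------------------------


class _GNode:
    __slots__ = ("kind", "sp", "depth", "children", "wgd")

    def __init__(self, kind, sp, depth, wgd=False):
        self.kind = kind  # root|dup|spec|leaf|loss
        self.sp = sp  # species node at/under which the event sits
        self.depth = depth  # cumulative species-path distance from the root
        self.children = []
        self.wgd = wgd


def _evolve_edge(parent, sp_node, offset, ctx):
    """Continue one gene lineage along the species branch above ``sp_node``
    starting ``offset`` into the branch."""
    rng, dup_rate, loss_rate, wgd_set, wgd_p = ctx
    L = sp_node.length
    depth_top = _sp_depth(sp_node) - L
    pos = offset
    wgd_point = L / 2.0 if sp_node.name in wgd_set else None
    while True:
        t_dup = pos + rng.exponential(1.0 / dup_rate) if dup_rate > 0 else math.inf
        t_loss = pos + rng.exponential(1.0 / loss_rate) if loss_rate > 0 else math.inf
        t_wgd = wgd_point if wgd_point is not None and wgd_point > pos else math.inf
        t_min = min(t_dup, t_loss, t_wgd, L)
        if t_min == L:
            if sp_node.is_leaf:
                node = _GNode("leaf", sp_node, depth_top + L)
                parent.children.append(node)
            else:
                node = _GNode("spec", sp_node, depth_top + L)
                parent.children.append(node)
                for sp_child in sp_node.children:
                    _evolve_edge(node, sp_child, 0.0, ctx)
            return
        if t_min == t_wgd:
            pos = t_wgd
            wgd_point = None
            if rng.random() < wgd_p:
                node = _GNode("dup", sp_node, depth_top + pos, wgd=True)
                parent.children.append(node)
                for _ in range(2):
                    _evolve_edge(node, sp_node, pos, ctx)
                return
            continue
        if t_loss <= t_dup:
            parent.children.append(_GNode("loss", sp_node, depth_top + t_loss))
            return
        pos = t_dup
        node = _GNode("dup", sp_node, depth_top + pos)
        parent.children.append(node)
        for _ in range(2):
            _evolve_edge(node, sp_node, pos, ctx)
        return


def _sp_depth(sp_node) -> float:
    d = 0.0
    n = sp_node
    while n.parent is not None:
        d += n.length
        n = n.parent
    return d


def simulate_gene_tree(
    species_tree: PhyloTree,
    dup_rate: float,
    loss_rate: float,
    seed: int | np.random.Generator = 0,
    wgd_branches: set | None = None,
    wgd_probability: float = 0.8,
    og_id: str = "OG0",
    min_genes: int = 1,
    min_species: int = 1,
    max_retries: int = 500,
) -> tuple[PhyloTree, GeneSpeciesMap, OrthogroupTruth]:
    """One duplication-loss gene family evolved along the species tree.

    Branch lengths are the raw species-path lengths (no rate jitter yet).
    Families falling below ``min_genes`` genes or ``min_species`` species
    are resampled; all-extinct after ``max_retries`` draws is an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wgd_set = set(wgd_branches or ())
    ctx = (rng, dup_rate, loss_rate, wgd_set, wgd_probability)
    for _ in range(max_retries):
        root = _GNode("root", species_tree.root, 0.0)
        for sp_child in species_tree.root.children:
            _evolve_edge(root, sp_child, 0.0, ctx)
        result = _harvest(root, og_id)
        if result is None:
            continue
        tree, gsmap, truth = result
        if len(tree.leaves) >= min_genes and len(set(gsmap.values())) >= min_species:
            return tree, gsmap, truth
    raise SimulationError(
        f"gene family extinct or below size thresholds after {max_retries} draws"
    )


def _harvest(root: _GNode, og_id: str):
    survives: dict[int, bool] = {}

    def mark_all(g: _GNode):
        for c in g.children:
            mark_all(c)
        if g.kind == "leaf":
            survives[id(g)] = True
        elif g.kind == "loss":
            survives[id(g)] = False
        else:
            survives[id(g)] = any(survives[id(c)] for c in g.children)

    mark_all(root)
    if not survives[id(root)]:
        return None

    counter = [0]
    built_origin: dict[int, _GNode] = {}
    depth_of: dict[int, float] = {}

    def build(g: _GNode):
        kids = [c for c in g.children if survives[id(c)]]
        if g.kind == "leaf":
            counter[0] += 1
            node = PhyloNode(label=f"{og_id}_g{counter[0]}")
        elif len(kids) == 1:
            return build(kids[0])
        else:
            node = PhyloNode()
            for k in kids:
                node.add_child(build(k))
        built_origin[id(node)] = g
        depth_of[id(node)] = g.depth
        return node

    top = build(root)
    if top.is_leaf or len(top.children) < 2:
        return None  # single surviving lineage: no family to analyse
    for parent_node in _iter_nodes(top):
        for child in parent_node.children:
            child.length = depth_of[id(child)] - depth_of[id(parent_node)]
    tree = PhyloTree(top)

    gsmap = GeneSpeciesMap()
    truth = OrthogroupTruth()
    for node in tree.postorder:
        g = built_origin[id(node)]
        if node.is_leaf:
            gsmap[node.label] = g.sp.label
        elif g.kind == "dup":
            truth.dup_nodes.add(node.name)
            if g.wgd:
                truth.wgd_dup_nodes.add(node.name)
            for child in node.children:
                truth.post_dup_branches.add(child.name)
    return tree, gsmap, truth


def _iter_nodes(root: PhyloNode):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# Trait evolution
# ---------------------------------------------------------------------------


def simulate_trait(
    gene_tree: PhyloTree,
    post_dup_branches: set,
    alpha: float,
    beta: float,
    kappa: float = 1.0,
    seed: int | np.random.Generator = 0,
    root_state: int | None = None,
) -> tuple[dict, list, dict]:
    """Evolve the binary targeting trait down the gene tree.

    The root state is drawn from the stationary distribution unless fixed.
    Branches named in ``post_dup_branches`` (the two immediate children of
    each duplication) use rates ``kappa * alpha`` and ``kappa * beta``.
    Returns ``(tip_states, flips, node_states)`` where each flip is
    ``(child_node_name, direction, depth_fraction)`` with the position of
    the flip along the branch in [0, 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if root_state is None:
        p1 = alpha / (alpha + beta) if alpha + beta > 0 else 0.0
        root_state = int(rng.random() < p1)
    node_states = {gene_tree.root.index: root_state}
    flips = []
    for node in gene_tree.preorder:
        for child in node.children:
            mult = kappa if child.name in post_dup_branches else 1.0
            state = node_states[node.index]
            length = child.length or 0.0
            pos = 0.0
            while True:
                rate = (alpha if state == 0 else beta) * mult
                if rate <= 0:
                    break
                pos += rng.exponential(1.0 / rate)
                if pos >= length:
                    break
                state = 1 - state
                flips.append(
                    (child.name, "gain" if state == 1 else "loss", pos / length if length else 0.0)
                )
            node_states[child.index] = state
    tip_states = {lf.label: node_states[lf.index] for lf in gene_tree.leaves}
    return tip_states, flips, node_states


def apply_branch_rates(
    gene_tree: PhyloTree,
    change_branches: set,
    rho: float = 1.0,
    sigma: float = 0.05,
    family_sigma: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> None:
    """Turn species-path lengths into molecular lengths in place.

    Every branch is multiplied by a single per-family lognormal rate
    factor (gene-level rate variation; ancestral estimation is invariant
    to this uniform rescaling), a small per-branch lognormal wiggle, and
    by ``rho`` on branches where the targeting trait changed — the
    plantable molecular-rate elevation recovered by the rate analysis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    family = float(np.exp(rng.normal(0.0, family_sigma))) if family_sigma > 0 else 1.0
    for node in gene_tree.postorder:
        if node.parent is None or node.length is None:
            continue
        jitter = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
        node.length = (
            node.length
            * family
            * jitter
            * (rho if node.name in change_branches else 1.0)
        )


# ---------------------------------------------------------------------------
# Sequences and term annotations
# ---------------------------------------------------------------------------


def simulate_sequences(
    tip_states: dict,
    seed: int | np.random.Generator = 0,
    length: int = 120,
) -> dict[str, str]:
    """Protein sequences; state-1 genes get a PTS1 tripeptide or an
    N-terminal PTS2 nonapeptide, others are motif-free (rejection
    sampled)."""
    from .pts import classify_pts1, classify_pts2

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out = {}
    for gene in sorted(tip_states):
        while True:
            seq = "M" + "".join(rng.choice(aa, size=length - 1))
            p1, _ = classify_pts1(seq)
            p2, _ = classify_pts2(seq)
            if not p1 and not p2:
                break
        if tip_states[gene]:
            if rng.random() < 0.5:
                seq = seq[:-3] + str(rng.choice(["SKL", "SRL", "ARM"]))
            else:
                motif = "R" + str(rng.choice(["L", "I"])) + "".join(
                    rng.choice(aa, size=5)
                ) + "HL"
                start = int(rng.integers(1, 22))  # keeps the 9-mer within residues 1-30
                seq = seq[:start] + motif + seq[start + 9 :]
        out[gene] = seq
    return out


def simulate_term_annotations(
    foreground: list,
    background: list,
    p_foreground: float = 0.4,
    p_background: float = 0.05,
    planted_term: str = "T_planted",
    n_null_terms: int = 20,
    p_null: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> dict[str, set]:
    """Orthogroup-level term sets with one planted enriched term.

    The planted term is carried by foreground orthogroups with probability
    ``p_foreground`` and by the remaining background with
    ``p_background``; null terms are carried uniformly at ``p_null``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fg = set(foreground)
    table: dict[str, set] = {}
    for og in background:
        terms = set()
        p = p_foreground if og in fg else p_background
        if rng.random() < p:
            terms.add(planted_term)
        for j in range(n_null_terms):
            if rng.random() < p_null:
                terms.add(f"T{j:03d}")
        table[og] = terms
    return table


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig, seed: int = 0) -> SimulatedDataset:
    """Generate a full study: species tree, gene families, traits, lengths.

    The true species-branch placement of each flip is resolved from the
    flip's absolute depth along the species tree, giving per-event ground
    truth that the change caller's mappings can be scored against.
    """
    ss = np.random.SeedSequence(seed)
    sp_seed, wgd_seed, *og_seeds = ss.spawn(2 + config.n_orthogroups)
    species_tree, annotation = simulate_species_tree(
        config.n_species,
        config.birth_rate,
        np.random.default_rng(sp_seed),
        config.root_age,
    )
    if config.n_wgd_branches:
        rng = np.random.default_rng(wgd_seed)
        internal = [
            n.name
            for n in species_tree.internal_nodes
            if n.parent is not None
        ]
        chosen = rng.choice(internal, size=min(config.n_wgd_branches, len(internal)), replace=False)
        annotation.wgd_branches = set(map(str, chosen))

    sp_node_depth = {species_tree.root.index: 0.0}
    for node in species_tree.preorder:
        for c in node.children:
            sp_node_depth[c.index] = sp_node_depth[node.index] + c.length
    sp_leaf_by_label = {lf.label: lf for lf in species_tree.leaves}

    orthogroups = []
    for i, og_ss in enumerate(og_seeds):
        rng = np.random.default_rng(og_ss)
        og_id = f"OG{i:04d}"
        tree, gsmap, truth = simulate_gene_tree(
            species_tree,
            config.dup_rate,
            config.loss_rate,
            rng,
            wgd_branches=annotation.wgd_branches,
            wgd_probability=config.wgd_probability,
            og_id=og_id,
            min_genes=config.min_genes,
            min_species=config.min_species,
            max_retries=config.max_retries,
        )
        tip_states, flips, node_states = simulate_trait(
            tree,
            truth.post_dup_branches,
            config.alpha,
            config.beta,
            config.kappa,
            rng,
        )
        truth.node_states = {
            tree.postorder[i2].name: s for i2, s in node_states.items()
        }
        gene_depth = {tree.root.index: 0.0}
        for node in tree.preorder:
            for c in node.children:
                gene_depth[c.index] = gene_depth[node.index] + (c.length or 0.0)
        name_to_node = {n.name: n for n in tree.postorder}
        for child_name, direction, frac in flips:
            child = name_to_node[child_name]
            d = gene_depth[child.parent.index] + frac * (child.length or 0.0)
            sp_leaf = sp_leaf_by_label[gsmap[tree.leaves_under(child)[0].label]]
            truth.events.append(
                (child_name, direction, _branch_at_depth(sp_leaf, sp_node_depth, d))
            )
            truth.change_branches.add(child_name)
        apply_branch_rates(
            tree,
            truth.change_branches,
            rho=config.rho,
            sigma=config.rate_jitter_sigma,
            family_sigma=config.family_rate_sigma,
            seed=rng,
        )
        orthogroups.append(SimOrthogroup(og_id, tree, gsmap, tip_states, truth))
    return SimulatedDataset(config, species_tree, annotation, orthogroups)


def _branch_at_depth(sp_leaf, sp_node_depth, d) -> str | None:
    """True species branch of a flip: the edge on the root-to-species path
    whose depth interval contains the flip depth."""
    node = sp_leaf
    while node.parent is not None:
        top = sp_node_depth[node.parent.index]
        bottom = sp_node_depth[node.index]
        if top < d <= bottom + 1e-12:
            return node.name
        node = node.parent
    return None
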