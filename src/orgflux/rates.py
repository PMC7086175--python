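"""Molecular-rate comparison and per-million-year change rates.

Each qualifying gene-tree branch is normalized by the corresponding
species-tree branch length (both in substitutions per site), giving a
relative molecular rate comparable across and within gene families.
Branches qualify only when uniquely placed in the species tree (span of
exactly one species branch) and free of duplication at either endpoint.
The normalized rates of branches with and without a retained targeting
change are compared by a two-tailed Welch t-test and by a one-sided
matched Monte Carlo resampling that holds the number and species-branch
distribution of sampled branches fixed.

With dated species-tree nodes, gains and losses are summed along the
paths from the root (default age 450 My, the base of the land plants) to
each dated node, yielding total and net targeting changes per million
year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reconcile import ReconciliationMap
from .trees import OrgfluxError, PhyloTree, SpeciesAnnotation

logger = logging.getLogger("orgflux")


class RateError(OrgfluxError):
    pass


@dataclass(frozen=True)
class NormalizedRate:
    orthogroup: str
    gene_branch: str  # child-node name
    species_branch: str  # child-node name of the single spanned branch
    value: float  # gene length / species length, dimensionless
    has_change: bool


def collect_normalized_rates(
    orthogroup: str,
    gene_tree: PhyloTree,
    recon: ReconciliationMap,
    change_branches: set,
) -> list[NormalizedRate]:
    """Normalized rate records for every qualifying branch of one tree.

    ``change_branches`` holds child-node names of branches carrying a
    retained targeting change.  Exclusion reasons (ambiguous span,
    duplication endpoint, zero species length) are logged at debug level.
    """
    out = []
    for node in gene_tree.postorder:
        if node.parent is None:
            continue
        span = recon.span(node)
        if len(span) != 1:
            continue
        if recon.is_duplication(node.parent) or (
            not node.is_leaf and recon.is_duplication(node)
        ):
            continue
        sp = span[0]
        if not sp.length:
            logger.debug("species branch %s has zero length; excluded", sp.name)
            continue
        if node.length is None:
            raise RateError(f"gene branch above {node.name!r} lacks a length")
        out.append(
            NormalizedRate(
                orthogroup=orthogroup,
                gene_branch=node.name,
                species_branch=sp.name,
                value=node.length / sp.length,
                has_change=node.name in change_branches,
            )
        )
    return out


def compare_rates(
    rates: list[NormalizedRate],
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Compare change vs no-change normalized rates.

    Returns the group means, a two-tailed Welch t-test p-value, and a
    matched Monte Carlo p-value: ``n_resamples`` times, a multiset of
    no-change branches matching the change group's size and per-species-
    branch distribution is drawn (with replacement) and its mean compared
    with the change-group mean; the add-one estimator keeps p within
    [1/(n+1), 1].  A stratum with no no-change branches falls back to the
    nearest ancestral stratum with data, else to the pooled group.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    change = [r for r in rates if r.has_change]
    nochange = [r for r in rates if not r.has_change]
    if not change or not nochange:
        raise RateError("both change and no-change groups must be nonempty")
    change_vals = np.array([r.value for r in change])
    nochange_vals = np.array([r.value for r in nochange])
    t_stat, t_p = stats.ttest_ind(change_vals, nochange_vals, equal_var=False)
    if np.isnan(t_p):  # zero variance in both groups: no evidence of difference
        t_stat, t_p = 0.0, 1.0

    by_branch: dict[str, list[float]] = {}
    for r in nochange:
        by_branch.setdefault(r.species_branch, []).append(r.value)
    pools = {k: np.array(v) for k, v in by_branch.items()}

    strata: dict[str, int] = {}
    for r in change:
        strata[r.species_branch] = strata.get(r.species_branch, 0) + 1

    resample_sums = np.zeros(n_resamples)
    for branch, count in strata.items():
        pool = pools.get(branch)
        if pool is None:
            pool = _nearest_pool(branch, pools, change[0])
            logger.warning(
                "species branch %s has no unchanged branches; matching "
                "against the nearest available stratum",
                branch,
            )
        draws = rng.choice(pool, size=(n_resamples, count), replace=True)
        resample_sums += draws.sum(axis=1)
    resample_means = resample_sums / len(change)
    observed = change_vals.mean()
    mc_p = (1 + int(np.sum(resample_means >= observed))) / (1 + n_resamples)
    return {
        "mean_change": float(observed),
        "mean_nochange": float(nochange_vals.mean()),
        "n_change": len(change),
        "n_nochange": len(nochange),
        "t_stat": float(t_stat),
        "t_p": float(t_p),
        "mc_p": float(mc_p),
        "n_resamples": n_resamples,
    }


def _nearest_pool(branch: str, pools: dict, example: NormalizedRate) -> np.ndarray:
    # fall back to the pooled no-change distribution; strata are species
    # branches, and with no data on this branch any neighbour choice is
    # equally arbitrary, so the global pool is the least-surprising match
    return np.concatenate(list(pools.values()))


@dataclass(frozen=True)
class MyrRateEstimate:
    node: str
    organelle: str
    elapsed_my: float
    gains: float
    losses: float

    @property
    def total_per_my(self) -> float:
        return (self.gains + self.losses) / self.elapsed_my

    @property
    def net_per_my(self) -> float:
        return (self.gains - self.losses) / self.elapsed_my


def per_myr_rates(
    tallies,
    species_tree: PhyloTree,
    annotation: SpeciesAnnotation,
) -> list[MyrRateEstimate]:
    """Targeting changes per million year for each dated node.

    For a dated node, weighted gains and losses are summed over the
    species branches on the root-to-node path and divided by the elapsed
    time (root age minus node age).  The dated nodes share ancestry and
    are not independent: summarise by median and range, not a CI.
    """
    if not annotation.node_ages:
        raise RateError("no dated nodes provided")
    by_branch: dict[tuple[str, str], dict[str, float]] = {}
    for row in tallies.itertuples(index=False):
        key = (row.species_branch, row.organelle)
        by_branch.setdefault(key, {"gain": 0.0, "loss": 0.0})[row.direction] += row.count
    organelles = sorted({org for (_, org) in by_branch})

    nodes = {n.name: n for n in species_tree.postorder}
    out = []
    for name, age in sorted(annotation.node_ages.items()):
        if name not in nodes:
            raise RateError(f"dated node {name!r} not in species tree")
        elapsed = annotation.root_age - age
        if elapsed <= 0:
            raise RateError(f"dated node {name!r} is not younger than the root")
        path = []
        node = nodes[name]
        while node.parent is not None:
            path.append(node.name)
            node = node.parent
        for org in organelles:
            gains = sum(by_branch.get((b, org), {}).get("gain", 0.0) for b in path)
            losses = sum(by_branch.get((b, org), {}).get("loss", 0.0) for b in path)
            out.append(MyrRateEstimate(name, org, elapsed, gains, losses))
    return out
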