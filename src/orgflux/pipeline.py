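"""End-to-end orchestration of the targeting-evolution analysis.

``analyze_dataset`` runs the in-memory pipeline on a simulated (or
assembled) dataset: per-orthogroup ancestral estimation, change calling,
species-branch tallies, the duplication-association test, the normalized
molecular-rate comparison, per-million-year change rates, and optional
term enrichment.  ``run_pipeline`` is the file-based wrapper used by the
command line: it simulates a dataset from a config, writes every stage's
table, and a JSON run manifest with the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestral import fit_mk
from .changes import call_changes, tally_changes
from .duplication import (
    classify_origins,
    duplication_change_test,
    fossil_change_frequency,
    find_fossil_duplicate_branches,
    flag_child_changes,
    select_high_confidence_nodes,
)
from .enrichment import enrich
from .rates import collect_normalized_rates, compare_rates, per_myr_rates
from .reconcile import lca_reconcile
from .simulate import SimConfig, SimulatedDataset, simulate_dataset, simulate_term_annotations
from .trees import OrgfluxError, write_newick

logger = logging.getLogger("orgflux")


@dataclass
class PipelineResult:
    events: list = field(default_factory=list)
    tallies: pd.DataFrame | None = None
    dup_records: list = field(default_factory=list)
    dup_test: dict | None = None
    rate_records: list = field(default_factory=list)
    rate_test: dict | None = None
    myr_rates: list = field(default_factory=list)
    fossil: dict | None = None
    enrichment: pd.DataFrame | None = None
    reconciliations: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "n_events": len([e for e in self.events if not e.within_species]),
            "n_gains": sum(1 for e in self.events if e.direction == "gain"),
            "n_losses": sum(1 for e in self.events if e.direction == "loss"),
        }
        if self.dup_test:
            out["duplication_association"] = self.dup_test
        if self.rate_test:
            out["rate_comparison"] = self.rate_test
        if self.myr_rates:
            totals = [m.total_per_my for m in self.myr_rates]
            nets = [m.net_per_my for m in self.myr_rates]
            out["changes_per_my"] = {
                "median_total": float(np.median(totals)),
                "range_total": [float(min(totals)), float(max(totals))],
                "median_net": float(np.median(nets)),
            }
        if self.fossil:
            out["fossil_duplicates"] = self.fossil
        return out


def analyze_dataset(
    dataset: SimulatedDataset,
    mode: str = "mrca",
    threshold: float = 0.5,
    constraint: str = "ARD",
    root_prior: str = "uniform",
    n_resamples: int = 1000,
    seed: int = 0,
    og_terms: dict | None = None,
    run_rate_test: bool = True,
    run_dup_test: bool = True,
) -> PipelineResult:
    """Run every analysis stage over the dataset's orthogroups."""
    result = PipelineResult()
    species_tree = dataset.species_tree
    organelle = dataset.config.organelle
    rng = np.random.default_rng(seed)

    for og in dataset.orthogroups:
        recon = lca_reconcile(og.tree, species_tree, og.gsmap)
        fit = fit_mk(
            og.tree, og.tip_states, constraint=constraint, root_prior=root_prior
        )
        events = call_changes(
            og.og_id,
            organelle,
            og.tree,
            og.tip_states,
            fit.marginal,
            recon,
            og.gsmap,
            mode=mode,
            threshold=threshold,
        )
        records = select_high_confidence_nodes(og.og_id, recon)
        flag_child_changes(records, events, og.tree)
        classify_origins(records, recon, dataset.annotation)

        change_branches = {e.child_node for e in events}
        result.rate_records.extend(
            collect_normalized_rates(og.og_id, og.tree, recon, change_branches)
        )
        result.events.extend(events)
        result.dup_records.extend(records)
        result.reconciliations[og.og_id] = recon
        result.fits[og.og_id] = fit

    result.tallies = tally_changes(result.events, species_tree)

    if run_dup_test:
        try:
            result.dup_test = duplication_change_test(
                result.dup_records, n_resamples=n_resamples, seed=rng
            )
        except OrgfluxError as exc:
            logger.warning("duplication test skipped: %s", exc)
    if run_rate_test:
        try:
            result.rate_test = compare_rates(
                result.rate_records, n_resamples=n_resamples, seed=rng
            )
        except OrgfluxError as exc:
            logger.warning("rate comparison skipped: %s", exc)
    if dataset.annotation.node_ages:
        result.myr_rates = per_myr_rates(
            result.tallies, species_tree, dataset.annotation
        )
    if dataset.annotation.wgd_branches:
        fossil = []
        for og in dataset.orthogroups:
            fossil.extend(
                find_fossil_duplicate_branches(
                    result.reconciliations[og.og_id], dataset.annotation
                )
            )
        result.fossil = fossil_change_frequency(fossil, result.events)

    if og_terms is not None:
        targeted = {
            og.og_id
            for og in dataset.orthogroups
            if any(og.tip_states.values())
        }
        changed = {e.orthogroup for e in result.events} & targeted
        if changed and targeted:
            result.enrichment = enrich(changed, targeted, og_terms)
    return result


def load_dataset(
    directory: str | Path,
    organelle: str = "chloroplast",
    root_age: float = 450.0,
) -> SimulatedDataset:
    """Rebuild a dataset from the artifact layout written by the pipeline:
    ``species.nwk``, ``genetrees/*.nwk``, ``map.tsv`` and ``states.tsv``
    (plus optional ``wgd.tsv`` / ``ages.tsv``).  Lets every stage run
    stand-alone on previously written files."""
    from .simulate import OrthogroupTruth, SimOrthogroup
    from .trees import (
        GeneSpeciesMap,
        SpeciesAnnotation,
        read_newick,
        read_species_annotation,
    )

    directory = Path(directory)
    species_tree = read_newick((directory / "species.nwk").read_text())
    wgd = directory / "wgd.tsv"
    ages = directory / "ages.tsv"
    annotation = read_species_annotation(
        str(wgd) if wgd.exists() else None,
        str(ages) if ages.exists() else None,
        root_age=root_age,
    )
    annotation.validate(species_tree)
    gsmap_all = pd.read_csv(directory / "map.tsv", sep="\t", dtype=str)
    states_all = pd.read_csv(directory / "states.tsv", sep="\t")
    gene_species = dict(zip(gsmap_all["gene_id"], gsmap_all["species_id"]))
    gene_state = dict(zip(states_all["gene_id"].astype(str), states_all["state"].astype(int)))

    orthogroups = []
    for path in sorted((directory / "genetrees").glob("*.nwk")):
        tree = read_newick(path.read_text())
        gsmap = GeneSpeciesMap({g: gene_species[g] for g in tree.leaf_labels})
        tip_states = {g: gene_state.get(g, 0) for g in tree.leaf_labels}
        orthogroups.append(
            SimOrthogroup(path.stem, tree, gsmap, tip_states, OrthogroupTruth())
        )
    config = SimConfig(organelle=organelle, root_age=root_age)
    return SimulatedDataset(config, species_tree, annotation, orthogroups)


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> dict:
    """Simulate a dataset, analyse it, and write all artifacts.

    ``config`` holds a ``simulate`` block (SimConfig fields) and optional
    ``mode``, ``threshold``, ``n_resamples``, ``terms`` keys.  Returns the
    manifest dictionary (also written as ``manifest.json``).
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    sim_block = config.get("simulate", {})
    unknown = set(sim_block) - sim_fields
    if unknown:
        raise OrgfluxError(f"unknown simulate config fields: {sorted(unknown)}")
    sim_config = SimConfig(**sim_block)
    dataset = simulate_dataset(sim_config, seed=seed)

    og_terms = None
    if config.get("terms", True):
        changed_hint = [og.og_id for og in dataset.orthogroups if og.truth.change_branches]
        og_terms = simulate_term_annotations(
            changed_hint,
            [og.og_id for og in dataset.orthogroups],
            seed=np.random.default_rng(seed + 2**20),
        )

    result = analyze_dataset(
        dataset,
        mode=config.get("mode", "mrca"),
        threshold=config.get("threshold", 0.5),
        n_resamples=config.get("n_resamples", 1000),
        seed=seed + 1,
        og_terms=og_terms,
    )

    (outdir / "species.nwk").write_text(write_newick(dataset.species_tree) + "\n")
    genedir = outdir / "genetrees"
    genedir.mkdir(exist_ok=True)
    map_rows = []
    state_rows = []
    for og in dataset.orthogroups:
        (genedir / f"{og.og_id}.nwk").write_text(write_newick(og.tree) + "\n")
        for gene, sp in sorted(og.gsmap.items()):
            map_rows.append({"gene_id": gene, "species_id": sp})
        for gene, st in sorted(og.tip_states.items()):
            state_rows.append({"gene_id": gene, "state": st})
    pd.DataFrame(map_rows).to_csv(outdir / "map.tsv", sep="\t", index=False)
    pd.DataFrame(state_rows).to_csv(outdir / "states.tsv", sep="\t", index=False)
    if dataset.annotation.node_ages:
        pd.DataFrame(
            [{"node": k, "age_my": v} for k, v in sorted(dataset.annotation.node_ages.items())]
        ).to_csv(outdir / "ages.tsv", sep="\t", index=False)
    if dataset.annotation.wgd_branches:
        pd.DataFrame(
            [{"branch": b} for b in sorted(dataset.annotation.wgd_branches)]
        ).to_csv(outdir / "wgd.tsv", sep="\t", index=False)
    events_df = pd.DataFrame(
        [
            {
                "orthogroup": e.orthogroup,
                "organelle": e.organelle,
                "direction": e.direction,
                "parent_node": e.parent_node,
                "child_node": e.child_node,
                "assignment": ";".join(f"{b}:{float(w):.6g}" for b, w in e.assignments),
                "n_support_genes": e.n_support_genes,
            }
            for e in result.events
        ]
    )
    events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
    result.tallies.to_csv(outdir / "tallies.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrich.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {"simulate": sim_block, "mode": config.get("mode", "mrca")},
        "elapsed_s": round(time.time() - t0, 3),
        "summary": result.summary(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
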