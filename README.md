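# orgflux

Charting gains and losses of organellar targeting signals across plant
gene families.

Most proteins of the chloroplast, mitochondrion, peroxisome and
secretory pathway are nucleus-encoded and reach their compartment via a
targeting signal — an N-terminal transit/signal peptide or a peroxisomal
PTS1/PTS2 motif.  Because these signals are short and modular, they are
gained and lost during evolution, continuously re-wiring organellar
proteomes.  `orgflux` is a pipeline for quantifying that process from
comparative genomic data: given a species tree, per-family gene trees, a
gene→species map and per-gene localization predictions, it

1. classifies peroxisomal targeting signals by rule (PTS1 C-terminal
   tripeptides; PTS2 nonapeptide `R[LI]X5HL` in residues 1–30) and
   merges them with external predictor calls (dual-peroxisomal labels);
2. reconciles gene trees to the species tree by last-common-ancestor
   mapping, labelling duplication and speciation nodes;
3. estimates ancestral targeting states by maximum likelihood under a
   two-state Markov model (gain rate α, loss rate β; equal-rates or
   all-rates-different), with marginal probabilities from Felsenstein
   pruning: P(targeted) ≥ 0.5 assigns the targeted state;
4. calls retained gains and losses with a stringent filter (>75% of
   descendant genes retain the changed state, >75% under the sister
   branch retain the ancestral state, ≥2 species subtend the branch) and
   maps them to species-tree branches;
5. compares normalized molecular rates (gene branch length ÷ species
   branch length) of change vs no-change branches (Welch t-test and a
   matched Monte Carlo that fixes the number and phylogenetic
   distribution of sampled branches), and converts branch tallies into
   changes per million years from dated nodes;
6. tests whether changes occur more often on the two branches
   immediately following high-confidence gene duplications than after
   speciations (upper-tail hypergeometric and matched resampling), split
   by whole-genome vs single-gene duplication origin, including "fossil"
   duplicates; and
7. runs functional-term enrichment of changed gene families
   (hypergeometric with Benjamini–Hochberg correction, q ≤ 0.01)
   against the organelle-targeted background.

A fully ground-truthed synthetic-data generator (duplication–loss gene
trees along a Yule species tree, two-rate binary trait evolution with a
post-duplication multiplier κ, molecular-rate elevation ρ on change
branches, planted PTS motifs and term enrichment) exercises every stage
end to end; see `docs/methods.md` for models, parameters and caveats.

## Worked example

Simulate a 20-species, 50-family dataset in which targeting changes are
five times more likely on post-duplication branches (κ = 5), run the
full pipeline, and print the headline numbers:

```sh
printf 'simulate: {kappa: 5.0}\n' > demo.yaml
orgflux run --config demo.yaml --outdir demo --seed 7
```

```json
{
  "n_events": 56,
  "n_gains": 166,
  "n_losses": 113,
  "duplication_association": {
    "n_dup": 2331,
    "n_spec": 1185,
    "k_dup": 216,
    "k_spec": 29,
    "freq_dup": 0.09266409266409266,
    "freq_spec": 0.024472573839662448,
    "hypergeom_p": 4.163690536186015e-16,
    "mc_p": 0.000999000999000999,
    "n_resamples": 1000
  },
  "rate_comparison": {
    "mean_change": 1.0886446964159033,
    "mean_nochange": 1.0059163332431253,
    "n_change": 41,
    "n_nochange": 10018,
    "t_stat": 2.085991139846701,
    "t_p": 0.04334735486143299,
    "mc_p": 0.017982017982017984,
    "n_resamples": 1000
  },
  "changes_per_my": {
    "median_total": 0.013198849313472812,
    "range_total": [0.0, 0.047352809428912346],
    "median_net": 0.008754243879478683
  }
}
```

Reading the output: 279 retained gain/loss events were called (166
gains, 113 losses), of which 56 map unambiguously to internal species
branches; the rest sit on within-species (post-duplication) branches.
Among 2,331 informative high-confidence duplication nodes, 9.3% show a
targeting change on an immediate child branch versus 2.4% of 1,185
comparable speciation nodes — a strong enrichment (hypergeometric
p ≈ 4e-16; matched Monte Carlo p at its 1/1001 floor), recovering the
planted κ = 5 effect.  Branches carrying a change also show an ~8%
higher normalized molecular rate, though at these sample sizes that
signal is marginal (Welch p = 0.043) — rate elevation was not planted
here (ρ = 1).  The `demo/` directory holds every intermediate
artifact (trees, localization states, events, per-branch tallies,
enrichment table, JSON manifest); each stage can also be run separately
(`orgflux pts|reconcile|ace|changes|rates|duptest|enrich --help`).

The numbers above are what the command prints for seed 7; any fixed
seed reproduces its output bit for bit.

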