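# Methods

`orgflux` reconstructs the history of organellar targeting signals across
gene families: which extant proteins carry a signal, which ancestral
proteins did, where on the species phylogeny signals were gained or lost,
how fast those changes accumulate, and whether they are associated with
gene duplication.  This note documents the models, the tunable
parameters, the synthetic-data generator, and the design choices made
where reasonable alternatives existed.

## Targeting classification

Chloroplast, mitochondrial and secretory predictions are ingested as a
table (the output of an external predictor such as TargetP); `orgflux`
itself implements only the rule-based peroxisomal classifier:

* **PTS1** — the final three residues must be one of nine tripeptides
  (SRL, SRM, SRI, ARL, ARM, PRL, SKL, SKM, AKL).
* **PTS2** — the nonapeptide `R-[LI]-X5-H-L` must lie in the N-terminal
  region (residues 1–30).  "Lie in" is interpreted as the whole 9-mer
  inside the window (start ≤ 22); a permissive variant requiring only the
  start inside the window is available (`anchor="start"`), since the
  prose convention is genuinely ambiguous.  Matching is case-insensitive
  after stripping a trailing stop symbol; the ambiguity code `X` matches
  only the five wildcard positions.

A protein with a PTS on top of a positive external prediction is marked
*dual peroxisomal*; for per-organelle analyses dual proteins count as
present for both the peroxisome trait and their external compartment.
Genes absent from the localization table are treated as untargeted with a
warning.

## Reconciliation

Gene trees are taken as rooted and binary.  Native reconciliation maps
every internal gene node to the species-tree LCA of its descendant
species; a node is a duplication when its mapping equals that of a child.
Pre-reconciled trees (e.g. from a joint inference program) can be
ingested from a sidecar table instead.  A gene branch *spans* the ordered
path of species branches between its endpoint mappings; gene loss can
make one gene branch span several consecutive species branches, and
within-species (post-duplication) branches span none.

## Ancestral character estimation

Presence/absence of each targeting signal is a binary trait evolving
along the gene tree under a two-state continuous-time Markov chain with
gain rate α and loss rate β per substitutions-per-site of branch length
(bounds 1e-8–1e3; zero-length branches floored at 1e-9).  Two
parameterisations: ER (α = β, 1 parameter) and ARD (free, 2 parameters);
ARD is the pipeline default, and a χ²(1) likelihood-ratio test compares
the two.  The likelihood is computed by Felsenstein pruning with
per-node rescaling; the gradient with respect to (α, β) is propagated
analytically through the same recursion, and rates are estimated by
bounded L-BFGS-B on the log-rate scale from three deterministic starts
(an ER-profile point, 0.1 and 1.0).  Monomorphic tip data produce
boundary fits, flagged rather than raised.  Node probabilities are
marginal (empirical-Bayes) state probabilities from combined
downward/upward passes under the fitted rates.  The root prior is
uniform over the two states by default (stationary available); results
are mildly prior-sensitive for small families, which is why the prior is
exposed.

## Change calling

Marginal probabilities are binarized winner-takes-all (targeted iff
P ≥ 0.5; the tie goes to targeted).  A candidate change is a branch whose
endpoint states differ.  A candidate is retained only if

1. strictly more than 75% of extant genes descending from the change
   branch show the changed state,
2. strictly more than 75% of genes under the sister branch keep the
   ancestral state, and
3. the change branch subtends genes from ≥ 2 species.

Descendant states are the *observed* tip localizations, so every
retained call rests on at least three extant genes (the exhaustive
enumeration in the acceptance suite confirms 3 is the floor).  Nested
candidates are filtered independently and may co-occur.  Retained events
map onto species branches through the reconciliation span: wholly onto
the most recent spanned branch (`mrca`, primary) or split equally
(`split`, sensitivity).  Weights are exact rationals, so the tallied
totals conserve the event count under both modes; because of rule 3 an
event can never map to a terminal species branch, which is why headline
tallies cover nonterminal branches only.

## Rate analyses

**Normalized molecular rate** — gene branch length divided by the
corresponding species branch length, computed only for branches uniquely
placed (span = 1) with no duplication at either endpoint.  Branches with
and without a retained change are compared by a two-tailed Welch t-test
and a one-sided matched Monte Carlo: 1,000 resamples of the no-change
group matching the change group's size and per-species-branch
distribution, add-one p-value (so p ∈ [1/1001, 1]).  A stratum with no
unchanged branches falls back to the pooled no-change distribution with
a warning.

**Per-million-year rates** — with dated species-tree nodes (root age 450
My by default), weighted gains and losses are summed along each
root-to-node path and divided by the elapsed time.  Dated nodes share
ancestry, so the summary is a median and range, not a confidence
interval.

## Duplication association

High-confidence duplication nodes retain the duplication in every
descendant species of both child clades.  High-confidence speciation
nodes are speciation nodes with no evidence of gene loss anywhere below
them; duplications below are tolerated when they are themselves fully
retained (`speciation_scope="local"`, the default), so complete
retention of all genes in all descendant species holds for both classes.
The stricter variant (`"subtree"`: no duplication at all below) is
available; it restricts the control class to families that stayed
single-copy, which empties it in duplication-rich data.

Each node is scored for a retained change on either immediate child
branch.  Only *informative* nodes — both child branches subtending ≥ 2
species — enter the 2×2 test: a change can never pass the ≥2-species
filter below a terminal branch, and informative duplication nodes always
have two callable children, so dropping one-callable-child speciation
nodes is required for the classes to be comparable (with them included
the κ=1 null rejects at ~30% instead of ~5%).  The test is an upper-tail
hypergeometric on (class × child-change), plus a matched Monte Carlo
that resamples speciation nodes to the duplication set's size and
species-node distribution.  Because post-duplication child branches are
partial species-branch segments while speciation child branches are full
species branches, the comparison is slightly conservative with respect
to the duplication-enrichment direction under the null.

At the reference simulation conditions with κ = 5, the hypergeometric
test rejects at p < 0.01 in roughly 88% of datasets (94% at p < 0.05);
under κ = 1 the rejection rate at the 0.05 level is ~2–5%.  The power
ceiling is set by the winner-takes-all caller's recall of true
post-duplication flips (~60–65%: a fully changed duplicate clade can
pull the duplication node's own marginal past 0.5, or push the inferred
transition one branch down) together with the conservatism of the
informativeness rule; these are properties of the method, not of the
generator.

Duplications are stratified into WGD (mapped below a species branch
flagged as carrying a whole-genome duplication) versus single-gene
origin.  Fossil duplicates are gene branches whose span crosses a
WGD-flagged branch without a retained duplication mapped to it —
lineages that must have duplicated at the WGD and lost one copy again —
and their change frequency is reported alongside.

## Term enrichment

Orthogroups inherit the union of their member genes' terms (optional
parent-map propagation for hierarchical vocabularies).  Enrichment of
changed orthogroups against the background of orthogroups with ≥ 1
organelle-targeted protein uses an upper-tail hypergeometric test per
term with Benjamini–Hochberg correction; significance at q ≤ 0.01.
Terms carried by fewer than two background orthogroups are not tested.

## Synthetic data and what passing tests show

The generator produces the reference study conditions used throughout
the validation suite:

| parameter | default | meaning |
|---|---|---|
| n_species | 20 | Yule species tree, birth rate 1.0, root age 450 My |
| n_orthogroups | 50 | families per dataset (≥4 genes, ≥2 species) |
| dup_rate | 0.7 | duplications per unit branch length |
| loss_rate | 0.02 | losses per unit branch length |
| α, β | 0.04, 0.08 | trait gain/loss rates per unit branch length |
| κ | 1 | trait-rate multiplier on the two post-duplication branches |
| ρ | 1 | molecular-length multiplier on true change branches |
| family_rate_sigma | 0.25 | lognormal sd of the per-family rate factor |
| rate_jitter_sigma | 0.05 | lognormal sd of the per-branch rate wiggle |
| wgd_probability | 0.8 | per-lineage duplication chance at a WGD branch midpoint |

Gene families evolve by Poisson duplication/loss along the species tree
(WGD duplications at flagged-branch midpoints); the binary trait evolves
from a stationary-distribution root state with realised flips recorded
as ground truth, including their true species-branch placement; κ = 1
and ρ = 1 recover the null model exactly.  Sequences for
peroxisome-state genes carry a valid PTS1 or in-window PTS2; term
annotations plant one enriched term (40% in changed families vs 5%
elsewhere).

Two generator choices deserve emphasis:

* **Duplication-dense, low-loss families.**  A desk-scale study (50
  families, 20 species) has ~400× fewer families than a full
  phylogenomic dataset; concentrating duplications keeps the
  high-confidence node classes in the hundreds so the association test
  operates in a sane counting regime, while reproducing the observed
  frequency regime (~3% child-change at speciation nodes, ~10% after
  duplication under κ = 5).  Gene loss only thins both high-confidence
  classes without changing the comparison.
* **Two-component rate variation.**  Winner-takes-all placement
  preferentially localises a change to the longer of the candidate
  branches, so if branch-level rate noise dominates, called change
  branches are length-selected and the rate-comparison null is
  anti-conservative — and the standardised bias is independent of the
  noise scale.  Putting the dominant variance at the family level (to
  which ancestral estimation is exactly invariant) removes that channel;
  the residual per-branch wiggle keeps the comparison non-degenerate.
  This mirrors real data, where among-gene rate variation dominates.
  The corollary — that ACE-based change calling has an intrinsic
  long-branch attraction for event placement — is a genuine limitation
  of the method worth bearing in mind when interpreting rate-elevation
  results on real data.

What the simulations do **not** emulate: sequence-level evolution (no
alignments or substitution models — branch lengths are drawn, not
estimated), gene-tree inference error, incomplete lineage sorting,
horizontal transfer, dosage effects, and correlated targeting traits.
Passing tests therefore validate the statistical machinery downstream of
tree and localization inference, not the robustness of upstream
predictors.

## Numerical choices

Likelihood convergence at 1e-10 relative tolerance; rates bounded in
[1e-8, 1e3]; branch lengths floored at 1e-9; P ≥ 0.5 ties binarize to
targeted; >75% retention thresholds are strict inequalities; Monte Carlo
p-values use the add-one estimator; split-mode weights are exact
`Fraction`s; every stochastic routine takes a seed or numpy `Generator`
and whole datasets derive all randomness from one `SeedSequence`.

## Known limitations

* Dual targeting between two organellar states is modelled as
  independent loss + gain in the two per-organelle analyses.
* The fossil-duplicate definition (span through a WGD branch without a
  retained duplication) cannot distinguish a true fossil duplicate from
  a WGD branch the family simply never duplicated at — it is an upper
  bound, as is any operational criterion for an invisible event.
* Per-family ARD fits on small families are noisy; the retention filter,
  not the raw marginals, carries the evidential weight of a call.
* The association between rate elevation and change calls is partially
  confounded by placement selection (above); the per-family rate design
  quantifies and controls this in simulation, but on real data the
  confound is irreducible without joint modelling.
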