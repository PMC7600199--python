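# Methods

## The analysis in one paragraph

Two experimental models of polyQ-expanded ATXN1 aggregation are compared
stage by stage: an inducible cell model (one Day-0 baseline, three
post-induction time-points) and a transgenic mouse model (three ages,
each with its own age-matched control group), three replicates per
group. Genes differentially expressed at each stage feed a gene-set
over-representation test; the pathways significant in *both* models at a
matched stage (the common dysregulated pathways) supply the proteins for
stage-specific PPI networks, whose motif content, union structure and
centrality dynamics identify candidate intervention points, finally
overlaid with drug–target interactions and a blood–brain-barrier
consensus.

## Synthetic data: what it emulates and what it does not

The generator (`synthetic_data`) reproduces the *statistical structure*
of the paired study, not any real gene-level values.

- **Abundance model.** Per-gene baseline log2-FPKM ~ N(`baseline_log_mean`
  = 3.0, `baseline_log_sd` = 1.5), i.e. log-normal FPKM — the standard
  heavy-tailed abundance model. Replicate noise is additive Gaussian on
  the log2 scale (`noise_sd`), which makes the t-test's assumptions
  controllable; the distribution family of real FPKM data is not
  characterized by the source study, so these defaults are conventional,
  not fitted.
- **Planted perturbations.** Each planted pathway has an onset stage, an
  effect size |log2FC| and a direction; effects persist from onset
  through every later stage and, for shared pathways, act identically in
  both models (unshared ones perturb the cell model only and serve as
  negative controls for the cross-model intersection). `mixed` direction
  draws each member gene's sign independently, downregulated with
  probability `frac_downregulated` (default 0.6, reflecting the
  predominantly-down character of polyQ-aggregation transcriptomes).
- **Pathway memberships** are drawn disjointly (without replacement from
  the remaining pool) so each gene's ground-truth fold-change is owned by
  at most one pathway; the manifest records memberships, per-gene true
  log2FC per model per stage, planted hubs, and planted drug facts.
- **Interactome.** Within-pathway pairs are wired with probability
  `ppi_within_pathway_prob` = 0.45 and confidences U(0.95, 1.0);
  background pairs with probability 0.002 and confidences U(0.30, 1.0),
  so the high-confidence filter retains planted modules and a thin
  background. The first member of each pathway is wired to every other
  member (a planted hub). Tissue scores are U(0, 10) for background genes
  and U(5, 10) for pathway members, so planted modules survive the 4.8
  nervous-system filter while the filter still acts on the background.
- **Orthology.** 90% of mouse genes map 1:1 to their true human ortholog
  at the top rank class (score 10); the rest carry an additional spurious
  rank-1–4 mapping, exercising the high-rank filter (default
  `min_rank` = 8) and the deterministic collision rules.
- **Drugs.** Each prioritized target receives `n_drugs_per_target` drugs
  with U(0,1) interaction scores; about half are planted fully
  BBB-positive (8/8 positive calls), the rest get 1–8 negative calls.

Not emulated: read-level sequencing noise, library-size artifacts,
correlated genes within pathways beyond the shared mean shift,
inter-pathway crosstalk, and any resemblance to real gene identifiers.
Passing tests therefore demonstrate the *pipeline logic* recovers planted
structure under its stated assumptions — not performance on real RNA-seq.

## Differential expression

FC = (mean case FPKM + c) / (mean control FPKM + c) with pseudocount
c = 0.25 FPKM; the ratio rule is undefined at control 0 and the
pseudocount is the package's guard (any non-negative value may be
passed). The test is Welch's two-sided two-sample t by default (the
R-ecosystem default), with a pooled-variance `student` switch. Rows
constant in both groups give p = 1 when the means agree, p = 0 otherwise.
DEG calling is strict on both thresholds: |log2FC| > 0.5 AND p < 0.05,
with no multiple-testing correction at this stage — selection is
deliberately on raw p, matching the workflow this package reimplements.
Under the null simulation the realized type-I fraction at p < 0.05 is
slightly conservative (~0.034) because the t-test runs on the skewed
FPKM scale at n = 3.

## Orthology mapping

Deterministic by construction: drop mappings below `min_rank`; a source
with several surviving targets keeps the highest rank (ties →
lexicographically smallest target id); several sources landing on one
target within a time-point keep the highest-rank pair (ties →
lexicographically smallest source id). Dropped rows are counted and
logged. The mapping is idempotent under an identity map.

## Over-representation and common pathways

One-sided hypergeometric upper tail (the exact test behind the standard
enrichment web tools); depletion is not tested. The background is the
intersection of the measured gene universe with the collection's
universe, so set sizes K are background-restricted — a self-consistent
and testable choice where the original tool's internal background is
unknowable. Pathway selection is strict p < α (α = 0.05), per matched
stage; the per-stage intersection of the two models' significant sets
defines the common pathways, and sets common at every stage are flagged
persistent. Direction concordance of shared DEGs (DEG at ≥1 time-point
in both models; per-model direction = sign of the largest-|log2FC| DEG
call) is a two-sided exact binomial sign test against 0.5 — a documented
stand-in, since the upstream analysis names no test; with zero shared
genes the p-value is reported as undefined (NaN), never 1 or 0.

## Stage networks and the union

Induced subgraph on the stage's common-pathway members only (no
first-neighbor expansion), tissue filter ≥ 4.8 and edge filter ≥ 0.950
both inclusive ("or above"), then degree-0 deletion. The two filters
commute (property-tested). The union keeps each node's exact
stage-membership set; the three named patterns get the conventional
colors (all = yellow, middle-specific = green, late-specific = magenta)
and every residual pattern keeps its literal label (e.g. `early+middle`)
rather than being forced into a named group.

## Motif significance

Exact census of connected induced 4-node subgraphs via ESU enumeration
with bitmask adjacency; the class is determined by the induced edge
count and maximum degree. The null model is attempted double-edge swaps
(default 10 × edge count attempts), which preserve the degree sequence
exactly and never introduce self-loops or multi-edges; graphs admitting
no legal swap (stars, a lone triangle) return unchanged and their null
is degenerate. Per-class z = (real − mean)/sd over the ensemble; classes
with zero null sd have undefined z, and the aggregate is the unweighted
mean of the defined per-class z values (undefined if none) — the
original tool's single-number aggregation is undocumented, so its
printed z values are not reproduction targets. The ensemble default is
1000; the test suite and acceptance script use 20–200 members, which
this package treats as adequate for the small synthetic networks it
builds (the Monte-Carlo error of the aggregate is checked against a
2000-member reference in the tests).

## Centralities and prioritization

DC = neighbor count; BC = unnormalized pair-dependency sum over
unordered pairs, endpoints excluded (a `normalized` variant is a flag
away in networkx but the raw sum matches the defining formula);
closeness is reported twice because the literature's conventions clash —
the raw farness Σ_j d(i,j) (under which *small* is central) and
CC = (n_c − 1)/farness within the node's component (under which *large*
is central); all ranking and trajectory logic uses CC. Heatmap scaling
is min-max to [0,1] per metric per stage; constant columns map to 0.5
(no ordering information). Trajectories compare late vs early scaled
values against a tolerance (default 0.05 on the scaled axis, standing in
for by-eye heatmap classification); nodes missing a stage are flagged
`absent-some-stages` with a partial magnitude over their present span —
absence is never imputed as zero. Prioritization: inhibition candidates
(DC and BC increasing), stimulation candidates (BC and CC decreasing),
persistent-high-CC (CC ≥ the stage's `cc_quantile` = 0.8 quantile at
every stage). Ties in `top_nodes` break alphabetically.

## Drug overlay and BBB consensus

Edges restricted to listed targets with interaction score ≥ 0.5
(inclusive; the threshold is interpreted as a minimum interaction
confidence). Drugs without surviving edges drop out; listed targets
remain as zero-degree nodes so per-target drug counts are always
reportable. The BBB verdict is strict consensus over exactly 8 calls
(ADABoost/SVM × MACCS/Openbabel/Molprint/PubChem): all positive →
permeable; any negative → not-permeable; missing or partial →
incomplete. The rule is monotone: flipping a positive call can only move
a verdict away from permeable. Predictor internals are out of scope;
calls are inputs.

## Pipeline, determinism and problem sizes

A single `PipelineConfig` (YAML-serializable, CLI-overridable) drives
the run; the resolved config is written beside the outputs. All
randomness derives from one seed through independent named
`SeedSequence` streams, so identical config + seed yields byte-identical
reports (tested). Errors abort with the failing stage's name. The
default synthetic study used by the acceptance script is 400 genes, 8
pathways of 10–14 genes, 3 replicates, noise_sd = 0.05, |log2FC| = 1
planted in three shared pathways (onsets early/middle/late) plus one
unshared distractor, motif ensemble 200 — sizes chosen so the whole
script completes in well under a minute while every stage still has
non-trivial structure to recover.

## Known limitations

- The generator's independence assumptions (genes, replicates, edges)
  make recovery easier than on real data; effect sizes below ~0.5 log2
  units or noise_sd approaching the effect size will degrade recovery,
  which the calibration properties quantify only at the null.
- Closeness-based prioritization depends on component structure; an
  isolated clique trivially maximizes CC, which is why persistent-high-CC
  is reported with its quantile rather than as a significance claim.
- The binomial concordance test treats genes as independent draws.
- Motif z-scores from swap ensembles are known to depend on the null's
  mixing; the swap budget (10 × edges) follows field practice and
  determinism is guaranteed, but mixing is not formally verified.
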