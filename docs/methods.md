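# Methods

This note documents the models and procedures implemented in `chemtx`,
the parameters that matter, the numerical conventions, and what the
synthetic data generator does and does not emulate.

## Vector representation

Both modalities are dense ternary vectors over one ordered gene
universe (`GeneUniverse`); the ordering defines the vector index and
gene identifiers are matched exactly (no symbol normalisation — mapping
between identifier schemes is out of scope). Target vectors encode
activation (+1) / inhibition (−1) of a protein by the compound;
transcriptomic vectors encode up/down differential-expression calls.

**Union across experiments.** A compound measured in several
experiments gets one transcriptomic vector: the union of all DEGs, with
discrepancies (a gene called up in some experiments, down in others)
resolved by a 2× majority rule — the gene is +1 iff it was called up in
more than twice as many experiments as down (`n_up > 2·n_down`,
strictly), −1 symmetrically, 0 otherwise. "More than two times" is read
as a strict inequality; exact 2× ratios and ties resolve to 0, the
conservative choice. Each experiment counts once regardless of cell
line. The alternative single-experiment representation
(`select_max_deg`, the experiment with the most DEGs) is provided for
sensitivity analysis; ties there are broken by input order with a
logged warning, since any other rule would be equally arbitrary.

Genes listed as both up and down *within one experiment* are rejected
at construction time rather than resolved — that is a data error, not a
discrepancy between experiments.

## Enrichment

Target vectors typically have 1–5 nonzero entries while transcriptomic
vectors have hundreds, so direct correlation is dominated by zeros.
Two routes densify the target vector; in both, original target entries
are never overwritten and a gene receiving conflicting signs is set
to 0 — cancellation is the only order-independent, symmetric choice.

**Pathway co-membership.** Gene sets are size-filtered to 15–300 genes
(inclusive bounds; standard enrichment practice — tiny sets are
unstable, giant sets uninformative). Every non-target universe gene
sharing at least one retained set with a target inherits that target's
sign. Genes in sets but absent from the universe are ignored at
projection. `subset_gene_sets` supports the sensitivity analyses
(dropping the k largest sets, or keeping a size band).

**Signed network propagation.** Signs propagate breadth-first from all
seed (target) genes through a directed network whose edges carry
activation (+1) / inhibition (−1) polarity; a newly reached gene's sign
is `source sign × edge polarity`. The resulting value of every gene is
determined by its *shortest* signed routes from the seed set: the
common sign product when all minimal-length routes agree, 0 when they
disagree. To make that invariant hold, a conflicted gene is marked
visited with value 0 and propagates its *conflict* onward (genes first
reached only through it are likewise 0); it never contributes a sign.
Sketch of why the BFS equals exhaustive minimal-path enumeration: every
prefix of a minimal-length route is itself minimal, so each
intermediate node on such a route is reached at its own minimal level
with a value that already summarises all of its minimal routes — by
induction the level-k assignment equals the minimal-path rule at depth
k. The equality is verified against an independent exhaustive
enumerator on random graphs in the test suite.

Self-loops never propagate. Contradictory duplicate edges (same
endpoints, both polarities) are collapsed to a single conflict-carrying
edge. Depth is restricted to 1–5 levels (deeper propagation saturates
the vector); an override flag exists for experiments.

## Metrics

* **Pearson** over all positions, zeros included, computed by the
  standard centred formula and clipped to [−1, 1] against rounding. If
  either vector is constant the value is undefined; undefined values
  are excluded from all means (and flagged, never silently zeroed into
  an average).
* **Signed Jaccard**: shared elements are positions with equal nonzero
  sign; the union is positions nonzero in either vector. A sign-blind
  switch (any co-nonzero position counts as shared) is exposed for
  sensitivity analysis, since pair overlap questions ("do these
  compounds share a target at all?") are sign-blind by nature.

For permutation work both metrics have matrix forms: the full
compound × compound cross-metric matrix is computed once and a pairing
shuffle is then just an indexing pass, which is what makes 100,000
iterations cheap.

## Permutation nulls and p-values

All empirical p-values are one-sided upper-tail with a +1 pseudocount:
`p = (1 + #{null ≥ observed}) / (n_iter + 1)`, so the smallest
achievable p is `1/(n_iter+1)` and p is never 0. Upper tail matches the
directional question (does enrichment *increase* agreement?).
Bonferroni adjustment multiplies by a caller-supplied number of
simultaneous tests (default 1).

1. **Pairing shuffle** (`pair_shuffle_test`): the observed statistic is
   the mean metric over aligned compound pairs; each iteration shuffles
   the transcriptomic collection against the fixed target collection.
   Default 100,000 iterations.
2. **Occurrence-preserving gene-set null** (`random_gene_sets` +
   `gene_set_permutation_test`): each random collection keeps every
   set's name and size, with members drawn per set from the pooled
   multiset of gene occurrences. Draws use systematic
   probability-proportional-to-size sampling in a freshly shuffled
   order, giving *exact* per-gene inclusion expectations — naive
   sequential weighted sampling without replacement measurably
   under-samples frequent genes. The null statistic re-runs the full
   pathway enrichment per random collection (conservative: the
   alternative of randomising only the enrichment output would not
   preserve the enrichment mechanics). Default 1000 collections.
3. **XSWAP network null** (`xswap` + `network_permutation_test`):
   repeated edge-pair rewiring (a→b, c→d) → (a→d, c→b), rejected if it
   would create a self-loop or duplicate edge; polarity travels with
   the source's edge. Every node's in/out-degree, the edge count and
   the polarity multiset are conserved exactly. Default 10·|E| swap
   attempts (standard burn-in) and 100 random networks; the observed
   statistic propagates targets through the real network, each null
   draw through a fresh randomisation. Compounds whose propagated
   vector is all-zero are excluded from all means with a warning.

## Pairwise analyses

Pairs of compounds are eligible only if tested in at least one shared
cell line (discarding cross-cell-line variability). By default each
pair's transcriptomic vectors are rebuilt as the union over experiments
from the *shared* cell lines only; a flag restores the global union,
since which convention the upstream resources use is ambiguous.
The pair table carries the signed Jaccard of target vectors and of
transcriptomic vectors plus a sign-blind shared-target flag.

* `similarity_correlation`: Pearson between the two similarity columns,
  null by permuting the transcriptomic column.
* `shared_target_fraction(threshold)`: retention is `≥ threshold`
  (pairs *below* the cutoff are filtered out, so boundary pairs are
  kept); a strict `>` switch exists.
* `same_target_pairs`: pairs with target Jaccard exactly 1 — identical
  targets affected in the same direction; a single flipped sign
  excludes the pair.

## Structural case study

Morgan fingerprints at radius 2 / 2048 bits (the community-standard
ECFP4 equivalent) with Tanimoto similarity; Bemis–Murcko framework
identity on canonical scaffold SMILES (acyclic molecules have empty
frameworks and compare equal, with a warning). The shipped cardenolide
pair digitoxigenin/sarmentogenin scores Tanimoto 0.741 under these
defaults (0.737 at 1024 bits; 0.75 with count fingerprints) — the
second decimal is sensitive to fingerprint settings, which published
analyses often leave unreported. Structures are flat SMILES;
stereochemistry is irrelevant to the default (achirality-blind)
fingerprint. The concordance overlay labels every network node as
target / concordant / discordant / single-compound / no-change /
unmeasured, where `unmeasured` means absent from the gene universe and
`no-change` means measured but zero in both vectors.

## Synthetic data generator

`SyntheticConfig` defaults emulate a full-scale compound-perturbation
resource: 4938 measured genes, 2152 compounds with both modalities,
most compounds with 1–5 targets (distribution
{1: .40, 2: .25, 3: .15, 4: .12, 5: .08}), 10 cell lines, 20% of
compounds profiled at 2–4 concentrations, 150 pathways with log-uniform
sizes in 15–300 (the long tail of pathway databases), a random directed
network at mean degree 3 with 60% activating edges, and a 5% chance
that a compound copies an existing compound's full signed target set
(producing the same-target pairs the pairwise analyses need).

The planted signal: each compound's "enriched neighbourhood" is the
union of its pathway-enriched and 3-level network-propagated vectors
(where the two routes disagree the gene is unplanted). Per experiment,
each neighbourhood gene is differentially expressed with its propagated
sign with probability `effect_strength`; every other gene fires at
`background_de_rate` (default 0.05) with a random sign. The targets
themselves are excluded from planting, mirroring the empirical
observation that targets are rarely differentially expressed — so raw
target/transcriptomic correlation is null even at high effect strength,
while enriched vectors recover the signal. At `effect_strength = 0` the
data are pure noise, which is what the calibration tests check.

What the generator does *not* emulate: expression magnitudes (only
ternary calls), realistic pathway overlap structure (sets are uniform
samples), scale-free degree distributions, batch effects, or
correlated noise across experiments. Passing tests therefore
demonstrate correctness of the machinery and detectability of a planted
causal signal — not that real data contain such a signal.

## Problem sizes and determinism

Every random component is driven by explicit integer seeds through
`numpy.random.default_rng`; identical config + seed gives bit-identical
output, and the pipeline records every stage seed in its summary JSON.
The test suite and `scripts/acceptance.py` run the analyses at desk
scale — e.g. 100–600 genes, 100–300 compounds, 1000 shuffles for
calibration replicates, 100–200 random collections/networks — chosen so
the full suite completes in minutes while keeping every statistical
check well-powered. The acceptance script reports the
shared-target contrast at transcriptomic-similarity threshold 0.3
because at desk scale pair similarity scores sit lower than in a
full-size study; the threshold scales with the problem, not with any
desired outcome.

## Known limitations

* Identifier matching is exact; no cross-database gene symbol mapping.
* The union rule weights every experiment equally (no cell-line
  weighting), and the discrepancy rule's 2× constant is fixed.
* Conflict cancellation (both enrichment routes) is one defensible
  convention; real regulatory logic may resolve conflicts
  asymmetrically.
* The gene-set null preserves per-gene occurrence in expectation, not
  exactly per draw; sets larger than the feasible inclusion bound are
  handled by capping and redistribution.
* Pearson on ternary vectors is dominated by the zero class when
  vectors are sparse; the signed Jaccard is the more interpretable
  metric in that regime, which is why both are always reported.
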