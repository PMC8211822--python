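# Methods

`cappscan` re-implements, as a reusable and fully tested pipeline, the
comparative-genomics workflow used to discover and classify
CRISPR-Associated Primase-Polymerases (CAPPs): extract the gene
neighborhood around each homolog hit, keep neighborhoods with CRISPR-Cas
context, quantify which genes recur at which positions, place the homologs
on a bootstrapped distance tree, and split them into classes and
domain-architecture types.  Because the original screen ran against
database-scale homolog searches that cannot be reproduced at desk scale,
every stage here is exercised on synthetic genomes and protein families
with planted, machine-readable ground truth.

## Neighborhood extraction

A genome annotation (GFF3 or a 7-column feature-table TSV; 1-based
inclusive coordinates on disk, 0-based half-open internally) is reduced to
its gene list per contig.  For each focal accession the window of up to
W = 20 genes per side (40 in total) is extracted, truncating at contig
edges rather than erroring.  Positions are signed relative ranks, oriented
along the focal gene's reading direction: -1 is the adjacent upstream gene,
+1 the adjacent downstream gene, so minus-strand operons align with
plus-strand ones.  Orientation is a deliberate normalisation choice — the
occurrence heatmap speaks of genes upstream and downstream of the focal
gene — and can be disabled (`--no-orient`) to keep raw genomic order.
Overlapping windows from multiple hits are kept independent; no merging
rule is applied.

## Keyword validation and the occurrence matrix

A neighborhood is kept when some neighbor's product name contains "CRISPR"
and some neighbor's name contains "Cas1", both as case-insensitive
substrings (one gene may satisfy both filters).  Over the validated
regions, `counts[k][p]` is the number of regions whose gene at position `p`
exists and matches keyword `k`; percentages divide by the global number of
validated regions.  A region whose truncated window has no gene at `p`
simply contributes no count there; the alternative per-position
denominator (number of regions that do have a gene at `p`) is available as
an option since neither convention is obviously right for edge-truncated
windows.  The shipped keyword list ({CRISPR, Cas1, Cas2, primase,
polymerase, helicase, nuclease, transposase, argonaute}) is a configurable
default; for real data the list is analysis-specific and must be supplied.

## Distances, tree, and bootstrap

Pairwise distances use the proportion of differing residues `p` over
columns where neither row has a gap or X (pairwise deletion; complete
deletion available), corrected for multiple hits with Kimura's protein
distance

    d = -ln(1 - p - 0.2 p^2),

which is monotone on [0, p_max) with p_max = (-1 + sqrt(1.8))/0.4 ≈ 0.8541.
The original analysis used a commercial workbench's "Kimura protein"
distance setting whose exact internals are undocumented; Kimura's standard
approximation is the natural open implementation and is recorded as such.
Saturated pairs (p ≥ p_max) raise an error by default — a single capped
distance can distort the whole topology — with an explicit `cap` opt-in.

Trees are built with Saitou–Nei neighbor joining: join the pair minimising
`Q(i,j) = (m-2) d(i,j) - Σ_k d(i,k) - Σ_k d(j,k)`, with limb lengths from
the standard formulas.  Ties in Q break on the lexicographically smallest
pair of cluster representatives (the minimal leaf label in each cluster),
making the output deterministic.  Negative limb lengths are clamped to
zero with the deficit moved to the sister limb, preserving the joined
pair's distance.  Bootstrap support resamples alignment columns with
replacement to the original length, rebuilds NJ per replicate, and reports
for each internal edge of the reference tree the percentage of replicates
containing the same bipartition (reference-tree mapping, not majority-rule
consensus, matching how a single annotated tree is usually drawn).
Replicate RNG streams derive from (master seed, attempt counter), so
results are independent of execution order; replicates with saturated
pairs are rejected and redrawn, and more than 50% rejections aborts.
The default replicate count is 100.

## Classification

Domain architectures (ordered N→C labels from {TPR, AEP, PriCT, RT,
Helicase, VirE_N}) are typed by ordered rules: TPR before AEP → CAPP-TPR;
RT before AEP → CAPP-RT; AEP before Helicase → CAPP-Helicase; a lone AEP or
VirE_N catalytic domain, optionally decorated with PriCT, is the CAPP_B
pattern; anything else is unclassified.  PriCT alone is never diagnostic.

The two top-level classes are separated on the tree by the longest internal
edge on the path between two seed leaves (one per class).  The original
classification combined two non-intersecting homolog datasets with tree
inspection; the longest-inter-seed-edge rule is a deterministic,
reproducible proxy for that deep split and is documented as an
interpretation.  Architecture/clade conflicts (e.g. a CAPP_B-pattern
protein inside the CAPP_A clade) are flagged in the output, never silently
overridden, since no resolution rule exists.

## Synthetic data and what it does (not) show

Genomes: per contig, a fixed number of non-overlapping genes with random
lengths (300–1500 aa equivalent) and intergenic gaps (20–200 bp); operon
templates are planted as consecutive genes (gene order reversed on the
minus strand, planted with probability `strand_policy` = 0.5); background
product names come from a pool screened at generation time to contain no
tracked keyword, which makes planted-recovery checks exact.  Defaults
(3 contigs × 50 genes, one [CAPP, Cas1, Cas2] operon per contig) give full
40-gene windows when the plant lands centrally and exercise edge
truncation otherwise.

Proteins: a 20-state equal-frequency, equal-rate Markov substitution model
(protein analogue of Jukes–Cantor) along a known guide tree; per site and
branch the substitution count is Poisson(rate × length), each substitution
uniform over the 19 other residues.  Two leaves at path distance d differ
with probability `p = (19/20)(1 - e^{-20 d / 19})`, which the tests verify
against an independent matrix-exponential evaluation and against simulated
alignments.  No indels are generated, so the alignment is implicit and the
upstream multiple-alignment step stays out of scope.  The standard
two-family condition — two clades of 10 sequences, within-family branch
lengths of 0.02–0.08, joined by an edge of 1.0 expected substitutions per
site, 200 sites — represents the deeply diverged homolog families of the
study at a size where a 100-replicate bootstrap runs in seconds.

What passing on this generator does **not** show: robustness to indels and
alignment error, rate heterogeneity across sites or lineages,
compositional bias, annotation noise in real product names (keyword
matching is exact substring search), or non-coding features interleaved
with genes.  Real-data runs ingest an externally computed alignment and
CDD-style domain annotations for exactly this reason.

## Numerical notes and limitations

- **Kimura correction under the equal-rates generator.**  The exact
  inversion for this generator is `d = -(19/20) ln(1 - 20p/19)`; Kimura's
  formula (tuned to empirical amino-acid data) overestimates d by ~+1.7%
  at d = 0.1, ~+10% at d = 0.6, ~+19% at d = 1.0.  Path-length recovery is
  therefore asserted as a mean relative error under 15% at depths ≤ 0.6
  (per-pair bound 30%, since binomial noise at 1000 sites is ±10% of d for
  short pairs).  Topology and support recovery are unaffected, since the
  correction is strictly monotone.
- **Bootstrap calibration limit.**  A literally zero-variance alignment
  (one column pattern repeated) always has some pair at p = 1, outside the
  correction's domain; the calibration test instead uses a strongly
  repetitive block alignment (pairwise p ≤ 0.6) where every replicate
  reconstructs the reference topology and all supports are 100%.
- **Heatmap TSV round-trip.**  Percentages are printed to 1 decimal; the
  reader reconstructs integer counts from the `n_regions` header, which is
  exact for up to a few hundred regions.
- **Determinism.**  Every generator and the bootstrap consume
  `numpy.random.default_rng` streams keyed by explicit seeds; identical
  config + seed reproduces byte-identical run directories.
- **Problem sizes.**  The analysis scripts and acceptance computation use
  5 genomes × 50 genes, 16–20 sequences × 200 sites, and 100 bootstrap
  replicates — sizes at which the planted structure is unambiguous and a
  full run takes seconds.
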