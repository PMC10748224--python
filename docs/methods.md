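# Methods

This note documents the model assumptions, parameter choices and numerical
conventions behind `hrrnet`, and what the synthetic benchmark does and does
not demonstrate.

## Input model

The pipeline assumes a bulk expression matrix in FPKM-like units (nonnegative,
length/depth-normalised) over an ordered stage design with replicate columns
named `<stage>_<replicate>`.  Differential-expression statistics are consumed,
never produced: the DEG table carries one row per gene × adjacent-stage
comparison with a log₂ fold change and an FDR, as emitted by DESeq2/edgeR-type
tools.  Annotation is a GMT term → gene mapping; TF status is a plain
gene → family table.

## Screens

- *Expressed*: FPKM ≥ `fpkm_min` (default 2) in at least one **stage mean**.
  "One transcriptome per stage" is the default reading because each stage is
  one library condition; `stage_level_filter: false` switches to
  any-single-sample.  The filter is idempotent and order-preserving.
- *Candidates*: union over all comparisons of rows with FDR ≤ 0.05 **and**
  |log₂FC| ≥ 1, plus an optional curated list.  All four printed boundaries
  here and below are inclusive.  Union-over-comparisons is used because the
  analysis pools differential genes across the stage series rather than
  requiring a specific contrast.

## Correlation and HRR

Pearson *r* is computed over replicate-level samples (21 columns in the
default design), not stage means — replicates contribute real degrees of
freedom to the correlation estimate; a flag recomputes on stage means.
Zero-variance genes have undefined correlations: they are flagged, stored as
r = 0 and excluded from the network.

Partner ranking for HRR uses |r| (descending, rank 1 = strongest), because
negatively correlated pairs past the same absolute threshold are admitted as
(dashed/negative) edges.  Ties in |r| are broken by lexicographic gene id so
the transform is a pure function of its input.  HRR(A,B) = max of the two
mutual ranks, an integer in [1, n−1].

Edges require |r| ≥ `r_min` (0.8) and HRR ≤ `hrr_max` (10/20/30; default 30,
the loosest printed cutoff).  Each edge records `r`, `hrr`, `sign` and a
`weight` used by the flow clustering.

### Edge weight rules

Two rules are provided:

- `cutoff_bin` (default): every admitted edge gets the constant weight
  1/(`hrr_max` − 5), i.e. 1/5, 1/15, 1/25 at cutoffs 10, 20, 30.  This is the
  published cutoff-to-weight correspondence, and it makes Markov flow treat
  all admitted edges equally — the topology (who is connected) carries the
  information, which is the HRR philosophy: the threshold already encodes
  rank confidence.
- `inverse_hrr`: weight = 1/HRR per edge.  Useful as a per-edge strength for
  reporting, but as a flow weight its four-order-of-magnitude skew
  (1.0 → ~0.03) makes inflation 3.0 shatter dense co-expression groups into
  mutual-top-partner fragments of 2–3 genes; it is therefore not the
  clustering default.

Intramodular connectivity (below) always scores Σ 1/HRR regardless of the
flow-weight rule, reading the `hrr` edge attribute directly.

## Markov clustering

Dense NumPy implementation of expansion/inflation flow simulation:
column-stochastic transition matrix, expand = matrix power e (default 2),
inflate = entrywise power I (default 3.0) + column renormalisation, prune
entries < 1e-5 (never a column's maximum) and renormalise, stop when the
largest entry change < 1e-8 or after 200 iterations (non-convergence returns
the current state with a flag; in practice the benchmark converges in ~10
iterations).

Self-loops are set to each node's strongest incident edge weight (the
canonical choice, keeping the loop on the scale of the node's own flow);
isolated nodes get a constant loop so their column stays stochastic.  A
"min 1" floor on loops was rejected: with constant 1/25 edge weights it
makes self-retention dominate all neighbour flow and every node becomes a
singleton attractor.

Cluster extraction is deterministic: attractors are rows with positive
diagonal; attractors sharing residual flow form one attractor system; every
other node joins the system receiving the largest share of its outgoing
flow, with ties resolved toward the larger then lower-id cluster.  Cluster
ids are ordered by size (descending), then by lexicographically smallest
member, so relabeling nodes permutes the clustering without changing it.

Cluster filtering: a surviving cluster needs ≥ 3 genes **and** at least one
significantly enriched term.  The published removal sentence is ambiguous
between OR- and AND-removal; OR-removal (keep ⇔ both merits) is the default
because every published surviving cluster is both ≥ 6 genes and annotated.
`cluster_filter_rule: and` switches to strict-AND removal.

## Enrichment

Per cluster, every term with ≥ 1 member is tested with the hypergeometric
upper tail P(X ≥ k) (scipy's survival function; verified in the suite
against exact rational enumeration to 1e-12 for all universes N ≤ 25).
BH adjustment is applied **within the cluster's own term family** — verdicts
are per-cluster decisions; pooling families across clusters is available by
pre-merging clusters upstream.  A term is significant when FDR < 0.05 and
k ≥ 2.  The universe defaults to the genes that entered the network (the
candidate set), matching the network's scope; restricting or widening it is
a one-call change on the `AnnotationMap`.  Raw-p tiers
(significant < 0.05, highly < 0.01, very highly < 0.001) are report labels
only; all filtering uses the FDR.

## Modules, hubs, key genes, TFs

Cluster eigenprofiles are means of member z-scored stage profiles (z-scores
use the population sd, n in the denominator; constant genes z to zero — the
convention only rescales, never reorders).  Average-linkage agglomeration on
1 − r between eigenprofiles is cut at distance 1 − `merge_r`
(default 0.9): high enough that the ten planted archetypes — whose pairwise
profile correlation is ≤ 0.5 by construction — never merge, low enough to
reunite same-archetype clusters that MCL split.  Module ids sort by
peak-stage index then size, so module 1 peaks earliest.

Connectivity is the weighted within-module degree Σ 1/HRR (a `degree` mode
counts edges instead).  Ranking ties break by higher mean expression over
all samples, then gene id; rank-1 ties are recorded in the hub report rather
than silently dropped.  Top 10 (or all, for smaller modules) are hubs; rank
1 is the key gene.  TF partners are any labelled TF with |key-gene
correlation| ≥ 0.8, taken from the raw correlation matrix rather than the
thresholded graph, since the criterion is stated on correlation alone.

## Synthetic benchmark

The generator emulates the structure the analysis assumes: ten archetype
profiles over seven stages (seven single-stage peaks, an early VS–FM
plateau, a late BS-1–BS-3 plateau, and a nondecreasing rise to FS), designed
so that distinct archetypes correlate at r ≤ 0.5 (and |r| ≤ 0.75, below the
edge threshold) on both the log and the FPKM scale.  Expression is
exp(profile + gene offset + ε) with ε ~ N(0, 0.2²) i.i.d. per gene and
sample — multiplicative noise on FPKM, matching its heavy-tailed behaviour;
the planted hub's ε is halved so its tighter profile adherence surfaces as
connectivity.  Profile amplitude is 3 natural-log units over a ~10-FPKM
baseline, so every archetype's largest adjacent-stage step clears the
|log₂FC| ≥ 1 screen with margin.  The synthetic FDR column is anchored to
the *true* profile step (small FDR where the true |log₂FC| ≥ 1), not fitted
from counts — DE model fitting is outside the pipeline's scope.  Each
module's two terms cover 90% of members and 2% of outsiders; three members
per module plus ten background genes carry TF labels.  All randomness flows
from one `numpy` generator seeded by the truth's seed, making every output
file byte-reproducible.

Default problem size (10 × 20 planted + 100 background genes, 21 samples)
runs the full pipeline in under a second; the test suite and the acceptance
script use it unchanged.

What passing recovery tests shows: the pipeline's stages compose correctly
and the planted structure (block membership, hub identity) is recoverable
under the stated noise.  What it does not show: robustness to library-size
artefacts, batch effects, count overdispersion, correlated noise between
replicates, or annotation incompleteness — none of which the generator
models.  On the benchmark, module-assignment ARI is 1.0 and 9/10 planted
hubs appear in their module's top-10 hub list (seed 1); the planted hub is
rarely the single top-connectivity gene, because with 21 samples chance
noise alignment among near-perfectly correlated module mates decides rank 1
even though the hub ranks above the module median.

## Degenerate inputs and conventions

- Empty screen results warn rather than raise; an empty network is legal.
- Path metrics (diameter, characteristic path length) average over
  connected pairs only; single-node graphs report 0.
- Centralization uses Freeman degree centralization, 0 for n ≤ 2;
  heterogeneity is sd(degree)/mean(degree).
- The qPCR utility implements 2^−ΔΔCt with an explicit calibrator sample;
  validation correlates stage-mean fold changes against stage-mean FPKM and
  reports undefined correlations (zero variance) as missing.
- Manifest `artifact_hash` fingerprints artifact contents and counts,
  independent of absolute paths; timestamps live in a separate field so
  determinism can be checked by dropping one key.
- The reproduction script pins BLAS to a single thread: multi-threaded
  matrix multiplication changes floating-point reduction order, which can
  flip a borderline attractor assignment between otherwise identical runs.

## Known limitations

- MCL is dense (O(n³) per iteration): fine to a few thousand network genes,
  not for whole-transcriptome graphs.
- Exact reproduction of any published cluster-by-cluster composition is out
  of reach by design: it depends on unreleased data and unstated plugin
  settings; the package reproduces the method, with every knob logged.
- The enrichment model ignores the annotation DAG (no ancestor
  propagation) and tests terms independently.
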