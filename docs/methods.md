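# Methods

This note documents the models, parameter choices and numerical
conventions behind `disconet`, and what the synthetic cohorts do and do
not establish about behaviour on real data.

## Synthetic cohorts

`generate_cohort` emulates a multi-dataset microarray compendium on the
log2 scale. Each gene has a constant baseline intensity drawn from
N(7, 1.5²) — typical microarray magnitudes — and each sample adds:

* **measurement noise**: i.i.d. N(0, `noise_sd`²), default 0.5 log2
  units;
* **batch effects**: one additive per-gene shift vector per dataset,
  drawn N(0, `batch_shift_sd`²), default 0.3. This is a location-only
  batch model; real batch effects also distort scale. A scale component
  is deliberately omitted from the default generator so that the batch-
  correction tests isolate the location behaviour; the correction
  itself handles scale regardless.
* **planted modules**: `n_modules` disjoint gene blocks whose members
  share a per-sample latent factor, `signal = noise_sd·(√r·f + √(1−r)·ε)`
  with `f, ε ~ N(0,1)`, so the expected within-module pairwise Pearson
  correlation equals `module_correlation` (default 0.8) exactly — the
  simplest mechanism with an analytic target.
* **planted differential expression**: per disease, a fraction
  `de_fraction` (default 0.05) of genes shifted by ±`de_lfc` (default
  2.0) in case samples. DE genes are drawn from outside the modules by
  default so DE recovery and co-expression recovery do not confound
  each other (`de_overlaps_modules=True` lifts this).

**Modules are disease-specific.** Each module is assigned round-robin
to one disease and its latent factor is active only in that disease's
case samples. A globally active module would light up every disease
network equally, making pathway→disease similarity recovery
unidentifiable; tying modules to diseases is what gives the similarity
statistics a ground truth to recover. Control samples carry no module
signal, so the normal network is a background reference.

Default cohort sizes (3 diseases × 2–3 datasets × 30–40 samples, 300
genes) are chosen so that every default disease clears the ≥50-sample /
≥2-dataset inclusion filter and the whole pipeline runs in seconds;
analyses in the tests that need more power (e.g. DE recovery at 1,000
genes, 30 vs 30 samples) configure their own sizes explicitly.

What passing tests on these cohorts do **not** show: robustness to
heavy-tailed intensity distributions, probe-level artefacts,
scale-distorting batch effects, correlated (non-block) co-expression
structure, or confounding between disease label and batch. The
generator's gene identifiers are synthetic symbols; no gene-registry
semantics are implied.

## Preprocessing

Order of operations: per-dataset quantile normalisation → merge →
batch correction → probe collapsing. Normalisation is per dataset only
and is not re-applied after merging, matching the convention that each
dataset is pre-processed independently before integration.

* **Quantile normalisation** maps every sample onto the mean sorted
  profile; ties receive the mean of the reference values at their rank
  positions, which makes the transform idempotent (to 1e-12).
* **Batch correction** is a direct per-gene location–scale
  standardisation: each batch is centred, rescaled to the gene's
  df-weighted pooled within-batch standard deviation, and recentred on
  the gene's grand mean. It is a deterministic, closed-form stand-in
  for empirical-Bayes batch correction: with many genes and moderate
  batch sizes the shrinkage of per-batch parameters matters little, and
  on the generator's additive shifts the adjustment is exact. Batches
  with one sample, or genes with zero within-batch variance, get a
  location-only adjustment (with a warning for the former).
* **Probe collapsing** keeps the most variable probe per gene
  (unbiased, n−1 variance); equal-variance ties go to the
  lexicographically smallest probe id so results are reproducible.
* **Disease inclusion**: a disease needs ≥50 samples over ≥2 datasets
  and must not carry an excluded (over-broad) label, 'cancer' by
  default. Controls are pooled only from datasets contributing to a
  retained disease and relabelled 'normal'.

## Co-expression networks

Correlations use all samples carrying the disease label, controls
excluded; the normal network uses the pooled controls. Zero-variance
genes (which quantile normalisation can produce at the rank extremes)
are dropped before correlation, and the per-network `universe_size` is
recorded post-drop.

The signed adjacency `((1+r)/2)^β` keeps negative correlations near 0
instead of folding them onto positives. β defaults to 12, the common
convention for signed networks; `pick_soft_power` implements the usual
scale-free-fit selection (signed R² of log-frequency vs log-binned
connectivity, target 0.8, smallest qualifying candidate) for users who
prefer a data-driven power, but is off by default to keep runs
deterministic and comparable.

The unsigned TOM formula on this signed adjacency is used; diagonal
defined as 1. Edge retention keeps `⌈fraction·n(n−1)/2⌉` pairs — the
ceiling convention reproduces the canonical 2,036,667 edges at 1% of a
20,183-gene universe. The retention fraction is interpreted exactly at
its decimal representation (via `Fraction`) so that e.g. 1% of 19,900
pairs is 199, not a floating-point artefact's 200. Ties at the
retention cut break by lexicographic gene-pair order.

## Differential expression and consensus

The per-gene test is Welch's two-sample t against the pooled controls
of the disease's own datasets, BH-adjusted across genes. The package's
scientific contribution is the consensus construction, not the DE
engine; Welch's t is an unshrunk, deterministic stand-in for a
moderated-t engine and is swappable behind
`differential_expression`. Rows where both groups are constant get
p = 1 (no evidence of change). Genes with log2FC exactly 0 are
direction 'zero' and excluded from both consensus sides.

Significance filtering (adjusted p < 0.05, strict) happens per disease
*before* the consensus averages, so the consensus summarises only genes
that were individually significant — mean adjusted p and mean log2FC
per (gene, direction), with the contributing disease count. The
extreme-gene cuts (mean adjusted p < 0.01, |mean log2FC| > 1.75) are
strict inequalities.

## Similarity statistics and enrichment

The pathway-based statistic's denominator counts *all* pathway pairs,
including proteins absent from the network — it measures how much of
the pathway the network recovers, not how dense the recovered part is.
The interactome-based statistic conditions on knowledge-supported
edges; when the interaction graph supports no edge inside a pathway the
value is undefined and propagated as missing rather than 0, since "no
knowledge" must not be conflated with "no overlap". All relation types,
including `has_component`, count as supporting edges (a flag on the
knowledge-graph reader can exclude types upstream if desired).

Row standardisation maps constant rows to all zeros (a row with no
contrast carries no ranking information); missing entries are ignored
in the min/max and stay missing. Heat-map row ordering uses
average-linkage hierarchical clustering on Euclidean distance —
presentation only.

ORA default universe is the caller-supplied measured-gene set (the
union of network nodes in the pipeline); the Fisher p-value is the
exact upper hypergeometric tail, and adjustment across pathways uses
Benjamini–Yekutieli, which stays valid under the strong dependence of
overlapping pathways.

## Overlay semantics

A pathway interaction edge matches a co-expression network iff *any*
protein pair across the two endpoint expansions (complexes expand to
their members) is a network edge — one strong co-expressed pair is
taken as evidence for the drawn interaction. Edge classes
{pathway∩both, pathway∩disease, pathway∩normal, pathway-only}
partition the interaction edges; disease-network correlations between
pathway-covered proteins that match no drawn interaction are added as
'coexpression-only'. Complex nodes get a consensus direction only when
every member agrees on a non-zero direction; any member missing from
the DE table yields 'unknown', disagreement yields 'mixed'.

## Knowledge graph conventions

Edge direction is discarded (all overlap and similarity analyses treat
edge sets as undirected); causal relation types survive as labels, and
an edge reported with several types counts one instance per type in the
relation distribution so fractions sum to 1. The graph is restricted to
pathway-annotated proteins, guaranteeing every node at least one
annotation.

## Determinism and numerics

All generator randomness flows from a single integer seed through a
sequential PRNG; the pipeline derives named per-stage substreams by
hashing `seed:stage` (values kept below 2³¹). TSV floats are written
with `%.10g`, making reruns byte-identical. Occurrence, ranking and
top-k operations break ties lexicographically throughout.

## Known limitations

* The location–scale batch adjustment does not pool information across
  genes; for very small batches on real data an empirical-Bayes
  correction is preferable.
* Welch's t loses power versus a moderated t at very small sample
  sizes; the inclusion filter's 50-sample floor mitigates this.
* Similarity values depend on the retention fraction; comparisons are
  meaningful only between networks built with the same fraction on the
  same universe.
* The generator plants block-structured modules; methods that exploit
  finer correlation geometry are not stress-tested here.
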