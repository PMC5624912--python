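# Methods

This note documents the models and procedures `gangliotype` implements, the
parameters that matter, the design choices made where the published
description left the design open, and what the synthetic-data generator does
and does not emulate.

## Data model

The pipeline consumes a dense genes × cells FPKM matrix. FPKM values are
already length- and depth-normalized, so no further normalization is
applied; all correlation and PCA steps operate on log₂(FPKM + 1) by default
(a raw-FPKM mode is retained behind `log=False` for replication attempts).
The log transform is a design choice: the source analyses display log₂ FPKM
throughout but do not state the transform used for clustering. Gene symbols
are matched case-sensitively and exactly; fuzzy matching would hide data
errors. Missing values are not permitted — a cell with no measurement must
be an absent column.

## Gene filters

Three regimes, each with inclusive (≥) thresholds unless stated:

| filter | parameters (default) | role |
|---|---|---|
| high expression | mean FPKM ≥ 200 over all cells | level-1 clustering set |
| group selective | detected (> 0 FPKM) in ≥ 2 in-group cells; in-group mean ≥ 1; in/out fold ≥ 5 | level-2 clustering set |
| detection | FPKM ≥ (or >) 10 in ≥ 3 cells | large-gene-set PCAs |

Decisions taken where the criteria were stated loosely:

- "Expression in at least 2 neurons" is read as FPKM > 0 in ≥ 2 in-group
  cells — the weakest faithful reading; the detection level is configurable
  (`FilterSpec.detect_threshold_fpkm`).
- Fold ratios are computed on means of raw FPKM with pseudocount ε = 0.01
  added to numerator and denominator, so a zero out-group mean yields a
  finite ratio. ε is far below the FPKM ≥ 1 mean criterion and cannot
  demote a genuinely selective gene.
- One published detection filter is stated with a strict inequality; the
  `strict` flag exposes both dialects.

All filters are monotone: raising any threshold can only shrink the
returned set (property-tested).

## Clustering

Cell–cell similarity is the Pearson correlation coefficient over the
selected gene set; the distance is 1 − r (the standard affine choice — the
source fixes the distance family as "centered Pearson correlation" but not
the map). UPGMA (average linkage) is implemented in-package: at each step
the pair of clusters with minimal mean inter-cluster distance merges, with
equal-distance ties resolved toward the lexicographically smallest node-index
pair, making trees bit-reproducible across platforms. Merge heights equal
mean inter-cluster distances and are non-decreasing. Tests verify exact
agreement (topology and heights) with an independent exhaustive oracle that
re-averages leaf-pair distances from the original matrix at every step.

**Flat cuts.** `cut_tree(tree, k, min_cluster_size)` treats `k` as the
number of *retained* clusters: the tree is descended, increasing the flat
cluster count from `k`, until exactly `k` clusters of at least
`min_cluster_size` cells exist; all remaining cells are `unassigned`. With
`min_cluster_size=1` this is the ordinary k-cut. This definition was chosen
because cells that genuinely fail to cluster (the level-2 outliers) split
off at the *top* of the dendrogram: a literal cut into k flat clusters
would spend clusters on single stragglers and merge the real sub-groups.
The first level uses k = 2 at the root (the first-order separation); the
second level uses k = 3 with a minimum size of 3, so sub-branches of one or
two cells are reported `unassigned` rather than forced into a type.
Retained clusters are named C1, C2, … by decreasing size; mapping to
biological names (gustatory/somatosensory, T1–T3) is done downstream by
marker evidence, never by size alone. Accordingly, the level-2 target
cluster defaults to the larger level-1 cluster but can be overridden
(`target_cluster`) when marker evidence says otherwise.

**PCA.** PCA of cells in gene space on log-transformed, per-gene
mean-centered values, without unit-variance scaling — centering-only keeps
highly expressed genes dominant in the loadings, matching the observation
that top loadings are highly expressed genes; `standardize=True` exposes the
alternative, since the source does not say whether genes were scaled.
Component signs are fixed so the largest-magnitude loading is positive.
Concordance between a dendrogram partition and PCA is quantified by
clustering the top-2 PC scores (UPGMA, Euclidean) at the same k and
computing the adjusted Rand index, with `unassigned` cells excluded
pairwise; a single-cluster partition yields NaN with a warning.

## Marker ranking and panel classification

Markers for a cluster are the genes passing the group-selective filter
(cluster vs. all other assigned cells), ranked by
log₂(fold) × in-cluster detected fraction — a score monotone in both
selectivity and prevalence, the two properties exemplar markers need; the
source shows exemplars but gives no formula. Ties break alphabetically.

Panel classification reproduces the post-hoc assignment of independently
profiled cells from presence/absence calls on a small receptor panel. A
call is `present` iff FPKM ≥ threshold (default 1; 20 for the
Htr3a-style "significant expression" call). The shipped ordered rules are:
P2rx2⁻P2rx3⁻ → somatosensory; P2rx3⁺P2rx2⁻ → T2; P2rx2⁺Htr3a⁻ → T1;
P2rx2⁺Htr3a⁺ → T1-or-T3; anything else → ambiguous. The panel contains no
rule separating T1 from T3, so the joint label is deliberate. "Strong
expression of P2rx2/3" is encoded as P2rx2 present, since the T2 contrast
keys on P2rx2 absence.

## Ca²⁺ scoring

Default acquisition: one frame per 1.5 s (0.67 Hz). Parameters and
decisions:

- Baseline F₀ and noise are the mean and s.d. of the 10 frames immediately
  before each stimulus onset; the noise enters the 5-s.d. response rule in
  ΔF/F units (the source does not say which frames define baseline noise).
- The 40-s peak window starts at stimulus *onset* (27 frames at the default
  rate); whether it starts at onset or offset is unstated, and onset is the
  conservative choice.
- "Flat baseline" QC is quantified as every pre-stimulus baseline within
  ±10 % of the recording's first baseline (configurable `drift_tolerance`);
  recovery requires fluorescence to return within the same tolerance of the
  local baseline within 3 min of each stimulus.
- The two KCl-alone events flanking each KCl+GABA application are taken
  within the same five-stimulus block (positions 3 and 5 of
  5HT, ATP, KCl, KCl+GABA, KCl); inhibition is averaged over the two blocks.
- Response flags are set only when the call agrees between the two blocks;
  inconsistent cells are excluded from functional clustering, mirroring the
  replication requirement of the assay.
- For clustering, the inhibition feature is divided by 100 so its numeric
  range matches ΔF/F before Euclidean distances are formed (feature scaling
  is unstated in the source).

## Validation arithmetic

ΔΔCq assumes amplification efficiency exactly 2 (no efficiency correction,
matching the stated method): fold = 2^(ΔCq_after − ΔCq_before), with
replicates averaged before differencing. Values below 1 indicate enrichment
and are reported as such. ROI normalization subtracts the mean of the four
weakest neuronal ROIs per image, clamps negative values at 0 (values below
background are not addressed in the source), and scales to the image
maximum; the output is invariant to additive shifts and positive rescaling.

## Synthetic data

The expression simulator plants the study design directly: 96 cells in
groups of 37 (somatosensory), 33/6/18 (gustatory sub-clusters T1/T2/T3) and
2 gustatory outliers, with 17,000 genes. In log₂ space each value is a
per-gene baseline (Normal(1.5, 2.0) for unstructured genes) plus planted
shifts plus per-cell Normal(0, 0.4) noise, exponentiated to FPKM; values
below 1 FPKM drop to zero with probability 0.3 (threshold dropout).

Planted tiers: 250 high-expression neutral genes (baseline ≈ 2^8.5 FPKM);
300 gustatory-wide and 300 somatosensory-wide markers (baseline ≈ 2^6,
shifted +4 log₂ in their class — these, plus the neutral tier, populate the
mean ≥ 200 FPKM pool that drives level-1 clustering); 150 markers per
sub-cluster carrying the gustatory-wide +4 plus an equal extra shift in
their own sub-cluster (the gustatory-wide component is what lets them
survive the taste-selective filter); 30 % of T2 markers are additionally
expressed at a reduced level (+1 log₂) in somatosensory cells, emulating
the Mafb-like shared pattern. Each outlier cell owns 400 private genes
that are taste-selective like sub-cluster markers but carry large random
per-gene shifts (Normal(0, 6) log₂) in that cell only. The private
perturbation must be this strong: with weaker shifts an outlier cell
remains *more* correlated with every sub-cluster than sub-clusters are with
each other (measured ≈ 0.38 outlier-to-cluster distance vs ≈ 0.46
cross-cluster at shift s.d. 4), and the planted "does not cluster well"
property would simply be false; at the default the distances are ≈ 0.55 vs
≈ 0.38. Four named receptor-panel genes (P2rx2, P2rx3, Htr3a, Gabra1) are
planted at class-dependent levels consistent with the panel rules.

What the generator does **not** emulate: count-level sampling noise
(negative-binomial counts are out of scope — the pipeline consumes already
normalized FPKM), gene–gene correlation beyond the planted block structure,
doublets (excluded upstream at capture QC), batch effects, and the
long-tailed library-size variation of real single-cell data. Passing the
recovery tests therefore shows that the pipeline correctly recovers the
structure it assumes, at realistic separation and noise — not that real
data will separate this cleanly.

The trace simulator builds the two-block protocol (9-s stimuli, 81-s gaps,
first onset at frame 12) with unit-peak transients (rise τ = 2 frames ×
decay τ = 6 frames, truncated to return exactly to baseline within 24
frames, i.e. inside the 40-s scoring window), amplitudes ΔF/F 0.5 for ATP
and 5HT responders and 1.0 for KCl, baseline F = 100, and i.i.d. Gaussian
frame noise (default s.d. 2 % of baseline). The KCl+GABA amplitude is the
KCl amplitude scaled by (1 − inhibition/100) — the exact inverse of the
inhibition statistic — so noiseless recordings score back their planted
parameters to machine precision. Default planted inhibition levels are
(70, 40, 20, 50) % for the four archetypes: graded, and deliberately not
aligned with the transmitter-response archetypes, since inhibition does not
track cell type in the real recordings. Inhibition recovery is assessed at
the level of the planted archetype means; single-cell estimates carry
≈ 1.5 percentage points of s.d. from peak-picking noise alone at the
default noise level.

## Determinism and problem sizes

Every stochastic component is driven by an explicit integer seed through
`numpy.random.default_rng`; pipelines, reports and fixture bundles are
bit-reproducible (bundle manifests carry sha256 checksums per file and a
hash of the generating configuration). Unit tests run on a scaled-down
simulation (2,500 genes, same 96-cell design) for speed; the acceptance
checks run the full 17,000-gene default and 120-cell recordings, which fit
comfortably in a couple of minutes on one CPU.

## Known limitations

- UPGMA is O(n³) in pure Python/NumPy — fine for hundreds of cells, not for
  tens of thousands.
- The GEO deposit's processed-file layout is not described in the
  publication; the reader supports generic TSV/CSV/MatrixMarket layouts
  rather than guessing the deposit's schema, so replication on real data
  requires a one-off conversion.
- The panel classifier cannot separate T1 from T3; this reflects the panel,
  not an implementation limit.
- Whether the published fold-ratio criterion was computed on raw-FPKM means
  or after a transform is unstated; raw-FPKM means are used and flagged in
  the configuration.
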