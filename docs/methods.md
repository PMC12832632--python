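# Methods

This note documents the models and procedures implemented in `regenhubnet`,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was genuinely open.

## Pipeline overview

The package analyses a regeneration time course: one tissue section per
condition (uninjured controls, then a days-post-injury series), each section
a cell × gene normalized expression matrix with per-cell annotations and
spatial coordinates. All network analysis is performed independently per
(cell-type, condition) context. The stages are: detection filtering →
metacell aggregation → soft-power selection → adjacency/TOM → module
detection → eigengenes/kME/hubs → cross-context set algebra and hub
frequencies → marker time course and spatial co-localization.

## Metacells

Correlation estimates on sparse single-cell profiles are dominated by
sampling noise; aggregating each cell with its `k − 1` nearest neighbours
within its annotation group averages that noise before network construction.

- `k` (default 25): cells per metacell. Groups with fewer than `k` cells
  yield no metacells and are flagged, mirroring the silent exclusion of
  small cell-types in published workflows.
- `max_shared` (default 30, clamped below `k`): maximum member overlap
  between any two accepted metacells. The acceptance rule is a greedy,
  seed-ordered pass over candidate neighbourhoods with a per-pair overlap
  cap. Published descriptions do not fix the semantics of the overlap
  parameter (per-pair versus reuse count); the per-pair cap is this
  package's documented reading. Note that with `k = 25` and
  `max_shared = 30` the cap is vacuous (overlap cannot exceed 24), which
  matches the behaviour of the parameter combination as commonly used.
- `n_components` (default 20): PCA dimensionality of the neighbour-search
  embedding, truncated when the group is small.
- Aggregation is by sum; normalization (per-metacell scaling to the median
  total, then log1p) makes the sum/mean choice immaterial downstream.
- The detection filter ("expressed in ≥ 5% of cells") is evaluated on
  **cells**, before aggregation: a gene expressed in 2% of cells is nonzero
  in up to 25× as many metacells, so filtering after aggregation would
  defeat the filter's purpose.

## Soft threshold and scale-free fit

Signed networks are the default (`a_ij = ((1 + cor)/2)^β`, Pearson
correlation over metacells); unsigned (`|cor|^β`) is available by flag.
The fit index bins the connectivities `k_i = Σ_{j≠i} a_ij` into `n_bins`
(default 10) equal-width bins and regresses `log10`(bin frequency) on
`log10`(mean bin connectivity) over non-empty bins; the index is
`−sign(slope)·r²`, so increasing degree laws score negatively rather than
being rewarded. The selected power is the lowest candidate (default 1…30)
with index ≥ 0.80; a context with no qualifying candidate is excluded from
all downstream stages but recorded in every report. Exclusion is an
expected outcome on real data and on the synthetic default world (roughly a
third of contexts, varying by seed).

`r2_threshold` is deliberately unconstrained: values above 1 are
unattainable by construction and force exclusion everywhere (useful for
testing the exclusion path); values ≤ 0 accept the first candidate.

## Module detection

Modules are detected on the dissimilarity `1 − TOM` with average-linkage
hierarchical clustering. Published tree-cutting (dynamic hybrid) is not
re-derived line-for-line; the package uses a deterministic variant validated
by planted-module recovery:

1. **Adaptive static cut.** Candidate cut heights are fractions 0.90…0.995
   (step 0.005) of the maximum merge height. For each, branches below the
   cut are recursively split wherever a merge height exceeds both children's
   internal heights by a gap threshold (`0.25 − 0.05·deep_split`, default
   `deep_split = 2`). The cut retained is the one covering the most genes
   with valid cores, preferring fewer clusters; a "core" spanning more than
   half the genes is only valid if it is tight (top merge in the lower half
   of the height range) — otherwise it is the undifferentiated near-root
   blur, not a module.
2. **kME completion.** When expression is available, cluster cores (minimum
   size `min_module_size / 3`, at least 6) are completed by eigengene
   proximity, the analogue of dynamic tree cut's PAM stage: grey genes with
   correlation ≥ `kme_assign` (default 0.70) to a core eigengene join the
   best-correlated core; core genes whose own-module kME falls below
   `kme_stay` (default 0.30) are released.
3. **Merging.** Modules whose eigengenes correlate at ≥ `1 − merge_cut`
   (default merge_cut 0.25) are merged iteratively.
4. **Size filter and labels.** Modules smaller than `min_module_size`
   (default 30) become grey. Surviving modules are labelled `M1, M2, …` by
   descending size, ties broken by the lexicographically smallest member
   gene, so outputs are bit-stable across runs.

An all-grey outcome is valid. The size filter runs after completion and
merging: enforcing it on raw cores would discard genuine modules that the
cut fragments, and the completion stage is precisely what reassembles them.

## Eigengenes, kME, hubs

The module eigengene is the first right singular direction's sample scores
of the standardized member-gene matrix, sign-oriented so its mean
correlation with the members is non-negative, then scaled to unit variance;
`variance_explained` is the leading singular value's share of total
variance. kME is the Pearson correlation of a gene with a module eigengene,
computed against **all** modules (cross-module diagnostics), while hub
ranking uses own-module kME only. Ranking is by signed kME by default
(appropriate for signed networks, where anti-correlated genes are not
module members); `use_absolute=True` ranks by |kME|. Ties break
lexicographically by gene id. Constant genes have undefined kME and are
recorded as missing, never silently zero.

Hub frequency counts distinct (context, module) pairs in which a gene is a
hub, carrying the best (minimum) rank; output is sorted by occurrences then
gene id.

## Set algebra

"Present at a timepoint" pools over cell-types: a gene counts as present if
it belongs to any non-grey module in any cell-type at that timepoint; the
per-cell-type stratification is kept in the membership atlas for drill-down.
Regeneration-specific genes are present at ≥ 1 post-injury timepoint and at
none of the controls; the shared set is the intersection over all
post-injury timepoints. Identifier handling: `AMEX60DD`-prefixed ids are
split (case-sensitively) from ortholog-annotated symbols; raw exported
names are standardized by taking the first non-empty pipe-delimited field,
stripping a trailing all-caps alphabetic `_TAXON` suffix (conservative, so
symbols containing underscores are not mangled), and upper-casing. Which
pipe field holds the symbol is not standardized upstream; "first non-empty"
is this package's documented choice.

PPI edge tables (STRING-style exports) are filtered at a combined score
≥ 0.40 (inclusive), deduplicated as undirected pairs keeping the maximum
score; the 0–999 score dialect is detected (any score > 1) and divided by
1000. Degree classes follow the convention: high connectivity > 10
interactions, low connectivity 1–3.

## Spatial co-localization

Marker positivity is expression > 0 on the normalized scale (configurable);
the positive-cell fraction uses **all** cells of a section as denominator,
not an annotation subset. Two quantitative readings of co-localization are
provided, since the underlying question ("the marker lies in or near the
population's territory") is inherently qualitative:

- **Cell coordinates:** a positive cell co-localizes iff an annotated cell
  lies within a Euclidean radius (KD-tree query; an O(n²) oracle backs the
  tests).
- **Pixels:** RGB thresholding of a rendered marker map (conjunction of
  per-channel ≥/≤ bounds; alpha ignored unless named), binary dilation with
  a Euclidean disk (Chebyshev square available) for visibility, and a
  composite that renders tissue in ITU-R 601 grayscale, the marker on a red
  gradient (80→255 scaled by original intensity), the population in pure
  yellow, overlap drawn red-over-yellow, and transparent background outside
  tissue and masks. All rendering constants are fixed so PNGs are
  bit-identical across runs.

## Synthetic data

The generator defines the study conditions every test runs under. Defaults:
8 timepoints (juvenile control + 2/5/10/15/20/30/60 DPI), 4 cell-types of
150 cells laid out as Gaussian blobs, 300 genes, 2 shared + 2
regeneration-only planted modules of 30 genes, target within-module
correlation 0.7, marker course (0.06, 0.37, 0.33, 0.25, 0.24, 0.28, 0.07,
0.06) — the injury-induced rise-and-decay profile of a recurrently observed
neuropeptide marker. 10% of genes carry `AMEX60DD_…` identifiers and 10% of
symbol-named genes are also emitted in raw pipe-delimited, taxon-suffixed
form.

The expression model has four layers, chosen so that the data exhibit the
correlation texture the network machinery is built for:

1. **Planted modules.** Each module spans a 2-D latent factor subspace;
   member gene g sits at angle `t_g ~ U[0, 1.3]` with loading
   `l_g ~ U[0.5, 1.2]`: `x_g = l_g (cos t_g · F1 + sin t_g · F2) + s·ε`.
   The noise scale `s` is calibrated numerically per module so the mean
   pairwise pre-clipping correlation equals the configured
   `within_module_rho` exactly. The angular spread gives modules internal
   sub-structure — graded correlations, hub-like and peripheral members —
   rather than a rank-one block; single-factor equal-loading blocks produce
   degenerate (bumped) degree distributions that no soft power can render
   scale-free.
2. **Background programs.** Half of the background genes (configurable) sit
   in small weak programs (geometric sizes 3–24, strengths `0.1 +
   0.5·Beta(1,2)`, always below the module-detection size), the continuum
   of weak co-regulation real transcriptomes show.
3. **Cell-state factors.** Every gene loads on 8 global state factors with
   heavy-tailed per-gene scales (sd 0.3 × clipped exponential; module
   members damped 2×, as program-dominated genes track global state less).
   This is the per-gene biological variance that survives metacell
   averaging; without it, aggregation polarises the correlation spectrum
   and every context fails the scale-free criterion.
4. **Condition specificity.** Regeneration-only module factors are active
   only in DPI-labelled sections. In control sections those genes are
   additionally sparse (≈2% detection), so the 5% detection filter removes
   them from control networks — the same mechanism by which
   injury-induced programs are absent from control co-expression modules in
   the real workflow.

Marker positivity is imposed post hoc (exactly `round(fraction × n_cells)`
designated cells receive a positive draw; all others are exactly zero), so
the configured course is realized exactly, not stochastically. All outputs
are deterministic given the seed.

What the generator does **not** emulate: raw read processing, UMI counting,
variance-stabilising transformation residuals, batch effects, realistic
tissue geometry, or dropout-driven zero inflation of the background. Tests
passing on this data therefore validate the algorithmic chain (filtering,
aggregation, thresholding, clustering, ranking, set algebra, geometry), not
robustness to those real-data artefacts.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to exercise
every code path with comfortable statistical margins: recovery fixtures use
200 cells × 500 genes with four planted modules (the 500-gene panel keeps
the degree distribution smooth enough that the soft-power search succeeds
across seeds); the end-to-end pipeline uses the default 8-section,
4-cell-type, 300-gene world (32 network contexts per run). On this scale a
full pipeline run takes a few seconds and the complete test suite well under
a minute.

## Known limitations

- The branch-cutting variant is validated by planted-structure recovery,
  not by label-for-label parity with the reference dynamic tree cut; on
  real data the two will differ in detail.
- Whether hub ranking should use signed or absolute kME is not settled
  upstream; signed is the default here.
- The per-pair `max_shared` reading makes the default 25/30 parameter pair
  vacuous (see above); metacell redundancy is therefore high, as in the
  reference workflow.
- The expression-slot ambiguity in upstream descriptions (counts versus
  variance-stabilised residuals) is not arbitrated: the pipeline accepts
  any normalized matrix as input.
- Exclusion of contexts that fail the scale-free criterion is faithful to
  the workflow but means per-seed variation in which contexts contribute to
  the derived gene sets; the regeneration-specific set is recovered with
  high recall but its total size varies with the seed.
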