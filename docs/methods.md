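# Methods

## Scope and model

`sencaf` classifies senescent cancer-associated fibroblasts in gene × cell
expression matrices and summarizes their distribution across samples and
CAF subtypes.  The chain is: depth normalization → expression-bin-matched
module scoring → a composite senescence index with a hard threshold →
single-positive subtype assignment → per-sample / per-subtype summaries.
A negative-binomial simulator with planted ground truth and two spatial
statistics (nearest-tumor distances, regional correlation) complete the
package.

## Normalization

Raw counts v in a cell with total T become `log1p(v * target_total / T)`
with `target_total = 1e4` and natural log — the de facto scRNA-seq
convention.  Cells with zero total count are dropped with a warning.
Normalization is invariant to per-cell depth scaling by construction.
Batch integration, QC filtering and doublet removal are upstream concerns
and out of scope.

## Module scoring

The score of gene set G in cell j is
`SC_j = mean[E_j(G)] − mean[E_j(C)]` on log-normalized expression E.
Controls C are matched by abundance: genes are ranked by across-cell mean
expression (ties broken lexicographically by symbol, making the ranking
deterministic) and cut into `nbin` equal-frequency bins whose sizes differ
by at most one; for each signature gene, `per_gene` controls are drawn
uniformly from its bin.

Parameter choices, all config-exposed:

- `nbin = 25`.  A bin count around 24–25 is the common practice for this
  kind of scoring; results are insensitive to ±5 bins at 2000 genes.
- `per_gene = 100` controls per signature gene.
- `exclude_self = True`: a signature gene never serves as its own control,
  which would deflate scores in small bins.  Draws are without replacement
  when the eligible bin population allows, with replacement otherwise.
- Scores are computed on log-normalized, not per-gene z-scaled, values:
  z-scaling would equalize the gene means that the bin matching is built
  on.  `expression="zscore"` provides the alternative for sensitivity
  analysis (bins are still formed on log-normalized means).
- Sub-seeds per signature are derived as
  `blake2s(seed, signature_name) mod 2^31`, so adding or removing one
  signature never perturbs another signature's control draws, and draws
  replay across processes (`hash()` is salted per interpreter and is not
  used).

Identities used as tests: SC is invariant to adding a constant to a cell's
expression vector; SC = 0 when the controls equal the signature; raising
one signature gene's expression by δ raises that cell's score by exactly
δ/|G|; random gene sets score ≈ 0 on average.

## Senescence index

`senescence_score = minmax01(SC_senescence) − minmax01(SC_cellcycle)`,
thresholded strictly at 0 (a score of exactly 0 is non-senescent).  The
score lives in [−1, 1]; ±1 are attained only at the extreme score
combinations.  Min-max scaling is computed over the pooled cell population
— the cohort the classification is meant to describe — with
`per_sample_scaling` offering within-sample scaling as an alternative.
Because minmax01 is invariant to positive affine transforms per column,
the classification is unaffected by per-column rescaling of the raw
scores.  A constant score column has no scale and maps to zeros with a
warning.

The senescence signature is the five markers CDKN2A, CDKN2B, CDKN1A,
CDKN1B and SERPINE1, scored with bin-matched controls like every other
signature; `index_mode="plain_mean"` substitutes the unadjusted 5-gene
mean for sensitivity analysis.  The default cell-cycle signature is a
frozen 53-gene list packaged with the code
(`src/sencaf/data/cell_cycle_signature.txt`).  It is a reconstruction of
the intersection of the widely used KEGG, REACTOME and WikiPathways
cell-cycle sets, frozen so that results do not drift with gene-set
databases and no network access is needed; it deliberately excludes the
four CDK-inhibitor senescence markers so the two signatures are disjoint.
`default_cell_cycle_signature(sources=...)` recomputes the intersection
from any three user-supplied lists; analyses of real data should report
the list actually used.

## Subtype assignment and summaries

A cell is assigned to iCAF / myCAF / apCAF iff exactly one subtype module
score is strictly positive (0 is not positive); otherwise it is
unassigned.  Summaries keep two denominators deliberately distinct:
per-sample senescent percentages count all cells of the sample, assigned
or not, while per-subtype percentages count only cells assigned to that
subtype, pooled across samples.  At cohort level the unweighted mean of
per-sample percentages and the pooled fraction over all cells are both
reported and never conflated.  Shipped subtype signatures are an editable
stub of commonly cited markers; tests and the simulator use planted marker
panels instead.

## The simulator

Counts are negative binomial via a gamma–Poisson mixture:
`counts[g,c] ~ NB(mean = baseline_g · libsize_c · fold(g,c), theta_g)`,
so empirical variance tracks `m + m²/θ`.  Defaults describe a
multi-patient fibroblast census: 21 samples of 100–250 cells, 2000 genes,
gene baselines LogNormal(−1.5, 1.2) (median ≈ 0.2 counts/cell, i.e. a
shallow droplet-style library of ~1000 counts/cell), dispersions
LogNormal(0, 0.5), library-size factors LogNormal(0, 0.35).  Planted
structure: subtype proportions (0.40, 0.40, 0.20) over iCAF/myCAF/apCAF
with 30 disjoint marker genes each at fold 4; per-sample senescent
probabilities Uniform(0.03, 0.32); in senescent cells the five senescence
genes go up 6-fold and the cell-cycle genes down 4-fold.  Signature and
marker genes draw their baselines from a moderately expressed stratum
(LogNormal(0, 0.5)) — marker panels in practice are not drawn from barely
detected genes, and a planted program carried by genes at 0.05 counts/cell
would be invisible at this depth by construction, not by method failure.
Effects are multiplicative on NB means (log-fold-changes), the scale on
which expression changes are usually discussed.

What the simulator does **not** emulate: batch effects and integration
artifacts, ambient RNA, doublets, overlapping or correlated subtype
programs, and the cluster geometry of real data.  Passing recovery tests
therefore shows the scoring/classification chain is correct and
well-calibrated under clean NB noise at realistic depth — not that the
senescence calls on any real dataset are biologically right; on real data
the signature lists and the upstream filtering dominate.

The point simulator places tumor cells uniformly in the unit square; each
CAF starts uniform and moves a fraction `attraction ∈ [0, 1]` of the way
toward its nearest tumor cell, with per-class overrides so an effect can
be planted in the p16+ class only.

## Spatial statistics

Nearest-neighbour distances use a KD-tree and are checked against a
double-loop oracle.  Group comparison uses Welch's unequal-variance t test
(the safe default for the very unequal group sizes of marker+/− CAF
comparisons; `equal_var=True` restores the pooled test); the degenerate
case of two equal constant groups returns t = 0, p = 1 with a warning.
Regional correlation is Spearman (average ranks for ties) or Pearson with
two-sided p-values; below n = 10 regions the Spearman p is computed by
exact permutation enumeration, above by the asymptotic approximation.  At
n = 57 regions the asymptotic p's empirical type-I error at α = 0.05
measures ≈ 5.2%.  Coordinates are treated as continuous planar positions;
any pixel/micron conversion is a single upstream scale factor.

## Pipeline and determinism

One global seed drives every stage through named 31-bit sub-seeds, so
identical config + seed reproduces all outputs byte-for-byte and stages
can be re-run in isolation.  Each run writes a manifest (package version,
config hash, seed, signature checksums) sufficient to replay the run
bit-identically.  Config files are strictly validated: unknown keys and
type mismatches are rejected by name before any computation.  Logs go to
stderr with stage tags; data only to files.

## Problem sizes and tolerances in the test suite

Recovery tests run the full pipeline over 20 fixed seeds at the default
simulator conditions (~3500 cells × 2000 genes per seed, ~30 s total) and
require: mean absolute error of per-sample senescent-fraction recovery
≤ 4 percentage points, cohort-mean recovery within ±4 points, and ≥ 90%
subtype accuracy among assigned cells (measured: MAE ≈ 1.6 points, bias
≈ +2, accuracy > 99%).  The pooled min-max threshold carries a small
positive bias — min-max normalization is outlier-sensitive, and the
senescent mode sits in the upper tail — which grows at smaller cohort
sizes; unit tests at ~800-cell scale therefore check the 20-seed mean, not
single seeds.  A null simulation (all planted folds 1, ~500 cells per
seed) must show no senescent/non-senescent score separation (median
rank-test p > 0.01).  Numerical oracle checks are at 1e-12 (scoring) and
1e-9 (distances).

## Known limitations

- The senescence index threshold (> 0 after pooled 0–1 scaling) adapts to
  the cohort: it is a relative, not an absolute, senescence call, and a
  cohort with no senescent cells will still rank cells.
- Whether per-subject percentages on real data should use all cells or
  only subtype-assigned cells as denominator is a reporting convention;
  both numbers are computed.
- The frozen cell-cycle list is a reconstruction (see above); swapping in
  a different list shifts raw cell-cycle scores but the pipeline is
  unchanged.
- The simulator's subtype programs are disjoint and independent; real
  iCAF/myCAF programs are partially anticorrelated, so real-data
  assignment rates will differ from the synthetic ones.
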