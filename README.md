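# sencaf

Senescence scoring and subtype analysis of cancer-associated fibroblasts
(CAFs) in single-cell RNA-seq data.

Tumors carry senescent CAFs — stromal fibroblasts locked in stable
proliferation arrest that express CDK inhibitors (p16/CDKN2A, p21/CDKN1A)
and a secretory program while shutting down cell-cycle transcription.
Identifying them in scRNA-seq requires more than averaging a marker list:
per-cell signature means are confounded by cell complexity and library
depth.  `sencaf` implements the control-adjusted scoring and classification
chain used for this purpose, end to end, for analysts working with
gene × cell count matrices of tumor fibroblasts.

## The method

**Module score.** For a gene set G in cell j, with log-normalized
expression E:

```
SC_j = mean[E_j(G)] − mean[E_j(C)]
```

where the control set C is drawn to match G's abundance profile: genes are
ranked by across-cell mean expression and cut into equal-frequency bins
(default 25), and for each gene of G, 100 control genes are sampled
uniformly from the same bin.  Subtracting the control mean cancels the
per-cell complexity component, so SC is comparable across cells.

**Senescence index.** Two module scores — the 5-gene senescence signature
(CDKN2A, CDKN2B, CDKN1A, CDKN1B, SERPINE1) and a 53-gene cell-cycle
signature (intersection of the KEGG, REACTOME and WikiPathways cell-cycle
sets, shipped frozen) — are each min-max scaled to [0, 1] over the pooled
cell population and subtracted:

```
Senescence Score = sen_norm(0-1) − cc_norm(0-1)
```

Cells with Senescence Score > 0 are called senescent (exactly 0 is not).

**Subtype assignment.** Cells are scored against iCAF / myCAF / apCAF
signatures and assigned to a subtype iff exactly one subtype score is
strictly positive; otherwise they stay unassigned.  Summaries report the
senescent percentage per sample (over all cells of the sample) and per
subtype (over assigned cells only), keeping the unweighted per-sample mean
distinct from the pooled fraction.

The package also bundles a negative-binomial count simulator with planted
senescent cells and subtype programs (so the whole chain is testable
without any download) and spatial statistics for detected-cell point
tables: nearest-tumor-cell distances with a Welch t comparison, and
Spearman/Pearson correlation of regional quantities.

## Worked example

```python
import sencaf
from sencaf.senescence import senescence_scores
from sencaf.subtypes import assign_subtype, summarize_senescence

cfg = sencaf.SimConfig(seed=7)   # 21 samples, 100-250 cells each, 2000 genes
matrix, truth = sencaf.simulate_counts(cfg)
ln = sencaf.lognormalize(matrix)
sigs = [sencaf.default_senescence_signature(),
        sencaf.default_cell_cycle_signature()] + truth.marker_signatures()
scores = sencaf.score_signatures(ln, sigs, seed=sencaf.subseed(7, "score"))
res = senescence_scores(scores)
labels = assign_subtype(scores)
ann = sencaf.make_annotation(ln.barcodes, ln.sample_labels(),
                             res.senescent, labels)
s = summarize_senescence(ann)
print(f"mean per-sample senescent %: {s.overall_mean_pct:.1f} "
      f"(range {s.overall_range[0]:.1f}-{s.overall_range[1]:.1f})")
```

Output:

```
cells: 3527  senescent: 652
mean per-sample senescent %: 18.6 (range 7.5-34.6)
  iCAF   n=1230  senescent=20.2%
  myCAF  n=1155  senescent=17.1%
  apCAF  n= 713  senescent=15.3%
planted per-sample mean: 16.8
subtype accuracy among assigned cells: 100.0%
```

The classifier recovers the planted per-sample senescent fractions (18.6%
called vs 16.8% planted here; the small positive bias is characteristic of
the pooled min-max threshold) and assigns essentially every cell to its
planted subtype.

The same analysis runs from the shell:

```
sencaf simulate --out sim/ --seed 7
sencaf score --matrix-dir sim/ \
    --subtype-signatures sim/subtype_signatures.yaml --out out/ --seed 7
```

writing `scores.tsv`, `annotation.tsv`, `summary.tsv`, `summary.md` and a
`manifest.json` that replays the run bit-identically.

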