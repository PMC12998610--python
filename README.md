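# linksig

Differential cell-cell signaling analysis for multi-subject single-cell
RNA-seq.

Ligand-receptor network inference estimates which cell types communicate in
a tissue, but most inference tools score one sample at a time and offer no
statistical basis for saying that signaling *differs* between conditions.
`linksig` addresses this for studies with biological replicates (or pooled
designs, via bootstrap pseudo-replicates): it infers binary signaling
linkages per subject, collates them across subjects, and tests each
linkage's presence for dependence on an experimental grouping variable.

## The model

Per subject, inference proceeds in the Domino style, combining ligand and
receptor expression with downstream transcription-factor (TF) activity:

1. **TF enrichment.** A TF is active in cell type *k* when its per-cell
   activity scores (AUCell-style, in [0, 1]) are higher in *k* than in all
   other cells by a one-sided Wilcoxon rank-sum test, p < `min_tf_pval`
   (default 0.001).
2. **Intracellular linkage** (cell type, TF, receptor): the TF is enriched
   in the type, the Spearman correlation of every receptor-complex
   component gene with the TF's activity is ≥ `rec_tf_cor_threshold`
   (default 0.15), and every component is expressed by ≥
   `min_rec_percentage` (default 0.05) of the type's cells. This
   constitutes active receipt of signaling via the receptor.
3. **Ligand sender** (cell type, ligand): every ligand-complex component
   has mean *scaled* (z-scored) expression strictly > 0 in the type.
4. **Intercellular linkage** (recipient, receptor, ligand, sender): an
   active receptor in the recipient paired with the ligand of a sender by
   the ligand-receptor database. Heteromeric complexes pass a gate only if
   every component passes.

The **Differential Cell Signaling Test (DCST)** then tabulates, for one
linkage, the number of subjects in each group that contain or lack it, and
applies Fisher's exact test (two groups: conditional-MLE odds ratio and the
two-sided probability-mass p-value; three or more groups: the
Freeman-Halton generalization). p-values are Benjamini-Hochberg adjusted
within the family of all unique linkages of that class incoming to the
recipient cell type. Any external inference method whose per-subject
interaction scores can be binarized (probability > 0.1 by default) can feed
the same test.

## Worked example

`examples/differential_test.py` simulates 8 samples per condition of a
two-cell-type network (types A and B; pairs L1-R1 and L2-R2, with paracrine
A→B signaling favored in condition C1 and autocrine B→B signaling in C2),
infers linkages per sample, and runs the DCST for recipient cell type B:

```
       linkage  C1_with  C2_with  odds_ratio  p_value    p_adj
(B, R1, L1, A)        7        0         inf 0.001399 0.004196
(B, R1, L1, B)        0        5         0.0 0.025641 0.038462
(B, R2, L2, A)        8        7         inf 1.000000 1.000000
```

The paracrine linkage is present in 7 of 8 C1 subjects and no C2 subject
(odds ratio ∞, BH-adjusted p = 0.004); the autocrine linkage shows the
mirror-image pattern; the condition-independent L2-R2 linkage is present
in nearly every subject of both arms and not significant. Other examples cover per-subject inference
(`infer_linkages.py`), bootstrap pseudo-replicates for pooled designs
(`bootstrap_pooled.py`), accessibility-aware targeted regulon scoring
(`targeted_regulons.py`), binarizing external interaction scores
(`adapt_external_scores.py`), and the benchmark sweep
(`benchmark_small.py`).

A `linksig` command-line tool exposes the same pipeline as subcommands
(`infer`, `summarize`, `dcst`, `bootstrap`, `benchmark`, `adapt`); run
`linksig --help`.

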