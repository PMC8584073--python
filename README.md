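# compartmarks

Which genomic marks tell you whether a piece of chromatin sits in
compartment A or compartment B?  `compartmarks` is a pipeline for answering
that question by classification: it maps epigenomic signals (ChIP-seq /
DNase-seq peaks, coverage tracks, genome segmentations) onto chromatin
loops or fixed 100 kb genomic windows, labels every region A or B from a
Hi-C subcompartment annotation, ranks each mark's feature representations
by importance, and benchmarks how predictable compartment identity is from
the full feature set.

It is aimed at regulatory-genomics analysts who have loop calls (BEDPE),
peak/coverage tracks (narrowPeak, BED5, bedGraph, optionally bigWig),
segmentation BEDs, and a subcompartment annotation, and want a reproducible
importance ranking plus a multi-classifier benchmark — and at method
developers, via a synthetic-epigenome generator with planted effect sizes
that makes every stage testable without external data.

## Method

1. **Labeling.** Subcompartments map onto compartments as A1, A2 → A and
   B1–B4 → B.  A loop (anchor-to-anchor span) or window is labeled A (B)
   when every annotation window it overlaps by ≥ 1 bp is in A (B); regions
   touching both compartments, or only unannotated territory, are excluded.
2. **Features.** Each mark yields up to four representations per region:
   *fraction* (share of the region covered by the merged peak union),
   *peak sum* / *peak mean* (signal of peaks overlapping the region),
   *whole signal mean* (length-weighted mean of the coverage step function,
   uncovered bases = 0), and per-state *state fractions* for segmentations
   collapsed to active / repressed / heterochromatin (unsegmented bases
   count as active).
3. **Ranking.** Every feature *g* gets an ANOVA F-statistic
   F(g) = MS_between / MS_within against the A/B label, and a Monte Carlo
   Feature Selection relative importance: over *s* random subsets of *m*
   features, *t* decision trees are grown on random stratified train
   splits, and each split node using *g* contributes
   wAcc^u · IG(node) · (n_node / n_train)^v to RI(g), where wAcc is the
   tree's mean per-class recall on its held-out third, IG the node's
   information gain, and n_node the training samples reaching the node.
   Features are ranked by the product of the min-max-normalized RI and F;
   each feature's standalone power is the mean 10-fold AUC of a 150-tree
   random forest trained on it alone.
4. **Benchmark.** Seven classifiers — GNB, KNN (k=5), LDA, AdaBoost,
   RBF-SVM, MLP (one hidden layer of 100 ReLU units), and a 150-tree
   random forest — share one stratified 10-fold assignment and report
   support-weighted Recall / Precision / F-score, Accuracy, mean and SD of
   per-fold AUCs, and the RMSE of the predicted class-A probability
   against the 0/1 label.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
epigenome (20 Mb genome, 5 informative marks with effect size δ=2 among 45
noise marks):

```
python analysis/01_simulate.py
python analysis/02_features.py
python analysis/03_rank_features.py
python analysis/04_classify.py
python analysis/05_effect_size_sweep.py
```

`02_features.py` reports the labeling outcome — on this genome every
window is single-compartment while boundary-straddling loops are dropped:

```
windows: kept 200/200 regions (100.0%), A share 52.0%; matrix 200 x 146
loops:   kept 188/300 regions (62.7%), A share 53.7%; matrix 188 x 146
```

`03_rank_features.py` shows the product ranking recovering all five
planted marks at the top (excerpt):

```
feature                      mark       representation    product  rank  rfo_auc_mean
inf_cov_2:whole_signal_mean  inf_cov_2  whole_signal_mean 0.968904     1        1.0000
inf_cov_3:whole_signal_mean  inf_cov_3  whole_signal_mean 0.735437     2        0.9944
inf_peak_1:peak_sum          inf_peak_1 peak_sum          0.051807     3        0.8806
...
informative marks in top decile (top 15): 5/5
```

`product` is minmax(RI) × minmax(F) — the consensus importance of the two
measures; `rfo_auc_mean` is that single feature's cross-validated random
forest AUC.  `04_classify.py` prints the benchmark table (windows mode):

```
           R       P  F-Score     ACC     AUC      SD    RMSE
GNB   1.0000  1.0000   1.0000  1.0000  1.0000  0.0000  0.0000
...
RFO   1.0000  1.0000   1.0000  1.0000  1.0000  0.0000  0.1491
Mean  0.9671  0.9673   0.9671  0.9671  0.9878  0.0160  0.1556
```

At δ=2 the planted marks make compartments almost perfectly separable;
`05_effect_size_sweep.py` traces the battery mean AUC from chance at δ=0
(0.5027) through 0.8862 at δ=0.5 to 0.9985 at δ=2.

The same stages are available as a CLI over on-disk files
(`compartmarks simulate | features | rank | classify`, see `--help`), with
YAML configs pointing at your own annotation, loop and track files.

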