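# Methods

This note documents the models, conventions and numerical choices behind
`compartmarks`, and what the synthetic-data experiments do and do not show.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) in every container
and file.  Peaks come from BED5 (signal = column 5, score) or ENCODE
narrowPeak (signal = column 7, signalValue — the score column is capped
for display and ignored).  Coverage is a per-chromosome step function;
bedGraph steps must be non-overlapping (an overlapping step function is
ambiguous and is rejected), bigWig is supported through pyBigWig behind
the same container.  Positions outside every step carry an implicit value
of 0, so means over regions are always defined.  BEDPE loop rows may list
their anchors in either order; inter-chromosomal rows are dropped with a
logged count, since the loops analysed here are intra-chromosomal
domains.  Parsers are strict: malformed lines raise errors naming the line
number rather than being skipped.

## Compartment labeling

Subcompartments collapse many-to-one: A1, A2 → A; B1, B2, B3, B4 → B.
A region is labeled by the set of compartments of all annotation windows
it overlaps by at least 1 bp: {A} → A, {B} → B, and both or none →
excluded.  Choices behind this:

* **Overlap threshold 1 bp.**  The simplest reading of "partially covered
  by both compartments"; no minimum-coverage fraction is imposed.  A
  coverage-fraction threshold would keep more boundary loops at the cost
  of an arbitrary cut-off.
* **Unannotated territory excludes.**  A region with no annotated overlap
  has no evidence for either class; it never enters the feature matrix.
* **Loop interval = anchor-to-anchor span.**  Features such as "fraction
  of the loop covered" integrate over the loop interior, not just the
  anchors.
* **Whole windows only.**  Genome tiling drops trailing partial windows,
  so every window region has identical length.

Classification is refused (with an explicit error) when labeling leaves
zero regions or a single class — downstream statistics are undefined then.

## Feature representations

Per mark and region: `fraction` is the merged-union peak coverage divided
by region length (overlapping peaks counted once); `peak_sum` and
`peak_mean` aggregate the full signal of every peak overlapping the region
by ≥ 1 bp.  Signals are deliberately **not** pro-rated by overlap length
by default — a peak is a called event, and its signal value is a property
of the event, not of the overlapped bases; a pro-rated variant is
available (`prorate=True`) for sensitivity analyses.  Regions with no
overlapping peaks get 0.0 for both sum and mean so matrices stay finite.
`whole_signal_mean` is the length-weighted mean of the coverage step
function with uncovered bases contributing 0.  `state_fraction:<class>`
collapses segmentation states onto active / repressed / heterochromatin
via a configurable mapping; bases assigned to neither repressed nor
heterochromatin — including unsegmented bases — count as active, and the
three fractions always sum to 1.  Fraction- and state-type computations
are exact interval arithmetic, verified against per-base brute-force
oracles to 1e-12 in the test suite.

Feature identifiers are `mark:representation`, and the matrix column order
follows the feature plan, so matrices are bit-reproducible.

## Feature ranking

**ANOVA F.**  One-way F with k=2 groups.  Zero within-class variance with
distinct class means yields an infinity sentinel ordered above all finite
scores (and mapped to the top of the [0,1] scale before normalization);
zero between- and within-class variance yields 0.

**MCFS relative importance.**  Defaults: s=300 feature subsets
(projections), subset size m=⌈√d⌉, t=5 trees per subset, exponents
u=v=1, tree depth cap 8, stratified 2/3–1/3 train/test split per tree.
These follow common practice in the MCFS reference-implementation family
and run at desk scale; all are configurable.  Trees are CART-style binary
trees split by information gain (entropy criterion), since information
gain is the quantity each node contributes to RI.  Tree induction is
delegated to scikit-learn's `DecisionTreeClassifier`; the RI aggregation
(wAcc^u · IG · node-fraction^v summed over nodes and trees) is computed
from the fitted tree structures.  A tree's weighted accuracy wAcc is the
unweighted mean of per-class recalls on its held-out split; trees with
wAcc ≤ 0.5 still contribute (no cut-off — a configurable floor exists and
defaults to 0).  RI is deterministic given the seed.  One consequence of
using library tree induction: candidate features are scanned in a seeded
random order inside each tree, so permuting matrix columns can flip
which of two near-equivalent splits a tree picks; RI is reproducible
bit-for-bit for a fixed matrix, and stable under column permutation for
clearly informative features, but noise-feature RI values may shift.

**Product ranking.**  Features are sorted by descending
minmax(RI) × minmax(F); min-max normalization maps constant vectors to
all-zeros.  Ties break by larger raw RI, then lexicographic feature
identifier, making output files deterministic.  Per-feature predictive
power is reported separately as the mean ± SD of per-fold AUCs of a
150-tree random forest trained on that single feature under stratified
10-fold cross-validation, with folds seeded independently of the
all-feature benchmark.

## Classifier benchmark

The battery: GNB (Gaussian likelihood), KNN (k=5), LDA, AdaBoost, RBF-SVM,
MLP (one hidden layer, 100 ReLU units, softmax output), RFO (150 trees);
all other hyperparameters are scikit-learn defaults.  The SVM's class
probabilities come from Platt-style sigmoid calibration
(`CalibratedClassifierCV(..., ensemble=False)`), since AUC and RMSE need
probabilities.  Features are standardized with train-fold mean/variance
for the distance- and margin-based models (GNB, KNN, LDA, SVM, MLP); tree
ensembles see raw values.  All classifiers share one stratified 10-fold
assignment so rows are comparable.

Metrics: Recall / Precision / F-score are support-weighted one-vs-rest
averages pooled across folds; accuracy is pooled.  Support-weighted recall
is algebraically identical to accuracy (Σₖ (nₖ/N)(TPₖ/nₖ) = ΣTPₖ/N), and
both columns are reported in the conventional table layout.  AUC is
computed per fold from the predicted class-A probability and summarized by
mean and sample standard deviation (ddof=1) across folds; a fold whose
test set contains one class has no defined AUC and raises an error
recommending a different seed or smaller k.  RMSE is
√(mean((P(A) − 1[label=A])²)) over all samples — defined on the
probability rather than the hard label, which is why a well-classifying
but poorly-calibrated model (AdaBoost, whose probabilities hover near 0.5)
can combine high accuracy with RMSE near 0.5.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not
their biology:

* **Compartments.**  Alternating A/B blocks with geometric lengths in
  100 kb window units — memoryless switching matches an "every ~400 kb on
  average" description.  The mean block of compartment c is
  2·f_c·(block scale), giving a long-run A fraction f_A (default 0.6)
  while the average block stays at the 400 kb default scale.  Each window
  draws a subcompartment uniformly within its block's compartment (A1/A2
  in A; B1/B2/B3 in B — B4 is a sub-0.5% singleton class in real
  annotations and is not simulated).
* **Loops.**  Log-normal spans parameterized by median 185 kb and
  log-scale σ=0.6, chosen so ~99% of the mass falls inside the
  [40 kb, 3 Mb] truncation bounds before resampling; 5 kb anchors;
  uniform placement; category counts configurable (defaults proportioned
  like published CTCF-convergent / CTCF-tandem / RNAPII loop sets).
* **Marks.**  The planted effect size δ acts multiplicatively on peak
  rate (rate ×(1+δ) in the enriched compartment), additively in units of
  the step SD on coverage means, and as an odds tilt on segmentation
  states (active ×(1+δ) in A; repressed and heterochromatin ×(1+δ/2) in
  B).  δ=0 marks are identically distributed in both compartments.
  Within-window draws are independent, so synthetic features carry no
  spatial autocorrelation beyond the label blocks themselves.

Everything is deterministic given the configuration seed, every emitted
file round-trips through the package's own parsers, and the manifest
records which marks carry signal so recovery experiments are
self-describing.

What passing synthetic tests shows: the pipeline's interval arithmetic,
labeling rule, ranking statistics and benchmark machinery behave correctly
and recover planted signal of known effect size, with chance-level
performance when no signal exists.  What it does not show: anything about
real enrichment patterns — real marks are spatially autocorrelated,
cross-correlated with each other, and enriched with effect sizes that vary
along the genome, none of which the generator models.  Benchmarks on real
data (hundreds of features over tens of thousands of loops) will sit well
below the near-perfect synthetic δ=2 numbers.

## Problem sizes and experiment design

The bundled experiments use a 20 Mb two-chromosome genome (~200 windows,
300 loops) with 5 informative marks among 45 noise marks (146 features),
and a 40 Mb genome for null-level measurements; these sizes give stable
recovery statistics while keeping a full study run in minutes on one CPU.
Null battery AUC on a single ~400-window dataset has a chance spread of
about ±0.04, so null levels are measured as means over a few seeded
datasets.  Effect-size sweeps reuse matched seeds across δ so curves are
comparable.

## Known limitations

* MCFS here scores single features only; the interdependency-graph part
  of the MCFS literature (co-occurrence of features along decision paths)
  is out of scope, as are p-value cut-offs for "important" features — the
  pipeline ranks, it does not test.
* Loop categories are taken from the input files; CTCF motif orientation
  is never recomputed.
* No signal normalization between assays is attempted; representations
  are computed on the tracks as given.
* The R/P/F-vs-fold question (pooled across folds vs averaged per fold)
  is resolved as pooled; only AUC is per-fold, which is the only metric
  whose fold spread is reported.
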