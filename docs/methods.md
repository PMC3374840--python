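# Methods

## Problem and model

`mksubloc` predicts the subcellular location(s) of human-style proteins from
Gene Ontology (GO) annotations, in the multi-label setting where a protein
may reside in several of K compartments at once.  Two sources of annotation
are kept deliberately separate:

* **target GO terms** — the protein's own GOA associations, split by aspect
  into three binary indicator vectors `t_F`, `t_C`, `t_P` over closed
  per-aspect vocabularies (molecular function, cellular component,
  biological process);
* **homolog GO terms** — the union (logical OR) of the associations of the
  protein's top-H BLAST homologs, ranked by ascending E-value, giving
  `h_F`, `h_C`, `h_P`.

Homology transfer is powerful but risky: a homolog can be *convergent*
(same localization pattern) or *divergent* (different pattern), regardless
of sequence identity, and divergent homologs inject noise ("negative
transfer").  Keeping the six views separate lets a kernel-weighting stage
suppress noisy views rather than diluting the clean ones.

Each view m yields a Gaussian Gram matrix
`K_m(x, y) = exp(-γ ||x_m - y_m||²)` (for binary vectors the squared
distance is the Hamming distance) and the final kernel is the convex
combination `K = Σ_m w_m K_m`, `w_m ≥ 0`, `Σ w_m = 1`.

**Kernel weights** are non-parametric: each view alone is scored by inner
cross-validation.  One-vs-rest SVMs are trained per fold on that view's
kernel, the pooled validation predictions form a multi-label confusion
matrix, and the view's score is the class-averaged `(SE + max(MCC, 0))/2`;
scores are normalized into weights (uniform if all scores vanish).  The
clipping at 0 keeps weights non-negative for views worse than chance.

**Classification** is one-vs-rest on the combined precomputed kernel over
*locative* instances (a protein in m compartments contributes m copies, one
per compartment; its copy for class c is a positive example of c and its
other copies are negatives — the mild label noise this creates is inherent
to the locative formulation).  Each binary SVM's decision value f is mapped
to a posterior through Platt's sigmoid `p = 1/(1 + exp(A f + B))`, with
(A, B) fitted by regularized maximum likelihood (prior-corrected targets
`t⁺ = (N⁺+1)/(N⁺+2)`, `t⁻ = 1/(N⁻+2)`; Newton iterations with backtracking,
tolerance 1e-10, ≤ 100 iterations) on decision values from an internal
3-fold CV, never on resubstitution outputs.  The K per-class posteriors are
normalized to sum to 1.

**Labelling.**  Two rules serve two purposes:

* *thresholding* (`p_c ≥ θ`, top-1 fallback so every protein gets at least
  one location) produces the deliverable multi-label prediction;
* *ranked assignment* drives evaluation over locative copies: the top-N
  classes by probability (N = true cardinality; ties broken by catalog
  order) are matched to the N true locations — a true location in the top-N
  is a diagonal hit, and each missed true location is paired, in descending
  probability order, with a distinct non-true top-N class.  Plain argmax
  would cap locative accuracy for multiplex proteins, so multi-assignment
  is required for the metrics to be attainable.

## Evaluation scenarios

Query-side annotation availability defines three regimes:

* **optimistic** — queries keep their own GO terms; all six views enter
  both the training Gram and the query-vs-training cross kernel;
* **moderate** — queries are novel proteins with no GO terms: for the three
  target views the cross kernel is computed between the *query's homolog
  vector* and the training proteins' *target vectors* (the training side is
  unchanged); the homolog views are used as-is;
* **pessimistic** — whole protein families without GO annotation: the
  target views are dropped from both sides and the weights are re-estimated
  on the self-contained 3-view homolog system rather than renormalized from
  the 6-view weights.

## Metrics

Rows of the K×K multi-label confusion matrix are true locations of locative
instances; columns are the ranked-assignment predictions.  Per class, with
TP the diagonal cell, SE = TP/(TP+FN), SP = TP/(TP+FP) (positive predictive
value — this is the convention under which small-compartment summary rows
reproduce as exact count ratios), and the binary MCC with 0 substituted for
vanishing denominators.  Overall accuracy is trace/total; overall MCC is
Gorodkin's K-category correlation coefficient R_K of the matrix.

For multiplex proteins, within each cardinality group N = |T|:
LHR_n = fraction with exactly n true labels hit (n = N is the complete hit
rate), PLMR = fraction with P = T exactly, NT-LHR_n = fraction with exactly
n labels outside T.  The probability threshold is chosen on a grid
(default 0.01…0.30 step 0.01, covering the useful operating points
0.07–0.09) maximizing PLMR, ties broken by fewer mean extra labels, then
the larger θ.

## Cross-validation protocol

Two-level CV: the outer 5-fold CV estimates performance, the inner 3-fold
CV (on the outer training side only) estimates kernel weights — 3 folds
rather than 5 keep the H × γ × C model selection affordable.  Outer folds
split *distinct* proteins, stratified by each protein's first
catalog-ordered location, so a multiplex protein never straddles the
train/test boundary; vocabularies, views, kernel weights, Platt
coefficients and thresholds are all recomputed from the training side of
each fold.  For multi-labelling estimation, only multiplex proteins rotate
through the test folds; singlex proteins always train.

Hyperparameter defaults: H = 1 (one homolog transferred — the optimum under
rank-increasing divergence), γ = 2⁻³, C = 8, θ = 0.09.  Search grids, where
a sweep is wanted: γ ∈ {2⁻⁷…2¹}, C ∈ {2⁻⁵…2⁷}, coordinate search fixing one
hyperparameter at a time in the order H → γ → C.

## Synthetic benchmark

The generator (`mksubloc.synthetic`) emulates the statistical structure the
method targets, with defaults defining the standard study conditions:

| parameter | default | meaning |
|---|---|---|
| K | 6 | subcellular locations |
| vocab sizes F/C/P | 120 / 80 / 150 | GO terms per aspect |
| signature sizes F/C/P | 4 / 8 / 4 | disjoint class-specific terms (C dominant) |
| dropout | 0.2 | per-term loss on target annotations |
| background | 0.02 | per-term spurious annotation rate |
| proteins | 600 | distinct proteins |
| multiplex fractions | 15% / 4% / 1% | 2- / 3- / 4-label proteins |
| homologs | 7 | ranked hits per protein |
| divergence(r) | 0.1 + 0.1·(r−1) | P(rank-r homolog is divergent) |
| annotation loss | 0.3 | extra per-term loss on convergent homologs |

A divergent homolog draws its annotations from a uniformly random
non-member class's signatures; a convergent homolog re-runs the protein's
own sampling with additional annotation loss.  E-values grow with rank
(10^-(80-10r)), identities fall, so the parser's E-value ranking recovers
the generative rank order.  Class signatures are disjoint by default so the
ground truth is well-posed; the C aspect carries the largest signatures,
which is why the cellular-component kernels earn the highest weights.

What the generator does **not** emulate: the GO DAG (terms are flat
indicators, no ancestor closure), evidence codes, real term-frequency
distributions, sequence-level homology (homology exists only as the hit
table), and the severe class imbalance of curated human datasets.  Passing
the recovery tests therefore shows the estimator recovers *this* generative
structure, not that real-data accuracies would be matched; published
results on curated human data depend on version-locked GOA/Swiss-Prot
releases and are out of scope here.

## Numerical choices and degenerate inputs

* BLAST ranking is a total order: ascending E-value, then descending
  identity, then lexicographic subject — permutation-invariant parsing.
* Self-hits are removed so a query's own GO terms never leak into its
  homolog views.
* Proteins with no homologs (or unannotated homologs) get zero homolog
  vectors and a warning, not an error.
* Closed vocabularies: terms first seen at prediction time are ignored.
  Vocabularies include terms seen on training homologs, otherwise homolog
  views would be near-empty at training time.
* SE/SP are 0 on empty rows/columns; MCC is 0 when any margin factor is 0.
* Inner-CV weight folds that lose a whole class on very small datasets are
  skipped; if every fold degenerates the view scores 0.
* All stochastic steps (fold shuffles, world generation) take explicit
  seeds; identical configuration and seed give byte-identical reports.

## Problem sizes used in the test-suite

Unit tests run on 10–40-protein worlds; the statistical-recovery suite runs
the full two-level CV on the 600-protein standard conditions (a few minutes
on one CPU).  The acceptance script repeats the three scenario CVs, the
H ∈ {1, 7} sweep and the multiplex CV at the same 600-protein scale.

## Known limitations

* The per-view score `(SE + max(MCC,0))/2` saturates when several views are
  individually near-perfect, compressing weight contrasts among clean
  views (the contrast is strongest among homolog views, where noise
  actually separates them).
* Platt calibration per class followed by sum-normalization is one of
  several defensible couplings of one-vs-rest posteriors; pairwise coupling
  is a known alternative.
* Threshold selection inside `run_multiplex_cv` (when no fixed threshold is
  given) scores the training-side multiplex proteins with the fold's own
  model rather than a nested CV, trading a small optimistic bias for a
  3-fold runtime saving; the default is a fixed θ = 0.09.
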