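# Methods

This note records the models, conventions and design choices behind
`cycleclass`, in the spirit of a statistical methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

Counts are normalized per cell to a fixed total (default 10,000) and
transformed with the natural `log(1+x)`. The original analysis also
regressed out mitochondrial fraction and UMI covariates during scaling;
we deliberately do not replicate that step — it is entangled with a
specific toolkit's scaling implementation and is not needed for any
property we test. Classifier features are the top 1,536 genes by plain
variance of log-normalized expression, ties broken lexicographically so
the ranking is deterministic and invariant to cell order; toolkit-
specific dispersion measures were avoided for the same
reproducibility reason. The pipeline order is fixed as
normalize → variable-gene selection.

Query alignment renames genes through a homology table (pairs filtered
to be one-to-one in both directions), restricts/reorders to the model's
feature list, and fills absent features so that, after the model's
standardization, they contribute z = 0 (the training mean). Filling
with a raw zero instead would push every linear score toward the
low-expression direction; the mean-fill is the unbiased choice. A query
missing more than 95% of the features is rejected outright.

## Classifier back-ends

All four back-ends consume cells × features z-scores computed with the
training mean/SD stored on the model.

* **NN** — fully connected 100/50/25 hidden units, ReLU, softmax
  output, cross-entropy loss, Adam, mini-batches of 128, at most 50
  epochs, fixed initialization seed. This is the published ACTINN
  architecture; the optimizer settings are our defaults and are
  exposed through `hyperparams`.
* **SVMrej** — linear-kernel SVM with Platt probability calibration;
  the rejection cutoff θ = 0.7 is *inclusive* (max probability exactly
  0.7 is assigned, 0.699… is `Unknown`). θ = 0 disables rejection.
  Rejection is available for every back-end but defaults to 0 for the
  others, matching how the methods are usually reported.
* **RF** — 100 trees, class-frequency-weighted.
* **KNN** — the reference is projected onto its top 30 principal
  components; queries are projected into the same space and classified
  by majority vote of the 10 nearest reference cells (vote fractions
  serve as probabilities).

With an empty feature list (which arises at the 100% point of the
sensitivity sweep) training degrades to a majority-class predictor
rather than erroring, so sensitivity curves are total functions of the
removal fraction.

Cross-validation is repeated random subsampling: each iteration holds
out a uniform random subset (default 1,000 cells), trains on the rest
and scores the holdout. A "100-fold" scheme with 1,000-cell holdouts
cannot be a disjoint partition of a ~6,000-cell dataset, so Monte-Carlo
CV is the only consistent reading. Rejected (`Unknown`) holdout cells
count as errors. Per-class F1 uses the convention F1 = 0 when
precision + recall = 0, keeping summaries total when a class is absent
from a small holdout.

## Statistical kernels

* Hypergeometric enrichment p-values are upper-tail, P(X ≥ k), summed
  in log space (log-gamma binomials + logsumexp) so extreme
  enrichments do not underflow; the lower tail is available by flag.
  The representation factor RF = kN/(Kn) accompanies every result.
* Benjamini–Hochberg adjustment is the standard step-up with
  monotonicity enforcement, applied within each cluster's gene family
  in marker discovery.
* The two-proportion test uses the pooled z statistic *without*
  continuity correction, so z² equals the 2×2 Pearson chi-square
  exactly; note R's `prop.test` default applies the Yates correction
  and will differ slightly.

## Phase topology

Medoids are per-phase means of normalized expression, computed by
default over the classifier feature space (the choice of gene space is
not determined by the original description; using the features keeps
the network comparable to the classifier and stable). Canberra terms
with zero denominator contribute 0 — the formula is undefined there and
this is the usual convention. An absolute distance cutoff (such as the
published 240) is tied to a particular gene space and is not portable,
so the default mode instead chooses the smallest observed distance at
which the mean degree reaches a target (default 2.0, the mean degree of
a closed cycle); the absolute-cutoff mode remains available.

Marker discovery uses Welch's unequal-variance t-test (the robust
reading of "t-statistic-based" discovery), natural-log fold-changes,
and BH (not Bonferroni) adjustment. Genes identical in both groups get
p = 1 rather than NaN.

## Tumor logic

"High expression" for excluding differentiated-cell clusters is
formalized as: the cluster's mean expression of a panel gene is ≥ 2
standard deviations above the across-cluster mean (z computed over
cluster means, population SD) *and* at least 50% of the cluster's
cells express the gene. Both knobs are exposed; note the z-threshold
is only reachable with ≥ 5 clusters (the maximum z over n clusters is
√(n−1)). The stem-like rule is evaluated on raw counts as pure
presence/absence; the required gene is SOX2 (one description writes
"SOX", which we read as SOX2 per the surrounding text). Copy-number
confirmation and expression-subtype calling are out of scope (external
tools).

## Eigengenes and survival

The eigengene z-scores each signature gene across samples (zero-
variance genes are dropped with a warning), takes first-principal-
component scores via SVD, flips the sign if the scores anticorrelate
with the per-sample mean z-score — making "high score = high signature
expression" canonical — and rescales to unit variance. It is invariant
to per-gene affine rescaling of the input and equivariant under sample
permutation.

Cox regression uses Efron tie handling (lifelines) with the
standardized eigengene entered directly; tumor grade is an ordered
numeric covariate and IDH status a binary indicator, matching the
single-coefficient-per-covariate usage. Constant and collinear
covariates are rejected before fitting.

The quartile contrast takes the top and bottom ⌊qn⌋ samples by score
(ties broken by stable input order so group sizes are exact), computes
Kaplan–Meier curves and medians (∞ when the curve never reaches 0.5),
and compares groups with a hand-implemented Fleming–Harrington G-ρ
weighted log-rank statistic, weights S(t⁻)^ρ from the left-continuous
pooled KM estimate. ρ is not specified by the original analysis;
default ρ = 1 (late-difference weighting, distinct from the plain
log-rank) with ρ = 0 reducing exactly to the standard log-rank test —
an identity the test suite checks against lifelines. If no events are
observed the test is reported as undefined (NaN) with a warning.

## The synthetic world

`simulate_cycle_counts` emulates a cycling neural stem/progenitor
population. Defaults are the observed state frequencies — Neural G0
17.3%, G1 36.7%, Late G1 6.4%, S 7.2%, S/G2 10.9%, G2/M 10.6%,
M/Early G1 8.4% — with the remaining 2.5% assigned to the G1/other
outgroup, whose share was never reported (our invention, flagged
here). 5,000 genes, 3,000 cells, 100 markers per cycling phase,
1.5 log2 fold-change, mean library size 5,000 UMI with CV 0.3.

Modeling choices:

* **Noise** is negative-binomial with shared dispersion α = 0.5
  (var = μ + αμ²); dropout then arises naturally from low means rather
  than from a separate zero-inflation component.
* **Cyclic confusability**: 25% of each phase's markers are also
  elevated, at half effect (2^0.75), in the next phase around the
  cycle, so adjacent phases (e.g. Late G1/S) are genuinely harder and
  back-end comparisons are non-trivial.
* **The outgroup** is purely a low-library-size class (factor 0.3) —
  it has no marker block of its own, because the population it
  emulates is defined only by its reduced RNA content. Classifiers can
  still learn it from its depth/dropout signature.
* **Markers are expressed genes**: marker blocks are planted on the
  upper half of the baseline-expression distribution. A fold-change on
  a near-silent gene (mean count ≪ 1) compresses below any practical
  logFC threshold after log1p normalization and is undetectable *in
  principle*; real discovered markers are by construction expressed,
  so a "marker" in this world is too.

What the generator does **not** model: doublets, batch effects,
ambient RNA, gene–gene correlation beyond the phase structure, or
spliced/unspliced layers. A green test therefore establishes that the
pipeline recovers structure of this stated kind at these effect sizes —
not performance on any particular real dataset, and specifically not
the published real-data error rates, which require the original
accession downloads.

`simulate_survival_cohort` draws a latent factor g ~ N(0,1) per
sample; signature genes are g plus N(0, 0.5²) noise, and survival times
are exponential with hazard exp(β·g + covariate effects)/1000 days,
with β = −0.5 by default (higher signature → better outcome, the
direction reported for the quiescence signature). Grade (2/3/4,
effect +0.4 per step, centered) and IDH mutation (Bernoulli ½, effect
−0.5, centered) are the default covariates — signs chosen to match the
well-established clinical directions. Censoring is independent
uniform on [0, c], with c solved numerically so the realized censored
fraction matches the target (default 30%, a typical glioma-cohort
rate). Module correctness is established by parameter recovery on this
cohort, not by reproducing published cohort numbers.

## Numerical conventions and degenerate inputs

* All randomness flows from `numpy.random.default_rng(seed)`; a fixed
  config reproduces simulations and model training bit-for-bit on a
  given platform.
* Zero-total cells are dropped at normalization (counted in the log);
  an all-zero matrix is an error.
* Probability vectors are renormalized defensively and must sum to 1
  within 1e-6.
* Zero-variance features standardize to 0 rather than dividing by 0.
* Blank cells in dense input files are treated as corruption, not
  zeros.
* Result CSVs are written with stable column order and are
  byte-identical across repeated runs on identical inputs.
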