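# Methods

## The model and its assumptions

The pipeline treats intrinsic-subtype assignment as a supervised
five-class problem over a probes × samples log2 expression matrix, with
three deliberately simple ingredients:

**CM1 score.** For probe *i* and a one-vs-rest partition (class of
interest *X*, remaining classes *Y*),

    CM1_i = (mean_X − mean_Y) / (1 + range_Y).

The statistic is univariate and distribution-free: it only assumes that a
subtype-informative probe shifts its *mean* between the class and the
rest. The `1 +` in the denominator keeps the score finite for constant
rest groups, bounds |CM1| by the raw mean difference, and makes the score
invariant under adding a constant to all values (both means shift
equally, the range is unchanged) — properties the test suite asserts.
Per class, probes are ranked separately on the positive and negative side
(rank 1 = most extreme on that side); ranks printed for far-from-the-top
probes follow the same side-specific convention, which is an
interpretation choice documented here because a single signed rank column
could also be read as ordering by absolute score. Ties are broken
lexicographically by probe identifier so ranking is deterministic across
platforms.

**Strict-majority consensus.** Each of k classifiers votes one of the
five subtypes (individual classifiers always produce a label). The
consensus is the label with count > k/2; anything else — including an
exact k/2 tie — is the explicit outcome INC. The denominator is always
the full roster size: the panel is fixed, and abstentions do not exist.
With k = 1 the consensus degenerates to that classifier's prediction and
INC is impossible.

**Agreement suite.** Cramér's V uses the plain Pearson chi-squared
statistic without continuity correction; categories with a zero marginal
are dropped first (their expected counts are zero) with a warning.
Average sensitivity is the unweighted mean of per-class recall over the
*row* labelling's categories. Fleiss' kappa is computed on an s × c
ratings matrix with k raters per sample; a two-labelling comparison is
converted to k = 2 ratings over the union of categories. The Adjusted
Rand Index is computed from the contingency table with
binomial-coefficient sums. Both kappa and ARI are evaluated in exact
integer/`Fraction` arithmetic up to the final division, so values printed
to three decimals in reference material are matched without
floating-point ambiguity. The Jensen–Shannon distance is the square root
of the base-2 JS divergence, giving a true metric on [0, 1]; the base is
a design choice (it fixes the range), made here because the comparisons
it supports are of label *distributions* where a [0, 1] scale reads
naturally.

**INC as a category.** Reference agreement values for strict-majority
ensembles are only reproducible from their contingency tables when the
inconsistent outcome is scored as a sixth category for both kappa (k = 2)
and ARI; this package therefore defaults to `include_inc=True`, with
`include_inc=False` (drop INC samples, shrink N) available everywhere.
An INC call is a real disagreement of the panel, not missing data, so
counting it against agreement is also the statistically honest default.

One caveat on reference tables of this kind: in the transcribed
METABRIC/ROCK study tables, the ROCK-set kappa entries are *not*
derivable from the printed contingency blocks under either INC
convention (the discovery and validation kappas and all nine ARI entries
are). Those three entries were evidently computed on a sample subset or
rating construction the tables do not encode, so the consistency tests
cover exactly the fifteen derivable entries. A related transcription
note: the source tables' captions describe rows as consensus labels,
but the row sums equal the original subtype totals; rows are treated
here as the original labelling, which is the reading consistent with the
average-sensitivity values.

## Synthetic data: what it emulates and what it does not

The generator produces five unequally sized classes (default
93/54/17/12/24 — a 200-sample, luminal-A-dominated miniature of a real
discovery cohort's class imbalance), `markers_per_class` up- and
down-regulated probes per class shifted by ±`effect_size` (default 2.0
log2 units) on a flat background (default mean 8.0), with i.i.d. Gaussian
noise (default SD 0.5, i.e. effect/noise = 4, a "strong but not trivial"
separation). The second-platform view drops probes uniformly at random
(default 20 %), renames the survivors, and applies `scale·x + offset`
plus optional fresh noise — a caricature of an Illumina→Affymetrix
transfer with partial probe matching and different intensity scaling.

Deliberately **not** modelled: correlated co-expression modules,
probe-level artefacts (GC content, background correction), heavy-tailed
or heteroscedastic noise, class-dependent variance, survival times and
clinical covariates. Passing tests on this generator therefore
demonstrate that the machinery is correct and that the pipeline recovers
planted mean-shift structure at the stated signal-to-noise; they say
nothing about how well CM1 ranks probes under correlated biology, which
only real cohorts can show. All randomness flows from explicit seeds;
identical configs reproduce outputs bitwise.

## Classifier roster

The default roster holds 24 scikit-learn models spanning the six
classical families — bayesian (Gaussian/Bernoulli naive Bayes variants),
functions (logistic regression, ridge, linear and RBF SVM, a small MLP),
lazy (k-NN at k = 1/5/10, nearest centroid), meta (random forest, extra
trees, bagging, AdaBoost, gradient boosting, bagged LDA), rules (a
majority-class baseline, a one-feature stump, a shallow depth-3 table
tree) and trees (CART with Gini/entropy, a randomised tree). What the
consensus mechanism needs is *family diversity*, not any particular
member, so the roster is data, fully listed in
`cm1subtype.ensemble.DEFAULT_ROSTER`, and any named subset spanning ≥ 2
families can be substituted. Scale-sensitive models are wrapped in a
standardising pipeline. Each spec carries an explicit seed derived
deterministically from the run seed, so a fixed config reproduces the
prediction matrix exactly.

Cross-validation uses *stratified* folds with a fixed shuffle seed:
stratification is required at desk scale, where the smallest class
(12 samples by default) would otherwise risk empty folds. The fold
bookkeeping is returned with the prediction matrix so tests can assert
the hygiene property that no sample is predicted by a model trained on
it.

## Numerical and degenerate-input choices

* Min-max normalisation is per probe within a platform; constant rows map
  to all zeros (any constant placement is arbitrary and the probe carries
  no signal either way). The choice is documented and tested.
* Probe mapping with multiple targets keeps the target with the highest
  variance across the test samples; exact variance ties (vanishingly rare
  on real data) break lexicographically.
* `balanced_top_k` requires enough probes on each side and fails loudly
  otherwise rather than padding.
* ARI of two one-block partitions (denominator 0) is defined as 1.
* Fleiss' kappa with all ratings in one category is explicitly undefined
  and raises rather than returning NaN.
* JS divergence round-off below 0 is clipped before the square root.

## Problem sizes

Defaults were chosen so one full study (generation, CM1 ranking of 320
probes × 200 samples, a 24-model 10-fold consensus, transfer to a second
platform, and the agreement suite) completes in well under a minute, and
the test suite — which runs the consensus machinery several times — in a
few minutes on one CPU. These sizes are the package's study conditions,
not tuning knobs: the planted-recovery and consensus-accuracy properties
are asserted under exactly these defaults.

## Known limitations

* The agreement suite offers no confidence intervals or significance
  tests (and no weighted/Cohen kappa); values are point estimates.
* Per-classifier performance summaries across a roster are possible by
  applying the suite to each classifier's column of the prediction
  matrix, but no aggregated per-classifier report is built in.
* The CLI's `run-all` covers the cross-validation arm; the transfer arm
  is driven through the library (see `analysis/03_ensemble_consensus.py`).
* Survival analysis is out of scope by design.
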