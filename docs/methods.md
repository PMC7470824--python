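# Methods

`megword` re-implements, end to end on simulated data, a single-trial
word-decoding analysis for source-projected MEG: a searchlight correlation
classifier for 4-alternative word identification, a classifier-evidence
statistic linking neural representations to single-trial comprehension,
group-level cluster-permutation and Bayes-factor inference, representational
similarity analysis (RSA) against phonological and semantic word features,
and the adaptive staircase used to calibrate stimulus difficulty.  Because
the package is exercised on synthetic source activity with known ground
truth, every stage can be validated by parameter recovery rather than by
eyeballing maps.

## The simulated experiment (`synthgen`)

Each simulated participant performs a word-comprehension task: 18 target
words, 9 "numbers" and 9 "adjectives", each presented 10 times per condition
(defaults; all counts are configurable).  After every trial the participant
picks the word from four same-category alternatives (4-AFC, chance 25%): the
true word plus 3 foils drawn uniformly without replacement from the 8
same-category words, fixed per trial.

Source space is a regular cubic lattice (6 mm spacing; the smallest lattice
covering a cube of the requested extent).  Activity is sampled at 150 Hz.
Each word owns a fixed spatio-temporal template — i.i.d. standard-normal
values over (active-region grid points x 500 ms window samples), drawn once
per seed and scaled by `pattern_gain` — added to the trial's activity on top
of i.i.d. Gaussian noise (`noise_sd`, default 1).  The i.i.d. template keeps
the classifier's correlation geometry full rank while staying maximally
simple.  The two conditions either share templates (probing
cross-classification transfer) or draw independent ones (its negative
control).

Behaviour is generated from the representational fidelity of the stimulus in
a designated *relevant region*: the noise-free representational distance of
each trial (1 minus the mean template correlation with the trial's three
foils, restricted to the relevant region), z-scored across trials, enters a
logistic link `P(correct) = logistic(b0 + b1 d)`.  A correct trial responds
with the true word; an error picks one of the three foils uniformly.  With
`b1 = 0` and `b0 = logit(0.7)` mean accuracy sits at the study-typical 70%
level; for `b1 > 0` the helper `calibrated_intercept(slope, target)` solves
`E[logistic(b0 + b1 Z)] = target` over a standard-normal distance so the
cohort still averages ~70%.  Because behaviour is driven by the *noise-free*
generator distance through the same logistic the analysis assumes, the
neuro-behavioural analysis has a well-posed recovery target.

A second behaviour generator biases confusions by word-feature similarity
(response to an error trial drawn with probability proportional to
`exp(-distance/temperature)` in the phonological or semantic space); it
exists solely to give the RSA a directional ground truth.

Word features themselves are synthetic: phoneme strings of 2–8 ARPAbet
tokens and 300-dimensional unit-norm Gaussian semantic vectors, seeded.

What the generator deliberately does *not* emulate: sensor-level MEG, head
geometry and beamforming, temporal autocorrelation and 1/f structure of
neural noise, artifact rejection (trial counts stay balanced), and word
templates that drift over repetitions.  Synthetic templates are therefore
far cleaner than real evoked activity, and absolute decoding levels are much
higher than any plausible MEG experiment at comparable gain; passing tests
establish the correctness and calibration of the machinery, not expected
effect sizes on real data.  Only the chance-level contract (25%) transfers
directly.

## Feature extraction (`features`)

* **Searchlights** — all grid points within an inclusive radius (default
  12 mm) of a centre.  On the 6 mm lattice an interior 12 mm searchlight
  contains 33 points; the inclusive boundary is what produces that count.
* **Per-trial normalisation** — each (trial, grid point) time series is
  z-scored over the whole trial (population SD); zero-variance series are a
  named error.
* **Spatial smoothing** — Gaussian kernel with `sigma = fwhm/(2 sqrt(2 ln 2))`
  (default FWHM 3 mm), weights normalised per point, so constant maps are
  fixed points and the operation is linear.
* **Word window** — the 500 ms following word onset, re-binned at 20 ms by
  averaging samples (25 bins of 3 samples at 150 Hz).  Feature vectors are
  flattened with grid points outer and time bins inner; the correlation
  classifier is order-invariant but the layout is fixed for oracles.
* **Mirroring** — each point maps to the nearest point to (−x, y, z) within
  spacing/2 (unique on a regular lattice); missing partners are flagged, not
  fatal.

## The classifier and its evidence (`decode`)

For a test trial and searchlight, the Pearson correlation of its feature
vector is computed with every other trial of each of the four candidate
words — same-word references exclude the test trial (leave-one-trial-out);
foil references are all trials of the foil word in the same condition.
Correlations are averaged raw (no Fisher transform) within candidate and the
trial decodes as the candidate with the largest mean; exact ties go to the
smallest word id, which is deterministic and has probability zero on
continuous data.  Performance is the proportion correct, computed per task
category and then averaged.  The representational distance is
`d = mean within-word correlation − mean of the three per-foil means`; a
correctly decoded trial necessarily has `d > 0`.

Cross-condition decoding applies the same rule with the reference set drawn
entirely from the other condition (no leave-one-out); within-word references
do not mix conditions.

Two finite-sample facts worth knowing.  First, with 10 repetitions the true
word has 9 leave-one-out references versus 10 per foil, so the target's mean
correlation has slightly higher sampling variance; on pure noise this
inflates the expected maximum and chance performance sits a few tenths of a
percentage point above 25% — well inside the Monte-Carlo band the tests
assert.  Second, label permutations reuse the trial-by-trial correlation
matrix, which is what makes thousands of within-participant shuffles cheap.

## Linking evidence to comprehension (`neurobehav`)

Participants above 95% accuracy (strictly) are excluded from this analysis
only, mirroring the ceiling rule for the visual condition.  Per participant
and searchlight, accuracy is regressed on the standardised distance with a
logistic model penalised by a ridge term on the slope (`lambda` default 1 on
standardised d; the penalty is the minimal regularisation that keeps betas
finite on separable subsets — the intercept is unpenalised).  To neutralise
the ~70/30 class imbalance, each of 50 subsets (default) draws
`2·min(n_correct, n_wrong)` trials with equal class counts; slopes are
averaged over subsets, computed per category, then averaged.  The fit is a
vectorised 2-parameter Newton iteration; permutation surrogates (accuracy
labels shuffled within category, which keeps subset sizes constant) are
fitted for all permutations and subsets in one single-precision solve —
betas feed a t-test, so float32 is ample.

Group level: a one-sample t of betas against zero per searchlight, a
two-sided cluster permutation of that map against the label-shuffled
surrogate t-maps (first level at the Student quantile for the included
sample size), and a within-participant robust regression (Huber psi, tuning
constant 1.345, IRLS via statsmodels RLM) of the beta map on the
classification map, tested at the group level with a t and its JZS Bayes
factor.

## Group statistics (`stats`)

Cluster inference follows the standard nonparametric recipe.  For
classification maps the first-level threshold is the per-grid-point 99.95th
percentile of group-averaged permutation maps (classification is one-sided);
for t-maps it is the two-sided Student quantile, with positive and negative
clusters formed separately.  Clusters are contiguous sets on the lattice's
6-neighbour adjacency (the most conservative standard choice) of at least 10
points, scored by the summed statistic T_sum; the cluster p-value is
`(1 + exceedances)/(1 + n_perm)` against the permutation distribution of the
maximum cluster mass, hence unbiased and never exactly zero.  Fewer than 100
permutations triggers a warning rather than an error.

The first-level quantile is always *computed*, not hard-coded: for n = 18 it
prints as 2.1, while for n = 15 it is 2.145 (sometimes quoted rounded to
2.2 in the literature; the computed quantile is used).

JZS Bayes factors use the Zellner–Siow Cauchy prior on standardised effect
size (scale 0.707) integrated numerically (relative tolerance 1e-9 in the
quadrature, validated against an independent non-central-t x Cauchy integral
to 1e-6); correlations use the corresponding Jeffreys–Zellner–Siow marginal.
Verdicts follow the 3 / (1/3) convention.  Hemispheric lateralisation of a
cluster is the paired difference between its members and their mirrored
contralateral points (unmapped members dropped and counted), one t per
cluster, BH-FDR across clusters.

## RSA (`rsa`)

Per category: a phonological RDM from token-level Levenshtein distance
(unit costs by default; an optional substitution-cost table restores
feature-weighted distances), a semantic RDM from cosine distance of
length-normalised vectors, and a behavioural RDM from the 4-AFC confusions.
The confusion-to-dissimilarity rule is symmetrised and opportunity-
normalised: `1 − (C(i,j)+C(j,i)) / (O(i,j)+O(j,i))`, where opportunities
count trials in which the other word was available as a candidate; pairs
that never co-occur are missing (NaN) and excluded pairwise.  RDMs are
compared by Spearman correlation over the lower triangle (average ranks for
ties), Fisher z-transformed, averaged across categories; feature spaces are
contrasted with a paired Wilcoxon signed-rank test.

## Staircase (`staircase`)

A 1-up-3-down track on a 2-alternative task: the level drops one step only
after three consecutive correct responses and rises after any error,
converging where `p^3 = 0.5`, i.e. 79.4% correct.  Step sizes halve once
after the first two reversals (common practice; configurable); the converged
level is the mean of the last `n_converge` reversal levels (default 6; long
diagnostic runs use more).  Observers are monotone psychometric functions
with a 0.5 guessing floor; non-monotone observers are rejected up front.
The simulator's tracks are verified against an independent replay of the
update rule, and 10^4-trial runs put the observer's accuracy at the
converged level within 2 percentage points of 79.4%.

## Orchestration and problem sizes

`pipeline.run_full` chains simulate → smooth/z-score/window → decode (with
label-shuffled permutation maps) → cross-decode → classification cluster
statistics and lateralisation → neuro-behavioural analysis → robust
classification-vs-relevance regression → RSA, deriving one seed stream per
stage from a single top-level seed; identical configs and seeds produce
byte-identical TSV/JSON outputs (stage timings go to the log only), each
stamped with a hash of the scientific settings.

The numbered scripts under `analysis/` run the same stages on a 12-
participant cohort with the full 18-word design on a 5x5x5 lattice, word
patterns in a 19-point ball and the behaviour-driving core its central 7
points (gain 1.5 — chosen so the neuro-behavioural recovery is clearly
powered at 12 participants; classification saturates near the active region
at this gain, which is expected of noiseless templates).  Test and
acceptance runs use smaller instances still (3x3x3 to 5x5x5 lattices, 8–18
words, 60–500 permutations); the type-I and recovery suites state their
replicate counts in the tests.  These sizes are the package's own choices to
keep full runs in minutes while leaving every statistical check properly
powered.

## Known limitations

* The behavioural link uses the noise-free generator distance; real single-
  trial evidence is itself noisy, so empirical beta magnitudes are not
  comparable to the simulation's.
* The ridge form and strength of the penalised logistic regression, the
  confusion-RDM normalisation, and the staircase step schedule are
  documented defaults where the procedure admits several readings; all are
  exposed as parameters.
* Unit-cost token Levenshtein stands in for dictionary-based weighted
  phonological distance; supply a substitution-cost table for the weighted
  variant.
* Cluster adjacency is strict 6-connectivity; no TFCE or random-field
  alternatives are provided.
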