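# Methods

`kneephen` implements a phenotype-discovery workflow for knee-osteoarthritis
cohort data: a mixed-type baseline feature matrix is standardized, searched
for biclusters (subsets of knees coherent on subsets of features), the
separation of bicluster pairs is significance-tested against a single-Gaussian
null, longitudinal pain is decomposed into latent trajectory groups, and
96-month structural outcomes are classified and cross-tabulated by bicluster.
A seeded synthetic-cohort generator provides ground truth for every stage.

## Preprocessing

Nominal features expand to one 0/1 indicator per level; ordinal features are
coded 1..k in their declared order; continuous features may first pass
through a monotone shifted-log transform `t(x) = s·log(s·(x − a) + c)`
chosen by grid search over `c ∈ {0.01..5}·range(x)` (sign `s` follows the
direction of skew, anchor `a` at the data minimum or maximum) to minimize
|sample skewness|. Transformation is only attempted when |skewness| > 0.5;
identity wins whenever no candidate improves. Continuous and ordinal-coded
columns are then centered and scaled to mean 0, sd 1 (n−1 denominator);
indicator/binary columns stay on their native 0/1 scale, since a 0/1
proportion is already interpretable against the cohort and rescaling would
let rare indicators dominate the residue. Rows with any missing cell are
removed (complete-case analysis); every transform parameter is logged for
exact inversion. Standardizing ordinal codes is a config switch (default
on) because they enter the same residue computation as continuous columns.

## Biclustering

Quality of a submatrix (I, J) is the mean squared residue

    H(I,J) = mean_{i∈I, j∈J} (a_ij − a_iJ − a_Ij + a_IJ)²,

zero exactly when the submatrix is additive in row and column effects. The
greedy search deletes nodes until `H ≤ δ` (default δ = 0.2): a batch phase
removes every row (column) with d-score above `α·H` (α = 1.2) while the
dimension exceeds 100, then single-node deletion removes the worst row or
column one at a time (ties: rows before columns, then lowest index; size
floor 2×2), and node addition re-admits any column, then row, whose d-score
is at or below the current H, repeating to a fixed point. Inverse-row
addition (admitting sign-flipped rows) is off by default because clinical
features have directional meaning. A two-way-ANOVA R² — `1 − SSE/SST` on
the submatrix with `SSE = |I||J|·H` — summarizes each bicluster's fit.

Several biclusters are extracted by repeating the search and removing each
accepted bicluster's rows from the candidate pool; columns remain available
to all biclusters. This enforces the row-exclusive structure directly
rather than masking used cells with random values, which cannot guarantee
disjoint row sets. Extraction stops at `max_k` (default 6) biclusters,
when fewer than `min_rows` rows remain, or on non-convergence. δ must lie
in (0, msr_max), where msr_max is the whole matrix's MSR.

**Known limitation.** Greedy deletion stops at the *first* δ-crossing. When
planted blocks are much tighter than the threshold (block residue ≈ σ² far
below δ) against a unit-variance background, the submatrix at the crossing
necessarily retains extra background rows — roughly `r` extra rows with
residue variance v satisfying `(m·σ² + r·v)/(m + r) = δ` — plus a few
background columns that then gate row re-addition. Recovery of sharply
planted blocks therefore tops out near row-Jaccard 0.8 in the best case
and is typically lower; this is a property of the original greedy, matching
its published benchmark behavior on planted modules, not of this
implementation. On weakly coherent clinical data, where δ is a sizable
fraction of msr_max, the algorithm behaves as intended, producing large,
loose biclusters.

## Cluster-pair significance

For a pair of biclusters the test statistic is the cluster index
CI = within-class sum of squares / total sum of squares over the pooled
rows and *all* prepared columns. The null is a single Gaussian fitted to
the pooled pair: the noise floor is `(MAD of column-centered cells /
0.6745)²`, and sample-covariance eigenvalues are hard-thresholded from
below at that floor (the original procedure's estimator; the later
soft-thresholding variant is not used), padded at the floor when the
dimension exceeds n−1. Each of `n_sim` (default 1000) replicates draws n
points from the axis-aligned Gaussian with those eigenvalue variances and
records the best CI over seeded 2-means restarts (default 10, batched
Lloyd iterations). The z-score of the observed CI against the null CI
moments is reported; z < −2 flags a significant pair (one-sided normal
p < 0.023). The observed CI uses the given bicluster labels — the
hypothesis under test is the biclusters' separation — with a config switch
to re-split the observed data by 2-means instead. No multiplicity
correction is applied across pairs by default (exploratory use); a
Bonferroni option exists in the results table downstream. Covariance
estimation pools only the pair being tested. The null estimator is
slightly conservative (eigenvalue overestimation at moderate n), which
shows up as a type-I rate at or below the nominal 0.023.

For visualization each pair is projected onto the unit vector between the
class means (axis 1) and the leading principal component orthogonal to it
(axis 2).

## Trajectory model

Change-from-baseline pain at months 12, 24, 36, 48, 72, 96 (month-0 change
is identically zero and excluded) follows a finite mixture of polynomial
trajectories: knee i in group g has `y_t ~ N(poly_g(t/96), σ²)` with a
shared residual sd σ (per-group σ behind a flag). Months are rescaled by
/96 so coefficients stay O(1). Fitting is EM, best of `n_starts` (default
10) random hard-assignment starts, tolerance 1e-6 on the log-likelihood
with an iteration cap of 400; at the cap, a final improvement below 0.02
is accepted as practical convergence (near-degenerate mixtures crawl below
any strict tolerance; the residual climb is negligible on the BIC scale).
Converged restarts are preferred over higher-likelihood unconverged ones.
The M-step for each group's coefficients is a posterior-weighted least
squares over all observed visits.

The optional dropout extension models the probability of *first*
missingness at each visit with a per-group logistic in (intercept,
previous observed response) — the simplest covariate set of the dropout
extension — fitted by weighted Newton-Raphson inside the M-step; dropout
terms enter both the likelihood and the posteriors. Missingness is treated
as monotone; knees are included whenever they have the baseline visit and
at least one later observation.

Model selection fits G = 1..G_max from cubic means, iteratively removes
the highest-order coefficient of any group whose Wald test (from the
weighted-least-squares covariance `σ²(XᵀWX)⁻¹` at the EM fixed point)
exceeds p = 0.05, refits, and returns the BIC-minimizing model with
`BIC = −2·loglik + k·log(n_knees)` (minimized; SAS reports a different
sign convention). Posterior group probabilities assign each knee by
argmax; a maximum posterior of at least 0.8 flags a well-classified knee.
Confidence intervals for the mixing proportions come from the observed
information of the logit-transformed weights (central finite differences
with the other parameters profiled at their estimates) mapped through the
softmax Jacobian; a singular information matrix falls back to the trivial
[0, 1] interval. The response is plain normal, not censored normal:
change scores are unbounded in this formulation and censoring bounds
would be arbitrary.

## Outcomes

Radiographic progression levels over 96 months, from the KLG history:
1 baseline KLG 0–1 with no follow-up, 2 no incident disease, 3 incident
disease (any follow-up KLG ≥ 2), 4 baseline KLG ≥ 2 with no follow-up,
5 prevalent without progression, 6 progressive (any increase), 7 baseline
arthroplasty, 999 no KLG anywhere. Joint-space-width loss per compartment
is `100·(fitted(0) − fitted(96))/fitted(0)` from an ordinary
least-squares line of width (mm) on month; fitted losses above 100% are
truncated to 100, fitted gains beyond 40% (medial) / 50% (lateral) are
truncated to those magnitudes — truncation, not exclusion, is the default
(an exclusion mode exists) and truncation counts are reported. Knees with
an arthroplasty during follow-up contribute their observed visits to the
regression. Quartiles use linear interpolation (type-7). Cross-tabulation
produces per-bicluster category proportions, arthroplasty rates,
loss quartiles and trajectory-group proportions, plus a full-cohort row.

## Synthetic cohorts

The generator plants additive blocks `μ + r_i + c_j + ε`,
`ε ~ N(0, noise_sd²)`, in an iid standard-normal latent matrix (matching
the post-standardization scale the biclustering consumes), with pairwise
disjoint row sets mirroring the row-exclusive analysis. Binary columns
threshold the latent at a configurable quantile; ordinal and nominal
columns bin it into equal-probability levels. Pain panels are drawn from a
declared trajectory mixture with monotone per-visit dropout hazards that
can rise after month 48; outcome tables draw monotone KLG series,
arthroplasty flags and linear qJSW trajectories whose parameters differ by
planted bicluster. Defaults (four blocks covering ~70% of knees; four
trajectory groups at 76.4/11.2/9.0/3.4% — stable, improving, worsening,
transient — with residual sd 2; hazards 3% per visit rising to 8% after
month 48; block effects about one standard deviation with row/column
effect sd 0.5) are chosen as representative of a community knee cohort.
Everything is a pure function of the spec's seed.

What the generator does **not** emulate: real instrument distributions and
codebooks, inter-feature correlation outside planted blocks, intermittent
(non-monotone) missingness, baseline missingness patterns, and
person-level clustering of the two knees. Passing recovery tests therefore
demonstrate correctness of the machinery under the declared data-generating
process, not performance on any real cohort.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full
suite completes on one CPU in minutes: recovery benchmarks at 300×40 with
three planted blocks over 20 seeds; significance calibration with 200
replicates of n = 100, d = 10 and 200 null simulations each; trajectory
recovery at n = 500 knees over 20 seeds with 3 EM restarts; the bundled
end-to-end configuration at 400 knees × 40 features with 150 null
simulations per pair.
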