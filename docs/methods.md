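# Methods

This note documents the models, conventions, and numerical choices behind
`tractclust`, and what the synthetic cohorts do and do not establish about
real data.

## Confound model and residualization

Each tract's values are regressed, per cohort, on an intercept, age, age
squared, and gender by ordinary least squares, and the residuals are z-scored
(population variance) within the cohort. Age is centered before squaring —
same column space, better conditioning; residuals are unchanged.
Residualization is fitted strictly within cohorts, never pooled, because
absolute FA levels differ between scanning protocols; pooling would let a
site effect masquerade as a participant subtype. If only one gender is
present the gender column is dropped with a warning. Residualizing twice is a
no-op (checked to 1e-8). QC filtering is strict: a participant survives only
with between-volume displacement strictly below the threshold (default 3 mm).

## Signed quality index and its conventions

The similarity network holds Pearson correlations between participants'
residualized profiles, so weights are signed. The quality index splits the
weights into a positive layer `w+` and a negative layer stored as magnitudes
`w−` (the raw weights are in [−1, 0); the summand uses |w|, which is the only
reading that keeps the chance-expected term `e−_ij = s−_i s−_j / v−`
nonnegative and reproduces the asymmetric penalty of the reference
signed-modularity formulation). Sums run over ordered pairs; the diagonal is
zero and self-loops never enter (they appear only internally on aggregated
graphs, where they are required for the aggregation to preserve Q). Positive
within-module weight is rewarded at scale `1/v+`, negative within-module
weight penalized at the smaller scale `1/(v+ + v−)`. When the network has no
negative edges the index reduces exactly to Newman–Girvan weighted
modularity; an all-positive network placed in a single module scores 0
(telescoping). A network with no positive edges is an error. The resolution
parameter multiplies the chance-expected terms and defaults to 1 (the index
as defined has none); it is exposed for sensitivity analyses only.

## Louvain optimization and consensus

Optimization is the greedy two-phase Louvain heuristic generalized to the
signed index: starting from singletons, nodes are swept in a seeded random
order and moved to the community with the best strictly positive gain (first
encountered best wins, tolerance 1e-12 — deterministic under the seed), then
communities are aggregated and the sweep repeats. Gains are computed against
the ORIGINAL layer totals `v±`, which are invariant under aggregation, so Q
never decreases across passes. Correctness is tested against a term-by-term
brute-force evaluation of the index and against exhaustive set-partition
enumeration (Bell-number search) on networks with up to 8 nodes.

Consensus clustering runs `n_runs` (default 100) seeded instantiations,
forms the agreement matrix of co-assignment proportions, zeroes entries
below `tau` (default 0.5; the threshold is not prescribed by the index and is
exposed as configuration), and re-clusters the thresholded agreement network,
iterating until every run returns the identical partition (at most 50 outer
iterations, then an error with diagnostics). The reported Q is always
evaluated on the original network. If runs disagree at the convergence
check the next iteration re-clusters the agreement matrix; the failure
diagnostics report the highest-Q run.

## Detectability: what planted-group recovery can and cannot show

The synthetic cohort plants two balanced groups whose z-scored means differ
by `group_effect` on exactly two marker tracts (emulating the left/right
cingulum), with the remaining 18 tracts pure noise. This design has a hard
information-theoretic ceiling: with separation d on each of two independent
standardized tracts, the Bayes-optimal per-participant assignment accuracy
is Φ(d·√2/2) — about 0.80 at d = 1.2, an adjusted-Rand ceiling near 0.37 for
any clustering method. Recovery at ARI ≥ 0.9 requires d ≳ 2.8, and even then
the 18 uninformative tracts dilute the pairwise profile correlations (the
between-participant correlation noise SD is ≈ 1/√18 ≈ 0.24 regardless of d),
so modularity at resolution 1 tends to subdivide the true groups. Planted-
partition recovery is therefore validated on similarity networks directly
(noisy two-block networks with within-weight ≈ 0.5, between ≈ −0.3, edge
noise SD 0.25, where consensus recovers the planted split exactly), the same
regime in which the underlying community-detection machinery was originally
validated. Real cohorts in which this pipeline finds clean two-group
structure necessarily carry much stronger within-group profile correlation
than two informative tracts out of twenty can produce; a reported Q from
real data is an internal-consistency measure of the found partition, not
evidence that a latent truth was recovered. Passing the synthetic recovery
tests shows the machinery is correct, not that any particular cohort's
grouping is real.

## Agglomerative comparison

The silhouette scan clusters the residualized profiles agglomeratively under
ward / average / complete / single linkage over a range of k and reports the
mean silhouette per (k, linkage), always scored on the correlation distance
1 − r so the linkages are comparable. Ward linkage requires Euclidean
geometry and therefore operates on the profile rows; the other linkages use
the precomputed correlation distance.

## Group statistics

Per-tract comparisons apply a Shapiro–Wilk gate per group at p < 0.05 —
rejection in either group switches the tract from a two-sample t to a
Mann–Whitney U — with Bonferroni correction across tracts (`p·m`, capped at
1). The U statistic's p is exact by enumeration when n1·n2 ≤ 400 and there
are no ties, else the tie-corrected normal approximation. The summary-
statistic utilities (pooled t with SDs recovered as `se·√n`, df = n1+n2−2;
Welch TOST with `SE_diff = √(se1²+se2²)` and Welch–Satterthwaite df; Pearson
goodness-of-fit χ²) work from printed group summaries so that published
tables can be checked directly. The familywise error of the gated, corrected
tract scan is simulation-checked to sit near the nominal α.

## Transfer, median-split prediction, permutation inference

The percentile-range rule assigns a new participant to a discovery group iff
every marker-tract value falls inside that group's empirical 5th–95th
percentile range (an empirical member range, not a CI of the mean — a CI of
the mean would exclude most of the group's own members); inside both ranges
the nearer marker centroid (Euclidean) wins, inside neither the participant
is left unassigned (C0). The correlation rule labels by the stronger Pearson
correlation of the full profile with the two group mean profiles, subject to
a cutoff; raising the cutoff can only shrink the labelled set.

Prediction accuracy is the fraction of labelled participants whose
group-implied side of the behavioural median is correct; values exactly at
the median count as "above" (deterministic tie rule), and the score is
invariant to monotone transforms of the behaviour. The tuning harness splits
the sample into equal seeded thirds, learns the group→side mapping and the
cutoff (percentile split over {50, 55, 60, 65, 70}, or correlation cutoff)
on train→test, and scores the frozen rule on the untouched validation third.
Significance comes from shuffling group labels (C0 excluded) with the
add-one estimator p = (1 + #{perm ≥ obs}) / (1 + n_perm), which is never
zero and is slightly conservative. Because median-split accuracy lives on a
lattice of about n distinct values, its null p-values are exactly uniform
only up to that discreteness; calibration checks use uneven group sizes so
the lattice is fine enough for a Kolmogorov–Smirnov comparison.

## Connectome edge selection

Pipeline order is fixed: absolute threshold (counts strictly greater than 5
survive), consensus mask (edge present in ≥ 60% of participants, boundary
inclusive), log10 scaling (zeros stay zero; every surviving count is ≥ 6 so
there is no collision), then selection. The sample is split 80/20 (seeded);
the training 80% is divided into 4 disjoint random subsets (read as disjoint
folds rather than repeated resampling, for independence; configurable), and
an edge is selected iff its Mann–Whitney p < 0.05 with the same direction in
all four folds and again in the hold-out. The five-fold conjunction is the
multiplicity control — per-edge false retention is far below α — so no
further correction is applied within folds. Group membership within a fold
is the fold's own participants (not re-balanced). Edge-wise tests use a
vectorized tie-corrected normal-approximation Mann–Whitney over all edges at
once (group sizes here put n1·n2 well beyond the exact-enumeration regime);
it is unit-tested against scipy's scalar implementation column by column.

## DMN coupling

Component selection scores each spatial map by the mean z-scored activation
inside a reference DMN mask minus the mean outside, taking the argmax (ties
to the lowest index, logged). Seed ROIs are spheres of 8 mm radius around
MNI coordinates (PCC 0,−52,18; mPFC 1,50,−5; TPJ ±46,−68,32), realized as
voxels whose mm-space centers lie within the radius through the image
affine (0-based indices). Band-passing is a 4th-order Butterworth 0.01–0.1
Hz applied forward-backward (zero phase, squared magnitude response); only
the gain contract is normative — passband ≥ 0.9, ≥ 10× attenuation one
octave outside either edge. The partial correlation residualizes both seed
signals on the controls plus an intercept and correlates the residuals
(equal to the precision-matrix formula to 1e-10). The interaction model is
an OLS fit of raw partial r (not Fisher-z; configurable) on group, FA
(z-scored), and their product, with no default covariates; per-group simple
slopes of partial r on standardized FA are the reported betas.

## Synthetic cohort generator

The generator is the package's test surface for cohorts that cannot be
shipped. Defaults emulate a developmental sample: n = 80, ages uniform on
6–22 years, gender Bernoulli(0.5), 20 named tracts with baselines in
0.35–0.55, FA growing ~0.003/year with a small negative quadratic term and a
0.005 gender offset, residual SD 0.04 — keeping raw FA inside [0, 1] without
clipping. `group_effect` is the between-group marker separation in units of
the residual SD (applied as ±effect·noise_sd/2), so it is the standardized
effect downstream analyses see. Behavioural scores shift by 0.8 SD between
groups by default. Streamline counts are negative-binomial (dispersion 8 —
Poisson is too tight for tractography counts) with per-edge lognormal
baseline means (median ≈ 15, σ_log = 1.1) so that a realistic share of
edges fails the absolute and consensus thresholds; planted edges sit at
mean 40 and are multiplied by the group factor (default 0.5) in group 2.
Time series are four AR(1) channels (coefficient 0.3, TR 2 s, 270 volumes):
mPFC and PCC share a latent signal whose loading targets a per-subject
partial correlation r = clip(0.3 + slope_g·FA_z + η, ±0.95) with
between-subject jitter η (SD 0.1) — the slope parameter (defaults 0.38 vs
0.0) is thus directly the partial-correlation slope on standardized FA. The
±0.95 clip introduces a small (~0.04) downward slope bias for high-FA
subjects in the sloped group; this is an honest consequence of the bounded
correlation scale and stays well inside the recovery tolerance. All
randomness derives from one seed through named sub-streams (profiles /
behaviour / connectomes / timeseries), so generating one artifact never
perturbs another.

What the generator does not emulate: inter-tract correlation structure
(real tract FA values share global and regional factors), non-Gaussian FA
distributions, motion/QC artifacts beyond a displacement column, spatial
structure of component maps, and physiological noise in time series.
Passing tests on these cohorts validates the statistical machinery under
the stated model, not the behaviour of the pipeline on any particular real
sample.

## Degenerate inputs and tie rules

Zero-variance tracts and zero-variance participant profiles are errors
naming the offender; a QC filter that removes everyone is an error; an
assignment in which every participant is C0 is an error. Louvain ties break
to the first-encountered best gain under the seeded order; component-
selection ties break to the lowest index; median ties count as "above";
both-range assignment ties break by centroid distance. Consensus labels are
canonicalized to 1..k in order of first appearance.

## Problem sizes

Simulation-backed checks run at the sizes the analyses target: cohorts of
80–240 participants, 45-ROI connectomes, 270-volume time series; calibration
suites use 40–200 replicates, chosen so a full run of the test suite and the
acceptance script completes in a few minutes while leaving Monte-Carlo
margins comfortably wider than the asserted tolerances.
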