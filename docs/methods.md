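# Methods

This note documents the models, conventions and numerical choices behind
`fcclust`, in the order data flows through the pipeline.

## Synthetic cohorts

The clinical data the pipeline is designed for is access-restricted, so
all development and testing runs on synthetic cohorts that emulate its
structure: 132 subjects split 35/34/34/29 across control, early MCI,
late MCI and AD; 200 ROIs; 135 retained timepoints.

**Feature cohorts** (`generate_feature_cohort`) draw the clustering
substrate directly.  Group `g` contributes `n_g` rows from an isotropic
Gaussian around a group centroid.  In the default *simplex* mode the
centroids are mutually equidistant with pairwise distance
`sfc_effect · √n_features`, built from tiled order-4 Hadamard sign
patterns so every feature carries part of every contrast — `sfc_effect`
is therefore the per-feature RMS group difference in correlation units
(default 0.2, against a within-group SD of 0.1).  A *spectrum* mode
instead places the four centroids on a line (control → AD), for
experiments on the disease-continuum geometry.  All centroids sit on a
constant offset of 0.3, a typical connectivity level.

Within-group dispersion is *group-dependent*: the per-group SD
multipliers default to the cohort's demographic heterogeneity (age-SD
ratios 5.9/5.9/8.6/7.4, normalized to mean one → 0.85/0.85/1.24/1.06),
so patient groups — especially late MCI — form more diffuse clusters
than controls.  This matters: with perfectly homogeneous isotropic
groups, DBSCAN's widest-epsilon-step radius and OPTICS' reachability
threshold cut the same valley–peak gap and the two algorithms become
nearly equivalent, in accuracy and in noise robustness alike.  The
density inhomogeneity restores the regime the method is designed for — a
single global ε cannot fit all group densities equally well, whereas the
reachability ordering degrades more gracefully — and it is anchored in
the cohort's demographics rather than tuned.

**Time-series cohorts** (`generate_roi_timeseries`) simulate the ROI
signals themselves.  Affected ROI pairs (disjoint pairs `(2i, 2i+1)`,
100 by default) share a latent signal: the pair is generated as
`x_t = z_t`, `y_t = ρ_t z_t + √(1−ρ_t²) e_t` with unit white `z, e`, so
the instantaneous correlation is exactly `ρ_t`.  The correlation level
carries the static effect, `ρ_g = base_corr + sfc_effect · s_g` with
spectrum score `s_g ∈ {0, ⅓, ⅔, 1}`, and a sinusoidal modulation
carries the dynamic effect:
`ρ_t = ρ_g + (base_amplitude + dfc_effect · s_g) · sin(2πt/P + φ)`,
with period `P` drawn per subject-pair (default 40–80 TR) and random
phase.  Unaffected ROIs are independent white Gaussian series.  The two
knobs dial the two feature families nearly independently: the
full-series correlation converges to the time average of `ρ_t` (≈ ρ_g),
and the variance of sliding-window correlations tracks the modulation
amplitude.

They are not fully independent, however.  The sampling variance of a
windowed correlation is ≈ `(1−ρ²)²/w`, so the DFC-variance *estimate*
retains a weak dependence on the static level, and large modulation
amplitudes inflate the static-correlation estimator's variance.  Two
consequences, both verified empirically during design:

* the "static shift leaves DFC variance unchanged" property holds for
  moderate static shifts and is tested there;
* at 135 timepoints no single cohort makes *both* families cleanly
  separable.  The canonical analysis therefore evaluates each family on
  the scenario it is meant to detect (`fcclust.pipeline.study_scenario`):
  an SFC scenario (`sfc_effect = 0.35`) and a DFC scenario
  (`dfc_effect = 1.5`, `base_corr = 0.1`, period 60–90 TR).  These
  are the conditions under which the drivers, the acceptance script and
  the qualitative comparisons run.

Covariates (age, gender, motion) follow the cohort demographics
(per-group age means/SDs and sex ratios; motion is a half-normal
unit-scale score).  By default they carry no effect on features; the
`covariate_confound` switch injects an age slope into a quarter of the
features so covariate adjustment can be tested under both null and
confounded regimes.  The motion distribution is not reported for the
original cohort; the unit-scale choice is ours.

Everything is driven by one integer seed; identical configurations and
seeds give bit-identical cohorts.

## Feature extraction

Static FC is `np.corrcoef` per subject; zero-variance series raise an
error naming the ROI.  The sliding-window stride is fixed at one
timepoint; windows with zero variance yield flagged (NaN) correlations
excluded from the variance.  DFC variance is the sample variance
(ddof 1) of the windowed correlations; the all-pairs implementation uses
windowed running sums with rank-one Gram updates and is tested for exact
agreement with the scalar route.

**Adaptive window length.**  The stationarity criterion is: for
candidate lengths ascending through 20–60 timepoints (step 5), run the
Dickey–Fuller test (constant, no trend) on every window of the series
and accept the first length at which ≥ 80 % of windows reject the
unit-root null at α = 0.05.  Lag order defaults to zero because 20-point
windows leave no room for lagged differences — with augmentation the
test has essentially no power at this window size (rejection on white
noise drops from ~97 % to ~28 % per window).  The 80 % acceptance
fraction makes the decision stable across realizations of white-noise
series while random walks still fail every candidate (≈ 6 % of windows
reject).  A cohort uses one global window length — the median of
per-series lengths over a deterministic subsample of 12 series — so DFC
features stay commensurable across subjects; per-series and fixed-length
modes remain available.  All constants sit on `WindowSpec`.

**Feature selection.**  The multivariate covariance-adjusted test is
implemented as mass-univariate ANCOVA: for each candidate feature, the
partial F-test of the group term in
`feature ~ group + age + gender + motion`, computed for all features at
once by projecting out the reduced and full design matrices (QR), and
cross-checked against statsmodels OLS.  Features are ranked by p-value
(ties break by ascending feature index) and the top k = 100 kept, in
ascending-p order.  Ranking is the only role the test plays, which is
why the mass-univariate form suffices; an optional significance gate
(`alpha_gate`) and an optional Fisher-z transform of correlations are
off by default.  A rank-deficient covariate design raises an error
naming the collinear column.

## DBSCAN and radius selection

Classical density connectivity with Euclidean distances (O(n²) without
spatial indexing — cohorts are ~132 points).  A point's ε-neighborhood
*includes the point itself*; a core point has ≥ MinPts neighbors;
border points attach to the first cluster whose core point reaches them
in scan order (row order); outliers get label 0 and clusters are
numbered 1..K in discovery order.  MinPts defaults to 10.

Radius selection mirrors the two-stage recipe: the k-distance graph
(k = MinPts, distance to the k-th *other* point, sorted descending)
gives an initial ε estimate at the curve's elbow — automated as the
point of maximum perpendicular distance to the endpoint chord after
normalizing both axes to [0, 1], ties breaking to the middle index, a
deterministic stand-in for visual inspection.  DBSCAN then runs on a
uniform grid of 200 ε values in (0, 2·ε₀]; the number of clusters is
piecewise constant in ε, and the widest constant step with ≥ 2 clusters
wins (a huge ε trivially yields one cluster and would otherwise always
win; ties prefer smaller ε).  The chosen ε is the step's midpoint.  If
no step reaches two clusters the widest one-cluster step is used, with
a warning.

## OPTICS, extraction and the separation index

Core distance is the distance to the MinPts-th nearest neighbor
*counting the point itself*, undefined (`inf`) beyond the generating
distance; reachability of p is the minimum of
`max(core_dist(s), d(s, p))` over processed core points s.  The seed
queue pops the smallest current reachability, ties to the lowest point
index, so the ordering is deterministic.  The including-self convention
is stated explicitly because implementations differ by one; it is the
convention under which thresholding the reachability plot at `t`
partitions core points exactly like DBSCAN at `ε = t` with the same
MinPts — a property the test suite checks on random instances.  MinPts
defaults to 15 (mid recommended band), and the generating distance
defaults to the maximum pairwise distance, which is always "large
enough"; enlarging it further provably changes nothing.

**Threshold extraction.**  Scanning the ordering: reach > t with
core_dist ≤ t opens a new cluster, reach ≤ t joins the current one,
otherwise the point is an outlier.  The automatic threshold evaluates
every distinct threshold regime (intervals between consecutive sorted
reachability/core-distance values) and picks the midpoint of the widest
interval achieving the maximal count of *substantial* clusters — at
least MinPts members (a genuine density cluster cannot be smaller; tiny
"clusters" are ordering artifacts) — among regimes keeping at least 90 %
of points clustered (relaxed to 50 %, then to all regimes, if nothing
qualifies; a cut that discards most of the cohort does not describe its
structure).  This matters when cluster densities differ: the single
widest gap in the sorted reachability values can fall between two *peak
heights*, cutting only the tallest peak and merging everything else —
observed on the DFC scenario, where a perfect four-block ordering was
otherwise extracted as two clusters.  The simpler widest-gap rule
remains available (`rule="widest_gap"`).  ξ-steepness extraction is out
of scope.

**Separation index.**  For cluster k occupying a contiguous run of the
ordering, the left peak is its opening point and the right peak is the
next cluster's opening point (for the last cluster: the first position
past the run, if any).  `S_k` is the mean of the two peak heights over
the mean of the reachability values strictly between them; the final
index is the mean over clusters.  An infinite peak value (the start of
the plot) falls back to the opposite peak, logged; clusters with empty
valleys are skipped with a warning.  The index is scale-invariant and
strictly increases as valleys deepen, both under test.

## R-CLAN

Signal power S is the mean squared value of the clean feature matrix;
noise power for a target SNR is `N = S / 10^(SNR/10)`; corruption adds
i.i.d. `N(0, N)` to every cell of the *original* matrix at each rung.
Fresh per-rung corruption (rather than accumulating noise) is the
default because it makes each rung's nominal SNR exact; a cumulative
mode that tops up the noise variance is available behind a flag.
Realized SNR is calibrated to ±0.05 dB in the mean over draws.

The ladder starts at 100 dB, descends 1 dB per rung and stops at the
first rung whose purity differs from the baseline purity at the start —
"structure changed" is operationalized exactly as a changed overall
purity value, not any relabeling.  Clustering parameters (ε, MinPts,
threshold) are frozen from the clean data by default, isolating the
noise sensitivity of the clustering from that of parameter selection;
refitting per rung is one switch away.  The floor is 0 dB with explicit
censoring semantics, and a clusterer failure at a rung terminates the
ladder loudly.  One noise draw per rung from a single seeded stream is
the default (the draw-to-draw variance of the terminating SNR can be
reduced by majority-vote purity over replicates).

Two properties worth spelling out.  First, the whole ladder is exactly
invariant to rescaling the feature matrix — noise draws, selected
parameters and assignments scale together — which the tests assert
trace-for-trace.  Second, the terminating SNR *decreases* when
within-group dispersion grows: the automatically selected ε/threshold
scale with the data's own dispersion, giving proportionally more
absolute room for noise, while signal power is dominated by the constant
connectivity offset.  Robustness comparisons should therefore vary the
cluster *margin* (centroid separation) at fixed dispersion — doubling
the separation strictly lowers the terminating SNR — rather than read
the dispersion knob as "difficulty".

## Purity

Clusters are matched to groups one-to-one by maximizing total agreement
(Hungarian assignment on the contingency table); a greedy majority
matcher exists for sensitivity analysis.  Exactly one success rate per
group is reported, as a percentage of the full group size; outliers
count in the denominator and never as successes.  If the cluster count
differs from the group count, purity is still computed (extra clusters
unmatched, missing groups at 0 %) with a prominent warning.

## Problem sizes and determinism

The test suite runs the oracle-equivalence checks on 200 random
instances (n ≤ 40, d = 2), the cohort-level checks on 20 seeds of the
default 132 × 100 cohort, the R-CLAN ordering checks on 20 seeds × two
separations, and the time-series recovery checks on 10 seeds of
40-subject × 200-ROI cohorts — sizes at which the full suite completes
in a few minutes on one CPU while every qualitative claim is exercised
at the study's feature dimensionality.  The acceptance script runs the
two full 132-subject scenarios end to end.  Every random quantity
derives from explicit integer seeds; the end-to-end report is
byte-identical across repeated runs, which is itself under test.

## Limitations

The generator makes no attempt at scanner physics, motion artifacts,
spatial structure, hemodynamics or autocorrelated noise: ROI series are
white, effects are confined to designated pairs, and group geometry is
exactly simplex or linear.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its qualitative orderings
(OPTICS ≥ DBSCAN under density inhomogeneity; dynamic features more
distinct and more robust in their scenario) emerge for the documented
mechanistic reasons — not that the original clinical effect sizes or
success rates are reproduced.  Sliding-window correlation variance is an
intrinsically noisy statistic at ~135 timepoints; its group separability
here required larger modulation amplitudes than static shifts, and real
dynamic-connectivity effects need not be of that form.  Rician or
colored noise models and ξ-based OPTICS extraction are explicitly out of
scope.
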