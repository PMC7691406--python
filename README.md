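# fcclust

Unsupervised stratification of diagnostic groups from resting-state fMRI
functional-connectivity features, using density-based clustering with
fully automated parameter selection and two complementary robustness
protocols.

The package is aimed at neuroimaging researchers who want to ask: *do
connectivity features separate clinical groups without ever seeing the
labels, and how fragile is that separation?*  It reimplements, as a
tested pipeline over synthetic cohorts, an analysis strategy for
cognitive-impairment staging (healthy controls, early and late mild
cognitive impairment, Alzheimer's disease):

1. **Connectivity features.**  Static functional connectivity (SFC) is
   the whole-scan Pearson correlation between ROI time series, one value
   per ROI pair.  Dynamic functional connectivity is summarized by the
   variance over time of sliding-window Pearson correlations (windows
   overlap, stride one timepoint); the window length is chosen as the
   shortest length at which windows pass an augmented Dickey–Fuller
   stationarity screen.  Candidate features are ranked by a
   covariate-adjusted group F-test (`feature ~ group + age + gender +
   motion`) and the 100 smallest-p features are kept, giving a
   132 × 100 subjects × features matrix per feature family.
2. **DBSCAN** with the radius chosen by the *epsilon plot*: an initial
   estimate from the elbow of the k-distance graph, then DBSCAN evaluated
   on a grid of ε from 0 to twice that estimate; the cluster count that
   is stable over the widest ε range wins, and the midpoint of that range
   is the final ε.
3. **OPTICS**, which orders points by reachability distance
   `max(core_dist(s), d(s, p))`; valleys of the reachability plot are
   clusters.  A data-driven threshold cuts the plot, and each cluster's
   distinctness is scored by the **separation index**

   `S_k = ((RP(i) + RP(j)) / 2) / mean(RP(i+1), …, RP(j−1))`,

   the ratio of mean bounding-peak height to mean valley height; the
   final index averages S_k over clusters.
4. **R-CLAN** (recursive clustering using additive noise): white
   Gaussian noise is added to the clean feature matrix along a
   descending SNR ladder (100 dB, −1 dB per rung, `SNR = 10·log10(S/N)`
   with S the mean squared feature value).  The ladder stops at the
   first rung whose cluster purity differs from baseline; that
   *terminating SNR* measures robustness — the lower, the more noise the
   configuration tolerates.

Cluster purity matches clusters to diagnostic groups one-to-one
(optimal assignment on the contingency table) and reports the percentage
of correctly placed subjects, with outliers counted in the denominator.

Because the original clinical data is access-restricted, the package
ships a synthetic cohort generator (`fcclust.synthetic`) that emulates
the study's structure: 132 subjects (35/34/34/29 per group), 200 ROIs,
135 retained timepoints, group-shifted static correlation, group-shifted
correlation-modulation amplitude, demographically anchored covariates
and group-dependent dispersion.  Every stage of the pipeline is tested
against this generator.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/`:

```sh
python analysis/01_build_cohort_features.py   # simulate + extract features
python analysis/02_cluster_and_score.py       # DBSCAN + OPTICS + purity
python analysis/03_robustness_ladder.py       # R-CLAN SNR ladders
```

The second driver prints (seed 7):

```
scenario method  n_clusters  n_outliers  overall_purity  group_mean_purity  param  separation_index
     sfc dbscan           4           0           100.0              100.0 1.1889               NaN
     sfc optics           4           0           100.0              100.0 1.2176            1.3339
     dfc dbscan           4           0           100.0              100.0 0.8188               NaN
     dfc optics           4           0           100.0              100.0 0.8411            2.8560
```

Both methods recover exactly the four diagnostic groups from either
feature family (`param` is the selected ε for DBSCAN and the extraction
threshold for OPTICS).  The DFC-variance reachability plot is markedly
better separated than the SFC one (separation index 2.86 vs 1.33):
its valleys sit further below its peaks, so threshold extraction has
more margin.  The third driver prints the terminating SNRs:

```
scenario method  baseline_purity  terminating_snr_db  rungs
     sfc dbscan            100.0                23.0     78
     sfc optics            100.0                24.0     77
     dfc dbscan            100.0                24.0     77
     dfc optics            100.0                21.0     80
```

OPTICS on DFC-variance features is the most robust configuration
(purity unchanged down to 21 dB — roughly equal parts signal and double
the noise of any other configuration), mirroring the ordering the
separation index suggests.

The same machinery is scriptable through the `fcclust` CLI
(`fcclust simulate`, `fcclust features`, `fcclust cluster-dbscan`,
`fcclust cluster-optics`, `fcclust rclan`, `fcclust report`) or directly
from Python:

```python
from fcclust import SyntheticCohortConfig, generate_feature_cohort, purity
from fcclust.pipeline import cluster_optics_auto

fm, labels = generate_feature_cohort(SyntheticCohortConfig(seed=0))
outcome = cluster_optics_auto(fm, labels)
print(outcome.clustering.n_clusters)        # 4
print(outcome.report.overall_purity)        # 100.0
```

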