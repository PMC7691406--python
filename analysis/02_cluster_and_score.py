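"""Cluster both study feature matrices with DBSCAN and OPTICS.

For each scenario (SFC / DFC-variance): DBSCAN with the k-distance-elbow
plus epsilon-plot radius selection, and OPTICS with reachability-gap
threshold extraction, each scored for cluster purity against the
generating diagnostic groups.  The OPTICS reachability plot also yields
the per-cluster separation index.  Writes:

  results/clustering_summary.tsv   cluster counts, purities, indices
  results/purity_<scenario>.json   per-group success-rate tables
  results/epsplot_<scenario>.tsv   (eps, n_clusters) for replotting
  results/reachability_<scenario>.tsv  ordered reachability profiles

Run after 01:  python analysis/02_cluster_and_score.py
"""
import sys
from pathlib import Path

import pandas as pd

from fcclust import io as fio
from fcclust.pipeline import cluster_dbscan_auto, cluster_optics_auto

COHORTS = Path("scratch/cohorts")
RESULTS = Path("results")


def main() -> None:
    if not COHORTS.exists():
        print("run analysis/01_build_cohort_features.py first", file=sys.stderr)
        return 1
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for short in ("sfc", "dfc"):
        fm = fio.read_feature_matrix(COHORTS / f"features_{short}.tsv")
        labels = fio.read_labels(COHORTS / f"labels_{short}.tsv")
        fio.check_alignment(fm, labels)

        db = cluster_dbscan_auto(fm, labels)
        op = cluster_optics_auto(fm, labels)
        fio.write_epsilon_plot(db.eps_plot, RESULTS / f"epsplot_{short}.tsv")
        fio.write_reachability(op.profile, fm.subject_ids,
                               RESULTS / f"reachability_{short}.tsv")
        fio.write_json(
            {"dbscan": db.report, "optics": op.report,
             "separation_index": op.separation},
            RESULTS / f"purity_{short}.json",
        )
        for method, out in (("dbscan", db), ("optics", op)):
            rows.append({
                "scenario": short, "method": method,
                "n_clusters": out.clustering.n_clusters,
                "n_outliers": out.clustering.n_outliers,
                "overall_purity": round(out.report.overall_purity, 2),
                "group_mean_purity": round(out.report.group_mean, 2),
                "param": round(out.eps_plot.chosen_eps, 4) if out.eps_plot
                         else round(out.threshold, 4),
                "separation_index": round(out.separation.mean_index, 4)
                                    if out.separation else None,
            })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "clustering_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote clustering_summary.tsv, purity_*.json, epsplot_*.tsv, "
          f"reachability_*.tsv under {RESULTS}/")


if __name__ == "__main__":
    sys.exit(main())
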