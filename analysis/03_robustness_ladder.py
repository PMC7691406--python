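"""R-CLAN: additive-noise robustness of every method/feature combination.

Starting from 100 dB, white Gaussian noise is added to each clean study
feature matrix at 1 dB-lower SNR per rung (clustering parameters frozen
from the clean data) until cluster purity first changes; that rung's SNR
is the robustness statistic — lower means more noise tolerated.  Writes
results/rclan_summary.tsv and per-combination traces
results/rclan_<scenario>_<method>.json.

Run after 01:  python analysis/03_robustness_ladder.py
"""
import sys
from pathlib import Path

import pandas as pd

from fcclust import RCLANConfig
from fcclust import io as fio
from fcclust.pipeline import rclan_for_method

COHORTS = Path("scratch/cohorts")
RESULTS = Path("results")
SEED = 7


def main() -> None:
    if not COHORTS.exists():
        print("run analysis/01_build_cohort_features.py first", file=sys.stderr)
        return 1
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for short in ("sfc", "dfc"):
        fm = fio.read_feature_matrix(COHORTS / f"features_{short}.tsv")
        labels = fio.read_labels(COHORTS / f"labels_{short}.tsv")
        for method in ("dbscan", "optics"):
            res = rclan_for_method(fm, labels, method, RCLANConfig(seed=SEED))
            fio.write_rclan(res, RESULTS / f"rclan_{short}_{method}.json")
            rows.append({
                "scenario": short, "method": method,
                "baseline_purity": round(res.baseline_purity, 2),
                "terminating_snr_db": res.terminating_snr
                                      if not res.censored else "censored",
                "rungs": len(res.trace),
            })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "rclan_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nlower terminating SNR = clustering withstands more noise")


if __name__ == "__main__":
    sys.exit(main())
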