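"""R-CLAN: robustness of a clustering configuration under additive noise.

White Gaussian noise is added to the feature matrix along a descending
SNR ladder (default 100 dB down in 1 dB steps).  SNR follows the
conventional definition ``SNR = 10 * log10(S / N)`` with signal power
``S`` the mean squared value of the original features and noise power
``N`` the variance of the added noise.  At each rung the *original*
matrix is corrupted afresh at the target SNR, the (fixed-parameter)
clusterer is re-run, and cluster purity against the ground-truth groups
is recomputed.  The ladder terminates at the first rung whose purity
differs from the baseline purity at the starting SNR; that rung's SNR is
the robustness statistic — the lower, the more noise the configuration
tolerates.  Reaching the floor without a change is reported as censored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .containers import ClusteringResult, FeatureMatrix, GroupLabels
from .evaluation import purity

log = logging.getLogger(__name__)

Clusterer = Callable[[np.ndarray], ClusteringResult]


@dataclass
class RCLANConfig:
    snr_start: float = 100.0  # dB
    snr_step: float = 1.0     # dB per iteration
    snr_floor: float = 0.0    # dB; censoring point
    replicates_per_snr: int = 1
    seed: int = 0
    cumulative: bool = False  # add noise on top of the previous rung instead
                              # of corrupting the original at each target SNR

    def __post_init__(self) -> None:
        if self.snr_step <= 0:
            raise ValueError("snr_step must be positive")
        if self.snr_start <= self.snr_floor:
            raise ValueError("snr_start must exceed snr_floor")
        if self.replicates_per_snr < 1:
            raise ValueError("replicates_per_snr must be >= 1")


@dataclass
class RCLANResult:
    trace: list[tuple[float, float]]  # (snr_db, purity percent)
    terminating_snr: float | None     # None when censored at the floor
    censored: bool
    baseline_purity: float
    failure: str | None = field(default=None)  # clusterer error, if any


def signal_power(values: np.ndarray) -> float:
    """Mean squared value over all matrix entries."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty matrix")
    s = float(np.mean(v**2))
    if s == 0:
        raise ValueError("all-zero matrix: SNR undefined")
    return s


def noise_power_for_snr(s: float, snr_db: float) -> float:
    """Noise variance N with 10*log10(S/N) equal to the target SNR."""
    if s <= 0:
        raise ValueError("signal power must be positive")
    return s / 10.0 ** (snr_db / 10.0)


def corrupt_with_noise(
    fm: FeatureMatrix, snr_db: float, rng: np.random.Generator
) -> FeatureMatrix:
    """Fresh copy of ``fm`` with i.i.d. zero-mean Gaussian noise at the
    variance that realizes the target SNR; the input is untouched."""
    n = noise_power_for_snr(signal_power(fm.values), snr_db)
    noisy = fm.values + rng.normal(0.0, np.sqrt(n), fm.values.shape)
    return FeatureMatrix(
        values=noisy, feature_ids=list(fm.feature_ids), subject_ids=list(fm.subject_ids)
    )


def r_clan(
    fm: FeatureMatrix,
    truth: GroupLabels,
    clusterer: Clusterer,
    config: RCLANConfig | None = None,
) -> RCLANResult:
    """Run the descending-SNR ladder and report the terminating SNR.

    ``clusterer`` must map a feature matrix (numpy array) to a
    :class:`ClusteringResult` deterministically; its parameters are
    typically frozen from the clean data so the ladder isolates the noise
    sensitivity of the clustering itself.  With ``replicates_per_snr > 1``
    the rung purity is the majority (modal) purity over replicates.
    """
    config = config or RCLANConfig()
    rng = np.random.default_rng(config.seed)
    s_power = signal_power(fm.values)
    state = {"values": fm.values, "noise_var": 0.0}  # cumulative-mode carry

    def rung_purity(snr_db: float) -> float:
        n_target = noise_power_for_snr(s_power, snr_db)
        purities = []
        for _ in range(config.replicates_per_snr):
            if config.cumulative:
                extra = max(n_target - state["noise_var"], 0.0)
                noisy = state["values"] + rng.normal(0.0, np.sqrt(extra), fm.values.shape)
                state["values"] = noisy
                state["noise_var"] = max(n_target, state["noise_var"])
            else:
                noisy = fm.values + rng.normal(0.0, np.sqrt(n_target), fm.values.shape)
            result = clusterer(noisy)
            purities.append(purity(result, truth).overall_purity)
        vals, counts = np.unique(purities, return_counts=True)
        return float(vals[np.argmax(counts)])

    trace: list[tuple[float, float]] = []
    snr = config.snr_start
    try:
        baseline = rung_purity(snr)
    except Exception as exc:  # clusterer failure at the very first rung
        log.error("clusterer failed at the baseline rung: %s", exc)
        return RCLANResult(
            trace=[], terminating_snr=config.snr_start, censored=False,
            baseline_purity=float("nan"), failure=str(exc),
        )
    trace.append((snr, baseline))
    while snr - config.snr_step >= config.snr_floor - 1e-9:
        snr = snr - config.snr_step
        try:
            p = rung_purity(snr)
        except Exception as exc:
            log.error("clusterer failed at %.1f dB; treated as a structure change", snr)
            trace.append((snr, float("nan")))
            return RCLANResult(
                trace=trace, terminating_snr=snr, censored=False,
                baseline_purity=baseline, failure=str(exc),
            )
        trace.append((snr, p))
        if p != baseline:
            return RCLANResult(
                trace=trace, terminating_snr=snr, censored=False, baseline_purity=baseline
            )
    log.info("R-CLAN reached the %.1f dB floor without a purity change", config.snr_floor)
    return RCLANResult(
        trace=trace, terminating_snr=None, censored=True, baseline_purity=baseline
    )
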