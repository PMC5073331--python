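"""Spike- and burst-timing irregularity statistics.

* CV of the interspike intervals (per electrode, averaged over the active
  set): standard deviation / mean; 0 for a clock-like train, 1 for Poisson.
* Fano factor of spike counts in sliding 5 s windows (1 s step), averaged
  over active electrodes: variance / mean of the window counts.
* CV of the interburst intervals.
* IR, a burst-rate-independent irregularity measure: the mean absolute
  natural-log ratio of consecutive interburst intervals. Multiplying all
  intervals by a constant leaves IR (and CV) unchanged.

Sample (n-1) standard deviations are used throughout; with the small burst
counts of a 20-minute recording the bias of the n-denominator would not be
negligible.
"""

from __future__ import annotations

import numpy as np

from .types import BurstTrain, SpikeTrainSet

__all__ = ["cv", "fano_factor", "ir_metric", "cv_ibi", "cv_isi_network"]


def cv(intervals) -> float:
    """Coefficient of variation (sample SD / mean); NaN for < 2 intervals."""
    x = np.asarray(intervals, dtype=np.float64)
    if x.size < 2:
        return np.nan
    mean = x.mean()
    if mean <= 0:
        raise ValueError("interval mean must be positive")
    if np.all(x == x[0]):  # exact zero for perfectly regular intervals
        return 0.0
    return float(x.std(ddof=1) / mean)


def cv_isi_network(spikes: SpikeTrainSet) -> float:
    """Per-electrode CV of the interspike intervals, averaged over the
    electrodes that have at least two intervals; NaN if none do."""
    vals = [cv(np.diff(t)) for t in spikes.trains.values() if t.size >= 3]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan


def fano_factor(spikes: SpikeTrainSet, window: float = 5.0,
                step: float = 1.0) -> float:
    """Fano factor of windowed spike counts, averaged over electrodes.

    Counts are taken in ``window``-long segments slid by ``step`` (the
    windows overlap; the induced correlation between segments is part of
    the statistic's definition here). Electrodes with no spikes are
    excluded (zero mean leaves the ratio undefined).
    """
    if spikes.duration < window:
        return np.nan
    starts = np.arange(0.0, spikes.duration - window + 1e-9, step)
    ffs = []
    for t in spikes.trains.values():
        if t.size == 0:
            continue
        counts = (np.searchsorted(t, starts + window)
                  - np.searchsorted(t, starts)).astype(np.float64)
        mean = counts.mean()
        if mean == 0:
            continue
        ffs.append(counts.var(ddof=1) / mean)
    return float(np.mean(ffs)) if ffs else np.nan


def ir_metric(ibis) -> float:
    """Rate-independent burst irregularity: mean |ln(IBI_{i+1} / IBI_i)|.

    0 for perfectly periodic bursting; 2 ln 2 for iid exponential
    intervals. NaN for fewer than two intervals.
    """
    x = np.asarray(ibis, dtype=np.float64)
    if x.size < 2:
        return np.nan
    if np.any(x <= 0):
        raise ValueError("all interburst intervals must be positive")
    return float(np.mean(np.abs(np.log(x[1:] / x[:-1]))))


def cv_ibi(bursts: BurstTrain) -> float:
    """CV of the interburst intervals; NaN with fewer than 3 bursts."""
    return cv(bursts.ibis)
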