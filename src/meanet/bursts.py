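"""Network-burst analysis.

Three parallel views of the pooled activity of a culture:

* a two-step ISI rule labels each spike background vs burst-candidate
  (per-electrode ISIs against theta_1 = 100 ms, then pooled-train ISIs
  against theta_2 = 5 ms);
* the spike-density trace sums a unit-amplitude Gaussian (sigma = 50 ms)
  over every spike on the active electrodes;
* network bursts are the intervals where the density exceeds 10 Hz
  (referenced to 60 active channels and scaled proportionally with the
  actual active count), with duration, size (density area over the burst
  divided by the single-spike kernel area) and interburst intervals.

`culture_metrics` collects the per-recording statistic vector.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import (BACKGROUND, BURST_CANDIDATE, BurstTrain, CultureMetrics,
                    NetworkBurst, SpikeDensity, SpikeLabeling, SpikeTrainSet)

__all__ = [
    "label_background",
    "spike_density",
    "detect_network_bursts",
    "culture_metrics",
]


def _isolated(times: np.ndarray, theta: float) -> np.ndarray:
    """Boolean mask: both pre- and post-ISI exceed theta (edges: missing
    ISI counts as infinite)."""
    n = times.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    pre = np.empty(n)
    post = np.empty(n)
    pre[0] = np.inf
    post[-1] = np.inf
    if n > 1:
        d = np.diff(times)
        pre[1:] = d
        post[:-1] = d
    return (pre > theta) & (post > theta)


def label_background(spikes: SpikeTrainSet, theta1: float = 0.100,
                     theta2: float = 0.005) -> SpikeLabeling:
    """Two-step background / burst-candidate separation.

    Step 1 (per electrode): a spike whose pre- and post-ISI both exceed
    theta1 is background. Step 2: the surviving spikes of all electrodes
    are pooled into one train; a spike whose pooled pre- and post-ISI both
    exceed theta2 is also background. Everything else is a burst candidate.
    """
    labels: dict[int, np.ndarray] = {}
    stage: dict[int, np.ndarray] = {}
    pooled_times: list[np.ndarray] = []
    pooled_ref: list[tuple[int, np.ndarray]] = []

    for eid, t in spikes.trains.items():
        lab = np.full(t.size, BURST_CANDIDATE, dtype=np.int8)
        stg = np.zeros(t.size, dtype=np.int8)
        iso = _isolated(t, theta1)
        lab[iso] = BACKGROUND
        stg[iso] = 1
        labels[eid] = lab
        stage[eid] = stg
        remaining = np.nonzero(~iso)[0]
        if remaining.size:
            pooled_times.append(t[remaining])
            pooled_ref.append((eid, remaining))

    if pooled_times:
        times = np.concatenate(pooled_times)
        eids = np.concatenate([np.full(idx.size, eid)
                               for eid, idx in pooled_ref])
        idxs = np.concatenate([idx for _, idx in pooled_ref])
        order = np.argsort(times, kind="stable")
        iso2 = _isolated(times[order], theta2)
        for k in np.nonzero(iso2)[0]:
            eid = int(eids[order[k]])
            j = int(idxs[order[k]])
            labels[eid][j] = BACKGROUND
            stage[eid][j] = 2
    return SpikeLabeling(labels=labels, stage=stage)


def spike_density(spikes: SpikeTrainSet, sigma: float = 0.050,
                  amplitude: float = 1.0, dt: float = 0.001) -> SpikeDensity:
    """Gaussian spike-density trace over all spikes of the train set.

    Each spike contributes amplitude * exp(-(t - tau)^2 / (2 sigma^2)).
    Spikes are binned to the grid (dt << sigma, so the discretization is
    negligible) and convolved with the kernel truncated at +/- 5 sigma
    (truncation error < 1e-6 of the kernel mass).
    """
    n = int(round(spikes.duration / dt)) + 1
    times = np.arange(n) * dt
    all_spikes = spikes.all_spikes()
    if all_spikes.size == 0:
        return SpikeDensity(times=times, values=np.zeros(n), sigma=sigma,
                            amplitude=amplitude, dt=dt)
    counts = np.bincount(
        np.clip(np.round(all_spikes / dt).astype(np.int64), 0, n - 1),
        minlength=n).astype(np.float64)
    half = int(np.ceil(5.0 * sigma / dt))
    k = np.arange(-half, half + 1) * dt
    kernel = amplitude * np.exp(-0.5 * (k / sigma) ** 2)
    values = sps.oaconvolve(counts, kernel, mode="same")
    return SpikeDensity(times=times, values=values, sigma=sigma,
                        amplitude=amplitude, dt=dt)


def detect_network_bursts(density: SpikeDensity, threshold: float = 10.0,
                          n_active: int | None = None,
                          reference_channels: int = 60,
                          scale_with_active: bool = True,
                          ibi_convention: str = "gap") -> BurstTrain:
    """Threshold-crossing burst detection on the spike-density trace.

    The nominal threshold (10 Hz) is referenced to 60 active channels; with
    ``scale_with_active`` it is scaled by ``n_active / reference_channels``
    so per-electrode sensitivity stays constant as cultures mature. A burst
    runs from an upward crossing to the fall back below threshold (sub-bin
    onset/offset by linear interpolation); a burst already in progress at
    the recording edges is discarded. Burst size is the density area over
    the burst divided by the single-spike kernel area.
    """
    thr = threshold
    if scale_with_active:
        if n_active is None:
            raise ValueError("n_active required when scale_with_active")
        thr = threshold * n_active / reference_channels

    v = density.values
    t = density.times
    above = v > thr
    edges = np.diff(above.astype(np.int8))
    rises = np.nonzero(edges == 1)[0] + 1   # first index above
    falls = np.nonzero(edges == -1)[0] + 1  # first index back below
    # discard incomplete bursts at the recording edges
    if above.size and above[0] and falls.size:
        falls = falls[1:]
    if rises.size and falls.size and rises[-1] >= falls[-1]:
        rises = rises[:-1]
    elif rises.size and not falls.size:
        rises = rises[:0]

    bursts: list[NetworkBurst] = []
    kernel_area = density.kernel_area
    for r, f in zip(rises, falls):
        # linear interpolation of the crossing times
        onset = t[r - 1] + (thr - v[r - 1]) / (v[r] - v[r - 1]) * density.dt
        offset = t[f - 1] + (v[f - 1] - thr) / (v[f - 1] - v[f]) * density.dt
        area = float(np.trapezoid(v[r - 1:f + 1], t[r - 1:f + 1]))
        bursts.append(NetworkBurst(onset=onset, offset=offset,
                                   size=area / kernel_area))
    return BurstTrain(bursts=bursts, ibi_convention=ibi_convention)


def spikes_in_windows(spikes: SpikeTrainSet, bursts: BurstTrain) -> int:
    """Count spikes falling inside any detected burst window."""
    if bursts.n_bursts == 0:
        return 0
    onsets = bursts.onsets
    offsets = bursts.offsets
    total = 0
    for t in spikes.trains.values():
        if t.size == 0:
            continue
        lo = np.searchsorted(onsets, t, side="right") - 1
        inside = (lo >= 0) & (t <= offsets[np.clip(lo, 0, None)])
        total += int(inside.sum())
    return total


def culture_metrics(spikes: SpikeTrainSet,
                    labeling: SpikeLabeling | None = None,
                    bursts: BurstTrain | None = None,
                    n_active_at_final_div: int | None = None,
                    ) -> CultureMetrics:
    """Assemble the per-recording activity metrics.

    MFR divides the total active-electrode spike count by the recording
    duration and by the number of electrodes active at the final DIV
    (falling back, with the fallback recorded implicitly, to the current
    active count when that reference is unknown). The burst rate is per
    minute; the in-burst percentage is computed both from the detected
    burst windows and from the two-step labels.
    """
    m = CultureMetrics(culture_id=spikes.culture_id,
                       condition=spikes.condition, div=spikes.div)
    m.n_active_electrodes = spikes.n_electrodes
    total = spikes.n_spikes
    norm = n_active_at_final_div or spikes.n_active_at_final_div
    if not norm:
        norm = spikes.n_electrodes
    if norm:
        m.mfr = total / spikes.duration / norm

    if labeling is not None and total:
        m.pct_spikes_burst_labeled = 100.0 * labeling.n_burst_candidates() / total

    if bursts is not None:
        m.burst_rate = bursts.n_bursts / spikes.duration * 60.0
        if total:
            m.pct_spikes_in_bursts = (100.0 * spikes_in_windows(spikes, bursts)
                                      / total)
        if bursts.n_bursts:
            m.mean_burst_duration = float(np.mean(bursts.durations))
            m.mean_burst_size = float(np.mean(bursts.sizes))
        if bursts.ibis.size:
            m.mean_ibi = float(np.mean(bursts.ibis))
    return m
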