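"""Core data containers shared across the analysis stages.

All times are in seconds, voltages in microvolts, rates in Hz unless a
field name says otherwise. Containers are plain dataclasses: the pipeline
passes them between stages and the IO layer serializes them to CSV/HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RawRecording",
    "SpikeTrainSet",
    "GroundTruth",
    "SpikeLabeling",
    "SpikeDensity",
    "NetworkBurst",
    "BurstTrain",
    "CultureMetrics",
    "AutocovarianceResult",
    "GroupComparison",
]


@dataclass
class RawRecording:
    """Multichannel extracellular voltage trace.

    voltage has shape (n_channels, n_samples), in microvolts.
    """

    voltage: np.ndarray
    sampling_rate: float
    channel_ids: list[int]

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.voltage.shape[0]:
            raise ValueError("channel_ids length must match voltage rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GroundTruth:
    """Planted structure of a simulated culture.

    Burst onsets/offsets are the generative windows, before any detection.
    ``truncated`` flags bursts whose span was clipped at the recording end.
    """

    burst_onsets: np.ndarray
    burst_offsets: np.ndarray
    truncated: np.ndarray
    n_background_spikes: int
    n_burst_spikes: int
    spike_times: Optional[dict[int, np.ndarray]] = None
    warning: Optional[str] = None

    @property
    def n_bursts(self) -> int:
        return len(self.burst_onsets)

    @property
    def ibis(self) -> np.ndarray:
        """Planted interburst intervals (offset to next onset)."""
        if self.n_bursts < 2:
            return np.empty(0)
        return self.burst_onsets[1:] - self.burst_offsets[:-1]


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps plus recording metadata."""

    trains: dict[int, np.ndarray]
    duration: float
    culture_id: Optional[str] = None
    condition: Optional[str] = None
    div: Optional[int] = None
    n_active_at_final_div: Optional[int] = None
    dropped_electrodes: dict[int, str] = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean: dict[int, np.ndarray] = {}
        for eid, t in self.trains.items():
            t = np.asarray(t, dtype=np.float64)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"electrode {eid}: timestamps not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"electrode {eid}: timestamps outside [0, duration]"
                )
            clean[int(eid)] = t
        self.trains = clean

    @property
    def electrode_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def firing_rates(self) -> dict[int, float]:
        return {eid: t.size / self.duration for eid, t in self.trains.items()}

    def all_spikes(self) -> np.ndarray:
        """Pooled, sorted spike times across all electrodes."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.trains.values())))


BACKGROUND = 0
BURST_CANDIDATE = 1


@dataclass
class SpikeLabeling:
    """Background / burst-candidate label per spike, per electrode.

    ``labels[eid]`` is an int array aligned with the electrode's train
    (0 = background, 1 = burst candidate); ``stage[eid]`` records which
    step produced a background label (1 or 2; 0 = never labeled background).
    """

    labels: dict[int, np.ndarray]
    stage: dict[int, np.ndarray]

    def n_background(self) -> int:
        return int(sum(np.sum(l == BACKGROUND) for l in self.labels.values()))

    def n_burst_candidates(self) -> int:
        return int(sum(np.sum(l == BURST_CANDIDATE) for l in self.labels.values()))


@dataclass
class SpikeDensity:
    """Gaussian-convolved network spike-density trace on a uniform grid."""

    times: np.ndarray
    values: np.ndarray
    sigma: float
    amplitude: float
    dt: float

    @property
    def kernel_area(self) -> float:
        """Area of one spike's kernel: A * sigma * sqrt(2*pi)."""
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class NetworkBurst:
    onset: float
    offset: float
    size: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BurstTrain:
    """Ordered, non-overlapping network bursts and their interburst intervals."""

    bursts: list[NetworkBurst]
    ibi_convention: str = "gap"  # "gap": offset->next onset; "onset": onset->onset

    def __post_init__(self) -> None:
        ons = self.onsets
        offs = self.offsets
        if np.any(offs <= ons):
            raise ValueError("burst offset must exceed onset")
        if len(self.bursts) > 1 and np.any(ons[1:] < offs[:-1]):
            raise ValueError("bursts overlap or are unordered")

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.bursts])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([b.offset for b in self.bursts])

    @property
    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    @property
    def sizes(self) -> np.ndarray:
        return np.array([b.size for b in self.bursts])

    @property
    def ibis(self) -> np.ndarray:
        if self.n_bursts < 2:
            return np.empty(0)
        if self.ibi_convention == "onset":
            return np.diff(self.onsets)
        return self.onsets[1:] - self.offsets[:-1]


@dataclass
class CultureMetrics:
    """Per-recording statistic vector; NaN marks a metric that could not be
    computed (e.g. burst means of a burstless recording)."""

    culture_id: Optional[str] = None
    condition: Optional[str] = None
    div: Optional[int] = None
    n_active_electrodes: int = 0
    mfr: float = np.nan                 # Hz per active-electrode (final-DIV norm)
    burst_rate: float = np.nan          # bursts per minute
    pct_spikes_in_bursts: float = np.nan
    pct_spikes_burst_labeled: float = np.nan
    mean_burst_duration: float = np.nan  # s
    mean_burst_size: float = np.nan      # spike-equivalents
    mean_ibi: float = np.nan             # s
    cv_isi: float = np.nan
    fano_factor: float = np.nan
    cv_ibi: float = np.nan
    ir: float = np.nan
    autocov_half_width: float = np.nan   # s

    #: metric columns entering the group comparison, in reporting order
    METRIC_FIELDS = (
        "mfr",
        "burst_rate",
        "pct_spikes_in_bursts",
        "mean_burst_duration",
        "mean_burst_size",
        "mean_ibi",
        "cv_isi",
        "fano_factor",
        "cv_ibi",
        "ir",
        "autocov_half_width",
    )


@dataclass
class AutocovarianceResult:
    """Autocovariance curve over signed lags.

    ``lags`` runs symmetrically over [-max_lag, max_lag] in steps of the lag
    bin. The analysis is restricted to 0 < |tau|: the zero-lag entry of
    ``values`` is bridged by neighbor interpolation (so smoothing and
    crossing searches see a continuous curve) while the raw zero-lag
    variance is kept in ``zero_lag_value``; peak searches always exclude
    the zero-lag bin.
    """

    lags: np.ndarray
    values: np.ndarray
    bin_width: float
    half_width: Optional[float] = None
    saturated: bool = False
    per_electrode: Optional[dict[int, np.ndarray]] = None
    zero_lag_value: Optional[float] = None

    @property
    def zero_index(self) -> int:
        return int(np.argmin(np.abs(self.lags)))

    def nonzero_mask(self) -> np.ndarray:
        m = np.ones(self.lags.size, dtype=bool)
        m[self.zero_index] = False
        return m


@dataclass
class GroupComparison:
    """One metric x DIV two-condition test result."""

    metric: str
    div: int
    n_control: int
    n_deficient: int
    median_control: float
    median_deficient: float
    mean_control: float
    mean_deficient: float
    u_statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # "up" (deficient > control), "down", or "none"
    significant: bool
    jb_p_control: float = np.nan
    jb_p_deficient: float = np.nan

    @property
    def stars(self) -> str:
        if self.p_adjusted < 0.01:
            return "**"
        if self.p_adjusted < 0.05:
            return "*"
        return "ns"
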