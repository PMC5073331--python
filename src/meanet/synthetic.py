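"""Synthetic MEA culture generator.

Emulates the statistical structure of developing cortical cultures on a
60-electrode array: homogeneous Poisson background firing per electrode,
network bursts arriving as a gamma renewal process (independent control of
the interburst-interval mean and CV), per-burst electrode recruitment, and
a rise-and-fall within-burst spike envelope. Condition presets encode the
developmental fingerprint of control versus EHMT1-deficient cultures:
reduced firing and bursting early (DIV 13), increased burst-timing
irregularity late (DIV 17).

Optionally renders spike trains into raw voltage (biphasic templates in
Gaussian noise) so the spike-detection stage can be exercised end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .types import GroundTruth, RawRecording, SpikeTrainSet

__all__ = [
    "SimulationConfig",
    "ConditionPreset",
    "default_presets",
    "simulate_culture",
    "simulate_study",
    "synthesize_raw",
    "CONTROL",
    "DEFICIENT",
    "DIVS",
]

CONTROL = "control"
DEFICIENT = "deficient"
DIVS = (10, 13, 15, 17)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one simulated 20-minute MEA recording.

    Parameters
    ----------
    n_electrodes : electrodes on the array (the study's MEAs carry 60).
    duration : recording length in seconds (the study records 20 min).
    background_rate : homogeneous Poisson rate per electrode, Hz.
    burst_ibi_mean, burst_ibi_cv : mean and CV of the gamma renewal
        intervals between network-burst onsets (shape = 1/CV^2,
        scale = mean * CV^2).
    burst_duration_mean, burst_duration_cv : mean and CV of the per-burst
        envelope span (gamma distributed).
    spikes_per_burst_per_electrode : Poisson mean of spikes a recruited
        electrode fires in one burst.
    participation_prob : probability an electrode is recruited per burst.
    within_burst_envelope : "gamma" (rise-and-fall latency profile,
        shape 2) or "uniform".
    seed : RNG seed; identical seed + config gives bit-identical output.
    """

    n_electrodes: int = 60
    duration: float = 1200.0
    background_rate: float = 0.25
    burst_ibi_mean: float = 15.0
    burst_ibi_cv: float = 0.5
    burst_duration_mean: float = 0.5
    burst_duration_cv: float = 0.2
    spikes_per_burst_per_electrode: float = 8.0
    participation_prob: float = 0.7
    within_burst_envelope: str = "gamma"
    envelope_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for name in ("burst_ibi_mean", "burst_duration_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must be in [0, 1]")
        if self.burst_ibi_mean <= self.burst_duration_mean:
            raise ValueError("burst_ibi_mean must exceed burst_duration_mean")
        if self.within_burst_envelope not in ("gamma", "uniform"):
            raise ValueError("within_burst_envelope must be 'gamma' or 'uniform'")


@dataclass(frozen=True)
class ConditionPreset:
    """A (condition, DIV) cell of the study design with its generator config."""

    condition: str
    div: int
    config: SimulationConfig

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, DEFICIENT):
            raise ValueError(f"unknown condition {self.condition!r}")


def default_presets() -> dict[tuple[str, int], ConditionPreset]:
    """Developmental presets for both conditions at DIV 10, 13, 15, 17.

    Control cultures ramp up firing and bursting to a stationary level by
    DIV 15. The deficient presets encode the reported phenotype direction
    and approximate magnitude: at DIV 13, background firing is reduced by
    18% and the burst rate by 40% (hence longer interburst intervals) with
    24% longer bursts; by DIV 15-17 the rates recover, but at DIV 17 the
    interburst-interval CV is markedly higher (0.65 vs 0.40), producing the
    late increase in burst-timing irregularity (CV_IBI, IR, Fano factor).
    """
    control = {
        10: SimulationConfig(background_rate=0.15, burst_ibi_mean=60.0,
                             burst_ibi_cv=0.70, burst_duration_mean=0.40,
                             spikes_per_burst_per_electrode=3.0,
                             participation_prob=0.30),
        13: SimulationConfig(background_rate=0.25, burst_ibi_mean=15.0,
                             burst_ibi_cv=0.50, burst_duration_mean=0.50,
                             spikes_per_burst_per_electrode=8.0,
                             participation_prob=0.70),
        15: SimulationConfig(background_rate=0.30, burst_ibi_mean=10.0,
                             burst_ibi_cv=0.45, burst_duration_mean=0.60,
                             spikes_per_burst_per_electrode=10.0,
                             participation_prob=0.85),
        17: SimulationConfig(background_rate=0.30, burst_ibi_mean=10.0,
                             burst_ibi_cv=0.40, burst_duration_mean=0.60,
                             spikes_per_burst_per_electrode=10.0,
                             participation_prob=0.90),
    }
    # multipliers applied to the control config at each DIV
    deficient = {
        10: dict(background_rate=0.9),
        13: dict(background_rate=0.82, burst_ibi_mean=1.0 / 0.6,
                 burst_duration_mean=1.24),
        15: dict(background_rate=0.95, burst_ibi_mean=1.05),
        17: dict(burst_ibi_cv=0.65 / 0.40),
    }
    presets: dict[tuple[str, int], ConditionPreset] = {}
    for div, cfg in control.items():
        presets[(CONTROL, div)] = ConditionPreset(CONTROL, div, cfg)
        changes = {
            name: getattr(cfg, name) * mult
            for name, mult in deficient[div].items()
        }
        presets[(DEFICIENT, div)] = ConditionPreset(
            DEFICIENT, div, replace(cfg, **changes)
        )
    return presets


def _draw_gamma(rng: np.random.Generator, mean: float, cv: float,
                size: int) -> np.ndarray:
    """Gamma draws parametrized by mean and CV; degenerate at CV = 0."""
    if cv <= 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return rng.gamma(shape, scale, size=size)


def _burst_onsets(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Gamma-renewal burst onset times in [0, duration)."""
    onsets = []
    t = 0.0
    # draw in blocks; expected count + slack
    while True:
        block = _draw_gamma(rng, cfg.burst_ibi_mean, cfg.burst_ibi_cv, 64)
        for iv in block:
            t += iv
            if t >= cfg.duration:
                return np.array(onsets)
            onsets.append(t)


def _envelope_latencies(rng: np.random.Generator, cfg: SimulationConfig,
                        n: int, burst_dur: float) -> np.ndarray:
    """Spike latencies within one burst, in [0, burst_dur]."""
    if cfg.within_burst_envelope == "uniform":
        return rng.uniform(0.0, burst_dur, size=n)
    # gamma rise-and-fall profile with mean at burst_dur/2, rejection-clipped
    shape = cfg.envelope_shape
    scale = burst_dur / (2.0 * shape)
    lat = rng.gamma(shape, scale, size=n)
    for _ in range(100):
        bad = lat > burst_dur
        if not bad.any():
            break
        lat[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
    else:
        lat = np.clip(lat, 0.0, burst_dur)
    return lat


def simulate_culture(config: SimulationConfig,
                     keep_truth_spikes: bool = False) -> SpikeTrainSet:
    """Simulate one culture's spike trains with planted ground truth.

    Background spikes are homogeneous Poisson per electrode; network bursts
    arrive as a gamma renewal process, each recruiting each electrode with
    ``participation_prob``; recruited electrodes fire a Poisson-count volley
    positioned by the within-burst envelope. Bursts whose span would run
    past the recording end are truncated (recorded in the ground truth).

    Returns a :class:`SpikeTrainSet` whose ``ground_truth`` attribute holds
    the planted burst windows, spike-source counts, and any warning.
    """
    rng = np.random.default_rng(config.seed)
    warning = None
    if config.duration < config.burst_ibi_mean:
        warning = (
            f"duration {config.duration} s is shorter than the mean "
            f"interburst interval {config.burst_ibi_mean} s; the recording "
            "may contain no bursts"
        )
        warnings.warn(warning, stacklevel=2)

    onsets = _burst_onsets(rng, config)
    durations = _draw_gamma(rng, config.burst_duration_mean,
                            config.burst_duration_cv, onsets.size)
    offsets = onsets + durations
    truncated = offsets > config.duration
    offsets = np.minimum(offsets, config.duration)

    trains: dict[int, list[np.ndarray]] = {e: [] for e in range(config.n_electrodes)}
    n_burst_spikes = 0
    for onset, offset in zip(onsets, offsets):
        span = offset - onset
        recruited = rng.random(config.n_electrodes) < config.participation_prob
        counts = rng.poisson(config.spikes_per_burst_per_electrode,
                             size=config.n_electrodes)
        counts[~recruited] = 0
        for eid in np.nonzero(counts)[0]:
            lat = _envelope_latencies(rng, config, int(counts[eid]), span)
            trains[int(eid)].append(onset + lat)
            n_burst_spikes += int(counts[eid])

    n_background = 0
    for eid in range(config.n_electrodes):
        n = rng.poisson(config.background_rate * config.duration)
        if n:
            trains[eid].append(rng.uniform(0.0, config.duration, size=n))
            n_background += int(n)

    final: dict[int, np.ndarray] = {}
    truth_spikes: dict[int, np.ndarray] = {}
    for eid, parts in trains.items():
        t = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        final[eid] = t
        if keep_truth_spikes:
            truth_spikes[eid] = t.copy()

    truth = GroundTruth(
        burst_onsets=onsets,
        burst_offsets=offsets,
        truncated=truncated,
        n_background_spikes=n_background,
        n_burst_spikes=n_burst_spikes,
        spike_times=truth_spikes if keep_truth_spikes else None,
        warning=warning,
    )
    return SpikeTrainSet(trains=final, duration=config.duration,
                         ground_truth=truth)


def child_seed(master_seed: int, condition: str, culture_index: int,
               div: int) -> int:
    """Deterministic per-(culture, DIV) sub-seed from one master seed."""
    cond_idx = 0 if condition == CONTROL else 1
    ss = np.random.SeedSequence([int(master_seed), cond_idx,
                                 int(culture_index), int(div)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(
    presets: Union[Mapping[tuple[str, int], ConditionPreset],
                   Sequence[ConditionPreset]],
    n_cultures_per_condition: Union[int, Mapping[str, int]] = None,
    seed: int = 0,
    between_culture_cv: float = 0.3,
) -> list[SpikeTrainSet]:
    """Simulate the longitudinal two-condition study design.

    Each culture keeps its identity across DIVs: it is re-simulated at every
    DIV with the DIV-specific preset, a culture-level activity factor
    (lognormal, CV ``between_culture_cv``) scaling its background rate and
    burst rate at all ages, and a per-(culture, DIV) child seed derived from
    the master seed so any single recording is reproducible in isolation.

    Default group sizes follow the study design: 25 control, 19 deficient.
    """
    if n_cultures_per_condition is None:
        n_per = {CONTROL: 25, DEFICIENT: 19}
    elif isinstance(n_cultures_per_condition, int):
        n_per = {CONTROL: n_cultures_per_condition,
                 DEFICIENT: n_cultures_per_condition}
    else:
        n_per = dict(n_cultures_per_condition)
    if min(n_per.values()) < 2:
        raise ValueError("need at least 2 cultures per condition for group "
                         "statistics")

    if not isinstance(presets, Mapping):
        presets = {(p.condition, p.div): p for p in presets}
    divs = sorted({div for (_, div) in presets})
    for div in divs:
        for cond in (CONTROL, DEFICIENT):
            if (cond, div) not in presets:
                raise ValueError(f"preset missing for {cond}@DIV{div}")

    out: list[SpikeTrainSet] = []
    for cond in (CONTROL, DEFICIENT):
        for i in range(n_per[cond]):
            # culture-level activity factor, shared across DIVs
            fac_seed = np.random.SeedSequence(
                [int(seed), 0 if cond == CONTROL else 1, int(i), 999983])
            fac_rng = np.random.default_rng(fac_seed)
            if between_culture_cv > 0:
                log_sd = np.sqrt(np.log1p(between_culture_cv**2))
                factor = float(fac_rng.lognormal(-0.5 * log_sd**2, log_sd))
            else:
                factor = 1.0
            for div in divs:
                cfg = presets[(cond, div)].config
                cfg = replace(
                    cfg,
                    background_rate=cfg.background_rate * factor,
                    burst_ibi_mean=cfg.burst_ibi_mean / factor,
                    seed=child_seed(seed, cond, i, div),
                )
                sts = simulate_culture(cfg)
                sts.culture_id = f"{cond}-{i:02d}"
                sts.condition = cond
                sts.div = div
                out.append(sts)
    return out


def _biphasic_template(sampling_rate: float, amplitude: float) -> np.ndarray:
    """Biphasic extracellular spike template: sharp negative deflection
    (sigma 0.1 ms) followed by a slower 40% positive rebound (sigma 0.25 ms).
    ``amplitude`` sets the negative-peak magnitude in microvolts."""
    half = int(round(0.002 * sampling_rate))  # +/- 2 ms support
    t = (np.arange(-half, half + 1)) / sampling_rate
    neg = -np.exp(-0.5 * (t / 1.0e-4) ** 2)
    pos = 0.4 * np.exp(-0.5 * ((t - 5.0e-4) / 2.5e-4) ** 2)
    w = neg + pos
    return amplitude * w / np.abs(w.min())


def synthesize_raw(spikes: SpikeTrainSet, waveform_amplitude: float = 50.0,
                   noise_sd: float = 2.0, sampling_rate: float = 10_000.0,
                   dc_offset: float = 0.0,
                   seed: int = 0) -> RawRecording:
    """Render spike trains as raw voltage: biphasic templates added to
    zero-mean Gaussian noise (plus an optional DC offset).

    Overlapping spikes on one channel superpose additively. Ground-truth
    spike times are preserved on the input ``SpikeTrainSet``.
    """
    if sampling_rate < 4000:
        raise ValueError("sampling_rate too low for the ~1 kHz spike template")
    rng = np.random.default_rng(seed)
    n_samples = int(round(spikes.duration * sampling_rate))
    eids = spikes.electrode_ids
    if noise_sd > 0:
        voltage = rng.normal(0.0, noise_sd, size=(len(eids), n_samples))
    else:
        voltage = np.zeros((len(eids), n_samples))
    voltage += dc_offset

    template = _biphasic_template(sampling_rate, waveform_amplitude)
    half = (template.size - 1) // 2
    for row, eid in enumerate(eids):
        for t in spikes.trains[eid]:
            center = int(round(t * sampling_rate))
            lo = max(0, center - half)
            hi = min(n_samples, center + half + 1)
            voltage[row, lo:hi] += template[lo - (center - half):
                                            template.size - (center + half + 1 - hi)]
    return RawRecording(voltage=voltage, sampling_rate=sampling_rate,
                        channel_ids=list(eids))
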