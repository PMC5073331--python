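"""End-to-end study orchestration: simulate -> (detect) -> analyze -> compare.

A :class:`StudyConfig` holds every stage's parameters plus the master seed;
`run_pipeline` executes the stages in order, writes the intermediate
artifacts, and stamps every output with a hash of the configuration so a
rerun with the same config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .autocov import network_autocov
from .bursts import (culture_metrics, detect_network_bursts, label_background,
                     spike_density)
from .detection import DetectionParams, select_active
from .irregularity import cv_ibi, cv_isi_network, fano_factor, ir_metric
from .stats import (compare_study, comparisons_to_table, fingerprint_table,
                    metrics_to_table)
from .synthetic import default_presets, simulate_study
from .types import CultureMetrics, SpikeTrainSet

log = logging.getLogger("meanet")

__all__ = ["AnalysisParams", "StudyConfig", "analyze_culture",
           "run_pipeline", "load_config", "save_config"]


@dataclass(frozen=True)
class AnalysisParams:
    """Every analysis-stage knob with its standard default."""

    # activity selection
    min_rate: float = 0.1            # Hz; active electrode is > this
    max_rate: float = 100.0          # Hz; noise ceiling
    # burst separation / detection
    theta1: float = 0.100            # s, per-electrode background ISI
    theta2: float = 0.005            # s, pooled-train background ISI
    sigma: float = 0.050             # s, density kernel width
    amplitude: float = 1.0           # density kernel amplitude
    density_dt: float = 0.001        # s, density grid step
    burst_threshold: float = 10.0    # Hz at the reference channel count
    reference_channels: int = 60
    scale_with_active: bool = True
    ibi_convention: str = "gap"
    # irregularity
    ff_window: float = 5.0           # s
    ff_step: float = 1.0             # s
    # autocovariance
    max_lag: float = 2.0             # s
    lag_bin: float = 0.001           # s
    smoothing: float = 0.005         # s
    # stats
    fdr_method: str = "by"
    alpha: float = 0.05


@dataclass
class StudyConfig:
    out_dir: str = "study_out"
    seed: int = 0
    n_control: int = 25
    n_deficient: int = 19
    between_culture_cv: float = 0.3
    duration: float | None = None  # override the presets' recording length
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    detection: DetectionParams = field(default_factory=DetectionParams)


def config_hash(config: StudyConfig) -> str:
    """Hash of the scientific parameters (output location excluded)."""
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def save_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)),
                          encoding="utf-8")


def load_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    analysis = AnalysisParams(**raw.pop("analysis", {}))
    detection = DetectionParams(**raw.pop("detection", {}))
    return StudyConfig(analysis=analysis, detection=detection, **raw)


def analyze_culture(spikes: SpikeTrainSet,
                    params: AnalysisParams = AnalysisParams(),
                    n_active_at_final_div: int | None = None,
                    include_autocov: bool = True) -> CultureMetrics:
    """Full per-recording analysis: active-electrode selection, two-step
    labeling, spike density, network-burst detection, and every metric of
    the per-culture statistic vector."""
    try:
        active = select_active(spikes, params.min_rate, params.max_rate)
    except ValueError:
        # silent culture: metrics mostly missing, MFR zero
        m = CultureMetrics(culture_id=spikes.culture_id,
                           condition=spikes.condition, div=spikes.div)
        m.n_active_electrodes = 0
        m.mfr = 0.0
        m.burst_rate = 0.0
        return m
    labeling = label_background(active, params.theta1, params.theta2)
    density = spike_density(active, params.sigma, params.amplitude,
                            params.density_dt)
    bursts = detect_network_bursts(
        density, params.burst_threshold, n_active=active.n_electrodes,
        reference_channels=params.reference_channels,
        scale_with_active=params.scale_with_active,
        ibi_convention=params.ibi_convention)
    m = culture_metrics(active, labeling, bursts,
                        n_active_at_final_div=n_active_at_final_div)
    m.cv_isi = cv_isi_network(active)
    m.fano_factor = fano_factor(active, params.ff_window, params.ff_step)
    m.cv_ibi = cv_ibi(bursts)
    ibis = bursts.ibis
    m.ir = ir_metric(ibis) if ibis.size >= 2 and np.all(ibis > 0) else np.nan
    if include_autocov:
        try:
            ac = network_autocov(active, params.max_lag, params.lag_bin,
                                 params.smoothing)
            m.autocov_half_width = ac.half_width
        except ValueError:
            m.autocov_half_width = np.nan
    return m


def analyze_study(recordings: list[SpikeTrainSet],
                  params: AnalysisParams = AnalysisParams(),
                  include_autocov: bool = True) -> list[CultureMetrics]:
    """Analyze a longitudinal study, normalizing each culture's MFR by its
    active-electrode count at the final DIV."""
    final_div = max(r.div for r in recordings if r.div is not None)
    n_final: dict[str, int] = {}
    for r in recordings:
        if r.div == final_div:
            try:
                active = select_active(r, params.min_rate, params.max_rate)
                n_final[r.culture_id] = active.n_electrodes
            except ValueError:
                n_final[r.culture_id] = 0
    out = []
    for r in recordings:
        m = analyze_culture(r, params,
                            n_active_at_final_div=n_final.get(r.culture_id),
                            include_autocov=include_autocov)
        out.append(m)
    return out


def run_pipeline(config: StudyConfig):
    """Execute the full study: simulate both conditions at all DIVs,
    compute per-culture metrics, and run the group comparison.

    Writes metrics CSV, comparisons CSV, the fingerprint table, and a run
    manifest (version, seed, parameter hash) into ``config.out_dir``.
    Returns ``(metrics_table, comparisons, fingerprint)``.
    """
    from .io import write_metrics  # local import to avoid cycle at module load

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = config_hash(config)

    log.info("simulating study (seed=%d, n=%d/%d)", config.seed,
             config.n_control, config.n_deficient)
    presets = default_presets()
    if config.duration is not None:
        presets = {k: dataclasses.replace(
            p, config=dataclasses.replace(p.config, duration=config.duration))
            for k, p in presets.items()}
    recordings = simulate_study(
        presets,
        {"control": config.n_control, "deficient": config.n_deficient},
        seed=config.seed, between_culture_cv=config.between_culture_cv)
    log.info("simulated %d recordings", len(recordings))

    metrics = analyze_study(recordings, config.analysis)
    table = metrics_to_table(metrics)
    write_metrics(table, out / "metrics.csv", parameter_hash=phash)
    log.info("analyzed %d recordings (%d with bursts)", len(metrics),
             int(np.sum([m.burst_rate > 0 for m in metrics])))

    comparisons = compare_study(table, fdr_method=config.analysis.fdr_method,
                                alpha=config.analysis.alpha)
    ctab = comparisons_to_table(comparisons)
    write_metrics(ctab, out / "comparisons.csv", parameter_hash=phash)
    fp = fingerprint_table(comparisons)
    fp.to_csv(out / "fingerprint.csv")
    (out / "fingerprint.txt").write_text(fp.to_string(), encoding="utf-8")

    manifest = {"package": "meanet", "version": __version__,
                "seed": config.seed, "parameter_hash": phash,
                "n_recordings": len(recordings),
                "config": dataclasses.asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    return table, comparisons, fp
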