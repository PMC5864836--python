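"""End-to-end workflows: validation (vs. manometry) and ambulatory analysis.

Two orchestrations tie the modules together; no computation lives only
here.

* :func:`run_validation_pipeline` mirrors the in-clinic comparison: for a
  multichannel EGG recording and one or more antral pressure channels it
  reports percent-normal slow waves and the EGG-power/motility-index
  correlation under three montage conditions - the traditional electrode
  pair, the highest-SNR pair, and the highest-SNR pair after LMMSE
  artifact removal.
* :func:`run_ambulatory_pipeline` mirrors the free-living analysis:
  artifact removal, per-window features, isolated-meal-aligned normalized
  power, and sleep-aligned dominant frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import artifact as _artifact
from . import manometry as _manometry
from . import spectral as _spectral
from .io import BipolarSignal, EventLog, MultichannelRecording, traditional_pair
from .manometry import CorrelationResult, PressureRecording

__all__ = [
    "PipelineConfig",
    "run_validation_pipeline",
    "run_ambulatory_pipeline",
    "validation_group_stats",
]

CONDITIONS = ("traditional", "best_snr", "best_snr_cleaned")


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis constants in one place; defaults match the standard protocol."""

    analysis_band: tuple[float, float] = _spectral.ANALYSIS_BAND
    signal_band: tuple[float, float] = _spectral.SIGNAL_BAND
    background_band: tuple[float, float] = _spectral.BACKGROUND_BAND
    normal_band: tuple[float, float] = _spectral.NORMAL_BAND
    window_s: float = 240.0
    overlap_frac: float = 0.75
    peak_freq_hz: float = 0.05
    motility_threshold_mmhg: float = 9.0
    alpha: float = 0.01
    meal_pre_s: float = 3600.0
    meal_post_s: float = 5 * 3600.0

    def __post_init__(self) -> None:
        for band in (self.signal_band, self.background_band, self.normal_band):
            if not (self.analysis_band[0] <= band[0] and band[1] <= self.analysis_band[1]):
                raise ValueError(f"band {band} not nested in analysis band")
        if not (0 < self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in (0, 1)")


@dataclass
class ValidationReport:
    """Three-condition comparison for one subject."""

    percent_normal: dict[str, float]
    correlations: dict[str, dict[str, CorrelationResult]]  # channel -> condition -> result
    best_pair: tuple[str, str]
    best_pair_snr_db: float
    sigma_e_sq: float
    window_n: int
    notices: list[str] = field(default_factory=list)


def _percent_normal(sig: BipolarSignal, cfg: PipelineConfig) -> tuple[float, np.ndarray]:
    spec = _spectral.compute_spectrogram(sig, cfg.window_s, cfg.overlap_frac)
    feats = _spectral.egg_features(
        spec,
        signal_band=cfg.signal_band,
        background_band=cfg.background_band,
        analysis_band=cfg.analysis_band,
        normal_band=cfg.normal_band,
    )
    return float(100.0 * feats.is_normal.mean()), feats.band_power_db


def run_validation_pipeline(
    rec: MultichannelRecording,
    pressures: list[PressureRecording] | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> ValidationReport:
    """Three-condition EGG analysis, optionally against manometry.

    Conditions: the traditional pair (skipped with a notice if the
    recording has no electrode layout), the highest-SNR pair, and the
    highest-SNR pair after artifact removal.  For each pressure channel
    the EGG-power/motility-index regression is Bonferroni-adjusted by the
    number of channels.
    """
    pressures = pressures or []
    notices: list[str] = []
    signals: dict[str, BipolarSignal] = {}

    try:
        meas, ref = traditional_pair(rec)
        signals["traditional"] = _spectral.rereference(rec, meas, ref)
    except ValueError as exc:
        notices.append(f"traditional pair unavailable: {exc}")

    meas_b, ref_b, pair_snr = _spectral.best_pair(rec, cfg.window_s, cfg.overlap_frac)
    best_raw = _spectral.rereference(rec, meas_b, ref_b)
    signals["best_snr"] = best_raw

    decomp = _artifact.remove_artifacts(best_raw, peak_freq=cfg.peak_freq_hz)
    signals["best_snr_cleaned"] = decomp.cleaned

    percent: dict[str, float] = {}
    powers: dict[str, np.ndarray] = {}
    for cond, sig in signals.items():
        percent[cond], powers[cond] = _percent_normal(sig, cfg)

    correlations: dict[str, dict[str, CorrelationResult]] = {}
    n_channels = len(pressures)
    for p in pressures:
        mi = _manometry.motility_index(
            p, cfg.motility_threshold_mmhg, cfg.window_s, cfg.overlap_frac
        )
        per_cond: dict[str, CorrelationResult] = {}
        for cond, power in powers.items():
            n = min(power.size, mi.mi.size)
            per_cond[cond] = _manometry.correlate_egg_manometry(
                power[:n], mi.mi[:n], n_channels=n_channels
            )
        correlations[p.channel_id] = per_cond
    if not pressures:
        notices.append("no pressure channels: percent-normal-only report")

    return ValidationReport(
        percent_normal=percent,
        correlations=correlations,
        best_pair=(meas_b, ref_b),
        best_pair_snr_db=pair_snr,
        sigma_e_sq=decomp.sigma_e_sq,
        window_n=decomp.window_n,
        notices=notices,
    )


@dataclass
class AmbulatoryReport:
    """Daily free-living analysis products."""

    features: _spectral.EggFeatureSeries
    spectrogram: _spectral.Spectrogram
    isolated_meals: list
    meal_aligned: _spectral.AlignedFeatures | None
    sleep_aligned: _spectral.AlignedFeatures | None
    sigma_e_sq: float
    window_n: int
    notices: list[str] = field(default_factory=list)


def run_ambulatory_pipeline(
    sig: BipolarSignal,
    log: EventLog,
    cfg: PipelineConfig = PipelineConfig(),
) -> AmbulatoryReport:
    """Clean a day-long bipolar recording and extract event-aligned features."""
    notices: list[str] = []
    decomp = _artifact.remove_artifacts(sig, peak_freq=cfg.peak_freq_hz)
    spec = _spectral.compute_spectrogram(decomp.cleaned, cfg.window_s, cfg.overlap_frac)
    feats = _spectral.egg_features(
        spec,
        signal_band=cfg.signal_band,
        background_band=cfg.background_band,
        analysis_band=cfg.analysis_band,
        normal_band=cfg.normal_band,
    )

    meals = _spectral.find_isolated_meals(log)
    meal_aligned = None
    if meals:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                meal_aligned = _spectral.align_by_event(
                    feats, log, "meal", cfg.meal_pre_s, cfg.meal_post_s,
                    field="normalized_power_db", anchors=meals,
                )
        except ValueError as exc:
            notices.append(f"meal alignment failed: {exc}")
    else:
        notices.append("no isolated meals in the event log")

    sleep_aligned = None
    if log.with_tag("sleep_onset"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sleep_aligned = _spectral.align_by_event(
                    feats, log, "sleep_onset", 2 * 3600.0, 6 * 3600.0,
                    field="dominant_freq_hz",
                )
        except ValueError as exc:
            notices.append(f"sleep alignment failed: {exc}")

    return AmbulatoryReport(
        features=feats,
        spectrogram=spec,
        isolated_meals=meals,
        meal_aligned=meal_aligned,
        sleep_aligned=sleep_aligned,
        sigma_e_sq=decomp.sigma_e_sq,
        window_n=decomp.window_n,
        notices=notices,
    )


def validation_group_stats(
    reports: list[ValidationReport],
    metric: str = "percent_normal",
) -> dict[str, tuple[float, float]]:
    """Paired t-tests across subjects between the montage conditions.

    Returns ``{"traditional_vs_best_snr": (t, p), "best_snr_vs_cleaned": (t, p)}``
    for the chosen per-subject metric (percent_normal by default).
    """
    if len(reports) < 2:
        raise ValueError("need at least two subjects for a paired comparison")
    cols = {c: [] for c in CONDITIONS}
    for rep in reports:
        for c in CONDITIONS:
            if c not in rep.percent_normal:
                raise ValueError(f"report missing condition {c!r}")
            cols[c].append(rep.percent_normal[c])
    out = {}
    out["traditional_vs_best_snr"] = _manometry.paired_comparison(
        np.array(cols["traditional"]), np.array(cols["best_snr"])
    )
    out["best_snr_vs_cleaned"] = _manometry.paired_comparison(
        np.array(cols["best_snr"]), np.array(cols["best_snr_cleaned"])
    )
    return out
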