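"""Short-time spectral features of the gastric slow wave.

All EGG features derive from one spectrogram convention: consecutive
four-minute (240 s) segments with 75% overlap, Hamming-tapered, mean
removed per segment, power reported in dB (10*log10).  At the 5 Hz
analysis rate this gives a frequency resolution of 1/240 Hz, fine enough
to separate the 2-4 cpm (0.033-0.067 Hz) normal gastric band from brady-
and tachygastric activity within the 0.02-0.20 Hz analysis band.

Scalar features:

* ``snr`` - mean dB power in the 0.04-0.06 Hz signal band minus mean dB
  power over the rest of the 0.02-0.20 Hz analysis band.
* ``percent_normal`` - percentage of windows whose dominant frequency
  (argmax power in the analysis band) falls within 2-4 cpm; below 70% is
  conventionally considered abnormal.
* ``egg_features`` - per-window band power, normalized power (band power
  minus the 0.06-0.10 Hz background), dominant frequency, and normality.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import BipolarSignal, Event, EventLog, MultichannelRecording, rereference

__all__ = [
    "Spectrogram",
    "EggFeatureSeries",
    "AlignedFeatures",
    "compute_spectrogram",
    "snr",
    "best_pair",
    "percent_normal",
    "egg_features",
    "align_by_event",
    "find_isolated_meals",
    "ANALYSIS_BAND",
    "SIGNAL_BAND",
    "BACKGROUND_BAND",
    "NORMAL_BAND",
]

ANALYSIS_BAND = (0.02, 0.20)     # Hz, full gastric analysis band
SIGNAL_BAND = (0.04, 0.06)       # Hz, slow-wave signal band (~3 cpm)
BACKGROUND_BAND = (0.06, 0.10)   # Hz, background noise band
NORMAL_BAND = (2 / 60, 4 / 60)   # Hz, "normal" gastric band, 2-4 cpm

DB_FLOOR = -120.0  # dB floor; only guards log of exactly-zero power
_LIN_FLOOR = 10.0 ** (DB_FLOOR / 10.0)


@dataclass
class Spectrogram:
    """Windows x frequency power map in dB with its framing metadata."""

    times: np.ndarray        # window-center times, s
    freqs: np.ndarray        # Hz, strictly increasing
    power_db: np.ndarray     # (n_windows, n_freqs)
    window_s: float
    overlap_frac: float
    taper: str
    fs: float

    @property
    def n_windows(self) -> int:
        return self.power_db.shape[0]

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        """Bins whose center frequency lies in the closed band."""
        lo, hi = band
        return (self.freqs >= lo - 1e-12) & (self.freqs <= hi + 1e-12)


@dataclass
class EggFeatureSeries:
    """Per-window EGG features extracted from a spectrogram."""

    times: np.ndarray
    band_power_db: np.ndarray        # mean dB power, 0.04-0.06 Hz
    normalized_power_db: np.ndarray  # band power minus 0.06-0.10 Hz background
    dominant_freq_hz: np.ndarray     # argmax frequency in 0.02-0.20 Hz
    is_normal: np.ndarray            # dominant frequency within 2-4 cpm

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("band_power_db", "normalized_power_db",
                     "dominant_freq_hz", "is_normal"):
            if getattr(self, name).size != n:
                raise ValueError("feature series lengths differ")


@dataclass
class AlignedFeatures:
    """Event-aligned feature rows on a common relative-time grid."""

    rel_times: np.ndarray    # s relative to the anchor
    rows: np.ndarray         # (n_events, n_grid)
    mean: np.ndarray
    std: np.ndarray
    anchors: list[Event]


def compute_spectrogram(
    x: BipolarSignal,
    window_s: float = 240.0,
    overlap_frac: float = 0.75,
    taper: str = "hamming",
) -> Spectrogram:
    """Short-time power spectrogram of a bipolar signal.

    Each segment is mean-removed, tapered, and converted to a one-sided
    periodogram; power is reported in dB.  Window count is
    floor((L - W) / hop) + 1 with W = window_s*fs and hop = W*(1 -
    overlap_frac); times are window centers.
    """
    W = int(round(window_s * x.fs))
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    if len(x) < W:
        raise ValueError(
            f"record of {len(x)} samples shorter than one {W}-sample window"
        )
    noverlap = int(round(W * overlap_frac))
    freqs, times, Sxx = sps.spectrogram(
        x.samples,
        fs=x.fs,
        window=sps.get_window(taper, W),
        nperseg=W,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    power_db = 10.0 * np.log10(np.maximum(Sxx.T, _LIN_FLOOR))
    return Spectrogram(
        times=times,
        freqs=freqs,
        power_db=power_db,
        window_s=window_s,
        overlap_frac=overlap_frac,
        taper=taper,
        fs=x.fs,
    )


def _require_band(spec: Spectrogram, band: tuple[float, float]) -> np.ndarray:
    mask = spec.band_mask(band)
    if not mask.any():
        raise ValueError(
            f"no frequency bins inside band {band} at resolution "
            f"{1 / spec.window_s:.5f} Hz"
        )
    return mask


def snr(
    spec: Spectrogram,
    signal_band: tuple[float, float] = SIGNAL_BAND,
    analysis_band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Signal-to-noise ratio in dB, averaged over all windows.

    Mean dB power inside the 0.04-0.06 Hz signal band minus mean dB power
    at all other frequencies of the 0.02-0.20 Hz analysis band (dB-domain
    averaging).
    """
    sig = _require_band(spec, signal_band)
    ana = _require_band(spec, analysis_band)
    noise = ana & ~sig
    if not noise.any():
        raise ValueError("analysis band leaves no noise bins outside the signal band")
    return float(spec.power_db[:, sig].mean() - spec.power_db[:, noise].mean())


def best_pair(
    rec: MultichannelRecording,
    window_s: float = 240.0,
    overlap_frac: float = 0.75,
) -> tuple[str, str, float]:
    """Channel pair with the highest slow-wave SNR.

    Every unordered pair of channels is re-referenced by subtraction and
    scored with ``snr``; ties break deterministically toward the earlier
    pair in label order.  Returns (measurement, reference, snr_db).
    """
    if rec.n_channels < 2:
        raise ValueError("need at least two channels to select a pair")
    best: tuple[str, str, float] | None = None
    for a, b in itertools.combinations(rec.channel_labels, 2):
        sig = rereference(rec, a, b)
        if not np.any(sig.samples):
            value = -np.inf  # identical channels carry no signal
        else:
            value = snr(compute_spectrogram(sig, window_s, overlap_frac))
        if best is None or value > best[2]:
            best = (a, b, value)
    assert best is not None
    if not np.isfinite(best[2]):
        warnings.warn(
            "all channel pairs are identical (zero difference); returning "
            "the first pair",
            stacklevel=2,
        )
        a, b = rec.channel_labels[0], rec.channel_labels[1]
        return a, b, 0.0
    return best


def percent_normal(
    spec: Spectrogram,
    normal_band: tuple[float, float] = NORMAL_BAND,
    analysis_band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Percentage of windows with dominant power in the 2-4 cpm band.

    The dominant frequency of a window is the argmax of power over the
    0.02-0.20 Hz analysis band; a window is "normal" when it falls inside
    the closed 2-4 cpm band.  Values below 70% are conventionally read as
    abnormal gastric rhythm.
    """
    feats = egg_features(spec, analysis_band=analysis_band,
                         normal_band=normal_band)
    return float(100.0 * feats.is_normal.mean())


def egg_features(
    spec: Spectrogram,
    signal_band: tuple[float, float] = SIGNAL_BAND,
    background_band: tuple[float, float] = BACKGROUND_BAND,
    analysis_band: tuple[float, float] = ANALYSIS_BAND,
    normal_band: tuple[float, float] = NORMAL_BAND,
) -> EggFeatureSeries:
    """Per-window EGG feature series.

    * band_power_db: mean dB power in the signal band ("EGG power").
    * normalized_power_db: band power minus the mean dB power in the
      background band, controlling for noise variability between
      recordings and channels.
    * dominant_freq_hz: argmax frequency over the analysis band.
    * is_normal: dominant frequency within the closed normal band.
    """
    sig = _require_band(spec, signal_band)
    bg = _require_band(spec, background_band)
    ana = _require_band(spec, analysis_band)
    band_power = spec.power_db[:, sig].mean(axis=1)
    background = spec.power_db[:, bg].mean(axis=1)
    ana_freqs = spec.freqs[ana]
    dominant = ana_freqs[np.argmax(spec.power_db[:, ana], axis=1)]
    lo, hi = normal_band
    is_normal = (dominant >= lo - 1e-12) & (dominant <= hi + 1e-12)
    return EggFeatureSeries(
        times=spec.times,
        band_power_db=band_power,
        normalized_power_db=band_power - background,
        dominant_freq_hz=dominant,
        is_normal=is_normal,
    )


def align_by_event(
    features: EggFeatureSeries,
    log: EventLog,
    anchor_tag: str,
    pre_s: float,
    post_s: float,
    field: str = "normalized_power_db",
    anchors: list[Event] | None = None,
) -> AlignedFeatures:
    """Average a feature across repeated events on a relative-time grid.

    Each anchor event (e.g. meal completion) contributes one row, the
    feature linearly interpolated onto a grid from ``-pre_s`` to
    ``+post_s`` at the feature hop.  Events whose window extends beyond
    the feature coverage are dropped with a warning.  Returns rows plus
    the across-event mean and standard deviation.
    """
    values = np.asarray(getattr(features, field), dtype=float)
    times = features.times
    if anchors is None:
        anchors = log.with_tag(anchor_tag)
    if not anchors:
        raise ValueError(f"no events with tag {anchor_tag!r}")
    step = float(times[1] - times[0]) if times.size > 1 else max(pre_s + post_s, 1.0)
    rel = np.arange(-pre_s, post_s + step / 2, step)
    if rel.size == 0:
        rel = np.array([0.0])
    rows, used = [], []
    for ev in anchors:
        lo, hi = ev.time_s - pre_s, ev.time_s + post_s
        if lo < times[0] - step / 2 or hi > times[-1] + step / 2:
            warnings.warn(
                f"event at t={ev.time_s:.0f}s window [{lo:.0f}, {hi:.0f}]s "
                "extends beyond feature coverage; dropped",
                stacklevel=2,
            )
            continue
        rows.append(np.interp(rel + ev.time_s, times, values))
        used.append(ev)
    if not rows:
        raise ValueError("no anchor event fully covered by the feature series")
    mat = np.vstack(rows)
    return AlignedFeatures(
        rel_times=rel,
        rows=mat,
        mean=mat.mean(axis=0),
        std=mat.std(axis=0, ddof=0),
        anchors=used,
    )


def find_isolated_meals(
    log: EventLog,
    fast_before_s: float = 5 * 3600.0,
    quiet_after_s: float = 5 * 3600.0,
) -> list[Event]:
    """Meals preceded by >= 5 h of fasting and followed by 5 h without events.

    A meal qualifies when no other logged event of any kind falls in the
    open interval (t - fast_before_s, t) or (t, t + quiet_after_s).
    """
    meals = log.with_tag("meal")
    isolated = []
    for meal in meals:
        clear = True
        for other in log:
            if other is meal:
                continue
            dt = other.time_s - meal.time_s
            if -fast_before_s < dt < 0 or 0 < dt < quiet_after_s or dt == 0:
                clear = False
                break
        if clear:
            isolated.append(meal)
    return isolated
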