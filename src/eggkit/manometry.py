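"""Manometric motility index and EGG-manometry association statistics.

Antral manometry is the clinical gold standard for gastric contractility.
Contractility is summarized per analysis window by the motility index:
the natural logarithm of the area of the pressure excursion above a
9 mmHg threshold, computed over the same four-minute, 75%-overlap windows
as the EGG spectrogram so the two series align window for window.

The association between windowed EGG band power (dB) and the motility
index is assessed with ordinary least-squares regression; the two-sided
p-value tests the zero-slope null and is Bonferroni-adjusted for the
number of manometry channels.  Paired and unpaired two-sided t-tests
cover the across-subject comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PressureRecording",
    "MotilityIndexSeries",
    "CorrelationResult",
    "motility_index",
    "correlate_egg_manometry",
    "paired_comparison",
    "unpaired_comparison",
    "bonferroni",
]

MOTILITY_THRESHOLD_MMHG = 9.0
#: area floor, mmHg*s; windows with no supra-threshold activity get mi = ln(1) = 0
AREA_FLOOR = 1.0


@dataclass
class PressureRecording:
    """Single-channel manometric pressure in mmHg.

    Catheter sensors sit in the antrum at 1 cm spacing; each sensor is one
    recording.  Pressure is assumed already baseline-corrected.
    """

    samples: np.ndarray
    fs: float
    channel_id: str = "antrum"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("pressure recording must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class MotilityIndexSeries:
    """Windowed motility index, framed identically to the EGG spectrogram."""

    times: np.ndarray            # window centers, s
    mi: np.ndarray               # ln(mmHg*s)
    at_floor: np.ndarray         # True where no supra-threshold area
    threshold_mmhg: float
    window_s: float
    overlap_frac: float


@dataclass
class CorrelationResult:
    """Least-squares association between EGG power and motility index."""

    r: float
    slope: float
    intercept: float
    p_value: float
    p_adjusted: float
    n_windows: int

    @property
    def significant(self) -> bool:
        """Significance at the 0.01 level after Bonferroni adjustment."""
        return self.p_adjusted <= 0.01


def motility_index(
    p: PressureRecording,
    threshold: float = MOTILITY_THRESHOLD_MMHG,
    window_s: float = 240.0,
    overlap_frac: float = 0.75,
    area_floor: float = AREA_FLOOR,
) -> MotilityIndexSeries:
    """Windowed motility index of a pressure recording.

    Per window, area = sum over samples of max(p - threshold, 0) / fs
    (rectangle-rule integral, mmHg*s) and mi = ln(max(area, area_floor)).
    Window count and center times replicate the EGG spectrogram framing
    (W = window_s*fs samples, hop = W*(1 - overlap_frac)), so an EGG
    feature series and a motility index series computed with the same
    parameters on equal-length records align one-to-one.  All-NaN windows
    propagate NaN.
    """
    W = int(round(window_s * p.fs))
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    if p.samples.size < W:
        raise ValueError(
            f"record of {p.samples.size} samples shorter than one "
            f"{W}-sample window"
        )
    hop = W - int(round(W * overlap_frac))
    n_windows = (p.samples.size - W) // hop + 1
    mi = np.empty(n_windows)
    at_floor = np.zeros(n_windows, dtype=bool)
    times = (np.arange(n_windows) * hop + W / 2) / p.fs
    excess = np.maximum(p.samples - threshold, 0.0)
    for i in range(n_windows):
        w = excess[i * hop : i * hop + W]
        if np.all(np.isnan(w)):
            mi[i] = np.nan
            continue
        area = np.nansum(w) / p.fs
        if area < area_floor:
            at_floor[i] = True
            area = area_floor
        mi[i] = math.log(area)
    return MotilityIndexSeries(
        times=times,
        mi=mi,
        at_floor=at_floor,
        threshold_mmhg=threshold,
        window_s=window_s,
        overlap_frac=overlap_frac,
    )


def bonferroni(p_value: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, n_tests * p)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, n_tests * p_value)


def correlate_egg_manometry(
    egg_power_db: np.ndarray,
    mi: MotilityIndexSeries | np.ndarray,
    n_channels: int = 1,
) -> CorrelationResult:
    """Least-squares regression of motility index on EGG band power.

    ``egg_power_db`` is the per-window mean 0.04-0.06 Hz power in dB;
    ``mi`` the aligned motility index series.  Returns the correlation
    coefficient, fit, two-sided zero-slope p-value and its Bonferroni
    adjustment for ``n_channels`` manometry channels.  Windows where
    either series is NaN are dropped.
    """
    x = np.asarray(egg_power_db, dtype=float)
    y = mi.mi if isinstance(mi, MotilityIndexSeries) else np.asarray(mi, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"series lengths differ: {x.size} EGG windows vs {y.size} MI windows"
        )
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 aligned windows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        p_adjusted=bonferroni(float(fit.pvalue), n_channels),
        n_windows=int(x.size),
    )


def paired_comparison(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test for identical expected values.

    A constant nonzero shift (zero-variance differences) is reported as
    (signed inf, 0.0); identical samples are degenerate and raise.
    """
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = b - a
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            raise ValueError("identical samples: paired t-test degenerate")
        return math.copysign(math.inf, d.mean()), 0.0
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)


def unpaired_comparison(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Unpaired two-sided t-test assuming equal variances."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    nx, ny = x.size, y.size
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance: unpaired t-test degenerate")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
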