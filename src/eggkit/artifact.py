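"""LMMSE motion-artifact rejection with locally estimated statistics.

Skin-surface EGG recordings are contaminated by short (a few seconds or
less), high-amplitude (mV-scale) motion-artifact bursts riding on a
50-200 uV gastric slow wave near 0.05 Hz.  The bursts are broadband, so
band-pass filtering cannot remove them.  Instead the artifact is modelled
as additive interference,

    y = x + e,

where ``y`` is the observed bipolar signal, ``x`` the artifact and ``e``
the gastric (EGG) component.  Over a window of one average slow-wave cycle
the EGG is assumed zero-mean with variance sigma_e^2.  The linear
minimum mean-squared error estimate of the artifact then uses the local
mean and variance of ``y``:

    x_hat[t] = E[y][t] + g[t] * (y[t] - E[y][t]),
    g[t]     = max(0, Var(y)[t] - sigma_e^2) / max(Var(y)[t], sigma_e^2),

with sigma_e^2 estimated as the time-average of the local variance.  The
max() guards handle windows whose sample variance falls below the EGG
variance.  Where the local variance is at or below sigma_e^2 the gain is
zero and x_hat is pure local smoothing (so subtracting it detrends the
signal); inside a high-variance burst the gain approaches one and x_hat
tracks y, so the burst is subtracted out.  The cleaned EGG is

    e_hat = y - x_hat.

Each output sample depends only on its centered neighborhood, so the
estimator adapts to non-stationary signal, artifact and noise statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import BipolarSignal

__all__ = [
    "LocalMoments",
    "ArtifactDecomposition",
    "compute_local_moments",
    "default_window_n",
    "estimate_sigma_e_sq",
    "lmmse_artifact",
    "remove_artifacts",
]

# Gastric analysis band (Hz); the mean peak EGG frequency must lie inside it.
_BAND_LO, _BAND_HI = 0.02, 0.20


@dataclass
class LocalMoments:
    """Per-sample local mean (uV) and population variance (uV^2).

    ``window_n`` is the (odd) number of samples in the centered window;
    windows shrink at the record edges rather than padding.
    """

    local_mean: np.ndarray
    local_var: np.ndarray
    window_n: int

    def __post_init__(self) -> None:
        self.local_mean = np.asarray(self.local_mean, dtype=float)
        self.local_var = np.asarray(self.local_var, dtype=float)
        if self.local_mean.shape != self.local_var.shape:
            raise ValueError("moment series must have equal length")
        if np.any(self.local_var < 0):
            raise ValueError("local variance must be non-negative")
        if self.window_n < 3 or self.window_n % 2 == 0:
            raise ValueError("window_n must be odd and >= 3")


@dataclass
class ArtifactDecomposition:
    """Result of artifact rejection: observed = artifact + egg.

    ``egg`` is stored as the exact floating-point difference
    ``observed - artifact``, so the additive decomposition is preserved to
    machine precision by construction.
    """

    artifact: np.ndarray
    egg: np.ndarray
    sigma_e_sq: float
    window_n: int
    observed: BipolarSignal

    def __post_init__(self) -> None:
        if self.sigma_e_sq < 0:
            raise ValueError("sigma_e_sq must be non-negative")

    @property
    def cleaned(self) -> BipolarSignal:
        """The cleaned EGG wrapped as a signal with the input's metadata."""
        return BipolarSignal(
            self.egg,
            self.observed.fs,
            self.observed.measurement_label,
            self.observed.reference_label,
        )

    @property
    def gain(self) -> np.ndarray:
        """Per-sample LMMSE gain actually applied, in [0, 1)."""
        moments = compute_local_moments(self.observed, self.window_n)
        return _lmmse_gain(moments.local_var, self.sigma_e_sq)

    @property
    def artifact_burden(self) -> float:
        """Fraction of samples with gain > 0.5 (heavily suppressed)."""
        return float(np.mean(self.gain > 0.5))


def _as_array(y) -> np.ndarray:
    if isinstance(y, BipolarSignal):
        return y.samples
    return np.asarray(y, dtype=float)


def compute_local_moments(
    y, window_n: int, mode: str = "sliding"
) -> LocalMoments:
    """Local mean and population variance over centered windows.

    Parameters
    ----------
    y
        Signal samples (``BipolarSignal`` or array).
    window_n
        Odd window length in samples; edge windows are truncated to the
        available samples.
    mode
        ``"sliding"`` (per-sample centered window, default) or ``"block"``
        (disjoint blocks of ``window_n`` samples share one mean/variance;
        the historical segmented formulation).
    """
    x = _as_array(y)
    n = x.size
    if window_n % 2 == 0:
        raise ValueError("window_n must be odd for a centered window")
    if window_n < 3:
        raise ValueError("window_n must be >= 3")
    if window_n > n:
        raise ValueError(f"window_n {window_n} exceeds signal length {n}")

    if mode == "block":
        mean = np.empty(n)
        var = np.empty(n)
        for start in range(0, n, window_n):
            blk = x[start : start + window_n]
            m = blk.mean()
            mean[start : start + window_n] = m
            var[start : start + window_n] = ((blk - m) ** 2).mean()
        return LocalMoments(mean, var, window_n)
    if mode != "sliding":
        raise ValueError(f"unknown mode {mode!r}")

    half = window_n // 2
    mean = np.empty(n)
    var = np.empty(n)
    # interior: full centered windows, vectorized over a strided view
    sw = sliding_window_view(x, window_n)
    m = sw.mean(axis=-1)
    mean[half : n - half] = m
    var[half : n - half] = ((sw - m[:, None]) ** 2).mean(axis=-1)
    # edges: windows truncated to the available samples
    for t in range(half):
        w = x[: t + half + 1]
        mt = w.mean()
        mean[t] = mt
        var[t] = ((w - mt) ** 2).mean()
    for t in range(n - half, n):
        w = x[t - half :]
        mt = w.mean()
        mean[t] = mt
        var[t] = ((w - mt) ** 2).mean()
    return LocalMoments(mean, var, window_n)


def default_window_n(fs: float, peak_freq: float = 0.05) -> int:
    """Window length: one average slow-wave cycle, forced odd.

    The window covers the inverse of the mean peak EGG frequency (0.05 Hz,
    i.e. three cycles per minute, by default), so that the zero-mean EGG
    assumption holds within each window.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    if not (_BAND_LO <= peak_freq <= _BAND_HI):
        raise ValueError(
            f"peak_freq {peak_freq} Hz outside the gastric band "
            f"[{_BAND_LO}, {_BAND_HI}] Hz"
        )
    n = int(round(fs / peak_freq))
    if n % 2 == 0:
        n += 1
    return n


def estimate_sigma_e_sq(moments: LocalMoments) -> float:
    """EGG variance floor: the time-average of the local variance of y."""
    if moments.local_var.size == 0:
        raise ValueError("empty moment series")
    return float(moments.local_var.mean())


def _lmmse_gain(local_var: np.ndarray, sigma_e_sq: float) -> np.ndarray:
    num = np.maximum(0.0, local_var - sigma_e_sq)
    den = np.maximum(local_var, sigma_e_sq)
    gain = np.zeros_like(local_var)
    nz = den > 0
    gain[nz] = num[nz] / den[nz]
    return gain


def lmmse_artifact(y, moments: LocalMoments, sigma_e_sq: float) -> np.ndarray:
    """Estimate the artifact x_hat from the observation and its local moments.

    Where both the local variance and sigma_e^2 vanish (a constant
    signal) the gain is defined as zero, so x_hat collapses to the local
    mean; a degenerate-input warning is emitted.
    """
    x = _as_array(y)
    if x.shape != moments.local_mean.shape:
        raise ValueError("moments are not aligned with the signal")
    if sigma_e_sq < 0:
        raise ValueError("sigma_e_sq must be non-negative")
    if sigma_e_sq == 0 and np.any(moments.local_var == 0):
        warnings.warn(
            "degenerate input: zero local variance with zero sigma_e_sq; "
            "gain defined as 0 there",
            stacklevel=2,
        )
    gain = _lmmse_gain(moments.local_var, sigma_e_sq)
    return moments.local_mean + gain * (x - moments.local_mean)


def remove_artifacts(
    y: BipolarSignal,
    peak_freq: float = 0.05,
    window_n: int | None = None,
    sigma_e_sq: float | None = None,
    mode: str = "sliding",
) -> ArtifactDecomposition:
    """Estimate and subtract motion artifacts from a bipolar EGG signal.

    Runs the full LMMSE chain: local moments over one slow-wave cycle,
    EGG-variance floor as the mean local variance, per-sample gain, and
    subtraction of the estimated artifact.  Returns the additive
    decomposition ``observed = artifact + egg``.

    Parameters
    ----------
    y
        Observed bipolar signal (uV), typically already downsampled to 5 Hz.
    peak_freq
        Mean peak EGG frequency in Hz used to size the window (default
        0.05 Hz = 3 cpm).
    window_n
        Explicit window length (odd, samples); overrides ``peak_freq``.
    sigma_e_sq
        Explicit EGG variance floor (uV^2); estimated from the data when
        omitted.
    mode
        ``"sliding"`` or ``"block"`` moment estimation.
    """
    x = y.samples
    if np.any(~np.isfinite(x)):
        raise ValueError("input contains NaN or infinite samples")
    if window_n is None:
        window_n = default_window_n(y.fs, peak_freq)
    if x.size < window_n:
        raise ValueError(
            f"signal of {x.size} samples shorter than one window ({window_n})"
        )
    moments = compute_local_moments(x, window_n, mode=mode)
    if sigma_e_sq is None:
        sigma_e_sq = estimate_sigma_e_sq(moments)
    artifact = lmmse_artifact(x, moments, sigma_e_sq)
    egg = x - artifact
    return ArtifactDecomposition(
        artifact=artifact,
        egg=egg,
        sigma_e_sq=float(sigma_e_sq),
        window_n=int(window_n),
        observed=y,
    )
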