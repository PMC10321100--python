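"""Time-frequency decomposition and dB band-power contrasts.

The transform is a per-frequency sliding-window Fourier coefficient with a
Hanning taper whose length is five cycles of the analysed frequency, so the
spectral bandwidth scales proportionally with frequency. Complex
coefficients are retained: their magnitudes drive the power analyses and
their phases drive the connectivity module.

Power contrasts follow the double-difference logic: each third-stage power
map is expressed in dB relative to a first-stage baseline of matched
duration, and the Aha-vs-Ctrl contrast is the difference of those two dB
maps, ``Diff = (M3_Aha - M1_Aha) - (M3_Ctrl - M1_Ctrl)``, which cancels
stimulus-evoked components common to both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .epochs import EpochSet

#: canonical frequency bands, Hz (inclusive integer bins)
BANDS = {
    "theta": (4, 7),
    "alpha": (8, 12),
    "beta": (13, 30),
    "gamma": (31, 100),
}

#: default analysis windows, seconds relative to the alignment event
ANALYSIS_WINDOWS = {"stimulus": (-0.25, 0.75), "response": (-0.75, 0.25)}


@dataclass
class SpectralTensor:
    """Complex coefficients indexed (trial, channel, frequency, time).

    ``coeffs`` is NaN where the five-cycle window would extend beyond the
    epoch. Frequencies whose window does not fit in the epoch at all are
    recorded in ``missing_freqs`` and excluded from the frequency axis.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    n_cycles: float = 5.0
    missing_freqs: tuple[float, ...] = ()

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    def freq_index(self, f: float) -> int:
        idx = np.flatnonzero(np.isclose(self.freqs, f))
        if idx.size == 0:
            raise ValueError(f"frequency {f} Hz not on the grid")
        return int(idx[0])

    def time_slice(self, t_start: float, t_stop: float) -> "SpectralTensor":
        mask = (self.times >= t_start) & (self.times < t_stop)
        if not mask.any():
            raise ValueError("requested window has no time points")
        return SpectralTensor(
            coeffs=self.coeffs[..., mask],
            freqs=self.freqs,
            times=self.times[mask],
            fs=self.fs,
            n_cycles=self.n_cycles,
            missing_freqs=self.missing_freqs,
        )


@dataclass
class BandContrast:
    """Channel x time dB map for one band (a baseline-corrected contrast)."""

    values: np.ndarray  # (n_channels, n_times)
    band: str
    times: np.ndarray
    ch_names: list[str]


def _hann_kernel(f: float, fs: float, n_taps: int) -> np.ndarray:
    """Complex analysis kernel: Hanning envelope times e^{j 2 pi f t}.

    Normalized so a unit-amplitude sinusoid at ``f`` yields |coeff| = 1.
    """
    n_taps += 1 - n_taps % 2  # odd length, symmetric support
    window = np.hanning(n_taps)
    t = (np.arange(n_taps) - n_taps // 2) / fs
    return (2.0 / window.sum()) * window * np.exp(2j * np.pi * f * t)


def _kernel_taps(f: float, fs: float, n_cycles: float, window_s: float | None) -> int:
    """Taper length in samples: five cycles of f, or a fixed duration."""
    if window_s is not None:
        return int(round(window_s * fs))
    return int(round(n_cycles / f * fs))


def hann_window_gain(f_kernel: float, f_signal: float, fs: float,
                     n_cycles: float = 5.0) -> float:
    """Closed-form magnitude response of the analysis kernel at ``f_signal``."""
    kernel = _hann_kernel(f_kernel, fs, _kernel_taps(f_kernel, fs, n_cycles, None))
    t = (np.arange(kernel.size) - kernel.size // 2) / fs
    return float(abs(np.sum(kernel * 0.5 * np.exp(-2j * np.pi * f_signal * t))))


def tfr_hanning(
    epochs: EpochSet,
    freqs,
    t_step: float = 0.005,
    n_cycles: float = 5.0,
    window_s: float | None = None,
) -> SpectralTensor:
    """Hanning-taper time-frequency transform (five-cycle windows).

    Parameters
    ----------
    epochs : EpochSet
    freqs : iterable of float
        Frequency grid in Hz (the canonical grid is 1-Hz steps).
    t_step : float
        Stride of the output time axis, seconds (default 5 ms).
    n_cycles : float
        Window length in cycles of the analysed frequency (bandwidth
        scales with frequency — the spectral-analysis convention).
    window_s : float, optional
        Fixed window duration in seconds, overriding ``n_cycles`` (the
        sliding sub-window convention of the connectivity time courses).

    Window positions whose support extends beyond the epoch are NaN rather
    than zero-padded; frequencies that do not fit at all are dropped and
    listed in ``missing_freqs``.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    data = epochs.data
    n_samp = data.shape[-1]
    step = max(1, int(round(t_step * epochs.fs)))
    out_idx = np.arange(0, n_samp, step)
    times = epochs.times[out_idx]

    usable, missing = [], []
    for f in freqs:
        n_taps = _kernel_taps(f, epochs.fs, n_cycles, window_s) | 1
        (usable if n_taps <= n_samp else missing).append(f)
    if not usable:
        raise ValueError("epoch too short for the analysis window at any requested frequency")

    coeffs = np.full(
        (data.shape[0], data.shape[1], len(usable), out_idx.size), np.nan + 0j,
        dtype=complex,
    )
    for fi, f in enumerate(usable):
        kernel = _hann_kernel(f, epochs.fs, _kernel_taps(f, epochs.fs, n_cycles, window_s))
        conv = fftconvolve(data, np.conj(kernel[::-1])[None, None, :], mode="same", axes=-1)
        half = kernel.size // 2
        valid = (out_idx >= half) & (out_idx < n_samp - half)
        coeffs[:, :, fi, valid] = conv[..., out_idx[valid]]
    return SpectralTensor(
        coeffs=coeffs,
        freqs=np.asarray(usable),
        times=times,
        fs=epochs.fs,
        n_cycles=n_cycles,
        missing_freqs=tuple(missing),
    )


def band_average(tensor: SpectralTensor, band) -> np.ndarray:
    """Mean power over a band's inclusive frequency bins.

    ``band`` is a name from :data:`BANDS` or an ``(f_lo, f_hi)`` tuple.
    Returns a trial-averaged (n_channels, n_times) power map.
    """
    f_lo, f_hi = BANDS[band] if isinstance(band, str) else band
    mask = (tensor.freqs >= f_lo) & (tensor.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band ({f_lo}, {f_hi}) outside the frequency grid")
    return np.nanmean(tensor.power[:, :, mask, :], axis=(0, 2))


def db_baseline(power_stage3: np.ndarray, power_stage1: np.ndarray) -> np.ndarray:
    """dB conversion of third-stage power against a first-stage baseline.

    The baseline map is averaged over its own (matched-length) window, per
    channel, then ``10*log10(P3 / P1)`` is returned with P3's time axis.
    """
    p3 = np.asarray(power_stage3, dtype=float)
    p1 = np.asarray(power_stage1, dtype=float)
    if np.any(p3[np.isfinite(p3)] <= 0) or np.any(p1[np.isfinite(p1)] <= 0):
        raise ValueError("power maps must be strictly positive")
    baseline = np.nanmean(p1, axis=-1, keepdims=True)
    return 10.0 * np.log10(p3 / baseline)


def double_difference(
    aha3: np.ndarray, aha1: np.ndarray, ctrl3: np.ndarray, ctrl1: np.ndarray
) -> np.ndarray:
    """The Aha-vs-Ctrl double difference of dB-baselined power maps.

    A multiplicative component present equally in both third-stage maps
    (a stimulus-evoked response) cancels exactly.
    """
    if np.shape(aha3) != np.shape(ctrl3):
        raise ValueError("condition maps must share a shape")
    return db_baseline(aha3, aha1) - db_baseline(ctrl3, ctrl1)


def band_contrast(
    epochs: EpochSet,
    band: str,
    window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
    t_step: float = 0.005,
) -> BandContrast:
    """End-to-end double-difference contrast for one band.

    Runs the transform per experimental cell, averages power over the band,
    baselines each condition's third stage against its first stage (matched
    window length after stimulus onset) and differences the conditions.
    """
    f_lo, f_hi = BANDS[band]
    freqs = np.arange(f_lo, f_hi + 1)
    if baseline_window is None:
        baseline_window = (0.0, window[1] - window[0])
    maps = {}
    for condition in ("Aha", "Ctrl"):
        for stage, win in (("third", window), ("first", baseline_window)):
            cell = epochs.select(condition=condition, stage=stage)
            tensor = tfr_hanning(cell, freqs, t_step=t_step).time_slice(*win)
            maps[condition, stage] = band_average(tensor, (f_lo, f_hi))
            if stage == "third":
                times = tensor.times
    values = double_difference(
        maps["Aha", "third"], maps["Aha", "first"],
        maps["Ctrl", "third"], maps["Ctrl", "first"],
    )
    return BandContrast(values=values, band=band, times=times, ch_names=list(epochs.ch_names))
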