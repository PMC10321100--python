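"""Pairwise coherence and phase-locking value, with imaginary parts.

Both measures summarize the across-trial consistency of the phase relation
between two channels at one frequency. With per-trial complex coefficients
``A_k e^{j phi_k}`` and ``B_k e^{j theta_k}``:

* coherency = sum_k A_k B_k e^{j(phi_k - theta_k)}
              / sqrt(sum_k A_k^2) / sqrt(sum_k B_k^2)   (amplitude-weighted)
* phase resultant = (1/N) sum_k e^{j(phi_k - theta_k)}  (amplitude-blind)

Coherence C(f) is the magnitude of the coherency, PLV P(f) the magnitude
of the resultant; both lie in [0, 1]. Their imaginary parts (iCOH, iPLV)
vanish for strictly zero-lag coupling and therefore suppress the
instantaneous volume-conduction confound. Imaginary parts are kept signed
here (the sign carries lead/lag information); absolute values are taken
only where a lateralization quantity is formed.

Baseline correction is a plain subtraction of the first-stage value — a dB
transform is meaningless for quantities bounded in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .epochs import EpochSet
from .spectral import BANDS, SpectralTensor, tfr_hanning

METRICS = ("coherence", "icoh", "plv", "iplv")


def coherency(coeffs_a: np.ndarray, coeffs_b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Complex coherency across the trial axis.

    Magnitude is the coherence C(f); the imaginary part is iCOH. Entries
    with a zero-amplitude denominator are returned as NaN (undefined).
    """
    a = np.asarray(coeffs_a, dtype=complex)
    b = np.asarray(coeffs_b, dtype=complex)
    if a.shape != b.shape:
        raise ValueError("coefficient arrays must share a shape")
    if a.shape[axis] < 2:
        raise ValueError("need at least 2 trials")
    num = np.sum(a * np.conj(b), axis=axis)
    den = np.sqrt(np.sum(np.abs(a) ** 2, axis=axis)) * np.sqrt(
        np.sum(np.abs(b) ** 2, axis=axis)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan + 0j)


def plv(phases_a: np.ndarray, phases_b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Complex mean phase-difference resultant across the trial axis.

    Accepts phase angles (radians) or complex coefficients (whose angles
    are used — amplitude is discarded). Magnitude is the PLV; the
    imaginary part is iPLV.
    """
    a, b = np.asarray(phases_a), np.asarray(phases_b)
    if a.shape != b.shape:
        raise ValueError("phase arrays must share a shape")
    if a.shape[axis] < 2:
        raise ValueError("need at least 2 trials")
    if np.iscomplexobj(a):
        a = np.angle(a)
    if np.iscomplexobj(b):
        b = np.angle(b)
    return np.mean(np.exp(1j * (a - b)), axis=axis)


@dataclass
class ConnectivitySet:
    """Per-pair complex coherency and phase resultant on a (freq, time) grid.

    ``coh`` and ``plv_resultant`` have shape (n_pairs, n_freqs, n_times).
    Scalar views (via :meth:`values`) collapse the frequency axis after the
    metric is formed per 1-Hz bin; ``smooth`` (seconds) optionally applies
    an extra boxcar to the metric time course.
    """

    pairs: list[tuple[str, str]]
    band: str
    freqs: np.ndarray
    times: np.ndarray
    coh: np.ndarray
    plv_resultant: np.ndarray
    n_trials: int
    smooth: float = 0.0

    def __post_init__(self) -> None:
        for name, arr in (("coh", self.coh), ("plv", self.plv_resultant)):
            mags = np.abs(arr[np.isfinite(arr)])
            if mags.size and mags.max() > 1 + 1e-9:
                raise ValueError(f"{name} magnitude exceeds 1")

    def values(self, metric: str) -> np.ndarray:
        """Scalar (n_pairs, n_times) view for one metric."""
        if metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        base = self.coh if metric in ("coherence", "icoh") else self.plv_resultant
        scalar = np.abs(base) if metric in ("coherence", "plv") else np.imag(base)
        out = np.nanmean(scalar, axis=1)  # band mean after per-bin metric
        if self.smooth and self.times.size > 1:
            dt = float(np.median(np.diff(self.times)))
            size = max(1, int(round(self.smooth / dt)))
            out = uniform_filter1d(out, size=size, axis=-1, mode="nearest")
        return out

    def time_average(self, metric: str) -> np.ndarray:
        """Per-pair scalar averaged over the window (baseline use)."""
        return np.nanmean(self.values(metric), axis=-1)


@dataclass
class PairValues:
    """A scalar per-pair time course (possibly baseline-corrected)."""

    pairs: list[tuple[str, str]]
    times: np.ndarray
    values: np.ndarray  # (n_pairs, n_times)
    metric: str
    corrected: bool = False


def all_pairs(ch_names) -> list[tuple[str, str]]:
    names = list(ch_names)
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]


def pairwise_connectivity(
    tensor: SpectralTensor,
    ch_names: list[str],
    pairs: list[tuple[str, str]],
    band: str = "",
    smooth: float = 0.0,
) -> ConnectivitySet:
    """Coherency and phase resultant for the given channel pairs.

    Time points where the taper support was invalid (NaN coefficients)
    propagate as NaN; callers normally slice to the valid analysis window.
    """
    index = {c: i for i, c in enumerate(ch_names)}
    ia = np.array([index[a] for a, _ in pairs])
    ib = np.array([index[b] for _, b in pairs])
    ca = tensor.coeffs[:, ia]  # (trials, pairs, freqs, times)
    cb = tensor.coeffs[:, ib]
    coh = coherency(ca, cb, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        za = ca / np.abs(ca)
        zb = cb / np.abs(cb)
    resultant = np.mean(za * np.conj(zb), axis=0)
    return ConnectivitySet(
        pairs=list(pairs),
        band=band,
        freqs=tensor.freqs,
        times=tensor.times,
        coh=coh,
        plv_resultant=resultant,
        n_trials=tensor.coeffs.shape[0],
        smooth=smooth,
    )


def windowed_connectivity(
    epochs: EpochSet,
    band: str,
    window: tuple[float, float],
    pairs: list[tuple[str, str]] | None = None,
    channels: list[str] | None = None,
    t_step: float = 0.005,
    subwindow: float = 0.1,
    smooth: float = 0.0,
) -> ConnectivitySet:
    """Band connectivity time course inside an analysis window.

    Per-trial complex coefficients are fixed-duration Hanning-windowed
    Fourier coefficients (default 100-ms sub-windows) slid across the
    analysis window in ``t_step`` steps; metrics are formed per 1-Hz bin
    across trials at each step and band-averaged. ``smooth`` adds an
    optional extra boxcar on the metric time course.
    """
    if window[0] < epochs.times[0] or window[1] > epochs.times[-1] + 1 / epochs.fs:
        raise ValueError("analysis window lies outside the epoch")
    if channels is not None:
        epochs = epochs.pick(channels)
    if pairs is None:
        pairs = all_pairs(epochs.ch_names)
    f_lo, f_hi = BANDS[band] if isinstance(band, str) else band
    freqs = np.arange(f_lo, f_hi + 1)
    tensor = tfr_hanning(epochs, freqs, t_step=t_step, window_s=subwindow)
    # drop frequencies with no valid coefficient anywhere in the window
    tensor = tensor.time_slice(*window)
    keep = ~np.all(np.isnan(tensor.coeffs), axis=(0, 1, 3))
    tensor = SpectralTensor(
        coeffs=tensor.coeffs[:, :, keep],
        freqs=tensor.freqs[keep],
        times=tensor.times,
        fs=tensor.fs,
        n_cycles=tensor.n_cycles,
        missing_freqs=tensor.missing_freqs + tuple(tensor.freqs[~keep]),
    )
    if tensor.freqs.size == 0:
        raise ValueError(f"no frequency of band {band!r} fits the epoch/window")
    return pairwise_connectivity(
        tensor, epochs.ch_names, pairs, band=str(band), smooth=smooth
    )


def baseline_correct(
    conn3: ConnectivitySet, conn1: ConnectivitySet, metric: str
) -> PairValues:
    """Third-stage minus first-stage connectivity (plain subtraction).

    The first-stage value is the time average over its own matched-length
    window, per pair. Corrected values lie in [-1, 1] and keep the sign
    interpretation of the condition contrast.
    """
    if conn3.pairs != conn1.pairs:
        raise ValueError("pair sets differ between stages")
    corrected = conn3.values(metric) - conn1.time_average(metric)[:, None]
    return PairValues(
        pairs=list(conn3.pairs),
        times=conn3.times,
        values=corrected,
        metric=metric,
        corrected=True,
    )
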