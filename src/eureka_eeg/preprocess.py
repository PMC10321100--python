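"""Filtering, trial labeling, RT screening and trial-count equalization.

Labeling rule: a trial is ``Aha`` when its second-stage cue was congruent
and the third-stage response was "Yes"; ``Ctrl`` when the cue was
incongruent and the response was "No"; every other combination is
discarded. Only third-stage trials with RT strictly longer than 0.5 s
enter the analyses, and the larger condition group is randomly subsampled
to the smaller one's size before any Aha-vs-Ctrl comparison.

Artifact handling here is a simple peak-amplitude rejector; the visual /
ICA cleaning applied to real recordings is a manual process outside this
package's scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet

logger = logging.getLogger(__name__)

DEFAULT_HP_HZ = 0.3
DEFAULT_NOTCH_HZ = 50.0
MIN_RT_S = 0.5


def filter_continuous(
    data: np.ndarray,
    fs: float,
    hp_hz: float = DEFAULT_HP_HZ,
    notch_hz: float = DEFAULT_NOTCH_HZ,
    notch_q: float = 35.0,
) -> np.ndarray:
    """Zero-phase high-pass and notch filtering of continuous data.

    4th-order Butterworth high-pass (applied forward-backward) plus a
    2nd-order IIR notch; works on (..., n_samples) arrays.
    """
    if fs <= 2 * notch_hz:
        raise ValueError(f"fs = {fs} too low for a {notch_hz} Hz notch")
    data = np.asarray(data, dtype=float)
    # reflect-pad on the scale of the high-pass time constant, else edge
    # transients of the 0.3 Hz stage leak deep into the recording
    padlen = min(data.shape[-1] - 1, int(3 * fs / hp_hz))
    sos = signal.butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    out = signal.filtfilt(b, a, out, axis=-1, padlen=padlen)
    return out - out.mean(axis=-1, keepdims=True)


def label_trials(meta: pd.DataFrame) -> pd.DataFrame:
    """Assign condition labels from (congruent, response).

    Aha <=> congruent cue and "Yes"; Ctrl <=> incongruent cue and "No";
    everything else -> discard. Idempotent: relabeling changes nothing.
    """
    for col in ("congruent", "response"):
        if col not in meta.columns:
            raise ValueError(f"meta lacks required column {col!r}")
    out = meta.copy()
    congruent = out["congruent"].astype(bool)
    response = out["response"].astype(str)
    condition = np.where(
        congruent & (response == "Yes"),
        "Aha",
        np.where(~congruent & (response == "No"), "Ctrl", "discard"),
    )
    out["condition"] = condition
    return out


def screen_rt(epochs: EpochSet, min_rt: float = MIN_RT_S) -> EpochSet:
    """Keep only trials with RT strictly longer than ``min_rt`` seconds.

    Trials without a defined RT (first-stage presentations) are kept.
    An empty result is allowed and logged.
    """
    rt = epochs.meta["rt"].to_numpy(dtype=float)
    keep = np.isnan(rt) | (rt > min_rt)
    out = epochs.take(np.flatnonzero(keep))
    if out.n_trials == 0:
        logger.warning("RT screening removed every trial")
    else:
        logger.info("RT screening kept %d/%d trials", out.n_trials, epochs.n_trials)
    return out


def equalize_counts(
    aha: EpochSet, ctrl: EpochSet, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Randomly subsample the larger group to the smaller group's count.

    Sampling is without replacement and seed-deterministic; equal counts
    pass through untouched (no randomness consumed).
    """
    if aha.n_trials == 0 or ctrl.n_trials == 0:
        raise ValueError("both groups must be nonempty")
    if aha.n_trials == ctrl.n_trials:
        return aha, ctrl
    rng = np.random.default_rng(seed)
    target = min(aha.n_trials, ctrl.n_trials)
    larger, smaller = (aha, ctrl) if aha.n_trials > ctrl.n_trials else (ctrl, aha)
    idx = np.sort(rng.choice(larger.n_trials, size=target, replace=False))
    subsampled = larger.take(idx)
    return (subsampled, smaller) if larger is aha else (smaller, subsampled)


def reject_amplitude(epochs: EpochSet, threshold_uv: float) -> EpochSet:
    """Drop trials whose peak |amplitude| exceeds the threshold anywhere.

    A stand-in artifact rejector for synthetic and fixture data.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    n_dropped = int((~keep).sum())
    if n_dropped == epochs.n_trials:
        logger.warning("amplitude rejection dropped every trial (threshold %.1f uV)",
                       threshold_uv)
    elif n_dropped:
        logger.info("amplitude rejection dropped %d/%d trials", n_dropped,
                    epochs.n_trials)
    return epochs.take(np.flatnonzero(keep))


def extract_epochs(
    continuous: np.ndarray,
    fs: float,
    ch_names: list[str],
    event_samples: np.ndarray,
    meta: pd.DataFrame,
    tmin: float = -1.0,
    tmax: float = 1.0,
) -> EpochSet:
    """Cut alignment-event-locked epochs out of a continuous recording."""
    continuous = np.asarray(continuous, dtype=float)
    offsets = np.arange(int(round(tmin * fs)), int(round(tmax * fs)))
    trials = []
    for s in np.asarray(event_samples, dtype=int):
        idx = s + offsets
        if idx[0] < 0 or idx[-1] >= continuous.shape[-1]:
            raise ValueError(f"epoch around sample {s} exceeds the recording")
        trials.append(continuous[:, idx])
    return EpochSet(
        data=np.stack(trials),
        fs=fs,
        ch_names=list(ch_names),
        tmin=tmin,
        meta=meta,
    )


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read a standard EDF/EDF+ recording (requires the ``edf`` extra).

    Returns ``(data_uv, fs, ch_names)`` with data in microvolts. Untested
    against any specific study's recordings; provided for real-data use.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires mne (pip install eureka-eeg[edf])") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
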