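"""Epoched multichannel EEG container.

The :class:`EpochSet` is the pipeline's central object: a ``trials x
channels x samples`` array (microvolts) with per-trial metadata describing
the experimental cell each trial belongs to — condition (``Aha`` /
``Ctrl`` / ``discard``), presentation stage (``first`` / ``third``),
alignment of the time axis (stimulus onset or manual response) and the
reaction time of the third-stage response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("Aha", "Ctrl", "discard")
STAGES = ("first", "third")
ALIGNMENTS = ("stimulus", "response")

#: metadata columns every EpochSet carries
META_COLUMNS = ("condition", "stage", "alignment", "rt")


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoch voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel names, one per data row.
    tmin : float
        Time of the first sample relative to the alignment event, seconds.
    meta : pandas.DataFrame
        One row per trial; must contain ``condition``, ``stage``,
        ``alignment`` and ``rt`` (NaN where undefined, e.g. first-stage
        presentations without a response).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    tmin: float
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length does not match data")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta length does not match number of trials")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise ValueError(f"meta lacks columns: {sorted(missing)}")
        rt = self.meta["rt"].to_numpy(dtype=float)
        if np.any(rt[np.isfinite(rt)] <= 0):
            raise ValueError("defined reaction times must be positive")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the alignment event."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    # -- selection ---------------------------------------------------------
    def select(self, **filters) -> "EpochSet":
        """Subset trials by metadata equality, e.g. ``select(condition="Aha")``."""
        mask = np.ones(self.n_trials, dtype=bool)
        for key, value in filters.items():
            mask &= (self.meta[key] == value).to_numpy()
        return self.take(np.flatnonzero(mask))

    def take(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[indices],
            fs=self.fs,
            ch_names=list(self.ch_names),
            tmin=self.tmin,
            meta=self.meta.iloc[indices].reset_index(drop=True),
        )

    def pick(self, channels) -> "EpochSet":
        """Restrict to the named channels, in the given order."""
        idx = [self.ch_names.index(ch) for ch in channels]
        return EpochSet(
            data=self.data[:, idx],
            fs=self.fs,
            ch_names=list(channels),
            tmin=self.tmin,
            meta=self.meta.copy(),
        )

    def time_slice(self, t_start: float, t_stop: float) -> "EpochSet":
        """Crop to ``t_start <= t < t_stop`` (seconds, alignment-relative)."""
        t = self.times
        mask = (t >= t_start) & (t < t_stop)
        if not mask.any():
            raise ValueError("requested time window lies outside the epoch")
        first = int(np.flatnonzero(mask)[0])
        return EpochSet(
            data=self.data[:, :, mask],
            fs=self.fs,
            ch_names=list(self.ch_names),
            tmin=float(t[first]),
            meta=self.meta.copy(),
        )

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write the epoch container: ``/data`` array + ``/meta`` JSON block."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            meta = {
                "fs": self.fs,
                "ch_names": list(self.ch_names),
                "tmin": self.tmin,
                "trials": self.meta.to_dict(orient="list"),
            }
            f.create_dataset("meta", data=json.dumps(meta))

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            meta = json.loads(f["meta"][()])
        return cls(
            data=data,
            fs=float(meta["fs"]),
            ch_names=list(meta["ch_names"]),
            tmin=float(meta["tmin"]),
            meta=pd.DataFrame(meta["trials"]),
        )


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack EpochSets sharing fs, channels and time axis."""
    first = parts[0]
    for p in parts[1:]:
        if p.fs != first.fs or p.ch_names != first.ch_names:
            raise ValueError("cannot concatenate: channel sets or fs differ")
        if p.n_samples != first.n_samples or p.tmin != first.tmin:
            raise ValueError("cannot concatenate: time axes differ")
    return EpochSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        fs=first.fs,
        ch_names=list(first.ch_names),
        tmin=first.tmin,
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
    )
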