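"""Synthetic EEG with known ground truth.

Every downstream stage of the pipeline (spectral contrasts, coherence/PLV,
laterality indices, dimension curves, cluster statistics) has a recovery
test built on this generator. Epochs are sums of

* band-limited oscillations whose across-trial phase structure is
  parameterized directly: member channels of a coupling entry share a
  common per-trial phase, each perturbed by von Mises jitter of
  concentration ``kappa``. ``kappa = 0`` gives independent uniform phases
  (no locking); large ``kappa`` gives a deterministic phase relation, so
  the expected PLV between two members is ``(I1(kappa)/I0(kappa))**2``;
* 1/f-shaped Gaussian background noise (configurable spectral exponent);
* an optional instantaneous (zero-lag) linear mixing matrix emulating
  volume conduction — the confound the imaginary-part connectivity
  measures are designed to suppress.

Reaction times are lognormal per condition; the default location/shape
parameters reproduce the reported medians (Aha 1.13 s, Ctrl 2.00 s) and
distribution peaks (0.90 s / 1.50 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet, concat_epochs
from .montage import montage_1020

__all__ = [
    "Oscillation",
    "SynthSpec",
    "ManifoldCloud",
    "generate_epochs",
    "generate_null_pair",
    "generate_manifold",
]

# lognormal RT parameters (mu = ln median; sigma from ln(median/mode))
RT_DEFAULTS = {
    "Aha": (float(np.log(1.13)), float(np.sqrt(np.log(1.13 / 0.90)))),
    "Ctrl": (float(np.log(2.00)), float(np.sqrt(np.log(2.00 / 1.50)))),
}


@dataclass(frozen=True)
class Oscillation:
    """One band-limited source injected into a subset of trials/channels.

    ``kappa`` controls across-trial phase locking between the member
    channels; ``phase_lag`` adds a fixed per-channel-index lag (radians)
    so non-zero-lag coupling (visible to iCOH/iPLV) can be simulated.
    ``condition`` / ``stage`` restrict the entry to matching cells
    (``None`` matches every cell); ``window`` restricts it in time.
    """

    channels: tuple[str, ...]
    f_lo: float
    f_hi: float
    amplitude: float = 1.0
    kappa: float = 0.0
    phase_lag: float = 0.0
    window: tuple[float, float] | None = None
    condition: str | None = None
    stage: str | None = None
    amp_jitter: float = 0.25  # lognormal sigma of the per-trial amplitude

    def matches(self, condition: str, stage: str) -> bool:
        return (self.condition in (None, condition)) and (self.stage in (None, stage))


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic recording session."""

    n_trials_per_cell: int = 40
    channels: tuple[str, ...] = tuple(montage_1020().li_channels())
    fs: float = 1000.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    bands: tuple[Oscillation, ...] = ()       # background, kappa typically 0
    coupling: tuple[Oscillation, ...] = ()    # phase-coupled entries
    mixing: np.ndarray | None = None          # channels x channels, zero lag
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0             # microvolts RMS
    rt_distribution: dict = field(default_factory=lambda: dict(RT_DEFAULTS))
    alignment: str = "stimulus"
    seed: int = 0

    def validate(self) -> None:
        nyq = self.fs / 2
        for osc in self.bands + self.coupling:
            if not (0 < osc.f_lo < osc.f_hi < nyq):
                raise ValueError(
                    f"band edges ({osc.f_lo}, {osc.f_hi}) must satisfy "
                    f"0 < f_lo < f_hi < fs/2 = {nyq}"
                )
            if osc.kappa < 0:
                raise ValueError("kappa must be nonnegative")
            unknown = set(osc.channels) - set(self.channels)
            if unknown:
                raise ValueError(f"oscillation references unknown channels {sorted(unknown)}")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            n = len(self.channels)
            if m.shape != (n, n):
                raise ValueError(f"mixing matrix must be square {n}x{n}, got {m.shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError("mixing matrix rows must be finite")
        if self.n_trials_per_cell < 1:
            raise ValueError("n_trials_per_cell must be >= 1")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must be increasing")

    def has_condition_effects(self) -> bool:
        return any(o.condition is not None for o in self.bands + self.coupling)


@dataclass
class ManifoldCloud:
    """Point cloud with known intrinsic dimension, for dimension-recovery tests."""

    points: np.ndarray
    true_dimension: float
    kind: str


def _tukey(n: int, alpha: float = 0.2) -> np.ndarray:
    from scipy.signal.windows import tukey

    return tukey(n, alpha)


def _cell_signals(spec: SynthSpec, condition: str, stage: str,
                  rng: np.random.Generator) -> np.ndarray:
    """Unmixed source signals for one (condition, stage) cell."""
    n_tr = spec.n_trials_per_cell
    t = spec.epoch_window[0] + np.arange(
        int(round((spec.epoch_window[1] - spec.epoch_window[0]) * spec.fs))
    ) / spec.fs
    n_samp = t.size
    n_ch = len(spec.channels)
    ch_index = {c: i for i, c in enumerate(spec.channels)}
    data = np.zeros((n_tr, n_ch, n_samp))

    for osc in spec.bands + spec.coupling:
        if not osc.matches(condition, stage):
            continue
        idx = [ch_index[c] for c in osc.channels]
        f = rng.uniform(osc.f_lo, osc.f_hi, size=n_tr)           # shared across members
        common = rng.uniform(0, 2 * np.pi, size=n_tr)
        jitter = rng.vonmises(0.0, osc.kappa, size=(n_tr, len(idx)))
        amp = osc.amplitude * rng.lognormal(0.0, osc.amp_jitter, size=n_tr)
        lags = osc.phase_lag * np.arange(len(idx))
        phases = common[:, None] + lags[None, :] + jitter        # (n_tr, n_members)

        if osc.window is None:
            env = np.ones(n_samp)
        else:
            env = np.zeros(n_samp)
            mask = (t >= osc.window[0]) & (t < osc.window[1])
            if mask.any():
                env[mask] = _tukey(int(mask.sum()))
        wave = np.cos(
            2 * np.pi * f[:, None, None] * t[None, None, :] + phases[:, :, None]
        )
        data[:, idx, :] += amp[:, None, None] * env[None, None, :] * wave

    # 1/f background noise, normalized per trace to the requested RMS
    if spec.noise_amplitude > 0:
        white = rng.standard_normal((n_tr, n_ch, n_samp))
        spectrum = np.fft.rfft(white, axis=-1)
        freqs = np.fft.rfftfreq(n_samp, d=1 / spec.fs)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-spec.noise_exponent / 2)
        noise = np.fft.irfft(spectrum * shape, n=n_samp, axis=-1)
        rms = noise.std(axis=-1, keepdims=True)
        rms[rms == 0] = 1.0
        data += spec.noise_amplitude * noise / rms

    if spec.mixing is not None:
        m = np.asarray(spec.mixing, dtype=float)
        data = np.einsum("ij,kjs->kis", m, data)
    return data


def generate_epochs(spec: SynthSpec) -> EpochSet:
    """Draw the four-cell (Aha/Ctrl x first/third) synthetic EpochSet.

    Identical spec (including seed) gives bit-identical output.
    """
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed).spawn(5)
    rt_rng = np.random.default_rng(seeds[4])
    parts = []
    for i, (condition, stage) in enumerate(
        [("Aha", "first"), ("Aha", "third"), ("Ctrl", "first"), ("Ctrl", "third")]
    ):
        rng = np.random.default_rng(seeds[i])
        data = _cell_signals(spec, condition, stage, rng)
        mu, sigma = spec.rt_distribution[condition]
        if stage == "third":
            rt = rt_rng.lognormal(mu, sigma, size=spec.n_trials_per_cell)
        else:
            rt = np.full(spec.n_trials_per_cell, np.nan)
        meta = pd.DataFrame(
            {
                "condition": condition,
                "stage": stage,
                "alignment": spec.alignment,
                "rt": rt,
            }
        )
        parts.append(
            EpochSet(data=data, fs=spec.fs, ch_names=list(spec.channels),
                     tmin=spec.epoch_window[0], meta=meta)
        )
    return concat_epochs(parts)


def generate_null_pair(spec: SynthSpec) -> tuple[EpochSet, EpochSet]:
    """Two label-sets drawn from one generative process (true null).

    Any Aha-vs-Ctrl difference detected downstream is a false positive by
    construction. Rejects specs that contain condition-dependent effects.
    """
    spec.validate()
    if spec.has_condition_effects():
        raise ValueError("null pair requires a spec without condition-dependent effects")
    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    a = generate_epochs(replace(spec, seed=int(seeds[0].generate_state(1)[0] % 2**31)))
    b = generate_epochs(replace(spec, seed=int(seeds[1].generate_state(1)[0] % 2**31)))
    return a, b


# minimum ambient dimension needed to embed each manifold
_MANIFOLD_DIMS = {"line": 1, "circle": 2, "square": 2, "gaussian_iid": None}


def generate_manifold(kind: str, n: int, m: int, seed: int = 0) -> ManifoldCloud:
    """Sample ``n`` points on a named manifold embedded in ``m`` dimensions.

    ``line``/``circle``/``square`` are uniform on the unit manifold and
    rotated into the ambient space by a seeded orthogonal matrix;
    ``gaussian_iid`` is standard normal with intrinsic dimension ``m``.
    """
    if kind not in _MANIFOLD_DIMS:
        raise ValueError(f"unknown manifold kind {kind!r}")
    if n < 100:
        raise ValueError("n must be >= 100")
    min_ambient = _MANIFOLD_DIMS[kind]
    if min_ambient is not None and m < min_ambient:
        raise ValueError(
            f"ambient dimension {m} too small to embed a {kind} (needs >= {min_ambient})"
        )
    rng = np.random.default_rng(seed)
    if kind == "gaussian_iid":
        return ManifoldCloud(rng.standard_normal((n, m)), float(m), kind)
    local = np.zeros((n, m))
    if kind == "line":
        local[:, 0] = rng.uniform(0, 1, n)
        dim = 1.0
    elif kind == "circle":
        theta = rng.uniform(0, 2 * np.pi, n)
        local[:, 0] = np.cos(theta)
        local[:, 1] = np.sin(theta)
        dim = 1.0
    else:  # square
        local[:, :2] = rng.uniform(0, 1, (n, 2))
        dim = 2.0
    q, _ = np.linalg.qr(rng.standard_normal((m, m)))
    return ManifoldCloud(local @ q.T, dim, kind)
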