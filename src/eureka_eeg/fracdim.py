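"""Scale-resolved correlation dimension of multichannel activity vectors.

The correlation integral of a point cloud is C(delta) = (1/n^2) |{(i, j):
i != j, |x_i - x_j| < delta}| (ordered pairs, strict inequality); the
correlation dimension at a scale is the local slope of ln C(delta) versus
ln delta. The slope generally changes across scales, so the whole curve is
reported rather than a single number.

For EEG, the points are the per-sample channel vectors of one regional
electrode cluster (z-scored per channel, pooled across trials within the
analysis window); a third-stage curve minus the first-stage curve gives
the baseline-corrected change per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from . import cluster_stats
from .epochs import EpochSet
from .laterality import laterality_index
from .montage import Montage


@dataclass
class DimensionCurve:
    """Correlation integral and local slope on an ln(delta) grid."""

    ln_delta: np.ndarray
    c_delta: np.ndarray
    d_local: np.ndarray  # NaN at grid ends and where C = 0
    cluster: str = ""
    condition: str = ""
    n_points: int = 0


def zscore(epochs: EpochSet, window: tuple[float, float] | None = None) -> EpochSet:
    """Per-channel standardization over the analysis window.

    The mean and variance are pooled across trials and samples per
    channel, so affine per-channel transforms of the input are removed
    exactly. Zero-variance channels are rejected.
    """
    out = epochs if window is None else epochs.time_slice(*window)
    data = out.data
    mean = data.mean(axis=(0, 2), keepdims=True)
    std = data.std(axis=(0, 2), keepdims=True)
    degenerate = std <= 1e-12 * (np.abs(mean) + 1.0)
    if np.any(degenerate):
        bad = [out.ch_names[i] for i in np.flatnonzero(degenerate.ravel())]
        raise ValueError(f"zero-variance channels: {bad}")
    return EpochSet(
        data=(data - mean) / std,
        fs=out.fs,
        ch_names=list(out.ch_names),
        tmin=out.tmin,
        meta=out.meta.copy(),
    )


def correlation_integral(points: np.ndarray, deltas) -> np.ndarray:
    """C(delta) under the 1/n^2 ordered-pair normalization (strict <)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n >= 2) x m point array")
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    if np.any(deltas <= 0):
        raise ValueError("scales must be positive")
    n = pts.shape[0]
    dists = np.sort(pdist(pts))
    counts = np.searchsorted(dists, deltas, side="left")  # pairs with d < delta
    return 2.0 * counts / n**2


def dimension_curve(
    points: np.ndarray,
    ln_delta_grid: np.ndarray | None = None,
    n_scales: int = 40,
) -> DimensionCurve:
    """Scale-resolved dimension: central differences of ln C over ln delta.

    The default grid is log-spaced between the 1st and 99th percentile of
    the pairwise distances. Bins with C = 0 (and the grid ends) are NaN.
    """
    pts = np.asarray(points, dtype=float)
    if ln_delta_grid is None:
        d = pdist(pts)
        d = d[d > 0]
        if d.size == 0:
            raise ValueError("degenerate cloud: all points identical")
        lo, hi = np.percentile(d, [1, 99])
        ln_delta_grid = np.linspace(np.log(lo), np.log(hi), n_scales)
    ln_delta_grid = np.asarray(ln_delta_grid, dtype=float)
    if ln_delta_grid.size < 3:
        raise ValueError("need at least 3 grid points")
    c = correlation_integral(pts, np.exp(ln_delta_grid))
    if np.count_nonzero(c > 0) < 3:
        raise ValueError("fewer than 3 usable scales (C > 0)")
    with np.errstate(divide="ignore"):
        ln_c = np.where(c > 0, np.log(c), np.nan)
    d_local = np.full_like(ln_delta_grid, np.nan)
    d_local[1:-1] = (ln_c[2:] - ln_c[:-2]) / (ln_delta_grid[2:] - ln_delta_grid[:-2])
    return DimensionCurve(
        ln_delta=ln_delta_grid, c_delta=c, d_local=d_local, n_points=pts.shape[0]
    )


def plateau(curve: DimensionCurve, c_range: tuple[float, float] = (0.005, 0.05)) -> float:
    """Mid-scale plateau estimate: median local slope where C(delta) lies
    in ``c_range``: scales with enough pairs to be stable yet small enough
    that boundary effects (which bias the slope low near saturation) stay
    negligible."""
    sel = (curve.c_delta >= c_range[0]) & (curve.c_delta <= c_range[1])
    sel &= np.isfinite(curve.d_local)
    if not sel.any():
        raise ValueError("no usable scale bins in the plateau range")
    return float(np.median(curve.d_local[sel]))


def _cluster_points(
    cell: EpochSet, channels, decimate_s: float, max_points: int, rng
) -> np.ndarray:
    picked = cell.pick(list(channels))
    step = max(1, int(round(decimate_s * picked.fs)))
    data = picked.data[:, :, ::step]  # (trials, m, samples)
    pts = np.transpose(data, (0, 2, 1)).reshape(-1, data.shape[1])
    if max_points and pts.shape[0] > max_points:
        pts = pts[rng.choice(pts.shape[0], size=max_points, replace=False)]
    return pts


def cluster_dimension(
    epochs: EpochSet,
    montage: Montage,
    window: tuple[float, float] = (0.0, 0.5),
    ln_delta_grid: np.ndarray | None = None,
    decimate_s: float = 0.005,
    max_points: int = 2000,
    seed: int = 0,
    baseline_window: tuple[float, float] | None = None,
):
    """Dimension curves per regional electrode cluster and condition.

    Activity vectors are the per-sample m-channel value vectors of each
    cluster (m = cluster size), z-scored per channel and pooled across
    trials within the window, optionally decimated and subsampled to
    ``max_points``. Returns ``(raw, corrected)`` dicts keyed by
    ``(cluster, condition)``: raw third-stage curves and third-minus-first
    corrected curves on a shared ln(delta) grid.
    """
    if not montage.clusters:
        raise ValueError("montage defines no regional clusters")
    missing = set().union(*montage.clusters.values()) - set(epochs.ch_names)
    if missing:
        raise ValueError(f"cluster channels missing from data: {sorted(missing)}")
    if baseline_window is None:
        baseline_window = window
    if ln_delta_grid is None:
        # z-scored m-channel vectors: typical distances ~ sqrt(2 m)
        ln_delta_grid = np.linspace(0.0, 2.3, 40)
    rng = np.random.default_rng(seed)
    raw: dict[tuple[str, str], DimensionCurve] = {}
    corrected: dict[tuple[str, str], DimensionCurve] = {}
    for condition in ("Aha", "Ctrl"):
        stage3 = zscore(epochs.select(condition=condition, stage="third"), window)
        stage1 = zscore(epochs.select(condition=condition, stage="first"), baseline_window)
        for label, channels in montage.clusters.items():
            curves = {}
            for stage_name, cell in (("third", stage3), ("first", stage1)):
                pts = _cluster_points(cell, channels, decimate_s, max_points, rng)
                curve = dimension_curve(pts, ln_delta_grid)
                curve.cluster, curve.condition = label, condition
                curves[stage_name] = curve
            raw[label, condition] = curves["third"]
            corrected[label, condition] = DimensionCurve(
                ln_delta=ln_delta_grid,
                c_delta=curves["third"].c_delta,
                d_local=curves["third"].d_local - curves["first"].d_local,
                cluster=label,
                condition=condition,
                n_points=curves["third"].n_points,
            )
    return raw, corrected


def dimension_li(
    d_right_aha: np.ndarray,
    d_left_aha: np.ndarray,
    d_right_ctrl: np.ndarray,
    d_left_ctrl: np.ndarray,
    ln_delta: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Laterality of local dimension per scale bin, Aha versus Ctrl.

    Inputs are (n_subjects, n_bins) local-dimension arrays for the paired
    right/left clusters. LI is formed per subject, condition and scale
    bin; the condition difference is tested with the cluster permutation
    test over contiguous scale bins. Returns an
    :class:`~eureka_eeg.laterality.LIContrast`-style result: (li_aha,
    li_ctrl, difference, mask, test).
    """
    from .laterality import LIContrast

    li_aha = laterality_index(d_right_aha, d_left_aha)
    li_ctrl = laterality_index(d_right_ctrl, d_left_ctrl)
    if li_aha.shape != li_ctrl.shape:
        raise ValueError("scale grids differ between conditions")
    finite = np.all(np.isfinite(li_aha), axis=0) & np.all(np.isfinite(li_ctrl), axis=0)
    test = cluster_stats.permutation_test(
        np.where(finite, li_aha, 0.0),
        np.where(finite, li_ctrl, 0.0),
        adjacency=None,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )
    difference = np.full(li_aha.shape[1], np.nan)
    difference[finite] = np.mean(li_aha - li_ctrl, axis=0)[finite]
    return LIContrast(
        times=np.asarray(ln_delta),
        li_aha=li_aha,
        li_ctrl=li_ctrl,
        difference=difference,
        mask=test.mask((1, li_aha.shape[1]))[0],
        test=test,
    )
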