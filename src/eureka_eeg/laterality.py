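"""Hemispheric laterality index LI = (V_R - V_L) / (V_R + V_L).

V_R and V_L are averages over hemisphere-classified values: for
connectivity metrics, over electrode-pair values where right pairs are the
intra-right combinations plus right-midline combinations (left
correspondingly); cross-hemisphere and intra-midline pairs are excluded.
For regional quantities (power, dimension) V_R/V_L are the right/left
cluster values directly. Positive LI means right-lateralized.

Imaginary-part metrics (iCOH, iPLV) feed their absolute values into
V_R/V_L: the lead/lag sign is not a lateralization quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from . import cluster_stats
from .connectivity import PairValues
from .montage import Montage


@dataclass
class LITimecourse:
    """LI per time (or scale) bin, with the V_R/V_L it was formed from."""

    times: np.ndarray
    li: np.ndarray
    v_right: np.ndarray
    v_left: np.ndarray
    metric: str = ""
    #: which pairs fed V_R and V_L (the classification manifest)
    right_pairs: list = None
    left_pairs: list = None


@dataclass
class LIContrast:
    """Aha-vs-Ctrl LI difference with a temporal-cluster significance mask."""

    times: np.ndarray
    li_aha: np.ndarray       # (n_subjects, n_bins)
    li_ctrl: np.ndarray
    difference: np.ndarray   # mean over subjects of (aha - ctrl)
    mask: np.ndarray         # significant bins
    test: cluster_stats.ClusterTestResult


def classify_pairs(montage: Montage):
    """Split channel pairs into right, left and excluded sets.

    right = C(right, 2) + right x midline; left likewise; everything
    crossing hemispheres or lying within the midline is excluded.
    """
    r, l, m = set(montage.right), set(montage.left), set(montage.midline)
    if r & l or r & m or l & m:
        raise ValueError("electrode sets overlap")
    right_pairs = [tuple(p) for p in combinations(sorted(r), 2)]
    right_pairs += [tuple(p) for p in product(sorted(r), sorted(m))]
    left_pairs = [tuple(p) for p in combinations(sorted(l), 2)]
    left_pairs += [tuple(p) for p in product(sorted(l), sorted(m))]
    used = {frozenset(p) for p in right_pairs} | {frozenset(p) for p in left_pairs}
    excluded = [
        tuple(p)
        for p in combinations(sorted(r | l | m), 2)
        if frozenset(p) not in used
    ]
    return right_pairs, left_pairs, excluded


def laterality_index(v_right, v_left):
    """(V_R - V_L) / (V_R + V_L); NaN where the denominator is zero.

    Nonnegative inputs give LI in [-1, 1]; baseline-corrected connectivity
    values can be negative and push LI outside that range — such values
    are returned as-is (callers may flag them).
    """
    vr = np.asarray(v_right, dtype=float)
    vl = np.asarray(v_left, dtype=float)
    denom = vr + vl
    with np.errstate(invalid="ignore", divide="ignore"):
        li = (vr - vl) / denom
    return np.where(denom != 0, li, np.nan)


def li_timecourse(
    pair_values: PairValues, montage: Montage, absolute: bool | None = None
) -> LITimecourse:
    """LI per time bin from per-pair connectivity values.

    ``absolute`` defaults to True for imaginary-part metrics and False
    otherwise.
    """
    if absolute is None:
        absolute = pair_values.metric.startswith("i")
    right_pairs, left_pairs, _ = classify_pairs(montage)
    index = {frozenset(p): i for i, p in enumerate(pair_values.pairs)}
    try:
        ri = [index[frozenset(p)] for p in right_pairs]
        li_ = [index[frozenset(p)] for p in left_pairs]
    except KeyError as err:
        raise ValueError(f"pair {err} missing from the connectivity set") from None
    values = np.abs(pair_values.values) if absolute else pair_values.values
    v_r = values[ri].mean(axis=0)
    v_l = values[li_].mean(axis=0)
    return LITimecourse(
        times=pair_values.times,
        li=laterality_index(v_r, v_l),
        v_right=v_r,
        v_left=v_l,
        metric=pair_values.metric,
        right_pairs=right_pairs,
        left_pairs=left_pairs,
    )


def li_contrast_timecourse(
    aha: list[PairValues],
    ctrl: list[PairValues],
    montage: Montage,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    absolute: bool | None = None,
) -> LIContrast:
    """Subject-level LI time courses compared across conditions.

    ``aha`` and ``ctrl`` hold one PairValues per subject (matched order).
    Per-bin LI is formed per subject and condition; the paired Aha-Ctrl
    difference is tested with the temporal cluster permutation test.
    """
    if len(aha) != len(ctrl) or not aha:
        raise ValueError("need matched, nonempty per-subject lists")
    times = aha[0].times
    for pv in aha + ctrl:
        if pv.times.shape != times.shape or not np.allclose(pv.times, times):
            raise ValueError("time bins differ across subjects/conditions")
    li_aha = np.stack([li_timecourse(pv, montage, absolute).li for pv in aha])
    li_ctrl = np.stack([li_timecourse(pv, montage, absolute).li for pv in ctrl])
    test = cluster_stats.permutation_test(
        li_aha, li_ctrl, adjacency=None, n_perm=n_perm, alpha=alpha, seed=seed
    )
    return LIContrast(
        times=times,
        li_aha=li_aha,
        li_ctrl=li_ctrl,
        difference=(li_aha - li_ctrl).mean(axis=0),
        mask=test.mask((1, times.size))[0],
        test=test,
    )
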