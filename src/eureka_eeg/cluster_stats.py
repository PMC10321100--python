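"""Paired statistics with cluster-based permutation correction.

The multiple-comparisons problem over (channel/pair/scale, time) maps is
handled nonparametrically: pointwise paired statistics are thresholded at
p < 0.05, suprathreshold samples are clustered by spatial and temporal
adjacency, cluster statistics are summed, and the observed sums are ranked
against a null distribution obtained by randomly exchanging the condition
labels within subject (sign-flipping the paired differences), 1,000 times
by default. The null summary is the maximum |cluster sum| per permutation
(max-statistic convention, family-wise error control) and Monte-Carlo
p-values use the (b + 1)/(n_perm + 1) smoothing, so p is never exactly 0.

Pointwise tests outside the cluster machinery choose between the paired
t-test and the Wilcoxon signed-rank test with a Shapiro-Wilk normality
gate on the paired differences; behavioral reaction times are compared
with the (unpaired) Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components


@dataclass
class Cluster:
    """A connected set of suprathreshold (space, time) samples."""

    members: list[tuple[int, int]]
    stat_sum: float
    p_value: float = np.nan

    @property
    def times(self) -> list[int]:
        return sorted({t for _, t in self.members})


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    threshold: float
    n_perm: int
    alpha: float
    seed: int
    stat: str
    null_max: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]

    def mask(self, shape) -> np.ndarray:
        """Boolean (space, time) mask of samples in significant clusters."""
        out = np.zeros(shape, dtype=bool)
        for c in self.significant:
            for s, t in c.members:
                out[s, t] = True
        return out


# ---------------------------------------------------------------------------
# pointwise statistics


def _signed_rank_weights(d: np.ndarray) -> np.ndarray:
    """Midranks of |d| (zeros excluded), for the signed-rank z statistic."""
    r = np.zeros_like(d)
    nz = d != 0
    if nz.any():
        r[nz] = stats.rankdata(np.abs(d[nz]))
    return r


def _stat_from_diffs(diffs: np.ndarray, kind: str) -> np.ndarray:
    """Paired statistic per column of a (n_subjects, n_points) matrix."""
    n = diffs.shape[0]
    if kind == "t":
        mean = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        return np.where(sd > 0, t, 0.0)
    # signed-rank z = sum(sign * rank) / sqrt(sum rank^2)
    ranks = np.apply_along_axis(_signed_rank_weights, 0, diffs)
    denom = np.sqrt((ranks**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.sign(diffs) * ranks).sum(axis=0) / denom
    return np.where(denom > 0, z, 0.0)


def pointwise_stat(
    aha: np.ndarray,
    ctrl: np.ndarray,
    paired: bool = True,
    gate_normality: bool = True,
):
    """Per-coordinate paired statistic with a normality gate.

    For each map coordinate the paired differences are tested with
    Shapiro-Wilk (alpha 0.05): a paired t statistic where normality is not
    rejected, a Wilcoxon signed-rank z otherwise. Returns ``(stat_map,
    p_map, test_map)`` where ``test_map`` logs the gate decision ("t" or
    "wilcoxon") per coordinate.
    """
    a = np.asarray(aha, dtype=float)
    b = np.asarray(ctrl, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition maps must share a shape")
    if not paired:
        raise NotImplementedError("only the paired design is implemented")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    shape = a.shape[1:]
    diffs = (a - b).reshape(n, -1)
    stat_map = np.zeros(diffs.shape[1])
    p_map = np.ones(diffs.shape[1])
    test_map = np.empty(diffs.shape[1], dtype=object)
    for j in range(diffs.shape[1]):
        d = diffs[:, j]
        use_t = True
        if gate_normality and np.ptp(d) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                use_t = stats.shapiro(d).pvalue >= 0.05
        if use_t:
            stat_map[j] = _stat_from_diffs(d[:, None], "t")[0]
            p_map[j] = 2 * stats.t.sf(abs(stat_map[j]), df=n - 1)
            test_map[j] = "t"
        else:
            stat_map[j] = _stat_from_diffs(d[:, None], "wilcoxon")[0]
            p_map[j] = 2 * stats.norm.sf(abs(stat_map[j]))
            test_map[j] = "wilcoxon"
    return stat_map.reshape(shape), p_map.reshape(shape), test_map.reshape(shape)


# ---------------------------------------------------------------------------
# cluster construction


def _as_map(x: np.ndarray) -> np.ndarray:
    """Coerce (n_time,) or (n_space, n_time) to 2-D (space, time)."""
    x = np.asarray(x)
    return x[None, :] if x.ndim == 1 else x


def _edges(mask: np.ndarray, spatial_edges: np.ndarray | None):
    """Flat-index edge list of the suprathreshold subgraph."""
    s, t = mask.shape
    rows, cols = [], []
    both = mask[:, :-1] & mask[:, 1:]
    si, ti = np.nonzero(both)
    rows.append(si * t + ti)
    cols.append(si * t + ti + 1)
    if spatial_edges is not None and spatial_edges.size:
        i, j = spatial_edges[:, 0], spatial_edges[:, 1]
        both = mask[i] & mask[j]  # (n_edges, t)
        ei, ti = np.nonzero(both)
        rows.append(i[ei] * t + ti)
        cols.append(j[ei] * t + ti)
    return np.concatenate(rows), np.concatenate(cols)


def _clusters_from_mask(
    stat: np.ndarray, mask: np.ndarray, spatial_edges
) -> list[tuple[list[tuple[int, int]], float]]:
    """Connected components of the mask under the space x time graph."""
    if not mask.any():
        return []
    s, t = mask.shape
    nodes = np.flatnonzero(mask.ravel())
    rows, cols = _edges(mask, spatial_edges)
    remap = -np.ones(s * t, dtype=int)
    remap[nodes] = np.arange(nodes.size)
    graph = sparse.coo_matrix(
        (np.ones(rows.size), (remap[rows], remap[cols])), shape=(nodes.size, nodes.size)
    )
    n_comp, labels = connected_components(graph, directed=False)
    flat_stat = stat.ravel()[nodes]
    out = []
    for c in range(n_comp):
        member_nodes = nodes[labels == c]
        members = [(int(f // t), int(f % t)) for f in member_nodes]
        out.append((members, float(flat_stat[labels == c].sum())))
    return out


def _max_cluster_sum(stat: np.ndarray, threshold: float, spatial_edges) -> float:
    best = 0.0
    for mask in (stat > threshold, stat < -threshold):
        for _, total in _clusters_from_mask(stat, mask, spatial_edges):
            best = max(best, abs(total))
    return best


def build_clusters(
    stat_map: np.ndarray,
    threshold: float,
    adjacency: np.ndarray | None = None,
) -> list[Cluster]:
    """Cluster suprathreshold samples by spatial and temporal adjacency.

    ``stat_map`` is (n_space, n_time) (or (n_time,) for a purely temporal
    map); ``threshold`` is the critical statistic value; ``adjacency`` a
    symmetric boolean (n_space, n_space) channel/pair/scale neighbourhood.
    Positive and negative clusters are kept separate. An empty
    suprathreshold set yields an empty list.
    """
    stat = _as_map(stat_map)
    edges = _spatial_edges(adjacency, stat.shape[0])
    clusters = []
    for mask in (stat > threshold, stat < -threshold):
        for members, total in _clusters_from_mask(stat, mask, edges):
            clusters.append(Cluster(members=members, stat_sum=total))
    clusters.sort(key=lambda c: -abs(c.stat_sum))
    return clusters


def _spatial_edges(adjacency, n_space: int) -> np.ndarray | None:
    if adjacency is None:
        return None
    adj = np.asarray(adjacency, dtype=bool)
    if adj.shape != (n_space, n_space):
        raise ValueError("adjacency shape does not match the spatial dimension")
    i, j = np.nonzero(np.triu(adj, 1))
    return np.column_stack([i, j])


# ---------------------------------------------------------------------------
# permutation test


def permutation_test(
    aha: np.ndarray,
    ctrl: np.ndarray,
    adjacency: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stat: str = "t",
    threshold_p: float = 0.05,
) -> ClusterTestResult:
    """Cluster-based permutation test on paired condition maps.

    ``aha`` and ``ctrl`` are (n_subjects, n_space, n_time) (or without the
    space axis). Condition labels are exchanged within subject — a random
    sign flip of each subject's difference map — and the maximal
    |cluster sum| per permutation forms the null distribution.
    """
    if stat not in ("t", "wilcoxon"):
        raise ValueError("stat must be 't' or 'wilcoxon'")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    a3 = np.asarray(aha, dtype=float)
    b3 = np.asarray(ctrl, dtype=float)
    if a3.shape != b3.shape:
        raise ValueError("condition maps must share a shape")
    if a3.ndim == 2:  # (subjects, time)
        a3, b3 = a3[:, None, :], b3[:, None, :]
    n, s, t = a3.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    edges = _spatial_edges(adjacency, s)
    diffs = (a3 - b3).reshape(n, -1)

    if stat == "t":
        threshold = float(stats.t.ppf(1 - threshold_p / 2, df=n - 1))
        weights = diffs
        sumsq = (diffs**2).sum(axis=0)

        def stat_for_signs(signs: np.ndarray) -> np.ndarray:
            mean = signs @ weights / n
            var = (sumsq - n * mean**2) / (n - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                tval = mean / np.sqrt(var / n)
            return np.where(var > 0, tval, 0.0)

    else:
        threshold = float(stats.norm.ppf(1 - threshold_p / 2))
        ranks = np.apply_along_axis(_signed_rank_weights, 0, diffs)
        denom = np.sqrt((ranks**2).sum(axis=0))
        denom[denom == 0] = np.inf
        signed = np.sign(diffs) * ranks

        def stat_for_signs(signs: np.ndarray) -> np.ndarray:
            return (signs @ signed) / denom

    observed = stat_for_signs(np.ones(n)).reshape(s, t)
    clusters = build_clusters(observed, threshold, adjacency)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stat_maps = stat_for_signs(signs)  # (n_perm, s*t)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        null_max[p] = _max_cluster_sum(stat_maps[p].reshape(s, t), threshold, edges)

    for c in clusters:
        b = int(np.sum(null_max >= abs(c.stat_sum)))
        c.p_value = (b + 1) / (n_perm + 1)
    return ClusterTestResult(
        clusters=clusters,
        threshold=threshold,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        stat=stat,
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# behavioral comparison


def rank_sum(rt_a, rt_b):
    """Two-sided Wilcoxon rank-sum comparison of two RT samples.

    Returns ``(z, p, (median_a, median_b))``. For small tie-free samples
    the p-value is the exact Mann-Whitney enumeration; otherwise the
    normal approximation. The z statistic is always the asymptotic
    rank-sum z.
    """
    a = np.asarray(rt_a, dtype=float)
    b = np.asarray(rt_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    z, p_asym = stats.ranksums(a, b)
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    if no_ties and max(a.size, b.size) <= 20:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(p_asym)
    return float(z), p, (float(np.median(a)), float(np.median(b)))
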