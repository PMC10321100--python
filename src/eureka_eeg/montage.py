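"""Electrode montage: positions, adjacency, hemisphere sets, regional clusters.

The laterality analysis uses the low-resolution 10-20 electrode sets
(8 right, 8 left, 4 midline); the dimensionality analysis uses ten regional
clusters (left/right x frontal, central, temporal, parietal, occipital) of
8-10 electrodes each. High-density cluster membership is study hardware
specific, so the bundled default montage anchors each cluster on its
standard 10-20 electrodes and fills it with systematically named channels
at schematic scalp positions. Montages are plain JSON and fully editable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

RIGHT_1020 = ("Fp2", "F4", "F8", "C4", "T4", "P4", "T6", "O2")
LEFT_1020 = ("Fp1", "F7", "F3", "T3", "C3", "T5", "P3", "O1")
MIDLINE_1020 = ("Fz", "CPz", "Pz", "Oz")

# schematic head coordinates: x toward the right ear, y toward the nasion
_POS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.95), "O2": (0.31, -0.95),
    "CPz": (0.0, -0.25),
}

# cluster -> (anchor electrodes, number of filler channels)
_CLUSTER_PLAN = {
    "LF": (("Fp1", "F3", "F7"), 6),
    "RF": (("Fp2", "F4", "F8"), 6),
    "LC": (("C3",), 7),
    "RC": (("C4",), 7),
    "LT": (("T3", "T5"), 6),
    "RT": (("T4", "T6"), 6),
    "LP": (("P3",), 7),
    "RP": (("P4",), 7),
    "LO": (("O1",), 7),
    "RO": (("O2",), 7),
}

CLUSTER_LABELS = tuple(_CLUSTER_PLAN)


@dataclass
class Montage:
    """Channel geometry plus the named sets the analyses rely on."""

    positions: dict[str, tuple[float, float]]
    adjacency: frozenset  # of frozenset({a, b}) channel-name pairs
    right: tuple[str, ...] = RIGHT_1020
    left: tuple[str, ...] = LEFT_1020
    midline: tuple[str, ...] = MIDLINE_1020
    clusters: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = set(self.positions)
        for group in (self.right, self.left, self.midline):
            unknown = set(group) - names
            if unknown:
                raise ValueError(f"set members missing from montage: {sorted(unknown)}")
        r, l, m = set(self.right), set(self.left), set(self.midline)
        if r & l or r & m or l & m:
            raise ValueError("right/left/midline electrode sets must be disjoint")
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValueError("adjacency must be irreflexive pairs")
            if not pair <= names:
                raise ValueError(f"adjacency references unknown channels: {sorted(pair)}")
        for label, members in self.clusters.items():
            if not 8 <= len(members) <= 10:
                raise ValueError(f"cluster {label} must have 8-10 electrodes")
            if len(set(members)) != len(members) or not set(members) <= names:
                raise ValueError(f"cluster {label} members invalid")

    @property
    def ch_names(self) -> list[str]:
        return list(self.positions)

    def li_channels(self) -> list[str]:
        """The 20 electrodes feeding the laterality index."""
        return list(self.right) + list(self.left) + list(self.midline)

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency

    def adjacency_matrix(self, names: list[str]) -> np.ndarray:
        n = len(names)
        out = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                if self.adjacent(names[i], names[j]):
                    out[i, j] = out[j, i] = True
        return out

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "positions": {k: list(v) for k, v in self.positions.items()},
            "adjacency": sorted(sorted(p) for p in self.adjacency),
            "right": list(self.right),
            "left": list(self.left),
            "midline": list(self.midline),
            "clusters": {k: list(v) for k, v in self.clusters.items()},
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            positions={k: tuple(v) for k, v in payload["positions"].items()},
            adjacency=frozenset(frozenset(p) for p in payload["adjacency"]),
            right=tuple(payload["right"]),
            left=tuple(payload["left"]),
            midline=tuple(payload["midline"]),
            clusters={k: tuple(v) for k, v in payload.get("clusters", {}).items()},
        )


def _knn_adjacency(positions: dict[str, tuple[float, float]], k: int = 4) -> frozenset:
    """Symmetrized k-nearest-neighbour adjacency over schematic positions."""
    names = list(positions)
    xy = np.array([positions[n] for n in names])
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    pairs = set()
    for i in range(len(names)):
        for j in np.argsort(d[i])[:k]:
            pairs.add(frozenset((names[i], names[int(j)])))
    return frozenset(pairs)


def montage_1020() -> Montage:
    """The 20-electrode 10-20 montage used for connectivity laterality."""
    return Montage(positions=dict(_POS_1020), adjacency=_knn_adjacency(_POS_1020))


def default_montage() -> Montage:
    """10-20 electrodes plus filler channels forming ten regional clusters.

    Filler channels are laid out on a small deterministic ring around each
    cluster's anchor centroid; they stand in for the dense-net electrodes
    whose exact membership is hardware specific.
    """
    positions = dict(_POS_1020)
    clusters: dict[str, tuple[str, ...]] = {}
    for label, (anchors, n_fill) in _CLUSTER_PLAN.items():
        centroid = np.mean([_POS_1020[a] for a in anchors], axis=0)
        members = list(anchors)
        for i in range(n_fill):
            angle = 2 * np.pi * i / n_fill
            name = f"{label}{i + 1}"
            positions[name] = (
                round(float(centroid[0] + 0.13 * np.cos(angle)), 4),
                round(float(centroid[1] + 0.13 * np.sin(angle)), 4),
            )
            members.append(name)
        clusters[label] = tuple(members)
    return Montage(
        positions=positions,
        adjacency=_knn_adjacency(positions),
        clusters=clusters,
    )
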