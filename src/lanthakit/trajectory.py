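"""Post-processing operators for molecular-dynamics style trajectories.

Operates on toy trajectories of labelled 3-D point groups: a metal ion,
water oxygens, and two protein domains.  Provides first-coordination-
shell water counting (default cutoff 3.4 Å, the maximum ion-water
distance of the first shell), centre-of-mass and minimum inter-domain
distances, RMSF, optimal-superposition RMSD (Kabsch), and greedy
neighbour-count (Daura-style) conformer clustering at a default 1.7 Å
RMSD cutoff.

Lengths are Å throughout.  Inputs are assumed whole and centred — no
periodic-boundary imaging is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Frame",
    "Trajectory",
    "ClusterResult",
    "coordination_count",
    "coordination_fractions",
    "com_distance",
    "min_distance",
    "rmsd_superposed",
    "kabsch_rotation",
    "daura_cluster",
    "rmsf",
]

WATER_SHELL_CUTOFF = 3.4  # Å, inclusive
CLUSTER_CUTOFF = 1.7  # Å


@dataclass(frozen=True)
class Frame:
    """One snapshot: named groups of 3-D coordinates (Å), optional masses (Da)."""

    groups: Mapping[str, np.ndarray]
    masses: Mapping[str, np.ndarray] = field(default_factory=dict)
    time: float = 0.0  # ps

    def __post_init__(self):
        clean = {}
        for name, coords in self.groups.items():
            arr = np.asarray(coords, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
                raise ValueError(f"group {name!r} must be finite (n, 3) coordinates")
            clean[name] = arr
        object.__setattr__(self, "groups", clean)
        for name, m in self.masses.items():
            if name not in clean:
                raise ValueError(f"masses given for unknown group {name!r}")
            if len(np.asarray(m)) != len(clean[name]):
                raise ValueError(f"mass length mismatch for group {name!r}")

    def group(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"group {name!r} not present in frame")
        return self.groups[name]


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames sharing one group schema."""

    frames: Sequence[Frame]

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("trajectory needs >= 1 frame")
        schema = {k: v.shape for k, v in self.frames[0].groups.items()}
        for i, f in enumerate(self.frames):
            if {k: v.shape for k, v in f.groups.items()} != schema:
                raise ValueError(f"frame {i} does not match the group schema")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ClusterResult:
    """Partition of conformers: assignments, centroid indices, cutoff used."""

    assignment: Mapping[int, int]
    centroids: Mapping[int, int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster_id: int) -> list[int]:
        return sorted(i for i, c in self.assignment.items() if c == cluster_id)


def coordination_count(
    frame: Frame, ion_group: str = "ion", water_group: str = "water",
    cutoff: float = WATER_SHELL_CUTOFF,
) -> int:
    """Number of water points within ``cutoff`` Å of the ion (inclusive)."""
    ion = frame.group(ion_group)
    if ion.shape[0] != 1:
        raise ValueError("ion group must contain exactly one point")
    waters = frame.group(water_group)
    if waters.size == 0:
        return 0
    dists = np.linalg.norm(waters - ion[0], axis=1)
    return int(np.sum(dists <= cutoff))


def coordination_fractions(
    traj: Trajectory, cutoff: float = WATER_SHELL_CUTOFF,
    ion_group: str = "ion", water_group: str = "water",
) -> dict[str, float]:
    """Frame fractions with exactly 0, 1, 2 and with >= 1 inner-sphere waters."""
    counts = np.array(
        [coordination_count(f, ion_group, water_group, cutoff) for f in traj.frames]
    )
    n = len(traj)
    return {
        "0": float(np.mean(counts == 0)),
        "1": float(np.mean(counts == 1)),
        "2": float(np.mean(counts == 2)),
        ">=1": float(np.mean(counts >= 1)),
        "mean": float(counts.mean()),
        "n_frames": float(n),
    }


def _com(frame: Frame, group: str) -> np.ndarray:
    coords = frame.group(group)
    if coords.size == 0:
        raise ValueError(f"group {group!r} is empty")
    masses = np.asarray(frame.masses.get(group, np.ones(len(coords))), dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def com_distance(frame: Frame, group_a: str, group_b: str) -> float:
    """Distance between mass-weighted centroids (unit masses if absent)."""
    return float(np.linalg.norm(_com(frame, group_a) - _com(frame, group_b)))


def min_distance(frame: Frame, group_a: str, group_b: str) -> float:
    """Minimum distance over all cross-group atom pairs."""
    a, b = frame.group(group_a), frame.group(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    return float(cdist(a, b).min())


def kabsch_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation minimising ||R a - b|| for centered coordinates."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def rmsd_superposed(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (translation + proper rotation)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share an (n, 3) shape")
    if a.shape[0] < 3:
        raise ValueError("need >= 3 points for a meaningful superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot = kabsch_rotation(a, b)
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def daura_cluster(
    items: Sequence[np.ndarray], cutoff: float = CLUSTER_CUTOFF
) -> ClusterResult:
    """Greedy neighbour-count clustering on pairwise superposed RMSD.

    Iteratively the item with the most neighbours within ``cutoff``
    becomes a centroid and takes its whole neighbourhood as a cluster;
    the cluster is removed and the count repeated on the remainder.
    Ties go to the lowest index.
    """
    n = len(items)
    if n < 1:
        raise ValueError("need >= 1 item")
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = rmsd_superposed(items[i], items[j])
    neighbors = rmsd <= cutoff  # includes self

    remaining = set(range(n))
    assignment: dict[int, int] = {}
    centroids: dict[int, int] = {}
    cluster_id = 0
    while remaining:
        rem = sorted(remaining)
        counts = [int(neighbors[i, rem].sum()) for i in rem]
        center = rem[int(np.argmax(counts))]  # argmax takes the first max: lowest index
        members = [j for j in rem if neighbors[center, j]]
        for j in members:
            assignment[j] = cluster_id
        centroids[cluster_id] = center
        remaining -= set(members)
        cluster_id += 1
    return ClusterResult(assignment=assignment, centroids=centroids, cutoff=cutoff)


def rmsf(traj: Trajectory, group: str, superpose: bool = True,
         max_iter: int = 10, tol: float = 1e-10) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure (Å).

    With ``superpose`` each frame is rigidly fitted onto the running
    average structure (iterated to self-consistency) before deviations
    are accumulated, removing global rotation/translation.
    """
    if len(traj) < 2:
        raise ValueError("need >= 2 frames for RMSF")
    coords = np.stack([f.group(group) for f in traj.frames])  # (T, n, 3)
    if superpose:
        fitted = coords - coords.mean(axis=1, keepdims=True)
        mean = fitted[0].copy()
        for _ in range(max_iter):
            new_fitted = np.empty_like(fitted)
            for t in range(fitted.shape[0]):
                frame = fitted[t] - fitted[t].mean(axis=0)
                rot = kabsch_rotation(frame, mean - mean.mean(axis=0))
                new_fitted[t] = frame @ rot.T
            new_mean = new_fitted.mean(axis=0)
            fitted = new_fitted
            if np.linalg.norm(new_mean - mean) < tol:
                mean = new_mean
                break
            mean = new_mean
        coords = fitted
    mean = coords.mean(axis=0)
    dev = coords - mean
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))
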