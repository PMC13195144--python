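"""Spatially-aware compression of organ voxel clouds.

Reduces one organ's voxel-wise SUV sample (possibly hundreds of thousands
of points) to a small weighted representative sample that preserves the
distribution's shape including its heavy tails, which uniform random
downsampling destroys.

Voxels are embedded in a joint feature space (position scaled by
``spatial_weight`` over the cloud's diagonal extent, SUV scaled by a
robust sigma); the cheapest candidate pair under a Ward-style cost
sqrt(w_a w_b / (w_a + w_b)) * ||f_a - f_b|| is merged into a
weight-averaged centroid until the target size is reached. Candidate
pairs come from a k-nearest-neighbour graph maintained lazily through a
priority queue. Merging by weighted centroid conserves total weight and
the weighted mean SUV exactly; isolated tail points are expensive to
merge and therefore survive with small weights.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import LabeledPointCloud

__all__ = ["CompressedDistribution", "compress", "compression_fidelity"]

DEFAULT_TARGET = 3500
_KNN = 8


@dataclass
class CompressedDistribution:
    """Weighted representative SUV sample of one organ.

    ``weights`` are merged voxel counts (they sum to the source voxel
    count exactly); ``positions`` are the weighted centroids of the merged
    voxels.
    """

    organ: str
    values: np.ndarray
    weights: np.ndarray
    positions: np.ndarray
    source_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if not (len(self.values) == len(self.weights) == len(self.positions)):
            raise ValueError("inconsistent array lengths")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.values)


def _robust_sigma(values: np.ndarray) -> float:
    sd = float(np.std(values))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    return sigma if sigma > 0 else 1.0


def _features(positions: np.ndarray, values: np.ndarray, spatial_weight: float) -> np.ndarray:
    span = positions.max(axis=0) - positions.min(axis=0)
    diag = float(np.linalg.norm(span))
    pos_scale = spatial_weight / diag if diag > 0 else 0.0
    return np.column_stack([positions * pos_scale, values / _robust_sigma(values)])


def compress(
    cloud: LabeledPointCloud,
    target: int = DEFAULT_TARGET,
    spatial_weight: float = 1.0,
    seed: int = 0,
) -> CompressedDistribution:
    """Compress a single-organ cloud to at most `target` weighted points.

    The algorithm is deterministic (ties broken by lowest point index);
    `seed` is accepted for interface uniformity and reproducibility
    bookkeeping. Organs already at or below `target` pass through with
    unit weights.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    organs = set(cloud.labels.tolist())
    if len(organs) != 1:
        raise ValueError(f"compress expects a single-organ cloud, got labels {sorted(organs)}")
    organ = next(iter(organs))
    n = len(cloud)
    if n <= target:
        return CompressedDistribution(
            organ, cloud.suv.copy(), np.ones(n), cloud.positions.copy(), n
        )

    n_total = 2 * n - target  # n initial nodes + one new node per merge
    value = np.empty(n_total)
    weight = np.zeros(n_total)
    pos = np.empty((n_total, 3))
    feat = np.empty((n_total, 4))
    value[:n] = cloud.suv
    weight[:n] = 1.0
    pos[:n] = cloud.positions
    feat[:n] = _features(cloud.positions, cloud.suv, spatial_weight)
    alive = np.zeros(n_total, dtype=bool)
    alive[:n] = True
    candidates: list[list[int]] = [[] for _ in range(n_total)]

    heap: list[tuple[float, int, int]] = []

    def push_edges(i: int, neighbors: np.ndarray | list[int]) -> None:
        nbrs = [j for j in neighbors if j != i and alive[j]]
        if not nbrs:
            return
        d = np.linalg.norm(feat[nbrs] - feat[i], axis=1)
        ward = np.sqrt(weight[nbrs] * weight[i] / (weight[nbrs] + weight[i]))
        for j, cost in zip(nbrs, d * ward):
            a, b = (i, j) if i < j else (j, i)
            heapq.heappush(heap, (float(cost), a, b))
            candidates[i].append(j)

    def seed_heap() -> None:
        live = np.flatnonzero(alive)
        k = min(_KNN + 1, len(live))
        tree = cKDTree(feat[live])
        _, nbr = tree.query(feat[live], k=k)
        nbr = np.atleast_2d(nbr)
        for row, i in enumerate(live):
            push_edges(int(i), live[nbr[row]])

    seed_heap()
    n_alive = n
    nxt = n
    while n_alive > target:
        if not heap:
            seed_heap()  # candidate graph exhausted; rebuild on survivors
            continue
        _, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]):
            continue
        wa, wb = weight[a], weight[b]
        w = wa + wb
        value[nxt] = (wa * value[a] + wb * value[b]) / w
        pos[nxt] = (wa * pos[a] + wb * pos[b]) / w
        feat[nxt] = (wa * feat[a] + wb * feat[b]) / w
        weight[nxt] = w
        alive[a] = alive[b] = False
        alive[nxt] = True
        merged_cands = candidates[a] + candidates[b]
        candidates[a] = candidates[b] = []
        push_edges(nxt, list(dict.fromkeys(merged_cands)))
        nxt += 1
        n_alive -= 1

    live = np.flatnonzero(alive)
    live = live[np.argsort(value[live], kind="stable")]
    return CompressedDistribution(organ, value[live], weight[live], pos[live], n)


def compression_fidelity(
    original: LabeledPointCloud, compressed: CompressedDistribution
) -> float:
    """Weighted energy distance between source and compressed SUV samples."""
    from .connectome.distances import energy_distance  # deferred: avoids import cycle

    organs = set(original.labels.tolist())
    if organs != {compressed.organ}:
        raise ValueError(f"organ mismatch: {sorted(organs)} vs {compressed.organ!r}")
    return energy_distance(original.suv, compressed.values, None, compressed.weights)
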