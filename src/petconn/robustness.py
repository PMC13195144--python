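"""Segmentation-boundary noise simulation and connectome stability.

Boundary voxels are those whose k spatial nearest neighbours contain a
foreign anatomical label; each boundary voxel independently swaps, with
probability B (the blur ratio), to a label drawn uniformly from its
foreign-labelled neighbours. Swap decisions and candidate sets use the
ORIGINAL labels (single pass, order independent); positions and SUVs are
untouched, so only label assignments change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from ._rng import child_rng
from .cloud import LabeledPointCloud
from .connectome.build import Connectome, build_connectome, reduce_to_roi
from .schema import ROISchema

__all__ = [
    "PerturbationConfig",
    "find_boundary_voxels",
    "perturb_labels",
    "rerun_pipeline",
    "subject_stability",
    "edge_stability",
    "noise_attribution",
]


@dataclass(frozen=True)
class PerturbationConfig:
    k_neighbors: int = 15
    blur_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 <= self.blur_ratio <= 1.0:
            raise ValueError("blur_ratio must be in [0, 1]")


def _knn_indices(positions: np.ndarray, k: int) -> np.ndarray:
    """(N, k) neighbour indices, self excluded, ties broken by voxel index.

    Lattice point clouds have many exactly tied neighbour distances; the
    query over-fetches and re-sorts by (rounded distance, index) so that
    neighbourhoods are deterministic and nested in k.
    """
    n = len(positions)
    if k >= n:
        raise ValueError(f"k={k} must be < number of voxels ({n})")
    m = min(n, k + 33)  # enough slack to cover full tied shells on a lattice
    tree = cKDTree(positions)
    dist, idx = tree.query(positions, k=m)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    self_mask = idx == np.arange(n)[:, None]
    dist = np.where(self_mask, np.inf, np.round(dist, 6))
    order = np.lexsort((idx, dist))
    rows = np.arange(n)[:, None]
    return idx[rows, order[:, :k]]


def find_boundary_voxels(cloud: LabeledPointCloud, k: int = 15) -> np.ndarray:
    """Mask of voxels whose k-NN contains at least one foreign label."""
    if len(cloud) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} voxels")
    nbr = _knn_indices(cloud.positions, k)
    return (cloud.labels[nbr] != cloud.labels[:, None]).any(axis=1)


def perturb_labels(cloud: LabeledPointCloud, config: PerturbationConfig) -> LabeledPointCloud:
    """Stochastic boundary label swapping; non-boundary voxels unchanged."""
    nbr = _knn_indices(cloud.positions, config.k_neighbors)
    foreign = cloud.labels[nbr] != cloud.labels[:, None]
    boundary = np.flatnonzero(foreign.any(axis=1))
    new_labels = cloud.labels.copy()
    rng = child_rng(config.seed, "perturb")
    if config.blur_ratio > 0 and len(boundary):
        swap = rng.random(len(boundary)) < config.blur_ratio
        for v, do_swap in zip(boundary, swap):
            if not do_swap:
                continue
            cands = nbr[v][foreign[v]]
            new_labels[v] = cloud.labels[cands[rng.integers(len(cands))]]
    return LabeledPointCloud(
        cloud.positions.copy(), cloud.suv.copy(), new_labels, cloud.subject_id
    )


def rerun_pipeline(
    clouds: Sequence[LabeledPointCloud],
    perturbation: PerturbationConfig,
    schema: ROISchema,
    alpha: float = 1.0,
    target: int = 3500,
    seed: int = 0,
    level: str = "roi",
) -> tuple[list[Connectome | None], list[tuple[int, str]]]:
    """Perturb every subject's labels and re-run the connectome pipeline.

    Connectome seeds depend only on (seed, subject index), so B=0
    reproduces the baseline bit-identically. Per-subject failures are
    collected, not raised; the corresponding slot holds None.
    """
    perturbed = []
    failures: list[tuple[int, str]] = []
    for i, cloud in enumerate(clouds):
        sub_cfg = PerturbationConfig(
            perturbation.k_neighbors,
            perturbation.blur_ratio,
            int(child_rng(perturbation.seed, "subject", i).integers(0, 2**31 - 1)),
        )
        perturbed.append(perturb_labels(cloud, sub_cfg))
    out: list[Connectome | None] = []
    for i, cloud in enumerate(perturbed):
        try:
            conn = build_connectome(
                cloud,
                schema,
                alpha=alpha,
                target=target,
                seed=int(child_rng(seed, "connectome", i).integers(0, 2**31 - 1)),
            )
            if level == "roi":
                conn = reduce_to_roi(conn, schema)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation is the contract
            failures.append((i, f"{type(exc).__name__}: {exc}"))
            conn = None
        out.append(conn)
    return out, failures


def subject_stability(baseline: Connectome, perturbed: Connectome) -> float:
    """Spearman rank correlation of the two upper-triangle edge vectors."""
    if baseline.roi_names != perturbed.roi_names:
        raise ValueError("ROI set mismatch")
    a = baseline.upper_triangle()
    b = perturbed.upper_triangle()
    if len(a) < 3:
        raise ValueError("need at least 3 edges")
    rho = spearmanr(a, b).statistic
    return float(rho)


def edge_stability(
    baseline: Sequence[Connectome], replicates: Sequence[Sequence[Connectome]]
) -> np.ndarray:
    """Per-edge mean Spearman correlation across subjects, over replicates."""
    if len(baseline) < 3:
        raise ValueError("need at least 3 subjects")
    names = baseline[0].roi_names
    n = len(names)
    base = np.stack([c.C for c in baseline])
    mats = []
    for rep in replicates:
        if len(rep) != len(baseline):
            raise ValueError("replicate cohort not aligned to baseline subjects")
        pert = np.stack([c.C for c in rep])
        rho = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                rho[i, j] = rho[j, i] = spearmanr(base[:, i, j], pert[:, i, j]).statistic
        mats.append(rho)
    return np.mean(mats, axis=0)


def noise_attribution(
    baseline_contrast: np.ndarray,
    perturbed_contrast: np.ndarray,
    roi_groups: dict[str, Sequence[str]],
    roi_names: Sequence[str],
) -> dict[str, float]:
    """Fraction of total contrast variation attributable to each ROI group.

    Each edge's |difference| is attributed half to each endpoint's group
    (full weight if both endpoints fall in the same group); fractions over
    a disjoint exhaustive partition sum to 1.
    """
    baseline_contrast = np.asarray(baseline_contrast, dtype=float)
    perturbed_contrast = np.asarray(perturbed_contrast, dtype=float)
    if baseline_contrast.shape != perturbed_contrast.shape:
        raise ValueError("contrast matrices must share a shape")
    roi_of_group = {}
    for gname, members in roi_groups.items():
        for roi in members:
            roi_of_group[roi] = gname
    diff = np.abs(perturbed_contrast - baseline_contrast)
    iu, ju = np.triu_indices(len(roi_names), k=1)
    total = float(diff[iu, ju].sum())
    fractions = {g: 0.0 for g in roi_groups}
    if total == 0:
        return fractions
    for i, j in zip(iu, ju):
        w = float(diff[i, j])
        for endpoint in (roi_names[i], roi_names[j]):
            g = roi_of_group.get(endpoint)
            if g is not None:
                fractions[g] += 0.5 * w / total
    return fractions
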