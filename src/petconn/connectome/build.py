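"""Connectome assembly: compress → distances → MI correction → similarity.

Organ-level connectomes are built from a subject's labeled point cloud;
``reduce_to_roi`` collapses them to the canonical 13-ROI meta-organ graph
by averaging cross-ROI organ-pair similarities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .._rng import child_rng
from ..cloud import LabeledPointCloud
from ..compression import DEFAULT_TARGET, compress
from ..schema import ROISchema
from .distances import OrganDistribution, corrected_distance, energy_distance, mutual_information, similarity

__all__ = [
    "Connectome",
    "build_connectome",
    "build_cohort_connectomes",
    "reduce_to_roi",
    "with_alpha",
    "node_variability",
    "mi_effect_map",
    "save_connectome",
    "load_connectome",
]


@dataclass
class Connectome:
    """Symmetric organ/ROI similarity graph with its provenance matrices.

    At organ level the adjacency satisfies C = exp(-D (1 - alpha MI))
    off-diagonal with unit diagonal; ROI-level matrices are means of
    organ-level entries, so D and MI are retained for bookkeeping only.
    """

    roi_names: tuple[str, ...]
    D: np.ndarray
    MI: np.ndarray
    alpha: float
    C: np.ndarray
    level: str = "organ"
    subject_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.roi_names)
        for name in ("D", "MI", "C"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} has non-finite entries")
            setattr(self, name, m)
        if not np.allclose(np.diag(self.C), 1.0):
            raise ValueError("C diagonal must be 1")
        if self.level == "organ":
            mi_eff = np.minimum(self.MI, 1.0 - 1e-6) if self.alpha == 1.0 else self.MI
            expect = np.exp(-self.D * (1.0 - self.alpha * mi_eff))
            off = ~np.eye(len(self.roi_names), dtype=bool)
            if not np.allclose(self.C[off], expect[off], atol=1e-12, rtol=1e-9):
                raise ValueError("C inconsistent with exp(-D(1 - alpha MI))")

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle of C as a flat edge vector."""
        i, j = np.triu_indices(len(self.roi_names), k=1)
        return self.C[i, j]

    def edge_index(self) -> list[tuple[str, str]]:
        i, j = np.triu_indices(len(self.roi_names), k=1)
        return [(self.roi_names[a], self.roi_names[b]) for a, b in zip(i, j)]


def _organ_distributions(
    subject: LabeledPointCloud,
    organs: Sequence[str],
    target: int,
    spatial_weight: float,
    seed: int,
) -> dict[str, OrganDistribution]:
    dists = {}
    for organ in organs:
        sub = subject.select(organ)
        comp = compress(
            sub,
            target=target,
            spatial_weight=spatial_weight,
            seed=int(child_rng(seed, "compress", organ).integers(0, 2**31 - 1)),
        )
        dists[organ] = OrganDistribution.from_points(
            organ, comp.values, comp.positions[:, 2], comp.weights
        )
    return dists


def build_connectome(
    subject: LabeledPointCloud,
    schema: ROISchema,
    alpha: float = 1.0,
    target: int = DEFAULT_TARGET,
    seed: int = 0,
    spatial_weight: float = 1.0,
    allow_alpha_one: bool = True,
    mi_quantiles: int = 1024,
) -> Connectome:
    """Organ-level connectome for one subject.

    Every labeled organ is compressed, pairwise energy distances and
    mutual information are computed on the compressed samples, distances
    are corrected by ``alpha`` and mapped through exponential similarity.
    """
    schema.validate_labels(subject.labels)
    if not (0.0 <= alpha < 1.0 or (alpha == 1.0 and allow_alpha_one)):
        raise ValueError(f"alpha must be in [0, 1) (or 1 with allow_alpha_one), got {alpha}")
    organs = subject.organs()
    if len(organs) < 2:
        raise ValueError("need at least 2 labeled organs")

    dists = _organ_distributions(subject, organs, target, spatial_weight, seed)
    n = len(organs)
    D = np.zeros((n, n))
    MI = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            p, q = dists[organs[i]], dists[organs[j]]
            D[i, j] = D[j, i] = energy_distance(p.values, q.values, p.weights, q.weights)
            MI[i, j] = MI[j, i] = mutual_information(p, q, n_quantiles=mi_quantiles)
    C = _adjacency(D, MI, alpha)
    return Connectome(tuple(organs), D, MI, alpha, C, level="organ", subject_id=subject.subject_id)


def _adjacency(D: np.ndarray, MI: np.ndarray, alpha: float) -> np.ndarray:
    n = len(D)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d_star = corrected_distance(D[i, j], MI[i, j], alpha, allow_alpha_one=True)
            C[i, j] = C[j, i] = similarity(d_star)
    return C


def with_alpha(conn: Connectome, alpha: float, allow_alpha_one: bool = True) -> Connectome:
    """Recompute the adjacency of an organ-level connectome at another alpha."""
    if conn.level != "organ":
        raise ValueError("with_alpha requires an organ-level connectome")
    if not (0.0 <= alpha < 1.0 or (alpha == 1.0 and allow_alpha_one)):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    return Connectome(
        conn.roi_names,
        conn.D.copy(),
        conn.MI.copy(),
        alpha,
        _adjacency(conn.D, conn.MI, alpha),
        level="organ",
        subject_id=conn.subject_id,
    )


def reduce_to_roi(organ_level: Connectome, schema: ROISchema) -> Connectome:
    """Collapse an organ-level connectome to ROI level.

    Each ROI-pair edge is the mean similarity over all cross-ROI organ
    pairs; within-ROI organ pairs contribute only to the (unit) diagonal.
    ROIs with no organs present are dropped with a warning.
    """
    organ_names = organ_level.roi_names
    groups: dict[str, list[int]] = {}
    for idx, organ in enumerate(organ_names):
        groups.setdefault(schema.roi_of(organ), []).append(idx)
    missing = [r for r in schema.roi_names if r not in groups]
    if missing:
        warnings.warn(f"ROIs with no organs present, dropped: {missing}", stacklevel=2)
    rois = tuple(r for r in schema.roi_names if r in groups)

    n = len(rois)
    C = np.eye(n)
    D = np.zeros((n, n))
    MI = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            ia = np.asarray(groups[rois[a]])
            ib = np.asarray(groups[rois[b]])
            C[a, b] = C[b, a] = float(organ_level.C[np.ix_(ia, ib)].mean())
            D[a, b] = D[b, a] = float(organ_level.D[np.ix_(ia, ib)].mean())
            MI[a, b] = MI[b, a] = float(organ_level.MI[np.ix_(ia, ib)].mean())
    return Connectome(
        rois, D, MI, organ_level.alpha, C, level="roi", subject_id=organ_level.subject_id
    )


def build_cohort_connectomes(
    clouds: Sequence[LabeledPointCloud],
    schema: ROISchema,
    alpha: float = 1.0,
    target: int = DEFAULT_TARGET,
    seed: int = 0,
    level: str = "roi",
    **kwargs,
) -> list[Connectome]:
    """Connectomes for a cohort with per-subject child seeds.

    Subject i's connectome seed depends only on (seed, i), so re-running a
    subset (e.g. after label perturbation) reproduces baseline seeds.
    """
    out = []
    for i, cloud in enumerate(clouds):
        conn = build_connectome(
            cloud,
            schema,
            alpha=alpha,
            target=target,
            seed=int(child_rng(seed, "connectome", i).integers(0, 2**31 - 1)),
            **kwargs,
        )
        out.append(reduce_to_roi(conn, schema) if level == "roi" else conn)
    return out


def node_variability(cohort: Sequence[Connectome]) -> pd.Series:
    """Per-node sum of across-subject standard deviations of incident edges."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 connectomes")
    names = cohort[0].roi_names
    for c in cohort[1:]:
        if c.roi_names != names:
            raise ValueError("mismatched ROI sets across connectomes")
    stack = np.stack([c.C for c in cohort])
    sd = np.std(stack, axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    return pd.Series(sd.sum(axis=1), index=list(names), name="total_deviation")


def mi_effect_map(
    group_a: Sequence[Connectome],
    group_b: Sequence[Connectome],
    schema: ROISchema,
    scale: float = 1.0,
) -> np.ndarray:
    """Squared group difference of the MI-induced connectome variation.

    For each group the variation is mean ROI connectome at alpha=0 minus
    mean at alpha=1 (organ-level inputs are re-weighted at both alphas);
    the output is the elementwise squared difference of the two
    variations, optionally scaled for reporting.
    """

    def variation(conns: Sequence[Connectome]) -> np.ndarray:
        mats0, mats1 = [], []
        for conn in conns:
            if conn.level != "organ":
                raise ValueError("mi_effect_map expects organ-level connectomes")
            mats0.append(reduce_to_roi(with_alpha(conn, 0.0), schema).C)
            mats1.append(reduce_to_roi(with_alpha(conn, 1.0), schema).C)
        return np.mean(mats0, axis=0) - np.mean(mats1, axis=0)

    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    delta = variation(group_a) - variation(group_b)
    return scale * delta**2


def save_connectome(conn: Connectome, out_dir: str | Path, stem: str | None = None) -> Path:
    """Write C/D/MI as CSVs plus a JSON metadata sidecar; returns the sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or (conn.subject_id or "connectome")
    names = list(conn.roi_names)
    for mat, tag in ((conn.C, "C"), (conn.D, "D"), (conn.MI, "MI")):
        pd.DataFrame(mat, index=names, columns=names).to_csv(out_dir / f"{stem}.{tag}.csv")
    from .. import __version__

    meta = {
        "subject_id": conn.subject_id,
        "alpha": conn.alpha,
        "level": conn.level,
        "roi_names": names,
        "software_version": __version__,
    }
    meta_path = out_dir / f"{stem}.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta_path


def load_connectome(meta_path: str | Path) -> Connectome:
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    stem = meta_path.name[: -len(".json")]
    mats = {
        tag: pd.read_csv(meta_path.parent / f"{stem}.{tag}.csv", index_col=0).to_numpy()
        for tag in ("C", "D", "MI")
    }
    return Connectome(
        tuple(meta["roi_names"]),
        mats["D"],
        mats["MI"],
        float(meta["alpha"]),
        mats["C"],
        level=meta["level"],
        subject_id=meta["subject_id"],
    )
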